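"""Model-based synthetic affect ratings, standardization and exclusions.

:func:`simulate_ratings` plays a schedule through one of the generative
models (see :mod:`affectdyn.models`) and emits a rating at every fourth
trial: the latent trajectory value at that trial plus Gaussian observation
noise.  Latent trajectories run on the catalog-standardized stimulus norms
and are never conditioned on the emitted ratings.

Observed (or simulated) ratings live on a 0-100 slider whose resting
position is 50; model-scale values are mapped onto the slider by a fixed
affine transform for bookkeeping only — all modelling happens on the
standardized scale.  :func:`standardize_ratings` computes per-participant
z-scores (sample sd) pooled over all of a participant's ratings in a
dimension; :func:`apply_exclusions` implements the slider-non-use rules:
participants who left the slider unmoved on more than 80% of ratings on
either scale are dropped entirely, and participants whose control-block
arousal ratings are all unmoved are flagged out of control-arousal fits only.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping

import numpy as np
import pandas as pd

from .models import EDParams, WIParams, trajectory

__all__ = [
    "SLIDER_DEFAULT",
    "SLIDER_RANGE",
    "participant_blocks",
    "simulate_ratings",
    "standardize_ratings",
    "apply_exclusions",
    "ExclusionReport",
]

SLIDER_RANGE = (0.0, 100.0)
SLIDER_DEFAULT = 50.0
# model scale -> slider display scale (z of roughly +/-2.5 spans the slider)
_SLIDER_GAIN = 20.0

DIMENSIONS = ("valence", "arousal")


def _slider(values: np.ndarray) -> np.ndarray:
    return np.clip(SLIDER_DEFAULT + _SLIDER_GAIN * values, *SLIDER_RANGE)


def participant_blocks(
    schedule: pd.DataFrame,
    catalog: pd.DataFrame,
    participant_id: str,
    dimension: str,
    design: str = "task",
):
    """Extract per-block model inputs for one participant.

    Returns a list of ``(block_index, stimuli, relevance, rating_positions)``
    tuples, where ``stimuli`` are the catalog-standardized norms of the
    chosen dimension in presentation order, ``relevance`` is a boolean vector
    (``None`` for control blocks) and ``rating_positions`` are 0-based trial
    indices at which a rating was collected.
    """
    if dimension not in DIMENSIONS:
        raise ValueError(f"dimension must be one of {DIMENSIONS}")
    if design not in ("task", "control", "all"):
        raise ValueError("design must be 'task', 'control' or 'all'")
    norms = catalog.set_index("stimulus_id")[f"{dimension}_std"]
    sub = schedule[schedule["participant_id"] == participant_id]
    if sub.empty:
        raise ValueError(f"participant {participant_id!r} not in schedule")
    if design != "all":
        sub = sub[sub["block_type"] == design]
    out = []
    for block, bdf in sub.groupby("block_index"):
        bdf = bdf.sort_values("trial_index")
        stim = norms.loc[bdf["stimulus_id"]].to_numpy(dtype=float)
        if (bdf["block_type"] == "task").all():
            rel = (bdf["relevance"] == "relevant").to_numpy()
        else:
            rel = None
        pos = np.flatnonzero(bdf["is_rating_trial"].to_numpy())
        out.append((block, stim, rel, pos))
    return out


def simulate_ratings(
    schedule: pd.DataFrame,
    catalog: pd.DataFrame,
    model_name: str,
    params_by_participant: Mapping[str, Mapping[str, EDParams | WIParams]],
    noise_sd: float | Mapping[str, float] = 0.5,
    seed: int = 0,
    design: str = "all",
) -> pd.DataFrame:
    """Simulate slider ratings for every rating trial of a schedule.

    Parameters
    ----------
    params_by_participant
        ``{participant_id: {"valence": params, "arousal": params}}``.  Split
        (relevance-specific) parameters apply only to task blocks, so when
        they are supplied restrict ``design`` to 'task'; unsplit parameters
        can generate any design.
    noise_sd
        Gaussian observation noise on the model scale; a scalar or a
        ``{participant_id: sd}`` mapping.  Must be positive.
    design
        'all', 'task' or 'control': which blocks to generate ratings for.

    Returns a long-format ratings table with one row per rating trial and
    columns ``participant_id, block_index, block_type, rating_index,
    trial_index, valence, arousal, valence_raw, arousal_raw`` where the
    unsuffixed columns are model-scale values and ``*_raw`` their slider
    rendering.
    """

    def _sd(pid: str) -> float:
        sd = noise_sd[pid] if isinstance(noise_sd, Mapping) else float(noise_sd)
        if sd <= 0:
            raise ValueError("noise_sd must be positive")
        return sd

    rng = np.random.default_rng(seed)
    rows = []
    pids = schedule["participant_id"].unique()
    for pid in pids:
        if pid not in params_by_participant:
            raise ValueError(f"no parameters for participant {pid!r}")
        values = {}
        meta = None
        for dim in DIMENSIONS:
            params = params_by_participant[pid][dim]
            sim = []
            meta = []
            for block, stim, rel, pos in participant_blocks(
                schedule, catalog, pid, dim, design=design
            ):
                use_rel = rel if getattr(params, "split", False) else None
                if getattr(params, "split", False) and rel is None:
                    raise ValueError(
                        "split parameters cannot generate control-block ratings; "
                        "simulate the control design with unsplit parameters"
                    )
                traj = trajectory(model_name, params, stim, use_rel)
                noisy = traj[pos] + rng.normal(0.0, _sd(pid), size=pos.size)
                sim.append(noisy)
                block_type = "control" if rel is None else "task"
                meta.extend(
                    (block, block_type, k + 1, int(p) + 1)
                    for k, p in enumerate(pos)
                )
            values[dim] = np.concatenate(sim)
        for (block, btype, ridx, tidx), v, a in zip(
            meta, values["valence"], values["arousal"]
        ):
            rows.append((pid, block, btype, ridx, tidx, v, a))
    ratings = pd.DataFrame(
        rows,
        columns=[
            "participant_id",
            "block_index",
            "block_type",
            "rating_index",
            "trial_index",
            "valence",
            "arousal",
        ],
    )
    ratings["valence_raw"] = _slider(ratings["valence"].to_numpy())
    ratings["arousal_raw"] = _slider(ratings["arousal"].to_numpy())
    return ratings


def standardize_ratings(ratings: pd.DataFrame, source: str = "raw") -> pd.DataFrame:
    """Attach per-participant z-score columns ``valence_std``/``arousal_std``.

    Z-scores (sample sd, ddof=1) are computed over all of a participant's
    ratings in a dimension, pooling blocks.  A participant-dimension with
    zero variance is left as NaN and flagged for exclusion rather than
    divided by zero; callers should route such flags through
    :func:`apply_exclusions` style handling.

    ``source`` selects the input columns: 'raw' uses the slider columns
    (``*_raw``), 'model' the model-scale columns.
    """
    if source not in ("raw", "model"):
        raise ValueError("source must be 'raw' or 'model'")
    out = ratings.copy()
    for dim in DIMENSIONS:
        col = f"{dim}_raw" if source == "raw" else dim
        if col not in out.columns:
            raise ValueError(f"ratings table missing column {col!r}")
        grouped = out.groupby("participant_id")[col]
        mean = grouped.transform("mean")
        sd = grouped.transform(lambda x: x.std(ddof=1))
        z = (out[col] - mean) / sd
        z[sd == 0] = np.nan
        out[f"{dim}_std"] = z
    return out


@dataclass
class ExclusionReport:
    """Outcome of the slider-non-use exclusion rules."""

    excluded_participants: list[str] = field(default_factory=list)
    unmoved_fraction: dict[str, dict[str, float]] = field(default_factory=dict)
    control_arousal_excluded: list[str] = field(default_factory=list)


def apply_exclusions(
    ratings: pd.DataFrame,
    no_move_threshold: float = 0.8,
) -> tuple[pd.DataFrame, ExclusionReport]:
    """Apply the slider-non-use exclusion rules to a raw ratings table.

    A response counts as "unmoved" when the slider sits exactly at its
    resting position (50).  Participants with a strictly greater than
    ``no_move_threshold`` fraction of unmoved responses on either scale are
    removed from the returned table entirely.  Participants whose
    control-block arousal responses are all unmoved are retained but listed
    in ``control_arousal_excluded``: drop them from control-arousal model
    fits only.
    """
    report = ExclusionReport()
    keep = []
    for pid, df in ratings.groupby("participant_id", sort=False):
        fracs = {}
        drop = False
        for dim in DIMENSIONS:
            unmoved = (df[f"{dim}_raw"] == SLIDER_DEFAULT).mean()
            fracs[dim] = float(unmoved)
            if unmoved > no_move_threshold:
                drop = True
        report.unmoved_fraction[pid] = fracs
        if drop:
            report.excluded_participants.append(pid)
            continue
        keep.append(pid)
        control = df[df["block_type"] == "control"]
        if len(control) and (control["arousal_raw"] == SLIDER_DEFAULT).all():
            report.control_arousal_excluded.append(pid)
    filtered = ratings[ratings["participant_id"].isin(keep)].reset_index(drop=True)
    return filtered, report
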