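"""Tabular I/O, run configuration and the end-to-end pipeline.

All tabular artifacts are UTF-8 CSV with a header row; nested results are
JSON; run configuration is YAML.  Every stochastic stage takes an explicit
seed derived from the config, and :func:`run_pipeline` writes a manifest
recording package version, seeds and a SHA-256 content hash per artifact,
so two runs of the same config produce byte-identical manifests.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .bms import rfx_bms
from .catalog import generate_catalog
from .fitting import fit_all
from .recovery import sample_params
from .schedule import build_schedule
from .simulate import apply_exclusions, simulate_ratings, standardize_ratings

__all__ = [
    "SchemaError",
    "RunConfig",
    "read_ratings",
    "write_ratings",
    "read_config",
    "run_pipeline",
]

RATINGS_COLUMNS = [
    "participant_id",
    "block_index",
    "block_type",
    "rating_index",
    "trial_index",
    "valence",
    "arousal",
    "valence_raw",
    "arousal_raw",
]
_KEY = ["participant_id", "block_index", "rating_index"]


class SchemaError(ValueError):
    """A tabular file does not match the expected schema."""


def write_ratings(ratings: pd.DataFrame, path: str | Path) -> None:
    """Write a ratings table as long-format CSV (shortest round-trip floats)."""
    missing = [c for c in RATINGS_COLUMNS if c not in ratings.columns]
    if missing:
        raise SchemaError(f"ratings table missing columns: {missing}")
    ratings.to_csv(path, index=False)


def read_ratings(path: str | Path) -> pd.DataFrame:
    """Read a long-format ratings CSV, validating schema and key uniqueness."""
    df = pd.read_csv(path, float_precision="round_trip")
    missing = [c for c in RATINGS_COLUMNS if c not in df.columns]
    if missing:
        raise SchemaError(f"{path}: missing required column(s) {missing}")
    if df.duplicated(subset=_KEY).any():
        raise SchemaError(f"{path}: duplicate (participant, block, rating_index) keys")
    return df


@dataclass
class RunConfig:
    """Fully-seeded configuration of a pipeline run.

    Every stochastic stage has its own seed; a config loaded from YAML with
    any seed missing is rejected (reproducibility is not optional).
    """

    seed: int
    n_participants: int = 20
    model: str = "WI"
    design: str = "task"
    noise_sd: float = 0.5
    control_position: str = "alternating"
    n_restarts: int = 5
    alpha0: float = 1.0
    xp_samples: int = 1_000_000
    out_dir: str = "affectdyn_run"
    stage_seeds: dict = field(default_factory=dict)

    STAGES = ("catalog", "schedule", "params", "ratings", "fit", "bms")

    def __post_init__(self) -> None:
        if self.design not in ("task", "control"):
            raise ValueError("design must be 'task' or 'control'")
        if self.model.upper() not in ("ED", "WI"):
            raise ValueError("model must be 'ED' or 'WI'")
        if not self.stage_seeds:
            children = np.random.SeedSequence(self.seed).spawn(len(self.STAGES))
            self.stage_seeds = {
                name: int(c.generate_state(1)[0] % (2**31))
                for name, c in zip(self.STAGES, children)
            }
        missing = [s for s in self.STAGES if s not in self.stage_seeds]
        if missing:
            raise ValueError(f"config missing stage seeds: {missing}")


def read_config(path: str | Path) -> RunConfig:
    """Load a :class:`RunConfig` from YAML; absent seeds are rejected."""
    with open(path) as fh:
        raw = yaml.safe_load(fh) or {}
    if "seed" not in raw:
        raise ValueError(f"{path}: config must set an explicit seed")
    known = {f.name for f in dataclasses.fields(RunConfig)}
    unknown = set(raw) - known
    if unknown:
        raise ValueError(f"{path}: unknown config keys {sorted(unknown)}")
    return RunConfig(**raw)


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    h.update(path.read_bytes())
    return h.hexdigest()


def run_pipeline(config: RunConfig) -> dict:
    """Simulate, standardize, exclude, fit both models, and select.

    Writes catalog, schedule, ratings, per-fit JSON, group-level model
    selection JSON and a hash manifest into ``config.out_dir``; returns the
    manifest dictionary.
    """
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    seeds = config.stage_seeds

    catalog = generate_catalog(seed=seeds["catalog"])
    schedule = build_schedule(
        config.n_participants,
        catalog,
        control_position=config.control_position,
        seed=seeds["schedule"],
    )
    pids = list(schedule["participant_id"].unique())
    rng = np.random.default_rng(seeds["params"])
    split = config.design == "task"
    params = {
        pid: {
            "valence": sample_params(config.model, split, rng),
            "arousal": sample_params(config.model, split, rng),
        }
        for pid in pids
    }
    ratings = simulate_ratings(
        schedule,
        catalog,
        config.model,
        params,
        noise_sd=config.noise_sd,
        seed=seeds["ratings"],
        design=config.design,
    )
    ratings = standardize_ratings(ratings, source="raw")
    ratings, exclusions = apply_exclusions(ratings)

    fits = fit_all(
        ("ED", "WI"),
        schedule,
        catalog,
        ratings,
        design=config.design,
        seed=seeds["fit"],
        n_restarts=config.n_restarts,
        exclude={"arousal": set(exclusions.control_arousal_excluded)}
        if config.design == "control"
        else None,
    )
    selection = {}
    kept = list(ratings["participant_id"].unique())
    for dim in ("valence", "arousal"):
        sub = [f for f in fits if f.dimension == dim]
        by_pid = {}
        for f in sub:
            by_pid.setdefault(f.participant_id, {})[f.model_name] = f
        complete = [p for p in kept if len(by_pid.get(p, {})) == 2]
        lme = np.array(
            [[-by_pid[p][m].aic / 2.0 for m in ("ED", "WI")] for p in complete]
        )
        res = rfx_bms(
            lme,
            alpha0=config.alpha0,
            n_samples=config.xp_samples,
            seed=seeds["bms"],
        )
        selection[dim] = {"models": ["ED", "WI"], **res.to_dict()}

    catalog.to_csv(out / "catalog.csv", index=False)
    schedule.to_csv(out / "schedule.csv", index=False)
    write_ratings(ratings, out / "ratings.csv")
    with open(out / "fits.json", "w") as fh:
        json.dump([f.to_dict() for f in fits], fh, indent=1, sort_keys=True)
    with open(out / "model_selection.json", "w") as fh:
        json.dump(selection, fh, indent=1, sort_keys=True)
    with open(out / "exclusions.json", "w") as fh:
        json.dump(dataclasses.asdict(exclusions), fh, indent=1, sort_keys=True)

    artifacts = [
        "catalog.csv",
        "schedule.csv",
        "ratings.csv",
        "fits.json",
        "model_selection.json",
        "exclusions.json",
    ]
    manifest = {
        "version": __version__,
        "config": {k: v for k, v in dataclasses.asdict(config).items() if k != "out_dir"},
        "hashes": {name: _sha256(out / name) for name in artifacts},
    }
    with open(out / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=1, sort_keys=True)
    return manifest
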