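"""Posterior-predictive validation of the weighted-impact model.

If the WI model with the fitted parameters is an adequate account of the
group's ratings, then datasets simulated from those parameters, pushed
through the same lagged relevance-interaction regression, should yield
coefficient distributions that cover the coefficients estimated from the
observed ratings.  :func:`validate_wi_model` simulates ``n_sims`` full
datasets on the original schedules (schedules are reused, not regenerated,
so the stimulus and relevance streams match the reference analysis),
re-runs the regression on each, and reports per-coefficient simulated
quantiles plus a coverage indicator: whether the observed estimate lies
inside the central 95% of the simulated distribution.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .lagged import RegressionResult, build_lag_design, fit_hierarchical_lm
from .models import WIParams
from .simulate import simulate_ratings

__all__ = ["ValidationReport", "validate_wi_model", "simulated_coefficients"]


@dataclass
class ValidationReport:
    """Per-coefficient comparison of simulated and observed estimates."""

    summary: pd.DataFrame  # term, q2.5, q50, q97.5, observed, covered
    coefficients: pd.DataFrame  # one row per simulation, one column per term
    dimension: str
    n_sims: int
    seed: int

    @property
    def all_covered(self) -> bool:
        return bool(self.summary["covered"].all())


def simulated_coefficients(
    params_by_participant,
    schedule: pd.DataFrame,
    catalog: pd.DataFrame,
    dimension: str,
    noise_sd,
    n_sims: int = 100,
    seed: int = 0,
    design: str = "task",
    include_relevance: bool = True,
    method: str = "two_stage",
) -> pd.DataFrame:
    """Coefficient estimates from ``n_sims`` model-simulated datasets.

    Each simulation regenerates every participant's ratings from their WI
    parameters (same schedules), then fits the lagged regression.  Failed
    regressions are skipped with a warning column left out of the tally.
    """
    rows = []
    child_seeds = np.random.SeedSequence(seed).spawn(n_sims)
    for child in child_seeds:
        sim_seed = int(child.generate_state(1)[0] % (2**31))
        ratings = simulate_ratings(
            schedule,
            catalog,
            "WI",
            params_by_participant,
            noise_sd=noise_sd,
            seed=sim_seed,
            design=design,
        )
        design_tab = build_lag_design(
            schedule,
            ratings,
            catalog,
            dimension,
            include_relevance=include_relevance,
            design=design,
        )
        res = fit_hierarchical_lm(design_tab, method=method)
        rows.append(res.coef)
    return pd.DataFrame(rows).reset_index(drop=True)


def validate_wi_model(
    params_by_participant,
    schedule: pd.DataFrame,
    catalog: pd.DataFrame,
    observed: RegressionResult,
    dimension: str = "valence",
    noise_sd=0.5,
    n_sims: int = 100,
    seed: int = 0,
    design: str = "task",
    include_relevance: bool = True,
    method: str = "two_stage",
    interval: tuple[float, float] = (2.5, 97.5),
) -> ValidationReport:
    """Posterior-predictive coverage check of the WI model.

    Parameters
    ----------
    params_by_participant
        ``{participant_id: {"valence": WIParams, "arousal": WIParams}}`` —
        typically the per-participant MLE estimates.
    observed
        The reference regression result the simulations are compared with.
    noise_sd
        Scalar or per-participant mapping of observation noise (typically
        the fitted sigmas).
    interval
        Percentile bounds of the simulated coverage interval (central 95%
        by default).
    """
    for pid, per_dim in params_by_participant.items():
        if not isinstance(per_dim[dimension], WIParams):
            raise TypeError(f"participant {pid!r}: expected WIParams")
    coefs = simulated_coefficients(
        params_by_participant,
        schedule,
        catalog,
        dimension,
        noise_sd,
        n_sims=n_sims,
        seed=seed,
        design=design,
        include_relevance=include_relevance,
        method=method,
    )
    lo_p, hi_p = interval
    rows = []
    for term in coefs.columns:
        sims = coefs[term].to_numpy(dtype=float)
        lo, med, hi = np.percentile(sims, [lo_p, 50.0, hi_p])
        obs = float(observed.coef[term]) if term in observed.coef.index else np.nan
        rows.append(
            {
                "term": term,
                "sim_low": lo,
                "sim_median": med,
                "sim_high": hi,
                "observed": obs,
                "covered": bool(lo <= obs <= hi) if np.isfinite(obs) else False,
            }
        )
    return ValidationReport(
        summary=pd.DataFrame(rows),
        coefficients=coefs,
        dimension=dimension,
        n_sims=n_sims,
        seed=seed,
    )
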