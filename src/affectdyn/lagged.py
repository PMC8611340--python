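"""Lagged regression of momentary affect on recent stimulus norms.

Each affect rating follows exactly four images, so the natural descriptive
model regresses the (participant-standardized) rating on the standardized
normative affect of those four images: lag 1 is the image immediately
before the rating, lag 4 the earliest in the window.  Valence ratings are
modelled from normative valence only and arousal ratings from normative
arousal only.  For task blocks, affect-by-relevance interaction terms
(``S_lagk * rel_lagk``) probe whether cued relevance amplifies a stimulus's
affective impact; relevance main effects are deliberately absent from the
model, which asks whether relevance modulates the *impact of affect*, not
whether it shifts ratings by itself.

Two estimators of the group-level fixed effects are provided:

* ``mixed`` — a linear mixed model with participant random intercepts and
  random slopes on every predictor (statsmodels ``MixedLM``);
* ``two_stage`` — per-participant ordinary least squares followed by
  across-participant mean and standard error of the coefficient vectors
  (the classic summary-statistics approach, which agrees closely with the
  mixed model in this balanced within-participant design).

``auto`` tries the mixed fit and falls back to two-stage when it fails to
converge or is singular, flagging the fallback in the result.

The module also carries the post-hoc machinery of the analysis: pairwise
Wald tests between coefficients, Holm-Bonferroni step-down correction, and
the a-priori paired-t-test power computation.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .schedule import WINDOW

__all__ = [
    "RegressionResult",
    "build_lag_design",
    "fit_hierarchical_lm",
    "wald_compare",
    "holm_bonferroni",
    "paired_ttest_sample_size",
]

N_LAGS = WINDOW  # one lag per image between consecutive ratings


@dataclass
class RegressionResult:
    """Group-level fixed-effect estimates of the lagged affect regression."""

    coef: pd.Series
    se: pd.Series
    cov: pd.DataFrame
    pvals: pd.Series
    n_obs: int
    n_participants: int
    model_spec: str
    method: str
    fallback: bool = False
    per_participant: pd.DataFrame | None = field(default=None, repr=False)

    def conf_int(self, level: float = 0.95) -> pd.DataFrame:
        z = stats.norm.ppf(0.5 + level / 2)
        return pd.DataFrame(
            {"low": self.coef - z * self.se, "high": self.coef + z * self.se}
        )

    def summary_table(self) -> pd.DataFrame:
        ci = self.conf_int()
        return pd.DataFrame(
            {
                "term": self.coef.index,
                "estimate": self.coef.values,
                "ci_low": ci["low"].values,
                "ci_high": ci["high"].values,
                "p": self.pvals.values,
            }
        )


def build_lag_design(
    schedule: pd.DataFrame,
    ratings: pd.DataFrame,
    catalog: pd.DataFrame,
    dimension: str,
    include_relevance: bool = False,
    design: str = "task",
    value_col: str | None = None,
) -> pd.DataFrame:
    """One row per affect rating with its four lagged stimulus norms.

    ``S_lag1`` is the standardized norm (of ``dimension``) of the image
    presented immediately before the rating, ``S_lag4`` the earliest of the
    four; lags never cross a rating boundary.  With ``include_relevance``,
    ``S_lagk_x_rel`` interaction columns (norm times 0/1 relevance) are
    appended — only defined for the task design.
    """
    if include_relevance and design != "task":
        raise ValueError("relevance interactions exist only in the task design")
    if design not in ("task", "control", "all"):
        raise ValueError("design must be 'task', 'control' or 'all'")
    norms = catalog.set_index("stimulus_id")[f"{dimension}_std"]
    col = value_col or (
        f"{dimension}_std" if f"{dimension}_std" in ratings.columns else dimension
    )
    sched = schedule if design == "all" else schedule[schedule["block_type"] == design]
    rate = ratings if design == "all" else ratings[ratings["block_type"] == design]

    rows = []
    for (pid, block), bdf in sched.groupby(["participant_id", "block_index"]):
        bdf = bdf.sort_values("trial_index")
        stim = norms.loc[bdf["stimulus_id"]].to_numpy(dtype=float)
        rel = (bdf["relevance"] == "relevant").to_numpy(dtype=float)
        pos = np.flatnonzero(bdf["is_rating_trial"].to_numpy())
        robs = rate[(rate["participant_id"] == pid) & (rate["block_index"] == block)]
        robs = robs.sort_values("rating_index")
        if len(robs) != pos.size:
            raise ValueError(
                f"participant {pid} block {block}: {len(robs)} ratings for "
                f"{pos.size} rating trials"
            )
        values = robs[col].to_numpy(dtype=float)
        for k, p in enumerate(pos):
            row = {"participant_id": pid, "block_index": block, "rating": values[k]}
            for lag in range(1, N_LAGS + 1):
                row[f"S_lag{lag}"] = stim[p - (lag - 1)]
                if include_relevance:
                    row[f"rel_lag{lag}"] = rel[p - (lag - 1)]
                    row[f"S_lag{lag}_x_rel"] = stim[p - (lag - 1)] * rel[p - (lag - 1)]
            rows.append(row)
    out = pd.DataFrame(rows)
    return out.dropna(subset=["rating"]).reset_index(drop=True)


def _predictor_columns(design: pd.DataFrame) -> list[str]:
    cols = [f"S_lag{lag}" for lag in range(1, N_LAGS + 1)]
    cols += [c for c in design.columns if c.endswith("_x_rel")]
    return [c for c in cols if c in design.columns]


def _two_stage(design: pd.DataFrame, cols: list[str]) -> RegressionResult:
    names = ["(intercept)"] + cols
    betas = []
    pids = []
    for pid, df in design.groupby("participant_id", sort=False):
        x = np.column_stack([np.ones(len(df))] + [df[c].to_numpy() for c in cols])
        y = df["rating"].to_numpy(dtype=float)
        if len(df) < x.shape[1]:
            raise ValueError(f"participant {pid}: too few rows for the design")
        beta, *_ = np.linalg.lstsq(x, y, rcond=None)
        betas.append(beta)
        pids.append(pid)
    b = np.vstack(betas)
    n_sub = b.shape[0]
    if n_sub < 2:
        raise ValueError("need at least 2 participants")
    coef = b.mean(axis=0)
    cov = np.cov(b, rowvar=False, ddof=1) / n_sub
    cov = np.atleast_2d(cov)
    se = np.sqrt(np.diag(cov))
    tvals = coef / se
    pvals = 2 * stats.t.sf(np.abs(tvals), df=n_sub - 1)
    return RegressionResult(
        coef=pd.Series(coef, index=names),
        se=pd.Series(se, index=names),
        cov=pd.DataFrame(cov, index=names, columns=names),
        pvals=pd.Series(pvals, index=names),
        n_obs=len(design),
        n_participants=n_sub,
        model_spec="rating ~ " + " + ".join(cols),
        method="two_stage",
        per_participant=pd.DataFrame(b, columns=names, index=pids),
    )


def _mixed(design: pd.DataFrame, cols: list[str]) -> RegressionResult:
    from statsmodels.regression.mixed_linear_model import MixedLM

    names = ["(intercept)"] + cols
    exog = np.column_stack(
        [np.ones(len(design))] + [design[c].to_numpy() for c in cols]
    )
    model = MixedLM(
        design["rating"].to_numpy(dtype=float),
        exog,
        groups=design["participant_id"].to_numpy(),
        exog_re=exog,
    )
    # random-effects variances legitimately hit the zero boundary in small
    # simulations; only non-finite output counts as failure
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        result = model.fit(reml=True, method="lbfgs", maxiter=200)
    if not (
        np.all(np.isfinite(np.asarray(result.fe_params)))
        and np.all(np.isfinite(np.asarray(result.bse_fe)))
    ):
        raise np.linalg.LinAlgError("singular mixed fit")
    k = len(names)
    cov = np.asarray(result.cov_params())[:k, :k]
    coef = np.asarray(result.fe_params)
    se = np.sqrt(np.diag(cov))
    pvals = 2 * stats.norm.sf(np.abs(coef / se))
    return RegressionResult(
        coef=pd.Series(coef, index=names),
        se=pd.Series(se, index=names),
        cov=pd.DataFrame(cov, index=names, columns=names),
        pvals=pd.Series(pvals, index=names),
        n_obs=len(design),
        n_participants=design["participant_id"].nunique(),
        model_spec="rating ~ " + " + ".join(cols) + " + (1 + ... | participant)",
        method="mixed",
    )


def fit_hierarchical_lm(design: pd.DataFrame, method: str = "auto") -> RegressionResult:
    """Group-level fixed effects of the lagged design.

    ``method`` is 'mixed', 'two_stage' or 'auto' (mixed with silent fallback
    to two-stage on convergence failure; the fallback is flagged on the
    result).
    """
    cols = _predictor_columns(design)
    if not cols:
        raise ValueError("design has no lag columns")
    counts = design.groupby("participant_id").size()
    if (counts < 8).any():
        raise ValueError("every participant needs at least 8 ratings")
    if method == "two_stage":
        return _two_stage(design, cols)
    if method == "mixed":
        return _mixed(design, cols)
    if method != "auto":
        raise ValueError("method must be 'mixed', 'two_stage' or 'auto'")
    try:
        return _mixed(design, cols)
    except Exception:
        res = _two_stage(design, cols)
        res.fallback = True
        return res


def wald_compare(result: RegressionResult, name_i: str, name_j: str) -> tuple[float, float]:
    """Two-sided Wald z-test of coefficient equality, using the estimated
    coefficient covariance: z = (b_i - b_j) / sqrt(v_i + v_j - 2 cov_ij)."""
    for name in (name_i, name_j):
        if name not in result.coef.index:
            raise KeyError(f"coefficient {name!r} not in result")
    bi, bj = result.coef[name_i], result.coef[name_j]
    vi = result.cov.loc[name_i, name_i]
    vj = result.cov.loc[name_j, name_j]
    cij = result.cov.loc[name_i, name_j]
    var = vi + vj - 2 * cij
    if var <= 0:
        raise ValueError("non-positive variance of the contrast")
    z = float((bi - bj) / np.sqrt(var))
    p = float(2 * stats.norm.sf(abs(z)))
    return z, p


def holm_bonferroni(pvals, alpha: float = 0.05):
    """Holm step-down multiple-comparison correction.

    ``pvals`` is a mapping name -> p or a sequence of p-values.  Returns
    ``(reject, adjusted)`` with the same keys/order.  Adjusted p-values are
    the running maximum of ``(m - i) * p_(i)``, clipped at 1, so they are
    monotone in rank; ``reject`` marks adjusted p <= alpha.
    """
    if isinstance(pvals, dict):
        names = list(pvals)
        p = np.asarray([pvals[k] for k in names], dtype=float)
    else:
        p = np.asarray(list(pvals), dtype=float)
        names = None
    if np.any((p < 0) | (p > 1)):
        raise ValueError("p-values must lie in [0, 1]")
    m = p.size
    order = np.argsort(p, kind="stable")
    adj = np.empty(m)
    running = 0.0
    for rank, idx in enumerate(order):
        running = max(running, (m - rank) * p[idx])
        adj[idx] = min(1.0, running)
    reject = adj <= alpha
    if names is not None:
        return (
            {k: bool(r) for k, r in zip(names, reject)},
            {k: float(a) for k, a in zip(names, adj)},
        )
    return reject, adj


def paired_ttest_sample_size(
    dz: float,
    power: float = 0.95,
    alpha: float = 0.05,
    two_sided: bool = True,
    max_n: int = 100_000,
) -> int:
    """Smallest n achieving the target power for a paired (one-sample) t test.

    Uses the exact noncentral-t power function with noncentrality
    ``dz * sqrt(n)`` and ``n - 1`` degrees of freedom.
    """
    if not 0 < power < 1:
        raise ValueError("power must be in (0, 1)")
    if dz <= 0:
        raise ValueError("dz must be positive")
    for n in range(2, max_n + 1):
        if _paired_t_power(n, dz, alpha, two_sided) >= power:
            return n
    raise RuntimeError("no n up to max_n reaches the requested power")


def _paired_t_power(n: int, dz: float, alpha: float, two_sided: bool) -> float:
    df = n - 1
    nc = dz * np.sqrt(n)
    if two_sided:
        tc = stats.t.ppf(1 - alpha / 2, df)
        return float(1 - stats.nct.cdf(tc, df, nc) + stats.nct.cdf(-tc, df, nc))
    tc = stats.t.ppf(1 - alpha, df)
    return float(1 - stats.nct.cdf(tc, df, nc))
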