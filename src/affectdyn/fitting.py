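"""Per-participant maximum-likelihood fitting of the affect models.

Each participant's ratings in one dimension (valence or arousal) are fitted
under a normal likelihood: observed ratings are the latent model trajectory
at the rating trials plus iid Gaussian noise with free sd ``sigma``.
Optimization is bounded quasi-Newton (L-BFGS-B) with multiple uniform
restarts inside the parameter box; ``sigma`` is profiled analytically at
each candidate (its conditional MLE is the residual rms, clipped to its
bounds), which leaves a lower-dimensional, better-conditioned search while
still treating ``sigma`` as a counted free parameter.

Model evidence is summarized per fit by the Akaike information criterion,
AIC = 2k - 2 lnL, where k counts ``sigma`` plus the model parameters
(control fits: WI 3, ED 4; task fits with relevance-split parameters:
WI 4, ED 6).
"""

from __future__ import annotations

from dataclasses import dataclass, asdict

import numpy as np
import pandas as pd
from scipy import optimize

from .models import EDParams, WIParams, trajectory
from .simulate import participant_blocks

__all__ = [
    "DEFAULT_BOUNDS",
    "FitResult",
    "negative_log_likelihood",
    "fit_mle",
    "fit_participant",
    "fit_all",
    "aic",
    "n_free_params",
]

DEFAULT_BOUNDS = {
    "beta": (0.0, 1.0),
    "gamma": (0.0, 1.0),
    "w0": (-3.0, 3.0),
    "ws": (-5.0, 5.0),
    "x0": (-3.0, 3.0),
    "sigma": (1e-3, 5.0),
}

_LOG_2PI = float(np.log(2.0 * np.pi))

# parameter-vector layouts per (model, split): names in optimizer order
_LAYOUT = {
    ("WI", False): ("beta", "x0"),
    ("WI", True): ("beta_rel", "beta_irr", "x0"),
    ("ED", False): ("w0", "ws", "gamma"),
    ("ED", True): ("w0", "ws_rel", "ws_irr", "gamma_rel", "gamma_irr"),
}


def n_free_params(model_name: str, split: bool) -> int:
    """Number of counted free parameters, including sigma."""
    return len(_LAYOUT[(model_name.upper(), split)]) + 1


def _bound_for(name: str, bounds: dict) -> tuple[float, float]:
    for key in ("beta", "gamma", "ws", "w0", "x0", "sigma"):
        if name == key or name.startswith(key + "_"):
            return bounds[key]
    raise KeyError(name)


def _make_params(model_name: str, split: bool, theta: np.ndarray):
    names = _LAYOUT[(model_name.upper(), split)]
    kw = dict(zip(names, (float(v) for v in theta)))
    return EDParams(**kw) if model_name.upper() == "ED" else WIParams(**kw)


@dataclass
class FitResult:
    """Maximum-likelihood fit of one model to one participant-dimension."""

    model_name: str
    dimension: str
    participant_id: str
    params: EDParams | WIParams
    sigma: float
    loglik: float
    n_params: int
    n_obs: int
    aic: float
    converged: bool
    n_restarts_used: int

    def to_dict(self) -> dict:
        d = asdict(self)
        d["params"] = {k: v for k, v in asdict(self.params).items() if v is not None}
        return d


def negative_log_likelihood(
    model_name: str,
    params: EDParams | WIParams,
    sigma: float,
    observed: np.ndarray,
    blocks,
) -> float:
    """Gaussian negative log-likelihood of observed ratings.

    ``blocks`` is the per-block structure from
    :func:`affectdyn.simulate.participant_blocks`; ``observed`` concatenates
    the participant's ratings over those blocks in order.
    """
    if sigma <= 0:
        raise ValueError("sigma must be positive")
    pred = _predict(model_name, params, blocks)
    obs = np.asarray(observed, dtype=float)
    if obs.shape != pred.shape:
        raise ValueError(
            f"{obs.size} ratings do not align with {pred.size} rating trials"
        )
    resid = obs - pred
    n = obs.size
    return 0.5 * n * (_LOG_2PI + 2.0 * np.log(sigma)) + float(
        np.sum(resid**2)
    ) / (2.0 * sigma**2)


def _predict(model_name: str, params, blocks) -> np.ndarray:
    parts = []
    split = getattr(params, "split", False)
    for _block, stim, rel, pos in blocks:
        use_rel = rel if split else None
        traj = trajectory(model_name, params, stim, use_rel)
        parts.append(traj[pos])
    return np.concatenate(parts)


def _profiled_nll(resid_ss: float, n: int, sigma_bounds: tuple[float, float]) -> tuple[float, float]:
    sigma = float(np.sqrt(resid_ss / n)) if resid_ss > 0 else sigma_bounds[0]
    sigma = float(np.clip(sigma, *sigma_bounds))
    nll = 0.5 * n * (_LOG_2PI + 2.0 * np.log(sigma)) + resid_ss / (2.0 * sigma**2)
    return nll, sigma


def fit_mle(
    model_name: str,
    observed: np.ndarray,
    blocks,
    split: bool,
    bounds: dict | None = None,
    n_restarts: int = 10,
    seed: int = 0,
    participant_id: str = "",
    dimension: str = "valence",
) -> FitResult:
    """Fit one model to one participant-dimension by restarted bounded MLE.

    Returns the best of ``n_restarts`` L-BFGS-B runs started uniformly inside
    the parameter box (ties broken first-found); deterministic given
    ``seed``.  If no restart converges the best iterate is returned with
    ``converged=False``.
    """
    model_name = model_name.upper()
    bounds = {**DEFAULT_BOUNDS, **(bounds or {})}
    obs = np.asarray(observed, dtype=float)
    if obs.size < 8:
        raise ValueError(f"need at least 8 ratings, got {obs.size}")
    names = _LAYOUT[(model_name, split)]
    box = [_bound_for(name, bounds) for name in names]
    lo = np.array([b[0] for b in box])
    hi = np.array([b[1] for b in box])
    n = obs.size

    def objective(theta: np.ndarray) -> float:
        params = _make_params(model_name, split, np.clip(theta, lo, hi))
        resid = obs - _predict(model_name, params, blocks)
        nll, _ = _profiled_nll(float(np.sum(resid**2)), n, bounds["sigma"])
        return nll

    rng = np.random.default_rng(seed)
    best = None
    any_converged = False
    for _ in range(n_restarts):
        x0 = rng.uniform(lo, hi)
        res = optimize.minimize(
            objective,
            x0,
            method="L-BFGS-B",
            bounds=box,
            options={"ftol": 1e-10, "gtol": 1e-8, "maxiter": 500},
        )
        any_converged = any_converged or bool(res.success)
        if best is None or res.fun < best.fun - 1e-12:
            best = res
    theta = np.clip(best.x, lo, hi)
    params = _make_params(model_name, split, theta)
    resid = obs - _predict(model_name, params, blocks)
    nll, sigma = _profiled_nll(float(np.sum(resid**2)), n, bounds["sigma"])
    k = len(names) + 1
    loglik = -nll
    return FitResult(
        model_name=model_name,
        dimension=dimension,
        participant_id=participant_id,
        params=params,
        sigma=sigma,
        loglik=loglik,
        n_params=k,
        n_obs=n,
        aic=aic_value(k, loglik),
        converged=any_converged,
        n_restarts_used=n_restarts,
    )


def aic_value(n_params: int, loglik: float) -> float:
    return 2.0 * n_params - 2.0 * loglik


def aic(fit: FitResult) -> float:
    """AIC = 2k - 2 lnL of a fit."""
    if not np.isfinite(fit.loglik):
        raise ValueError("log-likelihood is not finite")
    return aic_value(fit.n_params, fit.loglik)


def fit_participant(
    model_name: str,
    schedule: pd.DataFrame,
    catalog: pd.DataFrame,
    ratings: pd.DataFrame,
    participant_id: str,
    dimension: str,
    design: str = "task",
    value_col: str | None = None,
    **kwargs,
) -> FitResult:
    """Fit one participant-dimension from schedule + ratings tables.

    ``design`` chooses the block subset and parameterization: 'task' fits
    relevance-split parameters on the four task blocks, 'control' unsplit
    parameters on the control block.  ``value_col`` names the ratings column
    to fit (defaults to the participant-standardized column ``{dim}_std`` if
    present, else the model-scale column ``{dim}``).
    """
    if design not in ("task", "control"):
        raise ValueError("design must be 'task' or 'control'")
    blocks = participant_blocks(schedule, catalog, participant_id, dimension, design)
    sub = ratings[
        (ratings["participant_id"] == participant_id)
        & (ratings["block_type"] == design)
    ].sort_values(["block_index", "rating_index"])
    col = value_col or (f"{dimension}_std" if f"{dimension}_std" in ratings else dimension)
    obs = sub[col].to_numpy(dtype=float)
    expected = sum(len(pos) for *_rest, pos in blocks)
    if obs.size != expected:
        raise ValueError(
            f"{participant_id}: {obs.size} ratings but schedule has {expected} rating trials"
        )
    return fit_mle(
        model_name,
        obs,
        blocks,
        split=(design == "task"),
        participant_id=participant_id,
        dimension=dimension,
        **kwargs,
    )


def fit_all(
    model_names,
    schedule: pd.DataFrame,
    catalog: pd.DataFrame,
    ratings: pd.DataFrame,
    dimensions=("valence", "arousal"),
    design: str = "task",
    seed: int = 0,
    exclude: dict | None = None,
    **kwargs,
) -> list[FitResult]:
    """Fit every (participant, model, dimension) combination.

    ``exclude`` maps a dimension to participant ids to skip for that
    dimension (e.g. all-unmoved control-arousal sliders).  Restart seeds are
    spawned deterministically per combination.
    """
    pids = list(ratings["participant_id"].unique())
    exclude = exclude or {}
    results = []
    ss = np.random.SeedSequence(seed)
    streams = iter(ss.spawn(len(pids) * len(list(model_names)) * len(dimensions)))
    for pid in pids:
        for model in model_names:
            for dim in dimensions:
                child = next(streams)
                if pid in exclude.get(dim, ()):
                    continue
                results.append(
                    fit_participant(
                        model,
                        schedule,
                        catalog,
                        ratings,
                        pid,
                        dim,
                        design=design,
                        seed=int(child.generate_state(1)[0] % (2**31)),
                        **kwargs,
                    )
                )
    return results
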