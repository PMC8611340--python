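"""Generative models of trial-by-trial momentary affect.

Two candidate models map an ordered sequence of (standardized) normative
stimulus values within an experimental block onto a latent affect trajectory,
one value per stimulus position:

* **Exponential decay (ED)** — momentary affect is a weighted sum of all
  stimuli seen so far in the block, geometrically discounted by a forgetting
  factor ``gamma`` in [0, 1].  ``gamma = 1`` weights every stimulus evenly;
  ``gamma = 0`` leaves only the most recent stimulus.

* **Weighted impact (WI)** — momentary affect is updated toward each incoming
  stimulus by a fraction ``beta`` in [0, 1] of the current gap
  (a Rescorla-Wagner-style delta rule).  ``beta = 0`` freezes the state at
  its initial value; ``beta = 1`` tracks the latest stimulus exactly.

Both models can carry separate parameters for task-relevant and
task-irrelevant stimuli (the "split" parameterization used for task blocks);
control-block fits use a single shared parameter set.  Trajectories restart
at every block boundary and are purely feedforward: they are never
re-anchored to observed ratings.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np

__all__ = [
    "EDParams",
    "WIParams",
    "ed_trajectory",
    "wi_trajectory_recursive",
    "wi_trajectory_closed",
    "trajectory",
]


def _check_unit(name: str, value: float) -> None:
    if not (0.0 <= value <= 1.0):
        raise ValueError(f"{name} must lie in [0, 1], got {value!r}")


@dataclass(frozen=True)
class EDParams:
    """Parameters of the exponential-decay model for one affect dimension.

    Either the unsplit fields (``ws``, ``gamma``) or all four split fields
    (``ws_rel``, ``ws_irr``, ``gamma_rel``, ``gamma_irr``) must be given.

    Parameters
    ----------
    w0
        Constant term around which the affective state fluctuates.
    ws, gamma
        Stimulus weight and forgetting factor for the unsplit (control) fit.
    ws_rel, ws_irr, gamma_rel, gamma_irr
        Relevance-specific weights and forgetting factors for task fits.
    """

    w0: float
    ws: float | None = None
    gamma: float | None = None
    ws_rel: float | None = None
    ws_irr: float | None = None
    gamma_rel: float | None = None
    gamma_irr: float | None = None

    def __post_init__(self) -> None:
        unsplit = self.ws is not None or self.gamma is not None
        split = any(
            v is not None
            for v in (self.ws_rel, self.ws_irr, self.gamma_rel, self.gamma_irr)
        )
        if unsplit and split:
            raise ValueError("give either (ws, gamma) or the four split fields, not both")
        if unsplit:
            if self.ws is None or self.gamma is None:
                raise ValueError("unsplit EDParams need both ws and gamma")
            _check_unit("gamma", self.gamma)
        elif split:
            for name in ("ws_rel", "ws_irr", "gamma_rel", "gamma_irr"):
                if getattr(self, name) is None:
                    raise ValueError(f"split EDParams missing {name}")
            _check_unit("gamma_rel", self.gamma_rel)
            _check_unit("gamma_irr", self.gamma_irr)
        else:
            raise ValueError("EDParams needs (ws, gamma) or the four split fields")
        for name in ("w0", "ws", "ws_rel", "ws_irr"):
            v = getattr(self, name)
            if v is not None and not np.isfinite(v):
                raise ValueError(f"{name} must be finite")

    @property
    def split(self) -> bool:
        return self.ws is None


@dataclass(frozen=True)
class WIParams:
    """Parameters of the weighted-impact model for one affect dimension.

    Parameters
    ----------
    x0
        Initial affective state at the start of each block (V0 or A0).
    beta
        Update weight for the unsplit (control) fit.
    beta_rel, beta_irr
        Relevance-specific update weights for task fits.
    """

    x0: float
    beta: float | None = None
    beta_rel: float | None = None
    beta_irr: float | None = None

    def __post_init__(self) -> None:
        unsplit = self.beta is not None
        split = self.beta_rel is not None or self.beta_irr is not None
        if unsplit and split:
            raise ValueError("give either beta or (beta_rel, beta_irr), not both")
        if unsplit:
            _check_unit("beta", self.beta)
        elif split:
            if self.beta_rel is None or self.beta_irr is None:
                raise ValueError("split WIParams need both beta_rel and beta_irr")
            _check_unit("beta_rel", self.beta_rel)
            _check_unit("beta_irr", self.beta_irr)
        else:
            raise ValueError("WIParams needs beta or (beta_rel, beta_irr)")
        if not np.isfinite(self.x0):
            raise ValueError("x0 must be finite")

    @property
    def split(self) -> bool:
        return self.beta is None


def _as_arrays(
    stimuli: Sequence[float],
    relevance: Sequence[bool] | None,
    split: bool,
) -> tuple[np.ndarray, np.ndarray | None]:
    s = np.asarray(stimuli, dtype=float)
    if s.ndim != 1:
        raise ValueError("stimuli must be one-dimensional")
    if split:
        if relevance is None:
            raise ValueError("relevance-split parameters require relevance flags")
        r = np.asarray(relevance, dtype=bool)
        if r.shape != s.shape:
            raise ValueError(
                f"stimuli ({s.size}) and relevance ({r.size}) length mismatch"
            )
        return s, r
    if relevance is not None:
        raise ValueError("relevance flags given but parameters are not split")
    return s, None


def ed_trajectory(
    params: EDParams,
    stimuli: Sequence[float],
    relevance: Sequence[bool] | None = None,
) -> np.ndarray:
    """Latent ED trajectory over one block of stimuli.

    The value after the t-th stimulus is

        w0 + sum_{j<=t} ws[r_j] * gamma[r_j]^(t-j) * S_j

    with ``0**0 == 1`` so that ``gamma = 0`` reproduces the pure-recency
    limit.  In the split case both the weight and the forgetting factor
    applied to stimulus j are chosen by stimulus j's own relevance, while the
    exponent ``t - j`` counts all intervening stimuli.
    """
    s, r = _as_arrays(stimuli, relevance, params.split)
    n = s.size
    out = np.empty(n)
    if not params.split:
        # single accumulator: y_t = gamma * y_{t-1} + S_t
        y = 0.0
        for t in range(n):
            y = params.gamma * y + s[t]
            out[t] = params.w0 + params.ws * y
        return out
    y_rel = 0.0
    y_irr = 0.0
    for t in range(n):
        y_rel *= params.gamma_rel
        y_irr *= params.gamma_irr
        if r[t]:
            y_rel += s[t]
        else:
            y_irr += s[t]
        out[t] = params.w0 + params.ws_rel * y_rel + params.ws_irr * y_irr
    return out


def wi_trajectory_recursive(
    params: WIParams,
    stimuli: Sequence[float],
    relevance: Sequence[bool] | None = None,
) -> np.ndarray:
    """Latent WI trajectory over one block, by the delta-rule recursion.

    V_t = V_{t-1} + beta[r_t] * (S_t - V_{t-1}), with V_0 = x0 at the block
    start.  Each value is a convex combination of x0 and the stimuli seen so
    far, so the trajectory stays inside their common range.
    """
    s, r = _as_arrays(stimuli, relevance, params.split)
    n = s.size
    out = np.empty(n)
    v = params.x0
    if not params.split:
        b = params.beta
        for t in range(n):
            v = v + b * (s[t] - v)
            out[t] = v
        return out
    for t in range(n):
        b = params.beta_rel if r[t] else params.beta_irr
        v = v + b * (s[t] - v)
        out[t] = v
    return out


def wi_trajectory_closed(
    params: WIParams,
    stimuli: Sequence[float],
) -> np.ndarray:
    """Closed-form WI trajectory (unsplit parameterization only).

    V_t = x0 * (1 - beta)^t + sum_{j<=t} beta * (1 - beta)^(t-j) * S_j.

    Algebraically identical to :func:`wi_trajectory_recursive`; kept as an
    explicit geometric-weighting form because it makes the correspondence
    with the ED model's discounted sum transparent.
    """
    if params.split:
        raise ValueError("closed form is defined only for unsplit WI parameters")
    s, _ = _as_arrays(stimuli, None, False)
    n = s.size
    beta = params.beta
    t = np.arange(1, n + 1, dtype=float)
    decay = (1.0 - beta) ** t  # (1-beta)^t, t = 1..n
    # explicit lower-triangular weight matrix (1-beta)^(t-j); 0**0 == 1 under
    # numpy's power so beta = 1 reduces to the identity weighting
    lag = t[:, None] - t[None, :]
    weights = np.where(lag >= 0, (1.0 - beta) ** np.maximum(lag, 0.0), 0.0)
    return params.x0 * decay + beta * (weights @ s)


def trajectory(
    model_name: str,
    params: EDParams | WIParams,
    stimuli: Sequence[float],
    relevance: Sequence[bool] | None = None,
) -> np.ndarray:
    """Dispatch on model name ('ED' or 'WI')."""
    name = model_name.upper()
    if name == "ED":
        if not isinstance(params, EDParams):
            raise TypeError("ED model requires EDParams")
        return ed_trajectory(params, stimuli, relevance)
    if name == "WI":
        if not isinstance(params, WIParams):
            raise TypeError("WI model requires WIParams")
        return wi_trajectory_recursive(params, stimuli, relevance)
    raise ValueError(f"unknown model {model_name!r}; expected 'ED' or 'WI'")
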