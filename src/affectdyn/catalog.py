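"""Synthetic stimulus catalogs with normative valence/arousal norms.

The study world uses a 200-image catalog: 100 pleasant and 100 unpleasant
images carrying population-normative valence and arousal ratings on a 1-7
scale, with the neutral valence band (3.5-4.5) excluded and the two
categories matched on mean arousal.  :func:`generate_catalog` emulates such
a catalog; :func:`standardize_catalog` attaches catalog-wide z-scores, which
are the stimulus values the generative models and regressions consume (the
models have no affine freedom, so stimulus and rating scales must match).
"""

from __future__ import annotations

import numpy as np
import pandas as pd

__all__ = ["CatalogError", "generate_catalog", "standardize_catalog", "validate_catalog"]

CATALOG_COLUMNS = [
    "stimulus_id",
    "valence_raw",
    "arousal_raw",
    "category",
    "valence_std",
    "arousal_std",
]

# Sampling windows for the synthetic norms.  Valence avoids the excluded
# neutral band with a small margin; arousal spans a common mid-range so the
# two categories can be mean-matched by rejection.
PLEASANT_VALENCE_RANGE = (4.6, 6.8)
UNPLEASANT_VALENCE_RANGE = (1.2, 3.4)
AROUSAL_RANGE = (3.0, 5.5)
MAX_ATTEMPTS = 1000


class CatalogError(RuntimeError):
    """Raised when catalog constraints cannot be satisfied."""


def generate_catalog(
    n_pleasant: int = 100,
    n_unpleasant: int = 100,
    arousal_match_tol: float = 0.1,
    seed: int = 0,
) -> pd.DataFrame:
    """Draw a synthetic stimulus catalog with arousal-matched categories.

    Valence norms are uniform on category-specific windows avoiding the
    neutral band; arousal norms are uniform on a shared window, redrawn until
    the two category means agree within ``arousal_match_tol`` (at most
    ``MAX_ATTEMPTS`` draws, then :class:`CatalogError`).

    Returns a DataFrame with columns ``stimulus_id, valence_raw, arousal_raw,
    category, valence_std, arousal_std``; the ``*_std`` columns are catalog
    z-scores (population variance).
    """
    if n_pleasant < 1 or n_unpleasant < 1:
        raise ValueError("need at least one stimulus per category")
    if arousal_match_tol <= 0:
        raise ValueError("arousal_match_tol must be positive")
    rng = np.random.default_rng(seed)
    val_p = rng.uniform(*PLEASANT_VALENCE_RANGE, size=n_pleasant)
    val_u = rng.uniform(*UNPLEASANT_VALENCE_RANGE, size=n_unpleasant)
    for _ in range(MAX_ATTEMPTS):
        aro_p = rng.uniform(*AROUSAL_RANGE, size=n_pleasant)
        aro_u = rng.uniform(*AROUSAL_RANGE, size=n_unpleasant)
        if abs(aro_p.mean() - aro_u.mean()) < arousal_match_tol:
            break
    else:
        raise CatalogError(
            f"could not match category arousal means within {arousal_match_tol} "
            f"after {MAX_ATTEMPTS} attempts"
        )
    cat = pd.DataFrame(
        {
            "stimulus_id": [f"P{i:03d}" for i in range(n_pleasant)]
            + [f"U{i:03d}" for i in range(n_unpleasant)],
            "valence_raw": np.concatenate([val_p, val_u]),
            "arousal_raw": np.concatenate([aro_p, aro_u]),
            "category": ["pleasant"] * n_pleasant + ["unpleasant"] * n_unpleasant,
        }
    )
    cat = standardize_catalog(cat)
    validate_catalog(cat, arousal_match_tol=arousal_match_tol)
    return cat


def standardize_catalog(catalog: pd.DataFrame) -> pd.DataFrame:
    """Attach catalog-wide z-score columns (population sd, ddof=0)."""
    out = catalog.copy()
    for dim in ("valence", "arousal"):
        raw = out[f"{dim}_raw"].to_numpy(dtype=float)
        sd = raw.std(ddof=0)
        if sd == 0:
            raise CatalogError(f"{dim} norms are constant; cannot standardize")
        out[f"{dim}_std"] = (raw - raw.mean()) / sd
    return out


def validate_catalog(catalog: pd.DataFrame, arousal_match_tol: float | None = None) -> None:
    """Independent audit of the catalog invariants; raises on violation."""
    missing = [c for c in CATALOG_COLUMNS if c not in catalog.columns]
    if missing:
        raise CatalogError(f"catalog missing columns: {missing}")
    if catalog["stimulus_id"].duplicated().any():
        raise CatalogError("duplicate stimulus_id")
    val = catalog["valence_raw"]
    aro = catalog["arousal_raw"]
    if ((val < 1) | (val > 7)).any() or ((aro < 1) | (aro > 7)).any():
        raise CatalogError("raw norms outside the 1-7 scale")
    pleasant = catalog["category"] == "pleasant"
    if (val[pleasant] <= 4.5).any() or (val[~pleasant] >= 3.5).any():
        raise CatalogError("valence norms intrude into the neutral band 3.5-4.5")
    for dim in ("valence", "arousal"):
        z = catalog[f"{dim}_std"].to_numpy(dtype=float)
        if abs(z.mean()) > 1e-9 or abs(z.var(ddof=0) - 1) > 1e-9:
            raise CatalogError(f"{dim}_std is not a unit-variance z-score")
    if arousal_match_tol is not None:
        diff = abs(aro[pleasant].mean() - aro[~pleasant].mean())
        if diff >= arousal_match_tol:
            raise CatalogError(
                f"category arousal means differ by {diff:.4f} >= {arousal_match_tol}"
            )
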