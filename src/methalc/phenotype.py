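"""Alcohol phenotype preparation shared by the prediction and EWAS stages.

Units are NHS alcohol units (8 g / 10 ml of pure ethanol) consumed per week.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

#: weekly-units threshold at or above which a drinker is moderate/heavy
MODERATE_HEAVY_THRESHOLD = {"F": 14.0, "M": 21.0}

CATEGORIES = ("non-drinker", "light/moderate", "moderate/heavy")


def log_units(units):
    """Natural log of (units + 1); 0 maps to 0, monotone in units."""
    arr = np.asarray(units, dtype=float)
    if np.any(arr < 0):
        raise ValueError("units must be nonnegative")
    out = np.log1p(arr)
    return float(out) if np.isscalar(units) else out


def categorize_drinker(units, sex):
    """Drinker category from weekly units and sex.

    Zero units -> non-drinker; at or above the sex-specific threshold
    (14 units/week for females, 21 for males, boundary inclusive) ->
    moderate/heavy; otherwise light/moderate.
    """
    if np.isscalar(units):
        return _categorize_one(float(units), sex)
    sexes = pd.Series(sex).to_numpy()
    return pd.Series(
        [_categorize_one(float(u), s) for u, s in zip(np.asarray(units, dtype=float), sexes)],
        index=units.index if isinstance(units, pd.Series) else None,
        name="drinker_category",
    )


def _categorize_one(units: float, sex: str) -> str:
    if sex not in MODERATE_HEAVY_THRESHOLD:
        raise ValueError(f"unknown sex code {sex!r}; expected 'F' or 'M'")
    if units < 0:
        raise ValueError("units must be nonnegative")
    if units == 0:
        return "non-drinker"
    if units >= MODERATE_HEAVY_THRESHOLD[sex]:
        return "moderate/heavy"
    return "light/moderate"


def residualize(y, covariates) -> np.ndarray:
    """Residual of y after least-squares projection onto [1, covariates].

    Raises on rank deficiency, naming the collinear columns.  Idempotent for a
    fixed covariate set; residuals are orthogonal to every covariate column.
    """
    y_arr = np.asarray(y, dtype=float)
    X = _design(covariates, len(y_arr))
    if y_arr.ndim != 1 or X.shape[0] != y_arr.shape[0]:
        raise ValueError("y and covariates have mismatched lengths")
    rank = np.linalg.matrix_rank(X)
    if rank < X.shape[1]:
        names = _collinear_columns(X, covariates)
        raise ValueError(f"covariate design is rank deficient; collinear columns: {names}")
    coef, *_ = np.linalg.lstsq(X, y_arr, rcond=None)
    resid = y_arr - X @ coef
    if isinstance(y, pd.Series):
        return pd.Series(resid, index=y.index, name=y.name)
    return resid


def _design(covariates, n: int) -> np.ndarray:
    C = np.asarray(covariates, dtype=float)
    if C.ndim == 1:
        C = C[:, None]
    if C.shape[0] != n:
        raise ValueError("covariate rows do not match y length")
    return np.column_stack([np.ones(n), C])


def _collinear_columns(X: np.ndarray, covariates) -> list:
    names = (
        list(covariates.columns)
        if isinstance(covariates, pd.DataFrame)
        else [f"col{i}" for i in range(X.shape[1] - 1)]
    )
    bad = []
    keep = [0]  # intercept
    for i in range(1, X.shape[1]):
        if np.linalg.matrix_rank(X[:, keep + [i]]) == len(keep):
            bad.append(names[i - 1])
        else:
            keep.append(i)
    return bad
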