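"""Phenome association battery: self-reported alcohol or its EpiScore versus
health, lifestyle, brain-imaging and mortality outcomes.

Exposures are standardized to unit SD, so continuous models report a
standardized beta, logistic models an OR per SD, and Cox models an HR per SD,
each with a Wald 95% CI.  p-values across an outcome battery are controlled
with Benjamini-Hochberg FDR.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
import statsmodels.api as sm
from lifelines import CoxPHFitter

_Z95 = 1.959963984540054


@dataclass
class AssociationResult:
    outcome: str
    exposure: str
    model: str        # linear | logistic | cox
    effect: float     # standardized beta | OR per SD | HR per SD
    ci_low: float
    ci_high: float
    p: float
    n: int
    p_fdr: float | None = None


def _zscore(x) -> np.ndarray:
    x = np.asarray(x, dtype=float)
    sd = x.std()
    if sd == 0:
        raise ValueError("exposure has zero variance")
    return (x - x.mean()) / sd


def _sex_numeric(sex) -> np.ndarray:
    arr = np.asarray(sex)
    return (arr == "M").astype(float) if arr.dtype.kind in "OUS" else arr.astype(float)


def fit_continuous(
    outcome, exposure, age, sex, outcome_label: str = "outcome",
    exposure_label: str = "exposure",
) -> AssociationResult | None:
    """Standardized beta from outcome ~ exposure + age + sex (both z-scored)."""
    y = np.asarray(outcome, dtype=float)
    if len(y) < 10:
        warnings.warn(f"{outcome_label}: fewer than 10 complete cases; skipped")
        return None
    y = _zscore(y)
    X = sm.add_constant(
        np.column_stack([_zscore(exposure), np.asarray(age, float), _sex_numeric(sex)])
    )
    fit = sm.OLS(y, X).fit()
    b, se = fit.params[1], fit.bse[1]
    return AssociationResult(
        outcome=outcome_label, exposure=exposure_label, model="linear",
        effect=float(b), ci_low=float(b - _Z95 * se), ci_high=float(b + _Z95 * se),
        p=float(fit.pvalues[1]), n=len(y),
    )


def fit_binary(
    outcome, exposure, age, sex, outcome_label: str = "outcome",
    exposure_label: str = "exposure",
) -> AssociationResult | None:
    """OR per SD of exposure from logistic outcome ~ exposure + age + sex."""
    y = np.asarray(outcome, dtype=float)
    if len(np.unique(y)) < 2:
        warnings.warn(f"{outcome_label}: outcome has a single class; skipped")
        return None
    X = sm.add_constant(
        np.column_stack([_zscore(exposure), np.asarray(age, float), _sex_numeric(sex)])
    )
    try:
        fit = sm.Logit(y, X).fit(disp=0)
    except Exception as err:  # perfect separation raises from statsmodels
        raise RuntimeError(
            f"{outcome_label}: logistic fit did not converge (separation?): {err}"
        ) from err
    if not np.isfinite(fit.bse[1]) or fit.bse[1] > 1e3:
        raise RuntimeError(f"{outcome_label}: logistic fit unstable (separation?)")
    b, se = fit.params[1], fit.bse[1]
    return AssociationResult(
        outcome=outcome_label, exposure=exposure_label, model="logistic",
        effect=float(np.exp(b)), ci_low=float(np.exp(b - _Z95 * se)),
        ci_high=float(np.exp(b + _Z95 * se)), p=float(fit.pvalues[1]), n=len(y),
    )


def fit_mortality(
    time, event, exposure, age, sex, outcome_label: str = "all_cause_mortality",
    exposure_label: str = "exposure",
) -> AssociationResult | None:
    """HR per SD of exposure from Cox PH time-to-death ~ exposure + age + sex."""
    t = np.asarray(time, dtype=float)
    ev = np.asarray(event, dtype=float)
    if np.any(t < 0):
        raise ValueError("survival times must be nonnegative")
    if not set(np.unique(ev)) <= {0.0, 1.0}:
        raise ValueError("event indicator must be binary")
    if ev.sum() == 0:
        warnings.warn(f"{outcome_label}: zero events; skipped")
        return None
    df = pd.DataFrame(
        {
            "time": t, "event": ev, "exposure": _zscore(exposure),
            "age": np.asarray(age, float), "sex": _sex_numeric(sex),
        }
    )
    cph = CoxPHFitter()
    cph.fit(df, duration_col="time", event_col="event")
    b = float(cph.params_["exposure"])
    se = float(cph.standard_errors_["exposure"])
    return AssociationResult(
        outcome=outcome_label, exposure=exposure_label, model="cox",
        effect=float(np.exp(b)), ci_low=float(np.exp(b - _Z95 * se)),
        ci_high=float(np.exp(b + _Z95 * se)),
        p=float(cph.summary.loc["exposure", "p"]), n=len(df),
    )


def fit_brain(
    outcome_volume, exposure, age, sex, icv, outcome_label: str = "brain_volume",
    exposure_label: str = "exposure",
) -> AssociationResult | None:
    """Standardized beta for a brain volume, additionally adjusting for
    intracranial volume."""
    icv = np.asarray(icv, dtype=float)
    if np.any(icv <= 0):
        raise ValueError("intracranial volume must be positive")
    y = np.asarray(outcome_volume, dtype=float)
    if len(y) < 10:
        warnings.warn(f"{outcome_label}: fewer than 10 complete cases; skipped")
        return None
    y = _zscore(y)
    X = sm.add_constant(
        np.column_stack(
            [_zscore(exposure), np.asarray(age, float), _sex_numeric(sex), icv]
        )
    )
    fit = sm.OLS(y, X).fit()
    b, se = fit.params[1], fit.bse[1]
    return AssociationResult(
        outcome=outcome_label, exposure=exposure_label, model="linear",
        effect=float(b), ci_low=float(b - _Z95 * se), ci_high=float(b + _Z95 * se),
        p=float(fit.pvalues[1]), n=len(y),
    )


def bh_fdr(p_values) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values."""
    p = np.asarray(p_values, dtype=float)
    if p.ndim != 1 or len(p) == 0:
        raise ValueError("p_values must be a nonempty 1-D vector")
    if np.any((p <= 0) | (p > 1)) or np.any(~np.isfinite(p)):
        raise ValueError("p-values must lie in (0, 1]")
    m = len(p)
    order = np.argsort(p, kind="mergesort")
    ranked = p[order] * m / np.arange(1, m + 1)
    adj = np.minimum.accumulate(ranked[::-1])[::-1]
    adj = np.minimum(adj, 1.0)
    out = np.empty(m)
    out[order] = adj
    return out


def adjust_battery(results: list[AssociationResult]) -> list[AssociationResult]:
    """Attach BH-FDR-adjusted p-values across one cohort's battery (all
    outcomes x both exposures corrected jointly)."""
    kept = [r for r in results if r is not None]
    if not kept:
        return []
    adj = bh_fdr([r.p for r in kept])
    for r, a in zip(kept, adj):
        r.p_fdr = float(a)
    return kept


def battery_table(results: list[AssociationResult]) -> pd.DataFrame:
    return pd.DataFrame(
        [
            {
                "outcome": r.outcome, "exposure": r.exposure, "model": r.model,
                "effect": r.effect, "ci_low": r.ci_low, "ci_high": r.ci_high,
                "p": r.p, "p_fdr": r.p_fdr, "n": r.n,
            }
            for r in results
            if r is not None
        ]
    )
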