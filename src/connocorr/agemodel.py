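"""Cubic age-trajectory decomposition of longitudinal regional series.

Each ROI's value series across one subject's sessions is fit by ordinary
least squares to a cubic polynomial in age. The fit splits every series into
a smooth *fitted age effect* and a *residual* (additive, exact), and the
correlation matrices of the raw, fitted and residual tables separate what
part of the within-person correlation structure is carried by slow aging
versus session-to-session fluctuation.

The polynomial is fit on an internally centered and scaled age basis for
conditioning (a raw cubic on ages spanning decades is ill-conditioned);
coefficients are reported back on the raw-age basis.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from numpy.polynomial import Polynomial

from .connmat import ConnMatrix, RegionalMeasureTable, corr_across_sessions

__all__ = [
    "AgeDecomposition",
    "fit_cubic_age",
    "decompose_table",
    "age_component_matrices",
]

_DEGREE = 3
_COND_LIMIT = 1e10


@dataclass
class AgeDecomposition:
    """Cubic fit of one ROI's series: raw-age-basis coefficients
    (beta0..beta3), fitted and residual series, and R^2 (NaN for a constant
    series, where explained variance is undefined)."""

    coefficients: np.ndarray
    fitted: np.ndarray
    residual: np.ndarray
    r_squared: float


def fit_cubic_age(values: np.ndarray, ages: np.ndarray) -> AgeDecomposition:
    """OLS cubic-in-age fit of one per-session value series.

    Requires at least 5 sessions with at least 4 distinct ages (4 parameters
    plus one). The returned fitted and residual series sum to the input
    exactly (to solver precision); residuals are orthogonal to the age design
    columns.
    """
    y = np.asarray(values, dtype=float)
    a = np.asarray(ages, dtype=float)
    if y.shape != a.shape or y.ndim != 1:
        raise ValueError(f"values {y.shape} and ages {a.shape} must be "
                         "matching 1-D arrays")
    if y.size < _DEGREE + 2:
        raise ValueError(f"need >= {_DEGREE + 2} sessions, got {y.size}")
    if np.unique(a).size < _DEGREE + 1:
        raise ValueError(
            f"need >= {_DEGREE + 1} distinct ages, got {np.unique(a).size}")

    m = a.mean()
    s = a.std()
    u = (a - m) / s
    X = np.vander(u, _DEGREE + 1, increasing=True)
    cond = np.linalg.cond(X)
    if cond > _COND_LIMIT:
        raise ValueError(
            f"age design is near-singular even after scaling "
            f"(condition number {cond:.3g})")
    coef_u, *_ = np.linalg.lstsq(X, y, rcond=None)
    fitted = X @ coef_u
    residual = y - fitted

    # map coefficients from the scaled basis u = (age - m)/s back to raw age
    poly = Polynomial(coef_u, domain=[m - s, m + s], window=[-1.0, 1.0])
    raw = poly.convert().coef
    coefficients = np.zeros(_DEGREE + 1)
    coefficients[:raw.size] = raw

    ss_tot = float(((y - y.mean()) ** 2).sum())
    ss_res = float((residual ** 2).sum())
    r2 = 1.0 - ss_res / ss_tot if ss_tot > 0 else np.nan
    return AgeDecomposition(coefficients, fitted, residual, r2)


def decompose_table(table: RegionalMeasureTable, subject
                    ) -> tuple[RegionalMeasureTable, RegionalMeasureTable]:
    """Apply the cubic age fit to every ROI of one subject's table.

    Returns (fitted_table, residual_table), both aligned session-for-session
    with the input; fitted + residual equals the input element-wise. ROI
    fits are independent — dropping one ROI never changes another's
    decomposition. Per-ROI failures are collected and reported together.
    """
    sub = table.for_subject(subject)
    X = sub.values()
    ages = sub.ages()
    fitted = np.empty_like(X)
    residual = np.empty_like(X)
    errors = {}
    for j, name in enumerate(sub.roi_names):
        try:
            dec = fit_cubic_age(X[:, j], ages)
        except ValueError as e:
            errors[name] = str(e)
            continue
        res = dec.residual
        # a residual at solver precision is an exact fit: make it exactly
        # zero so downstream correlation flags it as degenerate instead of
        # correlating floating-point noise
        if np.max(np.abs(res)) < 1e-10 * max(1.0, np.max(np.abs(X[:, j]))):
            res = np.zeros_like(res)
        residual[:, j] = res
        fitted[:, j] = X[:, j] - res
    if errors:
        raise ValueError(
            f"cubic age fit failed for {len(errors)} ROI(s): {errors}")
    return sub.with_values(fitted), sub.with_values(residual)


def age_component_matrices(table: RegionalMeasureTable, subject
                           ) -> dict[str, ConnMatrix]:
    """Across-session correlation matrices of the raw, fitted-age and
    residual series for one subject.

    Degenerate series (e.g. residuals of noise-free cubic data, which have
    zero variance) appear as flagged NaN rows, not as failures.
    """
    fitted_t, residual_t = decompose_table(table, subject)
    out = {}
    for mode, t in (("raw", table.for_subject(subject)),
                    ("age-fitted", fitted_t),
                    ("residual", residual_t)):
        cm = corr_across_sessions(t, subject)
        cm.provenance["mode"] = mode
        out[mode] = cm
    return out
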