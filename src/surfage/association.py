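"""Per-unit age-thickness association, variability (CV) maps, and normalized
residual fields.

A "unit" is a vertex for vertexwise analysis or a parcel after parcel
averaging. Association is the Pearson correlation of thickness with
chronological age per unit, with a Bonferroni threshold over the units tested
at that level. The normalized residuals of the per-unit linear age model are
the field whose spatial roughness the resel module measures.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats

__all__ = [
    "AssociationMap",
    "VariabilityMap",
    "ResidualField",
    "fit_age_association",
    "compute_cv",
    "residual_field",
    "median_r2",
]


@dataclass
class AssociationMap:
    """Per-unit Pearson r, r^2, t, and two-sided p with Bonferroni control."""

    r: np.ndarray
    t: np.ndarray
    p: np.ndarray
    n: int
    alpha: float
    degenerate: np.ndarray  # zero-variance units: r set to 0, never significant

    @property
    def r2(self) -> np.ndarray:
        return self.r**2

    @property
    def m(self) -> int:
        return self.r.size

    @property
    def bonferroni_alpha(self) -> float:
        return self.alpha / self.m

    @property
    def significant(self) -> np.ndarray:
        return (self.p < self.bonferroni_alpha) & ~self.degenerate


@dataclass
class VariabilityMap:
    """Cross-subject mean, SD (n-1 denominator) and CV = sigma/mu per unit."""

    mu: np.ndarray
    sigma: np.ndarray
    cv: np.ndarray
    cv_undefined: np.ndarray  # mu <= 0


@dataclass
class ResidualField:
    """Unit-norm residuals of the per-vertex linear age model (subjects x V).

    Each non-degenerate column has unit sum of squares and is orthogonal to
    the intercept and to age; degenerate (perfect-fit) columns are zero and
    flagged.
    """

    residuals: np.ndarray  # (n_subjects, V)
    degenerate: np.ndarray  # (V,) bool
    model: str = "thickness ~ 1 + age"


def fit_age_association(
    values: np.ndarray, ages: np.ndarray, alpha: float = 0.05
) -> AssociationMap:
    """Pearson correlation of each unit with age, t statistic and two-sided p.

    t = r * sqrt((n-2) / (1-r^2)) with n-2 degrees of freedom. Units with zero
    thickness variance are flagged degenerate and given r = 0.
    """
    values = np.asarray(values, dtype=np.float64)
    ages = np.asarray(ages, dtype=np.float64)
    n = ages.size
    if n < 4:
        raise ValueError("need at least 4 subjects")
    if np.ptp(ages) == 0:
        raise ValueError("ages are constant; association is undefined")
    xc = ages - ages.mean()
    yc = values - values.mean(axis=0)
    denom = np.sqrt((xc**2).sum() * (yc**2).sum(axis=0))
    degenerate = denom == 0
    with np.errstate(invalid="ignore", divide="ignore"):
        r = np.where(degenerate, 0.0, (xc @ yc) / np.where(degenerate, 1.0, denom))
    r = np.clip(r, -1.0, 1.0)
    with np.errstate(divide="ignore"):
        t = r * np.sqrt((n - 2) / np.maximum(1e-300, 1.0 - r**2))
    p = 2.0 * stats.t.sf(np.abs(t), df=n - 2)
    p = np.where(degenerate, 1.0, p)
    return AssociationMap(r=r, t=t, p=p, n=n, alpha=alpha, degenerate=degenerate)


def compute_cv(values: np.ndarray) -> VariabilityMap:
    """Cross-subject mean, sample SD, and coefficient of variation per unit."""
    values = np.asarray(values, dtype=np.float64)
    if values.shape[0] < 2:
        raise ValueError("need at least 2 subjects")
    mu = values.mean(axis=0)
    sigma = values.std(axis=0, ddof=1)
    undefined = mu <= 0
    with np.errstate(divide="ignore", invalid="ignore"):
        cv = np.where(undefined, np.nan, sigma / np.where(undefined, 1.0, mu))
    return VariabilityMap(mu=mu, sigma=sigma, cv=cv, cv_undefined=undefined)


def residual_field(vertex_values: np.ndarray, ages: np.ndarray) -> ResidualField:
    """Unit-normalized residuals of the per-vertex OLS fit on (intercept, age)."""
    values = np.asarray(vertex_values, dtype=np.float64)
    ages = np.asarray(ages, dtype=np.float64)
    n = ages.size
    if n < 4:
        raise ValueError("need at least 4 subjects")
    X = np.column_stack([np.ones(n), ages])
    coef, *_ = np.linalg.lstsq(X, values, rcond=None)
    resid = values - X @ coef
    ss = np.sqrt((resid**2).sum(axis=0))
    degenerate = ss <= 1e-12 * max(1.0, float(np.abs(values).max()))
    resid = np.where(degenerate[None, :], 0.0, resid / np.where(degenerate, 1.0, ss))
    return ResidualField(residuals=resid, degenerate=degenerate)


def median_r2(assoc: AssociationMap) -> float:
    """Median per-unit r^2 over non-degenerate units."""
    keep = ~assoc.degenerate
    if not keep.any():
        raise ValueError("all units are degenerate")
    return float(np.median(assoc.r2[keep]))
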