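"""Single-marker additive + dominance decomposition (Falconer-Mackay).

Genotype dosages 0/1/2 of a counted allele at frequency ``p`` are re-coded
into an additive regressor ``m`` taking values ``0-2p, 1-2p, 2-2p`` and a
dominance regressor ``w`` taking ``-2p^2, 2pq, -2q^2`` (``q = 1 - p``).  Under
exact Hardy-Weinberg genotype counts these two regressors are uncorrelated,
so the allele-substitution effect ``alpha`` and the dominance deviation ``d``
can be estimated simultaneously without collinearity.  The additive genotypic
value is recovered as ``a = alpha - (q - p) d`` and the model R^2 serves as a
proxy for the fraction of phenotypic variance explained by the marker.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats

from .types import PhenotypeVector

__all__ = [
    "DominanceCoding",
    "DominanceFit",
    "orthogonal_codes",
    "fit_additive_dominance",
    "allele_substitution",
]


@dataclass
class DominanceCoding:
    """Orthogonal additive (m) and dominance (w) codes for one marker."""

    p: float
    m: np.ndarray
    w: np.ndarray

    @property
    def q(self) -> float:
        return 1.0 - self.p


@dataclass
class DominanceFit:
    """OLS estimates of the additive + dominance model at one marker."""

    mu: float
    alpha: float
    alpha_se: float
    alpha_p: float
    d: float
    d_se: float
    d_p: float
    r2: float
    n: int
    p_allele: float

    @property
    def a(self) -> float:
        """Additive genotypic value, alpha - (q - p) d."""
        if np.isnan(self.d):
            return np.nan
        q = 1.0 - self.p_allele
        return self.alpha - (q - self.p_allele) * self.d


def orthogonal_codes(dosages, p: float) -> DominanceCoding:
    """Re-code 0/1/2 dosages into orthogonal additive/dominance regressors.

    ``p`` is the frequency of the counted allele (the caller may pass the
    sample frequency).  Missing dosages are rejected; impute first.
    """
    if not 0.0 < p < 1.0:
        raise ValueError("allele frequency must be in (0, 1)")
    dosages = np.asarray(dosages, dtype=float)
    if np.any(np.isnan(dosages)):
        raise ValueError("missing dosages; impute before coding")
    if not np.all(np.isin(dosages, (0.0, 1.0, 2.0))):
        raise ValueError("dosages must be 0, 1 or 2")
    q = 1.0 - p
    g = dosages.astype(int)
    m = np.array([0.0 - 2 * p, 1.0 - 2 * p, 2.0 - 2 * p])[g]
    w = np.array([-2 * p * p, 2 * p * q, -2 * q * q])[g]
    return DominanceCoding(p=p, m=m, w=w)


def allele_substitution(a: float, d: float, p: float) -> float:
    """Allele-substitution effect ``alpha = a + (q - p) d``."""
    if not 0.0 < p < 1.0:
        raise ValueError("allele frequency must be in (0, 1)")
    q = 1.0 - p
    return a + (q - p) * d


def fit_additive_dominance(
    y: PhenotypeVector | np.ndarray,
    dosages,
    p: float | None = None,
) -> DominanceFit:
    """OLS fit of phenotype on [1, m, w] at a single marker.

    ``p`` defaults to the sample frequency of the counted allele.  Standard
    errors and two-sided p-values follow classical OLS theory (t reference
    with n - k degrees of freedom).  When fewer than three genotype classes
    are present the dominance deviation is not estimable: ``d`` is reported
    as NaN and the model reduces to the additive regression.
    """
    yv = y.scores if isinstance(y, PhenotypeVector) else np.asarray(y, dtype=float)
    dosages = np.asarray(dosages, dtype=float)
    if yv.shape[0] != dosages.shape[0]:
        raise ValueError("phenotype and dosage lengths differ")
    if p is None:
        p = float(np.mean(dosages) / 2.0)
    classes = np.unique(dosages)
    coding = orthogonal_codes(dosages, p)
    n = yv.shape[0]
    if classes.size >= 3:
        X = np.column_stack([np.ones(n), coding.m, coding.w])
    else:
        X = np.column_stack([np.ones(n), coding.m])
    k = X.shape[1]
    XtX = X.T @ X
    beta = np.linalg.solve(XtX, X.T @ yv)
    resid = yv - X @ beta
    dof = n - k
    if dof <= 0:
        raise ValueError("not enough observations for the model")
    sigma2 = float(resid @ resid) / dof
    cov = sigma2 * np.linalg.inv(XtX)
    se = np.sqrt(np.diag(cov))
    tvals = beta / se
    pvals = 2.0 * stats.t.sf(np.abs(tvals), dof)
    ss_tot = float(np.sum((yv - yv.mean()) ** 2))
    r2 = 1.0 - float(resid @ resid) / ss_tot if ss_tot > 0 else 0.0
    if classes.size >= 3:
        d, d_se, d_p = beta[2], se[2], pvals[2]
    else:
        d, d_se, d_p = np.nan, np.nan, np.nan
    return DominanceFit(
        mu=float(beta[0]),
        alpha=float(beta[1]),
        alpha_se=float(se[1]),
        alpha_p=float(pvals[1]),
        d=float(d),
        d_se=float(d_se),
        d_p=float(d_p),
        r2=r2,
        n=n,
        p_allele=p,
    )
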