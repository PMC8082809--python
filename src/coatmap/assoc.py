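"""Marker QC, genomic relationships and mixed-linear-model association.

The scan follows the MLMA-LOCO scheme: for each chromosome a genomic
relationship matrix (GRM) is built from all *other* chromosomes, variance
components are estimated once by REML on that leave-one-chromosome-out GRM,
and every marker on the excluded chromosome is tested by generalized least
squares with covariance ``sigma2_g * G_loco + sigma2_e * I``.  Leaving the
tested chromosome out of the GRM prevents the marker's own effect from being
absorbed by the polygenic term (proximal contamination).

The GRM is the frequency-standardized (VanRaden) form: dosages are centered
at ``2 p_j`` and scaled by ``sqrt(2 p_j q_j)`` per marker, and the
cross-product is averaged over markers, so the diagonal is ~1 in expectation
under Hardy-Weinberg.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import optimize, stats

from .types import GenotypeMatrix, PhenotypeVector

__all__ = [
    "GRM",
    "VarianceComponents",
    "AssocResult",
    "qc_filter",
    "compute_grm",
    "fit_variance_components",
    "mlma_scan",
    "conditional_scan",
    "inflation_factor",
]


class EmptyAfterQCError(ValueError):
    """Raised when marker QC removes every marker."""


@dataclass
class GRM:
    """Genomic relationship matrix with its sample ids and marker count."""

    values: np.ndarray
    samples: list[str]
    n_markers: int
    excluded_chrom: str | None = None


@dataclass
class VarianceComponents:
    """REML variance estimates on one GRM."""

    sigma2_g: float
    sigma2_e: float
    loglik: float
    converged: bool = True
    boundary: bool = False
    note: str = ""

    @property
    def h2(self) -> float:
        tot = self.sigma2_g + self.sigma2_e
        return self.sigma2_g / tot if tot > 0 else np.nan


@dataclass
class AssocResult:
    """Per-marker association statistics (NaN rows for untestable markers)."""

    table: pd.DataFrame  # chrom, pos, id, beta, se, chisq, p

    def top_hit(self) -> pd.Series:
        t = self.table.dropna(subset=["p"])
        if t.empty:
            raise ValueError("no testable markers")
        return t.loc[t["p"].idxmin()]


def qc_filter(
    geno: GenotypeMatrix,
    min_call_rate: float = 0.90,
    min_maf: float = 0.02,
) -> tuple[GenotypeMatrix, pd.DataFrame]:
    """Remove markers with call rate or MAF strictly below the thresholds.

    Thresholds are exclusive ("lower than"): a marker at exactly the
    threshold is kept.  Returns the filtered matrix and a per-marker report
    with the exclusion reason(s).
    """
    for t in (min_call_rate, min_maf):
        if not 0.0 <= t <= 1.0:
            raise ValueError("thresholds must lie in [0, 1]")
    cr = geno.call_rate()
    maf = geno.maf()
    low_cr = cr < min_call_rate
    low_maf = np.nan_to_num(maf, nan=0.0) < min_maf
    reasons = []
    for lc, lm in zip(low_cr, low_maf):
        if lc and lm:
            reasons.append("low_call_rate;low_maf")
        elif lc:
            reasons.append("low_call_rate")
        elif lm:
            reasons.append("low_maf")
        else:
            reasons.append("")
    report = pd.DataFrame(
        {
            "id": geno.markers["id"].to_numpy(),
            "call_rate": cr,
            "maf": maf,
            "excluded": low_cr | low_maf,
            "reason": reasons,
        }
    )
    keep = ~(low_cr | low_maf)
    if not keep.any():
        raise EmptyAfterQCError("no markers survive QC")
    return geno.subset_markers(keep), report


def _standardized_dosages(geno: GenotypeMatrix, mask: np.ndarray) -> np.ndarray:
    """Mean-imputed, centered, frequency-scaled dosage columns under mask."""
    X = geno.dosages[:, mask].copy()
    freq = np.nanmean(X, axis=0) / 2.0
    # mean-impute missing dosages at 2p
    nanmask = np.isnan(X)
    if nanmask.any():
        X[nanmask] = np.broadcast_to(2.0 * freq, X.shape)[nanmask]
    poly = (freq > 0.0) & (freq < 1.0)
    X = X[:, poly]
    freq = freq[poly]
    Z = (X - 2.0 * freq) / np.sqrt(2.0 * freq * (1.0 - freq))
    return Z


def compute_grm(geno: GenotypeMatrix, exclude_chrom: str | None = None) -> GRM:
    """Frequency-standardized GRM, optionally leaving one chromosome out."""
    if exclude_chrom is None:
        mask = np.ones(geno.n_markers, dtype=bool)
    else:
        mask = (geno.markers["chrom"] != str(exclude_chrom)).to_numpy()
    Z = _standardized_dosages(geno, mask)
    m_used = Z.shape[1]
    if m_used < 2:
        raise ValueError("need at least two polymorphic markers for a GRM")
    G = (Z @ Z.T) / m_used
    return GRM(values=G, samples=list(geno.samples), n_markers=m_used,
               excluded_chrom=exclude_chrom)


def _reml_profile(lam: float, d: np.ndarray, ystar: np.ndarray, Xstar: np.ndarray):
    """Restricted log-likelihood profiled over sigma2_e at ratio lam=g/e."""
    v = lam * d + 1.0
    w = 1.0 / v
    Xw = Xstar * w[:, None]
    XtWX = Xstar.T @ Xw
    XtWy = Xw.T @ ystar
    beta = np.linalg.solve(XtWX, XtWy)
    resid = ystar - Xstar @ beta
    rss = float(resid * w @ resid)
    n, p = Xstar.shape
    sigma2_e = rss / (n - p)
    sign, logdet_xwx = np.linalg.slogdet(XtWX)
    ll = -0.5 * (
        (n - p) * np.log(sigma2_e)
        + np.sum(np.log(v))
        + logdet_xwx
        + (n - p)
    )
    return ll, sigma2_e, beta


def fit_variance_components(
    y: PhenotypeVector | np.ndarray,
    grm: GRM,
    covariates: np.ndarray | None = None,
) -> VarianceComponents:
    """REML estimates of (sigma2_g, sigma2_e) on one GRM.

    Works in the GRM eigenbasis: with ``K = U D U'`` the rotated model has a
    diagonal covariance ``sigma2_g D + sigma2_e I``, so the restricted
    likelihood is a one-dimensional function of the variance ratio, maximized
    by bounded scalar search.  Boundary estimates (sigma2_g -> 0) are allowed
    and flagged.
    """
    yv = y.scores if isinstance(y, PhenotypeVector) else np.asarray(y, dtype=float)
    n = yv.shape[0]
    K = grm.values
    if K.shape != (n, n):
        raise ValueError("GRM size does not match phenotype length")
    if not np.allclose(K, K.T, atol=1e-8):
        raise ValueError("GRM must be symmetric")
    X = np.ones((n, 1)) if covariates is None else np.column_stack(
        [np.ones(n), covariates]
    )
    d, U = np.linalg.eigh(K)
    d = np.clip(d, 0.0, None)
    ystar = U.T @ yv
    Xstar = U.T @ X
    note = ""
    if np.ptp(d) < 1e-8:
        # K proportional to I: only the total variance is identifiable
        note = "GRM numerically proportional to identity; sigma2_g unidentifiable"

    def neg_ll(log_lam: float) -> float:
        return -_reml_profile(np.exp(log_lam), d, ystar, Xstar)[0]

    res = optimize.minimize_scalar(
        neg_ll, bounds=(np.log(1e-6), np.log(1e6)), method="bounded",
        options={"xatol": 1e-6},
    )
    lam = float(np.exp(res.x))
    ll, sigma2_e, _ = _reml_profile(lam, d, ystar, Xstar)
    boundary = lam <= 2e-6 or lam >= 5e5
    sigma2_g = 0.0 if lam <= 2e-6 else lam * sigma2_e
    return VarianceComponents(
        sigma2_g=sigma2_g,
        sigma2_e=sigma2_e,
        loglik=float(ll),
        converged=bool(res.success),
        boundary=boundary,
        note=note,
    )


def _gls_marker_tests(
    ystar: np.ndarray,
    Xstar: np.ndarray,
    Gstar: np.ndarray,
    w: np.ndarray,
    sigma2_e: float,
) -> tuple[np.ndarray, np.ndarray]:
    """Per-marker GLS effect and SE with rotated inputs and weights w=1/v."""
    m = Gstar.shape[1]
    betas = np.full(m, np.nan)
    ses = np.full(m, np.nan)
    for j in range(m):
        Xj = np.column_stack([Xstar, Gstar[:, j]])
        Xw = Xj * w[:, None]
        XtWX = Xj.T @ Xw
        try:
            if np.linalg.cond(XtWX) > 1e10:  # collinear with covariates
                continue
            cov = np.linalg.inv(XtWX)
        except np.linalg.LinAlgError:
            continue
        beta = cov @ (Xw.T @ ystar)
        var_b = sigma2_e * cov[-1, -1]
        if var_b <= 0 or not np.isfinite(var_b):
            continue
        betas[j] = beta[-1]
        ses[j] = np.sqrt(var_b)
    return betas, ses


def mlma_scan(
    y: PhenotypeVector | np.ndarray,
    geno: GenotypeMatrix,
    covariates: np.ndarray | None = None,
    loco: bool = True,
    grms: dict[str, GRM] | None = None,
    vcs: dict[str, VarianceComponents] | None = None,
) -> AssocResult:
    """Mixed-linear-model association scan with LOCO correction.

    For each chromosome the polygenic covariance uses a GRM built from the
    other chromosomes (``loco=True``); with ``loco=False`` a single
    whole-genome GRM is shared.  Variance components are estimated once per
    GRM, not per marker.  Monomorphic or missing-only markers yield NaN rows.
    Precomputed ``grms`` / ``vcs`` keyed by chromosome may be supplied.
    """
    yv = y.scores if isinstance(y, PhenotypeVector) else np.asarray(y, dtype=float)
    n = yv.shape[0]
    X = np.ones((n, 1)) if covariates is None else np.column_stack(
        [np.ones(n), covariates]
    )
    chroms = geno.markers["chrom"].to_numpy()
    out_beta = np.full(geno.n_markers, np.nan)
    out_se = np.full(geno.n_markers, np.nan)
    for chrom in pd.unique(chroms):
        key = str(chrom) if loco else "__all__"
        if grms is not None and key in grms:
            grm = grms[key]
        else:
            grm = compute_grm(geno, exclude_chrom=chrom if loco else None)
            if grms is not None:
                grms[key] = grm
        if vcs is not None and key in vcs:
            vc = vcs[key]
        else:
            vc = fit_variance_components(yv, grm, covariates=covariates)
            if vcs is not None:
                vcs[key] = vc
        d, U = np.linalg.eigh(grm.values)
        d = np.clip(d, 0.0, None)
        v = vc.sigma2_g * d + vc.sigma2_e
        w = 1.0 / v
        idx = np.flatnonzero(chroms == chrom)
        Gc = geno.dosages[:, idx].copy()
        freq = np.nanmean(Gc, axis=0) / 2.0
        nanmask = np.isnan(Gc)
        if nanmask.any():
            Gc[nanmask] = np.broadcast_to(2.0 * freq, Gc.shape)[nanmask]
        poly = np.nanstd(Gc, axis=0) > 0
        ystar = U.T @ yv
        Xstar = U.T @ X
        Gstar = U.T @ Gc[:, poly]
        # sigma2_e=1 trick: weights already absorb the full covariance
        betas, ses = _gls_marker_tests(ystar, Xstar, Gstar, w, sigma2_e=1.0)
        sub = idx[poly]
        out_beta[sub] = betas
        out_se[sub] = ses
    with np.errstate(invalid="ignore", divide="ignore"):
        chisq = (out_beta / out_se) ** 2
        pvals = stats.chi2.sf(chisq, df=1)
    table = pd.DataFrame(
        {
            "chrom": geno.markers["chrom"].to_numpy(),
            "pos": geno.markers["pos"].to_numpy(),
            "id": geno.markers["id"].to_numpy(),
            "beta": out_beta,
            "se": out_se,
            "chisq": chisq,
            "p": pvals,
        }
    )
    return AssocResult(table=table)


def conditional_scan(
    y: PhenotypeVector | np.ndarray,
    geno: GenotypeMatrix,
    fixed_marker: str,
    covariates: np.ndarray | None = None,
    loco: bool = True,
) -> AssocResult:
    """Re-scan with a marker's dosage as an extra fixed covariate.

    The conditioned marker itself is reported as NaN.  Markers collinear with
    the covariate set (e.g. in perfect LD with the fixed marker) come out as
    NaN with a warning.
    """
    j = geno.marker_index(fixed_marker)
    dose = geno.dosages[:, j].copy()
    f = np.nanmean(dose) / 2.0
    if not 0.0 < f < 1.0:
        raise ValueError(f"fixed marker {fixed_marker!r} is monomorphic")
    dose[np.isnan(dose)] = 2.0 * f
    cov = dose[:, None] if covariates is None else np.column_stack([covariates, dose])
    res = mlma_scan(y, geno, covariates=cov, loco=loco)
    res.table.loc[j, ["beta", "se", "chisq", "p"]] = np.nan
    n_na = int(res.table["p"].isna().sum())
    if n_na > 1:
        warnings.warn(
            f"{n_na - 1} marker(s) untestable after conditioning (collinearity"
            " or monomorphism)",
            stacklevel=2,
        )
    return res


def inflation_factor(chisq) -> float:
    """Genomic inflation: through-origin regression of observed on expected
    1-df chi-square quantiles.

    Returns the slope, so lambda of ``c * chi2`` draws is ``c`` and a
    well-calibrated null scan gives ~1.
    """
    obs = np.sort(np.asarray(chisq, dtype=float))
    obs = obs[np.isfinite(obs)]
    if obs.size < 2:
        raise ValueError("need at least two finite statistics")
    if np.all(obs == 0.0):
        raise ValueError("all statistics are zero")
    k = obs.size
    theo = stats.chi2.ppf((np.arange(1, k + 1) - 0.5) / k, df=1)
    return float(obs @ theo / (theo @ theo))
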