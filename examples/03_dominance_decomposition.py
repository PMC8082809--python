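"""Additive + dominance decomposition at a single marker.

Re-codes 0/1/2 dosages into orthogonal regressors (m for the allele count,
w for dominance), fits y ~ mu + m*alpha + w*d by OLS and recovers the
additive genotypic value a = alpha - (q-p)d.  Under exact Hardy-Weinberg
counts cov(m, w) = 0, so both effects are estimated without collinearity.
"""

import numpy as np

from coatmap import qtl_effects as qe

rng = np.random.default_rng(3)
n, p = 432, 0.481
dosages = (rng.random((n, 2)) < p).sum(axis=1).astype(float)
codes = qe.orthogonal_codes(dosages, float(dosages.mean() / 2))
y = codes.m * 0.702 + codes.w * (-0.467) + rng.normal(0, np.sqrt(0.344), n)

fit = qe.fit_additive_dominance(y, dosages)
print(f"alpha = {fit.alpha:.3f} +- {fit.alpha_se:.3f} (p = {fit.alpha_p:.2e})")
print(f"d     = {fit.d:.3f} +- {fit.d_se:.3f} (p = {fit.d_p:.2e})")
print(f"a     = {fit.a:.4f} (derived: alpha - (q-p)d)")
print(f"R^2   = {100 * fit.r2:.1f}%  <- proxy for variance explained by the marker")
# Generated with alpha=0.702, d=-0.467, residual variance 0.344: the marker
# explains ~46.6% of the phenotypic variance in expectation.
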