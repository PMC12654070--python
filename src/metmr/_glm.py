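"""Minimal logistic-regression fits on genotype-aggregated case counts.

A per-variant GWAS logistic regression of disease status on allele dosage
depends on the data only through the 3 × 2 table of (genotype, case) counts,
so fits here take ``n_by_g`` and ``cases_by_g`` arrays with trailing
dimension 3 (dosages 0, 1, 2) and run a vectorized Newton–Raphson over any
number of leading replicate dimensions.  Degenerate tables (no cases, all
cases, or a monomorphic genotype) return NaN rather than raising.
"""

from __future__ import annotations

import numpy as np
from scipy import special, stats

_G = np.array([0.0, 1.0, 2.0])


def fit_logistic_counts(n_by_g, cases_by_g, max_iter: int = 40, tol: float = 1e-10):
    """Fit logit P(D=1) = a + b·g by maximum likelihood.

    Parameters
    ----------
    n_by_g, cases_by_g
        Arrays of shape ``(..., 3)``: individuals and cases per dosage.

    Returns
    -------
    dict with arrays ``beta``, ``se``, ``pval``, ``intercept``, ``converged``
    of shape ``(...)``.  NaN where the MLE is degenerate or Newton failed.
    """
    n = np.asarray(n_by_g, dtype=float)
    y = np.asarray(cases_by_g, dtype=float)
    if n.shape[-1] != 3 or y.shape[-1] != 3:
        raise ValueError("expected trailing dimension 3 (dosages 0, 1, 2)")

    total = n.sum(axis=-1)
    cases = y.sum(axis=-1)
    # dosage variance must be positive and cases strictly interior
    mean_g = (n * _G).sum(axis=-1) / np.maximum(total, 1.0)
    var_g = (n * _G**2).sum(axis=-1) / np.maximum(total, 1.0) - mean_g**2
    ok = (cases > 0) & (cases < total) & (var_g > 0)

    frac = np.clip(np.where(ok, cases / np.maximum(total, 1.0), 0.5), 1e-12, 1 - 1e-12)
    a = special.logit(frac)
    b = np.zeros_like(a)

    converged = np.zeros(a.shape, dtype=bool)
    for _ in range(max_iter):
        eta = a[..., None] + b[..., None] * _G
        mu = special.expit(eta)
        w = n * mu * (1.0 - mu)
        u0 = (y - n * mu).sum(axis=-1)
        u1 = ((y - n * mu) * _G).sum(axis=-1)
        i00 = w.sum(axis=-1)
        i01 = (w * _G).sum(axis=-1)
        i11 = (w * _G**2).sum(axis=-1)
        det = i00 * i11 - i01 * i01
        safe = ok & (det > 1e-300)
        det = np.where(safe, det, 1.0)
        da = (i11 * u0 - i01 * u1) / det
        db = (i00 * u1 - i01 * u0) / det
        da = np.where(safe, da, 0.0)
        db = np.where(safe, db, 0.0)
        # damp huge steps (separation drift)
        step = np.maximum(np.abs(da), np.abs(db))
        scale = np.where(step > 10.0, 10.0 / np.maximum(step, 1e-300), 1.0)
        a = a + da * scale
        b = b + db * scale
        converged = safe & (np.maximum(np.abs(da), np.abs(db)) < tol)
        if converged.all():
            break

    eta = a[..., None] + b[..., None] * _G
    mu = special.expit(eta)
    w = n * mu * (1.0 - mu)
    i00 = w.sum(axis=-1)
    i01 = (w * _G).sum(axis=-1)
    i11 = (w * _G**2).sum(axis=-1)
    det = i00 * i11 - i01 * i01
    good = ok & converged & (det > 1e-300)
    with np.errstate(divide="ignore", invalid="ignore"):
        se = np.sqrt(np.where(good, i00 / np.where(det > 0, det, 1.0), np.nan))
    beta = np.where(good, b, np.nan)
    intercept = np.where(good, a, np.nan)
    pval = 2.0 * stats.norm.sf(np.abs(beta) / se)
    return {
        "beta": beta,
        "se": se,
        "pval": pval,
        "intercept": intercept,
        "converged": good,
    }


def ols_sufficient(n_by_g, sum_x_by_g, ss_within_by_g):
    """OLS of an SD-standardized trait on dosage from per-genotype sums.

    Given per-dosage counts, trait sums, and within-group sums of squares
    (about the group mean), returns the slope, SE, two-sided normal p and
    the sample SD used for standardization.  Shapes ``(..., 3) -> (...)``.
    """
    n_g = np.asarray(n_by_g, dtype=float)
    s_g = np.asarray(sum_x_by_g, dtype=float)
    ss_g = np.asarray(ss_within_by_g, dtype=float)
    n = n_g.sum(axis=-1)
    sum_x = s_g.sum(axis=-1)
    with np.errstate(divide="ignore", invalid="ignore"):
        sum_x2 = (ss_g + np.where(n_g > 0, s_g**2 / np.maximum(n_g, 1.0), 0.0)).sum(
            axis=-1
        )
    sum_g = (n_g * _G).sum(axis=-1)
    sum_g2 = (n_g * _G**2).sum(axis=-1)
    sum_gx = (s_g * _G).sum(axis=-1)
    sxx = sum_g2 - sum_g**2 / n
    sxy = sum_gx - sum_g * sum_x / n
    syy = sum_x2 - sum_x**2 / n
    slope = sxy / sxx
    rss = syy - slope * sxy
    sigma2 = rss / (n - 2.0)
    se = np.sqrt(sigma2 / sxx)
    sd = np.sqrt(syy / (n - 1.0))
    beta = slope / sd
    se_std = se / sd
    pval = 2.0 * stats.norm.sf(np.abs(beta) / se_std)
    return {"beta": beta, "se": se_std, "pval": pval, "sd": sd}
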