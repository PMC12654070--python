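"""Wald-ratio causal estimation and significance tiering.

With a single instrument the causal effect of a 1-SD higher exposure on the
log-odds of disease is estimated by the Wald ratio β_MR = β_Y / β_X.  The
default standard error is the first-order delta approximation
SE = SE_Y / |β_X| (the conventional single-SNV implementation); the
second-order form sqrt(SE_Y²/β_X² + β_Y²·SE_X²/β_X⁴) additionally propagates
exposure-side noise and is always at least as large.  Inference uses the
standard-normal reference (summary-statistic asymptotics; cohorts ≫ 1000).

Estimates are reported as odds ratios per 1-SD genetically predicted
metabolite level, with Wald confidence intervals symmetric on the log scale.
Multiplicity is controlled by Bonferroni within outcome family: significant
below α / n_tests, suggestive below α, null otherwise.

:func:`ci_consistency` checks printed (OR, CI) triples: since the Wald CI is
symmetric on the log scale, the implied OR is the geometric mean
sqrt(CI_low · CI_high) and the implied SE is (ln CI_high − ln CI_low)/(2z).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats

TIER_SIGNIFICANT = "significant"
TIER_SUGGESTIVE = "suggestive"
TIER_NULL = "null"

FIRST_ORDER = "first_order"
SECOND_ORDER = "second_order"


@dataclass(frozen=True)
class MultiplicityConfig:
    """Bonferroni-within-outcome multiplicity control.

    ``n_tests`` is the number of metabolites actually tested for the outcome
    (83 in the published screen), recomputed from the data rather than
    hard-coded.
    """

    n_tests: int
    alpha: float = 0.05

    def __post_init__(self) -> None:
        if self.n_tests < 1:
            raise ValueError("n_tests must be >= 1")
        if not 0.0 < self.alpha < 1.0:
            raise ValueError("alpha must be in (0, 1)")

    @property
    def bonferroni_threshold(self) -> float:
        return self.alpha / self.n_tests

    @property
    def suggestive_threshold(self) -> float:
        return self.alpha


def wald_ratio(bx, se_x, by, se_y, se_method: str = FIRST_ORDER):
    """Wald-ratio point estimate and SE; accepts scalars or arrays.

    Raises on a zero exposure effect (undefined/weak instrument).
    """
    bx = np.asarray(bx, dtype=float)
    se_x = np.asarray(se_x, dtype=float)
    by = np.asarray(by, dtype=float)
    se_y = np.asarray(se_y, dtype=float)
    if np.any(bx == 0):
        raise ValueError("wald_ratio undefined for bx = 0")
    if np.any(se_x <= 0) or np.any(se_y <= 0):
        raise ValueError("standard errors must be positive")
    beta_mr = by / bx
    if se_method == FIRST_ORDER:
        se_mr = se_y / np.abs(bx)
    elif se_method == SECOND_ORDER:
        se_mr = np.sqrt(se_y**2 / bx**2 + by**2 * se_x**2 / bx**4)
    else:
        raise ValueError(f"unknown se_method: {se_method!r}")
    if beta_mr.ndim == 0:
        return float(beta_mr), float(se_mr)
    return beta_mr, se_mr


def to_odds_ratio(beta_mr, se_mr, level: float = 0.95):
    """Exponentiate a log-odds estimate to (OR, CI_low, CI_high, p).

    CI bounds are exp(β ± z·SE) with z the standard-normal quantile at
    (1 + level)/2; the p-value is the two-sided normal tail of |β|/SE.
    """
    beta_mr = np.asarray(beta_mr, dtype=float)
    se_mr = np.asarray(se_mr, dtype=float)
    if np.any(se_mr <= 0):
        raise ValueError("se_mr must be positive")
    z = stats.norm.ppf(0.5 + level / 2.0)
    or_ = np.exp(beta_mr)
    ci_low = np.exp(beta_mr - z * se_mr)
    ci_high = np.exp(beta_mr + z * se_mr)
    pval = 2.0 * stats.norm.sf(np.abs(beta_mr) / se_mr)
    if or_.ndim == 0:
        return float(or_), float(ci_low), float(ci_high), float(pval)
    return or_, ci_low, ci_high, pval


def classify_significance(pval: float, cfg: MultiplicityConfig) -> str:
    """Tier a p-value: significant / suggestive / null."""
    if not 0.0 < pval <= 1.0:
        raise ValueError(f"pval out of range: {pval}")
    if pval < cfg.bonferroni_threshold:
        return TIER_SIGNIFICANT
    if pval < cfg.suggestive_threshold:
        return TIER_SUGGESTIVE
    return TIER_NULL


@dataclass
class MRResult:
    """Wald-ratio estimate for one metabolite × outcome pair."""

    metabolite_id: str
    outcome_id: str
    rsid: str
    beta_mr: float
    se_mr: float
    or_: float
    ci_low: float
    ci_high: float
    pval: float
    tier: str
    gene: str = ""
    r2: float = float("nan")
    f_stat: float = float("nan")
    proxy_rsid: str | None = None
    proxy_r2: float | None = None
    method: str = "wald_ratio"
    se_method: str = FIRST_ORDER

    def to_row(self) -> dict:
        return {
            "metabolite": self.metabolite_id,
            "outcome": self.outcome_id,
            "rsid": self.rsid,
            "gene": self.gene,
            "beta": self.beta_mr,
            "se": self.se_mr,
            "OR": self.or_,
            "CI_low": self.ci_low,
            "CI_high": self.ci_high,
            "pval": self.pval,
            "tier": self.tier,
            "n_snv": 1,
            "R2": self.r2,
            "F": self.f_stat,
            "proxy_rsid": self.proxy_rsid,
            "proxy_r2": self.proxy_r2,
        }


def estimate_pair(
    pair,
    sentinel,
    outcome_id: str,
    cfg: MultiplicityConfig,
    se_method: str = FIRST_ORDER,
    level: float = 0.95,
) -> MRResult:
    """Build an MRResult from a harmonized pair and its sentinel instrument."""
    exp, out = pair.exposure, pair.outcome
    beta_mr, se_mr = wald_ratio(exp.beta, exp.se, out.beta, out.se, se_method)
    or_, lo, hi, pval = to_odds_ratio(beta_mr, se_mr, level)
    return MRResult(
        metabolite_id=sentinel.metabolite_id,
        outcome_id=outcome_id,
        rsid=sentinel.rsid,
        beta_mr=beta_mr,
        se_mr=se_mr,
        or_=or_,
        ci_low=lo,
        ci_high=hi,
        pval=pval,
        tier=classify_significance(pval, cfg),
        gene=sentinel.effector_gene,
        r2=sentinel.r2,
        f_stat=sentinel.f_stat,
        proxy_rsid=sentinel.proxy_rsid,
        proxy_r2=sentinel.proxy_r2,
        se_method=se_method,
    )


@dataclass(frozen=True)
class CIConsistency:
    """Diagnostics recovered from a printed (OR, CI_low, CI_high) triple."""

    or_printed: float
    implied_or: float
    implied_beta: float
    implied_se: float
    implied_pval: float
    ok: bool


def ci_consistency(
    or_printed: float,
    ci_low: float,
    ci_high: float,
    level: float = 0.95,
    or_tol: float = 0.005,
) -> CIConsistency:
    """Check a printed OR against its CI under log-scale Wald symmetry.

    The implied OR is the geometric mean of the bounds; the check passes if
    it agrees with the printed OR to within ``or_tol`` (two-decimal rounding
    by default).
    """
    if not 0.0 < ci_low < ci_high:
        raise ValueError("require 0 < ci_low < ci_high")
    z = stats.norm.ppf(0.5 + level / 2.0)
    implied_or = float(np.sqrt(ci_low * ci_high))
    implied_beta = float(np.log(implied_or))
    implied_se = float((np.log(ci_high) - np.log(ci_low)) / (2.0 * z))
    implied_pval = float(2.0 * stats.norm.sf(abs(implied_beta) / implied_se))
    return CIConsistency(
        or_printed=float(or_printed),
        implied_or=implied_or,
        implied_beta=implied_beta,
        implied_se=implied_se,
        implied_pval=implied_pval,
        ok=abs(implied_or - or_printed) <= or_tol,
    )
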