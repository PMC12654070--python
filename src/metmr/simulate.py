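"""Synthetic GWAS summary statistics with known causal ground truth.

The generator emulates the statistical structure the screen assumes:

* biallelic variants in Hardy–Weinberg proportions;
* an SD-scaled quantitative exposure with a single strong cis variant per
  metabolite (X = β_gx·G + ε, ε standard normal, standardized before
  regression);
* a rare binary outcome generated from the exposure through a logistic link,
  logit P(D=1) = α + θ·X + δ·G, with the intercept α solved so the expected
  case count matches the target case–control ratio (δ is a direct
  genotype→outcome path: pleiotropic contamination, 0 in the clean world);
* two non-overlapping cohorts (exposure and outcome genotypes are drawn
  independently), so the two-sample design holds by construction;
* optional palindromic alleles, sentinels missing from the outcome file with
  LD proxies, and annotation contamination.

Two equivalent simulation routes are provided.  ``simulate_pair`` draws
individual-level genotypes and phenotypes and regresses on them.
``simulate_summary`` draws the *sufficient statistics* of those same
regressions from their exact finite-sample distributions (per-genotype
counts are multinomial; per-genotype trait sums are normal and within-group
sums of squares are χ², independent by normal theory; per-genotype case
counts are binomial with the genotype-conditional risk obtained by
Gauss–Hermite integration over the residual).  Both routes induce the same
joint distribution of the emitted (beta, SE, p, EAF) — the estimators depend
on the data only through these statistics — and the fast route makes
replicate-heavy recovery and calibration experiments run in seconds.

The estimand caveat: a Wald ratio on a logistic-scale outcome targets the
conditional log-OR per 1-SD exposure, which differs slightly from θ under
non-collapsibility.  Recovery experiments therefore benchmark against a
logistic-regression oracle of D on X at n = 10⁶ (fit with statsmodels — an
independent code path from the package's own count-table Newton solver),
and report the θ-vs-oracle discrepancy rather than hiding it.
"""

from __future__ import annotations

import dataclasses
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import optimize, special, stats

from metmr import gwas_io, mr, reference
from metmr._glm import fit_logistic_counts, ols_sufficient
from metmr.gwas_io import (
    EXPOSURE_QUANTITATIVE,
    OUTCOME_BINARY,
    AssociationRecord,
    SummaryTable,
)
from metmr.instruments import LDTable, AnnotationTable

_GH_NODES, _GH_WEIGHTS = np.polynomial.hermite_e.hermegauss(41)
_GH_WEIGHTS = _GH_WEIGHTS / np.sqrt(2.0 * np.pi)

#: non-palindromic allele pairs used for synthetic variants
_NONPAL_PAIRS = (("A", "G"), ("A", "C"), ("T", "G"), ("T", "C"), ("G", "A"), ("C", "A"))
_PAL_PAIRS = (("A", "T"), ("T", "A"), ("C", "G"), ("G", "C"))


def child_seed(master_seed: int, index: int) -> int:
    """Deterministic per-metabolite seed (fixed arithmetic, < 2³¹)."""
    return (1_000_003 * int(master_seed) + 7_919 * int(index) + 12_345) % (2**31 - 1)


@dataclass(frozen=True)
class SimTruth:
    """Ground-truth parameters of one synthetic metabolite scenario."""

    metabolite_id: str
    rsid: str
    maf: float
    beta_gx: float  # genotype -> exposure effect, raw (pre-standardization) scale
    theta: float  # causal log-OR of a 1-SD exposure shift on disease
    n_exp: int = reference.EXPOSURE_N
    n_out: int = 50_000
    n_cases: int = 100
    seed: int = 0
    pleiotropy_delta: float = 0.0
    effect_allele: str = "A"
    other_allele: str = "G"
    chrom: str = "1"
    pos: int = 1_000_000
    gene: str = ""

    def __post_init__(self) -> None:
        if not 0.0 < self.maf <= 0.5:
            raise ValueError(f"maf must be in (0, 0.5]: {self.maf}")
        if not 0 < self.n_cases < self.n_out:
            raise ValueError("need 0 < n_cases < n_out")

    @property
    def case_fraction(self) -> float:
        return self.n_cases / self.n_out

    @property
    def exposure_sd(self) -> float:
        """Population SD of X = β_gx·G + ε."""
        return math.sqrt(self.beta_gx**2 * 2 * self.maf * (1 - self.maf) + 1.0)

    @property
    def r2(self) -> float:
        """Population variance explained by the variant (SD-scaled exposure)."""
        v = 2 * self.maf * (1 - self.maf)
        return v * self.beta_gx**2 / (v * self.beta_gx**2 + 1.0)

    @property
    def hwe_probs(self) -> np.ndarray:
        p = self.maf
        return np.array([(1 - p) ** 2, 2 * p * (1 - p), p**2])


def beta_gx_for_r2(r2: float, maf: float) -> float:
    """Raw genotype→exposure effect giving a target population R²."""
    if not 0.0 <= r2 < 1.0:
        raise ValueError("r2 must be in [0, 1)")
    v = 2 * maf * (1 - maf)
    return math.sqrt(r2 / (v * (1.0 - r2)))


def _genotype_risks(truth: SimTruth, alpha: float) -> np.ndarray:
    """P(D=1 | G=g), integrating the exposure residual by Gauss–Hermite."""
    g = np.arange(3.0)
    mean_x = truth.beta_gx * 2 * truth.maf
    x = (truth.beta_gx * g[:, None] + _GH_NODES[None, :] - mean_x) / truth.exposure_sd
    eta = alpha + truth.theta * x + truth.pleiotropy_delta * g[:, None]
    return special.expit(eta) @ _GH_WEIGHTS


def solve_intercept(truth: SimTruth) -> float:
    """Intercept α such that the expected case fraction equals n_cases/n_out."""
    target = truth.case_fraction

    def gap(alpha: float) -> float:
        return float(truth.hwe_probs @ _genotype_risks(truth, alpha)) - target

    lo, hi = -60.0, 20.0
    if gap(lo) > 0 or gap(hi) < 0:
        raise ValueError(f"unattainable case count {truth.n_cases} of {truth.n_out}")
    return float(optimize.brentq(gap, lo, hi, xtol=1e-12))


def _exposure_record(truth: SimTruth, bx: float, se: float, pval: float, eaf: float
                     ) -> AssociationRecord:
    return AssociationRecord(
        rsid=truth.rsid,
        effect_allele=truth.effect_allele,
        other_allele=truth.other_allele,
        beta=float(bx),
        se=float(se),
        pval=float(max(pval, 5e-324)),
        trait_id=truth.metabolite_id,
        chrom=truth.chrom,
        pos=truth.pos,
        eaf=float(eaf),
        n=truth.n_exp,
        gene=truth.gene or None,
    )


def _outcome_record(truth: SimTruth, outcome_id: str, by: float, se: float,
                    pval: float, eaf: float, n_cases: int) -> AssociationRecord:
    return AssociationRecord(
        rsid=truth.rsid,
        effect_allele=truth.effect_allele,
        other_allele=truth.other_allele,
        beta=float(by),
        se=float(se),
        pval=float(max(pval, 5e-324)),
        trait_id=outcome_id,
        chrom=truth.chrom,
        pos=truth.pos,
        eaf=float(eaf),
        n=truth.n_out,
        n_cases=int(n_cases),
    )


def simulate_exposure_cohort(
    truth: SimTruth, rng: np.random.Generator
) -> tuple[np.ndarray, np.ndarray]:
    """Individual-level exposure cohort: (genotypes, standardized trait)."""
    g = rng.binomial(2, truth.maf, truth.n_exp)
    x = truth.beta_gx * g + rng.standard_normal(truth.n_exp)
    x = (x - x.mean()) / x.std(ddof=1)
    return g, x


def simulate_exposure_record(
    truth: SimTruth, rng: np.random.Generator | None = None
) -> AssociationRecord:
    """Exposure-side summary association from an individual-level cohort."""
    rng = np.random.default_rng(truth.seed) if rng is None else rng
    g, x = simulate_exposure_cohort(truth, rng)
    n_g = np.bincount(g, minlength=3).astype(float)
    s_g = np.array([x[g == k].sum() for k in range(3)])
    ss_g = np.array(
        [((x[g == k] - x[g == k].mean()) ** 2).sum() if n_g[k] > 0 else 0.0
         for k in range(3)]
    )
    fit_x = ols_sufficient(n_g, s_g, ss_g)
    eaf_x = g.mean() / 2.0
    return _exposure_record(truth, fit_x["beta"], fit_x["se"], fit_x["pval"], eaf_x)


_MAX_REDRAWS = 50


def simulate_outcome_record(
    truth: SimTruth,
    outcome_id: str = "outcome",
    rng: np.random.Generator | None = None,
) -> AssociationRecord:
    """Outcome-side summary association from an individual-level cohort.

    A degenerate 3 × 2 table (e.g. no case carries the minor allele, which
    happens with appreciable probability at tiny case counts) leaves the
    per-variant logistic MLE undefined; such cohorts are redrawn, mimicking
    the minimum-count filters the source GWAS themselves apply.  Replicate
    experiments use :func:`simulate_summary` instead, which keeps degenerate
    fits as NaN and reports the effective replicate count.
    """
    rng = np.random.default_rng(truth.seed) if rng is None else rng
    alpha = solve_intercept(truth)
    mean_x = truth.beta_gx * 2 * truth.maf
    for _ in range(_MAX_REDRAWS):
        g2 = rng.binomial(2, truth.maf, truth.n_out)
        eps = rng.standard_normal(truth.n_out)
        x2 = (truth.beta_gx * g2 + eps - mean_x) / truth.exposure_sd
        prob = special.expit(alpha + truth.theta * x2 + truth.pleiotropy_delta * g2)
        d = rng.random(truth.n_out) < prob
        n_by_g = np.bincount(g2, minlength=3).astype(float)
        cases_by_g = np.bincount(g2, weights=d.astype(float), minlength=3)
        fit_y = fit_logistic_counts(n_by_g, cases_by_g)
        if bool(fit_y["converged"]):
            eaf_y = g2.mean() / 2.0
            return _outcome_record(
                truth, outcome_id, fit_y["beta"], fit_y["se"], fit_y["pval"],
                eaf_y, int(d.sum()),
            )
    raise RuntimeError(
        f"no defined per-variant fit in {_MAX_REDRAWS} cohorts for {truth.rsid}"
    )


def simulate_pair(
    truth: SimTruth,
    outcome_id: str = "outcome",
    rng: np.random.Generator | None = None,
) -> tuple[AssociationRecord, AssociationRecord]:
    """Simulate one (exposure, outcome) summary-association pair.

    Individual-level route: regresses on simulated genotypes and phenotypes
    in two independent, non-overlapping cohorts, so SEs, p-values and
    frequency noise carry their finite-sample behaviour.
    """
    rng = np.random.default_rng(truth.seed) if rng is None else rng
    exp_rec = simulate_exposure_record(truth, rng=rng)
    out_rec = simulate_outcome_record(truth, outcome_id, rng=rng)
    return exp_rec, out_rec


def simulate_summary(
    truth: SimTruth, replicates: int, rng: np.random.Generator | None = None
) -> dict[str, np.ndarray]:
    """Replicated summary statistics via exact sufficient-statistic sampling.

    Returns arrays of length ``replicates``: ``bx, se_x, px, eaf_x`` on the
    exposure side and ``by, se_y, py, eaf_y, n_cases`` on the outcome side.
    Distributionally identical to running :func:`simulate_pair`
    ``replicates`` times (see module docstring), but O(1) per replicate.
    """
    rng = np.random.default_rng(truth.seed) if rng is None else rng
    reps = int(replicates)

    # exposure: multinomial genotype counts; per-group normal sums and
    # chi-square within-group sums of squares (Cochran's theorem)
    n_g = rng.multinomial(truth.n_exp, truth.hwe_probs, size=reps).astype(float)
    mu_g = truth.beta_gx * np.arange(3.0)
    s_g = n_g * mu_g + np.sqrt(n_g) * rng.standard_normal((reps, 3))
    df = np.maximum(n_g - 1.0, 1.0)
    ss_g = np.where(n_g > 1, rng.chisquare(df), 0.0)
    fit_x = ols_sufficient(n_g, s_g, ss_g)
    eaf_x = (n_g[:, 1] + 2 * n_g[:, 2]) / (2.0 * truth.n_exp)

    # outcome: binomial case counts at the genotype-conditional risks
    alpha = solve_intercept(truth)
    risks = _genotype_risks(truth, alpha)
    n_g2 = rng.multinomial(truth.n_out, truth.hwe_probs, size=reps).astype(float)
    cases = rng.binomial(n_g2.astype(np.int64), risks[None, :]).astype(float)
    fit_y = fit_logistic_counts(n_g2, cases)
    eaf_y = (n_g2[:, 1] + 2 * n_g2[:, 2]) / (2.0 * truth.n_out)

    return {
        "bx": fit_x["beta"],
        "se_x": fit_x["se"],
        "px": fit_x["pval"],
        "eaf_x": eaf_x,
        "by": fit_y["beta"],
        "se_y": fit_y["se"],
        "py": fit_y["pval"],
        "eaf_y": eaf_y,
        "n_cases": cases.sum(axis=1),
    }


def conditional_logor_oracle(
    truth: SimTruth, n: int = 1_000_000, seed: int = 20_240_101
) -> float:
    """Benchmark estimand: conditional log-OR of D on X per 1-SD exposure.

    Fits a logistic regression of simulated disease status on the
    standardized exposure at large n using statsmodels — an independent
    route from the package's own genotype-count solver.
    """
    import statsmodels.api as sm

    rng = np.random.default_rng(seed)
    g = rng.binomial(2, truth.maf, n)
    eps = rng.standard_normal(n)
    mean_x = truth.beta_gx * 2 * truth.maf
    x = (truth.beta_gx * g + eps - mean_x) / truth.exposure_sd
    alpha = solve_intercept(truth)
    prob = special.expit(alpha + truth.theta * x + truth.pleiotropy_delta * g)
    d = (rng.random(n) < prob).astype(float)
    design = np.column_stack([np.ones(n), x])
    fit = sm.Logit(d, design).fit(disp=0)
    return float(fit.params[1])


# ---------------------------------------------------------------------------
# full synthetic screen bundle
# ---------------------------------------------------------------------------


@dataclass
class ScenarioConfig:
    """A stated synthetic world for the full screen.

    Defaults mirror the published screen's dimensions where they are stated
    (83 metabolites; exposure n = 8299; the four leukemia outcome case/
    control counts) and desk-scale choices elsewhere: outcome cohorts are
    scaled to 50,000 with case counts preserving each outcome's case
    fraction K (``paper_scale=True`` restores the published sizes), the
    instrument-strength range spans the reported first-stage F interval, and
    annotation contamination is set so roughly a fifth of sentinels are
    dropped by the pleiotropy screen, as in the published filtering
    narrative.
    """

    n_metabolites: int = reference.N_METABOLITES
    n_exp: int = reference.EXPOSURE_N
    outcomes: dict[str, tuple[int, int]] = field(
        default_factory=lambda: dict(reference.OUTCOME_DEFS)
    )
    paper_scale: bool = False
    scaled_n_out: int = 50_000
    # instrument-strength world: log-uniform R², U-shaped realistic MAF
    r2_range: tuple[float, float] = (0.006, 0.08)
    maf_range: tuple[float, float] = (0.05, 0.5)
    # planted causal effects (the rest of the screen is null)
    n_true_effects: int = 3
    theta_true: float = 1.5
    r2_true: float = 0.10
    # structural features exercised by the pipeline
    frac_palindromic: float = 0.10
    frac_missing_outcome: float = 0.10
    frac_extra_candidate: float = 0.30
    proxy_r2_range: tuple[float, float] = (0.85, 0.99)
    # outcome files report their own allele orientation: labels are randomly
    # swapped and (for non-palindromic variants) strand-flipped, which the
    # harmonization stage must undo
    frac_outcome_label_swap: float = 0.5
    frac_outcome_strand_flip: float = 0.3
    # pleiotropy-screen contamination (per-domain probability of a
    # genome-wide significant flagged annotation on a sentinel)
    contamination: dict[str, float] = field(
        default_factory=lambda: {
            "neoplastic": 0.05,
            "immune": 0.05,
            "hematologic": 0.04,
            "cardiometabolic": 0.05,
        }
    )
    outcome_gwas_contamination: float = 0.01
    benign_annotation_rate: float = 0.10
    seed: int = 1


@dataclass
class ScreenBundle:
    """Everything the pipeline consumes, plus the truth registry."""

    exposure_table: SummaryTable
    outcome_tables: dict[str, SummaryTable]
    ld_table: LDTable
    annotations: AnnotationTable
    drug_table: pd.DataFrame
    truth: pd.DataFrame

    def write(self, outdir: str | Path) -> dict[str, Path]:
        """Write the bundle in the canonical TSV dialects; returns the paths."""
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        paths = {"exposure": outdir / "exposure.tsv"}
        gwas_io.write_summary_stats(self.exposure_table, paths["exposure"])
        for outcome_id, table in self.outcome_tables.items():
            p = outdir / f"outcome_{outcome_id}.tsv"
            gwas_io.write_summary_stats(table, p)
            paths[f"outcome:{outcome_id}"] = p
        paths["ld"] = outdir / "ld.tsv"
        self.ld_table.write(paths["ld"])
        paths["annotations"] = outdir / "annotations.tsv"
        self.annotations.write(paths["annotations"])
        paths["drugs"] = outdir / "drugs.tsv"
        self.drug_table.to_csv(paths["drugs"], sep="\t", index=False)
        paths["truth"] = outdir / "truth.tsv"
        self.truth.to_csv(paths["truth"], sep="\t", index=False, float_format="%.12g")
        return paths


def _reorient_outcome_labels(
    rec: AssociationRecord, cfg: ScenarioConfig, rng: np.random.Generator
) -> AssociationRecord:
    """Re-express an outcome record in a random allele orientation.

    A label swap reports the other allele as the effect allele (negating the
    beta and complementing the EAF together); a strand flip relabels both
    alleles with their complements, numbers unchanged (skipped for
    palindromic variants, where it is a no-op).  Harmonization must undo
    both; the underlying association is untouched.
    """
    from metmr.harmonize import COMPLEMENT, is_palindromic

    ea, oa, beta, eaf = rec.effect_allele, rec.other_allele, rec.beta, rec.eaf
    if rng.random() < cfg.frac_outcome_label_swap:
        ea, oa, beta, eaf = oa, ea, -beta, 1.0 - eaf
    if not is_palindromic(ea, oa) and rng.random() < cfg.frac_outcome_strand_flip:
        ea, oa = COMPLEMENT[ea], COMPLEMENT[oa]
    return dataclasses.replace(
        rec, effect_allele=ea, other_allele=oa, beta=beta, eaf=eaf
    )


def _scaled_outcome_sizes(cfg: ScenarioConfig) -> dict[str, tuple[int, int]]:
    """(n_out, n_cases) per outcome, preserving K when scaling down."""
    sizes = {}
    for outcome_id, (n_cases, n_controls) in cfg.outcomes.items():
        n_total = n_cases + n_controls
        if cfg.paper_scale:
            sizes[outcome_id] = (n_total, n_cases)
        else:
            k = n_cases / n_total
            scaled_cases = max(int(round(cfg.scaled_n_out * k)), 5)
            sizes[outcome_id] = (cfg.scaled_n_out, scaled_cases)
    return sizes


def _random_position(rng: np.random.Generator) -> tuple[str, int]:
    """Random autosomal position avoiding the default exclusion regions."""
    while True:
        chrom = str(rng.integers(1, 23))
        pos = int(rng.integers(1_000_000, 240_000_000))
        if chrom == "6" and 25_000_000 <= pos <= 34_000_000:
            continue
        if chrom == "11" and 61_300_000 <= pos <= 61_900_000:
            continue
        return chrom, pos


def _proxy_outcome_record(
    truth: SimTruth,
    outcome_id: str,
    proxy_rsid: str,
    proxy_alleles: tuple[str, str],
    ld_r2: float,
    rng: np.random.Generator,
) -> AssociationRecord:
    """Outcome record for an LD proxy of a missing sentinel.

    The proxy genotype copies each sentinel allele with probability
    c = sqrt(r²) (else an independent draw at the same frequency), giving
    allele-level correlation c and genotype r² ≈ the target.  Degenerate
    fits are redrawn as in :func:`simulate_outcome_record`.
    """
    alpha = solve_intercept(truth)
    mean_x = truth.beta_gx * 2 * truth.maf
    c = math.sqrt(ld_r2)
    for _ in range(_MAX_REDRAWS):
        g = rng.binomial(2, truth.maf, truth.n_out)
        eps = rng.standard_normal(truth.n_out)
        x = (truth.beta_gx * g + eps - mean_x) / truth.exposure_sd
        prob = special.expit(alpha + truth.theta * x + truth.pleiotropy_delta * g)
        d = rng.random(truth.n_out) < prob
        # allele-copy construction of the correlated proxy genotype
        keep1 = rng.random(truth.n_out) < c
        keep2 = rng.random(truth.n_out) < c
        a1 = rng.random(truth.n_out) < truth.maf
        a2 = rng.random(truth.n_out) < truth.maf
        s1 = rng.random(truth.n_out) < 0.5  # which sentinel allele copies first
        sent1 = np.where(s1, g >= 1, g == 2)
        sent2 = np.where(s1, g == 2, g >= 1)
        gp = (
            np.where(keep1, sent1, a1).astype(int) + np.where(keep2, sent2, a2)
        ).astype(int)
        n_by_g = np.bincount(gp, minlength=3).astype(float)
        cases_by_g = np.bincount(gp, weights=d.astype(float), minlength=3)
        fit = fit_logistic_counts(n_by_g, cases_by_g)
        if bool(fit["converged"]):
            break
    else:
        raise RuntimeError(f"no defined proxy fit for {proxy_rsid}")
    rec = AssociationRecord(
        rsid=proxy_rsid,
        effect_allele=proxy_alleles[0],
        other_allele=proxy_alleles[1],
        beta=float(fit["beta"]),
        se=float(fit["se"]),
        pval=float(max(fit["pval"], 5e-324)),
        trait_id=outcome_id,
        chrom=truth.chrom,
        pos=truth.pos + 25_000,
        eaf=float(gp.mean() / 2.0),
        n=truth.n_out,
        n_cases=int(d.sum()),
    )
    return rec


def simulate_screen(cfg: ScenarioConfig | None = None) -> ScreenBundle:
    """Generate the full synthetic input set for one screen run.

    Deterministic in ``cfg.seed``: identical seed and config produce a
    byte-identical bundle.  Every emitted file passes validation with zero
    exclusions.
    """
    cfg = ScenarioConfig() if cfg is None else cfg
    master = np.random.default_rng(cfg.seed)
    sizes = _scaled_outcome_sizes(cfg)
    outcome_ids = list(cfg.outcomes)
    # planted effects cycle through outcomes, CLL first (the published
    # screen's significant hit was for CLL)
    planted_order = [o for o in ("CLL", "AML", "CML", "ALL") if o in outcome_ids]
    planted_order = planted_order or outcome_ids

    exposure_records: list[AssociationRecord] = []
    outcome_records: dict[str, list[AssociationRecord]] = {o: [] for o in outcome_ids}
    ld = LDTable()
    annotations = AnnotationTable()
    truth_rows: list[dict] = []
    drug_rows: list[dict] = []

    lo_r2, hi_r2 = cfg.r2_range
    for i in range(cfg.n_metabolites):
        met = f"met_{i + 1:03d}"
        rng = np.random.default_rng(child_seed(cfg.seed, i))
        planted = i < cfg.n_true_effects
        target_outcome = planted_order[i % len(planted_order)] if planted else None

        maf = float(rng.uniform(*cfg.maf_range))
        r2 = cfg.r2_true if planted else float(
            np.exp(rng.uniform(np.log(lo_r2), np.log(hi_r2)))
        )
        palindromic = rng.random() < cfg.frac_palindromic
        pairs = _PAL_PAIRS if palindromic else _NONPAL_PAIRS
        ea, oa = pairs[rng.integers(len(pairs))]
        chrom, pos = _random_position(rng)
        rsid = f"rs{1_000_000 + 97 * i}"
        gene = "SULT2A1" if planted and target_outcome == "CLL" else f"GENE{i + 1}"

        missing_from_outcome = rng.random() < cfg.frac_missing_outcome

        base = SimTruth(
            metabolite_id=met,
            rsid=rsid,
            maf=maf,
            beta_gx=beta_gx_for_r2(r2, maf),
            theta=0.0,
            n_exp=cfg.n_exp,
            n_out=50_000,
            n_cases=100,
            seed=child_seed(cfg.seed, i),
            effect_allele=ea,
            other_allele=oa,
            chrom=chrom,
            pos=pos,
            gene=gene,
        )

        # exposure record (and optionally a weaker independent candidate, to
        # exercise sentinel selection)
        exp_rec = simulate_exposure_record(base, rng=rng)
        exposure_records.append(exp_rec)
        if rng.random() < cfg.frac_extra_candidate:
            weak = dataclasses.replace(
                base,
                rsid=f"rs{1_000_000 + 97 * i + 1}",
                beta_gx=beta_gx_for_r2(max(r2 * 0.4, 1e-4), maf),
                pos=pos + 600_000,
            )
            exposure_records.append(simulate_exposure_record(weak, rng=rng))

        # proxy plumbing for sentinels missing from the outcome files
        proxy_rsid = f"rs{1_000_000 + 97 * i + 2}"
        proxy_alleles = _NONPAL_PAIRS[rng.integers(len(_NONPAL_PAIRS))]
        proxy_r2 = float(rng.uniform(*cfg.proxy_r2_range))
        if missing_from_outcome:
            ld.add(rsid, proxy_rsid, proxy_r2, {ea: proxy_alleles[0], oa: proxy_alleles[1]})
            if rng.random() < 0.5:
                # weaker second candidate exercises max-r² proxy choice
                alt_rsid = f"rs{1_000_000 + 97 * i + 3}"
                ld.add(rsid, alt_rsid, float(rng.uniform(0.5, 0.79)), {ea: ea, oa: oa})

        # outcome records per outcome, independent cohorts
        for outcome_id in outcome_ids:
            n_out, n_cases = sizes[outcome_id]
            theta = cfg.theta_true if outcome_id == target_outcome else 0.0
            t = dataclasses.replace(base, theta=theta, n_out=n_out, n_cases=n_cases)
            if missing_from_outcome:
                outcome_records[outcome_id].append(
                    _proxy_outcome_record(
                        t, outcome_id, proxy_rsid, proxy_alleles, proxy_r2, rng
                    )
                )
            else:
                rec = simulate_outcome_record(t, outcome_id=outcome_id, rng=rng)
                rec = _reorient_outcome_labels(rec, cfg, rng)
                outcome_records[outcome_id].append(rec)

        # annotations: own-metabolite association always; contamination per
        # flagged domain; occasional sub-threshold benign annotations
        used_rsid = proxy_rsid if missing_from_outcome else rsid
        annotations.add(used_rsid, met, "metabolite", float(exp_rec.pval))
        contaminated: list[str] = []
        for domain, rate in cfg.contamination.items():
            if rng.random() < rate:
                annotations.add(
                    used_rsid,
                    f"{domain} trait {i + 1}",
                    domain,
                    float(10 ** rng.uniform(-12, -8.5)),
                )
                contaminated.append(domain)
        outcome_hit = None
        if rng.random() < cfg.outcome_gwas_contamination:
            outcome_hit = outcome_ids[rng.integers(len(outcome_ids))]
            annotations.add(
                used_rsid, outcome_hit, "neoplastic", float(10 ** rng.uniform(-12, -8.5))
            )
        if rng.random() < cfg.benign_annotation_rate:
            domain = ["immune", "cardiometabolic"][rng.integers(2)]
            annotations.add(
                used_rsid, f"benign {domain} trait {i + 1}", domain,
                float(10 ** rng.uniform(-7, -5)),
            )

        # drug table: the CLL-planted metabolite mirrors the SULT2A1
        # substrate-only annotation block; a third of other genes get one
        # generic entry
        if gene == "SULT2A1":
            drug_rows.extend(
                reference.sult2a1_drug_frame(met).to_dict(orient="records")
            )
        elif rng.random() < 0.33:
            drug_rows.append(
                {
                    "metabolite": met,
                    "effector_gene": gene,
                    "protein_type": "Enzyme",
                    "drugbank_id": f"DB{90000 + i:05d}",
                    "drug_name": f"compound_{i + 1}",
                    "relation": "EnzymeBond",
                    "antagonist": 0,
                    "agonist": 0,
                    "substrate": 1,
                    "inhibitor": int(rng.random() < 0.3),
                    "inducer": 0,
                }
            )

        truth_rows.append(
            {
                "metabolite": met,
                "rsid": rsid,
                "gene": gene,
                "maf": maf,
                "r2": r2,
                "beta_gx": base.beta_gx,
                "theta": cfg.theta_true if planted else 0.0,
                "target_outcome": target_outcome or "",
                "palindromic": palindromic,
                "missing_from_outcome": missing_from_outcome,
                "proxy_rsid": proxy_rsid if missing_from_outcome else "",
                "proxy_r2": proxy_r2 if missing_from_outcome else np.nan,
                "contaminated_domains": ",".join(contaminated),
                "outcome_gwas_hit": outcome_hit or "",
                "seed": base.seed,
            }
        )

    exposure_table = SummaryTable(
        exposure_records, EXPOSURE_QUANTITATIVE, provenance="synthetic metabolite GWAS"
    )
    outcome_tables = {
        o: SummaryTable(recs, OUTCOME_BINARY, provenance=f"synthetic {o} GWAS")
        for o, recs in outcome_records.items()
    }
    drug_table = pd.DataFrame(drug_rows, columns=list(reference.DRUG_TABLE_COLUMNS))
    return ScreenBundle(
        exposure_table=exposure_table,
        outcome_tables=outcome_tables,
        ld_table=ld,
        annotations=annotations,
        drug_table=drug_table,
        truth=pd.DataFrame(truth_rows),
    )


# ---------------------------------------------------------------------------
# recovery and calibration experiments
# ---------------------------------------------------------------------------


def _wald_arrays(sims: dict[str, np.ndarray], se_method: str = mr.FIRST_ORDER):
    """Wald estimates/CIs/p for replicated summary stats (finite fits only)."""
    keep = (
        np.isfinite(sims["bx"]) & np.isfinite(sims["by"]) & np.isfinite(sims["se_y"])
        & np.isfinite(sims["se_x"]) & (sims["se_x"] > 0) & (sims["se_y"] > 0)
        & (sims["bx"] != 0)
    )
    beta_mr, se_mr = mr.wald_ratio(
        sims["bx"][keep], sims["se_x"][keep], sims["by"][keep], sims["se_y"][keep],
        se_method,
    )
    or_, lo, hi, pval = mr.to_odds_ratio(beta_mr, se_mr)
    return {
        "beta_mr": beta_mr,
        "se_mr": se_mr,
        "ci_low_log": np.log(lo),
        "ci_high_log": np.log(hi),
        "pval": pval,
        "n_effective": int(keep.sum()),
    }


def recovery_experiment(
    truths: Sequence[SimTruth],
    replicates: int = 500,
    seed: int = 1,
    alpha: float = 0.05,
    oracle_n: int = 1_000_000,
) -> pd.DataFrame:
    """Estimate bias, RMSE, CI coverage and rejection rate per scenario.

    For each ground-truth scenario, ``replicates`` independent two-sample
    summary datasets are generated and pushed through the Wald-ratio
    estimator; the benchmark is the conditional log-OR from the logistic
    oracle of D on X (not θ itself — non-collapsibility is reported, not
    hidden, as the ``oracle_minus_theta`` column).
    """
    if replicates < 1:
        raise ValueError("replicates must be >= 1")
    rows = []
    for j, truth in enumerate(truths):
        rng = np.random.default_rng(child_seed(seed, j))
        sims = simulate_summary(truth, replicates, rng=rng)
        w = _wald_arrays(sims)
        oracle = (
            conditional_logor_oracle(truth, n=oracle_n, seed=child_seed(seed, 10_000 + j))
            if truth.theta != 0.0
            else 0.0
        )
        est = w["beta_mr"]
        coverage = float(
            np.mean((w["ci_low_log"] <= oracle) & (oracle <= w["ci_high_log"]))
        )
        rows.append(
            {
                "metabolite": truth.metabolite_id,
                "theta": truth.theta,
                "oracle_logor": oracle,
                "oracle_minus_theta": oracle - truth.theta,
                "mean_beta_mr": float(est.mean()),
                "bias": float(est.mean() - oracle),
                "rmse": float(np.sqrt(np.mean((est - oracle) ** 2))),
                "coverage_95": coverage,
                "reject_rate": float(np.mean(w["pval"] < alpha)),
                "mean_f_stat": float(
                    np.mean((sims["bx"] / sims["se_x"]) ** 2)
                ),
                "n_effective": w["n_effective"],
                "replicates": replicates,
            }
        )
    return pd.DataFrame(rows)


def default_null_truths(
    n_metabolites: int = reference.N_METABOLITES,
    seed: int = 1,
    n_out: int = 100_000,
    case_fraction: float = 0.002,
) -> list[SimTruth]:
    """A family of null scenarios for calibration experiments.

    The outcome regime is CLL-like: case fraction ≈ 0.002 at a desk-scale
    cohort of 100,000 (≈ 200 cases), with MAF in [0.1, 0.5] and instrument
    R² log-uniform in [0.01, 0.1] so the per-variant Wald test is well into
    its asymptotic regime even at Bonferroni-level tail probabilities.
    """
    rng = np.random.default_rng(seed)
    truths = []
    n_cases = int(round(n_out * case_fraction))
    for i in range(n_metabolites):
        maf = float(rng.uniform(0.1, 0.5))
        r2 = float(np.exp(rng.uniform(np.log(0.01), np.log(0.1))))
        truths.append(
            SimTruth(
                metabolite_id=f"null_{i + 1:03d}",
                rsid=f"rs{2_000_000 + i}",
                maf=maf,
                beta_gx=beta_gx_for_r2(r2, maf),
                theta=0.0,
                n_out=n_out,
                n_cases=n_cases,
                seed=child_seed(seed, i),
            )
        )
    return truths


def fwer_experiment(
    replicates: int = 500,
    seed: int = 1,
    n_metabolites: int = reference.N_METABOLITES,
    alpha: float = 0.05,
) -> dict[str, float]:
    """Family-wise error of the Bonferroni rule across an all-null screen.

    Each replicate simulates the full 83-metabolite screen under the global
    null and rejects if any Wald p falls below α/83.  Also reports the
    pooled per-test type-I error at level α.
    """
    truths = default_null_truths(n_metabolites, seed=seed)
    cfg = mr.MultiplicityConfig(n_tests=n_metabolites, alpha=alpha)
    pmat = np.full((n_metabolites, replicates), np.nan)
    for i, truth in enumerate(truths):
        rng = np.random.default_rng(child_seed(seed, 50_000 + i))
        sims = simulate_summary(truth, replicates, rng=rng)
        beta_mr, se_mr = mr.wald_ratio(sims["bx"], sims["se_x"], sims["by"], sims["se_y"])
        pmat[i] = 2.0 * stats.norm.sf(np.abs(beta_mr) / se_mr)
    any_reject = np.nanmin(pmat, axis=0) < cfg.bonferroni_threshold
    return {
        "fwer": float(np.mean(any_reject)),
        "per_test_type1": float(np.nanmean(pmat < alpha)),
        "bonferroni_threshold": cfg.bonferroni_threshold,
        "replicates": float(replicates),
        "n_metabolites": float(n_metabolites),
    }


def simulated_power(
    case_fraction: float,
    n_total: int,
    r2: float,
    or_target: float,
    replicates: int = 10_000,
    seed: int = 1,
    alpha: float = 0.05,
    maf: float = 0.3,
    n_exp: int = reference.EXPOSURE_N,
) -> float:
    """Monte-Carlo rejection rate of the Wald test at a true OR per 1-SD.

    Used to validate the closed-form power approximation: simulates full
    two-sample replicates with θ = ln(OR) and counts two-sided rejections
    at level α.
    """
    truth = SimTruth(
        metabolite_id="power",
        rsid="rs1",
        maf=maf,
        beta_gx=beta_gx_for_r2(r2, maf),
        theta=float(np.log(or_target)),
        n_exp=n_exp,
        n_out=n_total,
        n_cases=max(int(round(n_total * case_fraction)), 1),
        seed=seed,
    )
    rng = np.random.default_rng(seed)
    sims = simulate_summary(truth, replicates, rng=rng)
    w = _wald_arrays(sims)
    return float(np.mean(w["pval"] < alpha))
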