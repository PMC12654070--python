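# Methods

## Design

The pipeline estimates, per metabolite × leukemia subtype, the causal effect
of a 1-SD higher genetically predicted plasma metabolite level on disease
log-odds, using exactly one instrument per metabolite (a *sentinel* SNV) and
summary statistics from two non-overlapping cohorts. All four outcomes are
analyzed independently with identical settings.

The instrumental-variable assumptions are the usual three: relevance
(enforced by the exposure-side genome-wide significance filter, p < 5 × 10⁻⁸
strict), exchangeability, and exclusion restriction (addressed — not
guaranteed — by the region exclusions and the annotation-based pleiotropy
screen). With a single instrument per metabolite, multi-variant diagnostics
(IVW/Egger heterogeneity, weighted median, Steiger, colocalization) are
structurally unavailable and deliberately out of scope.

## Estimator

For harmonized per-allele effects (β_X, SE_X) on the SD-scaled exposure and
(β_Y, SE_Y) on outcome log-odds:

- Wald ratio: β_MR = β_Y / β_X.
- SE, default (`first_order`): SE_Y / |β_X| — the conventional single-SNV
  implementation. `second_order` adds exposure-side noise:
  √(SE_Y²/β_X² + β_Y²·SE_X²/β_X⁴) ≥ first order always. With every
  instrument at F > 30 the two differ by < 2% (verified against a
  parametric-bootstrap SE in the tests).
- Inference uses the standard normal, not t: cohort sizes are in the
  thousands to hundreds of thousands and the estimates are
  summary-statistic asymptotics to begin with. p-values are two-sided;
  CIs are exp(β_MR ± z·SE) at 95%.
- Multiplicity: Bonferroni within outcome family, with n_tests equal to the
  number of metabolites actually estimated for that outcome (recomputed from
  the data; 83 in the published screen giving 0.05/83 = 6.02 × 10⁻⁴).
  p < α/n_tests is *significant*; α/n_tests ≤ p < α is *suggestive*.

## Instrument strength

R² for an SD-scaled exposure is 2·EAF·(1−EAF)·β², clamped to [0, 1);
monomorphic EAF ∈ {0, 1} is an error. The first-stage F statistic is the
standard (R²/k)/((1−R²)/(n−k−1)) with k = 1. F is reported and flagged when
≤ 10 but never used as a filter beyond the genome-wide significance
threshold — matching the source design, where the weakest retained
instrument had F = 36.5.

## Harmonization

Strand is inferred, never assumed: summary files carry no strand column, so
reverse-complement matching assigns one of four actions (`none`,
`swap_flip`, `strand_flip`, `strand_flip_and_swap`); a swap always negates
the outcome beta *and* complements its EAF together. Palindromic A/T and C/G
variants are resolved by minor/major frequency agreement and excluded as
ambiguous when either cohort's EAF lies inside the window [0.42, 0.58]
(closed, configurable) or the outcome EAF is missing. The window value
operationalizes "adequate allele-frequency information" conservatively; it
is a design choice of this package, not an inference about the original
analysts' setting. All 144 ordered allele configurations are enumerated in
the tests: each maps to exactly one action or exclusion, harmonizing an
already-harmonized pair is the identity, and a double swap restores the
original record exactly.

LD proxies are accepted only at r² strictly above 0.8, best-r² first, ties
by rsID; the LD table's allele correspondence (a bijection, stored with its
inverse for symmetry) translates the proxy's alleles into sentinel space
before harmonization.

## Pleiotropy screen

Offline and deterministic: a user-supplied annotation table (rsid, trait,
domain, p) stands in for a GWAS Catalog snapshot, with domains from a fixed
vocabulary {neoplastic, immune, hematologic, cardiometabolic, metabolite,
other}. The rsID actually used (proxy if assigned) is screened. A
genome-wide significant annotation for the target outcome itself drops the
instrument as `dropped_outcome_gwas` (checked first); any other genome-wide
significant annotation in the four flagged domains drops it as
`dropped_pleiotropy`. Retained instruments keep their annotations for
reporting. Live API queries are out of scope for reproducibility.

## Power

Closed form: power = Φ(ncp − z₁₋α/₂) with
ncp = |ln OR|·√(N·R²·K·(1−K)), the standard non-centrality for a
summary-level MR Wald test on a binary outcome with case fraction K. The
mirror tail Φ(−ncp − z₁₋α/₂) can be added (`mirror_tail=True`) for
exactness near the null, where it contributes up to α/2; the validation
suite compares the mirror-tail form against Monte-Carlo rejection rates
because simulated rejections are inherently two-sided. Across a 12-point
grid spanning K ∈ {0.001, 0.01, 0.1}, R² ∈ {0.02, 0.05} and
OR ∈ {0.90, 1.20, 1.50}, closed form and simulation agree within ±0.02 at
10,000 replicates per point. Degenerate scenarios (K ∈ {0,1}, or R² = 0
with OR ≠ 1) warn and return α/2 rather than raising.

## Synthetic world

The generator's defaults are the published screen's stated conditions where
stated, and desk-scale choices elsewhere:

- 83 metabolites; exposure cohort n = 8,299; outcome case/control counts
  AML 731/793,587; CML 474/793,588; ALL 313/706,277; CLL 1585/793,582.
- Outcome cohorts are scaled down to N = 50,000 with case counts scaled to
  preserve each outcome's case fraction (`paper_scale=True` restores full
  sizes). All four outcomes are in the rare-disease regime (K ≤ 0.002),
  where the log-OR closely approximates the log-RR and non-collapsibility
  attenuation is minimal.
- Instrument R² is log-uniform on [0.006, 0.08] (F ≈ 50–720 at n = 8,299,
  inside the published F range 36.5–4013); MAF uniform on [0.05, 0.5].
- Three planted causal effects with θ = 1.5 and instrument R² = 0.10,
  targeting CLL, AML, CML — θ and R² chosen so desk-scale detection power
  is ≈ 0.9–0.99 per effect (at the published θ ≈ 0.78 the scaled-down
  outcome cohorts would be hopelessly underpowered, which would validate
  nothing). Detection is therefore probabilistic run to run; integration
  tests assert on surviving planted effects under fixed seeds.
- 10% of sentinels are palindromic; 10% are absent from the outcome files
  and reachable through an LD proxy with r² ∈ [0.85, 0.99] (plus sub-0.8
  decoys to exercise the threshold); outcome files report their own random
  allele orientation (label swaps and strand flips) which harmonization
  must undo.
- Annotation contamination rates (~5% per flagged domain, 1% outcome-GWAS
  hits) are set so roughly a fifth of sentinels are dropped by the screen,
  matching the published filtering narrative's proportions (the published
  absolute counts, 171 → 103 → 102 → 83, require the real data and are not
  reproduced).

Mechanics: exposure X = β_gx·G + ε with G ~ Binomial(2, MAF) under
Hardy–Weinberg and ε ~ N(0,1), standardized by the sample SD before
regression; disease through logit P(D=1) = α + θ·X + δ·G with the intercept
solved by bisection so the expected case count hits the target (δ is an
optional direct pleiotropic path, 0 by default). Exposure and outcome
cohorts are drawn independently, so the two-sample design holds exactly.

Two equivalent simulation routes exist. `simulate_pair` regresses on
individual-level data. `simulate_summary` draws the *sufficient statistics*
of those regressions from their exact finite-sample distributions
(multinomial genotype counts; normal group sums plus independent χ²
within-group sums of squares by Cochran's theorem; binomial case counts at
genotype-conditional risks computed by 41-node Gauss–Hermite integration)
and fits the identical estimators to them. Because both OLS and the
genotype-dosage logistic regression depend on the data only through these
statistics, the two routes induce the same joint distribution of the
emitted (β, SE, p, EAF) — asserted distributionally in the tests — and the
fast route runs replicate-heavy experiments (tens of thousands of
replicates) in seconds. Per-variant logistic fits use an in-package
Newton–Raphson on the 3 × 2 (genotype, case) table; the *oracle* regression
of D on continuous X is fit with statsmodels, keeping the benchmark on an
independent code path.

Degenerate outcome tables (no case carries the minor allele — common at
tiny case counts) leave the MLE undefined: bundle generation redraws the
cohort (mirroring source-GWAS minimum-count filters), while replicate
experiments keep the NaN and report the effective replicate count.

Seeds: a master seed plus fixed-arithmetic child seeds per metabolite
(`child_seed`), all below 2³¹; identical seed and config give byte-identical
bundles and pipeline outputs.

## Estimand honesty

A Wald ratio on a logistic-scale outcome targets the *conditional* log-OR
per 1-SD exposure, which differs from the generative θ under
non-collapsibility. Recovery experiments therefore benchmark the mean
estimate against a logistic regression of D on X at n = 10⁶ (the oracle),
and report the oracle-vs-θ gap rather than hiding it; at the default
K = 0.002 the gap is ~1–2%.

## What a green test establishes — and what it does not

The synthetic world exercises the full estimator contract (finite-sample
SEs, frequency noise, harmonization algebra, screening bookkeeping,
calibration of p-values and of the Bonferroni family-wise error), but it
has no LD structure beyond the pairwise sentinel–proxy correlation, no
population stratification, no metabolite-ratio construction, no ancestry
mismatch and no sample overlap. Green tests validate the machinery, not the
published biological findings: reproducing which specific metabolites are
significant requires the real cohort summary statistics, which do not ship
with the package. What *is* checked against the publication is internal:
the Bonferroni threshold and, for every reported (OR, 95% CI) pair, that
the log-scale-symmetric CI reproduces the printed OR (geometric mean) and a
p-value consistent with the reported tier.

## Numerical choices

- Tie-breaks everywhere are (max criterion, min p, lexicographic rsID) for
  determinism.
- Validation never throws on content: each bad record carries exactly one
  primary reason code, in priority order missing_field → non_acgt →
  bad_range → duplicate, and reports satisfy n_input = n_valid +
  |exclusions| exactly.
- Result TSVs are written at 12 significant digits and round-trip exactly
  at that precision; the `null` tier is protected from pandas' default
  NA parsing on read.
- Newton iterations cap at 40 with step damping; non-converged or separated
  fits return NaN, never a crash.
- Monte-Carlo test tolerances are ~3 standard errors of the relevant
  binomial/Monte-Carlo noise, with fixed seeds.

## Known limitations

- First-order Wald SEs understate uncertainty for weak instruments; all
  shipped worlds keep F ≫ 10, and the second-order SE is available
  side-by-side.
- The power approximation ignores exposure-side noise (exact for the
  first-order test statistic, which reduces to β_Y/SE_Y) and mild
  non-collapsibility attenuation at common-disease case fractions; at
  K = 0.1 it is accurate to ~0.01–0.02 in the validated regime.
- The proxy generator's allele-copy construction matches the target r² only
  approximately (allele-level correlation √r²); the LD table records the
  stated, not realized, r².
- A variant instrumenting two metabolites is retained for both and flagged,
  as the source design is silent on the case.
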