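# metmr

Single-sentinel two-sample Mendelian randomization (MR) screen of plasma
metabolites against leukemia subtypes, implemented as a tested, reusable
pipeline over GWAS summary statistics.

## The scientific problem

Observational associations between circulating metabolites and leukemia are
confounded and subject to reverse causation. MR sidesteps this by using
germline variants as instrumental variables: if a variant G strongly and
specifically shifts a metabolite X, and disease D responds to the genetically
predicted shift in X, the association supports a causal effect of X on D —
provided G is (i) robustly associated with X, (ii) unconfounded with D, and
(iii) affects D only through X.

This package implements the *single-sentinel* design used to screen plasma
metabolites against four leukemia subtypes (AML, CML, ALL, CLL), each
analyzed independently:

- **Instrument selection.** One sentinel SNV per metabolite: the variant
  with the largest variance explained, R² = 2·EAF·(1−EAF)·β², among the
  metabolite's independent genome-wide significant signals
  (p < 5 × 10⁻⁸), ties broken by smaller p then rsID. Sentinels in the FADS
  and MHC regions are excluded. Strength is reported as the first-stage
  F = (R²/k)/((1−R²)/(n−k−1)), k = 1.
- **LD proxies.** A sentinel missing from an outcome file may be replaced by
  its best LD partner with r² > 0.8; the proxy identity, r² and allele
  correspondence are carried through the analysis.
- **Pleiotropy screen.** An offline annotation table (a GWAS Catalog
  snapshot stand-in) drops any instrument with a genome-wide significant
  association in a neoplastic, immune, hematologic or cardiometabolic
  domain, or with the target outcome itself.
- **Harmonization.** Exposure and outcome records are aligned to one effect
  allele, inferring strand flips from reverse-complement matching and
  resolving palindromic (A/T, C/G) variants by allele frequency; ambiguous
  palindromes (EAF in [0.42, 0.58]) are excluded.
- **Estimation.** With one instrument the causal log-odds per 1-SD higher
  metabolite is the Wald ratio β_MR = β_Y/β_X with SE β_Y's SE over |β_X|
  (second-order delta SE available), reported as OR with 95% Wald CI.
  Bonferroni within outcome (0.05/83 = 6.02 × 10⁻⁴ in the published screen)
  separates *significant* from *suggestive* (p < 0.05) findings.
- **Power.** Post hoc power at target ORs {0.90, 1.20, 1.50} from the
  non-centrality |ln OR|·√(N·R²·K(1−K)), which accounts for the outcome's
  case–control ratio K.
- **Synthetic data.** A generator emits full synthetic screens — HWE
  genotypes, SD-scaled exposures with one strong cis variant, rare binary
  outcomes through a logistic link at the published case–control ratios,
  palindromes, missing sentinels with LD proxies, annotation contamination —
  with a ground-truth registry, so estimator recovery, CI coverage, type-I
  error, family-wise error and power can be validated against known truth.

Real CLSA/FinnGen/UK Biobank downloads are out of scope; the pipeline reads
any tab-separated summary statistics through an explicit column-name
dialect mapping.

## Worked example

```bash
metmr simulate --seed 3 --out demo/       # synthetic 83-metabolite screen
metmr run --config demo/pipeline.yaml     # full pipeline
```

prints

```
wrote synthetic bundle (83 metabolites) to demo
pipeline config: demo/pipeline.yaml
estimated 280 metabolite-outcome pairs: 3 significant, 4 suggestive
outputs in demo/results
```

The three planted causal effects (θ = 1.5 per 1-SD, instrument R² = 0.10)
are recovered as the three significant rows; the four suggestive rows are
the expected false-positive load of ~280 null tests at p < 0.05:

```
metabolite outcome      rsid    gene     OR  CI_low  CI_high   pval        tier
   met_002     AML rs1000097   GENE2 5.4993  2.1541  14.0392 0.0004 significant
   met_003     CML rs1000194   GENE3 6.4122  2.5166  16.3378 0.0001 significant
   met_001     CLL rs1000000 SULT2A1 4.3293  2.6488   7.0759 0.0000 significant
   met_029     CLL rs1002716  GENE29 0.3000  0.1149   0.7834 0.0140  suggestive
   ...
```

`demo/results/` also contains the stage-by-stage filtering audit (with exact
count conservation), the instrument-strength table (R², F, n), the
harmonization audit (actions and exclusion reasons per sentinel), the power
table, the drug-annotation join (the synthetic CLL hit maps to SULT2A1 and
its eight published substrate drugs), and a manifest with the config hash
and seed — re-running with the same seed reproduces every file
byte-for-byte. `metmr run --plots` adds volcano and forest plots.

`metmr check` verifies the published worked values: the Bonferroni
threshold, and for every reported (OR, 95% CI) pair that the geometric-mean
implied OR and CI-implied p-value reproduce the printed estimate and tier
(e.g. CI (1.45, 3.31) → OR 2.19, p ≈ 2 × 10⁻⁴).

## Acceptance script

```bash
python scripts/acceptance.py --seed 1 --out results/acceptance.json
```

re-runs the main computation from scratch: the default synthetic screen
through the full pipeline, a 500-replicate parameter-recovery experiment
against a large-sample logistic oracle, null-calibration experiments
(per-test type-I error and the family-wise error of the 83-metabolite
Bonferroni rule), and the printed-value consistency suite, then writes the
results JSON to `--out`.

## Layout

```
src/metmr/
  gwas_io.py       summary-statistic records, TSV dialects, validation
  instruments.py   sentinel selection, R²/F, LD proxies, pleiotropy screen
  harmonize.py     effect-allele harmonization with audit trail
  mr.py            Wald ratio, OR/CI/p, significance tiers, CI diagnostics
  power.py         post hoc power for binary outcomes
  simulate.py      synthetic screens with known truth; recovery experiments
  pipeline.py      orchestration, audit, drug join, manifests
  reference.py     published worked values used by `metmr check`
  cli.py, plots.py
docs/methods.md    model, assumptions, numerical choices, limitations
```
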