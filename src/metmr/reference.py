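"""Reference values from the published metabolome-wide MR screen of plasma
metabolites against leukemia subtypes that this package re-implements.

These printed estimates (odds ratios with 95% CIs per metabolite–subtype
pair, study dimensions, and the SULT2A1 drug annotation table) are inputs to
the consistency-check suite (``metmr check``): a Wald CI is symmetric on the
log scale, so each printed (OR, CI) triple can be checked against its
geometric-mean implied OR and the p-value recovered from the implied SE.
No real cohort data ships with the package.
"""

from __future__ import annotations

import pandas as pd

from metmr.mr import ci_consistency

#: exposure GWAS sample size (plasma metabolites, one cohort)
EXPOSURE_N = 8299

#: number of metabolites/metabolite ratios in the screen's final instrument list
N_METABOLITES = 83

#: outcome GWAS dimensions: outcome -> (n_cases, n_controls)
OUTCOME_DEFS: dict[str, tuple[int, int]] = {
    "AML": (731, 793_587),
    "CML": (474, 793_588),
    "ALL": (313, 706_277),
    "CLL": (1585, 793_582),
}

#: reported first-stage F range across the 83 sentinels
F_RANGE = (36.5, 4013.0)

#: published per-pair estimates: (metabolite, outcome, OR, CI_low, CI_high, tier)
REPORTED_ASSOCIATIONS: tuple[tuple[str, str, float, float, float, str], ...] = (
    ("lithocholate sulfate (1)", "CLL", 2.19, 1.45, 3.31, "significant"),
    ("cortisol", "AML", 2.83, 1.01, 7.93, "suggestive"),
    ("cholesterol/cortisol", "AML", 0.35, 0.13, 0.97, "suggestive"),
    ("thyroxine", "AML", 0.34, 0.12, 1.00, "suggestive"),
    (
        "phosphate/linoleoyl-arachidonoyl-glycerol (18:2/20:4)",
        "CML",
        6.32,
        1.80,
        22.15,
        "suggestive",
    ),
    ("1,5-anhydroglucitol (1,5-AG)", "CML", 4.99, 1.64, 15.14, "suggestive"),
    ("beta-citrylglutamate", "CML", 0.63, 0.46, 0.86, "suggestive"),
    ("beta-alanine", "CML", 0.50, 0.26, 0.98, "suggestive"),
    (
        "bilirubin (Z,Z)/etiocholanolone glucuronide",
        "CML",
        0.67,
        0.46,
        0.99,
        "suggestive",
    ),
    ("choline", "ALL", 4.14, 1.06, 16.10, "suggestive"),
    ("beta-hydroxyisovalerate", "CLL", 2.55, 1.42, 4.57, "suggestive"),
    ("2'-deoxyuridine", "CLL", 1.67, 1.07, 2.59, "suggestive"),
    ("3-methoxytyrosine", "CLL", 2.24, 1.07, 4.70, "suggestive"),
    ("pregnenediol sulfate (C21H34O5S)", "CLL", 2.13, 1.05, 4.33, "suggestive"),
    (
        "N-acetylputrescine/(N(1) + N(8))-acetylspermidine",
        "CLL",
        0.55,
        0.35,
        0.87,
        "suggestive",
    ),
    ("5,6-dihydrothymine", "CLL", 0.46, 0.24, 0.88, "suggestive"),
    ("gamma-CEHC", "CLL", 0.73, 0.56, 0.96, "suggestive"),
    ("beta-citrylglutamate", "CLL", 0.83, 0.70, 0.99, "suggestive"),
)

#: the headline association: higher genetically proxied lithocholate
#: sulfate (1) and CLL risk
HEADLINE = REPORTED_ASSOCIATIONS[0]

#: published drug annotations for the effector enzyme of the CLL-significant
#: metabolite: all agents are SULT2A1 substrates, none antagonists/agonists/
#: inhibitors/inducers
SULT2A1_DRUGS: tuple[tuple[str, str], ...] = (
    ("DB05812", "Abiraterone"),
    ("DB12471", "Ibrexafungerp"),
    ("DB00968", "Methyldopa"),
    ("DB09073", "Palbociclib"),
    ("DB00960", "Pindolol"),
    ("DB01708", "Prasterone"),
    ("DB00675", "Tamoxifen"),
    ("DB00871", "Terbutaline"),
)

DRUG_TABLE_COLUMNS = (
    "metabolite",
    "effector_gene",
    "protein_type",
    "drugbank_id",
    "drug_name",
    "relation",
    "antagonist",
    "agonist",
    "substrate",
    "inhibitor",
    "inducer",
)


def sult2a1_drug_frame(metabolite: str = "lithocholate sulfate (1)") -> pd.DataFrame:
    """The SULT2A1 drug annotation rows as a drug-table DataFrame."""
    rows = [
        {
            "metabolite": metabolite,
            "effector_gene": "SULT2A1",
            "protein_type": "Enzyme",
            "drugbank_id": db_id,
            "drug_name": name,
            "relation": "EnzymeBond",
            "antagonist": 0,
            "agonist": 0,
            "substrate": 1,
            "inhibitor": 0,
            "inducer": 0,
        }
        for db_id, name in SULT2A1_DRUGS
    ]
    return pd.DataFrame(rows, columns=DRUG_TABLE_COLUMNS)


def check_reported(or_tol: float = 0.02, level: float = 0.95) -> pd.DataFrame:
    """Run the printed-value consistency suite over every reported pair.

    For each (OR, CI) triple the implied geometric-mean OR must reproduce
    the printed OR to ``or_tol``.  The default tolerance of 0.02 reflects
    that the published CI bounds are themselves rounded to two decimals,
    which propagates up to about ±0.01 into the geometric mean at OR ≈ 2;
    individual rows can be checked tighter (±0.005) when the bounds carry
    enough precision.  The p-value implied by the CI width must fall in the
    reported tier's p range (suggestive: 6.02 × 10⁻⁴ ≤ p < 0.05;
    significant: p < 6.02 × 10⁻⁴), with a small cushion above 0.05 for
    bounds printed as exactly 1.00.
    """
    bonf = 0.05 / N_METABOLITES
    rows = []
    for met, outcome, or_printed, lo, hi, tier in REPORTED_ASSOCIATIONS:
        diag = ci_consistency(or_printed, lo, hi, level=level, or_tol=or_tol)
        if tier == "significant":
            tier_ok = diag.implied_pval < bonf
        else:
            tier_ok = bonf <= diag.implied_pval < 0.055
        rows.append(
            {
                "metabolite": met,
                "outcome": outcome,
                "OR_printed": or_printed,
                "CI_low": lo,
                "CI_high": hi,
                "implied_OR": diag.implied_or,
                "implied_se": diag.implied_se,
                "implied_pval": diag.implied_pval,
                "or_ok": diag.ok,
                "tier_printed": tier,
                "tier_ok": tier_ok,
            }
        )
    return pd.DataFrame(rows)
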