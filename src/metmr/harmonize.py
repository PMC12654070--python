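"""Effect-allele harmonization between exposure and outcome records.

Summary-statistic files carry no strand column, so strand flips are inferred
from reverse-complement allele matching.  For a non-palindromic variant the
outcome record is reconciled to the exposure's effect allele by one of four
actions:

``none``
    alleles already aligned;
``swap_flip``
    outcome alleles are the exposure's swapped — negate the outcome beta and
    complement its EAF (always both together);
``strand_flip``
    outcome alleles are the reverse complement of the exposure's — relabel
    only, numbers unchanged;
``strand_flip_and_swap``
    reverse complement *and* swapped — relabel, negate, complement.

Palindromic variants (A/T or C/G) cannot be resolved by labels: both strand
readings produce the same letters.  They are resolved by allele frequency —
alignment is chosen so minor/major status agrees between cohorts — and are
excluded as ``palindromic_ambiguous`` whenever either frequency falls inside
the ambiguity window (default [0.42, 0.58]) or the outcome frequency is
missing.  Non-A/C/G/T alleles and irreconcilable labels are excluded with
reasons ``non_acgt`` and ``allele_mismatch``; harmonization never raises on
content.
"""

from __future__ import annotations

import dataclasses
from collections import Counter
from dataclasses import dataclass
from typing import Mapping, Sequence

from metmr.gwas_io import AssociationRecord, SummaryTable, VALID_ALLELES

COMPLEMENT = {"A": "T", "T": "A", "C": "G", "G": "C"}

DEFAULT_AMBIGUITY_WINDOW = (0.42, 0.58)

ACTION_NONE = "none"
ACTION_SWAP_FLIP = "swap_flip"
ACTION_STRAND_FLIP = "strand_flip"
ACTION_STRAND_FLIP_AND_SWAP = "strand_flip_and_swap"
ACTION_EXCLUDED = "excluded"

REASON_PALINDROMIC = "palindromic_ambiguous"
REASON_STRAND = "strand_unresolved"
REASON_NON_ACGT = "non_acgt"
REASON_MISMATCH = "allele_mismatch"

ACTIONS = (
    ACTION_NONE,
    ACTION_SWAP_FLIP,
    ACTION_STRAND_FLIP,
    ACTION_STRAND_FLIP_AND_SWAP,
    ACTION_EXCLUDED,
)


def is_palindromic(a1: str, a2: str) -> bool:
    """A/T and C/G variants are their own reverse complement."""
    return {a1, a2} in ({"A", "T"}, {"C", "G"})


@dataclass
class HarmonizedPair:
    """An exposure/outcome record pair aligned to one effect allele."""

    rsid: str
    exposure: AssociationRecord
    outcome: AssociationRecord  # post-alignment copy (unchanged if excluded)
    action: str
    exclusion_reason: str | None = None
    eaf_window: tuple[float, float] = DEFAULT_AMBIGUITY_WINDOW

    @property
    def excluded(self) -> bool:
        return self.action == ACTION_EXCLUDED


def translate_alleles(
    record: AssociationRecord, allele_map: Mapping[str, str]
) -> AssociationRecord | None:
    """Map a proxy record's alleles back into sentinel-allele space.

    ``allele_map`` maps sentinel alleles onto proxy alleles (the LD table's
    orientation); the inverse is applied here.  Returns ``None`` when the
    proxy record's alleles are not covered by the correspondence.
    """
    inv = {v: k for k, v in allele_map.items()}
    ea = inv.get(record.effect_allele)
    oa = inv.get(record.other_allele)
    if ea is None or oa is None:
        return None
    return dataclasses.replace(record, effect_allele=ea, other_allele=oa)


def _aligned(out: AssociationRecord, exp: AssociationRecord, flip: bool) -> AssociationRecord:
    """Outcome record relabelled onto the exposure's alleles; a flip negates
    beta and complements EAF together (never one without the other)."""
    return dataclasses.replace(
        out,
        effect_allele=exp.effect_allele,
        other_allele=exp.other_allele,
        beta=-out.beta if flip else out.beta,
        eaf=None if out.eaf is None else (1.0 - out.eaf if flip else out.eaf),
    )


def harmonize_pair(
    exp: AssociationRecord,
    out: AssociationRecord,
    ambiguity_window: tuple[float, float] = DEFAULT_AMBIGUITY_WINDOW,
) -> HarmonizedPair:
    """Align one outcome record to the exposure's effect allele."""

    def exclude(reason: str) -> HarmonizedPair:
        return HarmonizedPair(
            rsid=exp.rsid,
            exposure=exp,
            outcome=out,
            action=ACTION_EXCLUDED,
            exclusion_reason=reason,
            eaf_window=ambiguity_window,
        )

    def done(action: str, flip: bool) -> HarmonizedPair:
        return HarmonizedPair(
            rsid=exp.rsid,
            exposure=exp,
            outcome=_aligned(out, exp, flip),
            action=action,
            eaf_window=ambiguity_window,
        )

    e1, e2 = exp.effect_allele, exp.other_allele
    o1, o2 = out.effect_allele, out.other_allele
    for allele in (e1, e2, o1, o2):
        if allele not in VALID_ALLELES:
            return exclude(REASON_NON_ACGT)
    if e1 == e2 or o1 == o2:
        return exclude(REASON_NON_ACGT)

    if is_palindromic(e1, e2):
        if {o1, o2} != {e1, e2}:
            return exclude(REASON_MISMATCH)
        lo, hi = ambiguity_window
        if out.eaf is None:
            return exclude(REASON_PALINDROMIC)
        if exp.eaf is None:
            return exclude(REASON_PALINDROMIC)
        if lo <= exp.eaf <= hi or lo <= out.eaf <= hi:
            return exclude(REASON_PALINDROMIC)
        # frequency of the exposure's effect allele under the same-strand
        # reading of the outcome labels
        same_strand_eaf = out.eaf if o1 == e1 else 1.0 - out.eaf
        freq_agree = (exp.eaf < 0.5) == (same_strand_eaf < 0.5)
        if freq_agree:
            # labels are trustworthy as written
            return done(ACTION_NONE if o1 == e1 else ACTION_SWAP_FLIP, flip=o1 != e1)
        # frequencies indicate the outcome labels are on the opposite strand
        if o1 == e1:
            return done(ACTION_STRAND_FLIP_AND_SWAP, flip=True)
        return done(ACTION_STRAND_FLIP, flip=False)

    rc1, rc2 = COMPLEMENT[o1], COMPLEMENT[o2]
    if (o1, o2) == (e1, e2):
        return done(ACTION_NONE, flip=False)
    if (o1, o2) == (e2, e1):
        return done(ACTION_SWAP_FLIP, flip=True)
    if (rc1, rc2) == (e1, e2):
        return done(ACTION_STRAND_FLIP, flip=False)
    if (rc1, rc2) == (e2, e1):
        return done(ACTION_STRAND_FLIP_AND_SWAP, flip=True)
    return exclude(REASON_MISMATCH)


def harmonize_all(
    sentinels: Sequence,
    outcome_table: SummaryTable,
    proxies: Mapping[str, "object"] | None = None,
    ambiguity_window: tuple[float, float] = DEFAULT_AMBIGUITY_WINDOW,
) -> tuple[list[HarmonizedPair], dict[str, int]]:
    """Harmonize every active sentinel against an outcome table.

    ``proxies`` maps metabolite_id → :class:`metmr.instruments.ProxyAssignment`
    for sentinels resolved through an LD proxy; the proxy record's alleles
    are translated through the LD allele correspondence before harmonization.
    Returns one :class:`HarmonizedPair` per sentinel plus an audit counter of
    actions and exclusion reasons (conservation: inputs = harmonized +
    excluded).
    """
    proxies = proxies or {}
    by_rsid = outcome_table.by_rsid()
    pairs: list[HarmonizedPair] = []
    audit: Counter[str] = Counter()
    for s in sentinels:
        exp = s.record
        proxy = proxies.get(s.metabolite_id)
        out = by_rsid.get(proxy.rsid if proxy is not None else s.rsid)
        if out is None:
            pair = HarmonizedPair(
                rsid=exp.rsid,
                exposure=exp,
                outcome=exp,  # placeholder; pair is excluded
                action=ACTION_EXCLUDED,
                exclusion_reason=REASON_MISMATCH,
                eaf_window=ambiguity_window,
            )
        else:
            if proxy is not None:
                translated = translate_alleles(out, proxy.allele_map)
                if translated is None:
                    pairs.append(
                        HarmonizedPair(
                            rsid=exp.rsid,
                            exposure=exp,
                            outcome=out,
                            action=ACTION_EXCLUDED,
                            exclusion_reason=REASON_MISMATCH,
                            eaf_window=ambiguity_window,
                        )
                    )
                    audit["excluded:" + REASON_MISMATCH] += 1
                    continue
                out = translated
            pair = harmonize_pair(exp, out, ambiguity_window)
        pairs.append(pair)
        if pair.excluded:
            audit["excluded:" + (pair.exclusion_reason or "unknown")] += 1
        else:
            audit[pair.action] += 1
    return pairs, dict(audit)
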