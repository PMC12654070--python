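"""Sentinel-instrument selection, strength metrics, LD proxies and the
pleiotropy drop-list screen.

One variant instruments each metabolite: among the metabolite's independent
genome-wide significant signals (p < 5 × 10⁻⁸), the sentinel is the one with
the largest variance explained, ties broken by smaller p then lexicographic
rsID.  Sentinels falling in the FADS or MHC regions are excluded.  Instrument
strength is reported as R² = 2·EAF·(1−EAF)·β² (SD-scaled exposure) and the
first-stage F = (R²/k) / ((1−R²)/(n−k−1)) with k = 1; F is reported and
flagged when ≤ 10 but is not itself a filter.

When a sentinel is absent from an outcome file, a matched-ancestry LD proxy
with r² strictly above the threshold (default 0.8) may stand in; the proxy's
allele correspondence is carried into harmonization, and its identity and r²
propagate to the output tables.

The pleiotropy screen is offline and deterministic: a user-supplied
annotation table (standing in for a GWAS Catalog snapshot) is scanned for
genome-wide significant associations in domains offering alternative
pathways to leukemia risk (neoplastic, immune, hematologic, cardiometabolic)
or for the target outcome itself; flagged rsIDs form a drop list removed
before MR estimation.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from metmr.gwas_io import AssociationRecord

GW_SIG = 5e-8
PROXY_R2_MIN = 0.8
WEAK_F = 10.0

#: annotation domains; the first four are alternative-pathway ("flagged") domains
FLAGGED_DOMAINS = frozenset({"neoplastic", "immune", "hematologic", "cardiometabolic"})
DOMAINS = frozenset(FLAGGED_DOMAINS | {"metabolite", "other"})

#: default exclusion intervals (GRCh37 conventions, closed, configurable)
DEFAULT_EXCLUSION_REGIONS: dict[str, tuple[str, int, int]] = {
    "MHC": ("6", 25_000_000, 34_000_000),
    "FADS": ("11", 61_300_000, 61_900_000),
}

#: sentinel statuses
STATUS_ACTIVE = "active"
STATUS_UNINSTRUMENTED = "uninstrumented"
STATUS_EXCLUDED_REGION = "excluded_region"
STATUS_NO_OUTCOME_MATCH = "no_outcome_match"
STATUS_DROPPED_PLEIOTROPY = "dropped_pleiotropy"
STATUS_DROPPED_OUTCOME_GWAS = "dropped_outcome_gwas"

#: outcome label synonyms for the outcome-specific drop rule
OUTCOME_TRAIT_SYNONYMS: dict[str, frozenset[str]] = {
    "AML": frozenset({"aml", "acute myeloid leukemia", "acute myeloid leukaemia"}),
    "CML": frozenset({"cml", "chronic myeloid leukemia", "chronic myeloid leukaemia"}),
    "ALL": frozenset(
        {"all", "acute lymphoblastic leukemia", "acute lymphoblastic leukaemia"}
    ),
    "CLL": frozenset(
        {"cll", "chronic lymphocytic leukemia", "chronic lymphocytic leukaemia"}
    ),
}


def variance_explained(beta: float, eaf: float) -> float:
    """Variance in an SD-scaled exposure explained by one biallelic variant.

    R² = 2·eaf·(1−eaf)·β², clamped to [0, 1).  Requires 0 < eaf < 1.
    """
    if not 0.0 < eaf < 1.0:
        raise ValueError(f"monomorphic variant: eaf={eaf}")
    r2 = 2.0 * eaf * (1.0 - eaf) * beta * beta
    return float(min(max(r2, 0.0), np.nextafter(1.0, 0.0)))


def f_statistic(r2: float, n: int, k: int = 1) -> float:
    """First-stage F statistic, F = (R²/k) / ((1−R²)/(n−k−1))."""
    if not 0.0 <= r2 < 1.0:
        raise ValueError(f"r2 must be in [0, 1): {r2}")
    if n <= k + 1:
        raise ValueError(f"need n > k + 1 (n={n}, k={k})")
    return (r2 / k) / ((1.0 - r2) / (n - k - 1))


@dataclass
class SentinelInstrument:
    """The chosen per-metabolite instrument, with strength and provenance."""

    metabolite_id: str
    rsid: str
    effector_gene: str
    record: AssociationRecord
    r2: float
    f_stat: float
    proxy_rsid: str | None = None
    proxy_r2: float | None = None
    proxy_allele_map: dict[str, str] | None = None
    status: str = STATUS_ACTIVE
    status_reason: str | None = None
    annotations: list[tuple[str, str, float]] = field(default_factory=list)

    @property
    def weak(self) -> bool:
        return self.f_stat <= WEAK_F

    @property
    def rsid_used(self) -> str:
        """rsID actually looked up in the outcome table (proxy if assigned)."""
        return self.proxy_rsid if self.proxy_rsid is not None else self.rsid


@dataclass(frozen=True)
class ProxyAssignment:
    rsid: str
    r2: float
    allele_map: dict[str, str]  # sentinel allele -> proxy allele


def select_sentinel(
    metabolite_id: str,
    candidates: Sequence[AssociationRecord],
    r2_of: Mapping[str, float] | None = None,
    gw_threshold: float = GW_SIG,
) -> SentinelInstrument | None:
    """Pick the sentinel among a metabolite's independent signals.

    Eligible candidates must reach genome-wide significance (p strictly below
    ``gw_threshold``); among them the one with maximal R² wins, ties broken
    by smaller p then lexicographic rsID.  Returns ``None`` when no candidate
    qualifies (the metabolite is uninstrumented — not an error).

    ``r2_of`` maps rsid → variance explained; when omitted, R² is computed
    from each record's beta and EAF.
    """
    eligible = [c for c in candidates if c.is_valid() and c.pval < gw_threshold]
    if not eligible:
        return None

    def r2_for(rec: AssociationRecord) -> float:
        if r2_of is not None and rec.rsid in r2_of:
            return float(r2_of[rec.rsid])
        if rec.eaf is None:
            raise ValueError(f"cannot compute R² for {rec.rsid}: missing eaf")
        return variance_explained(rec.beta, rec.eaf)

    best = min(eligible, key=lambda c: (-r2_for(c), c.pval, c.rsid))
    r2 = r2_for(best)
    if best.n is None:
        raise ValueError(f"sentinel {best.rsid} lacks exposure sample size n")
    return SentinelInstrument(
        metabolite_id=metabolite_id,
        rsid=best.rsid,
        effector_gene=best.gene or "",
        record=best,
        r2=r2,
        f_stat=f_statistic(r2, best.n, k=1),
    )


def _norm_chrom(chrom: str | None) -> str | None:
    if chrom is None:
        return None
    c = str(chrom).strip()
    return c[3:] if c.lower().startswith("chr") else c


def apply_region_exclusions(
    sentinels: Iterable[SentinelInstrument],
    regions: Mapping[str, tuple[str, int, int]] | None = None,
) -> tuple[list[SentinelInstrument], list[SentinelInstrument]]:
    """Remove sentinels inside named exclusion intervals (closed bounds).

    Returns ``(kept, excluded)``; excluded sentinels get status
    ``excluded_region`` with the region name as the audit reason.  An empty
    region mapping is the identity.
    """
    regions = DEFAULT_EXCLUSION_REGIONS if regions is None else regions
    kept: list[SentinelInstrument] = []
    excluded: list[SentinelInstrument] = []
    for s in sentinels:
        chrom = _norm_chrom(s.record.chrom)
        pos = s.record.pos
        hit = None
        if chrom is not None and pos is not None:
            for name, (rchrom, start, end) in regions.items():
                if chrom == _norm_chrom(rchrom) and start <= pos <= end:
                    hit = name
                    break
        if hit is None:
            kept.append(s)
        else:
            s.status = STATUS_EXCLUDED_REGION
            s.status_reason = hit
            excluded.append(s)
    return kept, excluded


class LDTable:
    """Pairwise LD (r²) with allele correspondence, symmetric in (a, b).

    Each pair carries a bijective allele map from a's alleles onto b's; the
    table stores both orientations, inverting the map for the reverse
    direction.  On-disk format: TSV with columns ``rsid_a, rsid_b, r2,
    allele_map`` where the map is comma-separated ``A:C,G:T`` pairs.
    """

    def __init__(
        self, pairs: Iterable[tuple[str, str, float, Mapping[str, str]]] = ()
    ) -> None:
        self._partners: dict[str, list[tuple[str, float, dict[str, str]]]] = {}
        self._pairs: list[tuple[str, str, float, dict[str, str]]] = []
        for a, b, r2, amap in pairs:
            self.add(a, b, r2, amap)

    def add(self, a: str, b: str, r2: float, allele_map: Mapping[str, str]) -> None:
        if not 0.0 <= r2 <= 1.0:
            raise ValueError(f"r2 out of range for ({a}, {b}): {r2}")
        amap = {str(k).upper(): str(v).upper() for k, v in allele_map.items()}
        if len(set(amap.values())) != len(amap):
            raise ValueError(f"allele correspondence for ({a}, {b}) is not a bijection")
        inv = {v: k for k, v in amap.items()}
        self._pairs.append((a, b, float(r2), amap))
        self._partners.setdefault(a, []).append((b, float(r2), amap))
        self._partners.setdefault(b, []).append((a, float(r2), inv))

    def partners(self, rsid: str) -> list[tuple[str, float, dict[str, str]]]:
        return list(self._partners.get(rsid, ()))

    def __len__(self) -> int:
        return len(self._pairs)

    @staticmethod
    def _parse_map(text: str) -> dict[str, str]:
        out: dict[str, str] = {}
        for chunk in str(text).split(","):
            chunk = chunk.strip()
            if not chunk:
                continue
            k, v = chunk.split(":")
            out[k.strip()] = v.strip()
        return out

    @classmethod
    def read(cls, path: str | Path) -> "LDTable":
        df = pd.read_csv(path, sep="\t", dtype={"rsid_a": str, "rsid_b": str})
        return cls(
            (row.rsid_a, row.rsid_b, float(row.r2), cls._parse_map(row.allele_map))
            for row in df.itertuples()
        )

    def write(self, path: str | Path) -> None:
        rows = [
            {
                "rsid_a": a,
                "rsid_b": b,
                "r2": r2,
                "allele_map": ",".join(f"{k}:{v}" for k, v in sorted(amap.items())),
            }
            for a, b, r2, amap in self._pairs
        ]
        pd.DataFrame(rows, columns=["rsid_a", "rsid_b", "r2", "allele_map"]).to_csv(
            path, sep="\t", index=False, float_format="%.12g"
        )


def find_proxy(
    sentinel: SentinelInstrument,
    outcome_rsids: set[str],
    ld: LDTable,
    r2_min: float = PROXY_R2_MIN,
) -> ProxyAssignment | None:
    """Find the best LD proxy for a sentinel missing from an outcome table.

    Returns ``None`` when the sentinel is itself present (identity, no proxy
    needed) and when no outcome-present partner exceeds ``r2_min`` strictly
    (the caller then marks the metabolite ``no_outcome_match`` for that
    outcome).  Among qualifying partners the highest r² wins, ties broken by
    lexicographic rsID.
    """
    if sentinel.rsid in outcome_rsids:
        return None
    candidates = [
        (rsid, r2, amap)
        for rsid, r2, amap in ld.partners(sentinel.rsid)
        if rsid in outcome_rsids and r2 > r2_min
    ]
    if not candidates:
        return None
    rsid, r2, amap = min(candidates, key=lambda t: (-t[1], t[0]))
    return ProxyAssignment(rsid=rsid, r2=r2, allele_map=dict(amap))


class AnnotationTable:
    """Variant → trait annotations (offline GWAS Catalog stand-in).

    Columns: ``rsid, trait, domain, pval``; domains are drawn from the fixed
    vocabulary in :data:`DOMAINS`.
    """

    def __init__(self, entries: Iterable[tuple[str, str, str, float]] = ()) -> None:
        self._by_rsid: dict[str, list[tuple[str, str, float]]] = {}
        self._entries: list[tuple[str, str, str, float]] = []
        for rsid, trait, domain, pval in entries:
            self.add(rsid, trait, domain, pval)

    def add(self, rsid: str, trait: str, domain: str, pval: float) -> None:
        if domain not in DOMAINS:
            raise ValueError(f"unknown annotation domain: {domain!r}")
        self._entries.append((rsid, trait, domain, float(pval)))
        self._by_rsid.setdefault(rsid, []).append((trait, domain, float(pval)))

    def for_rsid(self, rsid: str) -> list[tuple[str, str, float]]:
        return list(self._by_rsid.get(rsid, ()))

    def __len__(self) -> int:
        return len(self._entries)

    @classmethod
    def read(cls, path: str | Path) -> "AnnotationTable":
        df = pd.read_csv(path, sep="\t", dtype={"rsid": str, "trait": str, "domain": str})
        return cls(
            (row.rsid, row.trait, row.domain, float(row.pval))
            for row in df.itertuples()
        )

    def write(self, path: str | Path) -> None:
        pd.DataFrame(
            self._entries, columns=["rsid", "trait", "domain", "pval"]
        ).to_csv(path, sep="\t", index=False, float_format="%.12g")


def _matches_outcome(trait: str, outcome_trait: str) -> bool:
    t = trait.strip().lower()
    o = outcome_trait.strip().lower()
    if t == o:
        return True
    synonyms = OUTCOME_TRAIT_SYNONYMS.get(outcome_trait.strip().upper())
    return synonyms is not None and t in synonyms


def screen_pleiotropy(
    sentinels: Iterable[SentinelInstrument],
    annotations: AnnotationTable,
    outcome_trait: str,
    gw_threshold: float = GW_SIG,
    flagged_domains: frozenset[str] = FLAGGED_DOMAINS,
) -> tuple[list[SentinelInstrument], list[SentinelInstrument]]:
    """Apply the drop-list screen to the rsIDs actually used (proxy-aware).

    A genome-wide significant annotation (p strictly below ``gw_threshold``)
    for the target outcome itself drops the instrument with status
    ``dropped_outcome_gwas``; otherwise any such annotation in a flagged
    domain drops it with ``dropped_pleiotropy``.  Retained instruments keep
    their annotations attached for reporting.  The screen is a pure function
    of (annotations, threshold, domain set): re-running changes nothing.
    """
    kept: list[SentinelInstrument] = []
    dropped: list[SentinelInstrument] = []
    for s in sentinels:
        anns = annotations.for_rsid(s.rsid_used)
        s.annotations = anns
        outcome_hit = any(
            pval < gw_threshold and _matches_outcome(trait, outcome_trait)
            for trait, _domain, pval in anns
        )
        pleio_hit = any(
            pval < gw_threshold
            and domain in flagged_domains
            and not _matches_outcome(trait, outcome_trait)
            for trait, domain, pval in anns
        )
        if outcome_hit:
            s = dataclasses.replace(
                s, status=STATUS_DROPPED_OUTCOME_GWAS, status_reason=outcome_trait
            )
            dropped.append(s)
        elif pleio_hit:
            domains_hit = sorted(
                {
                    d
                    for _t, d, p in anns
                    if p < gw_threshold and d in flagged_domains
                }
            )
            s = dataclasses.replace(
                s,
                status=STATUS_DROPPED_PLEIOTROPY,
                status_reason=",".join(domains_hit),
            )
            dropped.append(s)
        else:
            kept.append(s)
    return kept, dropped


def drop_list_frame(dropped: Sequence[SentinelInstrument]) -> pd.DataFrame:
    """Drop list as an exportable table with reason codes."""
    return pd.DataFrame(
        [
            {
                "metabolite": s.metabolite_id,
                "rsid": s.rsid_used,
                "status": s.status,
                "reason": s.status_reason,
            }
            for s in dropped
        ],
        columns=["metabolite", "rsid", "status", "reason"],
    )
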