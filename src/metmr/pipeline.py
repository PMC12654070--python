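"""End-to-end orchestration: raw summary tables → tiered MR results.

Stages run in order — read/validate → sentinel selection → region exclusion
→ outcome match/proxy → pleiotropy screen → harmonize → Wald ratio → tiering
→ power → drug join — each logged with counts, and all per-outcome analyses
are fully independent (permuting the outcome order changes nothing).  The
audit table proves stage conservation: at every stage kept + dropped equals
the previous stage's kept.

A run is deterministic given its config: the manifest records a config hash,
the seed and the package version, and re-running on the same synthetic
inputs reproduces every output byte-for-byte.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
import pandas as pd
import yaml

from metmr import gwas_io, harmonize, instruments, mr, power
from metmr.gwas_io import EXPOSURE_QUANTITATIVE, OUTCOME_BINARY, SummaryTable
from metmr.instruments import (
    AnnotationTable,
    LDTable,
    ProxyAssignment,
    SentinelInstrument,
)

logger = logging.getLogger("metmr.pipeline")


@dataclass
class PipelineConfig:
    """Paths and thresholds for one screen run."""

    exposure_path: str
    outcome_paths: dict[str, str]
    ld_path: str | None = None
    annotation_path: str | None = None
    drug_path: str | None = None
    out_dir: str | None = None
    gw_sig: float = instruments.GW_SIG
    proxy_r2_min: float = instruments.PROXY_R2_MIN
    ambiguity_window: tuple[float, float] = harmonize.DEFAULT_AMBIGUITY_WINDOW
    alpha: float = 0.05
    se_method: str = mr.FIRST_ORDER
    exclusion_regions: dict[str, tuple[str, int, int]] = field(
        default_factory=lambda: dict(instruments.DEFAULT_EXCLUSION_REGIONS)
    )
    or_targets: tuple[float, ...] = power.DEFAULT_OR_TARGETS
    exposure_dialect: dict[str, str] = field(default_factory=dict)
    outcome_dialect: dict[str, str] = field(default_factory=dict)
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0.0 < self.gw_sig < 1.0:
            raise ValueError("gw_sig must be in (0, 1)")
        if not 0.0 <= self.proxy_r2_min < 1.0:
            raise ValueError("proxy_r2_min must be in [0, 1)")
        if not 0.0 < self.alpha < 1.0:
            raise ValueError("alpha must be in (0, 1)")

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        if "ambiguity_window" in raw:
            raw["ambiguity_window"] = tuple(raw["ambiguity_window"])
        if "or_targets" in raw:
            raw["or_targets"] = tuple(raw["or_targets"])
        if "exclusion_regions" in raw:
            raw["exclusion_regions"] = {
                name: (str(v[0]), int(v[1]), int(v[2]))
                for name, v in raw["exclusion_regions"].items()
            }
        return cls(**raw)

    def to_yaml(self, path: str | Path) -> None:
        data = dataclasses.asdict(self)
        data["ambiguity_window"] = list(self.ambiguity_window)
        data["or_targets"] = list(self.or_targets)
        data["exclusion_regions"] = {
            k: [v[0], v[1], v[2]] for k, v in self.exclusion_regions.items()
        }
        with open(path, "w") as fh:
            yaml.safe_dump(data, fh, sort_keys=True)

    def config_hash(self) -> str:
        """Hash of the analytic configuration (output location excluded)."""
        data = dataclasses.asdict(self)
        data.pop("out_dir", None)
        payload = json.dumps(data, sort_keys=True, default=str).encode()
        return hashlib.sha256(payload).hexdigest()[:16]


@dataclass
class ResultsBundle:
    """All pipeline outputs for one run."""

    results: dict[str, pd.DataFrame]  # per-outcome MR result tables
    audit: pd.DataFrame  # stage-by-stage counts (conservation holds)
    instruments: pd.DataFrame  # sentinel strength table (R², F, n)
    power: pd.DataFrame
    drug_annotated: pd.DataFrame
    harmonization: pd.DataFrame  # one audit row per sentinel × outcome
    manifest: dict

    def combined_results(self) -> pd.DataFrame:
        frames = [df for df in self.results.values() if len(df)]
        if not frames:
            return pd.DataFrame(columns=list(gwas_io.RESULT_COLUMNS))
        return pd.concat(frames, ignore_index=True)

    def check_conservation(self) -> bool:
        """Every stage's input must equal kept + dropped, per outcome."""
        for (_outcome, _stage), row in self.audit.set_index(
            ["outcome", "stage"]
        ).iterrows():
            if row["n_in"] != row["n_kept"] + row["n_dropped"]:
                return False
        return True


def drug_join(results: pd.DataFrame, drugs: pd.DataFrame) -> pd.DataFrame:
    """Join significant/suggestive metabolites to their effector gene's drugs.

    Every result row is preserved; metabolites whose gene has no drug entry
    pass through unannotated, and null-tier rows are never joined.  The join
    is idempotent: re-joining an already annotated table first strips the
    drug columns it would add.
    """
    drug_cols = [c for c in drugs.columns if c != "metabolite"]
    base = results.drop(
        columns=[c for c in drug_cols if c in results.columns]
    ).drop_duplicates()
    if len(base) == 0:
        return base.copy()
    joinable = drugs.drop(columns=["metabolite"]).drop_duplicates()
    eligible = base["tier"].isin([mr.TIER_SIGNIFICANT, mr.TIER_SUGGESTIVE]) & base[
        "gene"
    ].isin(set(joinable["effector_gene"]))
    hits = base[eligible].merge(
        joinable, left_on="gene", right_on="effector_gene", how="left"
    )
    rest = base[~eligible].copy()
    out = pd.concat([hits, rest], ignore_index=True)
    sort_cols = [c for c in ("outcome", "metabolite", "drugbank_id") if c in out.columns]
    return out.sort_values(sort_cols, na_position="last").reset_index(drop=True)


def _outcome_sizes(table: SummaryTable) -> tuple[int, int]:
    """Outcome GWAS (n_total, n_cases) taken from its records."""
    ns = [r.n for r in table.valid_records() if r.n is not None]
    cases = [r.n_cases for r in table.valid_records() if r.n_cases is not None]
    if not ns or not cases:
        raise ValueError("outcome table lacks n / n_cases fields")
    return int(max(ns)), int(max(cases))


def run_pipeline(cfg: PipelineConfig) -> ResultsBundle:
    """Execute the full screen; never crashes on an empty stage.

    Any stage that leaves zero instruments produces a bundle with empty
    result tables and an explanatory audit instead of raising.
    """
    audit_rows: list[dict] = []

    def log_stage(outcome: str, stage: str, n_in: int, n_kept: int, detail: str = ""):
        audit_rows.append(
            {
                "outcome": outcome,
                "stage": stage,
                "n_in": n_in,
                "n_kept": n_kept,
                "n_dropped": n_in - n_kept,
                "detail": detail,
            }
        )
        logger.info("%s/%s: %d -> %d (%s)", outcome, stage, n_in, n_kept, detail)

    # ---- shared exposure-side stages -------------------------------------
    exposure = gwas_io.read_summary_stats(
        cfg.exposure_path, EXPOSURE_QUANTITATIVE, dialect=cfg.exposure_dialect
    )
    report = gwas_io.validate_table(exposure)
    reason_counts = pd.Series([r for _, r in report.exclusions]).value_counts().to_dict()
    log_stage("all", "read_validate", report.n_input, report.n_valid, str(reason_counts))

    candidates: dict[str, list] = {}
    for rec in exposure.valid_records():
        candidates.setdefault(rec.trait_id, []).append(rec)
    n_metabolites = len(candidates)

    sentinels: list[SentinelInstrument] = []
    uninstrumented: list[str] = []
    for met in sorted(candidates):
        s = instruments.select_sentinel(met, candidates[met], gw_threshold=cfg.gw_sig)
        if s is None:
            uninstrumented.append(met)
        else:
            sentinels.append(s)
    log_stage(
        "all", "sentinel_selection", n_metabolites, len(sentinels),
        f"uninstrumented={len(uninstrumented)}",
    )

    kept, region_excluded = instruments.apply_region_exclusions(
        sentinels, cfg.exclusion_regions
    )
    log_stage(
        "all", "region_exclusion", len(sentinels), len(kept),
        ",".join(sorted({s.status_reason or "" for s in region_excluded})),
    )

    instrument_rows = [
        {
            "metabolite": s.metabolite_id,
            "rsid": s.rsid,
            "gene": s.effector_gene,
            "r2": s.r2,
            "f_stat": s.f_stat,
            "n": s.record.n,
            "weak": s.weak,
            "status": s.status,
        }
        for s in kept + region_excluded
    ]
    instrument_table = pd.DataFrame(
        instrument_rows,
        columns=["metabolite", "rsid", "gene", "r2", "f_stat", "n", "weak", "status"],
    ).sort_values("metabolite").reset_index(drop=True)

    ld = LDTable.read(cfg.ld_path) if cfg.ld_path else LDTable()
    annotations = (
        AnnotationTable.read(cfg.annotation_path) if cfg.annotation_path
        else AnnotationTable()
    )
    drugs = (
        pd.read_csv(cfg.drug_path, sep="\t") if cfg.drug_path
        else pd.DataFrame(columns=["metabolite", "effector_gene"])
    )

    # ---- per-outcome stages (fully independent) --------------------------
    results: dict[str, pd.DataFrame] = {}
    harmonization_rows: list[dict] = []
    power_frames: list[pd.DataFrame] = []
    for outcome_id in sorted(cfg.outcome_paths):
        outcome_table = gwas_io.read_summary_stats(
            cfg.outcome_paths[outcome_id], OUTCOME_BINARY,
            dialect=cfg.outcome_dialect, trait_id=outcome_id,
        )
        outcome_rsids = outcome_table.rsids()

        matched: list[SentinelInstrument] = []
        proxies: dict[str, ProxyAssignment] = {}
        unmatched = 0
        for s in kept:
            if s.rsid in outcome_rsids:
                matched.append(s)
                continue
            proxy = instruments.find_proxy(s, outcome_rsids, ld, cfg.proxy_r2_min)
            if proxy is None:
                unmatched += 1
                continue
            s2 = dataclasses.replace(
                s, proxy_rsid=proxy.rsid, proxy_r2=proxy.r2,
                proxy_allele_map=proxy.allele_map,
            )
            proxies[s2.metabolite_id] = proxy
            matched.append(s2)
        log_stage(
            outcome_id, "outcome_match", len(kept), len(matched),
            f"proxies={len(proxies)} no_outcome_match={unmatched}",
        )

        screened, dropped = instruments.screen_pleiotropy(
            matched, annotations, outcome_id, gw_threshold=cfg.gw_sig
        )
        drop_counts = pd.Series([s.status for s in dropped]).value_counts().to_dict()
        log_stage(
            outcome_id, "pleiotropy_screen", len(matched), len(screened),
            str(drop_counts),
        )

        pairs, h_audit = harmonize.harmonize_all(
            screened, outcome_table, proxies, cfg.ambiguity_window
        )
        estimable = [
            (p, s) for p, s in zip(pairs, screened) if not p.excluded
        ]
        log_stage(outcome_id, "harmonize", len(screened), len(estimable), str(h_audit))
        for p, s in zip(pairs, screened):
            harmonization_rows.append(
                {
                    "outcome": outcome_id,
                    "metabolite": s.metabolite_id,
                    "rsid": s.rsid,
                    "proxy_rsid": s.proxy_rsid,
                    "action": p.action,
                    "exclusion_reason": p.exclusion_reason,
                    "eaf_exposure": p.exposure.eaf,
                    "eaf_outcome": p.outcome.eaf if not p.excluded else None,
                }
            )

        mcfg = mr.MultiplicityConfig(n_tests=max(len(estimable), 1), alpha=cfg.alpha)
        mr_results = [
            mr.estimate_pair(p, s, outcome_id, mcfg, cfg.se_method)
            for p, s in estimable
        ]
        n_sig = sum(r.tier == mr.TIER_SIGNIFICANT for r in mr_results)
        n_sugg = sum(r.tier == mr.TIER_SUGGESTIVE for r in mr_results)
        log_stage(
            outcome_id, "wald_ratio", len(estimable), len(mr_results),
            f"significant={n_sig} suggestive={n_sugg} "
            f"bonferroni={mcfg.bonferroni_threshold:.3g}",
        )

        results[outcome_id] = pd.DataFrame(
            [r.to_row() for r in mr_results], columns=list(gwas_io.RESULT_COLUMNS)
        ).sort_values(["metabolite"]).reset_index(drop=True)

        # power at the prespecified target ORs, per metabolite actually tested
        if estimable:
            n_total, n_cases = _outcome_sizes(outcome_table)
            r2_map = {s.metabolite_id: s.r2 for _p, s in estimable}
            power_frames.append(
                power.power_table(
                    {outcome_id: (n_total, n_cases)}, r2_map,
                    or_targets=cfg.or_targets, alpha=cfg.alpha,
                )
            )

    power_df = (
        pd.concat(power_frames, ignore_index=True) if power_frames
        else pd.DataFrame(
            columns=["outcome", "metabolite", "n_total", "n_cases", "r2",
                     "or_target", "power"]
        )
    )
    audit = pd.DataFrame(
        audit_rows, columns=["outcome", "stage", "n_in", "n_kept", "n_dropped", "detail"]
    )
    all_results = (
        pd.concat([df for df in results.values()], ignore_index=True)
        if results else pd.DataFrame(columns=list(gwas_io.RESULT_COLUMNS))
    )
    drug_annotated = (
        drug_join(all_results, drugs)
        if len(all_results) and len(drugs) else all_results.copy()
    )

    bundle = ResultsBundle(
        results=results,
        audit=audit,
        instruments=instrument_table,
        power=power_df,
        drug_annotated=drug_annotated,
        harmonization=pd.DataFrame(
            harmonization_rows,
            columns=["outcome", "metabolite", "rsid", "proxy_rsid", "action",
                     "exclusion_reason", "eaf_exposure", "eaf_outcome"],
        ),
        manifest={
            "config_hash": cfg.config_hash(),
            "seed": cfg.seed,
            "version": _package_version(),
            "n_metabolites": n_metabolites,
            "n_sentinels": len(sentinels),
            "outcomes": sorted(cfg.outcome_paths),
        },
    )
    if cfg.out_dir:
        write_bundle_outputs(bundle, cfg.out_dir)
    return bundle


def _package_version() -> str:
    from metmr import __version__

    return __version__


def write_bundle_outputs(bundle: ResultsBundle, out_dir: str | Path) -> dict[str, Path]:
    """Write every bundle table under ``out_dir`` (deterministic content)."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    paths: dict[str, Path] = {}
    for outcome_id, df in bundle.results.items():
        p = out / f"results_{outcome_id}.tsv"
        df.to_csv(p, sep="\t", index=False, float_format="%.12g")
        paths[f"results:{outcome_id}"] = p
    for name, df in (
        ("audit", bundle.audit),
        ("instruments", bundle.instruments),
        ("power", bundle.power),
        ("drugs_annotated", bundle.drug_annotated),
        ("harmonization", bundle.harmonization),
    ):
        p = out / f"{name}.tsv"
        df.to_csv(p, sep="\t", index=False, float_format="%.12g")
        paths[name] = p
    manifest_path = out / "manifest.json"
    with open(manifest_path, "w") as fh:
        json.dump(bundle.manifest, fh, indent=2, sort_keys=True)
        fh.write("\n")
    paths["manifest"] = manifest_path
    return paths
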