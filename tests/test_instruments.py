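"""Sentinel selection, instrument strength, proxies, pleiotropy screening."""

import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st

from metmr.gwas_io import AssociationRecord
from metmr.instruments import (
    AnnotationTable,
    LDTable,
    apply_region_exclusions,
    f_statistic,
    find_proxy,
    screen_pleiotropy,
    select_sentinel,
    variance_explained,
)


def _rec(rsid, pval=1e-10, beta=0.2, eaf=0.3, chrom="1", pos=10_000_000, n=8299):
    return AssociationRecord(
        rsid, "A", "G", beta, 0.02, pval, trait_id="met",
        chrom=chrom, pos=pos, eaf=eaf, n=n, gene="GENE1",
    )


class TestVarianceExplained:
    @pytest.mark.parametrize(
        "beta, eaf, expected",
        [(1.0, 0.5, 0.5), (0.0, 0.3, 0.0), (0.3, 0.1, 0.0162)],
    )
    def test_closed_form(self, beta, eaf, expected):
        assert variance_explained(beta, eaf) == pytest.approx(expected, abs=1e-12)

    def test_monomorphic_is_error(self):
        with pytest.raises(ValueError):
            variance_explained(0.2, 0.0)
        with pytest.raises(ValueError):
            variance_explained(0.2, 1.0)

    def test_matches_sample_r2_from_simulated_cohort(self, rng):
        # closed form vs the R² of an actual regression at n = 1e5
        n, maf, beta = 100_000, 0.1, 0.3
        g = rng.binomial(2, maf, n)
        x = beta * g + rng.standard_normal(n)
        x = (x - x.mean()) / x.std(ddof=1)
        slope = np.cov(g, x)[0, 1] / np.var(g, ddof=1)
        sample_r2 = np.corrcoef(g, x)[0, 1] ** 2
        assert variance_explained(slope, g.mean() / 2) == pytest.approx(
            sample_r2, rel=1e-2
        )


class TestFStatistic:
    def test_closed_form(self):
        assert f_statistic(0.1, 1001, 1) == pytest.approx(111.0, abs=1e-9)
        assert f_statistic(0.0, 1001) == 0.0

    def test_errors(self):
        with pytest.raises(ValueError):
            f_statistic(1.0, 1001)
        with pytest.raises(ValueError):
            f_statistic(0.1, 2, 1)

    @given(
        r2=st.floats(1e-6, 0.5),
        r2_step=st.floats(1e-6, 0.4),
        n=st.integers(100, 10_000),
        n_step=st.integers(1, 5_000),
    )
    def test_monotone_in_r2_and_n(self, r2, r2_step, n, n_step):
        assert f_statistic(r2 + r2_step, n) > f_statistic(r2, n)
        assert f_statistic(r2, n + n_step) > f_statistic(r2, n)


class TestSelectSentinel:
    def test_argmax_r2(self):
        cands = [_rec("rs1", beta=0.15), _rec("rs2", beta=0.26), _rec("rs3", beta=0.21)]
        s = select_sentinel("met", cands)
        assert s.rsid == "rs2"
        assert s.r2 == pytest.approx(variance_explained(0.26, 0.3))
        assert s.f_stat == pytest.approx(f_statistic(s.r2, 8299))

    def test_threshold_then_p_tiebreak(self):
        # equal R²: the sub-threshold candidate is ineligible, leaving rs_b
        cands = [_rec("rs_a", pval=1e-7), _rec("rs_b", pval=1e-9)]
        s = select_sentinel("met", cands)
        assert s.rsid == "rs_b"
        # both eligible with equal R²: smaller p wins
        cands = [_rec("rs_a", pval=1e-9), _rec("rs_b", pval=1e-12)]
        assert select_sentinel("met", cands).rsid == "rs_b"
        # full tie: lexicographic rsid
        cands = [_rec("rs_b", pval=1e-9), _rec("rs_a", pval=1e-9)]
        assert select_sentinel("met", cands).rsid == "rs_a"

    def test_no_genomewide_candidate_is_uninstrumented(self):
        cands = [_rec("rs1", pval=1e-6), _rec("rs2", pval=1e-6)]
        assert select_sentinel("met", cands) is None

    def test_boundary_p_is_ineligible(self):
        assert select_sentinel("met", [_rec("rs1", pval=5e-8)]) is None


def _sentinel(rsid="rs1", chrom="1", pos=10_000_000, **kw):
    rec = _rec(rsid, chrom=chrom, pos=pos)
    s = select_sentinel("met_" + rsid, [rec])
    for k, v in kw.items():
        setattr(s, k, v)
    return s


class TestRegionExclusions:
    @pytest.mark.parametrize(
        "chrom, pos, kept",
        [
            ("6", 30_000_000, False),  # inside MHC
            ("11", 61_500_000, False),  # inside FADS
            ("1", 61_500_000, True),
            ("6", 24_999_999, True),  # just outside (closed interval)
            ("6", 25_000_000, False),  # boundary included
        ],
    )
    def test_default_regions(self, chrom, pos, kept):
        kept_list, excluded = apply_region_exclusions([_sentinel(chrom=chrom, pos=pos)])
        assert (len(kept_list) == 1) is kept
        if not kept:
            assert excluded[0].status == "excluded_region"

    def test_empty_region_list_is_identity(self):
        s = _sentinel(chrom="6", pos=30_000_000)
        kept, excluded = apply_region_exclusions([s], regions={})
        assert kept == [s] and excluded == []


class TestFindProxy:
    def _ld(self):
        return LDTable(
            [
                ("rs1", "rsP1", 0.85, {"A": "T", "G": "C"}),
                ("rs1", "rsP2", 0.92, {"A": "A", "G": "G"}),
                ("rs1", "rsP3", 0.80, {"A": "A", "G": "G"}),
            ]
        )

    def test_highest_r2_wins(self):
        p = find_proxy(_sentinel(), {"rsP1", "rsP2", "rsP3"}, self._ld())
        assert p.rsid == "rsP2" and p.r2 == pytest.approx(0.92)

    def test_threshold_is_strict(self):
        assert find_proxy(_sentinel(), {"rsP3"}, self._ld()) is None

    def test_sentinel_present_means_no_proxy(self):
        assert find_proxy(_sentinel(), {"rs1", "rsP2"}, self._ld()) is None

    def test_ld_table_is_symmetric_with_inverted_map(self):
        ld = self._ld()
        partners = {rsid: amap for rsid, _r2, amap in ld.partners("rsP1")}
        assert partners["rs1"] == {"T": "A", "C": "G"}

    def test_non_bijective_map_rejected(self):
        with pytest.raises(ValueError):
            LDTable([("rs1", "rs2", 0.9, {"A": "T", "G": "T"})])

    def test_roundtrip(self, tmp_path):
        ld = self._ld()
        ld.write(tmp_path / "ld.tsv")
        back = LDTable.read(tmp_path / "ld.tsv")
        assert {r for r, _, _ in back.partners("rs1")} == {"rsP1", "rsP2", "rsP3"}


class TestPleiotropyScreen:
    def test_outcome_gwas_hit_takes_precedence(self):
        ann = AnnotationTable(
            [("rs1", "chronic lymphocytic leukemia", "neoplastic", 1e-9)]
        )
        kept, dropped = screen_pleiotropy([_sentinel()], ann, "CLL")
        assert not kept and dropped[0].status == "dropped_outcome_gwas"

    def test_metabolite_domain_annotations_are_benign(self):
        ann = AnnotationTable([("rs1", "some metabolite", "metabolite", 1e-30)])
        kept, dropped = screen_pleiotropy([_sentinel()], ann, "CLL")
        assert len(kept) == 1 and not dropped
        assert kept[0].annotations  # retained for reporting

    @pytest.mark.parametrize(
        "pval, is_dropped", [(2e-8, True), (1e-7, False)]
    )
    def test_genomewide_threshold_both_sides(self, pval, is_dropped):
        ann = AnnotationTable([("rs1", "LDL cholesterol", "cardiometabolic", pval)])
        kept, dropped = screen_pleiotropy([_sentinel()], ann, "CLL")
        if is_dropped:
            assert dropped[0].status == "dropped_pleiotropy"
        else:
            assert len(kept) == 1

    def test_proxy_rsid_is_screened_not_sentinel(self):
        ann = AnnotationTable([("rsP", "melanoma", "neoplastic", 1e-10)])
        s = _sentinel(proxy_rsid="rsP", proxy_r2=0.9)
        kept, dropped = screen_pleiotropy([s], ann, "CLL")
        assert dropped and dropped[0].status == "dropped_pleiotropy"

    def test_audit_conservation_and_determinism(self):
        ann = AnnotationTable(
            [
                ("rs1", "melanoma", "neoplastic", 1e-10),
                ("rs2", "some metabolite", "metabolite", 1e-10),
                ("rs3", "CLL", "neoplastic", 1e-10),
            ]
        )
        sentinels = [_sentinel(r) for r in ("rs1", "rs2", "rs3")]
        kept, dropped = screen_pleiotropy(sentinels, ann, "CLL")
        assert len(kept) + len(dropped) == 3
        kept2, dropped2 = screen_pleiotropy(sentinels, ann, "CLL")
        assert [s.rsid for s in kept2] == [s.rsid for s in kept]
        assert [s.status for s in dropped2] == [s.status for s in dropped]

    def test_unknown_domain_rejected(self):
        with pytest.raises(ValueError):
            AnnotationTable([("rs1", "x", "astrology", 1e-10)])
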