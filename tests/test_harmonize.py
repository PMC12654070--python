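"""Allele harmonization: action assignment, palindrome resolution, algebra."""

import itertools

import pytest

from metmr.gwas_io import AssociationRecord
from metmr.harmonize import (
    ACTION_EXCLUDED,
    ACTION_NONE,
    ACTION_STRAND_FLIP,
    ACTION_STRAND_FLIP_AND_SWAP,
    ACTION_SWAP_FLIP,
    COMPLEMENT,
    harmonize_all,
    harmonize_pair,
    translate_alleles,
)

ALLELES = "ACGT"


def _exp(ea="A", oa="G", beta=0.5, eaf=0.2):
    return AssociationRecord("rs1", ea, oa, beta, 0.05, 1e-10, trait_id="met", eaf=eaf)


def _out(ea="A", oa="G", beta=0.2, eaf=0.2):
    return AssociationRecord("rs1", ea, oa, beta, 0.1, 0.01, trait_id="CLL", eaf=eaf)


class TestActions:
    def test_identity(self):
        pair = harmonize_pair(_exp(), _out())
        assert pair.action == ACTION_NONE
        assert pair.outcome.beta == pytest.approx(0.2)
        assert pair.outcome.eaf == pytest.approx(0.2)

    def test_swap_flip_negates_and_complements_together(self):
        pair = harmonize_pair(_exp(), _out("G", "A", beta=0.2, eaf=0.8))
        assert pair.action == ACTION_SWAP_FLIP
        assert pair.outcome.beta == pytest.approx(-0.2)
        assert pair.outcome.eaf == pytest.approx(0.2)
        assert pair.outcome.alleles == ("A", "G")

    def test_strand_flip_relabels_only(self):
        pair = harmonize_pair(_exp(), _out("T", "C", beta=0.2, eaf=0.2))
        assert pair.action == ACTION_STRAND_FLIP
        assert pair.outcome.beta == pytest.approx(0.2)
        assert pair.outcome.alleles == ("A", "G")

    def test_strand_flip_and_swap(self):
        pair = harmonize_pair(_exp(), _out("C", "T", beta=0.2, eaf=0.8))
        assert pair.action == ACTION_STRAND_FLIP_AND_SWAP
        assert pair.outcome.beta == pytest.approx(-0.2)
        assert pair.outcome.eaf == pytest.approx(0.2)

    def test_mismatch_excluded(self):
        pair = harmonize_pair(_exp("A", "G"), _out("A", "C"))
        assert pair.action == ACTION_EXCLUDED
        assert pair.exclusion_reason == "allele_mismatch"

    def test_non_acgt_excluded_never_raises(self):
        pair = harmonize_pair(_exp("A", "G"), _out("I", "D"))
        assert pair.exclusion_reason == "non_acgt"


class TestPalindromes:
    def test_opposite_strand_labels_resolved_by_frequency(self):
        # exposure A freq 0.10; outcome reports A at 0.88: the outcome's "A"
        # is really the flipped-strand T, so beta negates and eaf complements
        pair = harmonize_pair(_exp("A", "T", eaf=0.10), _out("A", "T", beta=0.2, eaf=0.88))
        assert pair.action == ACTION_STRAND_FLIP_AND_SWAP
        assert pair.outcome.beta == pytest.approx(-0.2)
        assert pair.outcome.eaf == pytest.approx(0.12)

    def test_same_strand_agreeing_frequencies_pass_through(self):
        pair = harmonize_pair(_exp("A", "T", eaf=0.10), _out("A", "T", beta=0.2, eaf=0.12))
        assert pair.action == ACTION_NONE
        assert pair.outcome.beta == pytest.approx(0.2)

    def test_maximal_ambiguity_excluded(self):
        pair = harmonize_pair(_exp("A", "T", eaf=0.10), _out("A", "T", eaf=0.50))
        assert pair.exclusion_reason == "palindromic_ambiguous"

    def test_window_is_closed_and_configurable(self):
        out = _out("A", "T", eaf=0.42)
        assert harmonize_pair(_exp("A", "T", eaf=0.1), out).excluded
        wide = harmonize_pair(_exp("A", "T", eaf=0.1), out, ambiguity_window=(0.45, 0.55))
        assert not wide.excluded

    def test_missing_outcome_eaf_palindromic_excluded(self):
        pair = harmonize_pair(_exp("A", "T", eaf=0.1), _out("A", "T", eaf=None))
        assert pair.exclusion_reason == "palindromic_ambiguous"

    def test_missing_outcome_eaf_non_palindromic_resolved_by_labels(self):
        pair = harmonize_pair(_exp("A", "G", eaf=0.1), _out("G", "A", eaf=None))
        assert pair.action == ACTION_SWAP_FLIP
        assert pair.outcome.beta == pytest.approx(-0.2)
        assert pair.outcome.eaf is None


def _enumerate_pairs():
    for e1, e2 in itertools.permutations(ALLELES, 2):
        for o1, o2 in itertools.permutations(ALLELES, 2):
            yield e1, e2, o1, o2


class TestExhaustiveness:
    def test_every_configuration_maps_to_exactly_one_action(self):
        """All 12 × 12 ordered allele configurations resolve deterministically,
        and aligned pairs satisfy the post-alignment invariant."""
        seen = 0
        for e1, e2, o1, o2 in _enumerate_pairs():
            exp = _exp(e1, e2, eaf=0.2)
            out = _out(o1, o2, eaf=0.2 if o1 in (e1, COMPLEMENT[e1]) else 0.8)
            pair = harmonize_pair(exp, out)
            seen += 1
            assert pair.action in (
                ACTION_NONE, ACTION_SWAP_FLIP, ACTION_STRAND_FLIP,
                ACTION_STRAND_FLIP_AND_SWAP, ACTION_EXCLUDED,
            )
            if not pair.excluded:
                assert pair.outcome.effect_allele == exp.effect_allele
                assert pair.outcome.other_allele == exp.other_allele
        assert seen == 144

    def test_involution(self):
        """Harmonizing an already-harmonized pair is the identity."""
        for e1, e2, o1, o2 in _enumerate_pairs():
            exp = _exp(e1, e2, eaf=0.2)
            out = _out(o1, o2, eaf=0.2 if o1 in (e1, COMPLEMENT[e1]) else 0.8)
            pair = harmonize_pair(exp, out)
            if pair.excluded:
                continue
            again = harmonize_pair(exp, pair.outcome)
            assert again.action == ACTION_NONE
            assert again.outcome.beta == pair.outcome.beta
            assert again.outcome.eaf == pair.outcome.eaf

    def test_double_swap_flip_restores_original(self):
        out = _out("G", "A", beta=0.2, eaf=0.8)
        once = harmonize_pair(_exp(), out).outcome
        twice = harmonize_pair(
            AssociationRecord("rs1", "G", "A", 0.5, 0.05, 1e-10, eaf=0.8), once
        ).outcome
        assert twice.beta == pytest.approx(out.beta)
        assert twice.eaf == pytest.approx(out.eaf)
        assert twice.alleles == out.alleles


class TestProxyTranslation:
    def test_translation_then_harmonization_matches_brute_force(self):
        """Composing the LD allele correspondence with harmonization equals
        direct harmonization in sentinel-allele space, for every labelling of
        the proxy's two alleles."""
        amap = {"A": "C", "G": "T"}  # sentinel A/G <-> proxy C/T
        exp = _exp("A", "G", eaf=0.2)
        for (p1, p2), swapped in (( ("C", "T"), False), (("T", "C"), True)):
            out = _out(p1, p2, beta=0.2, eaf=0.8 if swapped else 0.2)
            translated = translate_alleles(out, amap)
            pair = harmonize_pair(exp, translated)
            # oracle: in sentinel space the proxy record is A/G or G/A
            direct = harmonize_pair(
                exp, _out("G" if swapped else "A", "A" if swapped else "G",
                          beta=0.2, eaf=out.eaf)
            )
            assert pair.action == direct.action
            assert pair.outcome.beta == direct.outcome.beta
            assert pair.outcome.eaf == direct.outcome.eaf

    def test_uncovered_alleles_return_none(self):
        assert translate_alleles(_out("A", "G"), {"A": "C", "G": "T"}) is None


class TestHarmonizeAll:
    def test_accounting(self, small_screen):
        from metmr import instruments

        _cfg, bundle = small_screen
        cands = {}
        for rec in bundle.exposure_table.valid_records():
            cands.setdefault(rec.trait_id, []).append(rec)
        sentinels = [
            s for met in sorted(cands)
            if (s := instruments.select_sentinel(met, cands[met])) is not None
        ]
        present = bundle.outcome_tables["CLL"].rsids()
        sentinels = [s for s in sentinels if s.rsid in present]
        pairs, audit = harmonize_all(sentinels, bundle.outcome_tables["CLL"])
        assert len(pairs) == len(sentinels)
        assert sum(audit.values()) == len(sentinels)
        n_excluded = sum(v for k, v in audit.items() if k.startswith("excluded"))
        assert n_excluded == sum(p.excluded for p in pairs)
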