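"""Synthetic-data generator: determinism, marginals, route equivalence."""

import numpy as np
import pandas as pd
import pytest

from metmr import gwas_io
from metmr.simulate import (
    ScenarioConfig,
    SimTruth,
    beta_gx_for_r2,
    child_seed,
    simulate_pair,
    simulate_screen,
    simulate_summary,
    solve_intercept,
    _genotype_risks,
)


def _truth(**kw):
    base = dict(
        metabolite_id="m", rsid="rs1", maf=0.3,
        beta_gx=beta_gx_for_r2(0.02, 0.3), theta=0.0,
        n_exp=8299, n_out=50_000, n_cases=100, seed=11,
    )
    base.update(kw)
    return SimTruth(**base)


class TestSimTruth:
    def test_r2_roundtrip(self):
        t = _truth()
        assert t.r2 == pytest.approx(0.02, rel=1e-12)

    def test_invalid_maf_rejected(self):
        with pytest.raises(ValueError):
            _truth(maf=0.0)
        with pytest.raises(ValueError):
            _truth(maf=0.7)


class TestInterceptSolver:
    def test_expected_case_fraction_matches_target(self):
        t = _truth(theta=1.0, n_cases=250)
        alpha = solve_intercept(t)
        k = float(t.hwe_probs @ _genotype_risks(t, alpha))
        assert k == pytest.approx(t.case_fraction, rel=1e-8)

    def test_realized_case_count_near_target(self):
        t = _truth(theta=1.5, n_out=50_000, n_cases=500, seed=5)
        _, out = simulate_pair(t)
        # binomial noise: 500 +- ~3.5 sd
        assert abs(out.n_cases - 500) < 5 * np.sqrt(500)

    def test_unattainable_case_count(self):
        with pytest.raises(ValueError):
            solve_intercept(_truth(n_cases=49_999, theta=-50.0, maf=0.5))


class TestSimulatePair:
    def test_deterministic_in_seed(self):
        a = simulate_pair(_truth())
        b = simulate_pair(_truth())
        assert a == b

    def test_eaf_law_of_large_numbers(self):
        t = _truth(n_exp=100_000, seed=3)
        exp, _ = simulate_pair(t)
        assert exp.eaf == pytest.approx(0.3, abs=0.01)

    def test_exposure_r2_matches_closed_form(self):
        # beta_gx = 0.25, maf = 0.3: R-hat^2 ~ 2*0.3*0.7*0.25^2/(...) at n=1e5
        t = _truth(n_exp=100_000, beta_gx=0.25, seed=9)
        exp, _ = simulate_pair(t)
        from metmr.instruments import variance_explained

        assert variance_explained(exp.beta, exp.eaf) == pytest.approx(t.r2, abs=0.004)

    def test_null_model_outcome_beta_within_3se(self):
        t = _truth(theta=0.0, n_cases=200, n_out=100_000)
        sims = simulate_summary(t, 300, rng=np.random.default_rng(4))
        z = np.abs(sims["by"] / sims["se_y"])
        assert np.mean(z < 3) >= 0.99

    def test_two_sample_independence(self):
        t = _truth(theta=0.0, n_cases=200, n_out=100_000)
        sims = simulate_summary(t, 400, rng=np.random.default_rng(8))
        r = np.corrcoef(sims["bx"], sims["by"])[0, 1]
        assert abs(r) < 0.15


@pytest.fixture(scope="module")
def routes():
    t = _truth(theta=0.8, n_cases=250, n_out=50_000)
    reps = 300
    rng = np.random.default_rng(21)
    individual = {"bx": [], "se_x": [], "by": [], "se_y": []}
    for _ in range(reps):
        e, o = simulate_pair(t, rng=rng)
        individual["bx"].append(e.beta)
        individual["se_x"].append(e.se)
        individual["by"].append(o.beta)
        individual["se_y"].append(o.se)
    individual = {k: np.array(v) for k, v in individual.items()}
    fast = simulate_summary(t, reps, rng=np.random.default_rng(22))
    return individual, fast


class TestRouteEquivalence:
    """Individual-level regression and sufficient-statistic sampling must
    induce the same distribution of the emitted summary statistics."""

    @pytest.mark.parametrize("key", ["bx", "by"])
    def test_means_agree(self, routes, key):
        ind, fast = routes
        pooled_se = np.sqrt(
            ind[key].var() / len(ind[key]) + fast[key].var() / len(fast[key])
        )
        assert abs(ind[key].mean() - fast[key].mean()) < 4 * pooled_se

    @pytest.mark.parametrize("key", ["bx", "by"])
    def test_spreads_agree(self, routes, key):
        ind, fast = routes
        ratio = ind[key].std() / fast[key].std()
        assert 0.75 < ratio < 1.33

    def test_reported_se_matches_sampling_sd(self, routes):
        # the per-replicate SE should estimate the actual spread of beta
        ind, fast = routes
        assert fast["se_y"].mean() == pytest.approx(fast["by"].std(), rel=0.15)
        assert ind["se_x"].mean() == pytest.approx(ind["bx"].std(), rel=0.15)


class TestScreenBundle:
    def test_same_seed_is_byte_identical(self, tmp_path):
        cfg = ScenarioConfig(n_metabolites=8, n_true_effects=1, seed=5)
        d1, d2 = tmp_path / "a", tmp_path / "b"
        simulate_screen(cfg).write(d1)
        simulate_screen(cfg).write(d2)
        for f1 in sorted(d1.iterdir()):
            assert f1.read_bytes() == (d2 / f1.name).read_bytes()

    def test_bundle_dimensions_and_validity(self, small_screen):
        cfg, bundle = small_screen
        assert len(bundle.truth) == cfg.n_metabolites
        assert set(bundle.outcome_tables) == {"AML", "CML", "ALL", "CLL"}
        # every emitted table passes validation with zero exclusions
        for table in [bundle.exposure_table, *bundle.outcome_tables.values()]:
            report = gwas_io.validate_table(table)
            assert report.n_valid == report.n_input
        # outcome case fractions preserved under scaling
        from metmr import reference

        for outcome, table in bundle.outcome_tables.items():
            cases, controls = reference.OUTCOME_DEFS[outcome]
            k_paper = cases / (cases + controls)
            rec = table.valid_records()[0]
            assert rec.n_cases / rec.n == pytest.approx(k_paper, rel=0.25)

    def test_missing_sentinels_have_ld_proxies(self, small_screen):
        _cfg, bundle = small_screen
        missing = bundle.truth[bundle.truth.missing_from_outcome]
        assert len(missing) >= 1
        for _, row in missing.iterrows():
            partners = bundle.ld_table.partners(row.rsid)
            assert any(r2 > 0.8 for _p, r2, _m in partners)
            for outcome_table in bundle.outcome_tables.values():
                assert row.rsid not in outcome_table.rsids()
                assert row.proxy_rsid in outcome_table.rsids()

    def test_missing_fraction_expectation(self):
        cfg = ScenarioConfig(n_metabolites=83, frac_missing_outcome=0.1, seed=12)
        bundle = simulate_screen(cfg)
        n_missing = int(bundle.truth.missing_from_outcome.sum())
        # ~Binomial(83, 0.1): mean 8.3, keep a wide deterministic band
        assert 2 <= n_missing <= 17

    def test_exposure_sentinels_reach_genomewide_significance(self, small_screen):
        _cfg, bundle = small_screen
        by_rsid = bundle.exposure_table.by_rsid()
        for _, row in bundle.truth.iterrows():
            assert by_rsid[row.rsid].pval < 5e-8


def test_child_seed_is_deterministic_and_bounded():
    assert child_seed(1, 5) == child_seed(1, 5)
    assert child_seed(1, 5) != child_seed(1, 6) != child_seed(2, 6)
    assert 0 <= child_seed(2**20, 10**4) < 2**31
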