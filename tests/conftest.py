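import numpy as np
import pytest
from hypothesis import settings

settings.register_profile("suite", deadline=None, derandomize=True, max_examples=50)
settings.load_profile("suite")


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(20_240_917)


@pytest.fixture(scope="session")
def small_screen():
    """A small synthetic screen bundle shared across pipeline tests."""
    from metmr.simulate import ScenarioConfig, simulate_screen

    cfg = ScenarioConfig(n_metabolites=24, n_true_effects=2, seed=3)
    return cfg, simulate_screen(cfg)


@pytest.fixture()
def screen_paths(small_screen, tmp_path):
    """The small bundle written to disk plus a ready pipeline config."""
    from metmr.pipeline import PipelineConfig

    cfg, bundle = small_screen
    paths = bundle.write(tmp_path / "bundle")
    pcfg = PipelineConfig(
        exposure_path=str(paths["exposure"]),
        outcome_paths={o: str(paths[f"outcome:{o}"]) for o in bundle.outcome_tables},
        ld_path=str(paths["ld"]),
        annotation_path=str(paths["annotations"]),
        drug_path=str(paths["drugs"]),
        out_dir=str(tmp_path / "results"),
        seed=cfg.seed,
    )
    return pcfg, bundle
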