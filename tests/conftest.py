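import numpy as np
import pytest
from hypothesis import settings

from adipomr.pipeline import StudyConfig, run_study
from adipomr.synthetic_data import SimConfig, make_fixture_tables, simulate_harmonised

settings.register_profile("ci", derandomize=True, max_examples=50, deadline=None)
settings.load_profile("ci")


@pytest.fixture
def hset8():
    """Deterministic 8-SNP independent instrument with a true effect of 0.3."""
    hset, _ = simulate_harmonised(
        SimConfig(seed=42, m_snps=8, causal_effect=0.3, n_exposure=200_000)
    )
    return hset


@pytest.fixture
def hset_corr():
    """Deterministic 5-SNP instrument with AR(1) LD (rho=0.5) and effect 0.2."""
    hset, _ = simulate_harmonised(
        SimConfig(seed=7, m_snps=5, ld_rho=0.5, causal_effect=0.2, n_exposure=200_000)
    )
    return hset


@pytest.fixture(scope="session")
def fixture_study(tmp_path_factory):
    """The synthetic 7-risk-factor x 3-endpoint toy study on disk."""
    out = tmp_path_factory.mktemp("toy_study")
    manifest = make_fixture_tables(out, seed=7)
    return out, manifest


@pytest.fixture(scope="session")
def study_report(fixture_study):
    out, _ = fixture_study
    config = StudyConfig.from_yaml(out / "study.yaml")
    return config, run_study(config)


@pytest.fixture
def rng():
    return np.random.default_rng(2026)
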