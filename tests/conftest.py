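import numpy as np
import pytest

from lexhub.corpus import CorpusConfig, assemble_corpus
from lexhub.network import NetworkConfig
from lexhub.runner import ExperimentConfig, run_experiment, scaled_profile


@pytest.fixture(scope="session")
def small_corpus():
    """A 5-set, 38-item corpus used by trial-construction and VWP tests."""
    return assemble_corpus(CorpusConfig(n_sets=5, n_fillers=8), seed=11)


@pytest.fixture(scope="session")
def toy_network_config():
    """Tiny architecture for gradient-oracle and dynamics tests."""
    return NetworkConfig(
        n_slots=2,
        visual_per_slot=3,
        word_len=3,
        phon_per_slot=2,
        n_sem=6,
        n_eye=2,
        n_hub=5,
    )


@pytest.fixture(scope="session")
def scaled_config():
    """The desk-scale experiment profile (5 sets, 200 hub units, 150k trials)."""
    return scaled_profile(ExperimentConfig(master_seed=1), 0.15)


@pytest.fixture(scope="session")
def scaled_run(scaled_config, tmp_path_factory):
    """Full scaled pipeline: both regimes trained, pre-tested and simulated.

    Session-scoped because training is the dominant cost; every test that
    needs a trained model shares this run.
    """
    out = tmp_path_factory.mktemp("scaled_run")
    return run_experiment(scaled_config, out, plots=False)
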