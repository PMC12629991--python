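import numpy as np
import pytest

from germ import (
    GermParams,
    SimulationConfig,
    compute_track,
    fit_normalization,
    score_transcript,
    simulate_transcriptome,
)


@pytest.fixture(scope="session")
def params():
    return GermParams()


@pytest.fixture(scope="session")
def small_transcriptome():
    """60 transcripts, 20% planted, shared across read-only tests."""
    cfg = SimulationConfig(n_genes=60, planted_fraction=0.2, seed=1234)
    models, truth = simulate_transcriptome(cfg)
    return models, truth


@pytest.fixture(scope="session")
def scored_transcriptome(small_transcriptome, params):
    models, truth = small_transcriptome
    raw = {t: score_transcript(m.spliced_sequence, params) for t, m in models.items()}
    stats = fit_normalization(raw, provenance="test")
    tracks = {
        t: compute_track(t, m.spliced_sequence, params, stats)
        for t, m in models.items()
    }
    return models, truth, raw, stats, tracks


@pytest.fixture()
def rng():
    return np.random.default_rng(99)


def random_seq(rng, length, alphabet="ACGT"):
    return "".join(rng.choice(list(alphabet), size=length))
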