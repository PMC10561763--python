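import numpy as np
import pytest
from hypothesis import settings, HealthCheck

settings.register_profile(
    "default",
    derandomize=True,
    max_examples=50,
    suppress_health_check=[HealthCheck.too_slow],
    deadline=None,
)
settings.load_profile("default")

from sexdepth import SimulationConfig, generate_genome, simulate_tracks
from sexdepth.io import DepthTrack


@pytest.fixture(scope="session")
def tiny_config():
    """Small genome: 3 autosomes, 1 X, 1 Y; 20-kb windows; noise-free."""
    return SimulationConfig(
        n_autosomes=3,
        n_x_contigs=1,
        n_y_contigs=1,
        contig_length_range=(200_000, 320_000),
        gc_segment_length=20_000,
        window_size=20_000,
        noise="none",
        seed=7,
    )


@pytest.fixture(scope="session")
def tiny_genome(tiny_config):
    return generate_genome(tiny_config)


@pytest.fixture(scope="session")
def tiny_tracks(tiny_genome, tiny_config):
    """sample_id -> (sex, DepthTrack) for the tiny noise-free genome."""
    lengths = tiny_genome.lengths
    return {
        sid: (sex, DepthTrack.from_records(recs, lengths))
        for sid, (sex, recs) in simulate_tracks(tiny_genome, tiny_config).items()
    }


@pytest.fixture
def rng():
    return np.random.default_rng(20240917)
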