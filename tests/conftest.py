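import numpy as np
import pytest

from repliquant import simulate as sim
from repliquant.config import AnalysisConfig
from repliquant.segmentation import segment


@pytest.fixture
def cfg():
    return AnalysisConfig()


@pytest.fixture
def late_s():
    """Noisy late-S nucleus with 3x protein enrichment, plus ground truth."""
    spec = sim.NucleusSpec(accumulation_fold=3.0, rng_seed=7)
    img, truth = sim.generate_nucleus(spec)
    return img, truth, spec


@pytest.fixture
def late_s_masks(late_s, cfg):
    img, truth, spec = late_s
    return segment(img, cfg)


@pytest.fixture
def noiseless():
    """Noise-free late-S nucleus: masks should match ground truth exactly."""
    spec = sim.NucleusSpec(
        accumulation_fold=3.0, camera_gain=0.0, read_noise_sd=0.0, rng_seed=7
    )
    img, truth = sim.generate_nucleus(spec)
    return img, truth, spec


def jaccard(a: np.ndarray, b: np.ndarray) -> float:
    union = np.logical_or(a, b).sum()
    return float(np.logical_and(a, b).sum() / union) if union else 1.0
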