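import warnings

import numpy as np
import pytest

from meibokit.errors import NonStarShapedWarning
from meibokit.pipeline import default_envelope
from meibokit.roi import ROIResult
from meibokit.synthetic import SyntheticParams, generate_meibography

# the polar tracer warns on slightly non-star-shaped discrete boundaries;
# irrelevant for most tests, asserted explicitly where it matters
warnings.filterwarnings("ignore", category=NonStarShapedWarning)


@pytest.fixture(scope="session")
def envelope():
    """The bundled reference envelope (200 synthetic regular glands)."""
    return default_envelope()


@pytest.fixture(scope="session")
def small_params():
    """A reduced frame that keeps the default anatomy (20 px glands,
    ~22 px intergland gaps) at a quarter of the pixel count."""
    return SyntheticParams(width_px=700, height_px=520, n_glands=15, seed=7)


@pytest.fixture(scope="session")
def small_sample(small_params):
    return generate_meibography(small_params)


@pytest.fixture(scope="session")
def small_truth_roi(small_sample):
    s = small_sample
    return ROIResult(mask=s.truth_roi, upper=s.truth_upper, lower=s.truth_lower)


def jaccard(a: np.ndarray, b: np.ndarray) -> float:
    union = (a | b).sum()
    return float((a & b).sum() / union) if union else 1.0
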