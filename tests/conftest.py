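import numpy as np
import pytest

import junctiondyn as jd
from junctiondyn.segmentation import SegmentationResult


@pytest.fixture(scope="session")
def monolayer_seed1():
    """Noise-free 20-cell monolayer with ground truth (seed 1)."""
    spec = jd.SyntheticMonolayerSpec(seed=1)
    series, gt = jd.generate_monolayer(spec)
    return spec, series, gt


@pytest.fixture(scope="session")
def seg_from_truth(monolayer_seed1):
    _, _, gt = monolayer_seed1
    return SegmentationResult.from_labels(gt.label_stack[0])


@pytest.fixture
def half_plane_labels():
    """Two half-planes separated by a horizontal border at row 31."""
    lab = np.ones((64, 64), dtype=int)
    lab[32:, :] = 2
    return lab
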