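import numpy as np
import pytest

from svhiston import (
    BrainMask,
    PhantomParams,
    ProbabilityVolume,
    SlicParams,
    SubjectRecord,
    build_brain_mask,
    generate_phantom,
    quantize,
    slic_segment,
)


@pytest.fixture
def rng():
    return np.random.default_rng(20240117)


def random_quantized_volumes(rng, shape=(8, 8, 8), levels=256):
    """Three random quantized tissue volumes plus a full mask."""
    vols = []
    for tissue in ("GM", "WM", "CSF"):
        data = rng.integers(0, levels, size=shape)
        vols.append(ProbabilityVolume(data.astype(np.int64), tissue, levels=levels))
    mask = BrainMask(np.ones(shape, dtype=bool))
    return vols, mask


@pytest.fixture
def small_subject():
    """One synthetic CN subject at a small grid for fast end-to-end tests."""
    params = PhantomParams(grid_size=32, wm_radius=6, gm_radius=10,
                           csf_radius=13, sigma=0.02)
    vols = generate_phantom("CN", params, seed=11)
    return SubjectRecord("s000", "CN", 71.0, "M", volumes=vols)


@pytest.fixture
def small_labeling(rng):
    """A SLIC labeling on a small random volume, with its inputs."""
    (gm, wm, csf), mask = random_quantized_volumes(rng, shape=(8, 8, 8))
    labeling = slic_segment(gm, wm, csf, mask,
                            SlicParams(n_supervoxels=4, max_iterations=3))
    return labeling, (gm, wm, csf), mask
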