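import numpy as np
import pytest

from mitoquant.stacks import ImageStack3D


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def flat_stack():
    """Constant-valued anisotropic two-channel stack."""
    shape = (10, 24, 24)
    return ImageStack3D(
        channels={"DAPI": np.full(shape, 7.0), "Top2": np.full(shape, 3.0)},
        spacing_nm=(200.0, 65.0, 65.0),
    )


def brute_force_multiotsu(counts, bin_values, n_classes):
    """Independent exhaustive Multi-Otsu oracle: plain-Python enumeration of
    every threshold tuple, maximizing sum_k W_k * mu_k^2 with strict '>' so
    the first (lexicographically smallest) maximizer wins."""
    import itertools

    counts = list(map(float, counts))
    vals = list(map(float, bin_values))
    nbins = len(counts)
    best_obj, best = -1.0, None
    for combo in itertools.combinations(range(1, nbins), n_classes - 1):
        bounds = (0,) + combo + (nbins,)
        obj = 0.0
        for a, b in zip(bounds[:-1], bounds[1:]):
            w = sum(counts[a:b])
            if w > 0:
                s = sum(c * v for c, v in zip(counts[a:b], vals[a:b]))
                obj += s * s / w
        if obj > best_obj:
            best_obj, best = obj, combo
    return np.array([vals[i] for i in best])
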