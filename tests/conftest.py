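import numpy as np
import pytest

from tilab import GridComposition, PredictionMap


@pytest.fixture
def rng():
    return np.random.default_rng(20260927)


def random_map(rng, rows, cols, *, p_background=0.2, patch_size_px=128,
               microns_per_pixel=0.55):
    """Random five-class prediction map for property tests."""
    probs = np.array([p_background, 0.25, 0.25, 0.2, 0.1])
    probs[1:] *= (1 - p_background) / probs[1:].sum()
    labels = rng.choice(5, size=(rows, cols), p=probs).astype(np.uint8)
    return PredictionMap(labels=labels, patch_size_px=patch_size_px,
                         microns_per_pixel=microns_per_pixel,
                         slide_id=f"rand-{rows}x{cols}")


def random_grid(rng, m=3, n=3):
    """Random grid composition with p_l + p_t <= 1 per cell."""
    frac = rng.dirichlet([1.0, 1.0, 1.0], size=(m, n))
    return GridComposition(p_l=frac[..., 0], p_t=frac[..., 1], cell_size_mm=0.28)
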