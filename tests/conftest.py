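import numpy as np
import pytest

from morphocanvas import mesh


@pytest.fixture
def flat_square():
    """Small flat square canvas (no curvature, no noise)."""
    return mesh.make_square_canvas(100.0, resolution=10.0,
                                   curvature_sagitta=0.0,
                                   z_noise_amplitude=0.0)


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


def set_uniform_polarity(canvas, direction=(0.0, 1.0, 0.0)):
    """Give every element (both surfaces) the same tangent polarity."""
    m = canvas.n_triangles
    dirs = np.tile(np.asarray(direction, dtype=float), (m, 1))
    defined = np.ones(m, dtype=bool)
    canvas.set_polarity_from_vectors(dirs, defined, "a")
    canvas.set_polarity_from_vectors(dirs, defined, "b")
    return canvas
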