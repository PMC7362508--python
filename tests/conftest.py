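import dataclasses

import pytest

from epifat import PhantomSpec, build_anatomy, render_dixon


@pytest.fixture(scope="session")
def small_spec():
    """Coarse fast phantom: same physical geometry as the default, sampled
    at 3 x 3 x 5 mm over 4 frames, noiseless."""
    return PhantomSpec(grid_shape=(32, 32, 24), voxel_spacing_mm=(3.0, 3.0, 5.0),
                       n_frames=4, rr_interval_ms=260.0, noise_sigma=0.0)


@pytest.fixture(scope="session")
def small_dataset(small_spec):
    labels = build_anatomy(small_spec)
    series, truth = render_dixon(labels, small_spec)
    return small_spec, labels, series, truth


@pytest.fixture(scope="session")
def default_noiseless():
    """The full-size study-geometry phantom without noise (shared across
    tests; treat as read-only)."""
    spec = dataclasses.replace(PhantomSpec(), noise_sigma=0.0)
    labels = build_anatomy(spec)
    series, truth = render_dixon(labels, spec)
    return spec, labels, series, truth
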