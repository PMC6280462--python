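import numpy as np
import pytest

from bmdir import (BinaryMask, DisplacementField, ImageVolume, PhantomSpec,
                   RefinementConfig, build_organ_mesh, generate_phantom)


def make_ball_mask(radius_mm=10.0, spacing=(1.0, 1.0, 1.0), margin_vox=3):
    """A solid ball mask centered in its grid."""
    sp = np.array(spacing)
    n = (2 * np.ceil(radius_mm / sp).astype(int) + 2 * margin_vox + 1)
    idx = np.stack(np.meshgrid(*[np.arange(k) for k in n], indexing="ij"), axis=-1)
    center = (n - 1) / 2.0 * sp
    pts = idx * sp
    mask = np.linalg.norm(pts - center, axis=-1) <= radius_mm
    return BinaryMask(mask, spacing)


def affine_field(vol_like, A, b):
    """u(x) = A @ x + b on the grid of `vol_like`, as a DisplacementField."""
    pts = vol_like.voxel_centers()
    u = pts @ np.asarray(A).T + np.asarray(b)
    return DisplacementField(u, vol_like.spacing, vol_like.origin)


SMALL_SPEC = PhantomSpec(shape=(40, 40, 40), spacing=(1.0, 1.0, 1.0),
                         semi_axes=(12.0, 10.0, 14.0), tube_radius_mm=2.0,
                         tube_bow_mm=2.0, push_sigma_mm=8.0,
                         push_standoff_mm=4.0, a_max_mm=3.0, n_stages=3,
                         texture_seed=11)


@pytest.fixture(scope="session")
def small_spec():
    return SMALL_SPEC


@pytest.fixture(scope="session")
def small_stages():
    """A small, fast 3-stage phantom for unit tests."""
    return generate_phantom(SMALL_SPEC)


@pytest.fixture(scope="session")
def ball_mask():
    return make_ball_mask()


@pytest.fixture(scope="session")
def ball_mesh(ball_mask):
    """Surface + tet mesh of the ball, sized per the sub-voxel rule."""
    return build_organ_mesh(ball_mask, RefinementConfig())


@pytest.fixture(scope="session")
def phantom64_stages():
    """The full-size study phantom (64 mm cube, 10 stages)."""
    return generate_phantom(PhantomSpec())


@pytest.fixture(scope="session")
def phantom64_mesh(phantom64_stages):
    organ = phantom64_stages[0].organ_ref
    return build_organ_mesh(organ, RefinementConfig())


@pytest.fixture()
def rng():
    return np.random.default_rng(42)


def smooth_test_image(shape=(24, 24, 24), spacing=(1.0, 1.0, 1.0), seed=5,
                      sigma=2.5):
    """A band-limited random image for warping tests."""
    from scipy import ndimage
    r = np.random.default_rng(seed)
    img = ndimage.gaussian_filter(r.standard_normal(shape), sigma=sigma)
    return ImageVolume(100 + 50 * img / img.std(), spacing)
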