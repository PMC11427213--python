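import numpy as np
import pytest

from silmas import NoiseModel, PhantomVolumeSpec, StripeSpec, add_stripes, make_attenuated_volume


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


def two_region_plane(
    ny=512,
    nx=512,
    mid_value=1000.0,
    dark_value=100.0,
    dark_rows=(340, 480),
    stripe_positions=((60, 4), (128, 16), (200, 4), (290, 16), (380, 4), (450, 16)),
    stripe_depth=0.3,
    noise_sigma=0.0,
    seed=11,
):
    """Mid-intensity field with a dark band and vertical super-Gaussian stripes.

    The dark band's edges run parallel to the stripe-normal direction so the
    phantom isolates the intensity-normalisation role of the bandpass filter.
    Returns (striped_noisy, clean, mid_mask, dark_mask).
    """
    img = np.full((ny, nx), mid_value)
    img[dark_rows[0] : dark_rows[1], :] = dark_value
    mid = np.ones((ny, nx), bool)
    mid[dark_rows[0] : dark_rows[1], :] = False
    dark = np.zeros((ny, nx), bool)
    dark[dark_rows[0] + 5 : dark_rows[1] - 5, :] = True
    specs = [StripeSpec(c, w, stripe_depth, 4) for c, w in stripe_positions]
    striped = add_stripes(img, specs)
    if noise_sigma > 0:
        striped = striped + np.random.default_rng(seed).normal(0, noise_sigma, img.shape)
    return striped, img, mid, dark


def _column_means(plane, region):
    plane = np.asarray(plane, dtype=float)
    cm = [
        plane[:, x][region[:, x]].mean()
        for x in range(plane.shape[1])
        if region[:, x].any()
    ]
    return np.array(cm)


def column_peak_to_trough(plane, region):
    """Peak-to-trough of region-restricted column means along the stripe-normal axis."""
    cm = _column_means(plane, region)
    return float(cm.max() - cm.min())


def column_mean_variance(plane, region):
    cm = _column_means(plane, region)
    return float(np.var(cm))


def dice(a, b):
    a = np.asarray(a, bool)
    b = np.asarray(b, bool)
    s = a.sum() + b.sum()
    return 1.0 if s == 0 else 2.0 * np.logical_and(a, b).sum() / s


def attenuated_phantom(
    shape=(8, 256, 256), mu_x=None, mu_z=0.0, snr=10.0, seed=1, kind="half_space"
):
    """Half-space tissue with tenfold attenuation across X by default."""
    nz, ny, nx = shape
    if mu_x is None:
        mu_x = np.log(10.0) / (nx - nx // 8)
    noise = NoiseModel("gaussian", sigma=1000.0 / snr) if snr else NoiseModel()
    spec = PhantomVolumeSpec(
        shape=shape,
        tissue_mask_kind=kind,
        mu_x=mu_x,
        mu_z=mu_z,
        base_intensity=1000.0,
        noise_model=noise,
        seed=seed,
    )
    return make_attenuated_volume(spec), spec
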