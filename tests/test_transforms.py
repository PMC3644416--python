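"""2D transforms: perfect reconstruction, shift-equivariance, consistency."""

import numpy as np
import pytest

from splinodule.errors import ConfigurationError
from splinodule.transforms import (
    dwt2,
    idwt2,
    iswt2,
    load_pyramid,
    max_levels,
    save_pyramid,
    swt2,
)

SQRT2 = np.sqrt(2.0)


@pytest.mark.parametrize("shape", [(8, 8), (33, 47), (64, 64), (31, 32)])
@pytest.mark.parametrize("boundary", ["symmetric", "zero", "periodic"])
def test_dwt2_perfect_reconstruction(all_banks, rng, shape, boundary):
    for fb in all_banks:
        x = rng.normal(size=shape)
        levels = 2 if min(shape) >= 8 else 1
        pyr = dwt2(x, fb, levels, boundary)
        rec = idwt2(pyr, fb)
        assert rec.shape == x.shape
        assert np.max(np.abs(rec - x)) < 1e-8, (fb.bank_id, shape, boundary)


def test_haar_level1_is_block_sums(haar_bank, rng):
    """Hand-computed 4x4 Haar oracle: approx = 2x2 block sums / 2, details likewise."""
    x = rng.normal(size=(4, 4))
    pyr = dwt2(x, haar_bank, 1, "periodic")
    b = x.reshape(2, 2, 2, 2)
    approx = (b[:, 0, :, 0] + b[:, 0, :, 1] + b[:, 1, :, 0] + b[:, 1, :, 1]) / 2
    h = (b[:, 0, :, 0] - b[:, 0, :, 1] + b[:, 1, :, 0] - b[:, 1, :, 1]) / 2
    v = (b[:, 0, :, 0] + b[:, 0, :, 1] - b[:, 1, :, 0] - b[:, 1, :, 1]) / 2
    d = (b[:, 0, :, 0] - b[:, 0, :, 1] - b[:, 1, :, 0] + b[:, 1, :, 1]) / 2
    np.testing.assert_allclose(pyr.approx, approx, atol=1e-12)
    np.testing.assert_allclose(pyr.details[0]["H"], h, atol=1e-12)
    np.testing.assert_allclose(pyr.details[0]["V"], v, atol=1e-12)
    np.testing.assert_allclose(pyr.details[0]["D"], d, atol=1e-12)


def test_constant_image_details_vanish(bior32_bank):
    pyr = dwt2(np.full((32, 32), 5.0), bior32_bank, 2)
    for lev in (1, 2):
        for key in "HVD":
            assert np.max(np.abs(pyr.detail(lev, key))) < 1e-10
    spyr = swt2(np.full((32, 32), 5.0), bior32_bank, 3)
    for lev in (1, 2, 3):
        for key in "HVD":
            assert np.max(np.abs(spyr.detail(lev, key))) < 1e-10


@pytest.mark.parametrize("boundary", ["symmetric", "periodic"])
def test_swt2_perfect_reconstruction(all_banks, rng, boundary):
    for fb in all_banks:
        x = rng.normal(size=(32, 32))
        pyr = swt2(x, fb, 3, boundary)
        rec = iswt2(pyr, fb)
        assert np.max(np.abs(rec - x)) < 1e-8, (fb.bank_id, boundary)


def test_swt2_subbands_share_input_shape(bior32_bank, rng):
    x = rng.normal(size=(33, 47))
    pyr = swt2(x, bior32_bank, 2, "symmetric")
    assert pyr.approximation().shape == x.shape
    for lev in (1, 2):
        for key in "HVD":
            assert pyr.detail(lev, key).shape == x.shape
    assert np.max(np.abs(iswt2(pyr, bior32_bank) - x)) < 1e-8


def test_swt2_shift_equivariance(bior32_bank, rng):
    x = rng.normal(size=(32, 32))
    p0 = swt2(x, bior32_bank, 3, "periodic")
    p1 = swt2(np.roll(np.roll(x, 3, 0), 5, 1), bior32_bank, 3, "periodic")

    def shifted(arr):
        return np.roll(np.roll(arr, 3, 0), 5, 1)

    dev = np.max(np.abs(p1.approximation() - shifted(p0.approximation())))
    for lev in (1, 2, 3):
        for key in "HVD":
            dev = max(dev, np.max(np.abs(p1.detail(lev, key) - shifted(p0.detail(lev, key)))))
    assert dev < 1e-10


def test_decimated_undecimated_consistency(bior12_bank, rng):
    """Even-index subsampling of level-1 undecimated details equals decimated."""
    x = rng.normal(size=(32, 32))
    pd = dwt2(x, bior12_bank, 1, "periodic")
    pu = swt2(x, bior12_bank, 1, "periodic")
    for key in "HVD":
        np.testing.assert_allclose(
            pd.details[0][key], pu.details[0][key][::2, ::2], atol=1e-10
        )
    np.testing.assert_allclose(pd.approx, pu.approx[::2, ::2], atol=1e-10)


def test_linearity(bior32_bank, rng):
    x = rng.normal(size=(16, 24))
    y = rng.normal(size=(16, 24))
    a, b = 2.5, -1.25
    p_mix = dwt2(a * x + b * y, bior32_bank, 2)
    p_x = dwt2(x, bior32_bank, 2)
    p_y = dwt2(y, bior32_bank, 2)
    np.testing.assert_allclose(p_mix.approx, a * p_x.approx + b * p_y.approx, atol=1e-10)
    for lev in (1, 2):
        for key in "HVD":
            np.testing.assert_allclose(
                p_mix.details[lev - 1][key],
                a * p_x.details[lev - 1][key] + b * p_y.details[lev - 1][key],
                atol=1e-10,
            )


def test_coefficient_count_accounting(bior12_bank, rng):
    """Total decimated coefficients: at least the pixel count, plus O(J*perimeter)."""
    x = rng.normal(size=(64, 64))
    levels = 3
    pyr = dwt2(x, bior12_bank, levels, "symmetric")
    total = pyr.total_count()
    assert total >= x.size
    filter_len = max(len(bior12_bank.ht), len(bior12_bank.gt))
    assert total <= x.size + 40 * levels * filter_len * (64 + 64)
    # periodic mode is non-expansive up to odd-size padding
    per = dwt2(x, bior12_bank, levels, "periodic")
    assert per.total_count() == x.size


def test_level_and_bank_validation(haar_bank, bior12_bank, rng):
    x = rng.normal(size=(16, 16))
    with pytest.raises(ConfigurationError):
        dwt2(x, haar_bank, 5)  # 2^5 > 16
    with pytest.raises(ConfigurationError):
        dwt2(x, haar_bank, 0)
    with pytest.raises(ConfigurationError):
        dwt2(rng.normal(size=8), haar_bank, 1)  # not 2D
    with pytest.raises(ConfigurationError):
        dwt2(x, haar_bank, 1, boundary="mirror")
    pyr = dwt2(x, haar_bank, 2)
    with pytest.raises(ConfigurationError):
        idwt2(pyr, bior12_bank)  # bank mismatch
    spyr = swt2(x, haar_bank, 2)
    with pytest.raises(ConfigurationError):
        iswt2(spyr, bior12_bank)
    with pytest.raises(ConfigurationError):
        idwt2(spyr, haar_bank)  # wrong mode
    with pytest.raises(ConfigurationError):
        iswt2(pyr, haar_bank)


def test_max_levels_default():
    assert max_levels((256, 256)) == 6
    assert max_levels((64, 512)) == 4
    assert max_levels((4, 4)) == 1


def test_pyramid_serialization_round_trip(bior12_bank, rng, tmp_path):
    x = rng.normal(size=(20, 28))
    pyr = dwt2(x, bior12_bank, 2, "symmetric")
    save_pyramid(pyr, tmp_path / "pyr")
    back = load_pyramid(tmp_path / "pyr")
    assert back.bank_id == pyr.bank_id
    rec = idwt2(back, bior12_bank)
    assert np.max(np.abs(rec - x)) < 1e-8
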