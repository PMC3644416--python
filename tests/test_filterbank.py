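"""Filter quadruples: construction, duality, and the B-spline wavelet form."""

import json

import numpy as np
import pytest
import pywt

from splinodule.bspline import binomial_filter
from splinodule.errors import ConfigurationError
from splinodule.filterbank import (
    FAMILY_PROPERTIES,
    Filter,
    FilterBank,
    check_biorthogonality,
    make_filterbank,
    wavelet_bspline_coeffs,
)

SQRT2 = np.sqrt(2.0)


def test_haar_quadruple(haar_bank):
    s = SQRT2 / 2.0
    np.testing.assert_allclose(haar_bank.h.taps, [s, s])
    np.testing.assert_allclose(haar_bank.ht.taps, [s, s])
    np.testing.assert_allclose(haar_bank.g.taps, [s, -s])
    np.testing.assert_allclose(haar_bank.gt.taps, [s, -s])
    res = check_biorthogonality(haar_bank)
    assert max(res.values()) < 1e-14


def test_bior_synthesis_is_binomial(bior12_bank, bior32_bank, semi3_bank):
    np.testing.assert_allclose(bior12_bank.h.taps, binomial_filter(1).taps, atol=1e-14)
    np.testing.assert_allclose(bior32_bank.h.taps, binomial_filter(3).taps, atol=1e-14)
    np.testing.assert_allclose(semi3_bank.h.taps, binomial_filter(3).taps, atol=1e-14)


@pytest.mark.parametrize("degree,dual", [(1, 2), (3, 2), (1, 4), (3, 4), (0, 1), (2, 1)])
def test_bior_duality(degree, dual):
    fb = make_filterbank("biorthogonal_spline", degree, dual)
    res = check_biorthogonality(fb)
    assert max(res.values()) < 1e-12


@pytest.mark.parametrize(
    "degree,dual,pywt_name",
    [(1, 2, "bior2.2"), (1, 4, "bior2.4"), (2, 3, "bior3.3")],
)
def test_bior_dual_matches_reference_taps(degree, dual, pywt_name):
    """Independent oracle: the PR linear system reproduces the classic CDF taps."""
    fb = make_filterbank("biorthogonal_spline", degree, dual)
    ref = np.asarray(pywt.Wavelet(pywt_name).dec_lo)
    ref = np.trim_zeros(ref)
    got = fb.ht.taps
    # pywt stores the analysis lowpass reversed relative to convolution order;
    # the filters are symmetric, so direct comparison is valid
    np.testing.assert_allclose(got, ref, atol=1e-10)


def test_semiortho_dual_truncation(semi3_bank):
    res = check_biorthogonality(semi3_bank)
    assert max(res.values()) < 1e-9  # limited by the documented 1e-10 truncation
    assert semi3_bank.metadata["truncation_tol"] == 1e-10
    assert len(semi3_bank.ht) > 20  # genuinely IIR-like tail


def test_perturbed_bank_detected(haar_bank):
    taps = haar_bank.ht.taps.copy()
    taps[0] += 0.01
    broken = FilterBank(
        family="haar", degree=0,
        synthesis_lowpass=haar_bank.h,
        analysis_lowpass=Filter(taps, haar_bank.ht.offset),
        synthesis_highpass=haar_bank.g,
        analysis_highpass=haar_bank.gt,
    )
    assert check_biorthogonality(broken)["lowpass"] >= 0.005


@pytest.mark.parametrize("degree,dual", [(1, 2), (3, 2), (1, 4)])
def test_analysis_highpass_vanishing_moments(degree, dual):
    """gtilde annihilates sampled polynomials up to the synthesis spline order."""
    fb = make_filterbank("biorthogonal_spline", degree, dual)
    k = fb.gt.indices().astype(float)
    for j in range(degree + 1):
        moment = float(np.sum(fb.gt.taps * k**j))
        assert abs(moment) < 1e-8, f"moment {j} = {moment}"


def test_spline_filters_symmetric(all_banks):
    for fb in all_banks:
        for name, f in fb.filters().items():
            sym = np.allclose(f.taps, f.taps[::-1], atol=1e-9)
            antisym = np.allclose(f.taps, -f.taps[::-1], atol=1e-9)
            assert sym or antisym, (fb.bank_id, name)


def test_family_configuration_errors():
    with pytest.raises(ConfigurationError):
        make_filterbank("haar", 1)
    with pytest.raises(ConfigurationError):
        make_filterbank("biorthogonal_spline", 1)  # missing dual order
    with pytest.raises(ConfigurationError):
        make_filterbank("biorthogonal_spline", 1, 1)  # parity violation
    with pytest.raises(ConfigurationError):
        make_filterbank("orthogonal_spline", 3)  # metadata-only family
    with pytest.raises(ConfigurationError):
        make_filterbank("no_such_family", 3)
    assert not FAMILY_PROPERTIES["orthogonal_spline"]["constructible"]


def test_wavelet_bspline_form(bior12_bank, haar_bank):
    # identity: delta * g = g
    form = wavelet_bspline_coeffs([1.0], bior12_bank.g, degree=1,
                                  g_offset=bior12_bank.g.offset)
    np.testing.assert_allclose(form.wavelet_coeffs.taps, bior12_bank.g.taps)
    assert form.wavelet_coeffs.offset == bior12_bank.g.offset
    # hand convolution
    form = wavelet_bspline_coeffs([1.0, 1.0], [1.0, -1.0])
    np.testing.assert_allclose(form.wavelet_coeffs.taps, [1.0, 0.0, -1.0])
    # independent convolution oracle: binomial(1) * haar highpass
    p = binomial_filter(1).taps
    g = haar_bank.g.taps
    expected = np.zeros(p.size + g.size - 1)
    for i, pv in enumerate(p):
        for j, gv in enumerate(g):
            expected[i + j] += pv * gv
    form = wavelet_bspline_coeffs(p, g)
    np.testing.assert_allclose(form.wavelet_coeffs.taps, expected, atol=1e-14)


def test_wavelet_bspline_empty_input_rejected():
    with pytest.raises(ConfigurationError):
        wavelet_bspline_coeffs([], [1.0])


def test_json_round_trip(bior32_bank):
    doc = bior32_bank.to_json()
    fb2 = FilterBank.from_json(doc)
    assert fb2.bank_id == bior32_bank.bank_id
    for name, f in bior32_bank.filters().items():
        f2 = fb2.filters()[name]
        np.testing.assert_allclose(f.taps, f2.taps)
        assert f.offset == f2.offset
    with pytest.raises(ConfigurationError):
        FilterBank.from_json(json.dumps({"family": "haar"}))
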