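"""Multi-scale blob detection, segmentation, shape gates, slice persistence."""

import numpy as np
import pytest
from skimage.measure import label as sk_label

from splinodule.detect import (
    DetectionConfig,
    NoduleCandidate,
    detect_pipeline,
    detect_slice,
    filter_by_shape,
    find_candidates,
    multiscale_response,
    segment_candidate,
    shape_features,
    slice_and_reduction,
)
from splinodule.errors import ConfigurationError
from splinodule.phantom import PhantomSpec, generate_slice


def gaussian_blob(shape, center, sigma, amplitude=80.0, base=110.0):
    rr, cc = np.mgrid[0:shape[0], 0:shape[1]]
    return base + amplitude * np.exp(
        -((rr - center[0]) ** 2 + (cc - center[1]) ** 2) / (2 * sigma**2)
    )


def test_constant_image_no_response(bior32_bank):
    responses = multiscale_response(np.full((64, 64), 9.0), bior32_bank, 3)
    for r in responses:
        assert np.max(np.abs(r)) < 1e-10


def test_blob_peak_location(bior32_bank):
    img = gaussian_blob((64, 64), (32, 32), sigma=4.0)
    responses = multiscale_response(img, bior32_bank, 3)
    best = max(responses, key=lambda r: r.max())
    peak = np.unravel_index(np.argmax(best), best.shape)
    assert np.hypot(peak[0] - 32, peak[1] - 32) <= 2.0


def test_scale_selection_orders_blob_sizes(bior32_bank):
    """The smaller blob peaks at a strictly lower level than the larger one.

    Isotropic detail magnitudes are compared after dividing by each level's
    white-noise gain (the norm of the equivalent a-trous filter), the scale
    at which level responses are commensurable.
    """
    from splinodule.denoise import _equivalent_filter_norms
    from splinodule.transforms import swt2

    norms = _equivalent_filter_norms(bior32_bank, 5)

    def best_level(sigma):
        img = gaussian_blob((256, 256), (128, 128), sigma=sigma)
        pyr = swt2(img, bior32_bank, 5, "symmetric")
        peaks = []
        for lev in range(1, 6):
            h, v, d = (pyr.detail(lev, k) for k in "HVD")
            r = np.sqrt(h * h + v * v + 2 * d * d)
            gain = np.sqrt(norms[lev - 1]["H"] ** 2 + norms[lev - 1]["V"] ** 2
                           + 2 * norms[lev - 1]["D"] ** 2)
            peaks.append(r[120:137, 120:137].max() / gain)
        return int(np.argmax(peaks)) + 1

    assert best_level(2.0) < best_level(8.0)


def test_find_candidates_cases(bior32_bank):
    cfg = DetectionConfig()
    zero = [np.zeros((64, 64))] * 3
    assert find_candidates(zero, cfg) == []

    spec = PhantomSpec(shape=(128, 128), n_nodules=1, n_vessels=0,
                       noise_sigma=0.0, seed=8)
    img, truth = generate_slice(spec)
    responses = multiscale_response(img, bior32_bank, 3)
    cands = find_candidates(responses, cfg)
    # all candidates cluster at the single nodule
    _, r, c = truth.nodules[0].center
    assert len(cands) >= 1
    assert all(np.hypot(cd.center[0] - r, cd.center[1] - c) < 2 * truth.nodules[0].radius
               for cd in cands[:1])
    dets = detect_slice(img, bior32_bank, cfg)
    assert len(dets) == 1
    assert np.hypot(dets[0].center[0] - r, dets[0].center[1] - c) <= cfg.match_radius


def test_two_separated_blobs_two_candidates(bior32_bank):
    img = np.full((128, 128), 110.0)
    for center in ((50, 44), (50, 84)):  # 40 px apart
        img += gaussian_blob((128, 128), center, sigma=4.0, base=0.0)
    cfg = DetectionConfig(field_margin=0.0)
    responses = multiscale_response(img, bior32_bank, 3)
    cands = find_candidates(responses, cfg)
    found = set()
    for cd in cands:
        for center in ((50, 44), (50, 84)):
            if np.hypot(cd.center[0] - center[0], cd.center[1] - center[1]) <= 5:
                found.add(center)
    assert len(found) == 2


def test_segment_disc_area(bior32_bank):
    img = np.full((64, 64), 100.0)
    rr, cc = np.mgrid[0:64, 0:64]
    img += 80.0 * (np.hypot(rr - 32, cc - 32) <= 6.0)
    cand = NoduleCandidate(center=(32, 32), scale_level=2, response=10.0)
    seg = segment_candidate(img, cand, DetectionConfig())
    assert seg is not None and not seg.boundary_touching
    assert seg.mask.sum() == pytest.approx(np.pi * 36, rel=0.2)
    # center lies inside the mask and the mask is 8-connected
    r0, c0 = seg.mask_offset
    assert seg.mask[seg.center[0] - r0, seg.center[1] - c0]
    assert sk_label(seg.mask, connectivity=2).max() == 1


def test_segment_uniform_window_discarded():
    img = np.full((64, 64), 100.0)
    cand = NoduleCandidate(center=(32, 32), scale_level=2, response=1.0)
    assert segment_candidate(img, cand, DetectionConfig()) is None


def test_segment_boundary_touching_flagged():
    img = np.full((64, 64), 100.0)
    rr, cc = np.mgrid[0:64, 0:64]
    img += 80.0 * (np.hypot(rr - 3, cc - 32) <= 6.0)  # disc clipped by image edge
    cand = NoduleCandidate(center=(3, 32), scale_level=2, response=1.0)
    seg = segment_candidate(img, cand, DetectionConfig())
    assert seg is not None
    assert seg.boundary_touching


def rasterized_disc(radius):
    n = 2 * radius + 5
    rr, cc = np.mgrid[0:n, 0:n]
    return np.hypot(rr - n // 2, cc - n // 2) <= radius


def test_shape_features_disc_rectangle_square():
    disc = shape_features(rasterized_disc(10))
    assert 0.85 <= disc.circularity <= 1.1
    assert 1.0 <= disc.aspect_ratio <= 1.1
    assert disc.convexity > 0.9

    rect = np.zeros((40, 10), dtype=bool)
    rect[5:35, 3:6] = True  # 30 x 3
    feats = shape_features(rect)
    assert feats.aspect_ratio >= 8.0
    assert feats.circularity <= 0.5

    square = np.zeros((14, 14), dtype=bool)
    square[2:12, 2:12] = True
    assert shape_features(square).extent == pytest.approx(1.0)

    with pytest.raises(ConfigurationError):
        shape_features(np.zeros((5, 5), dtype=bool))


def test_filter_by_shape_gates():
    cfg = DetectionConfig()
    disc_cand = NoduleCandidate(center=(12, 12), scale_level=2, response=5.0,
                                features=shape_features(rasterized_disc(10)))
    rect = np.zeros((40, 10), dtype=bool)
    rect[5:35, 3:6] = True
    rect_cand = NoduleCandidate(center=(20, 4), scale_level=2, response=5.0,
                                features=shape_features(rect))
    kept = filter_by_shape([disc_cand, rect_cand], cfg)
    assert kept == [disc_cand]
    assert filter_by_shape([], cfg) == []


def test_tightening_circularity_is_monotone():
    rng = np.random.default_rng(3)
    cands = []
    for _ in range(30):
        mask = rasterized_disc(int(rng.integers(3, 12)))
        if rng.random() < 0.5:  # stretch some into ellipses
            mask = np.repeat(mask, 2, axis=0)
        cands.append(NoduleCandidate(center=(5, 5), scale_level=2, response=1.0,
                                     features=shape_features(mask)))
    counts = []
    for min_circ in (0.2, 0.4, 0.6, 0.8, 1.0):
        cfg = DetectionConfig(min_circularity=min_circ)
        counts.append(len(filter_by_shape(cands, cfg)))
    assert all(a >= b for a, b in zip(counts, counts[1:]))


def test_slice_and_reduction_rules():
    cfg = DetectionConfig(min_persistence=3)

    def det(s, r, c, resp=1.0):
        return NoduleCandidate(center=(r, c), scale_level=2, response=resp,
                               slice_index=s)

    survivors = slice_and_reduction(
        [det(3, 50, 50, 1.0), det(4, 51, 50, 2.0), det(5, 50, 51, 1.5)], cfg
    )
    assert len(survivors) == 1
    assert survivors[0].slice_index == 4  # maximum-response member reported

    cfg2 = DetectionConfig(min_persistence=2)
    assert slice_and_reduction([det(3, 50, 50)], cfg2) == []

    # two interleaved tracks 50 px apart survive independently
    dets = [det(s, 40, 40) for s in (1, 2, 3)] + [det(s, 40, 90) for s in (1, 2, 3)]
    assert len(slice_and_reduction(dets, cfg)) == 2


def test_pipeline_single_nodule_with_compression(bior32_bank):
    spec = PhantomSpec(shape=(128, 128), n_nodules=1, n_vessels=0,
                       noise_sigma=0.0, seed=8)
    img, truth = generate_slice(spec)
    cfg = DetectionConfig()
    report = detect_pipeline(img, bior32_bank, cfg, compress_ratio=10.0)
    assert len(report["nodules"]) == 1
    _, r, c = truth.nodules[0].center
    d = report["nodules"][0]
    assert np.hypot(d["row"] - r, d["col"] - c) <= cfg.match_radius


def test_pipeline_vessel_only_and_flat(bior32_bank):
    spec = PhantomSpec(shape=(128, 128), n_nodules=0, n_vessels=3,
                       noise_sigma=0.0, seed=4)
    img, _ = generate_slice(spec)
    assert detect_pipeline(img, bior32_bank, DetectionConfig())["nodules"] == []
    flat = np.full((64, 64), 50.0)
    assert detect_pipeline(flat, bior32_bank, DetectionConfig())["nodules"] == []


def test_rotation_robustness(bior32_bank):
    spec = PhantomSpec(shape=(128, 128), n_nodules=2, n_vessels=2,
                       noise_sigma=0.0, seed=15)
    img, _ = generate_slice(spec)
    cfg = DetectionConfig()
    n0 = len(detect_pipeline(img, bior32_bank, cfg, denoise=False)["nodules"])
    n90 = len(detect_pipeline(np.rot90(img).copy(), bior32_bank, cfg,
                              denoise=False)["nodules"])
    assert n0 == n90


def test_config_validation():
    with pytest.raises(ConfigurationError):
        DetectionConfig(levels=1)
    with pytest.raises(ConfigurationError):
        DetectionConfig(min_persistence=0)
    with pytest.raises(ConfigurationError):
        DetectionConfig(response_threshold_k=0.0)
    with pytest.raises(ConfigurationError):
        DetectionConfig(min_area=100, max_area=50)
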