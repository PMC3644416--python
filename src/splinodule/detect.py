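"""Multi-scale spline-wavelet nodule detection.

Round, blob-like lesions respond strongly and isotropically in the detail
subbands of the undecimated spline-wavelet transform, with the responding
level tracking the lesion size.  The detector therefore works as follows:

1. :func:`multiscale_response` — isotropic detail magnitude
   ``sqrt(H^2 + V^2 + 2 D^2)`` per level of the stationary transform, each
   level normalized by its own robust scale (median absolute deviation), which
   makes one threshold meaningful across scales.
2. :func:`find_candidates` — 8-neighborhood local maxima above
   ``k x robust scale``, best level kept per location, duplicates within a
   match radius merged.
3. :func:`segment_candidate` — adaptive-threshold segmentation: Otsu's
   threshold inside a window of side ``4 * 2^level`` around the candidate,
   keeping the 8-connected component containing the center, holes filled.
4. :func:`shape_features` / :func:`filter_by_shape` — circularity, aspect
   ratio, extent, compactness, convexity and irregularity gates reject the
   elongated vessel/bronchus responses that mimic nodules in size and density.
5. :func:`slice_and_reduction` — for stacks, the logical-AND persistence rule:
   a detection survives only if re-found at a consistent position in at least
   ``min_persistence`` consecutive slices.  Nodules are 3D-compact and
   persist; vessels drift from slice to slice and drop out.  This 2D-plus-AND
   design is deliberately preferred over full 3D filtering for speed.

:func:`detect_pipeline` chains optional denoising, optional
compress-decompress at a configured ratio, per-slice detection, and the AND
reduction into one call.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np
from scipy import ndimage
from skimage.feature import peak_local_max
from skimage.filters import threshold_otsu
from skimage.measure import label as sk_label
from skimage.measure import regionprops
from skimage.segmentation import watershed

from .compress import compress, decompress
from .denoise import MAD_TO_SIGMA, ShrinkageRule, denoise_image
from .errors import ConfigurationError
from .filterbank import FilterBank, make_filterbank
from .transforms import swt2

__all__ = [
    "DetectionConfig",
    "NoduleCandidate",
    "ShapeFeatures",
    "detect_pipeline",
    "detect_slice",
    "filter_by_shape",
    "find_candidates",
    "multiscale_response",
    "segment_candidate",
    "shape_features",
    "slice_and_reduction",
]

def _disc(radius: int) -> np.ndarray:
    return np.hypot(*np.mgrid[-radius:radius + 1, -radius:radius + 1]) <= radius


@dataclass(frozen=True)
class ShapeFeatures:
    """Boundary-quantifying shape descriptors of a segmented candidate."""

    area: float
    perimeter: float
    circularity: float
    aspect_ratio: float
    extent: float
    compactness: float
    convexity: float
    irregularity: float

    def as_dict(self) -> dict:
        return {
            "area": self.area,
            "perimeter": self.perimeter,
            "circularity": self.circularity,
            "aspect_ratio": self.aspect_ratio,
            "extent": self.extent,
            "compactness": self.compactness,
            "convexity": self.convexity,
            "irregularity": self.irregularity,
        }


@dataclass
class NoduleCandidate:
    """A detected blob: position, scale, response, segmentation and features."""

    center: tuple[int, int]
    scale_level: int
    response: float
    mask: np.ndarray | None = None
    mask_offset: tuple[int, int] = (0, 0)
    features: ShapeFeatures | None = None
    slice_index: int = -1
    boundary_touching: bool = False

    def as_dict(self) -> dict:
        return {
            "slice": self.slice_index,
            "row": int(self.center[0]),
            "col": int(self.center[1]),
            "scale_level": int(self.scale_level),
            "response": float(self.response),
            "features": self.features.as_dict() if self.features else None,
        }


@dataclass
class DetectionConfig:
    """Detector knobs; the shape gates and persistence rule reject vessels."""

    levels: int = 4
    response_threshold_k: float = 3.5
    min_circularity: float = 0.6
    max_aspect_ratio: float = 2.5
    min_convexity: float = 0.8
    min_area: float = 20.0
    max_area: float = 2000.0
    max_coherence: float = 0.3
    field_margin: float = 8.0
    min_persistence: int = 2
    match_radius: float = 5.0
    reject_boundary_touching: bool = True
    boundary: str = "symmetric"

    def __post_init__(self):
        if self.levels < 2:
            raise ConfigurationError("detection needs levels >= 2")
        if self.min_persistence < 1:
            raise ConfigurationError("min_persistence must be >= 1")
        if self.match_radius <= 0 or self.response_threshold_k <= 0:
            raise ConfigurationError("match_radius and response_threshold_k must be > 0")
        if not (0 < self.min_circularity <= 1.2 and self.max_aspect_ratio >= 1
                and 0 < self.min_convexity <= 1 and 0 <= self.min_area < self.max_area):
            raise ConfigurationError("shape gates out of range")


def _robust_scale(arr: np.ndarray) -> float:
    med = np.median(arr)
    return float(np.median(np.abs(arr - med)) / MAD_TO_SIGMA)


def multiscale_response(image, fb: FilterBank, levels: int,
                        boundary: str = "symmetric") -> list[np.ndarray]:
    """Per-level isotropic detail magnitude, robust-scale normalized.

    Each returned response image has the input's shape; the blob of radius
    ``r`` peaks at the level whose equivalent filter width matches ``2r``.
    """
    if levels < 2:
        raise ConfigurationError("multiscale_response needs levels >= 2")
    pyr = swt2(image, fb, levels, boundary)
    responses = []
    for lev in range(1, levels + 1):
        h = pyr.detail(lev, "H")
        v = pyr.detail(lev, "V")
        d = pyr.detail(lev, "D")
        r = np.sqrt(h * h + v * v + 2.0 * d * d)
        s = _robust_scale(r)
        responses.append(r / s if s > 0 else r)
    return responses


def find_candidates(responses: list[np.ndarray], cfg: DetectionConfig) -> list[NoduleCandidate]:
    """Local-maximum extraction across space and scale (pre-segmentation)."""
    raw: list[tuple[float, int, int, int]] = []
    for lev, resp in enumerate(responses, start=1):
        scale = _robust_scale(resp)
        thr = cfg.response_threshold_k * scale
        local_max = (resp == ndimage.maximum_filter(resp, size=3)) & (resp > thr)
        for r, c in zip(*np.nonzero(local_max)):
            raw.append((float(resp[r, c]), lev, int(r), int(c)))
    raw.sort(key=lambda t: (-t[0], t[1], t[2], t[3]))
    kept: list[NoduleCandidate] = []
    for resp, lev, r, c in raw:
        if any(np.hypot(r - k.center[0], c - k.center[1]) <= cfg.match_radius for k in kept):
            continue
        kept.append(NoduleCandidate(center=(r, c), scale_level=lev, response=resp))
    return kept


def _center_component(binary: np.ndarray, center: tuple[int, int],
                      window: np.ndarray | None = None):
    """8-connected component containing ``center``, bridge-cut if necessary.

    Rim tapers can fuse a nodule with a nearby vessel into one component that
    crosses the window edge.  Morphological openings of growing radius are
    tried first; if they fail, the component is split at its narrowest neck by
    a distance-transform watershed.  A region produced by either split is only
    accepted when it is not a fragment cut out of a longer structure: it must
    adjoin at most one other bright region (a vessel continues on two sides),
    or — for nodules sitting in a vessel junction where several bridges adjoin
    — be simultaneously brighter than its surrounding ring and strongly
    disc-shaped.  Returns ``(mask, touching)`` or ``(None, True)`` when the
    center has no component.
    """
    best = None
    for radius in (0, 2, 3, 4):
        work = binary if radius == 0 else ndimage.binary_opening(binary, structure=_disc(radius))
        if not work[center]:
            continue
        labels = sk_label(work, connectivity=2)
        mask = ndimage.binary_fill_holes(labels == labels[center])
        touching = bool(_touches_edge(mask))
        if best is None or radius == 2:
            best = (mask, touching)
        if not touching:
            if radius > 2 and _continuations(binary, mask) > 1:
                # fragment of a longer structure (a vessel cut in two by the
                # opening), not a detached nodule
                continue
            return mask, touching
    ws = _watershed_region(binary, center)
    if ws is not None and not _touches_edge(ws):
        if _continuations(binary, ws) <= 1:
            return ws, False
        if window is not None and _is_bright_disc(ws, binary, window):
            return ws, False
    return best if best is not None else (None, True)


def _is_bright_disc(mask: np.ndarray, binary: np.ndarray, window: np.ndarray,
                    min_drop: float = 0.25) -> bool:
    """True when ``mask`` is a round region clearly brighter than its ring.

    Used to rescue nodules detached inside vessel junctions: the lesion core
    stands above the adjoining bridge/taper pixels, whereas a fragment cut out
    of a vessel is as bright as the strip continuing around it.
    """
    core = ndimage.binary_erosion(mask, structure=_disc(2))
    ring = binary & ndimage.binary_dilation(mask, structure=_disc(3)) & ~mask
    if core.sum() < 5 or ring.sum() < 5:
        return False
    background = np.median(window[~binary]) if (~binary).any() else float(window.min())
    drop = (window[core].mean() - window[ring].mean()) / max(
        window[core].mean() - background, 1e-9
    )
    f = shape_features(mask)
    return drop >= min_drop and f.circularity >= 0.8 and f.aspect_ratio <= 1.5


def _touches_edge(mask: np.ndarray) -> bool:
    return bool(mask[0, :].any() or mask[-1, :].any()
                or mask[:, 0].any() or mask[:, -1].any())


def _watershed_region(binary: np.ndarray, center: tuple[int, int]):
    """Distance-transform watershed region containing ``center``, holes filled."""
    edt = ndimage.gaussian_filter(ndimage.distance_transform_edt(binary), 1.0)
    coords = peak_local_max(edt, min_distance=3, labels=binary)
    if coords.size == 0:
        return None
    markers = np.zeros(binary.shape, dtype=int)
    markers[tuple(coords.T)] = np.arange(1, len(coords) + 1)
    labels = watershed(-edt, markers, mask=binary)
    if labels[center] == 0:
        return None
    return ndimage.binary_fill_holes(labels == labels[center])


def _continuations(binary: np.ndarray, mask: np.ndarray, min_pixels: int = 5) -> int:
    """Number of distinct bright structures adjoining ``mask`` in ``binary``.

    A nodule detached from a vessel by an opening leaves at most one adjoining
    region (the rim-taper bridge); a fragment cut out of a vessel leaves the
    strip continuing on both sides.
    """
    ring = binary & ndimage.binary_dilation(mask, structure=_disc(3)) & ~mask
    if not ring.any():
        return 0
    labels = sk_label(ring, connectivity=2)
    sizes = np.bincount(labels.ravel())[1:]
    return int(np.sum(sizes >= min_pixels))


def segment_candidate(image, cand: NoduleCandidate,
                      cfg: DetectionConfig) -> NoduleCandidate | None:
    """Adaptive-threshold segmentation in a window around the candidate.

    Otsu's threshold is computed inside a window of side ``4 * 2^level``
    around the center and the 8-connected component containing the center is
    kept (holes filled).  When that component is clipped by the window edge
    the window is doubled (at most twice) and segmentation repeated: a compact
    nodule then fits and detaches from the boundary, whereas a vessel keeps
    crossing the window at every size and stays ``boundary_touching`` — the
    flag the shape filter uses to reject it.

    Returns the candidate with its mask attached, or ``None`` when the window
    is degenerate / the center falls below the Otsu threshold (the discard
    signal — not an error).
    """
    image = np.asarray(image, dtype=float)
    r, c = cand.center
    # initial window side 4 * 2^level, capped: beyond level 3 the window would
    # span the whole organ field and Otsu would segment field-vs-background
    # instead of lesion-vs-field (the growth loop below still widens it when
    # the component is clipped)
    half = 2 * 2 ** min(cand.scale_level, 3)
    result = None
    for _grow in range(3):
        r0, r1 = max(0, r - half), min(image.shape[0], r + half + 1)
        c0, c1 = max(0, c - half), min(image.shape[1], c + half + 1)
        window = image[r0:r1, c0:c1]
        if window.size == 0 or np.ptp(window) <= 0:
            return None
        thr = threshold_otsu(window)
        binary = window >= thr
        if not binary[r - r0, c - c0]:
            return None
        mask, touching = _center_component(binary, (r - r0, c - c0), window)
        if mask is None:
            return None
        result = replace(cand)
        result.mask = mask
        result.mask_offset = (r0, c0)
        result.boundary_touching = touching
        if not touching:
            break
        half *= 2
    return result


def shape_features(mask: np.ndarray) -> ShapeFeatures:
    """Shape descriptors of one 8-connected binary mask."""
    mask = np.asarray(mask, dtype=bool)
    if not mask.any():
        raise ConfigurationError("shape_features needs a non-empty mask")
    props = regionprops(mask.astype(np.uint8))[0]
    area = float(props.area)
    perimeter = float(max(props.perimeter, 1.0))
    minor = float(props.axis_minor_length)
    major = float(props.axis_major_length)
    aspect = major / minor if minor > 1e-9 else float("inf")
    convexity = area / float(props.area_convex)
    return ShapeFeatures(
        area=area,
        perimeter=perimeter,
        circularity=4.0 * np.pi * area / perimeter ** 2,
        aspect_ratio=max(aspect, 1.0),
        extent=float(props.extent),
        compactness=perimeter ** 2 / area,
        convexity=convexity,
        irregularity=perimeter / (2.0 * np.sqrt(np.pi * area)) - 1.0,
    )


def filter_by_shape(cands: list[NoduleCandidate], cfg: DetectionConfig) -> list[NoduleCandidate]:
    """Keep candidates passing all shape gates; input order preserved."""
    out = []
    for cand in cands:
        f = cand.features
        if f is None:
            continue
        if cfg.reject_boundary_touching and cand.boundary_touching:
            continue
        if (
            f.circularity >= cfg.min_circularity
            and f.aspect_ratio <= cfg.max_aspect_ratio
            and f.convexity >= cfg.min_convexity
            and cfg.min_area <= f.area <= cfg.max_area
        ):
            out.append(cand)
    return out


def _recenter_on_mask(cand: NoduleCandidate) -> None:
    """Move the candidate center to its mask centroid (better localization).

    A local maximum often sits on the rim of a large lesion; the centroid of
    its segmented mask is the better position estimate.
    """
    r0, c0 = cand.mask_offset
    cy, cx = ndimage.center_of_mass(cand.mask)
    r, c = int(round(r0 + cy)), int(round(c0 + cx))
    rr, cc = r - r0, c - c0
    if 0 <= rr < cand.mask.shape[0] and 0 <= cc < cand.mask.shape[1] and cand.mask[rr, cc]:
        cand.center = (r, c)


def _dedupe(cands: list[NoduleCandidate], cfg: DetectionConfig) -> list[NoduleCandidate]:
    """Collapse detections of the same lesion into one representative.

    Local maxima at several scales (and on the rim of a large disc) segment
    the same component; after recentering their centroids coincide, so any
    candidate within the kept candidate's equivalent radius is a duplicate.
    Within a group the most disc-like segmentation wins (circularity, then
    response): a cleanly segmented lesion localizes its center far better
    than a strong but partially merged mask.
    """
    kept: list[NoduleCandidate] = []
    for cand in sorted(
        cands,
        key=lambda d: (-min(d.features.circularity, 1.0), -d.response, d.center),
    ):
        dup = False
        for other in kept:
            radius = max(cfg.match_radius, np.sqrt(other.features.area / np.pi))
            if np.hypot(cand.center[0] - other.center[0],
                        cand.center[1] - other.center[1]) <= radius:
                dup = True
                break
        if not dup:
            kept.append(cand)
    kept.sort(key=lambda d: d.center)
    return kept


def _coherence(image: np.ndarray, cand: NoduleCandidate) -> float:
    """Structure-tensor coherence ``(l1 - l2)/(l1 + l2)`` over the candidate mask.

    Gradients around a round lesion point in every direction (coherence near
    0); along a vessel they stay perpendicular to the ridge (coherence near
    1).  Averaging over the segmented mask (slightly dilated to include the
    rim) keeps neighboring structures out of the estimate.
    """
    r0, c0 = cand.mask_offset
    mh, mw = cand.mask.shape
    pad = 3
    rr0, cc0 = max(0, r0 - pad), max(0, c0 - pad)
    rr1 = min(image.shape[0], r0 + mh + pad)
    cc1 = min(image.shape[1], c0 + mw + pad)
    crop = image[rr0:rr1, cc0:cc1]
    region = np.zeros(crop.shape, dtype=bool)
    region[r0 - rr0:r0 - rr0 + mh, c0 - cc0:c0 - cc0 + mw] = cand.mask
    region = ndimage.binary_dilation(region, structure=_disc(2))
    gy = ndimage.gaussian_filter(crop, 1.0, order=(1, 0))
    gx = ndimage.gaussian_filter(crop, 1.0, order=(0, 1))
    jyy = float(np.sum(gy[region] ** 2))
    jxx = float(np.sum(gx[region] ** 2))
    jxy = float(np.sum((gx * gy)[region]))
    trace = jxx + jyy
    disc = np.sqrt(max(trace * trace / 4.0 - (jxx * jyy - jxy * jxy), 0.0))
    return float(2.0 * disc / (trace + 1e-12))


def _field_interior(image: np.ndarray, margin: float) -> np.ndarray | None:
    """Lung-field mask eroded by ``margin`` pixels, or ``None`` if degenerate.

    The bright field is segmented by a global Otsu threshold (holes — darker
    structures, none here by convention — filled).  Detections closer than
    ``margin`` to the field boundary are juxta-pleural artifacts (typically a
    vessel entering the field at the rim) and are excluded; phantom nodules
    are always placed with more clearance than this.
    """
    if np.ptp(image) <= 0:
        return None
    field = ndimage.binary_fill_holes(image >= threshold_otsu(image))
    if field.mean() < 0.05 or field.mean() > 0.95:
        return None
    return ndimage.distance_transform_edt(field) > margin


def detect_slice(image, fb: FilterBank, cfg: DetectionConfig,
                 slice_index: int = -1) -> list[NoduleCandidate]:
    """Full single-slice detection: response, maxima, segmentation, gates, dedup."""
    image = np.asarray(image, dtype=float)
    responses = multiscale_response(image, fb, cfg.levels, cfg.boundary)
    cands = find_candidates(responses, cfg)
    if cfg.field_margin > 0:
        interior = _field_interior(image, cfg.field_margin)
        if interior is not None:
            cands = [c for c in cands if interior[c.center]]
    segmented = []
    for cand in cands:
        seg = segment_candidate(image, cand, cfg)
        if seg is None:
            continue
        seg.features = shape_features(seg.mask)
        _recenter_on_mask(seg)
        seg.slice_index = slice_index
        segmented.append(seg)
    gated = filter_by_shape(segmented, cfg)
    isotropic = [
        cand for cand in gated if _coherence(image, cand) <= cfg.max_coherence
    ]
    return _dedupe(isotropic, cfg)


def slice_and_reduction(per_slice_detections: list[NoduleCandidate],
                        cfg: DetectionConfig) -> list[NoduleCandidate]:
    """Logical-AND persistence reduction across consecutive slices.

    A detection survives iff it is matched (center distance <=
    ``match_radius``) in at least ``min_persistence`` consecutive slices; each
    surviving group is reported once, at its maximum-response slice.
    """
    by_slice: dict[int, list[NoduleCandidate]] = {}
    for det in per_slice_detections:
        by_slice.setdefault(det.slice_index, []).append(det)

    tracks: list[list[NoduleCandidate]] = []
    open_tracks: list[list[NoduleCandidate]] = []
    for s in sorted(by_slice):
        dets = by_slice[s]
        still_open: list[list[NoduleCandidate]] = []
        candidates = list(dets)
        # tracks whose last member sits in the immediately preceding slice
        for track in open_tracks:
            last = track[-1]
            if last.slice_index != s - 1:
                tracks.append(track)
                continue
            best, best_d = None, None
            for det in candidates:
                d = np.hypot(det.center[0] - last.center[0], det.center[1] - last.center[1])
                if d <= cfg.match_radius and (best_d is None or d < best_d):
                    best, best_d = det, d
            if best is not None:
                track.append(best)
                candidates.remove(best)
                still_open.append(track)
            else:
                tracks.append(track)
        for det in candidates:
            still_open.append([det])
        open_tracks = still_open
    tracks.extend(open_tracks)

    survivors = []
    for track in tracks:
        if len(track) >= cfg.min_persistence:
            survivors.append(max(track, key=lambda d: d.response))
    survivors.sort(key=lambda d: (d.slice_index, d.center))
    return survivors


def detect_pipeline(data, fb: FilterBank, cfg: DetectionConfig,
                    denoise: bool = True,
                    denoise_rule: ShrinkageRule | None = None,
                    denoise_levels: int = 3,
                    compress_ratio: float | None = None,
                    compress_bank: FilterBank | None = None,
                    compress_levels: int = 4) -> dict:
    """Denoise -> (optional) compress/decompress -> detect -> AND-reduce.

    ``data`` is a 2D slice or a (slices, H, W) stack.  Returns a report dict
    with the final nodules, per-slice counts and the settings provenance.
    """
    data = np.asarray(data, dtype=float)
    is_stack = data.ndim == 3
    slices = data if is_stack else data[None]
    rule = denoise_rule or ShrinkageRule(mode="soft")
    cbank = compress_bank or make_filterbank("biorthogonal_spline", 1, 2)

    detections: list[NoduleCandidate] = []
    per_slice_counts = []
    for s, img in enumerate(slices):
        work = img
        if denoise:
            work = denoise_image(work, fb, denoise_levels, rule, cfg.boundary)
        if compress_ratio is not None and compress_ratio > 1.0:
            c = compress(work, cbank, compress_levels, compress_ratio)
            work = decompress(c, cbank)
        dets = detect_slice(work, fb, cfg, slice_index=s if is_stack else -1)
        per_slice_counts.append(len(dets))
        detections.extend(dets)

    final = slice_and_reduction(detections, cfg) if is_stack else detections
    return {
        "nodules": [d.as_dict() for d in final],
        "candidates": final,
        "per_slice_detections": detections,
        "per_slice_counts": per_slice_counts,
        "settings": {
            "bank_id": fb.bank_id,
            "denoise": denoise,
            "denoise_mode": rule.mode,
            "denoise_levels": denoise_levels,
            "compress_ratio": compress_ratio,
            "compress_bank": cbank.bank_id if compress_ratio else None,
            "detection": {
                "levels": cfg.levels,
                "response_threshold_k": cfg.response_threshold_k,
                "min_circularity": cfg.min_circularity,
                "max_aspect_ratio": cfg.max_aspect_ratio,
                "min_convexity": cfg.min_convexity,
                "area_range": [cfg.min_area, cfg.max_area],
                "min_persistence": cfg.min_persistence,
                "match_radius": cfg.match_radius,
            },
        },
    }
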