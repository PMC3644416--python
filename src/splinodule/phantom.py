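"""Synthetic CT-like slice and stack generator with exact ground truth.

A phantom slice is a dark background with a brighter elliptical "lung field"
(an inverted-attenuation convention: structures of interest are bright, which
keeps the whole pipeline sign-convention free), round nodules rendered as
radially smooth discs whose rim is a cosine taper crossing half contrast
exactly at the nominal radius, and vessels rendered as smooth curved polylines
of a given width — the elongated confounders whose size, shape and density
resemble nodules and make 2D detection hard.  Gaussian noise is added last and
the result is clipped to the 8-bit range [0, 255] (internally the image stays
real-valued).

Stacks add the third dimension the slice-persistence logic exploits: a nodule
spans a few consecutive slices with its radius modulated by a spherical-cap
profile, while vessels drift by 1-3 px between slices, decorrelating them
across the stack.  One seeded generator instance drives all randomness, so a
seed fully determines the output bit-for-bit.

Placement uses rejection sampling (100 attempts per structure); phantoms that
cannot be laid out raise :class:`GenerationError`.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage

from .errors import ConfigurationError, GenerationError

__all__ = [
    "Nodule",
    "PhantomSpec",
    "PhantomTruth",
    "Vessel",
    "generate_slice",
    "generate_stack",
]

BACKGROUND_LEVEL = 60.0
LUNG_FIELD_LEVEL = 110.0
EDGE_TAPER_PX = 1.5  # half-width of every cosine-taper rim
MAX_PLACEMENT_ATTEMPTS = 100


@dataclass
class PhantomSpec:
    """Parameters of one synthetic slice or stack; the seed fixes everything."""

    shape: tuple[int, int] = (256, 256)
    lung_field: tuple[float, float, float, float] | None = None  # (cy, cx, ry, rx)
    n_nodules: int = 3
    nodule_radius_range: tuple[float, float] = (4.0, 12.0)
    nodule_contrast_range: tuple[float, float] = (40.0, 80.0)
    n_vessels: int = 4
    vessel_width_range: tuple[float, float] = (2.0, 5.0)
    vessel_contrast: float = 45.0
    noise_sigma: float = 10.0
    n_slices: int = 1
    nodule_z_extent: int = 3
    seed: int = 0

    def __post_init__(self):
        for name in ("nodule_radius_range", "nodule_contrast_range", "vessel_width_range"):
            lo, hi = getattr(self, name)
            if lo > hi:
                raise ConfigurationError(f"{name} must be ordered, got ({lo}, {hi})")
        if self.noise_sigma < 0:
            raise ConfigurationError("noise_sigma must be >= 0")
        if self.n_slices < 1 or self.nodule_z_extent < 1:
            raise ConfigurationError("n_slices and nodule_z_extent must be >= 1")

    def resolved_field(self) -> tuple[float, float, float, float]:
        if self.lung_field is not None:
            return self.lung_field
        h, w = self.shape
        return (h / 2.0, w / 2.0, 0.38 * h, 0.42 * w)


@dataclass
class Nodule:
    center: tuple[int, int, int]  # (slice, row, col); slice 0 for single slices
    radius: float
    contrast: float
    z_start: int = 0
    z_extent: int = 1


@dataclass
class Vessel:
    polyline: np.ndarray  # (n_points, 2) float (row, col) base centerline
    width: float
    slice_offsets: list[tuple[int, int]] = field(default_factory=list)


@dataclass
class PhantomTruth:
    nodules: list[Nodule]
    vessels: list[Vessel]
    noise_sigma: float
    seed: int
    shape: tuple[int, int] = (256, 256)
    n_slices: int = 1


def _soft_disc(dist: np.ndarray, radius: float, taper: float = EDGE_TAPER_PX) -> np.ndarray:
    """Radial profile: 1 inside, cosine rim crossing 0.5 exactly at ``radius``."""
    t = np.clip((dist - (radius - taper)) / (2.0 * taper), 0.0, 1.0)
    return 0.5 * (1.0 + np.cos(np.pi * t))


def _field_map(spec: PhantomSpec) -> np.ndarray:
    cy, cx, ry, rx = spec.resolved_field()
    h, w = spec.shape
    rr, cc = np.mgrid[0:h, 0:w]
    # approximate signed distance to the ellipse rim in pixels
    rho = np.sqrt(((rr - cy) / ry) ** 2 + ((cc - cx) / rx) ** 2)
    dist_px = (rho - 1.0) * min(ry, rx)
    return _soft_disc(dist_px + min(ry, rx), min(ry, rx))


def _inside_field(spec: PhantomSpec, r: float, c: float, margin: float) -> bool:
    cy, cx, ry, rx = spec.resolved_field()
    return ((r - cy) / max(ry - margin, 1.0)) ** 2 + ((c - cx) / max(rx - margin, 1.0)) ** 2 <= 1.0


def _bezier(p0, p1, p2, n: int) -> np.ndarray:
    t = np.linspace(0.0, 1.0, n)[:, None]
    return (1 - t) ** 2 * p0 + 2 * (1 - t) * t * p1 + t ** 2 * p2


def _make_vessels(spec: PhantomSpec, rng: np.random.Generator) -> list[Vessel]:
    cy, cx, ry, rx = spec.resolved_field()
    vessels = []
    for _ in range(spec.n_vessels):
        width = rng.uniform(*spec.vessel_width_range)
        for _attempt in range(MAX_PLACEMENT_ATTEMPTS):
            th1 = rng.uniform(0.0, 2.0 * np.pi)
            th2 = th1 + np.pi + rng.uniform(-0.6, 0.6)
            p0 = np.array([cy + 0.85 * ry * np.sin(th1), cx + 0.85 * rx * np.cos(th1)])
            p2 = np.array([cy + 0.85 * ry * np.sin(th2), cx + 0.85 * rx * np.cos(th2)])
            mid = 0.5 * (p0 + p2)
            chord = p2 - p0
            norm = np.linalg.norm(chord)
            if norm < 0.5 * min(ry, rx):
                continue
            perp = np.array([-chord[1], chord[0]]) / norm
            p1 = mid + perp * rng.uniform(-0.25, 0.25) * norm
            pts = _bezier(p0, p1, p2, int(max(64, 2 * norm)))
            if _inside_field(spec, *p1, margin=2.0):
                vessels.append(Vessel(polyline=pts, width=float(width)))
                break
        else:
            raise GenerationError("could not place a vessel inside the lung field")
    return vessels


def _vessel_distance_map(shape, vessels: list[Vessel], offsets=None) -> np.ndarray:
    """Euclidean distance from each pixel to the nearest vessel centerline."""
    mask = np.zeros(shape, dtype=bool)
    for i, v in enumerate(vessels):
        pts = v.polyline
        if offsets is not None:
            pts = pts + np.asarray(offsets[i], dtype=float)
        rr = np.clip(np.round(pts[:, 0]).astype(int), 0, shape[0] - 1)
        cc = np.clip(np.round(pts[:, 1]).astype(int), 0, shape[1] - 1)
        mask[rr, cc] = True
    if not mask.any():
        return np.full(shape, np.inf)
    return ndimage.distance_transform_edt(~mask)


def _place_nodules(spec: PhantomSpec, rng: np.random.Generator,
                   vessel_dist: np.ndarray) -> list[tuple[float, float, float, float]]:
    """Returns (row, col, radius, contrast) tuples obeying the separation rules."""
    placed: list[tuple[float, float, float, float]] = []
    h, w = spec.shape
    for _ in range(spec.n_nodules):
        for _attempt in range(MAX_PLACEMENT_ATTEMPTS):
            # radius redrawn per attempt: large nodules need 2x their radius of
            # clearance from every vessel, which may only fit smaller lesions
            radius = rng.uniform(*spec.nodule_radius_range)
            contrast = rng.uniform(*spec.nodule_contrast_range)
            r = rng.uniform(0, h - 1)
            c = rng.uniform(0, w - 1)
            if not _inside_field(spec, r, c, margin=radius + 2 * EDGE_TAPER_PX + 2):
                continue
            if vessel_dist[int(round(r)), int(round(c))] < 2.0 * radius:
                continue
            if any(np.hypot(r - pr, c - pc) < radius + prad + 4.0
                   for pr, pc, prad, _ in placed):
                continue
            placed.append((r, c, radius, contrast))
            break
        else:
            raise GenerationError(
                "could not place a nodule after "
                f"{MAX_PLACEMENT_ATTEMPTS} attempts (field too crowded)"
            )
    return placed


def _render(spec: PhantomSpec, vessels, offsets, nodule_discs) -> np.ndarray:
    """Noise-free slice from structure descriptions."""
    h, w = spec.shape
    img = np.full((h, w), BACKGROUND_LEVEL)
    field = _field_map(spec)
    img += (LUNG_FIELD_LEVEL - BACKGROUND_LEVEL) * field
    # attenuation of distinct structures is not additive: in a true axial
    # slice vessels occupy disjoint tissue, so overlapping profiles (e.g. two
    # vessels crossing in the plane) take the maximum, not the sum
    structures = np.zeros((h, w))
    if vessels:
        # widths differ per vessel, so each centerline gets its own distance map
        for i, v in enumerate(vessels):
            d_i = _vessel_distance_map(spec.shape, [v],
                                       None if offsets is None else [offsets[i]])
            profile = spec.vessel_contrast * _soft_disc(d_i, v.width / 2.0 + EDGE_TAPER_PX) * field
            structures = np.maximum(structures, profile)
    rr, cc = np.mgrid[0:h, 0:w]
    for (r, c, radius, contrast) in nodule_discs:
        d = np.hypot(rr - r, cc - c)
        structures = np.maximum(structures, contrast * _soft_disc(d, radius))
    return img + structures


def generate_slice(spec: PhantomSpec) -> tuple[np.ndarray, PhantomTruth]:
    """Generate a single noisy slice and its exact ground truth."""
    if spec.n_slices != 1:
        raise ConfigurationError("generate_slice requires n_slices == 1")
    rng = np.random.default_rng(spec.seed)
    vessels = _make_vessels(spec, rng)
    vdist = _vessel_distance_map(spec.shape, vessels) if vessels else np.full(spec.shape, np.inf)
    discs = _place_nodules(spec, rng, vdist)
    img = _render(spec, vessels, None, discs)
    if spec.noise_sigma > 0:
        img = img + rng.normal(0.0, spec.noise_sigma, size=spec.shape)
    img = np.clip(img, 0.0, 255.0)
    truth = PhantomTruth(
        nodules=[
            Nodule(center=(0, int(round(r)), int(round(c))), radius=rad, contrast=con)
            for (r, c, rad, con) in discs
        ],
        vessels=vessels,
        noise_sigma=spec.noise_sigma,
        seed=spec.seed,
        shape=spec.shape,
        n_slices=1,
    )
    return img, truth


def generate_stack(spec: PhantomSpec) -> tuple[np.ndarray, PhantomTruth]:
    """Generate an ordered slice stack (n_slices, H, W) with 3D ground truth."""
    if spec.n_slices < 2:
        raise ConfigurationError("generate_stack requires n_slices >= 2")
    rng = np.random.default_rng(spec.seed)
    vessels = _make_vessels(spec, rng)
    vdist = _vessel_distance_map(spec.shape, vessels) if vessels else np.full(spec.shape, np.inf)
    discs = _place_nodules(spec, rng, vdist)

    extent = min(spec.nodule_z_extent, spec.n_slices)
    nodules = []
    for (r, c, radius, contrast) in discs:
        z0 = int(rng.integers(0, spec.n_slices - extent + 1))
        zc = z0 + (extent - 1) // 2
        nodules.append(Nodule(center=(zc, int(round(r)), int(round(c))),
                              radius=radius, contrast=contrast,
                              z_start=z0, z_extent=extent))

    # cumulative vessel drift: 1-3 px per slice along a random axis mix
    for v in vessels:
        offsets = [(0, 0)]
        for _ in range(1, spec.n_slices):
            step = rng.integers(1, 4)
            angle = rng.uniform(0.0, 2.0 * np.pi)
            dy = int(round(step * np.sin(angle)))
            dx = int(round(step * np.cos(angle)))
            if dy == 0 and dx == 0:
                dx = int(step)
            py, px = offsets[-1]
            offsets.append((py + dy, px + dx))
        v.slice_offsets = offsets

    stack = np.empty((spec.n_slices,) + tuple(spec.shape))
    for s in range(spec.n_slices):
        discs_s = []
        for nod, (r, c, radius, contrast) in zip(nodules, discs):
            dz = s - (nod.z_start + (nod.z_extent - 1) / 2.0)
            if not (nod.z_start <= s < nod.z_start + nod.z_extent):
                continue
            rel = 2.0 * dz / (nod.z_extent + 1.0)
            r_s = radius * np.sqrt(max(0.0, 1.0 - rel * rel))
            if r_s > 0.5:
                discs_s.append((r, c, r_s, contrast))
        offs = [v.slice_offsets[s] for v in vessels]
        img = _render(spec, vessels, offs, discs_s)
        if spec.noise_sigma > 0:
            img = img + rng.normal(0.0, spec.noise_sigma, size=spec.shape)
        stack[s] = np.clip(img, 0.0, 255.0)

    truth = PhantomTruth(
        nodules=nodules,
        vessels=vessels,
        noise_sigma=spec.noise_sigma,
        seed=spec.seed,
        shape=spec.shape,
        n_slices=spec.n_slices,
    )
    return stack, truth
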