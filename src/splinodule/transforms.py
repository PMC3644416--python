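"""Separable 2D spline-wavelet transforms.

Two variants, both with exact inverses:

* :func:`dwt2` / :func:`idwt2` — the decimated transform used for compression.
  In ``symmetric`` / ``zero`` boundary modes the transform is *expansive*: each
  subband holds every coefficient whose filter support touches the (extended)
  signal, so subband lengths are ``~N/2`` plus a constant number of boundary
  coefficients per side and perfect reconstruction holds for arbitrary sizes
  and filter lengths.  In ``periodic`` mode the transform is non-expansive
  (ceiling halving); odd extents are edge-padded by one sample and cropped on
  inversion.
* :func:`swt2` / :func:`iswt2` — the undecimated (a trous / stationary)
  transform used for denoising and detection: filters are upsampled by
  ``2^(level-1)``, no downsampling, every subband has the input's shape.
  ``periodic`` mode is exactly shift-equivariant.  ``symmetric`` mode
  pre-extends the image by the total filter reach with mirror samples and runs
  the periodic machinery on the extended domain; the pyramid keeps the
  extended arrays internally (cropped views are exposed), which makes the
  inverse exact for every bank, including even-length filters.

Indexing is row-major, 0-based, ``(row, col)`` order.  The analysis step is a
correlation with the analysis filters (``a(m) = sum_k x(k) htilde(k - 2m)``)
and synthesis a convolution with the synthesis filters, matching the filter
quadruple conventions of :mod:`splinodule.filterbank`.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from math import floor, log2
from pathlib import Path

import numpy as np

from .errors import ConfigurationError, FormatError
from .filterbank import Filter, FilterBank

__all__ = [
    "CoefficientPyramid",
    "dwt2",
    "idwt2",
    "swt2",
    "iswt2",
    "max_levels",
    "save_pyramid",
    "load_pyramid",
]

DETAIL_KEYS = ("H", "V", "D")  # horizontal, vertical, diagonal detail


def max_levels(shape) -> int:
    """Default maximum decomposition depth: ``floor(log2(min(H, W))) - 2``."""
    return max(1, int(floor(log2(min(shape)))) - 2)


# ---------------------------------------------------------------------------
# 1D building blocks (operate on the last axis)
# ---------------------------------------------------------------------------

def _support_range(n: int, f: Filter) -> tuple[int, int]:
    """Indices m whose shifted filter support ``[2m+o, 2m+o+L-1]`` meets [0, n)."""
    o, length = f.offset, len(f)
    return -((o + length - 1) // 2), (n - 1 - o) // 2


def _analyze_exp_last(x: np.ndarray, fb: FilterBank, boundary: str):
    """Expansive analysis along the last axis.

    Coefficients are kept for every index whose *synthesis* filter support
    meets the signal — exactly the set the inverse needs to reconstruct
    ``[0, n)``, making PR exact for any extension.  The extension margin is
    wide enough that each kept coefficient reads only properly extended
    samples, so in symmetric mode vanishing moments hold up to the boundary.
    """
    flo, fhi = fb.ht, fb.gt  # analysis filters
    n = x.shape[-1]
    lo_rng = _support_range(n, fb.h)
    hi_rng = _support_range(n, fb.g)
    m0 = min(lo_rng[0], hi_rng[0])
    m1 = max(lo_rng[1], hi_rng[1])
    nm = m1 - m0 + 1
    read_lo = 2 * m0 + min(flo.offset, fhi.offset)
    read_hi = 2 * m1 + max(flo.offset + len(flo), fhi.offset + len(fhi)) - 1
    if boundary == "symmetric":
        # every kept coefficient reads properly extended samples, so e.g.
        # vanishing moments hold up to the boundary and the approximation band
        # continues smoothly into its own boundary coefficients
        ext = max(0, -read_lo, read_hi - (n - 1))
        xe = np.pad(x, [(0, 0)] * (x.ndim - 1) + [(ext, ext)], mode="symmetric")
    else:
        ext = 0
        xe = x
    base = min(read_lo, -ext)
    top = max(read_hi, n + ext - 1)
    buf = np.zeros(x.shape[:-1] + (top - base + 1,))
    start = -ext - base
    buf[..., start:start + n + 2 * ext] = xe

    def corr(f):
        out = np.zeros(x.shape[:-1] + (nm,))
        for j, t in enumerate(f.taps):
            s = 2 * m0 + f.offset + j - base
            out += t * buf[..., s:s + 2 * nm:2]
        return out

    return corr(flo), corr(fhi), m0


def _synth_exp_last(a, d, flo: Filter, fhi: Filter, m0: int, n_out: int):
    nm = a.shape[-1]
    k_lo = 2 * m0 + min(flo.offset, fhi.offset)
    k_hi = 2 * (m0 + nm - 1) + max(flo.offset + len(flo), fhi.offset + len(fhi)) - 1
    buf = np.zeros(a.shape[:-1] + (k_hi - k_lo + 1,))
    for f, c in ((flo, a), (fhi, d)):
        for j, t in enumerate(f.taps):
            s = 2 * m0 + f.offset + j - k_lo
            buf[..., s:s + 2 * nm:2] += t * c
    return buf[..., -k_lo:-k_lo + n_out]


def _analyze_per_last(x: np.ndarray, flo: Filter, fhi: Filter):
    def corr(f):
        out = None
        for j, t in enumerate(f.taps):
            term = t * np.roll(x, -(f.offset + j), axis=-1)[..., ::2]
            out = term if out is None else out + term
        return out

    return corr(flo), corr(fhi)


def _synth_per_last(a, d, flo: Filter, fhi: Filter):
    n = 2 * a.shape[-1]
    out = np.zeros(a.shape[:-1] + (n,))
    for f, c in ((flo, a), (fhi, d)):
        u = np.zeros_like(out)
        u[..., ::2] = c
        for j, t in enumerate(f.taps):
            out += t * np.roll(u, f.offset + j, axis=-1)
    return out


def _tx(arr, axis):
    """View with ``axis`` moved last (2D only: transpose or identity)."""
    return arr.T if axis == 0 else arr


# ---------------------------------------------------------------------------
# Pyramid container
# ---------------------------------------------------------------------------

@dataclass
class CoefficientPyramid:
    """Multi-level 2D wavelet coefficients.

    ``details[i]`` holds the level-``i+1`` subbands ``H`` (highpass along
    columns), ``V`` (highpass along rows) and ``D`` (highpass along both);
    ``approx`` is the level-``levels`` approximation.  For the undecimated
    transform in symmetric mode the stored arrays are mirror-extended; use
    :meth:`detail` / :meth:`approximation` for input-shaped views.
    """

    mode: str  # "decimated" | "undecimated"
    levels: int
    bank_id: str
    boundary_mode: str
    original_shape: tuple[int, int]
    approx: np.ndarray
    details: list[dict[str, np.ndarray]]
    meta: dict = field(default_factory=dict)

    @property
    def pad(self) -> int:
        return int(self.meta.get("pad", 0))

    def _crop(self, arr: np.ndarray) -> np.ndarray:
        p = self.pad
        if p == 0:
            return arr
        h, w = self.original_shape
        return arr[p:p + h, p:p + w]

    def detail(self, level: int, key: str) -> np.ndarray:
        """Input-aligned view of one detail subband (level is 1-based)."""
        return self._crop(self.details[level - 1][key])

    def approximation(self) -> np.ndarray:
        return self._crop(self.approx)

    def map_details(self, func) -> None:
        """Apply ``func(arr, level, key) -> arr`` to every detail subband in place."""
        for i, bands in enumerate(self.details):
            for key in DETAIL_KEYS:
                bands[key] = func(bands[key], i + 1, key)

    def total_count(self) -> int:
        return int(self.approx.size + sum(b[k].size for b in self.details for k in DETAIL_KEYS))

    def detail_energy(self) -> float:
        return float(sum(np.sum(self._crop(b[k]) ** 2) for b in self.details for k in DETAIL_KEYS))


def _check_levels(image: np.ndarray, levels: int):
    if image.ndim != 2:
        raise ConfigurationError(f"expected a 2D image, got shape {image.shape}")
    if levels < 1:
        raise ConfigurationError("levels must be >= 1")
    if min(image.shape) < 2 ** levels:
        raise ConfigurationError(
            f"{levels} levels need min dimension >= {2 ** levels}, got {image.shape}"
        )


# ---------------------------------------------------------------------------
# Decimated transform
# ---------------------------------------------------------------------------

def dwt2(image, fb: FilterBank, levels: int, boundary: str = "symmetric") -> CoefficientPyramid:
    """Decimated separable 2D wavelet analysis."""
    image = np.asarray(image, dtype=float)
    _check_levels(image, levels)
    if boundary not in ("symmetric", "zero", "periodic"):
        raise ConfigurationError(f"unknown boundary mode {boundary!r}")

    a = image
    details: list[dict[str, np.ndarray]] = []
    level_meta = []
    for _ in range(levels):
        in_shape = a.shape
        if boundary == "periodic":
            pr, pc = a.shape[0] % 2, a.shape[1] % 2
            if pr:
                a = np.concatenate([a, a[-1:, :]], axis=0)
            if pc:
                a = np.concatenate([a, a[:, -1:]], axis=1)
            lo0, hi0 = _analyze_per_last(_tx(a, 0), fb.ht, fb.gt)
            lo0, hi0 = lo0.T, hi0.T
            ll, h = _analyze_per_last(lo0, fb.ht, fb.gt)
            v, d = _analyze_per_last(hi0, fb.ht, fb.gt)
            level_meta.append({"in_shape": in_shape, "pad": (pr, pc), "m0": (0, 0)})
        else:
            lo0, hi0, m0r = _analyze_exp_last(_tx(a, 0), fb, boundary)
            lo0, hi0 = lo0.T, hi0.T
            ll, h, m0c = _analyze_exp_last(lo0, fb, boundary)
            v, d, _ = _analyze_exp_last(hi0, fb, boundary)
            level_meta.append({"in_shape": in_shape, "pad": (0, 0), "m0": (m0r, m0c)})
        details.append({"H": h, "V": v, "D": d})
        a = ll

    return CoefficientPyramid(
        mode="decimated",
        levels=levels,
        bank_id=fb.bank_id,
        boundary_mode=boundary,
        original_shape=tuple(image.shape),
        approx=a,
        details=details,
        meta={"levels": level_meta},
    )


def idwt2(pyr: CoefficientPyramid, fb: FilterBank) -> np.ndarray:
    """Inverse of :func:`dwt2`; restores the original shape exactly."""
    if pyr.mode != "decimated":
        raise ConfigurationError("idwt2 expects a decimated pyramid")
    if pyr.bank_id != fb.bank_id:
        raise ConfigurationError(
            f"bank mismatch: pyramid built with {pyr.bank_id}, got {fb.bank_id}"
        )
    a = pyr.approx
    for lev in range(pyr.levels - 1, -1, -1):
        bands = pyr.details[lev]
        info = pyr.meta["levels"][lev]
        in_shape = info["in_shape"]
        pr, pc = info["pad"]
        n0, n1 = in_shape[0] + pr, in_shape[1] + pc
        if pyr.boundary_mode == "periodic":
            lo0 = _synth_per_last(a, bands["H"], fb.h, fb.g)
            hi0 = _synth_per_last(bands["V"], bands["D"], fb.h, fb.g)
            rec = _synth_per_last(lo0.T, hi0.T, fb.h, fb.g).T
        else:
            m0r, m0c = info["m0"]
            lo0 = _synth_exp_last(a, bands["H"], fb.h, fb.g, m0c, n1)
            hi0 = _synth_exp_last(bands["V"], bands["D"], fb.h, fb.g, m0c, n1)
            rec = _synth_exp_last(lo0.T, hi0.T, fb.h, fb.g, m0r, n0).T
        a = rec[: in_shape[0], : in_shape[1]]
    return a


# ---------------------------------------------------------------------------
# Undecimated (a trous) transform
# ---------------------------------------------------------------------------

def _swt_shift(x, f: Filter, scale: int, axis: int, forward: bool):
    """Correlate (forward) or convolve (inverse) with the a-trous filter."""
    out = None
    sign = -1 if forward else 1
    for j, t in enumerate(f.taps):
        term = t * np.roll(x, sign * (f.offset + j) * scale, axis=axis)
        out = term if out is None else out + term
    return out


def _swt_reach(fb: FilterBank, levels: int) -> int:
    span = max(
        max(abs(f.offset), abs(f.offset + len(f) - 1))
        for f in (fb.h, fb.ht, fb.g, fb.gt)
    )
    return int(span * (2 ** levels - 1)) + 2


def swt2(image, fb: FilterBank, levels: int, boundary: str = "symmetric") -> CoefficientPyramid:
    """Undecimated (stationary) 2D wavelet analysis; subbands keep the input shape."""
    image = np.asarray(image, dtype=float)
    _check_levels(image, levels)
    if boundary not in ("symmetric", "periodic"):
        raise ConfigurationError(f"unknown boundary mode {boundary!r}")

    pad = _swt_reach(fb, levels) if boundary == "symmetric" else 0
    a = np.pad(image, pad, mode="symmetric") if pad else image
    details = []
    for lev in range(1, levels + 1):
        s = 2 ** (lev - 1)
        lo0 = _swt_shift(a, fb.ht, s, 0, forward=True)
        hi0 = _swt_shift(a, fb.gt, s, 0, forward=True)
        ll = _swt_shift(lo0, fb.ht, s, 1, forward=True)
        h = _swt_shift(lo0, fb.gt, s, 1, forward=True)
        v = _swt_shift(hi0, fb.ht, s, 1, forward=True)
        d = _swt_shift(hi0, fb.gt, s, 1, forward=True)
        details.append({"H": h, "V": v, "D": d})
        a = ll

    return CoefficientPyramid(
        mode="undecimated",
        levels=levels,
        bank_id=fb.bank_id,
        boundary_mode=boundary,
        original_shape=tuple(image.shape),
        approx=a,
        details=details,
        meta={"pad": pad},
    )


def iswt2(pyr: CoefficientPyramid, fb: FilterBank) -> np.ndarray:
    """Inverse of :func:`swt2` (averaging/dual-frame a-trous inverse)."""
    if pyr.mode != "undecimated":
        raise ConfigurationError("iswt2 expects an undecimated pyramid")
    if pyr.bank_id != fb.bank_id:
        raise ConfigurationError(
            f"bank mismatch: pyramid built with {pyr.bank_id}, got {fb.bank_id}"
        )
    a = pyr.approx
    for lev in range(pyr.levels, 0, -1):
        s = 2 ** (lev - 1)
        bands = pyr.details[lev - 1]
        lo0 = 0.5 * (
            _swt_shift(a, fb.h, s, 1, forward=False)
            + _swt_shift(bands["H"], fb.g, s, 1, forward=False)
        )
        hi0 = 0.5 * (
            _swt_shift(bands["V"], fb.h, s, 1, forward=False)
            + _swt_shift(bands["D"], fb.g, s, 1, forward=False)
        )
        a = 0.5 * (
            _swt_shift(lo0, fb.h, s, 0, forward=False)
            + _swt_shift(hi0, fb.g, s, 0, forward=False)
        )
    p = pyr.pad
    if p:
        h, w = pyr.original_shape
        a = a[p:p + h, p:p + w]
    return a


# ---------------------------------------------------------------------------
# Debug serialization (directory of flat binary arrays + JSON manifest)
# ---------------------------------------------------------------------------

def save_pyramid(pyr: CoefficientPyramid, directory) -> None:
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    manifest = {
        "mode": pyr.mode,
        "levels": pyr.levels,
        "bank_id": pyr.bank_id,
        "boundary_mode": pyr.boundary_mode,
        "original_shape": list(pyr.original_shape),
        "meta": _jsonable(pyr.meta),
        "arrays": {},
    }

    def dump(name, arr):
        arr = np.ascontiguousarray(arr, dtype=np.float64)
        arr.tofile(directory / f"{name}.raw")
        manifest["arrays"][name] = {"shape": list(arr.shape), "dtype": "float64"}

    dump("approx", pyr.approx)
    for i, bands in enumerate(pyr.details):
        for key in DETAIL_KEYS:
            dump(f"level{i + 1}_{key}", bands[key])
    (directory / "manifest.json").write_text(json.dumps(manifest, indent=1))


def load_pyramid(directory) -> CoefficientPyramid:
    directory = Path(directory)
    try:
        manifest = json.loads((directory / "manifest.json").read_text())
    except (OSError, json.JSONDecodeError) as exc:
        raise FormatError(f"cannot read pyramid manifest: {exc}") from exc

    def load(name):
        spec = manifest["arrays"][name]
        arr = np.fromfile(directory / f"{name}.raw", dtype=spec["dtype"])
        return arr.reshape(spec["shape"])

    details = [
        {key: load(f"level{i + 1}_{key}") for key in DETAIL_KEYS}
        for i in range(manifest["levels"])
    ]
    meta = manifest["meta"]
    if "levels" in meta:
        for info in meta["levels"]:
            info["in_shape"] = tuple(info["in_shape"])
            info["pad"] = tuple(info["pad"])
            info["m0"] = tuple(info["m0"])
    return CoefficientPyramid(
        mode=manifest["mode"],
        levels=manifest["levels"],
        bank_id=manifest["bank_id"],
        boundary_mode=manifest["boundary_mode"],
        original_shape=tuple(manifest["original_shape"]),
        approx=load("approx"),
        details=details,
        meta=meta,
    )


def _jsonable(obj):
    if isinstance(obj, dict):
        return {k: _jsonable(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_jsonable(v) for v in obj]
    if isinstance(obj, np.integer):
        return int(obj)
    if isinstance(obj, np.floating):
        return float(obj)
    return obj
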