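"""Undecimated-transform shrinkage denoising and image-quality metrics.

The image is decomposed with the stationary (a trous) transform, every detail
subband is passed through a pointwise shrinkage operator, the approximation
band is left untouched, and the inverse transform is applied.  Because the
transform is shift-invariant, so is the whole denoiser — the reason this
transform is preferred over the decimated one for noise removal.

Four shrinkage operators are provided (``T`` is the threshold):

hard
    ``x * 1{|x| > T}``
soft
    ``sign(x) * max(|x| - T, 0)``
semisoft (firm)
    zero up to ``T``, identity beyond ``T2``, linear ramp in between
    (``T2 = 2T`` by default)
stein
    the nonnegative-garrote form ``x * max(1 - T^2/x^2, 0)``, the common
    reading of "Stein thresholding" in the shrinkage literature

None of them ever increases a coefficient's magnitude, and for ``|x| > T``
``|hard| >= |stein| >= |soft|`` pointwise.

When no threshold is given, the universal threshold ``sigma * sqrt(2 ln N)``
is used with ``sigma`` estimated per subband from the median absolute
coefficient (``per_level`` policy) or propagated from the level-1 estimate via
the equivalent-filter norms (``global`` policy).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .errors import ConfigurationError
from .filterbank import FilterBank
from .transforms import CoefficientPyramid, iswt2, swt2

__all__ = [
    "ShrinkageRule",
    "denoise_image",
    "estimate_sigma",
    "mse",
    "psnr",
    "shrink",
]

#: |median| of a standard normal; divides a median absolute value into a sigma.
MAD_TO_SIGMA = 0.6745

SHRINK_MODES = ("hard", "soft", "semisoft", "stein")


@dataclass
class ShrinkageRule:
    """Shrinkage operator specification.

    ``threshold=None`` selects the universal threshold per subband at apply
    time; ``upper_threshold`` (semisoft only) defaults to twice the threshold.
    """

    mode: str = "soft"
    threshold: float | None = None
    upper_threshold: float | None = None
    threshold_policy: str = "per_level"
    sigma_estimate: float = 0.0

    def __post_init__(self):
        if self.mode not in SHRINK_MODES:
            raise ConfigurationError(f"unknown shrinkage mode {self.mode!r}")
        if self.threshold_policy not in ("global", "per_level"):
            raise ConfigurationError(f"unknown threshold policy {self.threshold_policy!r}")
        if self.threshold is not None and self.threshold <= 0:
            raise ConfigurationError("threshold must be positive")
        if self.upper_threshold is not None:
            t = self.threshold if self.threshold is not None else 0.0
            if self.upper_threshold <= t:
                raise ConfigurationError("semisoft needs upper_threshold > threshold")


def shrink(x, rule: ShrinkageRule, threshold: float | None = None):
    """Apply the rule's shrinkage operator elementwise.

    ``threshold`` overrides ``rule.threshold`` (used internally when the
    threshold is chosen per subband).
    """
    t = threshold if threshold is not None else rule.threshold
    if t is None:
        raise ConfigurationError("no threshold available; set rule.threshold")
    t = float(t)
    if t < 0:
        raise ConfigurationError("threshold must be non-negative")
    scalar = np.isscalar(x) or np.ndim(x) == 0
    xa = np.asarray(x, dtype=float)
    ax = np.abs(xa)
    if rule.mode == "hard":
        out = np.where(ax > t, xa, 0.0)
    elif rule.mode == "soft":
        out = np.sign(xa) * np.maximum(ax - t, 0.0)
    elif rule.mode == "semisoft":
        t2 = rule.upper_threshold if rule.upper_threshold is not None else 2.0 * t
        if t2 <= t:
            raise ConfigurationError("semisoft needs upper_threshold > threshold")
        ramp = np.sign(xa) * t2 * (ax - t) / (t2 - t)
        out = np.where(ax <= t, 0.0, np.where(ax > t2, xa, ramp))
    else:  # stein / nonnegative garrote
        with np.errstate(divide="ignore", invalid="ignore"):
            gain = np.where(ax > t, 1.0 - (t * t) / np.where(ax > 0, xa * xa, 1.0), 0.0)
        out = xa * gain
    return float(out) if scalar else out


def estimate_sigma(pyr: CoefficientPyramid) -> float:
    """Robust noise scale: ``median(|level-1 diagonal coefficients|) / 0.6745``."""
    if not pyr.details:
        raise ConfigurationError("pyramid has no detail subbands")
    d1 = pyr.detail(1, "D")
    return float(np.median(np.abs(d1)) / MAD_TO_SIGMA)


def _equivalent_filter_norms(fb: FilterBank, levels: int) -> list[dict[str, float]]:
    """L2 norms of the per-subband equivalent a-trous analysis filters.

    White noise of unit variance produces detail coefficients of standard
    deviation equal to these norms; used by the ``global`` threshold policy.
    """
    def up(taps, s):
        if s == 1:
            return taps
        out = np.zeros((len(taps) - 1) * s + 1)
        out[::s] = taps
        return out

    norms = []
    low_chain = np.array([1.0])
    for lev in range(1, levels + 1):
        s = 2 ** (lev - 1)
        lo = np.convolve(low_chain, up(fb.ht.taps, s))
        hi = np.convolve(low_chain, up(fb.gt.taps, s))
        nl, nh = np.linalg.norm(lo), np.linalg.norm(hi)
        norms.append({"H": nl * nh, "V": nh * nl, "D": nh * nh})
        low_chain = lo
    return norms


def denoise_image(
    image,
    fb: FilterBank,
    levels: int,
    rule: ShrinkageRule,
    boundary: str = "symmetric",
) -> np.ndarray:
    """Stationary-wavelet shrinkage denoising of a 2D image.

    The output is not clipped; clip to the representable range at export time.
    """
    image = np.asarray(image, dtype=float)
    pyr = swt2(image, fb, levels, boundary)
    n_pixels = image.size
    universal = np.sqrt(2.0 * np.log(n_pixels))

    if rule.threshold is not None:
        thresholds = {(lev, key): rule.threshold
                      for lev in range(1, levels + 1) for key in ("H", "V", "D")}
    elif rule.threshold_policy == "per_level":
        thresholds = {}
        for lev in range(1, levels + 1):
            for key in ("H", "V", "D"):
                band = pyr.detail(lev, key)
                sigma = np.median(np.abs(band)) / MAD_TO_SIGMA
                thresholds[(lev, key)] = sigma * universal
    else:  # global policy: scale the level-1 estimate by equivalent-filter norms
        sigma1 = estimate_sigma(pyr)
        norms = _equivalent_filter_norms(fb, levels)
        base = norms[0]["D"]
        thresholds = {
            (lev, key): sigma1 * norms[lev - 1][key] / base * universal
            for lev in range(1, levels + 1)
            for key in ("H", "V", "D")
        }

    def apply(arr, lev, key):
        t = thresholds[(lev, key)]
        if t <= 0:
            return arr
        return shrink(arr, rule, threshold=t)

    pyr.map_details(apply)
    return iswt2(pyr, fb)


def mse(ref, test) -> float:
    """Mean squared difference."""
    ref = np.asarray(ref, dtype=float)
    test = np.asarray(test, dtype=float)
    if ref.shape != test.shape:
        raise ConfigurationError(f"shape mismatch: {ref.shape} vs {test.shape}")
    return float(np.mean((ref - test) ** 2))


def psnr(ref, test, max_value: float = 255.0) -> float:
    """Peak signal-to-noise ratio in dB; ``+inf`` for identical images."""
    err = mse(ref, test)
    if err == 0.0:
        return float("inf")
    return float(10.0 * np.log10(max_value * max_value / err))
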