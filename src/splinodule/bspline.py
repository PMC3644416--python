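"""Causal B-splines and their two-scale machinery.

The causal B-spline of degree ``n`` is the (n+1)-fold convolution of the
indicator of the unit interval.  It is supported on ``[0, n+1)``, non-negative,
integrates to one, and its integer shifts form a partition of unity and a Riesz
basis of the spline space of degree ``n``.  The associated two-scale filter is
the binomial filter ``h^n(k) = sqrt(2) * C(n+1, k) / 2^(n+1)``.

Evaluation uses the exact piecewise-polynomial (truncated-power) formula

    phi_n(x) = 1/n! * sum_{k=0}^{n+1} (-1)^k C(n+1, k) (x - k)_+^n

rather than grid interpolation, so identities such as the two-scale relation
can be verified to near machine precision.
"""

from __future__ import annotations

from dataclasses import dataclass
from math import comb, factorial

import numpy as np

from .errors import ConfigurationError

__all__ = [
    "BSplineBasis",
    "BSplineExpansion",
    "BinomialFilter",
    "RieszBounds",
    "binomial_filter",
    "bspline_eval",
    "riesz_bounds",
    "verify_two_scale",
]


def bspline_eval(degree: int, x) -> np.ndarray:
    """Evaluate the causal B-spline of the given degree at ``x``.

    Parameters
    ----------
    degree
        Spline degree ``n >= 0``.  Degree 0 is the indicator of ``[0, 1)``.
    x
        Scalar or array of evaluation points.

    Returns
    -------
    numpy.ndarray or float
        ``phi_n(x)``, exactly zero outside ``[0, n+1)``.
    """
    if degree < 0:
        raise ConfigurationError(f"B-spline degree must be >= 0, got {degree}")
    n = int(degree)
    xa = np.asarray(x, dtype=float)
    out = np.zeros_like(xa)
    for k in range(n + 2):
        t = xa - k
        if n == 0:
            tp = (t >= 0).astype(float)
        else:
            tp = np.where(t > 0.0, t, 0.0) ** n
        out += ((-1) ** k) * comb(n + 1, k) * tp
    out /= factorial(n)
    # The truncated-power sum telescopes to ~1e-13 residue beyond the support;
    # clamp so the compact-support contract is exact.
    out = np.where((xa < 0) | (xa >= n + 1), 0.0, out)
    if np.isscalar(x) or np.ndim(x) == 0:
        return float(out)
    return out


@dataclass(frozen=True)
class BinomialFilter:
    """Two-scale filter of the degree-``n`` B-spline: ``sqrt(2)((1+z^-1)/2)^(n+1)``."""

    degree: int
    taps: np.ndarray  # h^n(k), k = 0..n+1

    def __post_init__(self):
        object.__setattr__(self, "taps", np.asarray(self.taps, dtype=float))

    @property
    def transfer_gain_at_dc(self) -> float:
        return float(self.taps.sum())


def binomial_filter(degree: int) -> BinomialFilter:
    """Binomial two-scale filter ``h^n(k) = sqrt(2) * C(n+1, k) / 2^(n+1)``."""
    if degree < 0:
        raise ConfigurationError(f"filter degree must be >= 0, got {degree}")
    n = int(degree)
    taps = np.array([comb(n + 1, k) for k in range(n + 2)], dtype=float)
    taps *= np.sqrt(2.0) / 2.0 ** (n + 1)
    return BinomialFilter(degree=n, taps=taps)


def verify_two_scale(degree: int, grid) -> float:
    """Max residual of ``phi_n(x/2) - sqrt(2) * sum_k h^n(k) phi_n(x-k)`` over ``grid``."""
    x = np.asarray(grid, dtype=float)
    lhs = bspline_eval(degree, x / 2.0)
    h = binomial_filter(degree).taps
    rhs = np.zeros_like(x)
    for k, hk in enumerate(h):
        rhs += hk * bspline_eval(degree, x - k)
    rhs *= np.sqrt(2.0)
    return float(np.max(np.abs(lhs - rhs)))


@dataclass(frozen=True)
class RieszBounds:
    """Riesz-basis bounds ``0 < A_n <= B_n < inf`` of the shifted B-splines."""

    lower: float
    upper: float
    frequency_grid_size: int


def _autocorrelation_taps(degree: int) -> np.ndarray:
    """Sampled autocorrelation a(k) = <phi_n(.), phi_n(.-k)> = phi_{2n+1}(n+1+k), k=-n..n."""
    n = int(degree)
    k = np.arange(-n, n + 1)
    return bspline_eval(2 * n + 1, (n + 1) + k.astype(float))


def riesz_bounds(degree: int, frequency_grid_size: int = 1024) -> RieszBounds:
    """Riesz bounds of ``{phi_n(x - k)}`` via the frequency autocorrelation.

    The periodized autocorrelation ``A(w) = sum_k |phihat_n(w + 2 pi k)|^2``
    equals, by Poisson summation, the finite cosine polynomial with
    coefficients ``phi_{2n+1}(n+1+k)``; the bounds are its extrema over
    ``w in [0, pi]``, evaluated on a dense grid.  The sum over ``2 pi k``
    is therefore exact (no truncation tail).
    """
    if degree < 0:
        raise ConfigurationError(f"degree must be >= 0, got {degree}")
    if frequency_grid_size < 256:
        raise ConfigurationError("frequency_grid_size must be >= 256")
    a = _autocorrelation_taps(degree)
    n = int(degree)
    w = np.linspace(0.0, np.pi, int(frequency_grid_size))
    spectrum = np.zeros_like(w)
    for k, ak in zip(range(-n, n + 1), a):
        spectrum += ak * np.cos(k * w)
    return RieszBounds(
        lower=float(spectrum.min()),
        upper=float(spectrum.max()),
        frequency_grid_size=int(frequency_grid_size),
    )


class BSplineBasis:
    """Causal B-spline basis of a fixed degree.

    Bundles exact evaluation, the binomial two-scale filter, and Riesz-bound
    diagnostics for one degree.
    """

    def __init__(self, degree: int, evaluation_grid_step: float = 1e-3):
        if degree < 0:
            raise ConfigurationError(f"degree must be >= 0, got {degree}")
        if evaluation_grid_step <= 0:
            raise ConfigurationError("evaluation_grid_step must be positive")
        self.degree = int(degree)
        self.evaluation_grid_step = float(evaluation_grid_step)

    @property
    def support(self) -> tuple[float, float]:
        """Half-open support ``[0, n+1)``."""
        return (0.0, float(self.degree + 1))

    def __call__(self, x):
        return bspline_eval(self.degree, x)

    def binomial_filter(self) -> BinomialFilter:
        return binomial_filter(self.degree)

    def riesz_bounds(self, frequency_grid_size: int = 1024) -> RieszBounds:
        return riesz_bounds(self.degree, frequency_grid_size)

    def two_scale_residual(self, grid=None) -> float:
        if grid is None:
            grid = np.arange(0.0, 2.0 * (self.degree + 1), self.evaluation_grid_step)
        return verify_two_scale(self.degree, grid)


@dataclass
class BSplineExpansion:
    """Spline ``s(x) = sum_k c(k) phi_n(x - k)`` given by its B-spline coefficients."""

    coefficients: np.ndarray
    degree: int
    first_index: int = 0

    def __post_init__(self):
        self.coefficients = np.asarray(self.coefficients, dtype=float)
        if self.coefficients.size == 0:
            raise ConfigurationError("expansion needs at least one coefficient")

    def __call__(self, x):
        xa = np.asarray(x, dtype=float)
        out = np.zeros_like(xa)
        for i, c in enumerate(self.coefficients):
            out += c * bspline_eval(self.degree, xa - (self.first_index + i))
        if np.isscalar(x) or np.ndim(x) == 0:
            return float(out)
        return out
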