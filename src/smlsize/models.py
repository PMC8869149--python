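"""Structural projection densities and their Gaussian convolutions.

The size-estimation model describes a line profile through a labeled
structure as the convolution ``D(x) = (S * G)(x)`` of a normalized 1D
structural projection density ``S`` with a Gaussian localization kernel
``G`` of width ``sigma``.  Four shape families are provided:

``sphere_surface``
    Uniform labeling of a spherical shell (or a cylinder surface seen in
    cross-section along its axis-parallel projection): the 1D projection is
    uniform on ``[-R, R]`` (hat-box property).
``sphere_volume``
    Uniform labeling of the solid ball: projection ``3(R^2 - x^2)/(4R^3)``.
``disc_solid``
    Uniform labeling of a filled in-plane disc: ``2 sqrt(R^2-x^2)/(pi R^2)``.
``disc_ring``
    Uniform labeling of a circle's circumference: ``1/(pi sqrt(R^2-x^2))``,
    integrable but divergent at ``|x| = R``.

All lengths are nanometres.  Closed forms are used where available;
otherwise the convolution is evaluated by deterministic Gauss-Legendre
quadrature after the sine substitution ``u = R sin(theta)``, which removes
the ring's endpoint singularity.  A slow adaptive-quadrature oracle is
provided for verification and is kept independent of the fast paths.
"""

from __future__ import annotations

from dataclasses import dataclass
from enum import Enum

import numpy as np
from scipy import integrate
from scipy.special import ndtr

from .errors import InvalidParameterError

__all__ = [
    "Shape",
    "GaussianKernel",
    "StructuralModel",
    "ModelProfile",
    "eval_structure",
    "eval_convolved",
    "quadrature_oracle",
]

_SQRT2PI = np.sqrt(2.0 * np.pi)


class Shape(str, Enum):
    """Supported structural shape families."""

    SPHERE_SURFACE = "sphere_surface"
    SPHERE_VOLUME = "sphere_volume"
    DISC_SOLID = "disc_solid"
    DISC_RING = "disc_ring"


def _coerce_shape(shape: "Shape | str") -> Shape:
    try:
        return Shape(shape)
    except ValueError:
        raise InvalidParameterError(
            f"unknown shape {shape!r}; expected one of "
            f"{[s.value for s in Shape]}"
        ) from None


@dataclass(frozen=True)
class GaussianKernel:
    """Isotropic Gaussian localization kernel of standard deviation ``sigma`` (nm)."""

    sigma: float

    def __post_init__(self) -> None:
        if not np.isfinite(self.sigma) or self.sigma <= 0:
            raise InvalidParameterError(
                f"kernel sigma must be finite and > 0, got {self.sigma}"
            )

    def pdf(self, x: np.ndarray) -> np.ndarray:
        """Normal density with mean 0 and standard deviation ``sigma``."""
        x = np.asarray(x, dtype=float)
        return np.exp(-0.5 * (x / self.sigma) ** 2) / (self.sigma * _SQRT2PI)


@dataclass(frozen=True)
class StructuralModel:
    """A shape family plus its radius parameter (nm)."""

    shape: Shape
    radius: float

    def __post_init__(self) -> None:
        object.__setattr__(self, "shape", _coerce_shape(self.shape))
        if not np.isfinite(self.radius) or self.radius <= 0:
            raise InvalidParameterError(
                f"radius must be finite and > 0, got {self.radius}"
            )

    @property
    def diameter(self) -> float:
        return 2.0 * self.radius


def eval_structure(model: StructuralModel, x) -> np.ndarray:
    """Evaluate the normalized projection density ``S(x)`` (per nm).

    Returns exactly 0 outside ``[-R, R]``.  For ``disc_ring`` the density
    diverges at ``|x| = R``; by convention ``+inf`` is returned there and
    callers must use the convolved form for fitting.
    """
    x = np.asarray(x, dtype=float)
    if not np.all(np.isfinite(x)):
        raise InvalidParameterError("x must be finite")
    R = model.radius
    out = np.zeros_like(x)
    inside = np.abs(x) <= R

    if model.shape is Shape.SPHERE_SURFACE:
        out[inside] = 1.0 / (2.0 * R)
    elif model.shape is Shape.SPHERE_VOLUME:
        out[inside] = 3.0 * (R**2 - x[inside] ** 2) / (4.0 * R**3)
    elif model.shape is Shape.DISC_SOLID:
        out[inside] = 2.0 * np.sqrt(R**2 - x[inside] ** 2) / (np.pi * R**2)
    elif model.shape is Shape.DISC_RING:
        at_edge = np.abs(x) == R
        interior = inside & ~at_edge
        out[interior] = 1.0 / (np.pi * np.sqrt(R**2 - x[interior] ** 2))
        out[at_edge] = np.inf
    return out


def _convolved_sphere_surface(R: float, sigma: float, x: np.ndarray) -> np.ndarray:
    # (1/2R) * [Phi((x+R)/s) - Phi((x-R)/s)]
    return (ndtr((x + R) / sigma) - ndtr((x - R) / sigma)) / (2.0 * R)


def _convolved_sphere_volume(R: float, sigma: float, x: np.ndarray) -> np.ndarray:
    # Closed form from integrating (R^2 - u^2) against the Gaussian over [-R, R]
    # via the substitution v = (u - x)/sigma.
    a = (-R - x) / sigma
    b = (R - x) / sigma
    phi_a = np.exp(-0.5 * a**2) / _SQRT2PI
    phi_b = np.exp(-0.5 * b**2) / _SQRT2PI
    cdf = ndtr(b) - ndtr(a)
    integral = (
        (R**2 - x**2 - sigma**2) * cdf
        - 2.0 * x * sigma * (phi_a - phi_b)
        - sigma**2 * (a * phi_a - b * phi_b)
    )
    return 3.0 * integral / (4.0 * R**3)


def _convolved_disc_gl(
    model: StructuralModel, kernel: GaussianKernel, x: np.ndarray
) -> np.ndarray:
    """Gauss-Legendre evaluation on theta in [-pi/2, pi/2] after u = R sin(theta).

    disc_ring:  D(x) = (1/pi)   int cos^0 * g(x - R sin t) dt
    disc_solid: D(x) = (2/pi)   int cos^2 * g(x - R sin t) dt
    Node count doubles until two successive estimates agree to 1e-11.
    """
    R = model.radius
    ring = model.shape is Shape.DISC_RING
    prev = None
    n = 128
    while True:
        nodes, weights = np.polynomial.legendre.leggauss(n)
        theta = nodes * (np.pi / 2.0)
        w = weights * (np.pi / 2.0)
        g = kernel.pdf(x[:, None] - R * np.sin(theta)[None, :])
        if ring:
            vals = g @ w / np.pi
        else:
            vals = (g * np.cos(theta)[None, :] ** 2) @ (w * 2.0 / np.pi)
        if prev is not None and np.max(np.abs(vals - prev)) < 1e-11:
            return vals
        if n >= 8192:
            return vals
        prev = vals
        n *= 2


def eval_convolved(model: StructuralModel, kernel: GaussianKernel, x) -> np.ndarray:
    """Evaluate ``D(x) = (S * G)(x)`` (per nm) at each ``x``."""
    x = np.asarray(x, dtype=float)
    scalar = x.ndim == 0
    x = np.atleast_1d(x)
    R, sigma = model.radius, kernel.sigma
    if model.shape is Shape.SPHERE_SURFACE:
        out = _convolved_sphere_surface(R, sigma, x)
    elif model.shape is Shape.SPHERE_VOLUME:
        out = _convolved_sphere_volume(R, sigma, x)
    else:
        out = _convolved_disc_gl(model, kernel, x)
    return out[0] if scalar else out


def quadrature_oracle(model: StructuralModel, kernel: GaussianKernel, x_grid) -> np.ndarray:
    """Brute-force adaptive quadrature of ``int S(u) G(x-u) du`` per grid point.

    Reference implementation only: slow, but independent of the closed forms
    and of the Gauss-Legendre path.  For ``disc_ring`` the endpoint
    singularity is removed by the substitution ``u = R sin(theta)``.
    """
    x_grid = np.asarray(x_grid, dtype=float)
    if not np.all(np.isfinite(x_grid)):
        raise InvalidParameterError("x_grid must be finite")
    R = model.radius
    out = np.empty(x_grid.shape, dtype=float)

    if model.shape is Shape.DISC_RING:
        def integrand(theta, x0):
            return kernel.pdf(x0 - R * np.sin(theta)) / np.pi

        lo, hi = -np.pi / 2.0, np.pi / 2.0
    else:
        def integrand(u, x0):
            return eval_structure(model, np.array(u)) * kernel.pdf(x0 - u)

        lo, hi = -R, R

    for i, x0 in np.ndenumerate(x_grid):
        val, _ = integrate.quad(
            integrand, lo, hi, args=(x0,), epsabs=1e-12, epsrel=1e-12, limit=400
        )
        out[i] = val
    return out


@dataclass(frozen=True)
class ModelProfile:
    """A fully parameterized predicted line profile.

    Predicted counts in a bin of width ``w`` centered at ``x`` are
    ``w * amplitude * D(x - center) + background``, so ``amplitude`` is the
    total expected localization count and ``background`` is counts per bin.
    """

    model: StructuralModel
    kernel: GaussianKernel
    amplitude: float
    background: float = 0.0
    center: float = 0.0

    def __post_init__(self) -> None:
        if not np.isfinite(self.amplitude) or self.amplitude <= 0:
            raise InvalidParameterError(
                f"amplitude must be finite and > 0, got {self.amplitude}"
            )
        if not np.isfinite(self.background) or self.background < 0:
            raise InvalidParameterError(
                f"background must be finite and >= 0, got {self.background}"
            )
        if not np.isfinite(self.center):
            raise InvalidParameterError("center must be finite")

    def predict(self, x, bin_width: float) -> np.ndarray:
        """Expected counts per bin at bin centers ``x``."""
        d = eval_convolved(self.model, self.kernel, np.asarray(x, float) - self.center)
        return bin_width * self.amplitude * d + self.background
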