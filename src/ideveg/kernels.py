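"""Dispersal kernel families for plants and water.

A dispersal kernel is a probability density on the line describing the
displacement of seeds (or redistributed water) from a parent location over
one dispersal event.  Four parametric families are supported:

* ``laplace``            -- phi(x) = (a/2) exp(-a|x|)
* ``asymmetric_laplace`` -- N exp(-a2 x) for x >= 0, N exp((a2-a1) x) for
  x < 0, with normaliser N = (a2-a1) a2 / (2 a2 - a1).  The parameter a1
  controls the asymmetry; a1 = 0 recovers the symmetric Laplace kernel with
  rate a2.  Asymmetric water dispersal models downhill flow (mean <= 0).
* ``gaussian``           -- phi(x) = (a_g/sqrt(pi)) exp(-a_g^2 x^2)
* ``power_law``          -- phi(x) = (b-1) a_p / (2 (1+a_p|x|)^b), an
  algebraically decaying ("fat-tailed") kernel; finite variance needs b > 3.
* ``delta``              -- the no-dispersal limit (a point mass at 0).

All kernels integrate to one.  Kernels are compared across families at equal
standard deviation: sigma = sqrt(2)/a (Laplace), 1/(sqrt(2) a_g) (Gaussian)
and sqrt(2)/(a_p sqrt(b^2-5b+6)) (power law).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Optional, TYPE_CHECKING

import numpy as np
from scipy import integrate, special

if TYPE_CHECKING:  # pragma: no cover
    from .simulator import Grid

__all__ = [
    "KernelSpec",
    "KernelParameterError",
    "InfiniteVarianceError",
    "kernel_pdf",
    "kernel_fourier",
    "kernel_std",
    "kernel_mean",
    "kernel_second_raw_moment",
    "width_from_std",
    "discretize_kernel",
    "tail_mass",
]

FAMILIES = ("laplace", "asymmetric_laplace", "gaussian", "power_law", "delta")


class KernelParameterError(ValueError):
    """Raised for invalid kernel parameters."""


class InfiniteVarianceError(ValueError):
    """Raised when a standard deviation is requested but does not exist."""


@dataclass(frozen=True)
class KernelSpec:
    """A dispersal kernel family together with its width/shape parameters.

    Exactly the parameters relevant to ``family`` must be supplied:
    ``a`` (laplace), ``a1``/``a2`` (asymmetric_laplace), ``a_g`` (gaussian),
    ``a_p``/``b`` (power_law); ``delta`` takes none.  Rates have units of
    1/length, ``b`` is dimensionless.
    """

    family: str
    a: Optional[float] = None
    a1: Optional[float] = None
    a2: Optional[float] = None
    a_g: Optional[float] = None
    a_p: Optional[float] = None
    b: Optional[float] = None

    def __post_init__(self) -> None:
        if self.family not in FAMILIES:
            raise KernelParameterError(f"unknown kernel family {self.family!r}")
        if self.family == "laplace":
            if self.a is None or self.a <= 0:
                raise KernelParameterError("laplace kernel requires rate a > 0")
        elif self.family == "asymmetric_laplace":
            if self.a1 is None or self.a2 is None:
                raise KernelParameterError("asymmetric_laplace requires a1 and a2")
            if not (self.a2 > self.a1 >= 0):
                raise KernelParameterError(
                    "asymmetric_laplace requires a2 > a1 >= 0"
                )
        elif self.family == "gaussian":
            if self.a_g is None or self.a_g <= 0:
                raise KernelParameterError("gaussian kernel requires rate a_g > 0")
        elif self.family == "power_law":
            if self.a_p is None or self.a_p <= 0:
                raise KernelParameterError("power_law kernel requires rate a_p > 0")
            if self.b is None or self.b <= 1:
                raise KernelParameterError(
                    "power_law kernel requires exponent b > 1 for integrability"
                )

    # Convenience delegates -------------------------------------------------
    def pdf(self, x):
        return kernel_pdf(self, x)

    def fourier(self, k):
        return kernel_fourier(self, k)

    def std(self) -> float:
        return kernel_std(self)

    def mean(self) -> float:
        return kernel_mean(self)

    @property
    def symmetric(self) -> bool:
        if self.family == "asymmetric_laplace":
            return self.a1 == 0.0
        return True

    def to_dict(self) -> dict:
        """Flat key-value representation (for configs and output headers)."""
        out = {"family": self.family}
        for key in ("a", "a1", "a2", "a_g", "a_p", "b"):
            val = getattr(self, key)
            if val is not None:
                out[key] = float(val)
        return out

    @classmethod
    def from_dict(cls, d: dict) -> "KernelSpec":
        return cls(**d)


def kernel_pdf(spec: KernelSpec, x):
    """Evaluate the kernel density phi(x) (vectorised over ``x``).

    The delta family has no density; requesting its pdf raises.
    """
    x = np.asarray(x, dtype=float)
    if spec.family == "laplace":
        return 0.5 * spec.a * np.exp(-spec.a * np.abs(x))
    if spec.family == "asymmetric_laplace":
        n = _asym_normaliser(spec.a1, spec.a2)
        # single exponent avoids overflow from evaluating the wrong branch
        expo = -spec.a2 * np.clip(x, 0.0, None) + (spec.a2 - spec.a1) * np.clip(
            x, None, 0.0
        )
        return n * np.exp(expo)
    if spec.family == "gaussian":
        return spec.a_g / np.sqrt(np.pi) * np.exp(-(spec.a_g**2) * x**2)
    if spec.family == "power_law":
        return (spec.b - 1) * spec.a_p / (2.0 * (1.0 + spec.a_p * np.abs(x)) ** spec.b)
    raise KernelParameterError("the delta kernel has no pointwise density")


def _asym_normaliser(a1: float, a2: float) -> float:
    return (a2 - a1) * a2 / (2.0 * a2 - a1)


def kernel_fourier(spec: KernelSpec, k):
    """Fourier transform phi_hat(k) = int phi(x) exp(-i k x) dx.

    Closed forms for laplace, gaussian, asymmetric_laplace and delta; the
    power-law transform is computed by quadrature (cosine weight, exploiting
    symmetry).  Symmetric families return real values, the asymmetric
    Laplace returns complex values.
    """
    k = np.asarray(k, dtype=float)
    if spec.family == "laplace":
        return spec.a**2 / (spec.a**2 + k**2)
    if spec.family == "gaussian":
        return np.exp(-(k**2) / (4.0 * spec.a_g**2))
    if spec.family == "delta":
        return np.ones_like(k)
    if spec.family == "asymmetric_laplace":
        n = _asym_normaliser(spec.a1, spec.a2)
        out = n * (1.0 / (spec.a2 + 1j * k) + 1.0 / (spec.a2 - spec.a1 - 1j * k))
        return out.real if spec.a1 == 0.0 else out
    if spec.family == "power_law":
        return _power_law_fourier(spec, k)
    raise AssertionError("unreachable")


def _power_law_fourier(spec: KernelSpec, k: np.ndarray):
    """phi_hat(k) = 2 int_0^inf phi(x) cos(kx) dx for the symmetric kernel."""
    scalar = k.ndim == 0
    kk = np.atleast_1d(k)
    out = np.empty_like(kk, dtype=float)
    half = lambda x: (spec.b - 1) * spec.a_p / (2.0 * (1.0 + spec.a_p * x) ** spec.b)
    for i, ki in enumerate(kk):
        ki = abs(float(ki))
        if ki == 0.0:
            out[i] = 1.0
            continue
        val, _ = integrate.quad(
            half, 0.0, np.inf, weight="cos", wvar=ki, limit=400, epsabs=1e-12,
            epsrel=1e-10,
        )
        out[i] = 2.0 * val
    return out[0] if scalar else out


def kernel_mean(spec: KernelSpec) -> float:
    """First moment of the kernel (non-zero only for asymmetric families)."""
    if spec.family == "asymmetric_laplace":
        n = _asym_normaliser(spec.a1, spec.a2)
        q = spec.a2 - spec.a1
        return n * (1.0 / spec.a2**2 - 1.0 / q**2)
    return 0.0


def kernel_second_raw_moment(spec: KernelSpec) -> float:
    """Second raw moment int phi(x) x^2 dx (equals the variance when mean 0)."""
    if spec.family == "laplace":
        return 2.0 / spec.a**2
    if spec.family == "gaussian":
        return 1.0 / (2.0 * spec.a_g**2)
    if spec.family == "delta":
        return 0.0
    if spec.family == "asymmetric_laplace":
        n = _asym_normaliser(spec.a1, spec.a2)
        q = spec.a2 - spec.a1
        return 2.0 * n * (1.0 / spec.a2**3 + 1.0 / q**3)
    if spec.family == "power_law":
        if spec.b <= 3:
            raise InfiniteVarianceError(
                f"power_law kernel with b = {spec.b} has infinite variance"
            )
        return 2.0 / (spec.a_p**2 * (spec.b - 2) * (spec.b - 3))
    raise AssertionError("unreachable")


def kernel_std(spec: KernelSpec) -> float:
    """Standard deviation of the kernel.

    Closed forms: sqrt(2)/a (Laplace), 1/(sqrt(2) a_g) (Gaussian),
    sqrt(2)/(a_p sqrt(b^2-5b+6)) (power law, requires b > 3).
    """
    if spec.family == "laplace":
        return np.sqrt(2.0) / spec.a
    if spec.family == "gaussian":
        return 1.0 / (np.sqrt(2.0) * spec.a_g)
    if spec.family == "power_law":
        if spec.b <= 3:
            raise InfiniteVarianceError(
                f"power_law kernel with b = {spec.b} has infinite variance"
            )
        return np.sqrt(2.0) / (np.sqrt(spec.b**2 - 5.0 * spec.b + 6.0) * spec.a_p)
    if spec.family == "delta":
        return 0.0
    if spec.family == "asymmetric_laplace":
        m1 = kernel_mean(spec)
        m2 = kernel_second_raw_moment(spec)
        return float(np.sqrt(m2 - m1**2))
    raise AssertionError("unreachable")


def width_from_std(
    family: str, sigma: float, b: Optional[float] = None
) -> KernelSpec:
    """Construct a kernel of the given family with standard deviation sigma.

    Inverts the closed-form standard deviations; sigma = 0 returns the delta
    kernel.  The power-law family additionally needs its exponent ``b > 3``.
    """
    if sigma < 0:
        raise KernelParameterError("sigma must be >= 0")
    if sigma == 0.0 or family == "delta":
        return KernelSpec("delta")
    if family == "laplace":
        return KernelSpec("laplace", a=np.sqrt(2.0) / sigma)
    if family == "gaussian":
        return KernelSpec("gaussian", a_g=1.0 / (np.sqrt(2.0) * sigma))
    if family == "power_law":
        if b is None or b <= 3:
            raise InfiniteVarianceError(
                "power_law needs exponent b > 3 to match a standard deviation"
            )
        a_p = np.sqrt(2.0) / (np.sqrt(b**2 - 5.0 * b + 6.0) * sigma)
        return KernelSpec("power_law", a_p=a_p, b=b)
    raise KernelParameterError(
        f"cannot build a {family!r} kernel from a standard deviation"
    )


def tail_mass(spec: KernelSpec, x_max: float) -> float:
    """Analytic probability mass outside [-x_max, x_max]."""
    if spec.family == "laplace":
        return float(np.exp(-spec.a * x_max))
    if spec.family == "gaussian":
        return float(special.erfc(spec.a_g * x_max))
    if spec.family == "power_law":
        return float((1.0 + spec.a_p * x_max) ** (1.0 - spec.b))
    if spec.family == "delta":
        return 0.0
    if spec.family == "asymmetric_laplace":
        n = _asym_normaliser(spec.a1, spec.a2)
        q = spec.a2 - spec.a1
        return float(
            n * (np.exp(-spec.a2 * x_max) / spec.a2 + np.exp(-q * x_max) / q)
        )
    raise AssertionError("unreachable")


def discretize_kernel(spec: KernelSpec, grid: "Grid") -> np.ndarray:
    """Sample the kernel at the mesh offsets for circular convolution.

    The returned vector uses the wrap-around ordering native to the discrete
    Fourier transform (zero offset first, then positive offsets, then the
    negative offsets wrapped to the end), so that
    ``ifft(fft(field) * fft(kvec))`` is the circular convolution on the grid.
    After truncation to the periodic domain the vector is renormalised so
    that ``dx * sum(kvec) == 1`` exactly; the spatially uniform steady
    states are then exact fixed points of the discrete map.

    A warning is emitted when the analytic tail mass outside the domain
    exceeds 1e-6 (heavy-tailed kernels on small domains).
    """
    m = grid.M
    dx = grid.dx
    if spec.family == "delta":
        vec = np.zeros(m)
        vec[0] = 1.0 / dx
        return vec
    tm = tail_mass(spec, grid.x_max)
    if tm > 1e-6:
        warnings.warn(
            f"kernel tail mass {tm:.2e} outside [-{grid.x_max}, {grid.x_max}] "
            "exceeds 1e-6; the truncated kernel may distort dispersal",
            RuntimeWarning,
            stacklevel=2,
        )
    # wrap-around offsets: 0, dx, 2 dx, ..., -2 dx, -dx
    idx = np.arange(m)
    idx[idx > m // 2] -= m
    offsets = idx * dx
    vec = kernel_pdf(spec, offsets)
    total = dx * vec.sum()
    if total <= 0:
        raise KernelParameterError("kernel mass vanished after discretisation")
    return vec / total
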