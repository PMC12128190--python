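"""Analytic potential-energy surfaces used as surrogates for molecular
energy landscapes.

Every potential exposes ``energy(x)`` (kcal·mol⁻¹) and an analytic
``gradient(x)``; both accept a single coordinate vector of length ``dim``
or a batch of shape ``(n, dim)``.  Gradients are exact, and the test suite
holds them to central finite differences of ``energy``.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Callable

import numpy as np

from .errors import InvalidParameterError

__all__ = [
    "Potential",
    "muller_brown",
    "double_well_1d",
    "harmonic_nd",
    "AlchemicalSystem",
    "HarmonicBias",
    "rescaled_1d",
]


class Potential:
    """A differentiable scalar potential on R^dim.

    Parameters
    ----------
    dim : int
        Dimensionality of the coordinate space.
    energy_fn, gradient_fn : callable
        Vectorised callables taking an ``(n, dim)`` array and returning
        ``(n,)`` energies / ``(n, dim)`` gradients.
    """

    def __init__(
        self,
        dim: int,
        energy_fn: Callable[[np.ndarray], np.ndarray],
        gradient_fn: Callable[[np.ndarray], np.ndarray],
        name: str = "potential",
    ):
        if dim < 1:
            raise InvalidParameterError(f"dim must be >= 1, got {dim}")
        self.dim = int(dim)
        self._energy = energy_fn
        self._gradient = gradient_fn
        self.name = name

    def _as_batch(self, x) -> tuple[np.ndarray, bool]:
        x = np.asarray(x, dtype=float)
        if x.ndim == 0 and self.dim == 1:
            return x.reshape(1, 1), True
        if x.ndim == 1:
            if x.shape[0] != self.dim:
                raise InvalidParameterError(
                    f"expected coordinate of length {self.dim}, got {x.shape[0]}"
                )
            return x.reshape(1, self.dim), True
        if x.ndim == 2 and x.shape[1] == self.dim:
            return x, False
        raise InvalidParameterError(
            f"expected shape (n, {self.dim}) or ({self.dim},), got {x.shape}"
        )

    def energy(self, x) -> float | np.ndarray:
        """Potential energy in kcal·mol⁻¹."""
        xb, single = self._as_batch(x)
        e = self._energy(xb)
        return float(e[0]) if single else e

    def gradient(self, x) -> np.ndarray:
        """Analytic gradient, kcal·mol⁻¹ per coordinate unit."""
        xb, single = self._as_batch(x)
        g = self._gradient(xb)
        return g[0] if single else g

    def __add__(self, other: "Potential") -> "Potential":
        if other.dim != self.dim:
            raise InvalidParameterError("cannot add potentials of different dim")
        return Potential(
            self.dim,
            lambda x: self._energy(x) + other._energy(x),
            lambda x: self._gradient(x) + other._gradient(x),
            name=f"{self.name}+{other.name}",
        )

    def __repr__(self) -> str:  # pragma: no cover
        return f"Potential({self.name}, dim={self.dim})"


# Canonical Müller–Brown parameters (four Gaussian wells/ridges).
_MB_A = np.array([-200.0, -100.0, -170.0, 15.0])
_MB_a = np.array([-1.0, -1.0, -6.5, 0.7])
_MB_b = np.array([0.0, 0.0, 11.0, 0.6])
_MB_c = np.array([-10.0, -10.0, -6.5, 0.7])
_MB_x0 = np.array([1.0, 0.0, -0.5, -1.0])
_MB_y0 = np.array([0.0, 0.5, 1.5, 1.0])


def muller_brown() -> Potential:
    """The Müller–Brown two-dimensional test surface.

    A sum of four anisotropic Gaussians with the canonical parameter set;
    the standard benchmark for minimum-energy-path methods.  Its two deepest
    minima lie near (−0.558, 1.442) and (0.623, 0.028).
    """

    def energy(x: np.ndarray) -> np.ndarray:
        dx = x[:, 0:1] - _MB_x0
        dy = x[:, 1:2] - _MB_y0
        terms = _MB_A * np.exp(_MB_a * dx**2 + _MB_b * dx * dy + _MB_c * dy**2)
        return terms.sum(axis=1)

    def gradient(x: np.ndarray) -> np.ndarray:
        dx = x[:, 0:1] - _MB_x0
        dy = x[:, 1:2] - _MB_y0
        terms = _MB_A * np.exp(_MB_a * dx**2 + _MB_b * dx * dy + _MB_c * dy**2)
        gx = (terms * (2.0 * _MB_a * dx + _MB_b * dy)).sum(axis=1)
        gy = (terms * (_MB_b * dx + 2.0 * _MB_c * dy)).sum(axis=1)
        return np.stack([gx, gy], axis=1)

    return Potential(2, energy, gradient, name="muller-brown")


def double_well_1d(h: float) -> Potential:
    """Symmetric one-dimensional double well V(x) = h·(x²−1)².

    Minima at x = ±1 with V = 0 and a barrier of height ``h`` (kcal·mol⁻¹)
    at x = 0.  Serves as the surrogate for a bistable conformational
    free-energy surface.
    """
    if h <= 0:
        raise InvalidParameterError(f"barrier height h must be > 0, got {h}")

    def energy(x: np.ndarray) -> np.ndarray:
        return h * (x[:, 0] ** 2 - 1.0) ** 2

    def gradient(x: np.ndarray) -> np.ndarray:
        return (4.0 * h * x[:, 0] * (x[:, 0] ** 2 - 1.0)).reshape(-1, 1)

    return Potential(1, energy, gradient, name=f"double-well(h={h})")


def harmonic_nd(k, center=None) -> Potential:
    """Separable harmonic well V(x) = Σᵢ ½·kᵢ·(xᵢ−cᵢ)².

    ``k`` are per-dimension spring constants in kcal·mol⁻¹·Å⁻²; the
    Boltzmann distribution at temperature kT is Gaussian with variance
    kT/kᵢ per dimension, which makes this the closed-form reference for
    sampler and TI tests.
    """
    k = np.atleast_1d(np.asarray(k, dtype=float))
    if np.any(k <= 0):
        raise InvalidParameterError(f"all spring constants must be > 0, got {k}")
    center = np.zeros_like(k) if center is None else np.broadcast_to(
        np.asarray(center, dtype=float), k.shape
    ).copy()

    def energy(x: np.ndarray) -> np.ndarray:
        return 0.5 * (k * (x - center) ** 2).sum(axis=1)

    def gradient(x: np.ndarray) -> np.ndarray:
        return k * (x - center)

    return Potential(len(k), energy, gradient, name="harmonic")


def rescaled_1d(p: Potential, lo: float, hi: float) -> Potential:
    """Affinely map a 1-D potential's natural domain [lo, hi] onto s ∈ [0, 1].

    Returns U(s) = V(lo + (hi−lo)·s); used to express bistable surrogates on
    the path-coordinate interval used by umbrella sampling.
    """
    if p.dim != 1:
        raise InvalidParameterError("rescaled_1d requires a 1-D potential")
    span = hi - lo
    if span <= 0:
        raise InvalidParameterError("require hi > lo")

    def energy(s: np.ndarray) -> np.ndarray:
        return p._energy(lo + span * s)

    def gradient(s: np.ndarray) -> np.ndarray:
        return span * p._gradient(lo + span * s)

    return Potential(1, energy, gradient, name=f"{p.name}|[{lo},{hi}]->s")


class HarmonicBias(Potential):
    """Harmonic restraint U(x) = ½·Σᵢ kᵢ·(xᵢ−x₀ᵢ)² usable as a sampler bias."""

    def __init__(self, center, k):
        center = np.atleast_1d(np.asarray(center, dtype=float))
        k = np.broadcast_to(np.asarray(k, dtype=float), center.shape).copy()
        if np.any(k <= 0):
            raise InvalidParameterError("bias force constants must be > 0")
        self.center = center
        self.k = k
        super().__init__(
            len(center),
            lambda x: 0.5 * (k * (x - center) ** 2).sum(axis=1),
            lambda x: k * (x - center),
            name="harmonic-bias",
        )


@dataclass
class AlchemicalSystem:
    """λ-coupled Hamiltonian H(λ) = (1−λ)·H0 + λ·H1.

    The coupling is linear, so ∂H/∂λ is simply H1(x) − H0(x) and is exact
    at every λ — the quantity averaged in thermodynamic integration.
    """

    H0: Potential
    H1: Potential

    def __post_init__(self):
        if self.H0.dim != self.H1.dim:
            raise InvalidParameterError("H0 and H1 must share a dimension")

    @property
    def dim(self) -> int:
        return self.H0.dim

    def hamiltonian(self, lam: float) -> Potential:
        """The mixed potential H(λ) as a Potential object."""
        if not 0.0 <= lam <= 1.0:
            raise InvalidParameterError(f"lambda must be in [0, 1], got {lam}")
        h0, h1 = self.H0, self.H1
        return Potential(
            self.dim,
            lambda x: (1.0 - lam) * h0._energy(x) + lam * h1._energy(x),
            lambda x: (1.0 - lam) * h0._gradient(x) + lam * h1._gradient(x),
            name=f"H(lambda={lam})",
        )

    def dhdl(self, x) -> float | np.ndarray:
        """∂H/∂λ = H1(x) − H0(x), kcal·mol⁻¹ (λ-independent for linear coupling)."""
        return self.H1.energy(x) - self.H0.energy(x)

    def swapped(self) -> "AlchemicalSystem":
        """The reverse transformation (H1 → H0); ΔF changes sign exactly."""
        return AlchemicalSystem(self.H1, self.H0)
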