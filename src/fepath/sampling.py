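"""Overdamped Langevin (Brownian) dynamics on analytic potentials.

The Euler–Maruyama update

    x ← x − dt·∇(V + bias)(x) + sqrt(2·kT·dt)·ξ,   ξ ~ N(0, I)

has the Boltzmann distribution exp(−(V+bias)/kT) as its stationary law in
the dt → 0 limit, which is all the free-energy machinery downstream needs:
restrained means for the string method, umbrella-window samples for WHAM,
and ⟨∂H/∂λ⟩ averages for thermodynamic integration.  At kT = 0 the update
is plain gradient descent.

Randomness comes from a counter-based Philox stream keyed on the user seed,
so identical inputs give bit-identical trajectories and per-replica streams
can be split deterministically.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .errors import IntegrationInstabilityError, InvalidParameterError
from .potentials import HarmonicBias, Potential

__all__ = ["Trajectory", "overdamped_langevin", "evolve_ensemble", "rng_stream"]

#: Coordinates beyond this magnitude abort the integration.
DEFAULT_INSTABILITY_BOUND = 1.0e6


def rng_stream(seed: int, replica: int = 0) -> np.random.Generator:
    """Counter-based RNG stream for a given seed, split per replica."""
    return np.random.Generator(np.random.Philox(key=seed).jumped(replica))


@dataclass
class Trajectory:
    """Stored frames of a sampler run.

    ``frames`` has shape (n_frames, dim); ``timestep`` is the number of
    sampler steps between stored frames; ``kt`` is the thermal energy in
    kcal·mol⁻¹ the run was performed at.
    """

    frames: np.ndarray
    timestep: int
    seed: int
    kt: float

    def __post_init__(self):
        self.frames = np.atleast_2d(np.asarray(self.frames, dtype=float))
        if self.frames.shape[0] < 1:
            raise InvalidParameterError("a trajectory needs at least one frame")

    @property
    def n_frames(self) -> int:
        return self.frames.shape[0]

    @property
    def dim(self) -> int:
        return self.frames.shape[1]


def evolve_ensemble(
    potential: Potential,
    x0: np.ndarray,
    dt: float,
    kt: float,
    nsteps: int,
    rng: np.random.Generator,
    bias_centers: np.ndarray | None = None,
    bias_k: float | np.ndarray | None = None,
    sample_every: int = 1,
    bound: float = DEFAULT_INSTABILITY_BOUND,
) -> np.ndarray:
    """Evolve a batch of independent walkers and return stored samples.

    Each walker ``i`` feels the potential plus, when ``bias_centers`` is
    given, its own harmonic restraint ½·k·|x − c_i|².  Returns an array of
    shape (n_samples, n_walkers, dim) with frames stored every
    ``sample_every`` steps (the initial positions are not stored).
    """
    if dt <= 0:
        raise InvalidParameterError(f"dt must be > 0, got {dt}")
    if kt < 0:
        raise InvalidParameterError(f"kT must be >= 0, got {kt}")
    x = np.atleast_2d(np.asarray(x0, dtype=float)).copy()
    n, dim = x.shape
    if dim != potential.dim:
        raise InvalidParameterError(
            f"walkers have dim {dim}, potential has dim {potential.dim}"
        )
    biased = bias_centers is not None
    if biased:
        bias_centers = np.asarray(bias_centers, dtype=float).reshape(n, dim)
        bias_k = np.broadcast_to(np.asarray(bias_k, dtype=float), (n, dim))

    noise_scale = np.sqrt(2.0 * kt * dt)
    n_samples = nsteps // sample_every
    out = np.empty((n_samples, n, dim))
    stored = 0
    for step in range(1, nsteps + 1):
        force = -potential.gradient(x)
        if biased:
            force = force - bias_k * (x - bias_centers)
        x = x + dt * force
        if kt > 0:
            x = x + noise_scale * rng.standard_normal((n, dim))
        if np.any(np.abs(x) > bound):
            bad = int(np.argwhere(np.abs(x) > bound)[0, 0])
            raise IntegrationInstabilityError(
                f"integration diverged at step {step} (walker {bad}: "
                f"|coordinate| > {bound:g}); reduce dt",
                step=step,
            )
        if step % sample_every == 0:
            out[stored] = x
            stored += 1
    return out[:stored]


def overdamped_langevin(
    potential: Potential,
    x0,
    dt: float,
    kt: float,
    nsteps: int,
    seed: int,
    bias: HarmonicBias | None = None,
    sample_every: int = 1,
    bound: float = DEFAULT_INSTABILITY_BOUND,
) -> Trajectory:
    """Run a single overdamped Langevin trajectory.

    Parameters
    ----------
    potential : Potential
        The energy surface V(x).
    x0 : array-like
        Initial coordinate vector.
    dt : float
        Integration step (coordinate-unit²·mol·kcal⁻¹ mobility absorbed).
    kt : float
        Thermal energy in kcal·mol⁻¹; 0 gives deterministic descent.
    nsteps : int
        Number of integration steps.
    seed : int
        RNG seed; identical seeds give bit-identical trajectories.
    bias : HarmonicBias, optional
        Harmonic restraint added to the potential.
    sample_every : int
        Store one frame per this many steps.

    Returns
    -------
    Trajectory
        Stored frames include the initial position as frame 0.
    """
    x0 = np.atleast_1d(np.asarray(x0, dtype=float))
    rng = rng_stream(seed)
    samples = evolve_ensemble(
        potential,
        x0.reshape(1, -1),
        dt,
        kt,
        nsteps,
        rng,
        bias_centers=None if bias is None else bias.center.reshape(1, -1),
        bias_k=None if bias is None else bias.k,
        sample_every=sample_every,
        bound=bound,
    )
    frames = np.concatenate([x0.reshape(1, -1), samples[:, 0, :]], axis=0)
    return Trajectory(frames=frames, timestep=sample_every, seed=seed, kt=kt)
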