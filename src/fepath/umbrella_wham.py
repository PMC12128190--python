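"""Umbrella sampling along a path coordinate and WHAM reconstruction.

Windows are harmonic biases ½·k·(s−s₀)² centred on a uniform grid of
s ∈ [0, 1].  Force constants are calibrated on-the-fly from short pilot
runs so every window's sample distribution has a homogeneous width: under
a harmonic bias the stationary s-spread scales as 1/√k, so the pilot
spread fixes the rescaling k → k·(σ_pilot/σ_target)² directly.

The biased window histograms are combined with the weighted histogram
analysis method (WHAM): the self-consistent equations

    p_j ∝ Σ_i n_ij / Σ_i N_i e^{f_i} e^{−b_ij/kT},
    e^{−f_i} = Σ_j e^{−b_ij/kT} p_j

are iterated until the window shift constants f_i are stationary, giving
the unbiased probability p(s) and the free-energy profile
A(s) = −kT·ln p(s), anchored at min A = 0.  Pointwise uncertainty bands
come from a block bootstrap over each window's trajectory.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np

from .errors import (
    ConvergenceError,
    InsufficientDataError,
    InvalidParameterError,
)
from .potentials import Potential
from .sampling import evolve_ensemble, rng_stream

__all__ = [
    "UmbrellaWindow",
    "FEProfile",
    "place_windows",
    "calibrate_force_constants",
    "sample_windows",
    "wham_solve",
    "bootstrap_profile",
    "boltzmann_reference_profile",
]

DEFAULT_N_BINS = 101
DEFAULT_TOL = 1e-8
DEFAULT_MAX_ITER = 100_000
DEFAULT_BOOT_BLOCK = 20  # consecutive samples per bootstrap block


@dataclass
class UmbrellaWindow:
    """One umbrella window: bias centre, force constant, and its samples."""

    center: float
    k: float
    samples: np.ndarray

    def __post_init__(self):
        if self.k <= 0:
            raise InvalidParameterError("window force constant must be > 0")
        self.samples = np.clip(np.asarray(self.samples, dtype=float).ravel(), 0.0, 1.0)

    def bias(self, s) -> np.ndarray:
        return 0.5 * self.k * (np.asarray(s, dtype=float) - self.center) ** 2


@dataclass
class FEProfile:
    """Free energy A(s) on a grid, anchored at min A = 0; NaN marks gaps."""

    s: np.ndarray
    free_energy: np.ndarray
    error: np.ndarray | None = None
    kt: float = 1.0

    def __post_init__(self):
        self.s = np.asarray(self.s, dtype=float)
        self.free_energy = np.asarray(self.free_energy, dtype=float)
        if np.any(np.diff(self.s) <= 0):
            raise InvalidParameterError("profile grid must be strictly increasing")
        if self.error is not None:
            self.error = np.asarray(self.error, dtype=float)
            if np.any(self.error[np.isfinite(self.error)] < 0):
                raise InvalidParameterError("uncertainty band must be >= 0")

    def barrier(self) -> float:
        """Highest finite free energy relative to the anchored minimum."""
        return float(np.nanmax(self.free_energy))


def place_windows(n_windows: int) -> np.ndarray:
    """Uniformly spaced window centres on [0, 1]."""
    if n_windows < 2:
        raise InvalidParameterError("need at least 2 umbrella windows")
    return np.linspace(0.0, 1.0, n_windows)


def calibrate_force_constants(
    pilot_samples,
    pilot_k,
    target_sd: float,
    k_min: float = 1e-2,
    k_max: float = 1e6,
) -> np.ndarray:
    """On-the-fly force constants from pilot-run spreads.

    Each window's constant is rescaled by (σ_pilot/σ_target)² — the exact
    correction for Gaussian window distributions — and clamped to
    [k_min, k_max].  A window already at the target spread keeps its
    constant; on a flat landscape the rule returns kT/σ_target² for a
    pilot run at constant kT/σ_pilot².
    """
    if target_sd <= 0:
        raise InvalidParameterError("target_sd must be > 0")
    pilot_k = np.broadcast_to(
        np.asarray(pilot_k, dtype=float), (len(pilot_samples),)
    )
    out = np.empty(len(pilot_samples))
    for i, samples in enumerate(pilot_samples):
        samples = np.asarray(samples, dtype=float).ravel()
        if len(samples) < 2:
            raise InsufficientDataError(
                f"window {i}: pilot run has {len(samples)} samples"
            )
        sd = samples.std(ddof=1)
        out[i] = np.clip(pilot_k[i] * (sd / target_sd) ** 2, k_min, k_max)
    return out


def sample_windows(
    potential: Potential,
    centers,
    k,
    kt: float,
    n_samples: int,
    seed: int,
    dt: float = 2e-4,
    sample_every: int = 5,
    burn_in: int = 2_000,
    replica: int = 0,
) -> list[UmbrellaWindow]:
    """Run all umbrella windows as a batch of biased Langevin walkers.

    Each window's walker starts at its centre, equilibrates for
    ``burn_in`` steps, then stores ``n_samples`` values of s every
    ``sample_every`` steps.
    """
    centers = np.asarray(centers, dtype=float)
    k = np.broadcast_to(np.asarray(k, dtype=float), centers.shape).copy()
    rng = rng_stream(seed, replica=replica)
    x = centers.reshape(-1, 1)
    if burn_in > 0:
        burn = evolve_ensemble(
            potential, x, dt, kt, burn_in, rng,
            bias_centers=centers.reshape(-1, 1), bias_k=k.reshape(-1, 1),
            sample_every=burn_in,
        )
        x = burn[-1]
    samples = evolve_ensemble(
        potential, x, dt, kt, n_samples * sample_every, rng,
        bias_centers=centers.reshape(-1, 1), bias_k=k.reshape(-1, 1),
        sample_every=sample_every,
    )
    return [
        UmbrellaWindow(center=float(centers[i]), k=float(k[i]),
                       samples=samples[:, i, 0])
        for i in range(len(centers))
    ]


def _window_arrays(windows, n_bins, kt):
    edges = np.linspace(0.0, 1.0, n_bins + 1)
    mids = 0.5 * (edges[:-1] + edges[1:])
    counts = np.stack(
        [np.histogram(w.samples, bins=edges)[0] for w in windows]
    ).astype(float)
    n_i = counts.sum(axis=1)
    bias = np.stack([w.bias(mids) for w in windows])  # (M, n_bins)
    log_c = -bias / kt
    return edges, mids, counts, n_i, log_c


def wham_solve(
    windows,
    kt: float,
    n_bins: int = DEFAULT_N_BINS,
    tol: float = DEFAULT_TOL,
    max_iter: int = DEFAULT_MAX_ITER,
) -> FEProfile:
    """Self-consistent WHAM solution for a set of umbrella windows.

    Direct iteration on the window log-shift constants until the largest
    change is below ``tol``; raises :class:`ConvergenceError` with the
    final residual if ``max_iter`` is exhausted.  Bins never visited by
    any window are reported as NaN gaps, not interpolated.  The profile is
    invariant under adding a constant to all biases and under duplicating
    samples.
    """
    windows = list(windows)
    if not windows or all(len(w.samples) == 0 for w in windows):
        raise InsufficientDataError("WHAM needs at least one window with samples")
    windows = [w for w in windows if len(w.samples) > 0]
    _, mids, counts, n_i, log_c = _window_arrays(windows, n_bins, kt)
    pooled = counts.sum(axis=0)
    occupied = pooled > 0
    if occupied.sum() < n_bins:
        gaps = n_bins - int(occupied.sum())
        warnings.warn(
            f"{gaps} of {n_bins} bins have no samples; reported as gaps",
            stacklevel=2,
        )
    # Disjoint-coverage diagnostic: sort windows by centre and check sample
    # ranges of neighbours touch.
    order = np.argsort([w.center for w in windows])
    for a, b in zip(order[:-1], order[1:]):
        if windows[a].samples.max() < windows[b].samples.min():
            warnings.warn(
                f"windows at s0={windows[a].center:.3f} and "
                f"s0={windows[b].center:.3f} do not overlap; "
                "profile may be disconnected",
                stacklevel=2,
            )

    log_f = np.zeros(len(windows))
    occ = np.flatnonzero(occupied)
    log_pool = np.log(pooled[occ])
    log_c_occ = log_c[:, occ]
    log_ni = np.log(n_i)
    from scipy.special import logsumexp

    for _ in range(max_iter):
        # log p_j (unnormalised) on occupied bins
        denom = logsumexp(log_ni[:, None] + log_f[:, None] + log_c_occ, axis=0)
        log_p = log_pool - denom
        new_log_f = -logsumexp(log_c_occ + log_p[None, :], axis=1)
        resid = float(np.max(np.abs(new_log_f - log_f)))
        log_f = new_log_f
        if resid < tol:
            break
    else:
        raise ConvergenceError(
            f"WHAM did not converge in {max_iter} iterations "
            f"(residual {resid:.3e} > tol {tol:.1e})",
            residual=resid,
        )
    free = np.full(n_bins, np.nan)
    free[occ] = -kt * log_p
    free -= np.nanmin(free)
    return FEProfile(s=mids, free_energy=free, kt=kt)


def bootstrap_profile(
    windows,
    kt: float,
    n_boot: int,
    seed: int,
    n_bins: int = DEFAULT_N_BINS,
    block: int = DEFAULT_BOOT_BLOCK,
    tol: float = DEFAULT_TOL,
    max_iter: int = DEFAULT_MAX_ITER,
    max_dropped_frac: float = 0.1,
) -> np.ndarray:
    """Pointwise bootstrap uncertainty band for a WHAM profile.

    Each replicate resamples every window's trajectory in blocks of
    ``block`` consecutive samples (respecting autocorrelation), re-solves
    WHAM, and re-anchors at its own minimum; the band is the pointwise
    standard deviation across replicates.  Replicates whose WHAM solve
    fails are dropped and counted; more than ``max_dropped_frac`` dropped
    replicates is an error.
    """
    if n_boot < 2:
        raise InvalidParameterError("n_boot must be >= 2")
    rng = rng_stream(seed)
    profiles = []
    dropped = 0
    for _ in range(n_boot):
        rep = []
        for w in windows:
            s = w.samples
            n = len(s)
            blocks = max(1, int(np.ceil(n / block)))
            starts = rng.integers(0, max(1, n - block + 1), size=blocks)
            resampled = np.concatenate([s[st : st + block] for st in starts])[:n]
            rep.append(UmbrellaWindow(w.center, w.k, resampled))
        try:
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                prof = wham_solve(rep, kt, n_bins=n_bins, tol=tol, max_iter=max_iter)
        except (ConvergenceError, InsufficientDataError):
            dropped += 1
            continue
        profiles.append(prof.free_energy)
    if dropped > max_dropped_frac * n_boot:
        raise ConvergenceError(
            f"{dropped}/{n_boot} bootstrap replicates failed to converge"
        )
    stack = np.stack(profiles)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)
        band = np.nanstd(stack, axis=0, ddof=1)
    return band


def boltzmann_reference_profile(
    potential: Potential,
    kt: float,
    n_bins: int = DEFAULT_N_BINS,
    oversample: int = 64,
) -> FEProfile:
    """Exact reference profile for a 1-D potential on the same binning.

    Integrates the Boltzmann weight exp(−U(s)/kT) over each bin with a
    fine trapezoidal sub-grid and returns A = −kT·ln p, anchored at 0.
    Independent of any sampling or reweighting, this is the oracle the
    WHAM profile is held to on analytic surrogates.
    """
    if potential.dim != 1:
        raise InvalidParameterError("reference profile requires a 1-D potential")
    edges = np.linspace(0.0, 1.0, n_bins + 1)
    mids = 0.5 * (edges[:-1] + edges[1:])
    log_mass = np.empty(n_bins)
    for j in range(n_bins):
        grid = np.linspace(edges[j], edges[j + 1], oversample)
        u = potential.energy(grid.reshape(-1, 1))
        u0 = u.min()
        log_mass[j] = -u0 / kt + np.log(
            np.trapezoid(np.exp(-(u - u0) / kt), grid)
        )
    free = -kt * log_mass
    free -= free.min()
    return FEProfile(s=mids, free_energy=free, kt=kt)
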