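"""Adaptive string method in collective-variable space.

A string is an ordered set of K nodes (CV vectors) connecting two
metastable states.  Each iteration, restrained sampling about every node
estimates the local mean CV; under a harmonic restraint that mean is
displaced from the node by ≈ −∇A/k, so moving each node a fraction of the
way toward its restrained mean drives the string down the free-energy
gradient.  Nodes are then redistributed to equal metric arc lengths so the
string converges to the minimum free energy path (MFEP) instead of
collapsing into the basins.  Convergence is monitored with the weighted
CV-space RMSD between successive strings (amu^1/2·Å).

Once converged, the frozen string defines a path collective variable
s ∈ [0, 1]: the normalised arc-length position of the orthogonal
projection of a CV vector onto the piecewise-linear path.  s is the
reaction coordinate used by the umbrella-sampling stage.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .collective_variables import DEG_TO_ANGSTROM, weighted_rmsd, wrap_degrees
from .errors import DegenerateStringError, InvalidParameterError
from .potentials import Potential
from .sampling import evolve_ensemble, rng_stream

__all__ = [
    "StringState",
    "PathCV",
    "init_string",
    "reparameterize",
    "string_iteration",
    "check_convergence",
    "run_string",
    "attempt_exchange",
    "path_s",
]

DEFAULT_K_RESTRAINT = 100.0  # kcal·mol⁻¹ per squared CV unit
DEFAULT_NODES = 24
DEFAULT_CONVERGENCE_THRESHOLD = 0.1  # amu^1/2·Å
DEFAULT_CONVERGENCE_WINDOW = 20  # iterations


def _circular_mask(kinds, dim) -> np.ndarray:
    if kinds is None:
        return np.zeros(dim, dtype=bool)
    if len(kinds) != dim:
        raise InvalidParameterError("kinds must have one entry per CV")
    return np.array([k == "dihedral" for k in kinds])


def _scale(weights, circ) -> np.ndarray:
    """Per-CV factor mapping CV differences to the metric length scale."""
    w = np.ones(len(circ)) if weights is None else np.asarray(weights, dtype=float)
    if np.any(w <= 0):
        raise InvalidParameterError("metric weights must be > 0")
    return np.sqrt(w) * np.where(circ, DEG_TO_ANGSTROM, 1.0)


def _seg_deltas(nodes, circ) -> np.ndarray:
    """Consecutive node differences, wrapped on circular CVs."""
    d = np.diff(nodes, axis=0)
    d[:, circ] = wrap_degrees(d[:, circ])
    return d


def _wrap_nodes(nodes, circ) -> np.ndarray:
    nodes = nodes.copy()
    nodes[:, circ] = wrap_degrees(nodes[:, circ])
    return nodes


@dataclass
class StringState:
    """Node positions plus iteration and convergence bookkeeping."""

    nodes: np.ndarray  # (K, n_cvs)
    kinds: list | None = None
    weights: np.ndarray | None = None
    iteration: int = 0
    rmsd_history: list = field(default_factory=list)
    converged: bool = False

    def __post_init__(self):
        self.nodes = np.atleast_2d(np.asarray(self.nodes, dtype=float))
        if self.nodes.shape[0] < 3:
            raise DegenerateStringError("a string needs at least 3 nodes")

    @property
    def n_nodes(self) -> int:
        return self.nodes.shape[0]

    @property
    def n_cvs(self) -> int:
        return self.nodes.shape[1]


def init_string(end_a, end_b, n_nodes: int, kinds=None, weights=None) -> StringState:
    """Linearly interpolated initial string between two endpoint CV vectors.

    Dihedral CVs are interpolated along the shorter arc (170° → −170° passes
    through ±180°, not 0°).
    """
    a = np.atleast_1d(np.asarray(end_a, dtype=float))
    b = np.atleast_1d(np.asarray(end_b, dtype=float))
    if n_nodes < 3:
        raise DegenerateStringError("need at least 3 nodes")
    circ = _circular_mask(kinds, len(a))
    delta = b - a
    delta[circ] = wrap_degrees(delta[circ])
    if np.allclose(delta, 0.0, atol=1e-12):
        raise DegenerateStringError("endpoints are identical")
    t = np.linspace(0.0, 1.0, n_nodes)[:, None]
    nodes = _wrap_nodes(a[None] + t * delta[None], circ)
    return StringState(nodes=nodes, kinds=kinds, weights=weights)


def reparameterize(nodes, weights=None, kinds=None) -> np.ndarray:
    """Resample a string to equal metric arc lengths along its polyline.

    New nodes are placed at equally spaced arc-length positions on the
    current piecewise-linear path, so consecutive along-path arc lengths
    are exactly equal, endpoints are unchanged, and the total arc length
    is preserved.  Dihedral CVs are unwrapped along the path before
    interpolation and re-wrapped afterwards.
    """
    nodes = np.atleast_2d(np.asarray(nodes, dtype=float))
    K, dim = nodes.shape
    if K < 3:
        raise DegenerateStringError("need at least 3 nodes")
    circ = _circular_mask(kinds, dim)
    scale = _scale(weights, circ)
    deltas = _seg_deltas(nodes, circ)
    seg_len = np.linalg.norm(deltas * scale, axis=1)
    total = seg_len.sum()
    if total <= 0:
        raise DegenerateStringError("string has zero total arc length")
    # Unwrap circular CVs cumulatively so interpolation is linear.
    unwrapped = np.concatenate([nodes[:1], nodes[:1] + np.cumsum(deltas, axis=0)])
    cum = np.concatenate([[0.0], np.cumsum(seg_len)])
    targets = np.linspace(0.0, total, K)
    out = np.empty_like(nodes)
    for d in range(dim):
        out[:, d] = np.interp(targets, cum, unwrapped[:, d])
    out[0], out[-1] = unwrapped[0], unwrapped[-1]
    return _wrap_nodes(out, circ)


def string_iteration(
    state: StringState,
    potential: Potential,
    k_restraint: float = DEFAULT_K_RESTRAINT,
    steps_per_node: int = 200,
    dt: float = 1e-4,
    kt: float = 0.5,
    step_size: float = 0.1,
    seed: int = 0,
    pin_endpoints: bool = False,
    burn_in: float = 0.5,
) -> StringState:
    """One string-method iteration: restrained sampling, node update,
    reparameterization.

    Every node runs ``steps_per_node`` overdamped Langevin steps restrained
    to its position with force constant ``k_restraint``; the post-burn-in
    mean CV is the update target, approached by a fraction ``step_size``.
    At kt = 0 the update reduces to damped gradient descent restricted to
    the string.  The RNG stream is split from ``seed`` by iteration index,
    so a full run is reproducible from one seed.
    """
    if k_restraint <= 0:
        raise InvalidParameterError("k_restraint must be > 0")
    nodes = state.nodes
    circ = _circular_mask(state.kinds, state.n_cvs)
    if circ.any():
        raise InvalidParameterError(
            "sampled string iterations support linear CVs only; "
            "map dihedral CVs to a linear chart first"
        )
    rng = rng_stream(seed, replica=state.iteration)
    samples = evolve_ensemble(
        potential,
        nodes,
        dt=dt,
        kt=kt,
        nsteps=steps_per_node,
        rng=rng,
        bias_centers=nodes,
        bias_k=k_restraint,
    )
    keep = samples[int(burn_in * samples.shape[0]) :]
    means = keep.mean(axis=0)
    new_nodes = nodes + step_size * (means - nodes)
    if pin_endpoints:
        new_nodes[0], new_nodes[-1] = nodes[0], nodes[-1]
    new_nodes = reparameterize(new_nodes, state.weights, state.kinds)
    tiled_w = None
    if state.weights is not None:
        tiled_w = np.tile(np.asarray(state.weights, dtype=float), state.n_nodes)
    tiled_k = None if state.kinds is None else list(state.kinds) * state.n_nodes
    rmsd = weighted_rmsd(
        new_nodes.ravel(), nodes.ravel(), weights=tiled_w, kinds=tiled_k
    )
    return StringState(
        nodes=new_nodes,
        kinds=state.kinds,
        weights=state.weights,
        iteration=state.iteration + 1,
        rmsd_history=state.rmsd_history + [rmsd],
        converged=state.converged,
    )


def check_convergence(
    state: StringState,
    threshold: float = DEFAULT_CONVERGENCE_THRESHOLD,
    window: int = DEFAULT_CONVERGENCE_WINDOW,
) -> bool:
    """True iff the last ``window`` string RMSDs are all ≤ ``threshold``.

    A history shorter than the window is insufficient evidence and returns
    False.
    """
    hist = state.rmsd_history
    if len(hist) < window:
        return False
    return all(r <= threshold for r in hist[-window:])


def run_string(
    state: StringState,
    potential: Potential,
    max_iterations: int = 300,
    threshold: float = DEFAULT_CONVERGENCE_THRESHOLD,
    window: int = DEFAULT_CONVERGENCE_WINDOW,
    seed: int = 0,
    **iteration_kwargs,
) -> StringState:
    """Iterate the string until convergence or ``max_iterations``."""
    for _ in range(max_iterations):
        state = string_iteration(state, potential, seed=seed, **iteration_kwargs)
        if check_convergence(state, threshold, window):
            state.converged = True
            break
    return state


def attempt_exchange(config_a, config_b, bias_a, bias_b, kt, rng):
    """Metropolis swap between two neighbouring nodes' configurations.

    Acceptance probability min{1, exp(−Δ/kT)} with
    Δ = bias_a(x_b) + bias_b(x_a) − bias_a(x_a) − bias_b(x_b); at kT = 0 a
    swap is accepted only if it does not raise the total bias energy.

    Returns (accepted, config_a', config_b').
    """
    delta = (
        bias_a.energy(config_b)
        + bias_b.energy(config_a)
        - bias_a.energy(config_a)
        - bias_b.energy(config_b)
    )
    if kt <= 0:
        accept = delta <= 0
    else:
        accept = rng.uniform() < min(1.0, np.exp(-delta / kt))
    if accept:
        return True, config_b, config_a
    return False, config_a, config_b


@dataclass
class PathCV:
    """A frozen converged string with its arc-length table.

    The path coordinate s of a CV vector is the normalised arc-length
    position of its metric projection onto the piecewise-linear path,
    clamped to [0, 1].  On an equidistant string, node k maps to
    s = k/(K−1) exactly.
    """

    nodes: np.ndarray
    kinds: list | None = None
    weights: np.ndarray | None = None

    def __post_init__(self):
        self.nodes = np.atleast_2d(np.asarray(self.nodes, dtype=float))
        K, dim = self.nodes.shape
        if K < 2:
            raise DegenerateStringError("a path needs at least 2 nodes")
        self._circ = _circular_mask(self.kinds, dim)
        self._scale = _scale(self.weights, self._circ)
        seg = _seg_deltas(self.nodes, self._circ) * self._scale
        self._seg_scaled = seg
        self._seg_len = np.linalg.norm(seg, axis=1)
        if np.any(self._seg_len == 0):
            raise DegenerateStringError("consecutive path nodes coincide")
        self.arc_table = np.concatenate([[0.0], np.cumsum(self._seg_len)])
        self.total_length = float(self.arc_table[-1])

    def s(self, z) -> float:
        """Path coordinate of CV vector ``z``; ties go to the lower segment."""
        z = np.atleast_1d(np.asarray(z, dtype=float))
        best = (np.inf, 0.0)  # (squared distance, arc position)
        for k in range(len(self.nodes) - 1):
            v = z - self.nodes[k]
            v[self._circ] = wrap_degrees(v[self._circ])
            v = v * self._scale
            d = self._seg_scaled[k]
            t = float(np.clip(v @ d / (d @ d), 0.0, 1.0))
            dist2 = float(((v - t * d) ** 2).sum())
            if dist2 < best[0] - 1e-15:
                best = (dist2, self.arc_table[k] + t * self._seg_len[k])
        return float(np.clip(best[1] / self.total_length, 0.0, 1.0))


def path_s(path: PathCV, z) -> float:
    """Functional wrapper around :meth:`PathCV.s`."""
    return path.s(z)
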