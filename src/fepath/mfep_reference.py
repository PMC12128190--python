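"""Exact minimum-energy-path references for analytic 2-D potentials.

On an analytic surface the minimum (free-)energy path between two basins
is the union of the steepest-descent paths falling away from the
intervening first-order saddle points.  This module traces that union on
a dense grid — locate each saddle by minimising |∇V|², step off it along
the negative-curvature eigenvector, then follow discrete steepest descent
cell by cell — giving a reference path that involves no string, sampling
or reweighting machinery.  It is the oracle the adaptive string method is
held to on benchmark surfaces.
"""

from __future__ import annotations

import numpy as np
from scipy.optimize import minimize

from .errors import InvalidParameterError
from .potentials import Potential

__all__ = ["find_saddle", "steepest_descent_path", "mean_nearest_distance"]


def find_saddle(potential: Potential, guess) -> np.ndarray:
    """Locate a stationary point near ``guess`` by minimising |∇V|²."""
    if potential.dim != 2:
        raise InvalidParameterError("saddle search implemented for 2-D surfaces")

    def gradnorm2(x):
        g = potential.gradient(x)
        return float(g @ g)

    res = minimize(
        gradnorm2,
        np.asarray(guess, dtype=float),
        method="Nelder-Mead",
        options={"xatol": 1e-12, "fatol": 1e-16, "maxiter": 20_000},
    )
    return res.x


def _hessian(potential: Potential, p, eps: float = 1e-5) -> np.ndarray:
    h = np.zeros((2, 2))
    for i in range(2):
        e = np.zeros(2)
        e[i] = eps
        h[:, i] = (potential.gradient(p + e) - potential.gradient(p - e)) / (2 * eps)
    return 0.5 * (h + h.T)


def steepest_descent_path(
    potential: Potential,
    saddle_guesses,
    bounds,
    grid_size: int = 1000,
    offset: float = 0.01,
) -> np.ndarray:
    """Steepest-descent path through the given saddles on a dense grid.

    ``bounds`` is ((x_lo, x_hi), (y_lo, y_hi)); the surface is tabulated
    on a ``grid_size`` × ``grid_size`` grid and, from each refined saddle,
    discrete steepest descent (lowest of the 8 neighbours) is followed on
    both sides of the negative-curvature eigenvector until a grid-local
    minimum.  Returns the concatenated path points, shape (n, 2).
    """
    if potential.dim != 2:
        raise InvalidParameterError("grid descent implemented for 2-D surfaces")
    (x_lo, x_hi), (y_lo, y_hi) = bounds
    xs = np.linspace(x_lo, x_hi, grid_size)
    ys = np.linspace(y_lo, y_hi, grid_size)
    xg, yg = np.meshgrid(xs, ys, indexing="ij")
    energy = potential.energy(
        np.stack([xg.ravel(), yg.ravel()], axis=1)
    ).reshape(grid_size, grid_size)

    def descend(i: int, j: int) -> list[tuple[int, int]]:
        path = [(i, j)]
        while True:
            i0, j0 = max(0, i - 1), max(0, j - 1)
            sub = energy[i0 : i + 2, j0 : j + 2]
            if energy[i, j] <= sub.min():
                return path
            di, dj = np.unravel_index(np.argmin(sub), sub.shape)
            i, j = i0 + di, j0 + dj
            path.append((i, j))

    def nearest_cell(p) -> tuple[int, int]:
        return (
            int(np.argmin(np.abs(xs - p[0]))),
            int(np.argmin(np.abs(ys - p[1]))),
        )

    cells: list[tuple[int, int]] = []
    for guess in saddle_guesses:
        saddle = find_saddle(potential, guess)
        evals, evecs = np.linalg.eigh(_hessian(potential, saddle))
        v_neg = evecs[:, np.argmin(evals)]
        for sign in (-1.0, 1.0):
            cells += descend(*nearest_cell(saddle + sign * offset * v_neg))
        cells.append(nearest_cell(saddle))
    return np.array([(xs[i], ys[j]) for i, j in cells])


def mean_nearest_distance(points: np.ndarray, reference: np.ndarray) -> float:
    """Mean over ``points`` of the distance to the nearest reference point."""
    points = np.atleast_2d(points)
    reference = np.atleast_2d(reference)
    d2 = ((points[:, None, :] - reference[None, :, :]) ** 2).sum(axis=2)
    return float(np.sqrt(d2.min(axis=1)).mean())
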