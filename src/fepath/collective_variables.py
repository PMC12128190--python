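"""Collective variables: geometric evaluators, a mixed-unit metric, and
selection of discriminating coordinates by distribution overlap.

CVs are scalar functions of atomic coordinates — interatomic distances (Å)
or proper dihedrals (degrees, IUPAC sign convention, wrapped to
[−180, 180)) — each carrying an amu^1/2 metric weight.  To compare strings
of mixed CVs with a single RMSD, dihedral differences are converted to a
length scale at 1° ≡ 0.02 Å (a declared, fixed conversion).

For conformational changes with no obvious reaction coordinate, candidate
CVs are ranked by the overlap coefficient of their marginal distributions
in the two end-state ensembles: Σ_bins min(p̂_A, p̂_B) on a common
normalised histogram, 1 for identical and 0 for disjoint distributions.
Coordinates whose overlap falls below a threshold discriminate the states
and are kept as CVs for the path calculation.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .errors import (
    GeometryError,
    InsufficientDataError,
    InvalidParameterError,
    SelectionError,
    ShapeError,
)

__all__ = [
    "CVDefinition",
    "eval_distance",
    "eval_dihedral",
    "wrap_degrees",
    "weighted_rmsd",
    "overlap_coefficient",
    "select_cvs",
    "DEG_TO_ANGSTROM",
    "DEFAULT_OVERLAP_THRESHOLD",
]

#: Length-equivalent of one degree of a dihedral CV in the mixed metric.
DEG_TO_ANGSTROM = 0.02

#: Overlap coefficient below which a CV is deemed state-discriminating.
DEFAULT_OVERLAP_THRESHOLD = 0.25


def wrap_degrees(d):
    """Wrap angles (degrees) into [−180, 180)."""
    return (np.asarray(d, dtype=float) + 180.0) % 360.0 - 180.0


def eval_distance(frame: np.ndarray, i: int, j: int) -> float:
    """Euclidean distance between atoms ``i`` and ``j`` of a frame, Å."""
    if i == j:
        raise SelectionError(f"distance needs two distinct atoms, got {i} twice")
    frame = np.asarray(frame, dtype=float)
    return float(np.linalg.norm(frame[j] - frame[i]))


def eval_dihedral(frame: np.ndarray, i: int, j: int, k: int, l: int) -> float:
    """Signed proper dihedral i–j–k–l in degrees.

    IUPAC convention: cis = 0, sign positive for clockwise rotation of the
    far bond when sighting from j toward k; result wrapped to [−180, 180)
    (planar trans is reported as −180).
    """
    if len({i, j, k, l}) != 4:
        raise SelectionError("dihedral needs four distinct atoms")
    frame = np.asarray(frame, dtype=float)
    b1 = frame[j] - frame[i]
    b2 = frame[k] - frame[j]
    b3 = frame[l] - frame[k]
    n1 = np.cross(b1, b2)
    n2 = np.cross(b2, b3)
    if np.linalg.norm(n1) < 1e-10 or np.linalg.norm(n2) < 1e-10:
        raise GeometryError("three collinear atoms: dihedral undefined")
    b2n = b2 / np.linalg.norm(b2)
    x = float(np.dot(n1, n2))
    y = float(np.dot(np.cross(n1, n2), b2n))
    return float(wrap_degrees(np.degrees(np.arctan2(y, x))))


@dataclass(frozen=True)
class CVDefinition:
    """One collective variable: a distance, dihedral, or raw coordinate.

    ``indices`` are 0-based atom indices (2 for a distance, 4 for a
    dihedral, 1 for a direct coordinate); ``weight`` is the amu^1/2 metric
    weight used in string RMSDs.
    """

    kind: str
    indices: tuple[int, ...]
    weight: float = 1.0
    label: str = ""

    def __post_init__(self):
        expected = {"distance": 2, "dihedral": 4, "coordinate": 1}
        if self.kind not in expected:
            raise InvalidParameterError(f"unknown CV kind {self.kind!r}")
        if len(self.indices) != expected[self.kind]:
            raise InvalidParameterError(
                f"{self.kind} CV needs {expected[self.kind]} atom indices, "
                f"got {len(self.indices)}"
            )
        if self.weight <= 0:
            raise InvalidParameterError("metric weight must be > 0")

    @property
    def is_circular(self) -> bool:
        return self.kind == "dihedral"

    def evaluate(self, frames: np.ndarray) -> np.ndarray:
        """Evaluate on (n_atoms, 3) or (n_frames, n_atoms, 3) coordinates."""
        frames = np.asarray(frames, dtype=float)
        single = frames.ndim == 2
        if single:
            frames = frames[None]
        if self.kind == "distance":
            i, j = self.indices
            vals = np.array([eval_distance(f, i, j) for f in frames])
        elif self.kind == "dihedral":
            i, j, k, l = self.indices
            vals = np.array([eval_dihedral(f, i, j, k, l) for f in frames])
        else:
            vals = frames[:, self.indices[0], 0]
        return vals[0] if single else vals


def cvs_from_config(entries) -> list[CVDefinition]:
    """Build CV definitions from a config list.

    Each entry is a mapping with ``kind``, ``atoms`` (1-based atom indices
    in PQR serial order), and optional ``weight`` and ``label``.  Indices
    are converted to 0-based.
    """
    out = []
    for i, entry in enumerate(entries):
        try:
            kind = entry["kind"]
            atoms = entry["atoms"]
        except (KeyError, TypeError) as exc:
            raise InvalidParameterError(
                f"CV entry {i}: need 'kind' and 'atoms' keys"
            ) from exc
        if any(int(a) < 1 for a in atoms):
            raise InvalidParameterError(f"CV entry {i}: atom indices are 1-based")
        out.append(
            CVDefinition(
                kind=kind,
                indices=tuple(int(a) - 1 for a in atoms),
                weight=float(entry.get("weight", 1.0)),
                label=str(entry.get("label", f"cv{i}")),
            )
        )
    return out


def _deltas(a, b, kinds):
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.shape != b.shape:
        raise ShapeError(f"CV vectors differ in shape: {a.shape} vs {b.shape}")
    d = a - b
    if kinds is not None:
        if len(kinds) != len(d):
            raise ShapeError("kinds must have one entry per CV")
        circ = np.array([k == "dihedral" for k in kinds])
        d = np.where(circ, wrap_degrees(d) * DEG_TO_ANGSTROM, d)
    return d


def weighted_rmsd(a, b, weights=None, kinds=None) -> float:
    """Metric-weighted RMSD between two CV vectors, amu^1/2·Å.

    sqrt(Σᵢ wᵢ·Δᵢ² / Σᵢ wᵢ) with dihedral differences wrapped to
    (−180, 180] and converted to length at 1° ≡ 0.02 Å.  ``kinds`` is an
    optional per-CV sequence ("distance"/"dihedral"/...); without it all
    CVs are treated as linear.
    """
    d = _deltas(a, b, kinds)
    w = np.ones_like(d) if weights is None else np.asarray(weights, dtype=float)
    if w.shape != d.shape:
        raise ShapeError("weights must have one entry per CV")
    if np.any(w <= 0):
        raise InvalidParameterError("weights must be > 0")
    return float(np.sqrt((w * d**2).sum() / w.sum()))


def _fd_bins(pooled: np.ndarray) -> int:
    """Freedman–Diaconis bin count on a pooled sample, clipped to [10, 200]."""
    n = len(pooled)
    iqr = np.subtract(*np.percentile(pooled, [75, 25]))
    span = pooled.max() - pooled.min()
    if iqr <= 0 or span <= 0:
        return 10
    width = 2.0 * iqr * n ** (-1.0 / 3.0)
    return int(np.clip(np.ceil(span / width), 10, 200))


def overlap_coefficient(
    samples_a, samples_b, n_bins: int | None = None, circular: bool = False
) -> float:
    """Histogram overlap coefficient Σ_bins min(p̂_A, p̂_B) in [0, 1].

    Both samples are histogrammed on a common binning over the pooled
    range (over the full circle [−180, 180) when ``circular``); histograms
    are normalised to unit mass before taking the bin-wise minimum.
    Defaults to Freedman–Diaconis binning on the pooled sample.
    """
    a = np.asarray(samples_a, dtype=float).ravel()
    b = np.asarray(samples_b, dtype=float).ravel()
    if len(a) == 0 or len(b) == 0:
        raise InsufficientDataError("overlap_coefficient needs non-empty samples")
    pooled = np.concatenate([a, b])
    if n_bins is None:
        n_bins = _fd_bins(pooled)
    if circular:
        edges = np.linspace(-180.0, 180.0, n_bins + 1)
        a = wrap_degrees(a)
        b = wrap_degrees(b)
    else:
        lo, hi = pooled.min(), pooled.max()
        if hi <= lo:
            hi = lo + 1e-12
        edges = np.linspace(lo, hi, n_bins + 1)
    pa, _ = np.histogram(a, bins=edges)
    pb, _ = np.histogram(b, bins=edges)
    pa = pa / pa.sum()
    pb = pb / pb.sum()
    return float(np.minimum(pa, pb).sum())


def select_cvs(
    ens_a: pd.DataFrame,
    ens_b: pd.DataFrame,
    cv_kinds: dict[str, str] | None = None,
    overlap_threshold: float = DEFAULT_OVERLAP_THRESHOLD,
    n_bins: int | None = None,
) -> pd.DataFrame:
    """Rank candidate CVs by two-state distribution overlap.

    ``ens_a`` and ``ens_b`` are tables with one column per candidate CV,
    evaluated on the two end-state ensembles.  ``cv_kinds`` optionally maps
    column name → kind (dihedral columns are binned circularly).  Returns a
    DataFrame with columns ``cv``, ``kind``, ``overlap``, ``discriminating``
    sorted by ascending overlap; a CV discriminates the states when its
    overlap is strictly below ``overlap_threshold``.
    """
    if list(ens_a.columns) != list(ens_b.columns):
        raise ShapeError(
            "ensembles must share the same CV columns: "
            f"{list(ens_a.columns)} vs {list(ens_b.columns)}"
        )
    cv_kinds = cv_kinds or {}
    rows = []
    for col in ens_a.columns:
        kind = cv_kinds.get(col, "linear")
        ovl = overlap_coefficient(
            ens_a[col].to_numpy(),
            ens_b[col].to_numpy(),
            n_bins=n_bins,
            circular=kind == "dihedral",
        )
        rows.append({"cv": col, "kind": kind, "overlap": ovl})
    report = pd.DataFrame(rows).sort_values("overlap", kind="stable")
    report["discriminating"] = report["overlap"] < overlap_threshold
    return report.reset_index(drop=True)
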