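"""Bond-probe electric fields from point-charge environments.

The probe sits at the midpoint of a chosen bond (in the enzyme
application, the substrate's C=O carbonyl) and the environment's Coulomb
field is projected on the unit vector from the bond's oxygen to its
carbon.  With that orientation a positive projected field favours the
development of negative charge on the carbonyl oxygen — the sign
convention under which catalytically helpful residues report positive
values.

Fields are reported in MV·cm⁻¹.  Contributions are summed per residue or
per structural motif (a labelled residue set); solvent atoms beyond a
cutoff radius of the probe (default 15 Å) are excluded while solute atoms
always contribute, and the probe's own residue is excluded from the
environment by default.  Over a trajectory the probe follows its bond
frame by frame and records carry the standard error of the per-frame
group sums.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .constants import COULOMB_KCAL_A_E2, KCAL_MOL_E_A_TO_MV_CM
from .errors import GeometryError, InvalidParameterError, ValidationError
from .structures import ChargedStructure

__all__ = [
    "FieldProbe",
    "define_probe",
    "atom_field",
    "field_decomposition",
    "field_report",
    "DEFAULT_SOLVENT_CUTOFF",
    "FIELD_REPORT_THRESHOLD",
]

DEFAULT_SOLVENT_CUTOFF = 15.0  # Å
FIELD_REPORT_THRESHOLD = 2.0  # MV·cm⁻¹
SINGULARITY_R = 0.1  # Å


@dataclass
class FieldProbe:
    """Field evaluation point and projection axis.

    ``position`` is the midpoint of the two probe atoms; ``direction`` is
    the unit vector from atom 1 to atom 2 (oxygen → carbon for a carbonyl
    probe).  ``atom_indices`` lets trajectory analyses re-derive the probe
    from each frame's coordinates.
    """

    position: np.ndarray
    direction: np.ndarray
    atom_indices: tuple[int, int] | None = None

    def __post_init__(self):
        self.position = np.asarray(self.position, dtype=float).reshape(3)
        self.direction = np.asarray(self.direction, dtype=float).reshape(3)
        norm = np.linalg.norm(self.direction)
        if abs(norm - 1.0) > 1e-12:
            if norm == 0:
                raise InvalidParameterError("probe direction has zero length")
            self.direction = self.direction / norm

    @classmethod
    def from_atom_pair(cls, pos1, pos2, atom_indices=None) -> "FieldProbe":
        pos1 = np.asarray(pos1, dtype=float)
        pos2 = np.asarray(pos2, dtype=float)
        bond = pos2 - pos1
        norm = np.linalg.norm(bond)
        if norm == 0:
            raise GeometryError("probe atoms coincide")
        return cls(0.5 * (pos1 + pos2), bond / norm, atom_indices)


def define_probe(structure: ChargedStructure, sel1: str, sel2: str) -> FieldProbe:
    """Probe at the midpoint of two uniquely selected atoms.

    ``sel1``/``sel2`` are ``RESNAME:ATOMNAME`` (or ``RESNAME:RESID:ATOMNAME``)
    selections, each resolving to exactly one atom; the direction runs from
    the first to the second (give the oxygen first for a carbonyl probe).
    Swapping the arguments negates the direction and keeps the position.
    """
    i = structure.select_one(sel1)
    j = structure.select_one(sel2)
    if i == j:
        raise InvalidParameterError("probe atoms must be distinct")
    return FieldProbe.from_atom_pair(
        structure.coords[i], structure.coords[j], atom_indices=(i, j)
    )


def atom_field(position, charge: float, probe: FieldProbe) -> float:
    """Projected Coulomb field of one point charge at the probe, MV·cm⁻¹.

    E = k_e·q·(r_p − r_a)/|r_p − r_a|³ projected on the probe direction,
    converted from kcal·mol⁻¹·e⁻¹·Å⁻¹ at 4.3364 MV·cm⁻¹ per unit.
    """
    rvec = probe.position - np.asarray(position, dtype=float)
    r = float(np.linalg.norm(rvec))
    if r < SINGULARITY_R:
        raise GeometryError(f"charge within {SINGULARITY_R} Å of the probe")
    e = COULOMB_KCAL_A_E2 * charge * rvec / r**3
    return float(e @ probe.direction) * KCAL_MOL_E_A_TO_MV_CM


def _frame_projection(coords, charge, probe: FieldProbe) -> np.ndarray:
    """Per-atom projected field for one frame (vectorised atom_field)."""
    rvec = probe.position[None, :] - coords
    r = np.linalg.norm(rvec, axis=1)
    contrib = np.zeros(len(coords))
    ok = r >= SINGULARITY_R
    if np.any(~ok & (charge != 0)):
        raise GeometryError("a charged atom sits on the probe position")
    proj = (rvec[ok] @ probe.direction) / r[ok] ** 3
    contrib[ok] = COULOMB_KCAL_A_E2 * charge[ok] * proj * KCAL_MOL_E_A_TO_MV_CM
    return contrib


def field_decomposition(
    structure: ChargedStructure,
    probe: FieldProbe,
    traj: np.ndarray | None = None,
    solvent_cutoff: float = DEFAULT_SOLVENT_CUTOFF,
    grouping: str = "residue",
    exclude_probe_residue: bool = True,
) -> pd.DataFrame:
    """Per-residue or per-motif projected electric field at the probe.

    Every frame, each atom's projected Coulomb contribution is summed
    within its group.  Solvent-flagged atoms farther than
    ``solvent_cutoff`` from the probe are excluded frame by frame; solute
    atoms always contribute.  The probe's own residue is excluded from
    the environment unless ``exclude_probe_residue=False``.  Motif
    records are the per-frame sums over member residues (``grouping=
    "motif"`` requires the structure's motif map).

    Returns a DataFrame with columns group, field, err (MV·cm⁻¹), where
    err is the standard error of the per-frame sums (0 for one frame).
    """
    if grouping not in ("residue", "motif"):
        raise InvalidParameterError(f"unknown grouping {grouping!r}")
    if grouping == "motif" and not structure.motifs:
        raise ValidationError("structure has no motif map")
    frames = structure.coords[None] if traj is None else np.asarray(traj, float)
    n_frames = frames.shape[0]

    excluded = np.zeros(structure.n_atoms, dtype=bool)
    if exclude_probe_residue and probe.atom_indices is not None:
        i = probe.atom_indices[0]
        excluded = structure._residue_mask(
            (structure.chain[i], int(structure.resid[i]))
        )

    res_keys = [k for k in structure.residue_keys()
                if not excluded[structure._residue_mask(k)].all()]
    res_masks = {k: structure._residue_mask(k) & ~excluded for k in res_keys}

    per_frame = np.zeros((n_frames, len(res_keys)))
    for f in range(n_frames):
        coords = frames[f]
        fp = probe
        if traj is not None and probe.atom_indices is not None:
            i, j = probe.atom_indices
            fp = FieldProbe.from_atom_pair(coords[i], coords[j], (i, j))
        contrib = _frame_projection(coords, structure.charge, fp)
        # Frame-wise solvent cutoff about the probe position.
        dist = np.linalg.norm(coords - fp.position[None, :], axis=1)
        keep = ~excluded & (~structure.is_solvent | (dist <= solvent_cutoff))
        contrib = np.where(keep, contrib, 0.0)
        for c, k in enumerate(res_keys):
            per_frame[f, c] = contrib[res_masks[k]].sum()

    if grouping == "motif":
        labels = list(structure.motifs)
        cols = []
        key_to_col = {k: c for c, k in enumerate(res_keys)}
        for label in labels:
            members = [key_to_col[k] for k in structure.motifs[label]
                       if k in key_to_col]
            cols.append(per_frame[:, members].sum(axis=1))
        per_frame = np.stack(cols, axis=1) if cols else per_frame[:, :0]
    else:
        labels = [structure.residue_label(k) for k in res_keys]

    mean = per_frame.mean(axis=0)
    if n_frames > 1:
        err = per_frame.std(axis=0, ddof=1) / np.sqrt(n_frames)
    else:
        err = np.zeros_like(mean)
    return pd.DataFrame({"group": labels, "field": mean, "err": err})


def field_report(
    records: pd.DataFrame, threshold: float = FIELD_REPORT_THRESHOLD
) -> pd.DataFrame:
    """Filter field records to |mean| > threshold, sorted by |mean| desc."""
    if len(records) == 0:
        return records.copy()
    keep = records[np.abs(records["field"]) > threshold]
    order = np.argsort(-np.abs(keep["field"].to_numpy()), kind="stable")
    return keep.iloc[order].reset_index(drop=True)
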