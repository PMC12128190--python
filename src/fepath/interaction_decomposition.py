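"""Per-residue ligand–environment interaction energies over trajectories.

For every environment residue R, the per-frame interaction energy is the
sum of Coulomb and Lennard-Jones pair energies over all (ligand atom,
R atom) pairs, with the full pair energy assigned to R — not split evenly
between ligand and receptor as the conventional MM-GBSA decomposition
does.  Under full assignment the per-residue energies sum exactly to the
direct ligand–environment total, which makes the table additive and
directly comparable across ligands; the even-split convention would halve
that sum.

Statistical errors follow a 10-block rule: the trajectory series is cut
into 10 contiguous blocks and the error is the standard deviation of the
block means.  Differential reports (ligand B minus ligand A) combine the
two errors in quadrature and filter residues by the magnitude of their
state-A interaction.

No distance cutoff is applied, and no implicit-solvent term is computed:
energies are gas-phase Coulomb + LJ.  The report schema carries an
``E_solv`` column for forward compatibility; it is always empty here.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .constants import COULOMB_KCAL_A_E2
from .errors import (
    GeometryError,
    InsufficientDataError,
    InvalidParameterError,
    SelectionError,
    ValidationError,
)
from .structures import ChargedStructure

__all__ = [
    "LJParams",
    "pair_energy",
    "per_residue_interaction",
    "block_error",
    "differential_report",
    "stabilizer_report",
]

SINGULARITY_R = 0.1  # Å
DEFAULT_BLOCKS = 10
STABILIZER_THRESHOLD = 15.0  # kcal·mol⁻¹
REPORT_THRESHOLD = 2.0  # kcal·mol⁻¹


@dataclass
class LJParams:
    """Per-atom Lennard-Jones well depths ε (kcal·mol⁻¹) and sizes σ (Å).

    Cross terms use Lorentz–Berthelot combination: arithmetic-mean σ,
    geometric-mean ε.
    """

    epsilon: np.ndarray
    sigma: np.ndarray

    def __post_init__(self):
        self.epsilon = np.asarray(self.epsilon, dtype=float)
        self.sigma = np.asarray(self.sigma, dtype=float)
        if np.any(self.epsilon < 0):
            raise InvalidParameterError("epsilon must be >= 0")
        if np.any(self.sigma <= 0):
            raise InvalidParameterError("sigma must be > 0")

    @classmethod
    def uniform(cls, n_atoms: int, epsilon: float = 0.1, sigma: float = 3.0):
        return cls(np.full(n_atoms, epsilon), np.full(n_atoms, sigma))

    @classmethod
    def zero_vdw(cls, n_atoms: int):
        """Pure-Coulomb parameter set (ε = 0 everywhere)."""
        return cls(np.zeros(n_atoms), np.ones(n_atoms))


def pair_energy(
    pos_a, charge_a: float, pos_b, charge_b: float,
    eps_a: float = 0.0, sigma_a: float = 1.0,
    eps_b: float = 0.0, sigma_b: float = 1.0,
) -> tuple[float, float]:
    """Coulomb and Lennard-Jones energy of one atom pair, kcal·mol⁻¹.

    E_elec = k_e·q_a·q_b/r and E_vdw = 4ε[(σ/r)¹² − (σ/r)⁶] with
    Lorentz–Berthelot combined parameters; no distance cutoff.  Pairs
    closer than 0.1 Å are a singularity error.
    """
    r = float(np.linalg.norm(np.asarray(pos_b, float) - np.asarray(pos_a, float)))
    if r <= SINGULARITY_R:
        raise GeometryError(f"atom pair at r = {r:.4f} Å <= {SINGULARITY_R} Å")
    e_elec = COULOMB_KCAL_A_E2 * charge_a * charge_b / r
    sigma = 0.5 * (sigma_a + sigma_b)
    eps = float(np.sqrt(eps_a * eps_b))
    sr6 = (sigma / r) ** 6
    e_vdw = 4.0 * eps * (sr6**2 - sr6)
    return e_elec, e_vdw


def _pairwise_frame(coords, charge, lj, lig_idx, env_idx):
    """Vectorised ligand×environment pair energies for one frame.

    Returns (n_lig, n_env) arrays of electrostatic and LJ energies.
    """
    d = coords[env_idx][None, :, :] - coords[lig_idx][:, None, :]
    r = np.sqrt((d**2).sum(axis=2))
    if np.any(r <= SINGULARITY_R):
        i, j = np.argwhere(r <= SINGULARITY_R)[0]
        raise GeometryError(
            f"ligand atom {lig_idx[i]} and environment atom {env_idx[j]} "
            f"overlap (r = {r[i, j]:.4f} Å)"
        )
    e_elec = COULOMB_KCAL_A_E2 * np.outer(charge[lig_idx], charge[env_idx]) / r
    sigma = 0.5 * (lj.sigma[lig_idx][:, None] + lj.sigma[env_idx][None, :])
    eps = np.sqrt(np.outer(lj.epsilon[lig_idx], lj.epsilon[env_idx]))
    sr6 = (sigma / r) ** 6
    e_vdw = 4.0 * eps * (sr6**2 - sr6)
    return e_elec, e_vdw


def per_residue_interaction(
    structure: ChargedStructure,
    ligand_key: tuple[str, int],
    lj: LJParams | None = None,
    traj: np.ndarray | None = None,
    stride: int = 1,
    n_blocks: int = DEFAULT_BLOCKS,
    split_evenly: bool = False,
) -> pd.DataFrame:
    """Per-residue interaction energies of a ligand with its environment.

    ``traj`` is an optional (n_frames, n_atoms, 3) coordinate array; when
    omitted the structure's own coordinates are the single frame.  Frames
    are subsampled by ``stride``.  ``ligand_key`` may be a (chain, resid)
    pair or a residue name unique in the structure.  The full pair energy
    is assigned to the environment residue; ``split_evenly`` applies the
    conventional halving instead (kept as a negative control).

    Returns a DataFrame with columns residue, E_elec, E_vdw, E_int, err,
    E_solv (always NaN) and the per-frame series in ``attrs["series"]``.
    """
    if stride < 1:
        raise InvalidParameterError("stride must be >= 1")
    if isinstance(ligand_key, str):
        mask = structure.resname == ligand_key
        keys = {(c, int(r)) for c, r in zip(structure.chain[mask], structure.resid[mask])}
        if not keys:
            raise SelectionError(f"no residue named {ligand_key!r}")
        if len(keys) > 1:
            raise SelectionError(f"residue name {ligand_key!r} is ambiguous: {keys}")
        ligand_key = keys.pop()
    lig_mask = structure._residue_mask(tuple(ligand_key))
    if not np.any(lig_mask):
        raise SelectionError(f"ligand residue {ligand_key} absent from structure")
    lj = LJParams.zero_vdw(structure.n_atoms) if lj is None else lj
    if len(lj.epsilon) != structure.n_atoms:
        raise InvalidParameterError("LJ parameter arrays must match atom count")

    lig_idx = np.flatnonzero(lig_mask)
    env_idx = np.flatnonzero(~lig_mask)
    env_keys = [
        (c, int(r)) for c, r in zip(structure.chain[env_idx], structure.resid[env_idx])
    ]
    res_keys = list(dict.fromkeys(env_keys))
    key_to_col = {k: i for i, k in enumerate(res_keys)}
    col = np.array([key_to_col[k] for k in env_keys])

    frames = structure.coords[None] if traj is None else np.asarray(traj, float)
    frames = frames[::stride]
    n_frames = frames.shape[0]
    scale = 0.5 if split_evenly else 1.0

    elec = np.zeros((n_frames, len(res_keys)))
    vdw = np.zeros((n_frames, len(res_keys)))
    for f in range(n_frames):
        e_elec, e_vdw = _pairwise_frame(frames[f], structure.charge, lj, lig_idx, env_idx)
        np.add.at(elec[f], col, scale * e_elec.sum(axis=0))
        np.add.at(vdw[f], col, scale * e_vdw.sum(axis=0))

    eint = elec + vdw
    if n_frames >= n_blocks:
        errs = [block_error(eint[:, j], n_blocks) for j in range(len(res_keys))]
    else:
        errs = [np.nan] * len(res_keys)
    out = pd.DataFrame(
        {
            "residue": [structure.residue_label(k) for k in res_keys],
            "E_elec": elec.mean(axis=0),
            "E_vdw": vdw.mean(axis=0),
            "E_int": eint.mean(axis=0),
            "err": errs,
            "E_solv": np.nan,
        }
    )
    out.attrs["series"] = {structure.residue_label(k): eint[:, j]
                           for j, k in enumerate(res_keys)}
    return out


def block_error(series, n_blocks: int = DEFAULT_BLOCKS) -> float:
    """Standard deviation of ``n_blocks`` contiguous block means.

    The series is split into ``n_blocks`` equal contiguous blocks of
    length ⌊n/n_blocks⌋; remainder frames at the tail are dropped.  The
    returned error is the (n−1)-normalised standard deviation of the
    block means.
    """
    series = np.asarray(series, dtype=float).ravel()
    if len(series) < n_blocks:
        raise InsufficientDataError(
            f"series of length {len(series)} cannot form {n_blocks} blocks"
        )
    size = len(series) // n_blocks
    blocks = series[: size * n_blocks].reshape(n_blocks, size)
    return float(blocks.mean(axis=1).std(ddof=1))


def differential_report(
    records_a: pd.DataFrame,
    records_b: pd.DataFrame,
    threshold: float = REPORT_THRESHOLD,
) -> pd.DataFrame:
    """Per-residue E_int(B) − E_int(A) with quadrature-combined errors.

    Both tables must cover the same residue universe.  Rows are kept only
    where |E_int(A)| exceeds ``threshold`` (the reference-state magnitude
    filter), sorted by |E_int(A)| descending.
    """
    set_a, set_b = set(records_a["residue"]), set(records_b["residue"])
    if set_a != set_b:
        diff = sorted(set_a.symmetric_difference(set_b))
        raise ValidationError(f"residue universes differ: {diff}")
    a = records_a.set_index("residue")
    b = records_b.set_index("residue").loc[a.index]
    out = pd.DataFrame(
        {
            "residue": a.index,
            "E_int_A": a["E_int"].to_numpy(),
            "E_int_B": b["E_int"].to_numpy(),
            "delta": b["E_int"].to_numpy() - a["E_int"].to_numpy(),
            "err": np.sqrt(
                np.nan_to_num(a["err"].to_numpy()) ** 2
                + np.nan_to_num(b["err"].to_numpy()) ** 2
            ),
        }
    ).reset_index(drop=True)
    out = out[np.abs(out["E_int_A"]) > threshold]
    order = np.argsort(-np.abs(out["E_int_A"].to_numpy()), kind="stable")
    return out.iloc[order].reset_index(drop=True)


def stabilizer_report(
    records_a: pd.DataFrame,
    records_b: pd.DataFrame,
    threshold: float = STABILIZER_THRESHOLD,
) -> tuple[list[str], list[str]]:
    """Residues interacting strongly with a region in either of two states.

    A residue qualifies when |E_int| exceeds ``threshold`` (absolute value:
    −16 and +16 both pass) in at least one state, and is assigned to the
    state whose interaction magnitude dominates.  Both lists are sorted by
    descending |E_int| of the dominant state.
    """
    a = records_a.set_index("residue")["E_int"] if len(records_a) else pd.Series(dtype=float)
    b = records_b.set_index("residue")["E_int"] if len(records_b) else pd.Series(dtype=float)
    stab_a, stab_b = [], []
    for res in sorted(set(a.index) | set(b.index)):
        ea = float(a.get(res, 0.0))
        eb = float(b.get(res, 0.0))
        if max(abs(ea), abs(eb)) <= threshold:
            continue
        if abs(ea) >= abs(eb):
            stab_a.append((abs(ea), res))
        else:
            stab_b.append((abs(eb), res))
    return (
        [res for _, res in sorted(stab_a, reverse=True)],
        [res for _, res in sorted(stab_b, reverse=True)],
    )
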