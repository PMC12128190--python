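"""Synthetic systems that emulate the statistical structure of enzyme
simulations at desk scale.

This module provides the inputs every analysis stage is exercised on:

* analytic multi-basin potentials with known minima and barriers
  (re-exported from :mod:`fepath.potentials`),
* a seeded overdamped Langevin sampler standing in for MD
  (re-exported from :mod:`fepath.sampling`),
* λ-coupled toy Hamiltonians with closed-form free-energy differences,
* ligand-in-pocket point-charge assemblies with a carbonyl-like probe
  bond, for the electric-field and interaction-decomposition stages,
* two-state collective-variable ensembles with one planted discriminating
  coordinate, for the CV-selection stage.

Every generator is a pure function of its seed: identical arguments give
bit-identical output.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .errors import InvalidParameterError
from .potentials import (  # noqa: F401  (re-exported surface)
    AlchemicalSystem,
    HarmonicBias,
    Potential,
    double_well_1d,
    harmonic_nd,
    muller_brown,
    rescaled_1d,
)
from .sampling import Trajectory, overdamped_langevin, rng_stream  # noqa: F401
from .structures import ChargedStructure

__all__ = [
    "Potential",
    "Trajectory",
    "AlchemicalSystem",
    "ToyComplex",
    "muller_brown",
    "double_well_1d",
    "harmonic_nd",
    "rescaled_1d",
    "overdamped_langevin",
    "make_toy_complex",
    "two_state_ensembles",
]


@dataclass
class ToyComplex:
    """A charged structure with one ligand residue bearing a probe bond.

    ``probe_pair`` holds the two atom selections defining the bond probe,
    ordered carbonyl-oxygen-first so the probe direction points O → C, the
    convention under which a positive projected field stabilises negative
    charge at the oxygen end.
    """

    structure: ChargedStructure
    ligand_key: tuple[str, int]
    probe_pair: tuple[str, str]

    def __post_init__(self):
        lig_mask = self.structure._residue_mask(self.ligand_key)
        if not np.any(lig_mask):
            raise InvalidParameterError(f"ligand residue {self.ligand_key} absent")
        a = self.structure.select_one(self.probe_pair[0])
        b = self.structure.select_one(self.probe_pair[1])
        if a == b:
            raise InvalidParameterError("probe atoms must be distinct")
        for idx in (a, b):
            if not lig_mask[idx]:
                raise InvalidParameterError("probe atoms must belong to the ligand")


def make_toy_complex(
    n_residues: int,
    atoms_per_residue: int = 4,
    seed: int = 0,
    neutral_residues: bool = False,
    n_solvent: int = 0,
    shell_radius: float = 7.0,
    chains: tuple[str, ...] = ("A", "D"),
) -> ToyComplex:
    """Assemble a ligand-in-pocket point-charge complex.

    One ligand residue (``LIG``, resid 1) sits at the origin carrying a
    carbonyl-like probe bond (atoms ``OD1`` and ``CG``, 1.23 Å apart,
    charges −0.55/+0.55 e).  ``n_residues − 1`` protein residues are placed
    on a shell of radius ``shell_radius`` Å with ``atoms_per_residue``
    atoms jittered about each residue centre and random partial charges;
    with ``neutral_residues`` each protein residue's charges are shifted to
    sum exactly to zero.  ``n_solvent`` single-atom waters are scattered at
    radii between 3 and 25 Å and flagged as solvent.

    Deterministic in ``seed``.
    """
    if n_residues < 2:
        raise InvalidParameterError("need at least a ligand and one residue")
    if atoms_per_residue < 1:
        raise InvalidParameterError("atoms_per_residue must be >= 1")
    rng = rng_stream(seed)

    serials, names, resnames, chain_ids, resids = [], [], [], [], []
    coords, charges, radii, solvent = [], [], [], []
    serial = 0

    def add_atom(name, resname, chain, resid, xyz, q, r, is_solv=False):
        nonlocal serial
        serial += 1
        serials.append(serial)
        names.append(name)
        resnames.append(resname)
        chain_ids.append(chain)
        resids.append(resid)
        coords.append(np.asarray(xyz, dtype=float))
        charges.append(q)
        radii.append(r)
        solvent.append(is_solv)

    # Ligand: carbonyl probe bond along +x plus optional extra atoms.
    add_atom("OD1", "LIG", "A", 1, (-1.23, 0.0, 0.0), -0.55, 1.5)
    add_atom("CG", "LIG", "A", 1, (0.0, 0.0, 0.0), 0.55, 1.7)
    lig_extra = max(0, atoms_per_residue - 2)
    lig_q = rng.uniform(-0.3, 0.3, size=lig_extra)
    if neutral_residues and lig_extra:
        lig_q -= lig_q.mean()
    for i in range(lig_extra):
        add_atom(
            f"C{i + 1}", "LIG", "A", 1,
            rng.normal(scale=0.8, size=3) + (0.8, 0.8, 0.0),
            float(lig_q[i]), 1.6,
        )

    # Protein residues on a shell around the ligand.
    for ri in range(2, n_residues + 1):
        u = rng.normal(size=3)
        center = shell_radius * u / np.linalg.norm(u)
        q = rng.uniform(-0.5, 0.5, size=atoms_per_residue)
        if neutral_residues:
            q -= q.mean()
        chain = chains[(ri - 2) % len(chains)]
        for ai in range(atoms_per_residue):
            add_atom(
                f"A{ai + 1}", "RES", chain, ri,
                center + rng.normal(scale=0.7, size=3),
                float(q[ai]), 1.6,
            )

    # Solvent: single-atom waters, some beyond a typical 15 Å cutoff.
    for wi in range(n_solvent):
        u = rng.normal(size=3)
        pos = rng.uniform(3.0, 25.0) * u / np.linalg.norm(u)
        add_atom(
            "O", "HOH", "W", n_residues + 1 + wi, pos,
            float(rng.uniform(-0.4, 0.4)), 1.4, is_solv=True,
        )

    # Two placeholder structural motifs partitioning the protein residues.
    protein_keys = [
        (chains[(ri - 2) % len(chains)], ri) for ri in range(2, n_residues + 1)
    ]
    half = len(protein_keys) // 2
    motifs = {}
    if protein_keys:
        motifs["alpha1"] = frozenset(protein_keys[:half] or protein_keys[:1])
        motifs["alpha4"] = frozenset(protein_keys[half:] or protein_keys[:1])

    structure = ChargedStructure(
        np.array(serials),
        np.array(names, dtype=object),
        np.array(resnames, dtype=object),
        np.array(chain_ids, dtype=object),
        np.array(resids),
        np.array(coords),
        np.array(charges),
        np.array(radii),
        np.array(solvent),
        motifs,
    )
    return ToyComplex(
        structure=structure,
        ligand_key=("A", 1),
        probe_pair=("LIG:OD1", "LIG:CG"),
    )


def two_state_ensembles(
    n_cvs: int,
    discriminating_index: int,
    shift: float,
    n_samples: int = 10_000,
    seed: int = 0,
    kinds=None,
    sigma: float = 1.0,
    dihedral_sigma_deg: float = 15.0,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Draw two CV-sample tables differing in a single coordinate.

    Both states share every per-CV distribution except the one at
    ``discriminating_index``, whose state-B mean is displaced by ``shift``
    (in CV units: Å for linear coordinates, degrees for dihedral-like
    ones).  ``kinds`` is a per-CV list of ``"linear"`` or ``"dihedral"``;
    linear coordinates are Gaussian with standard deviation ``sigma``,
    dihedral-like ones are wrapped Gaussians on [−180, 180) with standard
    deviation ``dihedral_sigma_deg``.

    Returns two DataFrames with columns ``cv0 … cv{n−1}``, deterministic in
    ``seed``.
    """
    if not 0 <= discriminating_index < n_cvs:
        raise InvalidParameterError(
            f"discriminating_index {discriminating_index} outside [0, {n_cvs})"
        )
    if kinds is None:
        kinds = ["linear"] * n_cvs
    if len(kinds) != n_cvs:
        raise InvalidParameterError("kinds must have one entry per CV")
    rng = rng_stream(seed)
    # Per-CV base means, fixed across states, deterministic in seed.
    base_means = np.array(
        [
            rng.uniform(-90, 90) if kinds[i] == "dihedral" else rng.uniform(-2, 2)
            for i in range(n_cvs)
        ]
    )
    tables = []
    for state in range(2):
        cols = {}
        for i in range(n_cvs):
            mean = base_means[i]
            if state == 1 and i == discriminating_index:
                mean = mean + shift
            sd = dihedral_sigma_deg if kinds[i] == "dihedral" else sigma
            draws = rng.normal(mean, sd, size=n_samples)
            if kinds[i] == "dihedral":
                draws = (draws + 180.0) % 360.0 - 180.0
            cols[f"cv{i}"] = draws
        tables.append(pd.DataFrame(cols))
    return tables[0], tables[1]
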