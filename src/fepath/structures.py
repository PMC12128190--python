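"""Charged point-particle structures and their on-disk formats.

A :class:`ChargedStructure` is the container shared by the electric-field
and interaction-decomposition stages: atoms with coordinates (Å), partial
charges (e) and radii (Å), grouped into residues and chains, with per-atom
solvent flags and an optional motif map (motif label → residue set, e.g.
the α1 helix).

On disk, structures are whitespace-separated PQR records and trajectories
are multi-frame XYZ.  Both readers validate as they parse and report the
offending line on failure.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .errors import ParseError, SelectionError, ValidationError

__all__ = [
    "ChargedStructure",
    "read_pqr",
    "write_pqr",
    "read_xyz",
    "write_xyz",
    "DEFAULT_SOLVENT_NAMES",
    "residue_display_label",
]

#: Residue names flagged as solvent on read (waters and common ions).
DEFAULT_SOLVENT_NAMES = frozenset(
    {"WAT", "HOH", "SOL", "TIP3", "TIP", "SPC", "NA+", "CL-", "NA", "CL", "K+", "K"}
)

#: Prime decoration per chain used in per-residue reports: the reference
#: protomer (chain A) is unprimed, the adjacent protomer contributing
#: active-site residues (chain D) gets one prime, chains B and C two and
#: three primes.
CHAIN_PRIMES = {"A": "", "D": "′", "B": "″", "C": "‴", "": ""}


def residue_display_label(resname: str, resid: int, chain: str) -> str:
    """Human-readable residue label with chain-to-prime decoration."""
    prime = CHAIN_PRIMES.get(chain)
    if prime is None:
        return f"{resname}{resid}:{chain}"
    return f"{resname}{resid}{prime}"


@dataclass
class ChargedStructure:
    """Atoms with positions, partial charges and radii, grouped by residue.

    All per-atom fields are parallel arrays of length ``n_atoms``.  Residue
    identity is the (chain, resid) pair.  ``motifs`` maps a motif label to
    the set of residue keys it comprises.
    """

    serial: np.ndarray
    name: np.ndarray
    resname: np.ndarray
    chain: np.ndarray
    resid: np.ndarray
    coords: np.ndarray
    charge: np.ndarray
    radius: np.ndarray
    is_solvent: np.ndarray
    motifs: dict[str, frozenset] = field(default_factory=dict)

    def __post_init__(self):
        n = len(self.serial)
        self.serial = np.asarray(self.serial, dtype=int)
        self.name = np.asarray(self.name, dtype=object)
        self.resname = np.asarray(self.resname, dtype=object)
        self.chain = np.asarray(self.chain, dtype=object)
        self.resid = np.asarray(self.resid, dtype=int)
        self.coords = np.asarray(self.coords, dtype=float).reshape(n, 3)
        self.charge = np.asarray(self.charge, dtype=float)
        self.radius = np.asarray(self.radius, dtype=float)
        self.is_solvent = np.asarray(self.is_solvent, dtype=bool)
        if len(set(self.serial.tolist())) != n:
            raise ValidationError("duplicate atom serial numbers")
        if not np.all(np.isfinite(self.coords)):
            raise ValidationError("non-finite coordinates")
        for label, keys in self.motifs.items():
            self.motifs[label] = frozenset(tuple(k) for k in keys)
            for key in self.motifs[label]:
                if not np.any(self._residue_mask(key)):
                    raise ValidationError(
                        f"motif {label!r} references unknown residue {key}"
                    )

    @property
    def n_atoms(self) -> int:
        return len(self.serial)

    def net_charge(self) -> float:
        return float(self.charge.sum())

    def _residue_mask(self, key: tuple[str, int]) -> np.ndarray:
        chain, resid = key
        return (self.chain == chain) & (self.resid == resid)

    def residue_keys(self) -> list[tuple[str, int]]:
        """Residue keys in order of first appearance."""
        seen: dict[tuple[str, int], None] = {}
        for c, r in zip(self.chain, self.resid):
            seen.setdefault((c, int(r)), None)
        return list(seen)

    def residue_name(self, key: tuple[str, int]) -> str:
        mask = self._residue_mask(key)
        return str(self.resname[mask][0])

    def residue_label(self, key: tuple[str, int]) -> str:
        return residue_display_label(self.residue_name(key), key[1], key[0])

    def select_one(self, selection: str) -> int:
        """Resolve a ``RESNAME:ATOMNAME`` or ``RESNAME:RESID:ATOMNAME``
        selection to exactly one atom index.

        Raises :class:`SelectionError` if the selection is empty or
        ambiguous, listing the matches in the latter case.
        """
        parts = selection.split(":")
        if len(parts) == 2:
            resname, atname = parts
            mask = (self.resname == resname) & (self.name == atname)
        elif len(parts) == 3:
            resname, resid, atname = parts
            mask = (
                (self.resname == resname)
                & (self.resid == int(resid))
                & (self.name == atname)
            )
        else:
            raise SelectionError(f"cannot parse selection {selection!r}")
        idx = np.flatnonzero(mask)
        if len(idx) == 0:
            raise SelectionError(f"selection {selection!r} matches no atom")
        if len(idx) > 1:
            matches = ", ".join(
                f"{self.resname[i]}:{self.resid[i]}:{self.name[i]}"
                f"(serial {self.serial[i]})"
                for i in idx
            )
            raise SelectionError(
                f"selection {selection!r} is ambiguous: matches {matches}"
            )
        return int(idx[0])

    def with_coords(self, coords: np.ndarray) -> "ChargedStructure":
        """Copy of this structure with replaced coordinates (one frame)."""
        return ChargedStructure(
            self.serial,
            self.name,
            self.resname,
            self.chain,
            self.resid,
            np.asarray(coords, dtype=float),
            self.charge,
            self.radius,
            self.is_solvent,
            dict(self.motifs),
        )


def read_pqr(path, solvent_names=DEFAULT_SOLVENT_NAMES) -> ChargedStructure:
    """Parse a whitespace-separated PQR file.

    ATOM/HETATM records are read as

        ATOM serial name resName [chainID] resSeq x y z q r

    the chain column being optional (detected per record).  Residues whose
    name is in ``solvent_names`` are flagged as solvent.  Malformed records
    raise :class:`ParseError` naming the line; duplicate serials raise
    :class:`ValidationError`.
    """
    serials, names, resnames, chains, resids = [], [], [], [], []
    coords, charges, radii = [], [], []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            rec = line.split()
            if not rec or rec[0] not in ("ATOM", "HETATM"):
                continue
            try:
                if len(rec) >= 11:
                    _, serial, name, resname, chain, resseq = rec[:6]
                    x, y, z, q, r = rec[6:11]
                elif len(rec) == 10:
                    _, serial, name, resname, resseq = rec[:5]
                    chain = ""
                    x, y, z, q, r = rec[5:10]
                else:
                    raise ValueError("too few fields")
                serials.append(int(serial))
                resids.append(int(resseq))
                coords.append((float(x), float(y), float(z)))
                charges.append(float(q))
                radii.append(float(r))
            except ValueError as exc:
                raise ParseError(
                    f"malformed PQR record at line {lineno}: {exc} "
                    f"({line.rstrip()!r})",
                    line=lineno,
                ) from exc
            names.append(name)
            resnames.append(resname)
            chains.append(chain)
    if not serials:
        raise ParseError(f"no ATOM/HETATM records in {path}")
    is_solvent = np.array([rn in solvent_names for rn in resnames])
    return ChargedStructure(
        np.array(serials),
        np.array(names, dtype=object),
        np.array(resnames, dtype=object),
        np.array(chains, dtype=object),
        np.array(resids),
        np.array(coords),
        np.array(charges),
        np.array(radii),
        is_solvent,
    )


def write_pqr(structure: ChargedStructure, path) -> None:
    """Write a structure as whitespace-separated PQR (inverse of read_pqr)."""
    with open(path, "w") as fh:
        for i in range(structure.n_atoms):
            chain = structure.chain[i] or ""
            fields = [
                "ATOM",
                f"{structure.serial[i]:>6d}",
                f"{structure.name[i]:<4s}",
                f"{structure.resname[i]:<4s}",
            ]
            if chain:
                fields.append(f"{chain:<2s}")
            fields += [
                f"{structure.resid[i]:>5d}",
                f"{structure.coords[i, 0]:>24.17g}",
                f"{structure.coords[i, 1]:>24.17g}",
                f"{structure.coords[i, 2]:>24.17g}",
                f"{structure.charge[i]:>24.17g}",
                f"{structure.radius[i]:>12.9g}",
            ]
            fh.write(" ".join(fields) + "\n")
        fh.write("END\n")


def read_xyz(path) -> tuple[list[str], np.ndarray]:
    """Read a multi-frame XYZ trajectory.

    Returns ``(labels, coords)`` with coords of shape (n_frames, n_atoms, 3).
    All frames must have the same atom count and order.
    """
    frames: list[np.ndarray] = []
    labels: list[str] = []
    with open(path) as fh:
        lines = fh.readlines()
    i, lineno = 0, 0
    while i < len(lines):
        if not lines[i].strip():
            i += 1
            continue
        try:
            nat = int(lines[i].split()[0])
        except ValueError as exc:
            raise ParseError(
                f"expected atom count at line {i + 1}", line=i + 1
            ) from exc
        block = lines[i + 2 : i + 2 + nat]
        if len(block) < nat:
            raise ParseError(f"truncated frame starting at line {i + 1}", line=i + 1)
        frame = np.empty((nat, 3))
        frame_labels = []
        for j, row in enumerate(block):
            rec = row.split()
            if len(rec) < 4:
                raise ParseError(
                    f"malformed XYZ record at line {i + 3 + j}", line=i + 3 + j
                )
            frame_labels.append(rec[0])
            try:
                frame[j] = [float(v) for v in rec[1:4]]
            except ValueError as exc:
                raise ParseError(
                    f"malformed coordinate at line {i + 3 + j}", line=i + 3 + j
                ) from exc
        if frames and frame.shape != frames[0].shape:
            raise ParseError(f"inconsistent atom count in frame at line {i + 1}")
        frames.append(frame)
        labels = frame_labels
        i += 2 + nat
    if not frames:
        raise ParseError(f"no frames in {path}")
    return labels, np.stack(frames)


def write_xyz(path, coords: np.ndarray, labels=None, comment: str = "") -> None:
    """Write (n_frames, n_atoms, 3) coordinates as multi-frame XYZ."""
    coords = np.asarray(coords, dtype=float)
    if coords.ndim == 2:
        coords = coords[None]
    n_frames, n_atoms, _ = coords.shape
    if labels is None:
        labels = ["X"] * n_atoms
    with open(path, "w") as fh:
        for f in range(n_frames):
            fh.write(f"{n_atoms}\n{comment} frame {f}\n")
            for a in range(n_atoms):
                x, y, z = coords[f, a]
                fh.write(f"{labels[a]:<4s} {x:>12.6f} {y:>12.6f} {z:>12.6f}\n")
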