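"""Trajectory-level structural descriptors for short displayed peptides.

Two descriptors drive the structure–function story of material-binding
peptides.  *Percent helicity* asks whether a peptide keeps the alpha-helical
scaffold over a conformational ensemble; here it is assigned from backbone
phi/psi windows with a minimum run length — a deliberately simple surrogate
for hydrogen-bond-based assignment programs, documented as such.  The
*improper dihedral Phi_ij* measures whether the polar side-chain atoms
(hydroxyl oxygen or thiol sulfur) of residues i and j point to the same face
of the peptide: it is the torsion over (polar_i, CA_i, CA_j, polar_j), and
|Phi_ij| <= 90 deg is read as rough same-face alignment — the geometry that
lets both side chains engage a flat surface simultaneously.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np

__all__ = [
    "Atom",
    "Conformation",
    "Trajectory",
    "ImproperDihedralSeries",
    "HelicityReport",
    "parse_structure",
    "write_pdb",
    "polar_side_chain_atom",
    "dihedral",
    "wrap_angle",
    "improper_phi",
    "improper_phi_series",
    "same_face_fraction",
    "backbone_dihedrals",
    "percent_helicity",
    "POLAR_SIDE_CHAIN_ATOMS",
    "GeometryError",
    "StructureParseError",
    "DescriptorError",
]

#: Residues bearing a single surface-relevant polar side-chain atom, and the
#: standard structure-file name of that atom.
POLAR_SIDE_CHAIN_ATOMS: dict[str, str] = {
    "SER": "OG",
    "THR": "OG1",
    "TYR": "OH",
    "CYS": "SG",
}

BACKBONE_ATOMS = ("N", "CA", "C")


class GeometryError(ValueError):
    """Degenerate geometry (collinear triplet, coincident points)."""


class StructureParseError(ValueError):
    """Structure file missing required atoms or malformed."""


class DescriptorError(ValueError):
    """A descriptor was requested for residues that cannot support it."""


@dataclass(frozen=True)
class Atom:
    residue_index: int  # 1-based
    residue_name: str   # 3-letter code
    atom_name: str
    xyz: tuple[float, float, float]


@dataclass
class Conformation:
    """One frame of a single-chain peptide with named atoms (coordinates in A)."""

    atoms: list[Atom]

    def __post_init__(self) -> None:
        indices = sorted({a.residue_index for a in self.atoms})
        if not indices:
            raise StructureParseError("conformation has no atoms")
        if indices != list(range(indices[0], indices[0] + len(indices))):
            raise StructureParseError("residue indices are not contiguous")
        for idx in indices:
            names = {a.atom_name for a in self.atoms if a.residue_index == idx}
            missing = set(BACKBONE_ATOMS) - names
            if missing:
                raise StructureParseError(
                    f"residue {idx} missing backbone atoms {sorted(missing)}"
                )

    @property
    def residue_indices(self) -> list[int]:
        return sorted({a.residue_index for a in self.atoms})

    @property
    def n_residues(self) -> int:
        return len(self.residue_indices)

    def residue_name(self, index: int) -> str:
        for a in self.atoms:
            if a.residue_index == index:
                return a.residue_name
        raise KeyError(f"no residue {index}")

    def coord(self, residue_index: int, atom_name: str) -> np.ndarray:
        for a in self.atoms:
            if a.residue_index == residue_index and a.atom_name == atom_name:
                return np.asarray(a.xyz, dtype=float)
        raise KeyError(f"atom {atom_name} of residue {residue_index} not found")


@dataclass
class Trajectory:
    """Ordered conformations sharing atom naming; frame_interval is metadata (ps)."""

    frames: list[Conformation]
    frame_interval: float = 1.0

    def __post_init__(self) -> None:
        if not self.frames:
            raise StructureParseError("trajectory has no frames")
        key0 = [(a.residue_index, a.atom_name) for a in self.frames[0].atoms]
        for i, frame in enumerate(self.frames[1:], start=1):
            key = [(a.residue_index, a.atom_name) for a in frame.atoms]
            if key != key0:
                raise StructureParseError(
                    f"frame {i} atom ordering/naming differs from frame 0"
                )

    @property
    def n_frames(self) -> int:
        return len(self.frames)


@dataclass(frozen=True)
class ImproperDihedralSeries:
    """Per-frame Phi_ij for one residue pair, with the atom quadruple recorded
    so the backbone-atom choice stays auditable."""

    pair: tuple[int, int]
    phi_ij: tuple[float, ...]
    atoms_used: tuple[str, str, str, str]


@dataclass(frozen=True)
class HelicityReport:
    per_frame_fraction: tuple[float, ...]
    percent_helicity: float


# ---------------------------------------------------------------------------
# I/O

def parse_structure(path: str | Path) -> Trajectory:
    """Read a single- or multi-model PDB file into a Trajectory (one frame
    per MODEL).  Atom naming is preserved; missing backbone atoms raise a
    parse error naming the residue."""
    from Bio.PDB import PDBParser

    parser = PDBParser(QUIET=True)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        structure = parser.get_structure("traj", str(path))
    frames = []
    for model in structure:
        atoms: list[Atom] = []
        for chain in model:
            for residue in chain:
                het, resseq, _ = residue.id
                if het.strip():
                    continue
                for atom in residue:
                    atoms.append(
                        Atom(
                            residue_index=int(resseq),
                            residue_name=residue.get_resname().strip(),
                            atom_name=atom.get_name().strip(),
                            xyz=tuple(float(v) for v in atom.coord),
                        )
                    )
        frames.append(Conformation(atoms=atoms))
    if not frames:
        raise StructureParseError(f"no models found in {path}")
    return Trajectory(frames=frames)


def _format_atom_line(serial: int, atom: Atom) -> str:
    name = atom.atom_name
    # standard PDB name alignment: 1-letter elements start in column 14
    padded = f" {name:<3s}" if len(name) < 4 else name
    element = name[0]
    x, y, z = atom.xyz
    return (
        f"ATOM  {serial:>5d} {padded:<4s} {atom.residue_name:<3s} A"
        f"{atom.residue_index:>4d}    {x:8.3f}{y:8.3f}{z:8.3f}"
        f"{1.00:6.2f}{0.00:6.2f}          {element:>2s}"
    )


def write_pdb(traj: Trajectory | Conformation, path: str | Path) -> None:
    """Write a Conformation (single model) or Trajectory (multi-model) PDB."""
    frames = traj.frames if isinstance(traj, Trajectory) else [traj]
    lines: list[str] = []
    multi = len(frames) > 1
    for m, frame in enumerate(frames, start=1):
        if multi:
            lines.append(f"MODEL     {m:>4d}")
        for serial, atom in enumerate(frame.atoms, start=1):
            lines.append(_format_atom_line(serial, atom))
        lines.append("TER")
        if multi:
            lines.append("ENDMDL")
    lines.append("END")
    Path(path).write_text("\n".join(lines) + "\n")


# ---------------------------------------------------------------------------
# Geometry

def polar_side_chain_atom(residue_name: str) -> str | None:
    """Standard name of the surface-relevant polar side-chain atom
    (SER->OG, THR->OG1, TYR->OH, CYS->SG); None for other residues."""
    return POLAR_SIDE_CHAIN_ATOMS.get(residue_name.upper())


def dihedral(p1, p2, p3, p4) -> float:
    """Signed torsion angle p1-p2-p3-p4 about the p2-p3 axis, right-hand
    convention, in degrees on (-180, 180]."""
    p1, p2, p3, p4 = (np.asarray(p, dtype=float) for p in (p1, p2, p3, p4))
    b1, b2, b3 = p2 - p1, p3 - p2, p4 - p3
    if np.linalg.norm(b2) < 1e-9:
        raise GeometryError("axis points p2 and p3 coincide")
    n1 = np.cross(b1, b2)
    n2 = np.cross(b2, b3)
    if np.linalg.norm(n1) < 1e-9 or np.linalg.norm(n2) < 1e-9:
        raise GeometryError("collinear bonded triplet; torsion undefined")
    m1 = np.cross(n1, b2 / np.linalg.norm(b2))
    angle = math.degrees(math.atan2(float(np.dot(m1, n2)), float(np.dot(n1, n2))))
    return 180.0 if angle <= -180.0 else angle


def wrap_angle(angle_deg: float) -> float:
    """Map any angle in degrees onto (-180, 180]."""
    a = (angle_deg + 180.0) % 360.0 - 180.0
    return 180.0 if a == -180.0 else a


def improper_phi(conf: Conformation, i: int, j: int) -> float:
    """Improper dihedral Phi_ij over (polar_i, CA_i, CA_j, polar_j).

    Both residues must carry a polar side-chain atom (Ser/Thr/Tyr/Cys).
    Symmetric under pair reversal, so the pair is canonicalized to i < j.
    """
    if i == j:
        raise DescriptorError("Phi_ij requires two distinct residues")
    i, j = (i, j) if i < j else (j, i)
    atoms = []
    for idx in (i, j):
        resname = conf.residue_name(idx)
        polar = polar_side_chain_atom(resname)
        if polar is None:
            raise DescriptorError(
                f"residue {idx} ({resname}) has no hydroxyl/sulfoxyl atom"
            )
        atoms.append(polar)
    pol_i, pol_j = atoms
    return dihedral(
        conf.coord(i, pol_i), conf.coord(i, "CA"),
        conf.coord(j, "CA"), conf.coord(j, pol_j),
    )


def improper_phi_series(traj: Trajectory, i: int, j: int) -> ImproperDihedralSeries:
    """Per-frame Phi_ij over a trajectory."""
    i, j = (i, j) if i < j else (j, i)
    frame0 = traj.frames[0]
    pol_i = polar_side_chain_atom(frame0.residue_name(i))
    pol_j = polar_side_chain_atom(frame0.residue_name(j))
    angles = tuple(improper_phi(frame, i, j) for frame in traj.frames)
    return ImproperDihedralSeries(
        pair=(i, j),
        phi_ij=angles,
        atoms_used=(f"{pol_i}:{i}", f"CA:{i}", f"CA:{j}", f"{pol_j}:{j}"),
    )


def same_face_fraction(
    traj: Trajectory, i: int, j: int, threshold: float = 90.0
) -> float:
    """Fraction of frames with |Phi_ij| <= threshold (degrees).

    Values near 1 mean the two side chains stay aligned on one face of the
    peptide — available for simultaneous surface contact."""
    series = improper_phi_series(traj, i, j)
    return float(np.mean([abs(a) <= threshold for a in series.phi_ij]))


def backbone_dihedrals(conf: Conformation) -> dict[int, tuple[float | None, float | None]]:
    """Per-residue (phi, psi): phi = C(i-1)-N-CA-C, psi = N-CA-C-N(i+1).

    phi is undefined (None) at the first residue, psi at the last.
    """
    indices = conf.residue_indices
    if len(indices) < 2:
        return {indices[0]: (None, None)} if indices else {}
    out: dict[int, tuple[float | None, float | None]] = {}
    for idx in indices:
        phi = psi = None
        if idx > indices[0]:
            phi = dihedral(
                conf.coord(idx - 1, "C"), conf.coord(idx, "N"),
                conf.coord(idx, "CA"), conf.coord(idx, "C"),
            )
        if idx < indices[-1]:
            psi = dihedral(
                conf.coord(idx, "N"), conf.coord(idx, "CA"),
                conf.coord(idx, "C"), conf.coord(idx + 1, "N"),
            )
        out[idx] = (phi, psi)
    return out


def percent_helicity(
    traj: Trajectory,
    phi_window: tuple[float, float] = (-100.0, -30.0),
    psi_window: tuple[float, float] = (-67.0, -7.0),
    min_run: int = 4,
) -> HelicityReport:
    """Trajectory-averaged percent of residues assigned alpha-helical.

    A residue is helical when both phi and psi fall in the windows and it
    belongs to a consecutive run of at least ``min_run`` such residues.
    The denominator is the assignable residues (both angles defined, i.e.
    interior residues), so an ideal helix scores 100%.  This phi/psi-window
    rule is a surrogate for hydrogen-bond-based assignment (STRIDE/DSSP);
    absolute values can differ from those programs.
    """
    n_res = traj.frames[0].n_residues
    if n_res < min_run:
        raise DescriptorError(
            f"need at least min_run={min_run} residues, got {n_res}"
        )
    fractions = []
    for frame in traj.frames:
        angles = backbone_dihedrals(frame)
        indices = frame.residue_indices
        in_window = []
        assignable = 0
        for idx in indices:
            phi, psi = angles[idx]
            if phi is None or psi is None:
                in_window.append(False)
                continue
            assignable += 1
            in_window.append(
                phi_window[0] <= phi <= phi_window[1]
                and psi_window[0] <= psi <= psi_window[1]
            )
        helical = [False] * len(indices)
        run_start = 0
        for k in range(len(indices) + 1):
            if k == len(indices) or not in_window[k]:
                if k - run_start >= min_run:
                    for m in range(run_start, k):
                        helical[m] = True
                run_start = k + 1
        fractions.append(sum(helical) / assignable if assignable else 0.0)
    return HelicityReport(
        per_frame_fraction=tuple(fractions),
        percent_helicity=float(np.mean(fractions)) * 100.0,
    )
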