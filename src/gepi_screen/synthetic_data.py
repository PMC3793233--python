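"""Synthetic inputs for the whole pipeline: libraries, panning rounds, structures.

Everything the analysis consumes can be generated here at desk scale and
with a seed: NNK/NNS-randomized display libraries (real libraries hold ~1e10
clones; statistical properties are already visible at 1e4-1e5), a minimal
stochastic model of affinity panning (per-cell Bernoulli retention followed
by regrowth to fixed population size), and peptide conformations built from
internal coordinates — ideal helices, noisy helices, extended strands and
random coils — carrying named backbone atoms plus the single polar
side-chain atom per Ser/Thr/Tyr/Cys that the structural descriptors need.
Side chains beyond that atom are intentionally absent; these are geometric
fixtures, not force-field ensembles.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from itertools import product
from typing import Mapping, Sequence

import numpy as np
from Bio.Seq import Seq

from .enrichment_stats import CodonScheme, ConfigError, _SCHEME_THIRD_BASE
from .sequence_io import AA_ALPHABET, InputError
from .structure_metrics import (
    Atom,
    Conformation,
    Trajectory,
    polar_side_chain_atom,
)

__all__ = [
    "PanningConfig",
    "PanningResult",
    "reverse_translate",
    "generate_naive_library",
    "simulate_biopanning",
    "ideal_helix",
    "extended_strand",
    "build_conformation",
    "noisy_helix_trajectory",
    "coil_trajectory",
    "scheme_codon_table",
    "AA3",
]

AA3: dict[str, str] = {
    "A": "ALA", "C": "CYS", "D": "ASP", "E": "GLU", "F": "PHE",
    "G": "GLY", "H": "HIS", "I": "ILE", "K": "LYS", "L": "LEU",
    "M": "MET", "N": "ASN", "P": "PRO", "Q": "GLN", "R": "ARG",
    "S": "SER", "T": "THR", "V": "VAL", "W": "TRP", "Y": "TYR",
}

# ---------------------------------------------------------------------------
# Libraries and panning


def scheme_codon_table(scheme: CodonScheme | str) -> dict[str, list[str]]:
    """Enumerate the non-stop codons of an NNN/NNK/NNS scheme per residue."""
    name = scheme.name if isinstance(scheme, CodonScheme) else scheme
    name = name.upper()
    if name not in _SCHEME_THIRD_BASE:
        raise ConfigError(
            f"codon enumeration needs an NNN/NNK/NNS scheme, got {name!r}"
        )
    table: dict[str, list[str]] = {}
    for b1, b2, b3 in product("ACGT", "ACGT", _SCHEME_THIRD_BASE[name]):
        codon = b1 + b2 + b3
        aa = str(Seq(codon).translate())
        if aa != "*":
            table.setdefault(aa, []).append(codon)
    return table


def reverse_translate(
    peptide: str, scheme: CodonScheme | str = "NNK", seed: int = 0
) -> str:
    """Sample one scheme-consistent codon per residue, uniformly, seeded."""
    bad = set(peptide) - AA_ALPHABET
    if bad:
        raise InputError(f"non-standard residues {sorted(bad)}")
    table = scheme_codon_table(scheme)
    rng = np.random.default_rng(seed)
    return "".join(table[aa][rng.integers(len(table[aa]))] for aa in peptide)


def generate_naive_library(
    n: int,
    length: int = 15,
    scheme: CodonScheme | str = "NNK",
    seed: int = 0,
) -> list[str]:
    """i.i.d. codon-sampled random peptides; stop codons rejected and resampled.

    Residue frequencies therefore converge to the scheme's non-stop-conditioned
    expectations.  Deterministic given the seed.
    """
    if n < 1:
        raise InputError("n must be >= 1")
    table = scheme_codon_table(scheme)
    aas = sorted(table)
    # sampling residues with the non-stop codon weights is equivalent to
    # codon sampling with stop rejection
    weights = np.array([len(table[aa]) for aa in aas], dtype=float)
    weights /= weights.sum()
    rng = np.random.default_rng(seed)
    draws = rng.choice(len(aas), size=(n, length), p=weights)
    alphabet = np.array(list(aas))
    return ["".join(row) for row in alphabet[draws]]


@dataclass(frozen=True)
class PanningConfig:
    """Minimal biopanning model: Bernoulli retention on the surface, then
    regrowth of survivors back to fixed population size.

    ``affinity`` maps binder peptides to per-round retention probability;
    everything else retains with ``background_retention``.  Increasing wash
    stringency is modeled by multiplying every retention probability by
    ``stringency_multiplier`` each successive round.
    """

    rounds: int = 4
    population_size: int = 100_000
    affinity: Mapping[str, float] = field(default_factory=dict)
    background_retention: float = 0.005
    stringency_multiplier: float = 1.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.rounds < 1:
            raise InputError("rounds must be >= 1")
        for pep, p in self.affinity.items():
            if not 0 < p <= 1:
                raise InputError(f"affinity for {pep} must be in (0, 1]")
        if not 0 <= self.background_retention <= 1:
            raise InputError("background_retention must be in [0, 1]")


@dataclass
class PanningResult:
    """Per-round populations (after regrowth) and recovered counts (survivors
    on the surface before regrowth); round 0 is the naive input population."""

    populations: list[dict[str, int]]
    recovered: list[dict[str, int]]
    halted_early: bool = False

    def share(self, peptide: str, round_index: int) -> float:
        pop = self.populations[round_index]
        total = sum(pop.values())
        return pop.get(peptide, 0) / total if total else 0.0


def simulate_biopanning(library: Sequence[str], cfg: PanningConfig) -> PanningResult:
    """Run ``cfg.rounds`` of retention + regrowth over a peptide library.

    Spiked binders (affinity keys absent from ``library``) are added as
    members.  Population size is conserved by each regrowth step.  If no
    cell survives a round the run halts gracefully with a warning flag.
    """
    import warnings as _warnings

    members = list(dict.fromkeys(list(library) + list(cfg.affinity)))
    rng = np.random.default_rng(cfg.seed)
    # naive input population: uniform multinomial over members
    init = rng.multinomial(cfg.population_size, [1 / len(members)] * len(members))
    population = dict(zip(members, (int(c) for c in init)))
    populations = [dict(population)]
    recovered: list[dict[str, int]] = []
    for rnd in range(cfg.rounds):
        stringency = cfg.stringency_multiplier ** rnd
        survivors: dict[str, int] = {}
        for pep, count in population.items():
            if count == 0:
                continue
            p = cfg.affinity.get(pep, cfg.background_retention) * stringency
            p = min(max(p, 0.0), 1.0)
            kept = int(rng.binomial(count, p))
            if kept:
                survivors[pep] = kept
        recovered.append(survivors)
        total = sum(survivors.values())
        if total == 0:
            _warnings.warn(
                f"biopanning round {rnd + 1}: no survivors; halting early",
                stacklevel=2,
            )
            return PanningResult(populations, recovered, halted_early=True)
        # regrowth: multinomial resampling back to population_size
        peps = sorted(survivors)
        probs = np.array([survivors[p] for p in peps], dtype=float)
        probs /= probs.sum()
        regrown = rng.multinomial(cfg.population_size, probs)
        population = dict(zip(peps, (int(c) for c in regrown)))
        populations.append(dict(population))
    return PanningResult(populations, recovered)


# ---------------------------------------------------------------------------
# Conformations from internal coordinates

# ideal backbone geometry (A, degrees)
B_N_CA, B_CA_C, B_C_N = 1.458, 1.525, 1.329
A_N_CA_C, A_CA_C_N, A_C_N_CA = 111.2, 116.2, 121.7

#: distance from CA to the reduced polar side-chain atom, along the CA->CB
#: direction (A): one bond for Ser/Thr-like oxygens, longer for Cys sulfur
#: and the Tyr ring hydroxyl.
POLAR_ATOM_DISTANCE = {"SER": 2.42, "THR": 2.42, "CYS": 2.81, "TYR": 6.41}

IDEAL_HELIX_PHI_PSI = (-57.0, -47.0)
EXTENDED_PHI_PSI = (180.0, 180.0)


def _place_atom(a, b, c, bond: float, angle_deg: float, torsion_deg: float) -> np.ndarray:
    """Natural-extension-of-reference-frame placement: position D so that
    |CD| = bond, angle(B,C,D) = angle, dihedral(A,B,C,D) = torsion."""
    a, b, c = (np.asarray(p, dtype=float) for p in (a, b, c))
    angle = math.radians(angle_deg)
    torsion = math.radians(torsion_deg)
    bc = c - b
    bc /= np.linalg.norm(bc)
    n = np.cross(b - a, bc)
    n /= np.linalg.norm(n)
    m = np.cross(n, bc)
    d_local = np.array(
        [
            -bond * math.cos(angle),
            bond * math.sin(angle) * math.cos(torsion),
            -bond * math.sin(angle) * math.sin(torsion),
        ]
    )
    return c + d_local[0] * bc + d_local[1] * m + d_local[2] * n


def _cb_direction(n_pos: np.ndarray, ca: np.ndarray, c_pos: np.ndarray) -> np.ndarray:
    """Unit CA->CB direction for an L-amino acid: tetrahedral off the
    backbone, on the side of the N-CA-C plane fixed by L chirality."""
    u = n_pos - ca
    u /= np.linalg.norm(u)
    v = c_pos - ca
    v /= np.linalg.norm(v)
    bisector = u + v
    bisector /= np.linalg.norm(bisector)
    perp = np.cross(u, v)
    perp /= np.linalg.norm(perp)
    theta = math.radians(51.7)  # gives ~110.5 deg N-CA-CB and C-CA-CB angles
    return -math.cos(theta) * bisector - math.sin(theta) * perp


def build_conformation(
    peptide: str,
    phis: Sequence[float],
    psis: Sequence[float],
    omega: float = 180.0,
) -> Conformation:
    """Build named-atom coordinates for a peptide from backbone torsions.

    ``phis[0]`` is unused (no preceding carbonyl) and ``psis[-1]`` only
    orients the final carbonyl; interior values are reproduced exactly by
    backbone dihedral measurement.  Ser/Thr/Tyr/Cys get CB plus their single
    polar side-chain atom along the idealized CA->CB direction.
    """
    peptide = peptide.upper()
    bad = set(peptide) - AA_ALPHABET
    if bad:
        raise InputError(f"non-standard residues {sorted(bad)}")
    n_res = len(peptide)
    if n_res < 2:
        raise InputError("need at least 2 residues to build a chain")
    if len(phis) != n_res or len(psis) != n_res:
        raise InputError("phis and psis must have one value per residue")

    coords: list[dict[str, np.ndarray]] = []
    # first residue: N at origin, CA on x, C in the xy-plane
    n0 = np.zeros(3)
    ca0 = np.array([B_N_CA, 0.0, 0.0])
    ang = math.radians(A_N_CA_C)
    c0 = ca0 + B_CA_C * np.array([-math.cos(ang), math.sin(ang), 0.0])
    coords.append({"N": n0, "CA": ca0, "C": c0})
    for i in range(1, n_res):
        prev = coords[-1]
        n_i = _place_atom(prev["N"], prev["CA"], prev["C"], B_C_N, A_CA_C_N, psis[i - 1])
        ca_i = _place_atom(prev["CA"], prev["C"], n_i, B_N_CA, A_C_N_CA, omega)
        c_i = _place_atom(prev["C"], n_i, ca_i, B_CA_C, A_N_CA_C, phis[i])
        coords.append({"N": n_i, "CA": ca_i, "C": c_i})

    atoms: list[Atom] = []
    for i, (aa, pos) in enumerate(zip(peptide, coords), start=1):
        resname = AA3[aa]
        for name in ("N", "CA", "C"):
            atoms.append(Atom(i, resname, name, tuple(pos[name])))
        if aa != "G":
            cb_dir = _cb_direction(pos["N"], pos["CA"], pos["C"])
            cb = pos["CA"] + 1.53 * cb_dir
            atoms.append(Atom(i, resname, "CB", tuple(cb)))
            polar = polar_side_chain_atom(resname)
            if polar is not None:
                p = pos["CA"] + POLAR_ATOM_DISTANCE[resname] * cb_dir
                atoms.append(Atom(i, resname, polar, tuple(p)))
    return Conformation(atoms=atoms)


def ideal_helix(peptide: str) -> Conformation:
    """Ideal right-handed alpha helix: phi = -57, psi = -47, omega = 180."""
    n = len(peptide)
    phi, psi = IDEAL_HELIX_PHI_PSI
    return build_conformation(peptide, [phi] * n, [psi] * n)


def extended_strand(peptide: str) -> Conformation:
    """Fully extended chain (phi = psi = 180): the 0%-helicity control."""
    n = len(peptide)
    return build_conformation(peptide, [180.0] * n, [180.0] * n)


def noisy_helix_trajectory(
    peptide: str, n_frames: int, noise_deg: float, seed: int = 0
) -> Trajectory:
    """Helical ensemble with i.i.d. Gaussian(0, noise_deg^2) perturbations of
    every phi/psi per residue per frame; noise_deg = 0 reproduces the ideal
    helix in every frame."""
    if n_frames < 1:
        raise InputError("n_frames must be >= 1")
    rng = np.random.default_rng(seed)
    n = len(peptide)
    phi0, psi0 = IDEAL_HELIX_PHI_PSI
    frames = []
    for _ in range(n_frames):
        phis = phi0 + rng.normal(0.0, noise_deg, size=n) if noise_deg else [phi0] * n
        psis = psi0 + rng.normal(0.0, noise_deg, size=n) if noise_deg else [psi0] * n
        frames.append(build_conformation(peptide, list(phis), list(psis)))
    return Trajectory(frames=frames)


def coil_trajectory(peptide: str, n_frames: int, seed: int = 0) -> Trajectory:
    """Random-coil ensemble: per residue per frame, phi is drawn uniformly
    from the sterically plausible region [-180, -30] u [30, 180] and psi
    uniformly from the full circle.  A null model for helicity and for the
    same-face statistics, not a thermodynamic coil."""
    if n_frames < 1:
        raise InputError("n_frames must be >= 1")
    rng = np.random.default_rng(seed)
    n = len(peptide)
    frames = []
    for _ in range(n_frames):
        raw = rng.uniform(0.0, 300.0, size=n)
        phis = np.where(raw < 150.0, -180.0 + raw, 30.0 + (raw - 150.0))
        psis = rng.uniform(-180.0, 180.0, size=n)
        frames.append(build_conformation(peptide, list(phis), list(psis)))
    return Trajectory(frames=frames)
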