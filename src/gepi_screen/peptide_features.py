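"""Sequence-level feature scores for candidate surface-binding peptides.

Oxide surfaces (alumina here) are thought to be engaged chiefly through
hydroxyl- and thiol-bearing side chains, so the first-order descriptors are
how many such residues a peptide carries and how widely they are spread
along it.  A helix-propensity mean (Pace–Scholtz scale) summarizes whether a
peptide is likely to hold the helical scaffold that keeps those side chains
presented on one face.  Exponential doubling-time fits for growth-control
curves round out the module.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from importlib import resources
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .sequence_io import AA_ALPHABET, InputError

__all__ = [
    "FeatureReport",
    "GrowthCurve",
    "HYDROXYL_SULFOXYL_RESIDUES",
    "count_hydroxyl_sulfoxyl",
    "positional_span",
    "helix_propensity_score",
    "load_pace_scholtz_scale",
    "feature_report",
    "fit_doubling_time",
    "GrowthFitError",
]

#: Ser/Thr/Tyr carry side-chain hydroxyls; Cys carries the thiol ("sulfoxyl")
#: group.  Met is excluded: its thioether has no exchangeable proton.
HYDROXYL_SULFOXYL_RESIDUES = frozenset("STYC")


class GrowthFitError(RuntimeError):
    """The OD series shows no exponential growth to fit."""


@dataclass(frozen=True)
class FeatureReport:
    peptide: str
    n_hydroxyl_sulfoxyl: int
    positions: tuple[int, ...]
    positional_span: float
    propensity_score: float


@dataclass(frozen=True)
class GrowthCurve:
    times: tuple[float, ...]
    od: tuple[float, ...]
    doubling_time: float
    fit_ci: tuple[float, float]


def count_hydroxyl_sulfoxyl(
    peptide: str, residue_set: frozenset[str] | set[str] = HYDROXYL_SULFOXYL_RESIDUES
) -> tuple[int, tuple[int, ...]]:
    """Count scored residues and return their 1-based positions."""
    bad = set(peptide) - AA_ALPHABET
    if bad:
        raise InputError(f"non-standard residues {sorted(bad)} in peptide")
    positions = tuple(i for i, aa in enumerate(peptide, start=1) if aa in residue_set)
    return len(positions), positions


def positional_span(positions: Sequence[int], peptide_length: int) -> float:
    """Fractional spread of scored positions: (max-min)/(length-1), in [0, 1].

    1.0 means the scored residues reach both termini; a single position
    spans 0.
    """
    if not positions:
        raise InputError("no positions given; span is undefined")
    if min(positions) < 1 or max(positions) > peptide_length:
        raise InputError("positions out of range for peptide length")
    if peptide_length < 2:
        return 0.0
    return (max(positions) - min(positions)) / (peptide_length - 1)


def load_pace_scholtz_scale() -> dict[str, float]:
    """Helix-propensity scale (kcal/mol vs Ala); lower favours the helix."""
    ref = resources.files("gepi_screen.data").joinpath("pace_scholtz_1998.tsv")
    with resources.as_file(ref) as path:
        df = pd.read_csv(path, sep="\t", comment="#")
    return dict(zip(df["residue"], df["ddG_kcal_mol"]))


def helix_propensity_score(
    peptide: str, scale: Mapping[str, float] | None = None
) -> float:
    """Mean helix-propensity free-energy cost over the peptide's residues."""
    scale = load_pace_scholtz_scale() if scale is None else scale
    missing = [aa for aa in set(peptide) if aa not in scale]
    if missing:
        raise InputError(f"residues {sorted(missing)} absent from propensity scale")
    if not peptide:
        raise InputError("empty peptide")
    return float(np.mean([scale[aa] for aa in peptide]))


def feature_report(
    peptide: str,
    residue_set: frozenset[str] | set[str] = HYDROXYL_SULFOXYL_RESIDUES,
    scale: Mapping[str, float] | None = None,
) -> FeatureReport:
    n, positions = count_hydroxyl_sulfoxyl(peptide, residue_set)
    span = positional_span(positions, len(peptide)) if positions else 0.0
    return FeatureReport(
        peptide=peptide,
        n_hydroxyl_sulfoxyl=n,
        positions=positions,
        positional_span=span,
        propensity_score=helix_propensity_score(peptide, scale),
    )


def fit_doubling_time(
    times: Sequence[float], od: Sequence[float], level: float = 0.95
) -> GrowthCurve:
    """Fit OD(t) = OD0 * 2^(t / T_d) and report T_d with a confidence interval.

    The model is linearized (log2 OD against time) and fitted by ordinary
    least squares; the interval on T_d comes from the t-interval on the slope.
    Times are minutes; OD positive; a non-positive fitted slope (no growth)
    raises :class:`GrowthFitError`.
    """
    t = np.asarray(times, dtype=float)
    y = np.asarray(od, dtype=float)
    if t.size < 4:
        raise InputError("need at least 4 time points")
    if np.any(np.diff(t) <= 0):
        raise InputError("times must be strictly increasing")
    if np.any(y <= 0):
        raise InputError("OD readings must be positive")
    res = stats.linregress(t, np.log2(y))
    if res.slope <= 0:
        raise GrowthFitError("no exponential growth: fitted slope <= 0")
    td = 1.0 / res.slope
    tcrit = stats.t.ppf(0.5 + level / 2, t.size - 2)
    slope_low = res.slope - tcrit * res.stderr
    slope_high = res.slope + tcrit * res.stderr
    # invert the slope interval; an interval crossing zero is unbounded above
    upper = math.inf if slope_low <= 0 else 1.0 / slope_low
    lower = 1.0 / slope_high
    return GrowthCurve(
        times=tuple(t), od=tuple(y), doubling_time=td, fit_ci=(lower, upper)
    )
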