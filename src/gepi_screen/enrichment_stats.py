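"""Residue-enrichment statistics for selected display-library populations.

The probability that a fully randomized library shows residue *r* at any
position is set by codon degeneracy: under an NNK scheme serine is encoded by
3 of the 31 non-stop codons, tryptophan by 1, so their null expectations
differ fivefold before any selection acts.  Observed residue counts across
the isolate population (weighted by isolate multiplicity) are therefore
compared against these codon-degeneracy expectations with exact binomial
(Clopper–Pearson) 95% confidence intervals; a residue or residue class is
called enriched when its expectation falls below the interval around the
observed proportion, depleted when it falls above.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from itertools import product
from typing import Mapping

import pandas as pd
from Bio.Seq import Seq
from scipy.stats import beta

from .sequence_io import AA_ALPHABET, InputError, IsolateTable

__all__ = [
    "CodonScheme",
    "ResidueCounts",
    "EnrichmentResult",
    "make_codon_scheme",
    "observed_counts",
    "exact_binomial_ci",
    "enrichment_table",
    "class_aggregate",
    "DEFAULT_CLASS_MAP",
    "bonferroni_level",
    "results_to_frame",
    "ConfigError",
]

AMINO_ACIDS = sorted(AA_ALPHABET)

#: Residue classes used to summarize enrichment trends.  The exact membership
#: of published category plots is rarely printed, so this is configurable;
#: the default partitions the alphabet.
DEFAULT_CLASS_MAP: dict[str, str] = {
    **{aa: "acidic" for aa in "DE"},
    **{aa: "basic" for aa in "KRH"},
    **{aa: "polar" for aa in "STNQYC"},
    **{aa: "non-polar" for aa in "GAP"},
    **{aa: "hydrophobic" for aa in "VLIMFW"},
}

_SCHEME_THIRD_BASE = {"NNN": "ACGT", "NNK": "GT", "NNS": "GC"}


class ConfigError(ValueError):
    """Unknown scheme name or incomplete configuration map."""


@dataclass(frozen=True)
class CodonScheme:
    """A randomization scheme with per-residue codon counts.

    ``expected_p`` is conditioned on non-stop codons, because displayed
    peptides cannot contain a stop.
    """

    name: str
    codons_per_aa: Mapping[str, int]
    n_stop_codons: int

    @property
    def total_codons(self) -> int:
        return sum(self.codons_per_aa.values()) + self.n_stop_codons

    @property
    def expected_p(self) -> dict[str, float]:
        non_stop = sum(self.codons_per_aa.values())
        return {aa: c / non_stop for aa, c in self.codons_per_aa.items()}


@dataclass(frozen=True)
class ResidueCounts:
    counts: Mapping[str, int]
    total_residues: int
    weighted: bool = True

    def __post_init__(self) -> None:
        if sum(self.counts.values()) != self.total_residues:
            raise InputError("residue counts do not sum to total_residues")


@dataclass(frozen=True)
class EnrichmentResult:
    residue: str
    k: int
    n: int
    observed_freq: float
    expected_freq: float
    ci_low: float
    ci_high: float
    status: str  # enriched | depleted | neutral
    aa_class: str | None = None


def make_codon_scheme(
    name: str, custom_codons: Mapping[str, int] | None = None
) -> CodonScheme:
    """Build a scheme by brute-force enumeration of its codons.

    ``NNN``/``NNK``/``NNS`` are enumerated from their base sets (N = any,
    K = G/T, S = G/C); ``custom`` takes an explicit residue -> codon-count map.
    """
    name = name.upper()
    if name == "CUSTOM":
        if not custom_codons:
            raise ConfigError("custom scheme requires a codon-count map")
        missing = AA_ALPHABET - set(custom_codons)
        zero = [aa for aa, c in custom_codons.items() if c < 1]
        if missing or zero:
            raise ConfigError(
                f"custom scheme must give every residue >= 1 codon "
                f"(missing {sorted(missing)}, zero {zero})"
            )
        return CodonScheme("custom", dict(custom_codons), n_stop_codons=0)
    if name not in _SCHEME_THIRD_BASE:
        raise ConfigError(f"unknown codon scheme {name!r}")
    counts: dict[str, int] = {aa: 0 for aa in AMINO_ACIDS}
    n_stop = 0
    for b1, b2, b3 in product("ACGT", "ACGT", _SCHEME_THIRD_BASE[name]):
        aa = str(Seq(b1 + b2 + b3).translate())
        if aa == "*":
            n_stop += 1
        else:
            counts[aa] += 1
    return CodonScheme(name, counts, n_stop_codons=n_stop)


def observed_counts(
    table: IsolateTable, weight_by_multiplicity: bool = True
) -> ResidueCounts:
    """Residue counts over the isolate population.

    With weighting, each residue of each isolate counts once per sequenced
    colony (multiplicity); variable-length peptides contribute their own
    length — a truncated isolate adds fewer residues, no padding.
    """
    if len(table) == 0:
        raise InputError("empty isolate table")
    counts = {aa: 0 for aa in AMINO_ACIDS}
    for iso in table:
        w = iso.multiplicity if weight_by_multiplicity else 1
        for aa in iso.peptide:
            if aa not in counts:
                raise InputError(f"{iso.name}: non-standard residue {aa!r}")
            counts[aa] += w
    return ResidueCounts(
        counts=counts,
        total_residues=sum(counts.values()),
        weighted=weight_by_multiplicity,
    )


def exact_binomial_ci(k: int, n: int, level: float = 0.95) -> tuple[float, float]:
    """Clopper–Pearson exact confidence interval for a binomial proportion.

    Computed from beta-distribution quantiles; the interval is asymmetric in
    general, with low = 0 at k = 0 and high = 1 at k = n.
    """
    if not 0 < level < 1:
        raise InputError(f"level must be in (0, 1), got {level}")
    if n < 1 or not 0 <= k <= n:
        raise InputError(f"require 0 <= k <= n with n >= 1, got k={k}, n={n}")
    alpha = 1.0 - level
    low = 0.0 if k == 0 else float(beta.ppf(alpha / 2, k, n - k + 1))
    high = 1.0 if k == n else float(beta.ppf(1 - alpha / 2, k + 1, n - k))
    return low, high


def _status(expected: float, ci_low: float, ci_high: float) -> str:
    if expected < ci_low:
        return "enriched"
    if expected > ci_high:
        return "depleted"
    return "neutral"


def enrichment_table(
    counts: ResidueCounts,
    scheme: CodonScheme,
    level: float = 0.95,
    class_map: Mapping[str, str] | None = None,
) -> list[EnrichmentResult]:
    """Per-residue observed vs expected frequencies with exact CIs.

    Emits one row per amino acid, zero-count residues included.  No
    multiple-testing correction is applied by default; pass
    ``level=bonferroni_level()`` for a Bonferroni-adjusted family.
    """
    if counts.total_residues < 1:
        raise InputError("no residues counted")
    class_map = DEFAULT_CLASS_MAP if class_map is None else class_map
    n = counts.total_residues
    expected = scheme.expected_p
    results = []
    for aa in AMINO_ACIDS:
        k = counts.counts.get(aa, 0)
        low, high = exact_binomial_ci(k, n, level)
        results.append(
            EnrichmentResult(
                residue=aa,
                k=k,
                n=n,
                observed_freq=k / n,
                expected_freq=expected.get(aa, 0.0),
                ci_low=low,
                ci_high=high,
                status=_status(expected.get(aa, 0.0), low, high),
                aa_class=class_map.get(aa),
            )
        )
    return results


def class_aggregate(
    results: list[EnrichmentResult],
    class_map: Mapping[str, str] | None = None,
    level: float = 0.95,
) -> list[EnrichmentResult]:
    """Aggregate per-residue rows into residue-class rows.

    Class counts and expectations are sums over members; the CI is recomputed
    on the class count, so class calls are exact in the same sense as
    per-residue calls.
    """
    class_map = DEFAULT_CLASS_MAP if class_map is None else class_map
    missing = AA_ALPHABET - set(class_map)
    if missing:
        raise ConfigError(f"class map missing residues {sorted(missing)}")
    by_class: dict[str, list[EnrichmentResult]] = {}
    for res in results:
        by_class.setdefault(class_map[res.residue], []).append(res)
    n = results[0].n
    rows = []
    for cls in sorted(by_class):
        members = by_class[cls]
        k = sum(m.k for m in members)
        p = sum(m.expected_freq for m in members)
        low, high = exact_binomial_ci(k, n, level)
        rows.append(
            EnrichmentResult(
                residue="+".join(sorted(m.residue for m in members)),
                k=k,
                n=n,
                observed_freq=k / n,
                expected_freq=p,
                ci_low=low,
                ci_high=high,
                status=_status(p, low, high),
                aa_class=cls,
            )
        )
    return rows


def bonferroni_level(level: float = 0.95, n_tests: int = 20) -> float:
    """Family-wise level for ``n_tests`` simultaneous intervals."""
    return 1.0 - (1.0 - level) / n_tests


def results_to_frame(results: list[EnrichmentResult]) -> pd.DataFrame:
    return pd.DataFrame(
        [
            {
                "residue": r.residue,
                "class": r.aa_class,
                "k": r.k,
                "n": r.n,
                "observed_freq": r.observed_freq,
                "expected_freq": r.expected_freq,
                "ci_low": r.ci_low,
                "ci_high": r.ci_high,
                "status": r.status,
            }
            for r in results
        ]
    )
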