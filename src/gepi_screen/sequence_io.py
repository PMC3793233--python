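"""Reading display-vector sequencing reads and building the peptide isolate table.

A biopanning round ends with Sanger sequencing of randomly picked colonies.
Each read carries the randomized insert of the display vector between fixed
flanking scaffold sequence.  This module extracts the insert, translates it,
flags integrity problems (truncation, internal stops, frameshifts), and
collapses identical peptides into a table of unique isolates with
multiplicities — the shape in which selection outcomes are reported and from
which residue-enrichment statistics are computed.
"""

from __future__ import annotations

import logging
from collections import OrderedDict
from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path
from typing import Iterable, Sequence

import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq

__all__ = [
    "SangerRead",
    "PeptideIsolate",
    "IsolateTable",
    "translate_dna",
    "extract_insert",
    "classify_isolate",
    "build_isolate_table",
    "isolates_from_reads",
    "read_fasta",
    "read_peptide_list",
    "write_isolate_table",
    "read_isolate_table",
    "load_reference_isolates",
    "AL_S1",
    "InputError",
    "ExtractionError",
]

logger = logging.getLogger(__name__)

DNA_ALPHABET = set("ACGTN")
AA_ALPHABET = set("ACDEFGHIKLMNPQRSTVWY")

#: Phage-derived aluminum-binding reference peptide (Al-S1) used for
#: cross-scaffold comparisons.
AL_S1 = "VPSSGPQDTRTT"


class InputError(ValueError):
    """Malformed sequence input (bad alphabet, empty sequence, ...)."""


class ExtractionError(ValueError):
    """Insert extraction failed (flank missing or out of order)."""


@dataclass(frozen=True)
class SangerRead:
    """One sequencing read: identifier plus DNA over {A, C, G, T, N}."""

    read_id: str
    dna: str

    def __post_init__(self) -> None:
        if not self.dna:
            raise InputError(f"read {self.read_id!r}: empty DNA sequence")
        bad = set(self.dna.upper()) - DNA_ALPHABET
        if bad:
            raise InputError(
                f"read {self.read_id!r}: invalid DNA characters {sorted(bad)}"
            )
        object.__setattr__(self, "dna", self.dna.upper())


@dataclass(frozen=True)
class PeptideIsolate:
    """One unique displayed peptide with its observation count and flags."""

    name: str
    peptide: str
    multiplicity: int = 1
    is_full_length: bool | None = None
    has_internal_stop: bool = False
    frameshift_suspected: bool = False

    @property
    def length(self) -> int:
        return len(self.peptide)

    def __post_init__(self) -> None:
        if self.multiplicity < 1:
            raise InputError(f"{self.name}: multiplicity must be >= 1")
        bad = set(self.peptide) - AA_ALPHABET
        if bad:
            raise InputError(
                f"{self.name}: non-standard residues {sorted(bad)} in peptide"
            )


@dataclass
class IsolateTable:
    """Deduplicated isolates; total_sequences counts every sequenced colony."""

    isolates: list[PeptideIsolate] = field(default_factory=list)

    @property
    def n_unique(self) -> int:
        return len({iso.peptide for iso in self.isolates})

    @property
    def total_sequences(self) -> int:
        return sum(iso.multiplicity for iso in self.isolates)

    def __iter__(self):
        return iter(self.isolates)

    def __len__(self) -> int:
        return len(self.isolates)

    def to_frame(self) -> pd.DataFrame:
        rows = [
            {
                "name": iso.name,
                "peptide": iso.peptide,
                "multiplicity": iso.multiplicity,
                "length": iso.length,
                "is_full_length": iso.is_full_length,
                "has_internal_stop": iso.has_internal_stop,
                "frameshift_suspected": iso.frameshift_suspected,
            }
            for iso in self.isolates
        ]
        return pd.DataFrame(rows)

    def expand(self) -> list[tuple[str, str]]:
        """Back out the per-colony (label, peptide) records, one per count."""
        records = []
        for iso in self.isolates:
            records.extend([(iso.name, iso.peptide)] * iso.multiplicity)
        return records


def translate_dna(dna: str, frame: int = 0) -> str:
    """Translate ``dna`` in the given reading frame with the standard code.

    Incomplete trailing codons are dropped; stop codons appear as ``'*'``;
    codons containing ``N`` translate to ``'X'``.
    """
    if frame not in (0, 1, 2):
        raise InputError(f"frame must be 0, 1 or 2, got {frame}")
    if not dna:
        raise InputError("empty DNA sequence")
    dna = dna.upper()
    bad = set(dna) - DNA_ALPHABET
    if bad:
        raise InputError(f"invalid DNA characters {sorted(bad)}")
    trimmed = dna[frame:]
    if len(trimmed) < 3:
        raise InputError("fewer than one complete codon after frame offset")
    trimmed = trimmed[: len(trimmed) - len(trimmed) % 3]
    # Bio.Seq renders ambiguous codons as X and stops as * already.
    return str(Seq(trimmed).translate())


def extract_insert(read: SangerRead, flank5: str, flank3: str) -> str:
    """Return the insert strictly between the first ``flank5`` occurrence and
    the last subsequent ``flank3`` occurrence.

    Taking the last (rightmost) 3' flank match keeps inserts intact when the
    insert itself ends in a prefix of the 3' flank; a partially repeated
    flank inside the insert would otherwise truncate it.
    """
    if not flank5 or not flank3:
        raise ExtractionError("both flanks must be non-empty")
    flank5, flank3 = flank5.upper(), flank3.upper()
    i = read.dna.find(flank5)
    if i < 0:
        raise ExtractionError(f"read {read.read_id!r}: 5' flank not found")
    start = i + len(flank5)
    j = read.dna.rfind(flank3)
    if j < start:
        raise ExtractionError(
            f"read {read.read_id!r}: 3' flank not found downstream of 5' flank"
        )
    return read.dna[start:j]


def classify_isolate(
    insert_dna: str, expected_len: int = 15
) -> tuple[bool, bool, bool]:
    """Integrity flags (is_full_length, has_internal_stop, frameshift_suspected)
    for a display insert, judged on its frame-0 translation."""
    peptide = translate_dna(insert_dna, frame=0)
    coding = peptide.rstrip("*") if peptide.endswith("*") else peptide
    has_internal_stop = "*" in coding[:expected_len]
    translated_len = len(coding.split("*")[0])
    is_full_length = translated_len == expected_len
    frameshift_suspected = len(insert_dna) % 3 != 0
    return is_full_length, has_internal_stop, frameshift_suspected


def build_isolate_table(
    peptides: Sequence[tuple[str, str]],
    expected_len: int = 15,
    allow_empty: bool = False,
    drop_ambiguous: bool = True,
) -> IsolateTable:
    """Merge identical peptide strings into unique isolates with multiplicities.

    Deduplication is at the amino-acid level (selection acts on the displayed
    peptide, and synonymous codon variants are the same isolate for reporting
    purposes).  The first label seen for a peptide names the merged isolate.
    Peptides containing ``'X'`` (from N base calls) are dropped with a warning
    unless ``drop_ambiguous`` is false.
    """
    if not peptides and not allow_empty:
        raise InputError("no peptide records supplied (pass allow_empty=True "
                         "to build an empty table)")
    merged: OrderedDict[str, list] = OrderedDict()
    for label, pep in peptides:
        if "X" in pep:
            if drop_ambiguous:
                logger.warning(
                    "dropping %s: ambiguous residue 'X' from uncalled base", label
                )
                continue
            raise InputError(f"{label}: ambiguous residue 'X'")
        if pep in merged:
            merged[pep][1] += 1
        else:
            merged[pep] = [label, 1]
    isolates = [
        PeptideIsolate(
            name=label,
            peptide=pep,
            multiplicity=count,
            is_full_length=len(pep) == expected_len,
        )
        for pep, (label, count) in merged.items()
    ]
    return IsolateTable(isolates=isolates)


def isolates_from_reads(
    reads: Iterable[SangerRead],
    flank5: str,
    flank3: str,
    expected_len: int = 15,
) -> IsolateTable:
    """Full read-to-table path: extract inserts, translate, flag, deduplicate."""
    records: list[tuple[str, str, tuple[bool, bool, bool]]] = []
    for read in reads:
        insert = extract_insert(read, flank5, flank3)
        flags = classify_isolate(insert, expected_len=expected_len)
        peptide = translate_dna(insert, frame=0).split("*")[0]
        if "X" in peptide:
            logger.warning("dropping read %s: uncalled base in insert", read.read_id)
            continue
        records.append((read.read_id, peptide, flags))
    table = build_isolate_table(
        [(rid, pep) for rid, pep, _ in records], expected_len=expected_len
    )
    # re-attach integrity flags from the first read of each unique peptide
    flag_by_pep = {}
    for _, pep, flags in records:
        flag_by_pep.setdefault(pep, flags)
    table.isolates = [
        PeptideIsolate(
            name=iso.name,
            peptide=iso.peptide,
            multiplicity=iso.multiplicity,
            is_full_length=flag_by_pep[iso.peptide][0],
            has_internal_stop=flag_by_pep[iso.peptide][1],
            frameshift_suspected=flag_by_pep[iso.peptide][2],
        )
        for iso in table.isolates
    ]
    return table


def read_fasta(path: str | Path) -> list[SangerRead]:
    return [SangerRead(rec.id, str(rec.seq)) for rec in SeqIO.parse(str(path), "fasta")]


def read_peptide_list(path: str | Path) -> list[tuple[str, str]]:
    """Read a two-column (label, peptide) whitespace/tab-separated file;
    a single peptide-only column is auto-labelled pep1, pep2, ..."""
    records = []
    for i, line in enumerate(Path(path).read_text().splitlines(), start=1):
        line = line.strip()
        if not line or line.startswith("#"):
            continue
        parts = line.split()
        if len(parts) == 1:
            records.append((f"pep{i}", parts[0].upper()))
        else:
            records.append((parts[0], parts[1].upper()))
    return records


def write_isolate_table(table: IsolateTable, path: str | Path) -> None:
    table.to_frame().to_csv(path, sep="\t", index=False)


def read_isolate_table(path: str | Path) -> IsolateTable:
    df = pd.read_csv(path, sep="\t")
    isolates = [
        PeptideIsolate(
            name=str(row["name"]),
            peptide=str(row["peptide"]),
            multiplicity=int(row["multiplicity"]),
            is_full_length=bool(row["is_full_length"])
            if "is_full_length" in df.columns and pd.notna(row.get("is_full_length"))
            else None,
            has_internal_stop=bool(row.get("has_internal_stop", False))
            if "has_internal_stop" in df.columns
            else False,
            frameshift_suspected=bool(row.get("frameshift_suspected", False))
            if "frameshift_suspected" in df.columns
            else False,
        )
        for _, row in df.iterrows()
    ]
    return IsolateTable(isolates=isolates)


def load_reference_isolates() -> IsolateTable:
    """The 17 aluminum-binding isolates recovered from round-4 biopanning
    (65 sequenced colonies; the dominant clone DBAD1 was seen 49 times)."""
    ref = resources.files("gepi_screen.data").joinpath("table1.tsv")
    with resources.as_file(ref) as path:
        df = pd.read_csv(path, sep="\t")
    isolates = [
        PeptideIsolate(
            name=row["name"],
            peptide=row["peptide"],
            multiplicity=int(row["multiplicity"]),
            is_full_length=len(row["peptide"]) == 15,
        )
        for _, row in df.iterrows()
    ]
    return IsolateTable(isolates=isolates)
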