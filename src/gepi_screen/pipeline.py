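"""End-to-end orchestration: config-driven runs and binding-assay arithmetic."""

from __future__ import annotations

import datetime
import logging
import math
from dataclasses import dataclass
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import yaml

from . import __version__
from .enrichment_stats import (
    ConfigError,
    class_aggregate,
    enrichment_table,
    make_codon_scheme,
    observed_counts,
    results_to_frame,
)
from .peptide_features import feature_report
from .sequence_io import (
    InputError,
    IsolateTable,
    build_isolate_table,
    isolates_from_reads,
    read_fasta,
    read_peptide_list,
    write_isolate_table,
)

__all__ = ["AssayCounts", "fold_change", "run_pipeline", "ConfigError"]

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class AssayCounts:
    """Recovered-cell counts (cells/mL) for one sample: replicates, mean, SEM."""

    label: str
    replicates: tuple[float, ...]

    @property
    def mean(self) -> float:
        return float(np.mean(self.replicates))

    @property
    def sem(self) -> float:
        if len(self.replicates) < 2:
            return 0.0
        return float(np.std(self.replicates, ddof=1) / math.sqrt(len(self.replicates)))


def fold_change(
    numerator: AssayCounts, denominator: AssayCounts
) -> tuple[float, float]:
    """Ratio of sample means with first-order (delta-method) SEM propagation.

    For R = x̄/ȳ, SEM(R) ≈ R * sqrt((SEMx/x̄)² + (SEMy/ȳ)²).
    """
    if denominator.mean <= 0:
        raise InputError(
            f"denominator sample {denominator.label!r} has non-positive mean"
        )
    ratio = numerator.mean / denominator.mean
    rel = 0.0
    if numerator.mean > 0:
        rel = math.sqrt(
            (numerator.sem / numerator.mean) ** 2
            + (denominator.sem / denominator.mean) ** 2
        )
    return ratio, ratio * rel


def _load_isolates(cfg: Mapping, base: Path) -> IsolateTable:
    if "reads_fasta" in cfg:
        reads = read_fasta(base / cfg["reads_fasta"])
        return isolates_from_reads(
            reads,
            flank5=cfg["flank5"],
            flank3=cfg["flank3"],
            expected_len=int(cfg.get("expected_len", 15)),
        )
    if "peptides_file" in cfg:
        records = read_peptide_list(base / cfg["peptides_file"])
        # peptide lists may carry a multiplicity third column via repetition
        return build_isolate_table(records, expected_len=int(cfg.get("expected_len", 15)))
    raise ConfigError("config must provide 'reads_fasta' or 'peptides_file'")


def run_pipeline(config: str | Path | Mapping, output_dir: str | Path | None = None) -> dict:
    """Run the read -> isolate-table -> enrichment -> features analysis.

    ``config`` is a YAML path or an equivalent mapping.  Keys: one of
    ``reads_fasta`` (+ ``flank5``/``flank3``) or ``peptides_file``; optional
    ``expected_len`` (15), ``scheme`` (NNK), ``level`` (0.95), ``class_map``
    (residue -> class), ``unweighted`` (false), ``output_dir``, ``seed``.
    All outputs are TSV plus a plain-text run log; identical config gives
    bit-identical outputs.
    """
    if isinstance(config, (str, Path)):
        base = Path(config).resolve().parent
        cfg = yaml.safe_load(Path(config).read_text())
    else:
        base = Path.cwd()
        cfg = dict(config)
    if not isinstance(cfg, Mapping):
        raise ConfigError("config must be a mapping")

    # validate before any stage runs
    for key in ("reads_fasta", "peptides_file"):
        if key in cfg and not (base / cfg[key]).exists():
            raise ConfigError(f"input path {cfg[key]!r} does not exist")
    if "reads_fasta" not in cfg and "peptides_file" not in cfg:
        raise ConfigError("config must provide 'reads_fasta' or 'peptides_file'")
    if "reads_fasta" in cfg and not ("flank5" in cfg and "flank3" in cfg):
        raise ConfigError("reads_fasta input requires 'flank5' and 'flank3'")

    out = Path(output_dir or cfg.get("output_dir", "gepi_screen_out"))
    out.mkdir(parents=True, exist_ok=True)
    log_lines = [
        f"gepi-screen {__version__}",
        f"started {datetime.datetime.now().isoformat(timespec='seconds')}",
        f"config: { {k: v for k, v in sorted(cfg.items())} }",
    ]

    table = _load_isolates(cfg, base)
    write_isolate_table(table, out / "isolates.tsv")
    log_lines.append(
        f"stage isolates: n_unique={table.n_unique} total={table.total_sequences}"
    )

    scheme = make_codon_scheme(cfg.get("scheme", "NNK"))
    level = float(cfg.get("level", 0.95))
    class_map = cfg.get("class_map")
    counts = observed_counts(table, weight_by_multiplicity=not cfg.get("unweighted", False))
    per_residue = enrichment_table(counts, scheme, level=level, class_map=class_map)
    per_class = class_aggregate(per_residue, class_map=class_map, level=level)
    results_to_frame(per_residue).to_csv(out / "enrichment_residues.tsv", sep="\t", index=False)
    results_to_frame(per_class).to_csv(out / "enrichment_classes.tsv", sep="\t", index=False)
    log_lines.append(
        f"stage enrich: scheme={scheme.name} level={level} N={counts.total_residues}"
    )

    feats = [feature_report(iso.peptide) for iso in table]
    import pandas as pd

    pd.DataFrame(
        [
            {
                "name": iso.name,
                "peptide": f.peptide,
                "n_hydroxyl_sulfoxyl": f.n_hydroxyl_sulfoxyl,
                "positions": ",".join(map(str, f.positions)),
                "positional_span": f.positional_span,
                "propensity_score": f.propensity_score,
            }
            for iso, f in zip(table, feats)
        ]
    ).to_csv(out / "features.tsv", sep="\t", index=False)
    log_lines.append("stage features: done")

    (out / "run.log").write_text("\n".join(log_lines) + "\n")
    return {
        "n_unique": table.n_unique,
        "total_sequences": table.total_sequences,
        "output_dir": str(out),
        "per_residue": per_residue,
        "per_class": per_class,
    }
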