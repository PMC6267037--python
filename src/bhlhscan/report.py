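"""Family-level summary statistics, expression filters and report assembly.

Threshold semantics follow the conventions of the source data sets exactly
as documented: TPM-unit matrices use a strict "greater than" inclusion rule
(default 10), FPKM/RPKM matrices an inclusive "at least" rule (default 5);
differential expression requires fold change at least 2 (|log2FC| >= 1)
with adjusted p <= 0.05, both boundaries inclusive.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd
import yaml

from ._util import percentage, round_half_up
from .io import ProteinRecord, write_table
from .scan import DomainHit

log = logging.getLogger(__name__)

UNITS = {"TPM", "FPKM", "RPKM"}
DEFAULT_THRESHOLDS = {"TPM": 10.0, "FPKM": 5.0, "RPKM": 5.0}


@dataclass
class ExpressionMatrix:
    """Gene x sample abundance matrix with its unit and sample->tissue map."""

    values: pd.DataFrame
    unit: str
    sample_tissue: dict[str, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.unit not in UNITS:
            raise ValueError(f"unknown expression unit {self.unit!r}")
        if (self.values.to_numpy() < 0).any():
            raise ValueError("expression values must be non-negative")


@dataclass
class DEStatsTable:
    """Differential-expression statistics: gene, contrast, log2fc, padj."""

    table: pd.DataFrame

    def __post_init__(self) -> None:
        required = {"gene", "contrast", "log2fc", "padj"}
        missing = required - set(self.table.columns)
        if missing:
            raise ValueError(f"DE table missing columns: {sorted(missing)}")
        padj = self.table["padj"].dropna()
        if ((padj < 0) | (padj > 1)).any():
            raise ValueError("adjusted p values must lie in [0, 1]")


def genome_fraction(n_family: int, n_coding: int) -> float:
    """Family share of the protein-coding gene space, as a two-decimal
    percentage (half-up)."""
    if n_coding <= 0:
        raise ValueError("n_coding must be positive")
    return round_half_up(100.0 * n_family / n_coding, 2)


def chromosome_distribution(records: list[ProteinRecord]) -> pd.DataFrame:
    """Counts per chromosome plus subgenome marginals and a scaffold bucket.

    Rows whose chromosome starts with 'scaffold' (or is empty) land in the
    scaffold bucket; marginal rows are tagged in the ``level`` column and
    always sum to the record count.
    """
    rows = []
    per_chrom: dict[str, int] = {}
    per_sub: dict[str, int] = {}
    scaffold = 0
    for r in records:
        if not r.chromosome or r.chromosome.lower().startswith("scaffold"):
            scaffold += 1
            continue
        per_chrom[r.chromosome] = per_chrom.get(r.chromosome, 0) + 1
        per_sub[r.subgenome] = per_sub.get(r.subgenome, 0) + 1
    for chrom in sorted(per_chrom):
        rows.append({"level": "chromosome", "name": chrom, "count": per_chrom[chrom]})
    for sub in sorted(per_sub):
        rows.append({"level": "subgenome", "name": sub, "count": per_sub[sub]})
    rows.append({"level": "scaffold", "name": "scaffold", "count": scaffold})
    rows.append({"level": "total", "name": "all", "count": len(records)})
    return pd.DataFrame(rows, columns=["level", "name", "count"])


def select_representative(
    transcripts: list[tuple[str, DomainHit, int]]
) -> str | None:
    """Pick one transcript per gene: fewest consensus mismatches, then
    longest protein, then lexicographically smallest transcript id.

    ``transcripts`` holds (transcript_id, hit, protein_length); only accepted
    hits compete. Returns None (logged) when no transcript is accepted.
    """
    accepted = [t for t in transcripts if t[1] is not None and t[1].accepted]
    if not accepted:
        if transcripts:
            log.warning(
                "gene of transcript %s has no accepted domain; excluded",
                transcripts[0][0],
            )
        return None
    best = min(accepted, key=lambda t: (t[1].total_mismatches, -t[2], t[0]))
    return best[0]


def expression_filter(matrix: ExpressionMatrix, min_value: float | None = None) -> list[str]:
    """Genes whose maximum across samples meets the unit's inclusion rule:
    strictly greater than the threshold for TPM, at least the threshold for
    FPKM/RPKM."""
    threshold = DEFAULT_THRESHOLDS[matrix.unit] if min_value is None else min_value
    maxima = matrix.values.max(axis=1)
    if matrix.unit == "TPM":
        keep = maxima > threshold
    else:
        keep = maxima >= threshold
    return sorted(matrix.values.index[keep])


def select_degs(
    de_stats: DEStatsTable | pd.DataFrame,
    fc_cutoff: float = 2.0,
    padj_cutoff: float = 0.05,
) -> dict[str, dict[str, set[str]]]:
    """Differentially expressed genes per contrast, split by direction.

    Inclusion: |log2FC| >= log2(fc_cutoff) and adjusted p <= padj_cutoff
    (both boundaries inclusive). Genes without an adjusted p are skipped
    and logged.
    """
    import numpy as np

    table = de_stats.table if isinstance(de_stats, DEStatsTable) else DEStatsTable(de_stats).table
    lfc_cut = float(np.log2(fc_cutoff))
    out: dict[str, dict[str, set[str]]] = {}
    for row in table.itertuples(index=False):
        out.setdefault(row.contrast, {"up": set(), "down": set()})
        if pd.isna(row.padj):
            log.warning("gene %s in contrast %s has no adjusted p; skipped", row.gene, row.contrast)
            continue
        if abs(row.log2fc) >= lfc_cut and row.padj <= padj_cutoff:
            out[row.contrast]["up" if row.log2fc > 0 else "down"].add(row.gene)
    return out


REQUIRED_STAGES = (
    "table1",
    "pattern_distribution",
    "conservation",
    "chromosome",
    "expression_sets",
)


def assemble_report(stages: dict[str, pd.DataFrame], out_dir, config: dict) -> Path:
    """Write the report bundle: one TSV per stage, a YAML config snapshot and
    a run log. Identical inputs and config give byte-identical tables."""
    missing = [s for s in REQUIRED_STAGES if s not in stages]
    if missing:
        raise ValueError(f"missing mandatory stage outputs: {missing}")
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    for name in REQUIRED_STAGES:
        frame = stages[name]
        reset = frame.reset_index() if frame.index.name else frame
        rows = [list(reset.columns)] + reset.astype(str).values.tolist()
        write_table(rows, out / f"{name}.tsv")
    with open(out / "config.yaml", "w", encoding="utf-8") as fh:
        yaml.safe_dump(config, fh, sort_keys=True)
    log_lines = [f"stage {name}: {len(stages[name])} rows" for name in REQUIRED_STAGES]
    (out / "run.log").write_text("\n".join(log_lines) + "\n", encoding="utf-8")
    return out
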