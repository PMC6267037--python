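"""Readers and writers for the formats the pipeline touches.

Coordinate conventions, used everywhere in the package:

* GTF intervals are 1-based and closed (standard GTF 2.2).
* Protein residue positions are 1-based (position 13 of a domain is the
  thirteenth residue, matching the Glu-13 / Arg-16 residue-rule numbering).
* CDS-nucleotide coordinates are 1-based over the spliced coding sequence
  in transcription order; the stop codon is not part of the CDS.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import gffutils
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from ._util import GAP, PROTEIN_ALPHABET

log = logging.getLogger(__name__)

_META_KEYS = ("species", "chromosome", "subgenome")


@dataclass
class ProteinRecord:
    """A protein sequence with the family-analysis metadata carried in its
    FASTA header as ``key=value`` tokens."""

    id: str
    sequence: str
    species: str = ""
    chromosome: str = ""
    subgenome: str = "none"

    def __post_init__(self) -> None:
        self.sequence = self.sequence.upper()
        if not self.sequence:
            raise ValueError(f"empty sequence for protein {self.id!r}")
        bad = set(self.sequence) - PROTEIN_ALPHABET
        if bad:
            raise ValueError(
                f"protein {self.id!r} contains characters outside the "
                f"amino-acid alphabet: {sorted(bad)}"
            )
        if self.subgenome not in {"A", "B", "D", "none"}:
            raise ValueError(f"invalid subgenome {self.subgenome!r} for {self.id!r}")


@dataclass
class GeneModel:
    """One transcript of a gene: exon and CDS intervals in transcription order.

    ``exons`` are (start, end) genomic intervals; ``cds`` are
    (start, end, frame) with the GTF frame column (bases to skip to reach the
    first complete codon). Transcription order means ascending genomic
    coordinates on the plus strand and descending on the minus strand.
    """

    gene_id: str
    transcript_id: str
    strand: str
    chromosome: str
    exons: list[tuple[int, int]] = field(default_factory=list)
    cds: list[tuple[int, int, int]] = field(default_factory=list)

    def __post_init__(self) -> None:
        if self.strand not in {"+", "-"}:
            raise ValueError(
                f"unknown strand {self.strand!r} for transcript {self.transcript_id!r}"
            )

    @property
    def cds_length(self) -> int:
        return sum(e - s + 1 for s, e, _ in self.cds)

    def validate(self) -> None:
        starts = [s for s, _ in self.exons]
        ordered = starts == sorted(starts) if self.strand == "+" else starts == sorted(starts, reverse=True)
        if not ordered:
            raise ValueError(f"exons of {self.transcript_id!r} not in transcription order")
        genomic = sorted(self.exons)
        for (s1, e1), (s2, e2) in zip(genomic, genomic[1:]):
            if s2 <= e1:
                raise ValueError(f"overlapping exons in {self.transcript_id!r}")
        for s, e, _ in self.cds:
            if not any(xs <= s and e <= xe for xs, xe in self.exons):
                raise ValueError(
                    f"CDS interval ({s}, {e}) of {self.transcript_id!r} "
                    "not contained in any exon"
                )
        if not self.cds:
            raise ValueError(f"transcript {self.transcript_id!r} has no CDS")
        if (self.cds_length - self.cds[0][2]) % 3 != 0:
            raise ValueError(
                f"CDS length of {self.transcript_id!r} not divisible by 3 "
                "after frame adjustment"
            )


@dataclass
class AlignmentBlock:
    """A rectangular multiple alignment: (id, gapped sequence) rows."""

    rows: list[tuple[str, str]]

    def __post_init__(self) -> None:
        if not self.rows:
            raise ValueError("alignment has no rows")
        width = len(self.rows[0][1])
        for rid, seq in self.rows:
            if len(seq) != width:
                raise ValueError(
                    f"ragged alignment: row {rid!r} has length {len(seq)}, "
                    f"expected {width}"
                )
            ungapped = set(seq.upper().replace(GAP, ""))
            if ungapped - PROTEIN_ALPHABET:
                raise ValueError(f"row {rid!r} contains non-amino-acid characters")
            if not ungapped:
                log.warning("alignment row %r is all gaps", rid)
        self.rows = [(rid, seq.upper()) for rid, seq in self.rows]

    @property
    def length(self) -> int:
        return len(self.rows[0][1])

    @property
    def n_rows(self) -> int:
        return len(self.rows)


# ---------------------------------------------------------------------------
# FASTA

def read_fasta(path) -> list[ProteinRecord]:
    """Read protein FASTA; header tokens of the form ``key=value`` populate
    the species/chromosome/subgenome metadata fields."""
    records: list[ProteinRecord] = []
    seen: set[str] = set()
    for rec in SeqIO.parse(str(path), "fasta"):
        if rec.id in seen:
            raise ValueError(f"duplicate FASTA id {rec.id!r}")
        seen.add(rec.id)
        meta = {}
        for token in rec.description.split()[1:]:
            if "=" in token:
                key, _, value = token.partition("=")
                if key in _META_KEYS:
                    meta[key] = value
        records.append(ProteinRecord(id=rec.id, sequence=str(rec.seq), **meta))
    if not records:
        raise ValueError(f"no FASTA records in {path}")
    return records


def write_fasta(records: list[ProteinRecord], path) -> None:
    out = []
    for r in records:
        desc = []
        if r.species:
            desc.append(f"species={r.species}")
        if r.chromosome:
            desc.append(f"chromosome={r.chromosome}")
        if r.subgenome != "none":
            desc.append(f"subgenome={r.subgenome}")
        out.append(SeqRecord(Seq(r.sequence), id=r.id, description=" ".join(desc)))
    SeqIO.write(out, str(path), "fasta")


def write_nucleotide_fasta(sequences: dict[str, str], path) -> None:
    out = [SeqRecord(Seq(s), id=name, description="") for name, s in sequences.items()]
    SeqIO.write(out, str(path), "fasta")


def read_nucleotide_fasta(path) -> dict[str, str]:
    return {rec.id: str(rec.seq).upper() for rec in SeqIO.parse(str(path), "fasta")}


# ---------------------------------------------------------------------------
# GTF

def read_gtf(path) -> list[GeneModel]:
    """Read exon/CDS features from a GTF 2.2 file into one GeneModel per
    transcript. Multi-transcript genes keep all transcripts; representative
    selection happens downstream."""
    db = gffutils.create_db(
        str(path),
        ":memory:",
        force=True,
        keep_order=True,
        disable_infer_genes=True,
        disable_infer_transcripts=True,
    )
    transcripts: dict[str, GeneModel] = {}
    order: list[str] = []
    any_cds = False
    for feature in db.all_features():
        if feature.featuretype not in {"exon", "CDS"}:
            continue
        tid = feature.attributes["transcript_id"][0]
        gid = feature.attributes["gene_id"][0]
        if tid not in transcripts:
            transcripts[tid] = GeneModel(
                gene_id=gid,
                transcript_id=tid,
                strand=feature.strand,
                chromosome=feature.seqid,
            )
            order.append(tid)
        model = transcripts[tid]
        if feature.featuretype == "exon":
            model.exons.append((feature.start, feature.end))
        else:
            any_cds = True
            frame = int(feature.frame) if feature.frame in {"0", "1", "2"} else 0
            model.cds.append((feature.start, feature.end, frame))
    if not transcripts:
        raise ValueError(f"no exon/CDS features in {path}")
    if not any_cds:
        raise ValueError(f"GTF {path} has exon features but no CDS features")
    models = []
    for tid in order:
        model = transcripts[tid]
        reverse = model.strand == "-"
        model.exons.sort(key=lambda iv: iv[0], reverse=reverse)
        model.cds.sort(key=lambda iv: iv[0], reverse=reverse)
        model.validate()
        models.append(model)
    return models


def write_gtf(models: list[GeneModel], path, source: str = "bhlhscan") -> None:
    lines = []
    for m in models:
        for s, e in sorted(m.exons):
            lines.append(_gtf_line(m, "exon", s, e, ".", source))
        frames = {(s, e): f for s, e, f in m.cds}
        for s, e in sorted(frames):
            lines.append(_gtf_line(m, "CDS", s, e, str(frames[(s, e)]), source))
    with open(path, "w", encoding="utf-8") as fh:
        fh.write("\n".join(lines) + "\n")


def _gtf_line(m: GeneModel, feature: str, start: int, end: int, frame: str, source: str) -> str:
    attrs = f'gene_id "{m.gene_id}"; transcript_id "{m.transcript_id}";'
    return "\t".join(
        [m.chromosome, source, feature, str(start), str(end), ".", m.strand, frame, attrs]
    )


# ---------------------------------------------------------------------------
# Alignments

def read_alignment(path) -> AlignmentBlock:
    rows = [(rec.id, str(rec.seq)) for rec in SeqIO.parse(str(path), "fasta")]
    return AlignmentBlock(rows=rows)


def write_alignment(block: AlignmentBlock, path) -> None:
    out = [SeqRecord(Seq(seq), id=rid, description="") for rid, seq in block.rows]
    SeqIO.write(out, str(path), "fasta")


# ---------------------------------------------------------------------------
# Tables

def write_table(rows: list[list], path, format: str = "tsv") -> None:
    """Write a rectangular table (first row = header) as UTF-8 TSV/CSV with a
    trailing newline. Raises on ragged rows."""
    if format not in {"tsv", "csv"}:
        raise ValueError(f"unsupported table format {format!r}")
    sep = "\t" if format == "tsv" else ","
    if not rows:
        raise ValueError("table needs at least a header row")
    width = len(rows[0])
    for i, row in enumerate(rows):
        if len(row) != width:
            raise ValueError(f"ragged table: row {i} has {len(row)} cells, expected {width}")
    with open(path, "w", encoding="utf-8", newline="\n") as fh:
        for row in rows:
            fh.write(sep.join(str(cell) for cell in row) + "\n")


def read_table(path, format: str = "tsv") -> list[list[str]]:
    sep = "\t" if format == "tsv" else ","
    with open(path, encoding="utf-8") as fh:
        return [line.rstrip("\n").split(sep) for line in fh if line.strip()]
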