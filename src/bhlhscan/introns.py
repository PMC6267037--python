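"""Intron positions and phases within the domain coding region.

Mapping convention: for an intron sitting after ``c`` spliced-CDS
nucleotides, let ``d = c - domain_cds_start + 1`` be the number of
domain-coding nucleotides upstream of the intron. The intron lies within the
domain coding region when ``1 <= d <= 3 * domain_length``; its interrupted
codon is ``ceil(d / 3)`` and its phase is ``d mod 3`` (phase 0 = exactly
between codons, after the named codon). Traversal is in transcription order,
so plus and minus strands map identically.

Recurring (position, phase) signatures across a family are collapsed into a
pattern registry: signatures are normalized onto a 60-residue domain scale
and merged when every intron pairs within a positional tolerance with equal
phase; labels (A, B, C, ...) are issued in first-encounter order over
lexicographically sorted gene ids, with a reserved label for intronless
domains.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import pandas as pd
import yaml
from sklearn.base import BaseEstimator

from ._util import percentage
from .io import GeneModel
from .scan import DomainHit

INTRONLESS_LABEL = "intronless"
NORMALIZED_SCALE = 60


@dataclass(frozen=True)
class IntronEvent:
    """One intron projected into domain coordinates."""

    domain_codon: int  # 1-based amino-acid position within the domain
    phase: int  # nucleotides of that codon upstream of the intron (0 = between codons)
    region: str

    def __post_init__(self) -> None:
        if self.phase not in {0, 1, 2}:
            raise ValueError(f"invalid intron phase {self.phase}")
        if self.domain_codon < 1:
            raise ValueError(f"invalid domain codon {self.domain_codon}")


@dataclass
class IntronPattern:
    """Ordered signature of (position on the 60-residue scale, phase) plus
    its registry label."""

    signature: tuple[tuple[float, int], ...]
    label: str

    @property
    def n_introns(self) -> int:
        return len(self.signature)


def domain_cds_interval(gene: GeneModel, hit: DomainHit) -> tuple[int, int]:
    """1-based spliced-CDS nucleotide interval coding for the domain."""
    start = 3 * (hit.start - 1) + 1
    end = 3 * hit.end
    if end > gene.cds_length:
        raise ValueError(
            f"domain of {hit.protein_id} ends at CDS position {end} but the "
            f"CDS of {gene.transcript_id} has only {gene.cds_length} nt"
        )
    return start, end


def cds_junction_offsets(gene: GeneModel) -> list[int]:
    """Spliced-CDS nucleotide counts upstream of each intron between
    consecutive CDS-bearing exons, in transcription order."""
    offsets = []
    cumulative = 0
    for s, e, _ in gene.cds[:-1]:
        cumulative += e - s + 1
        offsets.append(cumulative)
    return offsets


def map_introns_to_domain(gene: GeneModel, hit: DomainHit) -> list[IntronEvent]:
    """Project the gene's introns into domain-relative codon/phase events;
    introns outside the domain coding region are ignored."""
    dom_start, _ = domain_cds_interval(gene, hit)
    length = hit.length
    events = []
    for c in cds_junction_offsets(gene):
        d = c - dom_start + 1
        if not 1 <= d <= 3 * length:
            continue
        codon = math.ceil(d / 3)
        phase = d % 3
        # protein coordinate of the interrupted codon, for region lookup
        protein_pos = hit.start + codon - 1
        region = next(
            r for r, (s, e) in hit.region_spans.items() if s <= protein_pos <= e
        )
        events.append(IntronEvent(domain_codon=codon, phase=phase, region=region))
    return events


def normalize_signature(
    events: list[IntronEvent], domain_length: int
) -> tuple[tuple[float, int], ...]:
    """Rescale codon positions to the 60-residue reference scale so domains
    of different loop lengths can share a pattern."""
    return tuple(
        (round(e.domain_codon * NORMALIZED_SCALE / domain_length, 2), e.phase)
        for e in events
    )


class IntronPatternRegistry(BaseEstimator):
    """First-encounter pattern registry.

    fit(X) over ``{gene_id: (events, domain_length)}`` assigns labels in
    deterministic order (gene ids sorted lexicographically); transform maps
    event lists to labels, registering unseen signatures. Two signatures
    match when they have the same intron count, equal phases, and positions
    within ``tolerance`` residues on the 60-residue scale.
    """

    def __init__(self, tolerance: float = 2.0):
        self.tolerance = tolerance

    def _ensure_state(self) -> None:
        if not hasattr(self, "entries_"):
            self.entries_: list[tuple[tuple[tuple[float, int], ...], str]] = []
            self.n_labels_ = 0

    def _next_label(self) -> str:
        n = self.n_labels_
        label = ""
        while True:
            label = chr(ord("A") + n % 26) + label
            n = n // 26 - 1
            if n < 0:
                break
        self.n_labels_ += 1
        return label

    def _match(self, signature: tuple[tuple[float, int], ...]) -> str | None:
        for entry_sig, label in self.entries_:
            if len(entry_sig) != len(signature):
                continue
            ok = all(
                abs(p1 - p2) <= self.tolerance and f1 == f2
                for (p1, f1), (p2, f2) in zip(entry_sig, signature)
            )
            if ok:
                return label
        return None

    def assign(self, events: list[IntronEvent], domain_length: int = NORMALIZED_SCALE) -> IntronPattern:
        """Label one gene's events, registering a new pattern if needed."""
        self._ensure_state()
        if not events:
            return IntronPattern(signature=(), label=INTRONLESS_LABEL)
        signature = normalize_signature(events, domain_length)
        label = self._match(signature)
        if label is None:
            label = self._next_label()
            self.entries_.append((signature, label))
        return IntronPattern(signature=signature, label=label)

    def fit(self, X: dict[str, tuple[list[IntronEvent], int]], y=None):
        self._ensure_state()
        for gene_id in sorted(X):
            self.assign(*X[gene_id])
        return self

    def transform(self, X: dict[str, tuple[list[IntronEvent], int]]) -> dict[str, IntronPattern]:
        self._ensure_state()
        return {gene_id: self.assign(*X[gene_id]) for gene_id in sorted(X)}

    def fit_transform(self, X, y=None) -> dict[str, IntronPattern]:
        return self.fit(X).transform(X)

    # -- persistence -------------------------------------------------------
    def to_dict(self) -> dict:
        self._ensure_state()
        return {
            "tolerance": self.tolerance,
            "patterns": [
                {"label": label, "signature": [[p, f] for p, f in sig]}
                for sig, label in self.entries_
            ],
        }

    def save(self, path) -> None:
        with open(path, "w", encoding="utf-8") as fh:
            yaml.safe_dump(self.to_dict(), fh, sort_keys=False)

    @classmethod
    def load(cls, path) -> "IntronPatternRegistry":
        with open(path, encoding="utf-8") as fh:
            data = yaml.safe_load(fh)
        reg = cls(tolerance=data["tolerance"])
        reg._ensure_state()
        for entry in data["patterns"]:
            reg.entries_.append(
                (tuple((float(p), int(f)) for p, f in entry["signature"]), entry["label"])
            )
        reg.n_labels_ = len(reg.entries_)
        return reg


def assign_pattern(
    events: list[IntronEvent],
    registry: IntronPatternRegistry,
    domain_length: int = NORMALIZED_SCALE,
) -> IntronPattern:
    """Thin wrapper over :meth:`IntronPatternRegistry.assign`."""
    return registry.assign(events, domain_length)


def signature_of(pattern: IntronPattern) -> str:
    """Human-readable form of a normalized signature, e.g. ``35.0:0,50.5:1``."""
    if not pattern.signature:
        return "-"
    return ",".join(f"{pos:g}:{phase}" for pos, phase in pattern.signature)


def pattern_distribution(
    patterns: dict[str, IntronPattern], grouping: dict[str, str]
) -> pd.DataFrame:
    """Count and percentage of genes displaying each pattern, per group
    (species or subfamily); percentages are within-group, two decimals."""
    rows = []
    genes_by_group: dict[str, list[str]] = {}
    for gene_id in patterns:
        genes_by_group.setdefault(grouping[gene_id], []).append(gene_id)
    for group in sorted(genes_by_group):
        genes = genes_by_group[group]
        counts: dict[str, int] = {}
        for g in genes:
            counts[patterns[g].label] = counts.get(patterns[g].label, 0) + 1
        for label in sorted(counts):
            rows.append(
                {
                    "pattern": label,
                    "group": group,
                    "count": counts[label],
                    "percentage": percentage(counts[label], len(genes)),
                }
            )
    return pd.DataFrame(rows, columns=["pattern", "group", "count", "percentage"])


def gene_structure_stats(genes: list[GeneModel]) -> pd.DataFrame:
    """Per-transcript exon count, intronless flag, and the fraction of
    internal CDS exons that are phase-zero symmetric (both flanking introns
    phase 0)."""
    rows = []
    for gene in genes:
        phases = [c % 3 for c in cds_junction_offsets(gene)]
        internal = max(len(gene.cds) - 2, 0)
        symmetric = sum(
            1 for i in range(1, len(gene.cds) - 1)
            if phases[i - 1] == 0 and phases[i] == 0
        )
        rows.append(
            {
                "transcript_id": gene.transcript_id,
                "exon_count": len(gene.exons),
                "intronless": len(gene.cds) == 1,
                "symmetric_phase0_fraction": (
                    round(symmetric / internal, 4) if internal else 0.0
                ),
            }
        )
    return pd.DataFrame(rows, columns=["transcript_id", "exon_count", "intronless", "symmetric_phase0_fraction"])
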