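"""Column-wise conservation profiling of domain alignments.

Conservation here asks: in what fraction of the aligned domains does the
column's modal residue occur? By default the denominator counts every row
(gap-inclusive), so a mostly-gap column cannot be called conserved in at
least 50% of the domains; the gap-excluded variant used when *picking* the
consensus residue for scanning is available behind a flag.
"""

from __future__ import annotations

from ._util import GAP
from .io import AlignmentBlock
from .scan import RegionTemplate, build_consensus


def column_conservation(alignment: AlignmentBlock, gap_inclusive: bool = True) -> list[float]:
    """Per-column fraction of rows carrying the modal non-gap residue."""
    if alignment.n_rows < 2:
        raise ValueError("conservation needs at least 2 alignment rows")
    fractions = []
    for i in range(alignment.length):
        counts: dict[str, int] = {}
        for _, seq in alignment.rows:
            ch = seq[i]
            if ch != GAP:
                counts[ch] = counts.get(ch, 0) + 1
        if not counts:
            fractions.append(0.0)
            continue
        denom = alignment.n_rows if gap_inclusive else sum(counts.values())
        fractions.append(max(counts.values()) / denom)
    return fractions


def conserved_positions(
    alignment: AlignmentBlock, threshold: float = 0.5, gap_inclusive: bool = True
) -> list[int]:
    """1-based column indices whose conservation fraction meets the threshold."""
    fractions = column_conservation(alignment, gap_inclusive)
    return [i + 1 for i, f in enumerate(fractions) if f >= threshold]


def region_conservation_summary(
    alignment: AlignmentBlock,
    region_template: RegionTemplate | None = None,
    threshold: float = 0.5,
    gap_inclusive: bool = True,
) -> dict[str, int]:
    """Bucket the conserved positions by domain region.

    Columns are mapped to the ungapped consensus coordinate (all-gap columns
    carry no coordinate and can never be conserved); the region template is
    interpreted on that coordinate.
    """
    profile = build_consensus(alignment, region_template=region_template)
    tpl = region_template or profile.region_template
    # ungapped consensus coordinate per column (None for sentinel columns)
    coord = 0
    column_coord: list[int | None] = []
    for res, _ in profile.columns:
        if res == GAP:
            column_coord.append(None)
        else:
            coord += 1
            column_coord.append(coord)
    counts = {name: 0 for name in ("basic", "helix1", "loop", "helix2")}
    for col in conserved_positions(alignment, threshold, gap_inclusive):
        pos = column_coord[col - 1]
        if pos is None or pos > tpl.total:
            raise ValueError(f"conserved column {col} falls outside the region template")
        counts[tpl.region_of(pos)] += 1
    return counts
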