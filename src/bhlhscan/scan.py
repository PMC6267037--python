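"""Consensus-based bHLH domain detection.

The detector is deliberately simple and transparent: a seed multiple
alignment of known domains is collapsed to a per-column consensus (modal
residue plus conservation fraction); candidate placements in a query protein
are scored by counting mismatches against the consensus at the conserved
("consensus") positions only, and a placement is accepted when the total
mismatch count does not exceed a fixed budget (default 12). The loop between
the two helices is elastic: every loop length in a configurable range is
tried, surplus loop residues are not scored, and ties prefer loops closest
to the canonical six residues.

Domain architecture template (1-based domain coordinates)::

    basic   1 .. 17          DNA-contacting region, rich in Arg/Lys/His
    helix1  18 .. 32         first amphipathic helix
    loop    33 .. 32+loop    variable-length loop (mode 6)
    helix2  remaining 22     second helix (dimerization)
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator

from ._util import GAP, percentage
from .io import AlignmentBlock, ProteinRecord

LOOP_MODE = 6
REGIONS = ("basic", "helix1", "loop", "helix2")


@dataclass(frozen=True)
class RegionTemplate:
    """Lengths of the four domain regions on the consensus coordinate.
    ``loop`` is the loop length of the consensus itself; queries may use any
    loop length in the scanner's range."""

    basic: int = 17
    helix1: int = 15
    loop: int = 6
    helix2: int = 22

    @property
    def total(self) -> int:
        return self.basic + self.helix1 + self.loop + self.helix2

    def spans(self, loop_length: int | None = None) -> dict[str, tuple[int, int]]:
        """1-based inclusive spans for a domain with the given loop length."""
        loop = self.loop if loop_length is None else loop_length
        b = self.basic
        h1 = self.helix1
        return {
            "basic": (1, b),
            "helix1": (b + 1, b + h1),
            "loop": (b + h1 + 1, b + h1 + loop),
            "helix2": (b + h1 + loop + 1, b + h1 + loop + self.helix2),
        }

    def region_of(self, position: int, loop_length: int | None = None) -> str:
        for name, (s, e) in self.spans(loop_length).items():
            if s <= position <= e:
                return name
        raise ValueError(f"position {position} outside domain template")


@dataclass
class ConsensusProfile:
    """Per-column consensus of a seed domain alignment.

    ``columns`` holds (modal residue, conservation fraction) per alignment
    column; all-gap columns carry the sentinel residue '-' with fraction 0.
    ``consensus_positions`` (1-based) are the columns whose fraction meets the
    threshold; only those columns contribute to mismatch counting.
    """

    columns: list[tuple[str, float]]
    threshold: float = 0.5
    region_template: RegionTemplate = field(default_factory=RegionTemplate)

    def __post_init__(self) -> None:
        for res, frac in self.columns:
            if not 0.0 <= frac <= 1.0:
                raise ValueError(f"conservation fraction {frac} outside [0, 1]")
        if self.region_template.total != len(self.columns):
            raise ValueError(
                f"region template covers {self.region_template.total} positions "
                f"but the profile has {len(self.columns)} columns"
            )

    @property
    def length(self) -> int:
        return len(self.columns)

    @property
    def consensus_positions(self) -> list[int]:
        return [
            i + 1
            for i, (res, frac) in enumerate(self.columns)
            if res != GAP and frac >= self.threshold
        ]

    @property
    def consensus_sequence(self) -> str:
        return "".join(res for res, _ in self.columns)


@dataclass
class DomainHit:
    """A located bHLH domain in one protein (1-based inclusive coordinates)."""

    protein_id: str
    start: int
    end: int
    loop_length: int
    region_spans: dict[str, tuple[int, int]]
    mismatches_by_region: dict[str, int]
    accepted: bool = False

    @property
    def total_mismatches(self) -> int:
        return sum(self.mismatches_by_region.values())

    @property
    def length(self) -> int:
        return self.end - self.start + 1

    def domain_sequence(self, protein_sequence: str) -> str:
        return protein_sequence[self.start - 1 : self.end]


def build_consensus(
    alignment: AlignmentBlock,
    threshold: float = 0.5,
    region_template: RegionTemplate | None = None,
) -> ConsensusProfile:
    """Collapse a seed alignment to a consensus profile.

    Per column the modal non-gap residue is taken over a gap-excluded
    denominator (number of non-gap characters in the column); ties are broken
    alphabetically. An all-gap column is retained with the sentinel residue
    and fraction 0 so coordinates stay aligned.
    """
    if alignment.n_rows < 2:
        raise ValueError("consensus needs at least 2 alignment rows")
    columns: list[tuple[str, float]] = []
    for i in range(alignment.length):
        counts: dict[str, int] = {}
        for _, seq in alignment.rows:
            ch = seq[i]
            if ch != GAP:
                counts[ch] = counts.get(ch, 0) + 1
        if not counts:
            columns.append((GAP, 0.0))
            continue
        top = max(counts.values())
        residue = min(ch for ch, n in counts.items() if n == top)
        columns.append((residue, top / sum(counts.values())))
    if region_template is None:
        loop = len(columns) - (RegionTemplate().total - RegionTemplate().loop)
        if loop < 1:
            raise ValueError(
                f"alignment of {len(columns)} columns is too short for the "
                "default 17/15/loop/22 region template"
            )
        region_template = RegionTemplate(loop=loop)
    return ConsensusProfile(columns=columns, threshold=threshold, region_template=region_template)


def _scoring_arrays(profile: ConsensusProfile, loop_length: int):
    """(offsets, residues) of the consensus positions counted for a candidate
    with the given loop length. Offsets are 0-based from the domain start in
    the query; consensus loop positions beyond min(consensus loop, candidate
    loop) are not counted, and query loop residues beyond the consensus loop
    are never scored."""
    tpl = profile.region_template
    b, h1 = tpl.basic, tpl.helix1
    offsets, residues = [], []
    for pos in profile.consensus_positions:
        res = profile.columns[pos - 1][0]
        if pos <= b + h1:
            offsets.append(pos - 1)
        elif pos <= b + h1 + tpl.loop:
            j = pos - (b + h1)  # 1-based index within the consensus loop
            if j > min(tpl.loop, loop_length):
                continue
            offsets.append(b + h1 + j - 1)
        else:
            j = pos - (b + h1 + tpl.loop)  # 1-based index within helix2
            offsets.append(b + h1 + loop_length + j - 1)
        residues.append(res)
    return np.asarray(offsets, dtype=np.intp), np.frombuffer(
        "".join(residues).encode("ascii"), dtype=np.uint8
    )


def locate_domain(
    protein: ProteinRecord | str,
    profile: ConsensusProfile,
    loop_range: tuple[int, int] = (5, 15),
) -> DomainHit | None:
    """Exhaustively scan all (start offset, loop length) placements and return
    the one minimizing total mismatches at consensus positions.

    Ties are broken by smaller loop deviation from the canonical six residues,
    then smaller start, then smaller loop length. Returns None when the
    protein is shorter than the minimal domain length. 'X' never matches.
    """
    if isinstance(protein, ProteinRecord):
        pid, seq = protein.id, protein.sequence
    else:
        pid, seq = "query", protein.upper()
    tpl = profile.region_template
    fixed = tpl.basic + tpl.helix1 + tpl.helix2
    arr = np.frombuffer(seq.encode("ascii"), dtype=np.uint8)
    x_code = ord("X")

    best = None  # (total, |loop-6|, start0, loop)
    for loop in range(loop_range[0], loop_range[1] + 1):
        length = fixed + loop
        n_starts = len(seq) - length + 1
        if n_starts < 1:
            continue
        offsets, residues = _scoring_arrays(profile, loop)
        idx = np.arange(n_starts)[:, None] + offsets[None, :]
        window = arr[idx]
        mism = ((window != residues) | (window == x_code)).sum(axis=1)
        start0 = int(np.argmin(mism))
        key = (int(mism[start0]), abs(loop - LOOP_MODE), start0, loop)
        if best is None or key < best:
            best = key
    if best is None:
        return None

    total, _, start0, loop = best
    start = start0 + 1
    spans01 = profile.region_template.spans(loop)
    region_spans = {r: (start + s - 1, start + e - 1) for r, (s, e) in spans01.items()}
    offsets, residues = _scoring_arrays(profile, loop)
    by_region = {r: 0 for r in REGIONS}
    for off, res in zip(offsets, residues):
        ch = arr[start0 + off]
        if ch != res or ch == ord("X"):
            by_region[profile.region_template.region_of(int(off) + 1, loop)] += 1
    assert sum(by_region.values()) == total
    return DomainHit(
        protein_id=pid,
        start=start,
        end=start + fixed + loop - 1,
        loop_length=loop,
        region_spans=region_spans,
        mismatches_by_region=by_region,
    )


def accept_candidate(hit: DomainHit, max_mismatches: int = 12) -> bool:
    """Apply the low-stringency acceptance rule: a candidate passes when its
    total mismatch count from the consensus is at most ``max_mismatches``."""
    hit.accepted = hit.total_mismatches <= max_mismatches
    return hit.accepted


def _distribution(values: list[int], key_name: str) -> pd.DataFrame:
    if not values:
        return pd.DataFrame(columns=[key_name, "count", "percentage"])
    counts = pd.Series(values).value_counts().sort_index()
    total = int(counts.sum())
    return pd.DataFrame(
        {
            key_name: counts.index.to_numpy(),
            "count": counts.to_numpy(),
            "percentage": [percentage(int(c), total) for c in counts],
        }
    )


def domain_length_distribution(hits: list[DomainHit]) -> pd.DataFrame:
    """Length histogram of accepted domains with two-decimal percentages."""
    return _distribution([h.length for h in hits], "length")


def loop_length_distribution(hits: list[DomainHit]) -> pd.DataFrame:
    return _distribution([h.loop_length for h in hits], "loop_length")


class ConsensusDomainScanner(BaseEstimator):
    """Estimator wrapper around the consensus scan.

    fit(X) takes a seed :class:`AlignmentBlock` and builds the consensus
    profile; predict(X) takes protein records (or plain sequences) and returns
    one :class:`DomainHit` or None per protein, with the acceptance flag set
    from ``max_mismatches``.
    """

    def __init__(
        self,
        threshold: float = 0.5,
        max_mismatches: int = 12,
        loop_range: tuple[int, int] = (5, 15),
        region_template: RegionTemplate | None = None,
    ):
        self.threshold = threshold
        self.max_mismatches = max_mismatches
        self.loop_range = loop_range
        self.region_template = region_template

    def fit(self, X: AlignmentBlock, y=None):
        self.profile_ = build_consensus(X, self.threshold, self.region_template)
        self.consensus_positions_ = self.profile_.consensus_positions
        return self

    def predict(self, X: list[ProteinRecord | str]) -> list[DomainHit | None]:
        if not hasattr(self, "profile_"):
            raise RuntimeError("ConsensusDomainScanner is not fitted")
        hits = []
        for protein in X:
            hit = locate_domain(protein, self.profile_, self.loop_range)
            if hit is not None:
                accept_candidate(hit, self.max_mismatches)
            hits.append(hit)
        return hits
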