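"""Distinct 5'/3'-end calling and primary-vs-processed labelling.

The rule: a position within the first two bases of a contig (strand-aware) is
a distinct 5'-end when more than 5 reads share it; any other position
additionally requires the shared-end read count to reach at least 10% of the
contig's mean read coverage.  Symmetric rules apply to 3'-ends.  Primary
labels come from comparing the primary-enriched (s1) and processed-enriched
(s2) libraries: a 5'-end distinct in s1 is primary; one found only in s2 is
processed.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .coverage import Contig, CoverageTrack
from .types import SAMPLE_S1, SAMPLE_S2

MIN_END_READS = 5       # "more than 5 reads" -> strictly greater, i.e. >= 6
MEAN_FRACTION = 0.10    # "at least 10% of the mean number of reads covering the contig"
EDGE_BASES = 2          # "within the first two bases of a contig"
FLANK = 2               # ends are reported within contig +- 2 nt


def _category(n: int) -> str:
    return {0: "0", 1: "1", 2: "2"}.get(n, "m")


@dataclass(frozen=True)
class EndCall:
    position: int
    read_count: int
    samples_supporting: frozenset = frozenset()
    is_primary: bool | None = None


@dataclass
class TranscriptEnds:
    contig_id: str
    replicon: str
    strand: str
    five_prime: list[EndCall] = field(default_factory=list)
    three_prime: list[EndCall] = field(default_factory=list)

    @property
    def end_category_5(self) -> str:
        return _category(len(self.five_prime))

    @property
    def end_category_3(self) -> str:
        return _category(len(self.three_prime))

    def primary_positions(self) -> list[int]:
        return [e.position for e in self.five_prime if e.is_primary]


def _distinct_positions(counts: np.ndarray, lo: int, hi: int,
                        edge: tuple[int, int], mean_depth: float,
                        threshold: int = MIN_END_READS,
                        mean_fraction: float = MEAN_FRACTION) -> list[tuple[int, int]]:
    """1-based (position, count) calls in [lo, hi]; ``edge`` is the inclusive
    1-based range counting as the contig's first two bases."""
    out = []
    for pos in range(lo, hi + 1):
        n = int(counts[pos - 1])
        if n <= threshold:
            continue
        if edge[0] <= pos <= edge[1] or n >= mean_fraction * mean_depth:
            out.append((pos, n))
    return out


def call_distinct_ends(contig: Contig, track: CoverageTrack,
                       samples: tuple[str, ...] = (SAMPLE_S1, SAMPLE_S2),
                       merge_radius: int = 0) -> TranscriptEnds:
    """Distinct ends of one contig from the given samples' start/end counts.

    ``merge_radius`` > 0 merges calls closer than the radius into the
    best-supported one (reporting aid; default keeps ends separate since
    one-to-two-nt TSS scatter is a real phenomenon).
    """
    if contig.replicon not in track.lengths:
        raise ValueError(f"contig {contig.contig_id}: replicon "
                         f"{contig.replicon!r} not in track")
    n = track.lengths[contig.replicon]
    lo = max(1, contig.start - FLANK)
    hi = min(n, contig.end + FLANK)
    depth = track.pooled(contig.replicon, contig.strand, samples)
    mean_depth = float(depth[contig.start - 1:contig.end].mean())
    starts5 = track.pooled(contig.replicon, contig.strand, samples, "starts5")
    ends3 = track.pooled(contig.replicon, contig.strand, samples, "ends3")
    if contig.strand == "+":
        edge5 = (contig.start, contig.start + EDGE_BASES - 1)
        edge3 = (contig.end - EDGE_BASES + 1, contig.end)
    else:
        edge5 = (contig.end - EDGE_BASES + 1, contig.end)
        edge3 = (contig.start, contig.start + EDGE_BASES - 1)
    support = frozenset(s for s in samples
                        if track.array(contig.replicon, contig.strand, s)
                        [contig.start - 1:contig.end].any())
    five = [EndCall(p, c, support) for p, c in
            _distinct_positions(starts5, lo, hi, edge5, mean_depth)]
    three = [EndCall(p, c, support) for p, c in
             _distinct_positions(ends3, lo, hi, edge3, mean_depth)]
    if merge_radius > 0:
        five = _merge(five, merge_radius)
        three = _merge(three, merge_radius)
    return TranscriptEnds(contig.contig_id, contig.replicon, contig.strand,
                          five, three)


def _merge(calls: list[EndCall], radius: int) -> list[EndCall]:
    out: list[EndCall] = []
    for call in sorted(calls, key=lambda e: (-e.read_count, e.position)):
        if all(abs(call.position - kept.position) > radius for kept in out):
            out.append(call)
    return sorted(out, key=lambda e: e.position)


def label_primary(ends_s1: TranscriptEnds, ends_s2: TranscriptEnds) -> TranscriptEnds:
    """Merge per-sample end calls; a 5'-end is primary iff it is a distinct
    5'-end of the primary-enriched (s1) library."""
    if ends_s1.contig_id != ends_s2.contig_id:
        raise ValueError("end sets come from different contigs")

    def merged(calls1: list[EndCall], calls2: list[EndCall],
               flag_primary: bool) -> list[EndCall]:
        pos1 = {e.position: e for e in calls1}
        pos2 = {e.position: e for e in calls2}
        out = []
        for p in sorted(set(pos1) | set(pos2)):
            supp = frozenset((["s1"] if p in pos1 else [])
                             + (["s2"] if p in pos2 else []))
            count = max(pos1[p].read_count if p in pos1 else 0,
                        pos2[p].read_count if p in pos2 else 0)
            out.append(EndCall(p, count, supp,
                               (p in pos1) if flag_primary else None))
        return out

    return TranscriptEnds(
        ends_s1.contig_id, ends_s1.replicon, ends_s1.strand,
        merged(ends_s1.five_prime, ends_s2.five_prime, True),
        merged(ends_s1.three_prime, ends_s2.three_prime, False),
    )


def call_and_label(contig: Contig, track: CoverageTrack,
                   merge_radius: int = 0) -> TranscriptEnds:
    """Per-sample distinct ends + primary labels for one contig."""
    e1 = call_distinct_ends(contig, track, (SAMPLE_S1,), merge_radius)
    e2 = call_distinct_ends(contig, track, (SAMPLE_S2,), merge_radius)
    return label_primary(e1, e2)


def sample_support(contig: Contig, min_depth: float) -> str:
    """Table-2-style provenance of a contig: S1, S2 or S1&2 by which
    libraries reach the extension depth on their own."""
    s1 = contig.per_sample_depth.get(SAMPLE_S1, 0.0) >= min_depth
    s2 = contig.per_sample_depth.get(SAMPLE_S2, 0.0) >= min_depth
    if s1 and s2:
        return "S1&2"
    if s1:
        return "S1"
    if s2:
        return "S2"
    return "none"


def ends_summary(all_ends: list[TranscriptEnds], supports: dict[str, str],
                 classes: dict[str, str] | None = None):
    """Cross-tabulation of 5'-category x 3'-category x sample support
    (x class when given), as a tidy DataFrame."""
    import pandas as pd

    rows = []
    for te in all_ends:
        rows.append({
            "contig_id": te.contig_id,
            "class": (classes or {}).get(te.contig_id, "all"),
            "cat5": te.end_category_5,
            "cat3": te.end_category_3,
            "support": supports.get(te.contig_id, "none"),
        })
    df = pd.DataFrame(rows)
    if df.empty:
        return df
    return (df.groupby(["class", "cat5", "cat3", "support"])
            .size().rename("count").reset_index())
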