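"""Positional classification of contigs against the gene annotation.

Each called contig is placed relative to a model of a minimal transcription
unit (MTU): the CDS extended by an assumed 5'-UTR (60 nt) and 3'-UTR (20 nt).
Five classes result: trans-encoded sRNA (no MTU overlap on either strand),
cis-encoded antisense sRNA (opposite-strand MTU overlap, subtyped by the
overlapped part), mRNA leader (5'-end within 40 nt of the start codon, 3'-end
inside the ORF), sense sRNA (same-strand MTU overlap, four subtypes), and
whole-ORF transcripts.  Precedence orf_cover > leader > sense > antisense >
trans resolves multi-gene ambiguity; same-strand relations win over antisense.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .coverage import Contig
from .types import EXCLUDED_KINDS, Gene, GeneAnnotation

CLASS_RANK = {"orf_cover": 0, "leader": 1, "sense": 2, "antisense": 3}


@dataclass
class ClassifierParams:
    utr5: int = 60
    utr3: int = 20
    leader_window: int = 40
    cluster_gap: int = 200

    def __post_init__(self) -> None:
        if min(self.utr5, self.utr3, self.leader_window, self.cluster_gap) < 0:
            raise ValueError("parameters must be >= 0")
        if self.leader_window > self.utr5:
            raise ValueError("leader_window must not exceed utr5")


@dataclass
class ClassifiedTranscript:
    contig_id: str
    rna_class: str
    subtype: str
    associated_genes: list[str] = field(default_factory=list)
    relation_notes: str = ""


def _mtu_interval(g: Gene, p: ClassifierParams) -> tuple[int, int]:
    if g.strand == "+":
        return g.start - p.utr5, g.end + p.utr3
    return g.start - p.utr3, g.end + p.utr5


def _overlaps(a0: int, a1: int, b0: int, b1: int) -> bool:
    return a0 <= b1 and b0 <= a1


def _orient(g: Gene, pos: int) -> int:
    """Gene-oriented offset of a genomic position (0 = first CDS base)."""
    return pos - g.start if g.strand == "+" else g.end - pos


def _same_strand_relation(contig: Contig, g: Gene,
                          p: ClassifierParams) -> tuple[str, str] | None:
    cds_len = len(g)
    off5 = _orient(g, contig.five_prime)
    off3 = _orient(g, contig.three_prime)
    # (1) contig covers the whole ORF
    if off5 <= 0 and off3 >= cds_len - 1:
        return ("orf_cover", "")
    # (2) mRNA leader: 5'-end within [-leader_window, +1] of the start codon,
    # 3'-end strictly inside the CDS
    if -p.leader_window <= off5 <= 1 and 0 < off3 < cds_len - 1:
        return ("leader", "")
    # (3) sense subtypes
    cds_overlap = _overlaps(min(off5, off3), max(off5, off3), 0, cds_len - 1)
    if -p.utr5 <= off5 <= -p.leader_window - 1 and 0 <= off3 <= cds_len - 1:
        return ("sense", "1")
    if 0 <= off5 and off3 <= cds_len - 1:
        return ("sense", "2")
    if cds_overlap and off3 >= cds_len:
        return ("sense", "3")
    if off5 >= cds_len:
        return ("sense", "4")
    # placements the published decision table leaves open: confined upstream
    # of the CDS -> 1 (5'-UTR region); anything else downstream -> 4
    if off3 < 0:
        return ("sense", "1")
    return ("sense", "4")


def _antisense_subtype(contig: Contig, g: Gene, p: ClassifierParams) -> str:
    if g.strand == "+":
        utr5_iv = (g.start - p.utr5, g.start - 1)
        utr3_iv = (g.end + 1, g.end + p.utr3)
    else:
        utr5_iv = (g.end + 1, g.end + p.utr5)
        utr3_iv = (g.start - p.utr3, g.start - 1)
    parts = set()
    if _overlaps(contig.start, contig.end, *utr5_iv):
        parts.add("1")
    if _overlaps(contig.start, contig.end, g.start, g.end):
        parts.add("2")
    if _overlaps(contig.start, contig.end, *utr3_iv):
        parts.add("3")
    if parts == {"1", "2"} or parts == {"1"}:
        return "1"
    if parts == {"2", "3"} or parts == {"3"}:
        return "3"
    if parts == {"2"}:
        return "2"
    return "1/3"   # spans both UTRs


def classify_contig(contig: Contig, annotation: GeneAnnotation,
                    params: ClassifierParams | None = None) -> ClassifiedTranscript:
    params = params or ClassifierParams()
    genes = [g for g in annotation.on_replicon(contig.replicon)
             if g.kind not in EXCLUDED_KINDS]
    relations: list[tuple[str, str, Gene]] = []
    notes = []
    for g in genes:
        mlo, mhi = _mtu_interval(g, params)
        if not _overlaps(contig.start, contig.end, mlo, mhi):
            continue
        if g.strand == contig.strand:
            rel = _same_strand_relation(contig, g, params)
            if rel is not None:
                relations.append((rel[0], rel[1], g))
        else:
            relations.append(("antisense",
                              _antisense_subtype(contig, g, params), g))
        if g.kind == "transposase":
            notes.append(f"transposable-element association: {g.gene_id}")

    if not relations:
        left = right = None
        for g in genes:
            if g.end < contig.start and (left is None or g.end > left.end):
                left = g
            if g.start > contig.end and (right is None or g.start < right.start):
                right = g
        both_anti = (left is not None and right is not None
                     and left.strand != contig.strand
                     and right.strand != contig.strand)
        return ClassifiedTranscript(contig.contig_id, "trans",
                                    "1" if both_anti else "2",
                                    [], "; ".join(notes))

    best = min(CLASS_RANK[r[0]] for r in relations)
    chosen = [r for r in relations if CLASS_RANK[r[0]] == best]
    cls = chosen[0][0]
    parts = sorted({x for _, s, _ in chosen if s for x in s.split("/")},
                   key=int)
    subtype = "/".join(parts)
    gene_ids = [g.gene_id for _, _, g in chosen]
    return ClassifiedTranscript(contig.contig_id, cls, subtype, gene_ids,
                                "; ".join(notes))


def filter_excluded(contigs: list[Contig],
                    annotation: GeneAnnotation) -> tuple[list[Contig], list[Contig]]:
    """Remove contigs overlapping rRNA/tRNA/repeat features before
    classification.  Returns (kept, removed)."""
    kept, removed = [], []
    for contig in contigs:
        hit = any(g.kind in EXCLUDED_KINDS
                  and _overlaps(contig.start, contig.end, g.start, g.end)
                  for g in annotation.on_replicon(contig.replicon))
        (removed if hit else kept).append(contig)
    return kept, removed


def find_clusters(transcripts: list[ClassifiedTranscript],
                  contigs: list[Contig],
                  params: ClassifierParams | None = None) -> list[list[str]]:
    """Single-linkage chains of classified contigs separated by less than
    ``cluster_gap`` nt (strand-agnostic); only clusters of size >= 2."""
    params = params or ClassifierParams()
    wanted = {t.contig_id for t in transcripts}
    pool = sorted((c for c in contigs if c.contig_id in wanted),
                  key=lambda c: (c.replicon, c.start))
    clusters: list[list[str]] = []
    current: list[Contig] = []
    for c in pool:
        if (current and c.replicon == current[-1].replicon
                and c.start - current[-1].end - 1 < params.cluster_gap):
            current.append(c)
        else:
            if len(current) >= 2:
                clusters.append([x.contig_id for x in current])
            current = [c]
    if len(current) >= 2:
        clusters.append([x.contig_id for x in current])
    return clusters


def summarize(transcripts: list[ClassifiedTranscript], contigs: list[Contig]):
    """Counts per (replicon, class, subtype) and per-class length statistics
    (min, Q1, median, mean, Q3, max; quartiles by linear interpolation)."""
    import pandas as pd

    by_id = {c.contig_id: c for c in contigs}
    rows = [{"replicon": by_id[t.contig_id].replicon,
             "class": t.rna_class, "subtype": t.subtype,
             "length": len(by_id[t.contig_id])}
            for t in transcripts if t.contig_id in by_id]
    df = pd.DataFrame(rows)
    if df.empty:
        return (pd.DataFrame(columns=["replicon", "class", "subtype", "count"]),
                pd.DataFrame(columns=["class", "n", "min", "q1", "median",
                                      "mean", "q3", "max"]))
    counts = (df.groupby(["replicon", "class", "subtype"])
              .size().rename("count").reset_index())
    stats = []
    for cls, sub in df.groupby("class"):
        lens = sub["length"].to_numpy(dtype=float)
        q1, med, q3 = np.percentile(lens, [25, 50, 75])
        stats.append({"class": cls, "n": len(lens), "min": lens.min(),
                      "q1": q1, "median": med, "mean": lens.mean(),
                      "q3": q3, "max": lens.max()})
    return counts, pd.DataFrame(stats)
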