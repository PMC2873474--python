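"""Per-strand coverage tracks and seed-and-extend contig calling.

A contig is called from a coverage seed: a maximal run of positions with
depth >= C that is at least L_min long, extended on either side as long as
depth >= c.  Contigs whose extended length exceeds L_max are retained but
flagged over-length (the size fractionation of the emulated protocol makes
transcripts above L_max unobservable, so such calls indicate synthetic
misconfiguration rather than biology) and are excluded from default reports.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .types import SAMPLE_S1, SAMPLE_S2, SAMPLE_TOTAL, Genome, ReadAlignment

UNSTRANDED = "."


@dataclass
class ContigCallerParams:
    """(L, C, c) of the seed-and-extend rule.

    Presets: 454-like libraries (50-350, 10, 5); short-read libraries
    (50, 5, 2) with no effective upper length bound.
    """

    L_min: int = 50
    L_max: int = 350
    C: int = 10
    c: int = 5

    def __post_init__(self) -> None:
        if not (0 < self.c <= self.C):
            raise ValueError("require 0 < c <= C")
        if not (0 < self.L_min <= self.L_max):
            raise ValueError("require 0 < L_min <= L_max")

    @classmethod
    def preset_454(cls) -> "ContigCallerParams":
        return cls(50, 350, 10, 5)

    @classmethod
    def preset_short_read(cls) -> "ContigCallerParams":
        return cls(50, 10**9, 5, 2)


@dataclass(frozen=True)
class Contig:
    contig_id: str
    replicon: str
    strand: str
    start: int
    end: int
    mean_depth: float
    per_sample_depth: dict
    seed_start: int
    seed_end: int
    over_length: bool = False

    def __len__(self) -> int:
        return self.end - self.start + 1

    @property
    def five_prime(self) -> int:
        return self.start if self.strand == "+" else self.end

    @property
    def three_prime(self) -> int:
        return self.end if self.strand == "+" else self.start


class CoverageTrack:
    """Depth and biological 5'/3'-end count arrays per (replicon, strand,
    sample).  Arrays are 0-indexed internally; position p maps to index p-1.
    Unstranded alignments are stored under pseudo-strand ``"."``."""

    def __init__(self, genome: Genome):
        self.lengths = genome.lengths()
        self._tracks: dict[tuple[str, str, str], dict[str, np.ndarray]] = {}

    def _get(self, replicon: str, strand: str, sample: str):
        key = (replicon, strand, sample)
        if key not in self._tracks:
            n = self.lengths[replicon]
            self._tracks[key] = {
                "depth": np.zeros(n, dtype=np.int64),
                "starts5": np.zeros(n, dtype=np.int64),
                "ends3": np.zeros(n, dtype=np.int64),
            }
        return self._tracks[key]

    def add(self, read: ReadAlignment) -> None:
        if read.replicon not in self.lengths:
            raise ValueError(f"read {read.read_id}: unknown replicon {read.replicon}")
        n = self.lengths[read.replicon]
        if read.start < 1 or read.end > n:
            raise ValueError(f"read {read.read_id}: outside replicon bounds")
        strand = read.strand if read.strand is not None else UNSTRANDED
        tr = self._get(read.replicon, strand, read.sample)
        tr["depth"][read.start - 1:read.end] += 1
        if strand == "-":
            # biological 5'-end is the higher coordinate on the minus strand
            tr["starts5"][read.end - 1] += 1
            tr["ends3"][read.start - 1] += 1
        else:
            tr["starts5"][read.start - 1] += 1
            tr["ends3"][read.end - 1] += 1

    def samples(self) -> list[str]:
        return sorted({k[2] for k in self._tracks})

    def array(self, replicon: str, strand: str, sample: str,
              which: str = "depth") -> np.ndarray:
        key = (replicon, strand, sample)
        if key in self._tracks:
            return self._tracks[key][which]
        return np.zeros(self.lengths[replicon], dtype=np.int64)

    def pooled(self, replicon: str, strand: str, samples, which: str = "depth",
               include_unstranded: bool = False) -> np.ndarray:
        out = np.zeros(self.lengths[replicon], dtype=np.int64)
        for s in samples:
            out += self.array(replicon, strand, s, which)
            if include_unstranded:
                out += self.array(replicon, UNSTRANDED, s, which)
        return out


def build_coverage(alignments: list[ReadAlignment], genome: Genome) -> CoverageTrack:
    track = CoverageTrack(genome)
    for read in alignments:
        track.add(read)
    return track


def _runs_at_least(depth: np.ndarray, threshold: int) -> list[tuple[int, int]]:
    """Maximal runs (0-based, inclusive) where depth >= threshold."""
    mask = depth >= threshold
    if not mask.any():
        return []
    d = np.diff(mask.astype(np.int8))
    starts = list(np.nonzero(d == 1)[0] + 1)
    ends = list(np.nonzero(d == -1)[0])
    if mask[0]:
        starts.insert(0, 0)
    if mask[-1]:
        ends.append(len(mask) - 1)
    return list(zip(starts, ends))


def call_contigs(track: CoverageTrack, params: ContigCallerParams,
                 pool_samples: bool = True,
                 samples: tuple[str, ...] | None = None,
                 include_unstranded: bool = False) -> list[Contig]:
    """Seed-and-extend contig calls, sorted by (replicon, strand, start).

    By default the primary- and processed-enriched libraries are pooled for
    depth; the unstranded total library contributes only when
    ``include_unstranded`` is set.  Per-sample mean depths are retained on
    each contig for reporting.
    """
    if samples is None:
        samples = (SAMPLE_S1, SAMPLE_S2) if pool_samples else (SAMPLE_S1,)
    contigs: list[Contig] = []
    n_id = 0
    for replicon in sorted(track.lengths):
        for strand in ("+", "-"):
            depth = track.pooled(replicon, strand, samples,
                                 include_unstranded=include_unstranded)
            if depth.max(initial=0) < params.C:
                continue
            ext_runs = _runs_at_least(depth, params.c)
            seed_runs = _runs_at_least(depth, params.C)
            si = 0
            for lo, hi in ext_runs:
                seed = None
                while si < len(seed_runs) and seed_runs[si][1] <= hi:
                    s0, s1 = seed_runs[si]
                    if s0 >= lo and seed is None and s1 - s0 + 1 >= params.L_min:
                        seed = (s0, s1)
                    si += 1
                if seed is None:
                    continue
                n_id += 1
                span = hi - lo + 1
                per_sample = {
                    s: float(track.pooled(replicon, strand, (s,),
                                          include_unstranded=include_unstranded
                                          )[lo:hi + 1].mean())
                    for s in samples}
                contigs.append(Contig(
                    contig_id=f"RC{n_id:05d}",
                    replicon=replicon,
                    strand=strand,
                    start=lo + 1,
                    end=hi + 1,
                    mean_depth=float(depth[lo:hi + 1].mean()),
                    per_sample_depth=per_sample,
                    seed_start=seed[0] + 1,
                    seed_end=seed[1] + 1,
                    over_length=span > params.L_max,
                ))
    return contigs


def reported(contigs: list[Contig]) -> list[Contig]:
    """Default report: over-length contigs excluded."""
    return [c for c in contigs if not c.over_length]
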