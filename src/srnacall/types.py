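"""Shared domain types for the sRNA discovery pipeline.

Coordinates are 1-based and inclusive throughout (GFF3/SAM convention);
BED/bedGraph conversion happens only at the I/O boundary.  A transcript's
``tss``/``end3`` are strand-aware biological ends: on the minus strand the
5'-end (TSS) is the *higher* genomic coordinate.
"""

from __future__ import annotations

from dataclasses import dataclass, field

DNA_ALPHABET = set("ACGT")

_COMPLEMENT = str.maketrans("ACGTacgt", "TGCAtgca")


def revcomp(seq: str) -> str:
    return seq.translate(_COMPLEMENT)[::-1]

# library treatments of the dRNA-seq design
SAMPLE_S1 = "s1_primary"     # TPE+TAP treated: enriched for primary 5'-ends
SAMPLE_S2 = "s2_processed"   # untreated: retains processed (monophosphate) 5'-ends
SAMPLE_TOTAL = "total"       # unstranded total-RNA library
SAMPLES = (SAMPLE_S1, SAMPLE_S2, SAMPLE_TOTAL)

RNA_CLASSES = ("trans", "antisense", "leader", "sense", "orf_cover")

# annotation feature kinds whose contigs are excluded before classification
EXCLUDED_KINDS = frozenset({"rRNA", "tRNA", "repeat"})


@dataclass(frozen=True)
class Replicon:
    id: str
    sequence: str
    circular: bool = False

    def __post_init__(self) -> None:
        if not self.sequence:
            raise ValueError(f"replicon {self.id!r}: empty sequence")
        extra = set(self.sequence) - DNA_ALPHABET
        if extra:
            raise ValueError(f"replicon {self.id!r}: non-ACGT characters {sorted(extra)}")

    def __len__(self) -> int:
        return len(self.sequence)


@dataclass
class Genome:
    replicons: list[Replicon]

    def __post_init__(self) -> None:
        ids = [r.id for r in self.replicons]
        if len(ids) != len(set(ids)):
            raise ValueError("duplicate replicon ids")
        self._by_id = {r.id: r for r in self.replicons}

    def __getitem__(self, replicon_id: str) -> Replicon:
        return self._by_id[replicon_id]

    def __contains__(self, replicon_id: str) -> bool:
        return replicon_id in self._by_id

    def lengths(self) -> dict[str, int]:
        return {r.id: len(r) for r in self.replicons}

    def gc_fraction(self) -> float:
        gc = tot = 0
        for r in self.replicons:
            gc += r.sequence.count("G") + r.sequence.count("C")
            tot += len(r)
        return gc / tot


@dataclass(frozen=True)
class Gene:
    """An annotated feature; ``start <= end`` in genomic coordinates."""

    gene_id: str
    replicon: str
    strand: str
    start: int
    end: int
    kind: str = "CDS"

    def __post_init__(self) -> None:
        if self.start > self.end:
            raise ValueError(f"gene {self.gene_id}: start > end")
        if self.strand not in "+-":
            raise ValueError(f"gene {self.gene_id}: bad strand {self.strand!r}")

    def __len__(self) -> int:
        return self.end - self.start + 1


@dataclass
class GeneAnnotation:
    genes: list[Gene]

    def __post_init__(self) -> None:
        ids = [g.gene_id for g in self.genes]
        if len(ids) != len(set(ids)):
            raise ValueError("duplicate gene ids")

    def on_replicon(self, replicon: str) -> list[Gene]:
        return sorted((g for g in self.genes if g.replicon == replicon),
                      key=lambda g: g.start)

    def validate_against(self, genome: Genome) -> None:
        for g in self.genes:
            if g.replicon not in genome:
                raise ValueError(f"gene {g.gene_id}: unknown replicon {g.replicon}")
            if g.end > len(genome[g.replicon]):
                raise ValueError(f"gene {g.gene_id}: exceeds replicon bounds")


@dataclass(frozen=True)
class ReadAlignment:
    """One aligned read; ``strand`` is None for the unstranded protocol."""

    read_id: str
    replicon: str
    strand: str | None
    start: int
    end: int
    sample: str

    def __post_init__(self) -> None:
        if self.start > self.end:
            raise ValueError(f"read {self.read_id}: start > end")

    def __len__(self) -> int:
        return self.end - self.start + 1


@dataclass(frozen=True)
class PlantedTranscript:
    transcript_id: str
    replicon: str
    strand: str
    tss: int
    end3: int
    true_class: str
    true_subtype: str
    associated_gene: str | None
    is_primary: bool
    cleavage_site: int   # internal processed 5'-end used by the s2 library model

    @property
    def start(self) -> int:
        return min(self.tss, self.end3)

    @property
    def end(self) -> int:
        return max(self.tss, self.end3)

    def __len__(self) -> int:
        return self.end - self.start + 1


@dataclass
class SyntheticTruth:
    planted: list[PlantedTranscript] = field(default_factory=list)

    def __len__(self) -> int:
        return len(self.planted)

    def __iter__(self):
        return iter(self.planted)
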