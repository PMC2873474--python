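"""Synthetic dRNA-seq data generator.

Emulates the study design the pipeline assumes: a GC-rich multi-replicon
genome (a chromosome plus two plasmid-like replicons), annotated CDSs, planted
transcripts of every positional class with known TSS and 3'-end, and two
strand-specific 454-like read libraries — sample 1 enriched for primary
(triphosphate) 5'-ends, sample 2 showing processed/staggered 5'-ends — plus an
optional unstranded short-read total-RNA library.

All randomness flows through ``numpy.random.default_rng`` seeded from
``SimulationConfig.rng_seed``; identical configs give identical outputs.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

from .types import (
    SAMPLE_S1,
    SAMPLE_S2,
    SAMPLE_TOTAL,
    Gene,
    GeneAnnotation,
    Genome,
    PlantedTranscript,
    ReadAlignment,
    Replicon,
    SyntheticTruth,
)

# class proportions follow the study's observed candidate mix
DEFAULT_CLASS_MIX = {
    "trans": 0.16,
    "antisense": 0.09,
    "leader": 0.34,
    "sense": 0.40,
    "orf_cover": 0.01,
}

# per-class probability that a planted transcript is primary (has a true TSS
# retained in the TPE+TAP library), mirroring the reported per-class fractions
DEFAULT_PRIMARY_PROB = {
    "trans": 0.74,
    "antisense": 0.46,
    "leader": 0.60,
    "sense": 0.18,
    "orf_cover": 0.50,
}

SUBTYPE_MIX = {
    "antisense": {"1": 0.2, "2": 0.3, "3": 0.5},
    "sense": {"1": 0.06, "2": 0.64, "3": 0.24, "4": 0.06},
}


class PlacementError(RuntimeError):
    """No legal placement found for a requested transcript class."""


class SizingError(ValueError):
    """Requested gene count does not fit the genome length."""


@dataclass
class SimulationConfig:
    replicon_lengths: tuple[int, ...] = (300_000, 120_000, 80_000)
    n_genes: int = 200
    gc_fraction: float = 0.62
    class_mix: dict[str, float] = field(default_factory=lambda: dict(DEFAULT_CLASS_MIX))
    n_transcripts: int = 120
    mean_depth: float = 25.0
    background_read_rate: float = 0.2   # expected background reads per kb per strand
    end_noise_sd: float = 0.0           # Gaussian 5'/3' jitter, nt
    rng_seed: int = 0
    # geometry
    intergenic_min: int = 150
    utr5: int = 60
    utr3: int = 20
    leader_window: int = 40
    circular: bool = False
    # read model
    min_read_len: int = 50
    max_read_len: int = 350
    short_read_len: int = 36            # unstranded total-RNA protocol
    full_length_fraction: float = 0.6   # fraction of reads reaching the true 3'-end
    primary_prob: dict[str, float] = field(default_factory=lambda: dict(DEFAULT_PRIMARY_PROB))

    def validate(self) -> None:
        if abs(sum(self.class_mix.values()) - 1.0) > 1e-9:
            raise ValueError("class_mix proportions must sum to 1")
        if self.mean_depth < 0:
            raise ValueError("mean_depth must be >= 0")
        if not 0.0 <= self.gc_fraction <= 1.0:
            raise ValueError("gc_fraction must be in [0, 1]")


def _replicon_ids(n: int) -> list[str]:
    names = ["chr"] + [f"pSym{chr(ord('A') + i)}" for i in range(n - 1)]
    return names[:n]


def generate_genome(config: SimulationConfig) -> tuple[Genome, GeneAnnotation]:
    """Random genome with iid bases at the configured GC and non-overlapping
    CDSs on both strands separated by at least ``intergenic_min`` nt."""
    config.validate()
    rng = np.random.default_rng([config.rng_seed, 1])
    gc = config.gc_fraction
    p = np.array([(1 - gc) / 2, gc / 2, gc / 2, (1 - gc) / 2])
    bases = np.array(list("ACGT"))

    replicons = []
    for rid, length in zip(_replicon_ids(len(config.replicon_lengths)),
                           config.replicon_lengths):
        seq = "".join(bases[rng.choice(4, size=length, p=p)])
        replicons.append(Replicon(rid, seq, circular=config.circular))
    genome = Genome(replicons)

    total_len = sum(config.replicon_lengths)
    genes: list[Gene] = []
    gene_no = 0
    # distribute genes proportionally to replicon length (largest remainder)
    quotas = _largest_remainder(
        {r: config.n_genes * l / total_len
         for r, l in zip(_replicon_ids(len(config.replicon_lengths)),
                         config.replicon_lengths)})
    for rep in replicons:
        n = quotas[rep.id]
        if n == 0:
            continue
        # CDS lengths: multiples of 3; include short genes so that whole-ORF
        # transcripts (<= 350 nt incl. margins) can be planted
        lens = 3 * rng.integers(50, 301, size=n)            # 150..900 nt
        n_short = max(1, n // 10) if n else 0
        lens[:n_short] = 3 * rng.integers(50, 100, size=n_short)  # 150..297 nt
        rng.shuffle(lens)
        slack = len(rep) - int(lens.sum()) - (n + 1) * config.intergenic_min
        if slack < 0:
            raise SizingError(
                f"{n} genes do not fit replicon {rep.id} of {len(rep)} nt")
        extra = rng.multinomial(slack, np.full(n + 1, 1.0 / (n + 1)))
        pos = 0
        for i in range(n):
            pos += config.intergenic_min + int(extra[i])
            start = pos + 1
            end = start + int(lens[i]) - 1
            pos = end
            strand = "+" if rng.random() < 0.5 else "-"
            kind = rng.choice(
                ["CDS", "tRNA", "rRNA", "repeat", "transposase"],
                p=[0.93, 0.02, 0.01, 0.02, 0.02])
            gene_no += 1
            genes.append(Gene(f"g{gene_no:04d}", rep.id, strand, start, end,
                              kind=str(kind)))
    annotation = GeneAnnotation(genes)
    annotation.validate_against(genome)
    return genome, annotation


def _largest_remainder(weights: dict, total: int | None = None) -> dict:
    if total is None:
        total = round(sum(weights.values()))
    floors = {k: int(math.floor(v)) for k, v in weights.items()}
    rem = total - sum(floors.values())
    order = sorted(weights, key=lambda k: (floors[k] - weights[k], str(k)))
    for k in order[:rem]:
        floors[k] += 1
    return floors


# ---------------------------------------------------------------------------
# transcript planting

def _oriented(gene: Gene, off5: int, off3: int) -> tuple[int, int]:
    """Map gene-oriented offsets (0 = first CDS base, negative = upstream of
    the start codon) to genomic (tss, end3)."""
    if gene.strand == "+":
        return gene.start + off5, gene.start + off3
    return gene.end - off5, gene.end - off3


def _mtu(gene: Gene, utr5: int, utr3: int) -> tuple[int, int]:
    if gene.strand == "+":
        return gene.start - utr5, gene.end + utr3
    return gene.start - utr3, gene.end + utr5


def plant_transcripts(genome: Genome, annotation: GeneAnnotation,
                      config: SimulationConfig) -> SyntheticTruth:
    """Plant transcripts of every requested class so that each placement
    provably satisfies its class's positional rule against the annotation."""
    config.validate()
    rng = np.random.default_rng([config.rng_seed, 2])
    counts = _largest_remainder(
        {c: p * config.n_transcripts for c, p in config.class_mix.items()},
        config.n_transcripts)
    gene_classes = {"antisense", "leader", "sense", "orf_cover"}
    if any(counts.get(c, 0) for c in gene_classes) and not annotation.genes:
        raise ValueError("gene-associated classes requested but annotation is empty")

    cds_genes = [g for g in annotation.genes if g.kind == "CDS"]
    rng.shuffle(cds_genes)
    genes_by_rep = {r.id: annotation.on_replicon(r.id) for r in genome.replicons}
    used: dict[str, list[tuple[int, int]]] = {}
    free_genes = list(cds_genes)

    # strand-agnostic reservation: an 80-nt margin keeps planted transcripts,
    # and the promoter words later written upstream of their TSSs, disjoint
    def reserve(replicon: str, strand: str, start: int, end: int,
                margin: int = 80) -> bool:
        ivs = used.setdefault(replicon, [])
        for s, e in ivs:
            if start - margin <= e and end + margin >= s:
                return False
        ivs.append((start, end))
        return True

    def neighbors(gene_list: list[Gene], start: int, end: int):
        left = right = None
        for g in gene_list:
            if g.end < start:
                if left is None or g.end > left.end:
                    left = g
            elif g.start > end:
                if right is None or g.start < right.start:
                    right = g
        return left, right

    planted: list[PlantedTranscript] = []
    tno = 0

    def add(replicon: str, strand: str, tss: int, end3: int, cls: str,
            subtype: str, gene_id: str | None) -> None:
        nonlocal tno
        tno += 1
        prim = bool(rng.random() < config.primary_prob.get(cls, 0.5))
        lo, hi = min(tss, end3), max(tss, end3)
        # processed 5'-end used by the s2 library, drawn once per transcript
        if hi - lo >= 21:
            site_off = int(rng.integers(10, hi - lo - 9))
        else:
            site_off = (hi - lo) // 2
        cleave = tss + site_off if strand == "+" else tss - site_off
        planted.append(PlantedTranscript(
            f"t{tno:04d}", replicon, strand, tss, end3, cls, subtype,
            gene_id, prim, cleave))

    max_len = min(config.max_read_len, 350)
    min_len = max(config.min_read_len, 50)

    def draw_len(lo: int, hi: int) -> int:
        """Transcript length: short-biased within [lo, hi] (study sizes
        cluster near ~115 nt)."""
        lo = max(lo, min_len)
        hi = min(hi, max_len)
        if hi < lo:
            raise PlacementError("no legal length")
        x = lo + (hi - lo) * rng.beta(1.3, 3.0)
        return int(round(x))

    def take_gene(pred, cls: str) -> Gene:
        for i, g in enumerate(free_genes):
            if pred(g):
                return free_genes.pop(i)
        raise PlacementError(f"no suitable free gene for class {cls!r}")

    # --- gene-associated classes -----------------------------------------
    for cls in ("orf_cover", "leader", "sense", "antisense"):
        want = counts.get(cls, 0)
        made = 0
        attempts = 0
        while made < want:
            attempts += 1
            if attempts > 50 * want + 200:
                raise PlacementError(f"could not place all {cls!r} transcripts")
            if cls == "orf_cover":
                g = take_gene(lambda g: len(g) <= max_len - 10, cls)
                m5 = int(rng.integers(2, 15))
                m3 = int(rng.integers(1, 10))
                tss, end3 = _oriented(g, -m5, len(g) - 1 + m3)
                subtype = ""
            elif cls == "leader":
                g = take_gene(lambda g: len(g) >= min_len + 45, cls)
                off5 = int(rng.integers(-config.leader_window, 2))  # [-40, +1]
                hi3 = min(off5 + max_len - 1, len(g) - 2)
                off3 = int(rng.integers(max(off5 + min_len - 1, 1), hi3 + 1))
                tss, end3 = _oriented(g, off5, off3)
                subtype = ""
            elif cls == "sense":
                subtype = _draw_key(rng, SUBTYPE_MIX["sense"])
                if subtype == "1":
                    g = take_gene(lambda g: len(g) >= 60, cls)
                    off5 = int(rng.integers(-config.utr5,
                                            -config.leader_window))  # [-60,-41]
                    hi3 = min(off5 + max_len - 1, len(g) - 2)
                    off3 = int(rng.integers(max(off5 + min_len - 1, 1), hi3 + 1))
                elif subtype == "2":
                    g = take_gene(lambda g: len(g) >= min_len + 8, cls)
                    span = draw_len(min_len, len(g) - 6)
                    off5 = int(rng.integers(2, len(g) - span - 2))
                    off3 = off5 + span - 1
                elif subtype == "3":
                    g = take_gene(lambda g: len(g) >= min_len + 8, cls)
                    off3 = len(g) - 1 + int(rng.integers(1, config.utr3 + 1))
                    span = draw_len(min_len, min(max_len, off3 - 1))
                    off5 = off3 - span + 1
                    if off5 < 2:   # would touch leader window / cover the ORF
                        off5 = 2
                else:  # subtype 4: starts inside the 3'-UTR
                    g = take_gene(lambda g: True, cls)
                    off5 = len(g) - 1 + int(rng.integers(1, config.utr3 + 1))
                    off3 = off5 + draw_len(min_len, 65) - 1
                tss, end3 = _oriented(g, off5, off3)
            else:  # antisense
                subtype = _draw_key(rng, SUBTYPE_MIX["antisense"])
                if subtype == "2":
                    g = take_gene(lambda g: len(g) >= min_len + 12, cls)
                    span = draw_len(min_len, len(g) - 10)
                    a = int(rng.integers(4, len(g) - span - 4))
                    lo_off, hi_off = a, a + span - 1
                elif subtype == "1":
                    g = take_gene(lambda g: len(g) >= 130, cls)
                    up = int(rng.integers(10, config.leader_window + 1))
                    span = draw_len(min_len, min(max_len, up + len(g) - 65))
                    lo_off, hi_off = -up, -up + span - 1
                else:  # subtype 3: antisense to the 3'-UTR
                    g = take_gene(lambda g: len(g) >= 130, cls)
                    down = int(rng.integers(5, config.utr3 + 1))
                    span = draw_len(min_len, min(max_len, down + len(g) - 65))
                    hi_off = len(g) - 1 + down
                    lo_off = hi_off - span + 1
                strand = "-" if g.strand == "+" else "+"
                a5, a3 = _oriented(g, lo_off, hi_off)   # in gene orientation
                lo, hi = min(a5, a3), max(a5, a3)
                tss, end3 = (hi, lo) if strand == "-" else (lo, hi)
                if not reserve(g.replicon, strand, lo, hi):
                    continue
                add(g.replicon, strand, tss, end3, cls, subtype, g.gene_id)
                made += 1
                continue
            lo, hi = min(tss, end3), max(tss, end3)
            if hi > len(genome[g.replicon]) or lo < 1:
                continue
            if not reserve(g.replicon, g.strand, lo, hi):
                continue
            add(g.replicon, g.strand, tss, end3, cls, subtype, g.gene_id)
            made += 1

    # --- trans: intergenic, outside every minimal transcription unit ------
    want = counts.get("trans", 0)
    if want:
        slots = []   # (replicon, lo, hi) free of all MTUs
        for rep in genome.replicons:
            gl = genes_by_rep[rep.id]
            mtus = sorted(_mtu(g, config.utr5, config.utr3) for g in gl)
            pos = 1
            for ms, me in mtus + [(len(rep) + 1, len(rep) + 1)]:
                if ms - 1 - pos + 1 >= min_len + 12:
                    slots.append((rep.id, pos + 5, ms - 6))
                pos = max(pos, me + 1)
        rng.shuffle(slots)
        made = 0
        attempts = 0
        while made < want:
            attempts += 1
            if attempts > 50 * want + 200:
                raise PlacementError("could not place all 'trans' transcripts")
            rid, lo_s, hi_s = slots[int(rng.integers(len(slots)))]
            span = draw_len(min_len, hi_s - lo_s + 1)
            lo = int(rng.integers(lo_s, hi_s - span + 2))
            hi = lo + span - 1
            strand = "+" if rng.random() < 0.5 else "-"
            if not reserve(rid, strand, lo, hi):
                continue
            left, right = neighbors(genes_by_rep[rid], lo, hi)
            both_anti = (left is not None and right is not None
                         and left.strand != strand and right.strand != strand)
            subtype = "1" if both_anti else "2"
            tss, end3 = (lo, hi) if strand == "+" else (hi, lo)
            add(rid, strand, tss, end3, "trans", subtype, None)
            made += 1

    planted.sort(key=lambda t: (t.replicon, t.start))
    return SyntheticTruth(planted)


def _draw_key(rng: np.random.Generator, mix: dict[str, float]) -> str:
    keys = sorted(mix)
    p = np.array([mix[k] for k in keys], dtype=float)
    return keys[int(rng.choice(len(keys), p=p / p.sum()))]


# ---------------------------------------------------------------------------
# promoter planting

def plant_promoters(genome: Genome, truth: SyntheticTruth, promoter_word: str,
                    gap: int = 7) -> Genome:
    """Write ``promoter_word`` into the genome so that its 3'-most base ends
    ``gap`` nt upstream of each primary transcript's TSS (strand-aware).
    Returns a new :class:`Genome`; the input is left untouched."""
    seqs = {r.id: list(r.sequence) for r in genome.replicons}
    comp = str.maketrans("ACGT", "TGCA")
    w = len(promoter_word)
    for t in truth:
        if not t.is_primary:
            continue
        seq = seqs[t.replicon]
        if t.strand == "+":
            # motif occupies [tss-gap-w, tss-gap-1]: `gap` intervening bases
            start = t.tss - gap - w - 1   # 0-based index of first motif base
            if start < 0:
                continue
            seq[start:start + w] = list(promoter_word)
        else:
            # motif occupies [tss+gap+1, tss+gap+w], written reverse-complement
            start0 = t.tss + gap
            if start0 + w > len(seq):
                continue
            rc = promoter_word.translate(comp)[::-1]
            seq[start0:start0 + w] = list(rc)
    return Genome([Replicon(r.id, "".join(seqs[r.id]), r.circular)
                   for r in genome.replicons])


# ---------------------------------------------------------------------------
# read simulation

def simulate_reads(truth: SyntheticTruth, genome: Genome,
                   config: SimulationConfig, protocol: str) -> list[ReadAlignment]:
    """Simulate one library.

    * ``s1_primary``: reads only from primary transcripts; 5'-ends at the TSS
      plus Gaussian noise (sd ``end_noise_sd``, rounded).
    * ``s2_processed``: reads from all transcripts; 5'-ends at the TSS with
      probability 0.5, else at the transcript's planted cleavage site.
    * ``total``: unstranded fixed-length short reads from all transcripts.

    Per-transcript read counts are Poisson(``mean_depth``); uniform background
    reads are added at ``background_read_rate`` per kb (per strand for the
    stranded protocols).
    """
    if protocol not in (SAMPLE_S1, SAMPLE_S2, SAMPLE_TOTAL):
        raise ValueError(f"unknown protocol {protocol!r}")
    config.validate()
    rng = np.random.default_rng(
        [config.rng_seed, 3, (SAMPLE_S1, SAMPLE_S2, SAMPLE_TOTAL).index(protocol)])
    reads: list[ReadAlignment] = []
    n = 0

    def emit(replicon: str, strand: str | None, lo: int, hi: int) -> None:
        nonlocal n
        rep = genome[replicon]
        lo = max(1, lo)
        hi = min(len(rep), hi)
        if hi < lo:
            return
        n += 1
        reads.append(ReadAlignment(f"{protocol}_{n:06d}", replicon, strand,
                                   lo, hi, protocol))

    def emit_wrapped(replicon: str, strand: str | None, lo: int, hi: int) -> None:
        """Circular replicons wrap; reported as two alignment segments."""
        rep = genome[replicon]
        L = len(rep)
        if not rep.circular or (1 <= lo and hi <= L):
            emit(replicon, strand, lo, hi)
            return
        nonlocal n
        lo0 = (lo - 1) % L + 1
        length = hi - lo + 1
        n += 1
        rid = f"{protocol}_{n:06d}"
        first = min(L, lo0 + length - 1)
        reads.append(ReadAlignment(rid + "/1", replicon, strand, lo0, first,
                                   protocol))
        rest = length - (first - lo0 + 1)
        if rest > 0:
            reads.append(ReadAlignment(rid + "/2", replicon, strand, 1, rest,
                                       protocol))

    def noise() -> int:
        if config.end_noise_sd <= 0:
            return 0
        return int(round(rng.normal(0.0, config.end_noise_sd)))

    for t in truth:
        if protocol == SAMPLE_S1 and not t.is_primary:
            continue
        k = rng.poisson(config.mean_depth)
        for _ in range(k):
            if protocol == SAMPLE_TOTAL:
                rl = config.short_read_len
                span = len(t)
                if span <= rl:
                    lo, hi = t.start, t.end
                else:
                    lo = t.start + int(rng.integers(0, span - rl + 1))
                    hi = lo + rl - 1
                emit_wrapped(t.replicon, None, lo, hi)
                continue
            if protocol == SAMPLE_S1:
                p5 = t.tss + noise() * (1 if t.strand == "+" else -1)
            else:
                # processed-enriched library: every transcript's 5' boundary
                # appears; primary transcripts additionally show staggered
                # internal processing ends ("alternative 5'-ends")
                if t.is_primary:
                    p5 = t.tss if rng.random() < 0.5 else t.cleavage_site
                else:
                    p5 = t.tss
                p5 += noise() * (1 if t.strand == "+" else -1)
            if t.strand == "+":
                avail = t.end3 + noise() - p5 + 1
            else:
                avail = p5 - (t.end3 + noise()) + 1
            if avail < 1:
                continue
            if avail <= config.min_read_len or rng.random() < config.full_length_fraction:
                rl = avail
            else:
                rl = int(rng.integers(config.min_read_len, avail + 1))
            if t.strand == "+":
                emit_wrapped(t.replicon, "+", p5, p5 + rl - 1)
            else:
                emit_wrapped(t.replicon, "-", p5 - rl + 1, p5)

    # uniform background ("degradation") reads
    for rep in genome.replicons:
        lam = config.background_read_rate * len(rep) / 1000.0
        strands = [None] if protocol == SAMPLE_TOTAL else ["+", "-"]
        for strand in strands:
            for _ in range(rng.poisson(lam)):
                if protocol == SAMPLE_TOTAL:
                    rl = config.short_read_len
                else:
                    rl = int(rng.integers(config.min_read_len,
                                          config.max_read_len + 1))
                lo = int(rng.integers(1, max(2, len(rep) - rl + 2)))
                emit_wrapped(rep.id, strand, lo, lo + rl - 1)

    return reads


def simulate_dataset(config: SimulationConfig, promoter_word: str | None = None):
    """Convenience wrapper: genome, annotation, truth and all three libraries."""
    genome, annotation = generate_genome(config)
    truth = plant_transcripts(genome, annotation, config)
    if promoter_word:
        genome = plant_promoters(genome, truth, promoter_word)
    libs = {p: simulate_reads(truth, genome, config, p)
            for p in (SAMPLE_S1, SAMPLE_S2, SAMPLE_TOTAL)}
    return genome, annotation, truth, libs
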