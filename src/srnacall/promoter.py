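"""Sigma-70 promoter model: pseudocount-smoothed PSSM with exact score
P-values, upstream scanning of primary 5'-ends, and literal matching of the
consensus motif CTTGAC-N17-CTATAT.

P-value semantics follow matrix-search practice: P(score) is the probability
that a random word drawn from the 0-order background model scores at least
as high.  It is computed exactly by dynamic-programming convolution of the
per-column score distributions on an integer lattice; matrix scores are
rationalized to the same lattice, so reported P-values are exact for the
scores the scanner produces.

Two scanner architectures are provided.  The default model scans one
full-width matrix spanning -35 box, spacer and -10 box, the geometry the
printed P-value cutoff presumes; a two-box mode (6 + variable spacer + 6,
combined P-value = product of box P-values) is available where spacer-length
flexibility matters more than calibrated significance.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field

import numpy as np

from .types import Genome, revcomp

BASES = "ACGT"
BASE_INDEX = {b: i for i, b in enumerate(BASES)}

CONSENSUS_BOX35 = "CTTGAC"
CONSENSUS_BOX10 = "CTATAT"
CONSENSUS_SPACER = 17
DEFAULT_PSEUDOCOUNT = 0.01
DEFAULT_PVALUE_CUTOFF = 2.155343e-11

MIN_LOG_ODDS = -100.0   # bits; floor applied before lattice discretization


class PssmError(ValueError):
    pass


@dataclass
class Pssm:
    counts: np.ndarray          # (width, 4) float counts
    pseudocount: float = DEFAULT_PSEUDOCOUNT
    background: np.ndarray = field(
        default_factory=lambda: np.full(4, 0.25))
    lattice_delta: float = 1e-4  # bits per lattice bin

    def __post_init__(self) -> None:
        self.counts = np.asarray(self.counts, dtype=float)
        self.background = np.asarray(self.background, dtype=float)
        if self.counts.ndim != 2 or self.counts.shape[1] != 4:
            raise PssmError("counts must have shape (width, 4)")
        if abs(self.background.sum() - 1.0) > 1e-9:
            raise PssmError("background must sum to 1")
        n = self.counts.sum(axis=1, keepdims=True)
        self.probs = (self.counts + self.pseudocount) / (n + 4 * self.pseudocount)
        with np.errstate(divide="ignore"):
            lo = np.log2(self.probs / self.background)
        lo = np.maximum(lo, MIN_LOG_ODDS)
        self._ints = np.round(lo / self.lattice_delta).astype(np.int64)
        self.log_odds = self._ints * self.lattice_delta
        self._dist = None

    @property
    def width(self) -> int:
        return self.counts.shape[0]

    def score(self, word: str) -> float:
        if len(word) != self.width:
            raise PssmError(f"word length {len(word)} != width {self.width}")
        try:
            idx = [BASE_INDEX[b] for b in word]
        except KeyError as e:
            raise PssmError(f"non-ACGT base {e}") from None
        return int(self._ints[np.arange(self.width), idx].sum()) * self.lattice_delta

    def max_score(self) -> float:
        return int(self._ints.max(axis=1).sum()) * self.lattice_delta

    def min_score(self) -> float:
        return int(self._ints.min(axis=1).sum()) * self.lattice_delta

    def _score_distribution(self):
        """Exact distribution of the lattice score of a background word."""
        if self._dist is not None:
            return self._dist
        lo = self._ints.min(axis=1)
        dist = np.array([1.0])
        offset = 0
        for col in range(self.width):
            span = int(self._ints[col].max() - lo[col])
            new = np.zeros(len(dist) + span)
            for b in range(4):
                shift = int(self._ints[col, b] - lo[col])
                new[shift:shift + len(dist)] += dist * self.background[b]
            dist = new
            offset += int(lo[col])
        survival = np.cumsum(dist[::-1])[::-1]
        self._dist = (offset, dist, survival)
        return self._dist

    def pvalue(self, score: float) -> float:
        """Exact P(background word scores >= ``score``)."""
        offset, dist, survival = self._score_distribution()
        idx = int(round(score / self.lattice_delta)) - offset
        if idx <= 0:
            return 1.0
        if idx >= len(dist):
            return 0.0
        return float(survival[idx])

    def consensus(self) -> str:
        return "".join(BASES[i] for i in self.probs.argmax(axis=1))

    def to_json(self) -> str:
        return json.dumps({
            "counts": self.counts.tolist(),
            "pseudocount": self.pseudocount,
            "background": self.background.tolist(),
            "lattice_delta": self.lattice_delta,
        })

    @classmethod
    def from_json(cls, text: str) -> "Pssm":
        d = json.loads(text)
        return cls(np.array(d["counts"]), d["pseudocount"],
                   np.array(d["background"]), d["lattice_delta"])


def build_pssm(training: list[str], pseudocount: float = DEFAULT_PSEUDOCOUNT,
               background=None) -> Pssm:
    """PSSM from equal-length ACGT training sequences.

    Column probability P(b) = (count_b + pseudocount) / (n + 4*pseudocount);
    log-odds are log2(P(b) / background(b)).
    """
    if not training:
        raise PssmError("empty training set")
    w = len(training[0])
    if any(len(s) != w for s in training):
        raise PssmError("ragged training sequence lengths")
    counts = np.zeros((w, 4))
    for s in training:
        for i, b in enumerate(s.upper()):
            if b not in BASE_INDEX:
                raise PssmError(f"non-ACGT base {b!r} in training sequence")
            counts[i, BASE_INDEX[b]] += 1
    bg = np.full(4, 0.25) if background is None else np.asarray(background, float)
    return Pssm(counts, pseudocount, bg)


def genome_background(genome: Genome) -> np.ndarray:
    """0-order base frequencies of the input genome (both strands averaged,
    i.e. A=T and C=G by construction)."""
    counts = np.zeros(4)
    for r in genome.replicons:
        for i, b in enumerate(BASES):
            counts[i] += r.sequence.count(b)
    at = (counts[0] + counts[3]) / 2
    cg = (counts[1] + counts[2]) / 2
    sym = np.array([at, cg, cg, at])
    return sym / sym.sum()


def synthetic_sigma70_training(n: int = 25, seed: int = 20100405) -> list[str]:
    """Synthetic stand-in for an experimentally derived promoter compilation
    (the real training promoters are not part of this artifact).

    Generates ``n`` full-width promoter sequences: near-consensus -35/-10
    boxes (8% per-position degeneracy) around an AT-rich 17-nt spacer, the
    composition bacterial sigma-70 spacers typically show.
    """
    rng = np.random.default_rng(seed)
    spacer_p = {"A": 0.4, "T": 0.4, "C": 0.1, "G": 0.1}
    out = []
    for _ in range(n):
        seq = []
        for b in CONSENSUS_BOX35:
            seq.append(b if rng.random() > 0.08 else BASES[rng.integers(4)])
        for _ in range(CONSENSUS_SPACER):
            seq.append(rng.choice(list(spacer_p), p=list(spacer_p.values())))
        for b in CONSENSUS_BOX10:
            seq.append(b if rng.random() > 0.08 else BASES[rng.integers(4)])
        out.append("".join(seq))
    return out


@dataclass(frozen=True)
class PromoterHit:
    replicon: str
    strand: str
    box35_start: int     # genomic coordinate of the 5'-most motif base
    spacer: int
    score: float
    pvalue: float
    target_contig: str
    tss: int


@dataclass
class PromoterModel:
    box35: Pssm
    box10: Pssm
    spacer_range: tuple[int, int] = (15, 19)
    pvalue_cutoff: float = DEFAULT_PVALUE_CUTOFF
    joint: Pssm | None = None
    max_tss_gap: int = 10   # -10 box must end within this many nt of the TSS

    def __post_init__(self) -> None:
        if self.spacer_range[0] > self.spacer_range[1]:
            raise ValueError("spacer_min must be <= spacer_max")

    @classmethod
    def default(cls, background=None) -> "PromoterModel":
        """Full-width model from the synthetic promoter compilation."""
        training = synthetic_sigma70_training()
        w35 = len(CONSENSUS_BOX35)
        joint = build_pssm(training, DEFAULT_PSEUDOCOUNT, background)
        box35 = build_pssm([s[:w35] for s in training], DEFAULT_PSEUDOCOUNT,
                           background)
        box10 = build_pssm([s[-len(CONSENSUS_BOX10):] for s in training],
                           DEFAULT_PSEUDOCOUNT, background)
        return cls(box35, box10, joint=joint)

    @classmethod
    def consensus_two_box(cls, background=None,
                          pvalue_cutoff: float = DEFAULT_PVALUE_CUTOFF) -> "PromoterModel":
        """Two-box model trained on the literal consensus boxes."""
        return cls(build_pssm([CONSENSUS_BOX35], DEFAULT_PSEUDOCOUNT, background),
                   build_pssm([CONSENSUS_BOX10], DEFAULT_PSEUDOCOUNT, background),
                   pvalue_cutoff=pvalue_cutoff)

    def consensus_word(self) -> str:
        if self.joint is not None:
            return self.joint.consensus()
        mid = (self.spacer_range[0] + self.spacer_range[1]) // 2
        return self.box35.consensus() + "A" * mid + self.box10.consensus()


def _oriented_upstream(genome: Genome, replicon: str, strand: str, tss: int,
                       window: int) -> tuple[str, int]:
    """Upstream window in transcript orientation.  Returns (sequence, n_avail)
    where sequence[-1] is the base immediately 5' of the TSS."""
    seq = genome[replicon].sequence
    n = len(seq)
    if strand == "+":
        lo = max(1, tss - window)
        sub = seq[lo - 1:tss - 1]
    else:
        hi = min(n, tss + window)
        sub = revcomp(seq[tss:hi])
    return sub, len(sub)


def _genomic_start(strand: str, tss: int, dist_to_tss: int, width: int) -> int:
    """Genomic coordinate of the 5'-most motif base given its oriented offset.
    ``dist_to_tss`` is the gap between motif 3'-end and the TSS."""
    if strand == "+":
        return tss - dist_to_tss - width
    return tss + dist_to_tss + width


def scan_upstream(model: PromoterModel, genome: Genome, ends,
                  window: int = 100) -> list[PromoterHit]:
    """Scan the strand-aware window upstream of each primary 5'-end for
    promoter placements whose -10 box ends within ``max_tss_gap`` nt of the
    TSS; report placements passing the model's P-value cutoff.  Multiple
    hits per TSS are allowed."""
    hits: list[PromoterHit] = []
    for te in ends:
        for tss in te.primary_positions():
            sub, avail = _oriented_upstream(genome, te.replicon, te.strand,
                                            tss, window)
            if avail < window:
                warnings.warn(
                    f"upstream window truncated to {avail} nt at "
                    f"{te.replicon}:{tss}{te.strand}", stacklevel=2)
            for gap in range(1, model.max_tss_gap + 1):
                if model.joint is not None:
                    w = model.joint.width
                    end = avail - gap          # index past motif in sub
                    if end - w < 0 or end > avail:
                        continue
                    word = sub[end - w:end]
                    if len(word) != w:
                        continue
                    score = model.joint.score(word)
                    pval = model.joint.pvalue(score)
                    if pval <= model.pvalue_cutoff:
                        hits.append(PromoterHit(
                            te.replicon, te.strand,
                            _genomic_start(te.strand, tss, gap, w),
                            w - model.box35.width - model.box10.width,
                            score, pval, te.contig_id, tss))
                else:
                    w10, w35 = model.box10.width, model.box35.width
                    for spacer in range(model.spacer_range[0],
                                        model.spacer_range[1] + 1):
                        total = w35 + spacer + w10
                        end = avail - gap
                        if end - total < 0:
                            continue
                        word = sub[end - total:end]
                        s35 = model.box35.score(word[:w35])
                        s10 = model.box10.score(word[-w10:])
                        score = s35 + s10
                        pval = (model.box35.pvalue(s35)
                                * model.box10.pvalue(s10))
                        if pval <= model.pvalue_cutoff:
                            hits.append(PromoterHit(
                                te.replicon, te.strand,
                                _genomic_start(te.strand, tss, gap, total),
                                spacer, score, pval, te.contig_id, tss))
    return hits


def match_consensus(sequence: str, strand: str = "+") -> list[int]:
    """1-based start positions of literal CTTGAC + N17 + CTATAT matches in
    reading orientation.  For the minus strand the sequence is searched as
    its reverse complement and positions refer to the 5'-most motif base on
    the forward coordinate system."""
    seq = sequence.upper() if strand == "+" else revcomp(sequence.upper())
    w35, w10, sp = CONSENSUS_BOX35, CONSENSUS_BOX10, CONSENSUS_SPACER
    total = len(w35) + sp + len(w10)
    out = []
    for i in range(len(seq) - total + 1):
        if seq.startswith(w35, i) and seq.startswith(w10, i + len(w35) + sp):
            out.append(i + 1 if strand == "+"
                       else len(seq) - (i + total) + 1)
    return sorted(out)


def match_consensus_genome(genome: Genome, replicon: str,
                           interval: tuple[int, int] | None = None,
                           strand: str = "+") -> list[int]:
    seq = genome[replicon].sequence
    lo = 1 if interval is None else interval[0]
    hi = len(seq) if interval is None else interval[1]
    rel = match_consensus(seq[lo - 1:hi], strand)
    return [p + lo - 1 for p in rel]
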