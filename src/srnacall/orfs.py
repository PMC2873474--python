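"""Small-ORF and ribosome-binding-site screening of sRNA candidates.

A candidate peptide-coding region is a complete ORF (start codon through an
in-frame stop, both within the transcript) of at least 60 nt, measured start
through stop codon inclusive.  RBS presence is scored as the minimum
hybridization free energy of the 16S rRNA anti-Shine-Dalgarno tail (UCCUCCA)
against the window upstream of the start codon over all ungapped offsets,
using the same nearest-neighbour stacking energies as the structure module;
a site is called when that energy is at or below the configured threshold.
"""

from __future__ import annotations

from dataclasses import dataclass, field

from .coverage import Contig
from .structure import STACKING
from .types import Gene, GeneAnnotation

STOP_CODONS = {"TAA", "TAG", "TGA"}
RNA_PAIRS = frozenset({"AU", "UA", "GC", "CG", "GU", "UG"})


@dataclass
class RbsParams:
    anti_sd: str = "UCCUCCA"
    energy_threshold: float = -3.4535
    window: tuple[int, int] = (-20, -4)   # nt relative to the start codon
    start_codons: frozenset = frozenset({"ATG", "GTG", "TTG"})

    def __post_init__(self) -> None:
        if self.energy_threshold >= 0:
            raise ValueError("energy_threshold must be negative")
        if self.window[0] >= self.window[1] or self.window[1] > 0:
            raise ValueError("window must be an upstream interval")


@dataclass
class OrfCall:
    frame: int              # 0..2 on the given (sense) strand
    start: int              # 1-based within the transcript sequence
    stop: int               # 1-based last base of the stop codon
    length: int             # start..stop inclusive
    rbs_energy: float | None = None
    has_rbs: bool = False
    relation_to_gene: str = "none"


def find_orfs(sequence: str, min_len: int = 60,
              start_codons: frozenset = RbsParams().start_codons) -> list[OrfCall]:
    """All complete ORFs of at least ``min_len`` nt on the given strand.

    Every start codon with an in-frame stop inside the sequence yields one
    ORF (nested starts sharing a stop are all reported).
    """
    seq = sequence.upper()
    if set(seq) - set("ACGT"):
        raise ValueError("sequence contains non-ACGT characters")
    out: list[OrfCall] = []
    n = len(seq)
    for frame in range(3):
        stops_after: dict[int, int] = {}
        stop_at = None
        # walk codons right-to-left to know each position's next in-frame stop
        positions = list(range(frame, n - 2, 3))
        for p in reversed(positions):
            codon = seq[p:p + 3]
            if codon in STOP_CODONS:
                stop_at = p
            stops_after[p] = stop_at
        for p in positions:
            if seq[p:p + 3] in start_codons:
                sp = stops_after.get(p)
                if sp is None or sp < p:
                    continue
                length = sp + 3 - p
                if length >= min_len:
                    out.append(OrfCall(frame, p + 1, sp + 3, length))
    return sorted(out, key=lambda o: (o.start, o.stop))


def duplex_energy(window: str, anti_sd: str) -> tuple[float | None, int | None]:
    """Minimum ungapped RNA:RNA hybridization energy of ``anti_sd`` against
    the window (transcript sense, 5'->3'), summing stacking energies over
    consecutive complementary pairs.  Returns (energy, best_offset)."""
    w = window.upper().replace("T", "U")
    a = anti_sd.upper().replace("T", "U")
    m = len(a)
    if len(w) < m:
        return None, None
    best, best_off = 0.0, None
    rev = a[::-1]   # anti-SD read 3'->5' against the window read 5'->3'
    for off in range(len(w) - m + 1):
        seg = w[off:off + m]
        paired = [seg[i] + rev[i] in RNA_PAIRS for i in range(m)]
        e = 0.0
        for i in range(m - 1):
            if paired[i] and paired[i + 1]:
                e += STACKING[(seg[i] + rev[i], seg[i + 1] + rev[i + 1])]
        if e < best or best_off is None:
            best, best_off = e, off
    return best, best_off


def rbs_energy(upstream: str, params: RbsParams | None = None) -> tuple[float | None, bool]:
    """(energy, has_rbs) for the upstream window of one ORF; a no-call
    (None, False) results when the window is shorter than the anti-SD."""
    params = params or RbsParams()
    e, _ = duplex_energy(upstream, params.anti_sd)
    if e is None:
        return None, False
    return e, e <= params.energy_threshold


def orf_upstream_window(sequence: str, orf: OrfCall,
                        params: RbsParams | None = None) -> str:
    params = params or RbsParams()
    lo = orf.start - 1 + params.window[0]          # 0-based inclusive
    hi = orf.start - 1 + params.window[1] + 1      # 0-based exclusive
    return sequence[max(0, lo):max(0, hi)]


def scan_transcript(sequence: str, min_len: int = 60,
                    params: RbsParams | None = None) -> list[OrfCall]:
    """ORFs plus RBS calls for one transcript sequence (sense strand)."""
    params = params or RbsParams()
    orfs = find_orfs(sequence, min_len, params.start_codons)
    for orf in orfs:
        e, has = rbs_energy(orf_upstream_window(sequence, orf, params), params)
        orf.rbs_energy, orf.has_rbs = e, has
    return orfs


def relate_orf_to_gene(orf: OrfCall, contig: Contig,
                       annotation: GeneAnnotation,
                       gene_id: str | None) -> OrfCall:
    """Set ``relation_to_gene`` by comparing the ORF's genomic frame and stop
    with the contig's associated gene.  ORFs starting at the gene's own start
    codon are marked ``excluded_gene_start`` (they lack an in-frame stop on
    the sRNA itself in the situation being screened for)."""
    if gene_id is None:
        orf.relation_to_gene = "none"
        return orf
    gene = next(g for g in annotation.genes if g.gene_id == gene_id)
    # genomic coordinates of the ORF
    if contig.strand == "+":
        g_start = contig.start + orf.start - 1
        g_stop = contig.start + orf.stop - 1     # last base of stop codon
    else:
        g_start = contig.end - orf.start + 1
        g_stop = contig.end - orf.stop + 1
    if gene.strand == "+":
        gene_start_codon = gene.start
        gene_stop_last = gene.end
        same_frame = (g_start - gene_start_codon) % 3 == 0 and contig.strand == "+"
    else:
        gene_start_codon = gene.end
        gene_stop_last = gene.start
        same_frame = (gene_start_codon - g_start) % 3 == 0 and contig.strand == "-"
    if contig.strand == gene.strand and g_start == gene_start_codon:
        orf.relation_to_gene = "excluded_gene_start"
        return orf
    orf_lo, orf_hi = min(g_start, g_stop), max(g_start, g_stop)
    orf_overlaps_gene = min(orf_hi, gene.end) >= max(orf_lo, gene.start)
    if contig.strand == gene.strand and same_frame and g_stop == gene_stop_last:
        orf.relation_to_gene = "same_frame_shared_stop"
    elif orf_overlaps_gene:
        orf.relation_to_gene = "overlapping_other_frame"
    elif ((gene.strand == "+" and orf_hi < gene.start)
          or (gene.strand == "-" and orf_lo > gene.end)):
        # ORF in the transcript but upstream of the CDS
        orf.relation_to_gene = "within_5utr"
    else:
        orf.relation_to_gene = "none"
    return orf
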