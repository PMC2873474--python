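"""Readers and writers for the pipeline's file formats.

GFF3 and SAM intervals are 1-based inclusive; BED6 and bedGraph are written
0-based half-open.  The TSV alignment dialect has six columns: read_id,
replicon, strand (+/-/. for unstranded), start, end, sample.
"""

from __future__ import annotations

import os
from pathlib import Path

import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from .coverage import Contig, CoverageTrack
from .types import (
    Gene,
    GeneAnnotation,
    Genome,
    PlantedTranscript,
    ReadAlignment,
    Replicon,
    SyntheticTruth,
)

FLOAT_FORMAT = "%.6g"   # fixed float rendering keeps outputs byte-reproducible


class ParseError(ValueError):
    pass


# --- FASTA -----------------------------------------------------------------

def write_fasta(genome: Genome, path) -> None:
    records = [SeqRecord(Seq(r.sequence), id=r.id,
                         description="circular" if r.circular else "linear")
               for r in genome.replicons]
    SeqIO.write(records, str(path), "fasta")


def read_fasta(path) -> Genome:
    replicons = [Replicon(rec.id, str(rec.seq).upper(),
                          circular="circular" in rec.description)
                 for rec in SeqIO.parse(str(path), "fasta")]
    return Genome(replicons)


# --- GFF3 ------------------------------------------------------------------

_GFF_TYPE = {"CDS": "CDS", "rRNA": "rRNA", "tRNA": "tRNA",
             "repeat": "repeat_region", "transposase": "mobile_genetic_element"}
_GFF_TYPE_BACK = {v: k for k, v in _GFF_TYPE.items()}


def write_gff3(annotation: GeneAnnotation, path) -> None:
    with open(path, "w") as fh:
        fh.write("##gff-version 3\n")
        for g in sorted(annotation.genes, key=lambda g: (g.replicon, g.start)):
            fh.write("\t".join([
                g.replicon, "srnacall", _GFF_TYPE.get(g.kind, g.kind),
                str(g.start), str(g.end), ".", g.strand, ".",
                f"ID={g.gene_id}",
            ]) + "\n")


def read_gff3(path) -> GeneAnnotation:
    genes = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            fields = line.split("\t")
            if len(fields) != 9:
                raise ParseError(f"{path}:{lineno}: expected 9 columns")
            rep, _src, ftype, start, end, _score, strand, _phase, attrs = fields
            try:
                start_i, end_i = int(start), int(end)
            except ValueError:
                raise ParseError(f"{path}:{lineno}: non-integer coordinates")
            if end_i < start_i:
                raise ParseError(f"{path}:{lineno}: end < start")
            gene_id = None
            for kv in attrs.split(";"):
                if kv.startswith("ID="):
                    gene_id = kv[3:]
            if gene_id is None:
                raise ParseError(f"{path}:{lineno}: missing ID attribute")
            genes.append(Gene(gene_id, rep, strand, start_i, end_i,
                              kind=_GFF_TYPE_BACK.get(ftype, ftype)))
    return GeneAnnotation(genes)


def write_candidates_gff3(transcripts, contigs: list[Contig], path) -> None:
    """Classified candidates as GFF3 ncRNA features."""
    by_id = {c.contig_id: c for c in contigs}
    with open(path, "w") as fh:
        fh.write("##gff-version 3\n")
        for t in transcripts:
            c = by_id[t.contig_id]
            attrs = (f"ID={t.contig_id};class={t.rna_class};"
                     f"subtype={t.subtype or '.'};"
                     f"associated_genes={','.join(t.associated_genes) or '.'}")
            fh.write("\t".join([
                c.replicon, "srnacall", "ncRNA", str(c.start), str(c.end),
                FLOAT_FORMAT % c.mean_depth, c.strand, ".", attrs]) + "\n")


# --- SAM -------------------------------------------------------------------

def write_sam(alignments: list[ReadAlignment], genome: Genome, path) -> None:
    """Minimal SAM: header with @SQ lines, FLAG 0x10 for minus-strand reads,
    match-only CIGAR.  Unstranded alignments are not representable in SAM
    and are rejected; use the TSV dialect for the total-RNA library."""
    with open(path, "w") as fh:
        fh.write("@HD\tVN:1.6\tSO:coordinate\n")
        for r in genome.replicons:
            fh.write(f"@SQ\tSN:{r.id}\tLN:{len(r)}\n")
        for a in sorted(alignments, key=lambda a: (a.replicon, a.start)):
            if a.strand is None:
                raise ValueError(
                    f"read {a.read_id}: unstranded reads cannot go to SAM")
            flag = 16 if a.strand == "-" else 0
            fh.write("\t".join([
                a.read_id, str(flag), a.replicon, str(a.start), "255",
                f"{len(a)}M", "*", "0", "0", "*", "*"]) + "\n")


def read_sam(path, sample: str) -> list[ReadAlignment]:
    import pysam

    out = []
    with pysam.AlignmentFile(str(path), "r", check_sq=False) as fh:
        for rec in fh:
            if rec.is_unmapped:
                continue
            out.append(ReadAlignment(
                rec.query_name, rec.reference_name,
                "-" if rec.is_reverse else "+",
                rec.reference_start + 1, rec.reference_end, sample))
    return out


# --- TSV dialects ----------------------------------------------------------

def write_alignments_tsv(alignments: list[ReadAlignment], path) -> None:
    df = pd.DataFrame([{
        "read_id": a.read_id, "replicon": a.replicon,
        "strand": a.strand or ".", "start": a.start, "end": a.end,
        "sample": a.sample} for a in alignments])
    if df.empty:
        df = pd.DataFrame(columns=["read_id", "replicon", "strand", "start",
                                   "end", "sample"])
    df.to_csv(path, sep="\t", index=False)


def read_alignments_tsv(path) -> list[ReadAlignment]:
    df = pd.read_csv(path, sep="\t", dtype={"strand": str})
    out = []
    for row in df.itertuples(index=False):
        strand = None if row.strand == "." else row.strand
        out.append(ReadAlignment(str(row.read_id), str(row.replicon), strand,
                                 int(row.start), int(row.end), str(row.sample)))
    return out


def write_truth_tsv(truth: SyntheticTruth, path) -> None:
    pd.DataFrame([{
        "transcript_id": t.transcript_id, "replicon": t.replicon,
        "strand": t.strand, "tss": t.tss, "end3": t.end3,
        "true_class": t.true_class, "true_subtype": t.true_subtype or ".",
        "associated_gene": t.associated_gene or ".",
        "is_primary": int(t.is_primary), "cleavage_site": t.cleavage_site,
    } for t in truth]).to_csv(path, sep="\t", index=False)


def read_truth_tsv(path) -> SyntheticTruth:
    df = pd.read_csv(path, sep="\t")
    return SyntheticTruth([PlantedTranscript(
        str(r.transcript_id), str(r.replicon), str(r.strand), int(r.tss),
        int(r.end3), str(r.true_class),
        "" if str(r.true_subtype) == "." else str(r.true_subtype),
        None if str(r.associated_gene) == "." else str(r.associated_gene),
        bool(r.is_primary), int(r.cleavage_site)) for r in
        df.itertuples(index=False)])


def write_contigs_tsv(contigs: list[Contig], path) -> None:
    rows = []
    for c in contigs:
        row = {"contig_id": c.contig_id, "replicon": c.replicon,
               "strand": c.strand, "start": c.start, "end": c.end,
               "length": len(c), "mean_depth": c.mean_depth,
               "seed_start": c.seed_start, "seed_end": c.seed_end,
               "over_length": int(c.over_length)}
        for s, v in sorted(c.per_sample_depth.items()):
            row[f"depth_{s}"] = v
        rows.append(row)
    df = pd.DataFrame(rows)
    if df.empty:
        df = pd.DataFrame(columns=["contig_id", "replicon", "strand", "start",
                                   "end", "length", "mean_depth", "seed_start",
                                   "seed_end", "over_length"])
    df.to_csv(path, sep="\t", index=False, float_format=FLOAT_FORMAT)


def read_contigs_tsv(path) -> list[Contig]:
    df = pd.read_csv(path, sep="\t")
    out = []
    for r in df.itertuples(index=False):
        per_sample = {c[len("depth_"):]: getattr(r, c)
                      for c in df.columns if c.startswith("depth_")}
        out.append(Contig(str(r.contig_id), str(r.replicon), str(r.strand),
                          int(r.start), int(r.end), float(r.mean_depth),
                          per_sample, int(r.seed_start), int(r.seed_end),
                          bool(r.over_length)))
    return out


# --- BED / bedGraph (0-based half-open) ------------------------------------

def write_contigs_bed(contigs: list[Contig], path) -> None:
    with open(path, "w") as fh:
        for c in contigs:
            fh.write("\t".join([
                c.replicon, str(c.start - 1), str(c.end), c.contig_id,
                str(int(round(min(1000, c.mean_depth)))), c.strand]) + "\n")


def write_bedgraph(track: CoverageTrack, replicon: str, strand: str,
                   samples, path) -> None:
    depth = track.pooled(replicon, strand, samples)
    with open(path, "w") as fh:
        fh.write(f'track type=bedGraph name="{replicon}{strand}"\n')
        i = 0
        n = len(depth)
        while i < n:
            j = i
            while j + 1 < n and depth[j + 1] == depth[i]:
                j += 1
            if depth[i] > 0:
                fh.write(f"{replicon}\t{i}\t{j + 1}\t{int(depth[i])}\n")
            i = j + 1


def ensure_dir(path) -> Path:
    p = Path(path)
    os.makedirs(p, exist_ok=True)
    return p
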