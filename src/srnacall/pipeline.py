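"""End-to-end pipeline: alignments + annotation -> classified sRNA candidates
with transcript ends, promoter predictions, structure Z-scores and small-ORF
screens, plus the optional hybridization filters.

The stage chain mirrors the discovery workflow the package implements:
coverage -> contigs -> distinct ends / primary labels -> classification ->
clusters and summaries -> promoter scan -> shape Z-scores -> ORF/RBS screen.
Every run writes a JSON manifest with all seeds and parameters; re-running
with the same configuration reproduces every output byte for byte.
"""

from __future__ import annotations

import dataclasses
import json
import logging
import sys
import time
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .arrays import ProbeSignal, call_array_candidates, call_chip_candidates, ma_values
from .classify import (
    ClassifierParams,
    classify_contig,
    filter_excluded,
    find_clusters,
    summarize,
)
from .coverage import ContigCallerParams, build_coverage, call_contigs, reported
from .ends import call_and_label, ends_summary, sample_support
from .io import (
    FLOAT_FORMAT,
    ensure_dir,
    read_alignments_tsv,
    read_fasta,
    read_gff3,
    read_sam,
    write_alignments_tsv,
    write_candidates_gff3,
    write_contigs_bed,
    write_contigs_tsv,
    write_fasta,
    write_gff3,
    write_sam,
    write_truth_tsv,
)
from .orfs import RbsParams, relate_orf_to_gene, scan_transcript
from .promoter import PromoterModel, genome_background, scan_upstream
from .simulate import SimulationConfig, simulate_dataset
from .structure import background_distribution, shape_probabilities, zscore
from .types import SAMPLE_TOTAL, Genome, revcomp

log = logging.getLogger("srnacall")

def _df(rows: list, columns: list[str]) -> pd.DataFrame:
    """DataFrame that keeps its header even when there are no rows."""
    return pd.DataFrame(rows) if rows else pd.DataFrame(columns=columns)



@dataclass
class StructureSettings:
    k: int = 300                 # samples per transcript fold
    k_background: int = 120     # samples per background window
    n_windows: int = 30
    policy: str = "random"
    max_transcripts: int = 5    # fold the shortest N candidates
    max_length: int = 140


@dataclass
class PipelineConfig:
    genome_fasta: str = ""
    annotation_gff3: str = ""
    alignments: dict = field(default_factory=dict)  # sample -> path (SAM or TSV)
    probe_table: str | None = None        # two-channel TSV
    chip_table: str | None = None         # chip-mode TSV
    output_dir: str = "srnacall_out"
    contig_params: ContigCallerParams = field(default_factory=ContigCallerParams.preset_454)
    classifier_params: ClassifierParams = field(default_factory=ClassifierParams)
    rbs_params: RbsParams = field(default_factory=RbsParams)
    structure: StructureSettings = field(default_factory=StructureSettings)
    promoter_window: int = 100
    rng_seed: int = 0
    log_level: str = "INFO"

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        cfg = cls()
        for key, value in raw.items():
            if not hasattr(cfg, key):
                raise ValueError(f"unknown configuration key {key!r}")
            current = getattr(cfg, key)
            if dataclasses.is_dataclass(current) and isinstance(value, dict):
                setattr(cfg, key, dataclasses.replace(current, **value))
            else:
                setattr(cfg, key, value)
        return cfg


def _read_alignment_file(path: str, sample: str):
    if str(path).endswith(".sam"):
        return read_sam(path, sample)
    return read_alignments_tsv(path)


def read_inputs(config: PipelineConfig):
    genome = read_fasta(config.genome_fasta)
    annotation = read_gff3(config.annotation_gff3)
    annotation.validate_against(genome)
    alignments = {}
    for sample, path in config.alignments.items():
        alignments[sample] = _read_alignment_file(path, sample)
    return genome, annotation, alignments


def _contig_sequence(genome: Genome, contig) -> str:
    seq = genome[contig.replicon].sequence[contig.start - 1:contig.end]
    return revcomp(seq) if contig.strand == "-" else seq


def run_pipeline(config: PipelineConfig) -> dict:
    logging.basicConfig(stream=sys.stderr, level=config.log_level,
                        format="%(levelname)s %(name)s: %(message)s")
    outdir = ensure_dir(config.output_dir)
    t0 = time.time()
    genome, annotation, alignments = read_inputs(config)
    all_reads = [r for sample in sorted(alignments) for r in alignments[sample]]
    log.info("inputs: %d replicons, %d genes, %d reads (%.1fs)",
             len(genome.replicons), len(annotation.genes), len(all_reads),
             time.time() - t0)

    # coverage and contigs
    track = build_coverage(all_reads, genome)
    contigs_all = call_contigs(track, config.contig_params)
    contigs = reported(contigs_all)
    write_contigs_tsv(contigs_all, outdir / "contigs.tsv")
    write_contigs_bed(contigs, outdir / "contigs.bed")
    log.info("contigs: %d called, %d reported", len(contigs_all), len(contigs))

    # exclusion and classification
    kept, removed = filter_excluded(contigs, annotation)
    classified = [classify_contig(c, annotation, config.classifier_params)
                  for c in kept]
    clusters = find_clusters(classified, kept, config.classifier_params)
    counts, sizes = summarize(classified, kept)
    counts.to_csv(outdir / "class_counts.tsv", sep="\t", index=False)
    sizes.to_csv(outdir / "class_sizes.tsv", sep="\t", index=False,
                 float_format=FLOAT_FORMAT)
    with open(outdir / "clusters.tsv", "w") as fh:
        fh.write("cluster_id\tmembers\n")
        for i, members in enumerate(clusters, 1):
            fh.write(f"cl{i:03d}\t{','.join(members)}\n")
    log.info("classified %d candidates (%d excluded as rRNA/tRNA/repeat), "
             "%d clusters", len(classified), len(removed), len(clusters))

    # transcript ends
    by_id = {c.contig_id: c for c in kept}
    ends = [call_and_label(c, track) for c in kept]
    end_rows = []
    for te in ends:
        for kind, lst in (("5p", te.five_prime), ("3p", te.three_prime)):
            for e in lst:
                end_rows.append({
                    "contig_id": te.contig_id, "end": kind,
                    "position": e.position, "read_count": e.read_count,
                    "samples": "&".join(sorted(e.samples_supporting)) or ".",
                    "is_primary": ("." if e.is_primary is None
                                   else int(e.is_primary))})
    _df(end_rows, ["contig_id", "end", "position", "read_count",
                   "samples", "is_primary"]).to_csv(outdir / "ends.tsv",
                                                   sep="\t", index=False)
    supports = {c.contig_id: sample_support(c, config.contig_params.c)
                for c in kept}
    classes = {t.contig_id: t.rna_class for t in classified}
    summary = ends_summary(ends, supports, classes)
    summary.to_csv(outdir / "end_summary.tsv", sep="\t", index=False)

    # candidate table
    cand_rows = []
    for t in classified:
        c = by_id[t.contig_id]
        te = next(e for e in ends if e.contig_id == t.contig_id)
        cand_rows.append({
            "contig_id": t.contig_id, "replicon": c.replicon,
            "strand": c.strand, "start": c.start, "end": c.end,
            "length": len(c), "class": t.rna_class,
            "subtype": t.subtype or ".",
            "genes": ",".join(t.associated_genes) or ".",
            "support": supports[t.contig_id],
            "cat5": te.end_category_5, "cat3": te.end_category_3,
            "n_primary_5p": len(te.primary_positions()),
            "notes": t.relation_notes or "."})
    cand_df = _df(cand_rows, ["contig_id", "replicon", "strand", "start",
                              "end", "length", "class", "subtype", "genes",
                              "support", "cat5", "cat3", "n_primary_5p",
                              "notes"])
    cand_df.to_csv(outdir / "candidates.tsv", sep="\t", index=False)
    write_candidates_gff3(classified, kept, outdir / "candidates.gff3")

    # promoter scan upstream of primary 5'-ends
    model = PromoterModel.default(genome_background(genome))
    hits = scan_upstream(model, genome, ends, config.promoter_window)
    _df([{
        "contig_id": h.target_contig, "replicon": h.replicon,
        "strand": h.strand, "box35_start": h.box35_start, "tss": h.tss,
        "spacer": h.spacer, "score": round(h.score, 4),
        "pvalue": f"{h.pvalue:.6e}"} for h in hits],
        ["contig_id", "replicon", "strand", "box35_start", "tss", "spacer",
         "score", "pvalue"]).to_csv(outdir / "promoters.tsv", sep="\t",
                                    index=False)
    log.info("promoter scan: %d hits", len(hits))

    # structure Z-scores for a bounded, deterministic candidate subset
    st = config.structure
    chosen = sorted((c for c in kept if len(c) <= st.max_length),
                    key=lambda c: (len(c), c.contig_id))[:st.max_transcripts]
    shape_rows = []
    bg_cache: dict[tuple[str, int, str, str], object] = {}
    for c in chosen:
        seq = _contig_sequence(genome, c)
        prof = shape_probabilities(seq, k=st.k, seed=config.rng_seed)
        key = (prof.shape, len(seq), c.replicon, c.strand)
        if key not in bg_cache:
            bg_cache[key] = background_distribution(
                genome, c.strand, prof.shape, len(seq), st.policy,
                st.n_windows, seed=config.rng_seed, k=st.k_background,
                replicon=c.replicon)
        bg = bg_cache[key]
        if bg.error:
            z = float("nan")
        else:
            z = zscore(prof, bg, c.contig_id).z
        shape_rows.append({
            "contig_id": c.contig_id, "length": len(c),
            "shape": prof.shape, "prob": round(prof.prob, 4),
            "E": "." if bg.mean is None else round(bg.mean, 4),
            "S": "." if bg.sd is None else round(bg.sd, 4),
            "Z": "." if np.isnan(z) else round(z, 3),
            "windows": bg.n_windows_used,
            "mfe_structure": prof.mfe_representative})
    _df(shape_rows, ["contig_id", "length", "shape", "prob", "E", "S", "Z",
                     "windows", "mfe_structure"]).to_csv(
        outdir / "shapes.tsv", sep="\t", index=False)
    log.info("structure: %d transcripts folded", len(shape_rows))

    # small-ORF / RBS screen
    orf_rows = []
    for t in classified:
        c = by_id[t.contig_id]
        seq = _contig_sequence(genome, c)
        gene_id = t.associated_genes[0] if t.associated_genes else None
        for orf in scan_transcript(seq, params=config.rbs_params):
            relate_orf_to_gene(orf, c, annotation, gene_id)
            if orf.relation_to_gene == "excluded_gene_start":
                continue
            orf_rows.append({
                "contig_id": t.contig_id, "frame": orf.frame,
                "orf_start": orf.start, "orf_stop": orf.stop,
                "orf_len": orf.length,
                "rbs_energy": ("." if orf.rbs_energy is None
                               else round(orf.rbs_energy, 4)),
                "has_rbs": int(orf.has_rbs),
                "relation": orf.relation_to_gene})
    _df(orf_rows, ["contig_id", "frame", "orf_start", "orf_stop",
                   "orf_len", "rbs_energy", "has_rbs", "relation"]).to_csv(
        outdir / "orfs.tsv", sep="\t", index=False)
    log.info("ORF screen: %d ORFs", len(orf_rows))

    # optional hybridization screens
    report_extra = {}
    if config.probe_table:
        probes = _read_probe_table(config.probe_table, two_channel=True)
        ma = ma_values(probes)
        cands = call_array_candidates(ma)
        pd.DataFrame([{"probe_id": p.probe_id, "M": round(p.M, 4),
                       "A": round(p.A, 4),
                       "candidate": int(p.probe_id in set(cands))}
                      for p in ma]).to_csv(outdir / "array_candidates.tsv",
                                           sep="\t", index=False)
        report_extra["array_candidates"] = len(cands)
    if config.chip_table:
        probes = _read_probe_table(config.chip_table, two_channel=False)
        regions = call_chip_candidates(probes, annotation=annotation)
        pd.DataFrame([{"replicon": r.replicon, "start": r.start,
                       "end": r.end, "probes": ",".join(r.probe_ids)}
                      for r in regions]).to_csv(outdir / "chip_regions.tsv",
                                                sep="\t", index=False)
        report_extra["chip_regions"] = len(regions)

    report = {
        "n_reads": len(all_reads),
        "n_contigs": len(contigs_all),
        "n_reported": len(contigs),
        "n_excluded": len(removed),
        "n_candidates": len(classified),
        "class_counts": {cls: int((cand_df["class"] == cls).sum())
                         for cls in sorted(cand_df["class"].unique())}
        if not cand_df.empty else {},
        "n_clusters": len(clusters),
        "n_promoter_hits": len(hits),
        "n_orfs": len(orf_rows),
        **report_extra,
    }
    manifest = {
        "version": __version__,
        "rng_seed": config.rng_seed,
        "parameters": {
            "contig_params": dataclasses.asdict(config.contig_params),
            "classifier_params": dataclasses.asdict(config.classifier_params),
            "rbs_params": {
                "anti_sd": config.rbs_params.anti_sd,
                "energy_threshold": config.rbs_params.energy_threshold,
                "window": list(config.rbs_params.window),
                "start_codons": sorted(config.rbs_params.start_codons)},
            "structure": dataclasses.asdict(config.structure),
            "promoter_window": config.promoter_window,
        },
        "inputs": {"genome": str(config.genome_fasta),
                   "annotation": str(config.annotation_gff3),
                   "alignments": {k: str(v)
                                  for k, v in sorted(config.alignments.items())}},
        "report": report,
    }
    with open(outdir / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=2, sort_keys=True)
    log.info("pipeline finished in %.1fs", time.time() - t0)
    return report


def _read_probe_table(path, two_channel: bool) -> list[ProbeSignal]:
    df = pd.read_csv(path, sep="\t")
    out = []
    for r in df.itertuples(index=False):
        if two_channel:
            out.append(ProbeSignal(str(r.probe_id), str(r.replicon),
                                   str(r.strand), int(r.start), int(r.end),
                                   channel_small=float(r.channel_small),
                                   channel_long=float(r.channel_long)))
        else:
            out.append(ProbeSignal(str(r.probe_id), str(r.replicon),
                                   str(r.strand), int(r.start), int(r.end),
                                   signal=float(r.signal),
                                   background=float(r.background)))
    return out


# ---------------------------------------------------------------------------
# synthetic end-to-end run and truth-based evaluation

def write_synthetic_dataset(sim: SimulationConfig, outdir,
                            plant_promoter: bool = True) -> dict:
    """Generate and write a full synthetic dataset; returns the file map."""
    outdir = ensure_dir(outdir)
    word = PromoterModel.default().consensus_word() if plant_promoter else None
    genome, annotation, truth, libs = simulate_dataset(sim, word)
    write_fasta(genome, outdir / "genome.fasta")
    write_gff3(annotation, outdir / "annotation.gff3")
    write_truth_tsv(truth, outdir / "truth.tsv")
    paths = {"genome_fasta": str(outdir / "genome.fasta"),
             "annotation_gff3": str(outdir / "annotation.gff3"),
             "truth": str(outdir / "truth.tsv"),
             "alignments": {}}
    for sample, reads in libs.items():
        if sample == SAMPLE_TOTAL:
            p = outdir / f"{sample}.tsv"
            write_alignments_tsv(reads, p)
        else:
            p = outdir / f"{sample}.sam"
            write_sam(reads, genome, p)
        paths["alignments"][sample] = str(p)
    return paths


def run_synthetic(sim: SimulationConfig, outdir,
                  pipeline_overrides: dict | None = None) -> dict:
    """Simulate, run the full pipeline, and evaluate against the truth."""
    outdir = ensure_dir(outdir)
    paths = write_synthetic_dataset(sim, outdir / "data")
    config = PipelineConfig(
        genome_fasta=paths["genome_fasta"],
        annotation_gff3=paths["annotation_gff3"],
        alignments={s: p for s, p in paths["alignments"].items()
                    if s != SAMPLE_TOTAL},
        output_dir=str(outdir / "results"),
        rng_seed=sim.rng_seed,
    )
    for key, value in (pipeline_overrides or {}).items():
        setattr(config, key, value)
    report = run_pipeline(config)
    evaluation = evaluate_run(sim, paths, Path(config.output_dir))
    with open(outdir / "evaluation.json", "w") as fh:
        json.dump(evaluation, fh, indent=2, sort_keys=True)
    report["evaluation"] = evaluation
    return report


def evaluate_run(sim: SimulationConfig, paths: dict, results_dir: Path) -> dict:
    """Compare pipeline outputs with the planted truth: recovery rate,
    classification accuracy, primary-TSS labelling and promoter recovery."""
    from .io import read_contigs_tsv, read_truth_tsv

    truth = read_truth_tsv(paths["truth"])
    contigs = [c for c in read_contigs_tsv(results_dir / "contigs.tsv")
               if not c.over_length]
    cand = pd.read_csv(results_dir / "candidates.tsv", sep="\t")
    ends = pd.read_csv(results_dir / "ends.tsv", sep="\t")
    promoters = pd.read_csv(results_dir / "promoters.tsv", sep="\t")

    def jaccard(a0, a1, b0, b1):
        inter = min(a1, b1) - max(a0, b0) + 1
        union = max(a1, b1) - min(a0, b0) + 1
        return inter / union if inter > 0 else 0.0

    matched = {}
    for t in truth:
        best, best_j = None, 0.0
        for c in contigs:
            if c.replicon != t.replicon or c.strand != t.strand:
                continue
            j = jaccard(t.start, t.end, c.start, c.end)
            if j > best_j:
                best, best_j = c, j
        if best is not None and best_j >= 0.8:
            matched[t.transcript_id] = best.contig_id
    class_of = dict(zip(cand["contig_id"], cand["class"]))
    n_match = len(matched)
    n_correct = sum(1 for t in truth
                    if t.transcript_id in matched
                    and class_of.get(matched[t.transcript_id]) == t.true_class)

    prim5 = ends[(ends["end"] == "5p") & (ends["is_primary"] == "1")]
    prim_pos = {}
    for row in prim5.itertuples(index=False):
        prim_pos.setdefault(row.contig_id, set()).add(int(row.position))
    primaries = [t for t in truth if t.is_primary and t.transcript_id in matched]
    n_prim_ok = sum(
        1 for t in primaries
        if any(abs(p - t.tss) <= 1
               for p in prim_pos.get(matched[t.transcript_id], ())))
    prom_tss = set(zip(promoters["contig_id"], promoters["tss"]))
    n_prom_ok = sum(
        1 for t in primaries
        if any(cid == matched[t.transcript_id] and abs(p - t.tss) <= 1
               for cid, p in prom_tss))
    return {
        "n_planted": len(truth),
        "n_recovered": n_match,
        "recovery_rate": n_match / len(truth) if len(truth) else float("nan"),
        "n_class_correct": n_correct,
        "classification_accuracy": n_correct / n_match if n_match else float("nan"),
        "n_planted_primary_recovered": len(primaries),
        "n_primary_tss_labeled": n_prim_ok,
        "primary_tss_rate": n_prim_ok / len(primaries) if primaries else float("nan"),
        "n_promoter_recovered": n_prom_ok,
        "promoter_recovery_rate": (n_prom_ok / len(primaries)
                                   if primaries else float("nan")),
    }
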