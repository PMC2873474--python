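"""Synthetic-data generator: determinism, composition, planting rules and
the read-end model."""

import math
from collections import Counter

import numpy as np
import pytest

from conftest import make_contig, small_config
from srnacall.classify import ClassifierParams, classify_contig
from srnacall.simulate import (
    SimulationConfig,
    generate_genome,
    plant_transcripts,
    simulate_dataset,
    simulate_reads,
)
from srnacall.types import SAMPLE_S1, SAMPLE_S2, SAMPLE_TOTAL


def test_empty_annotation_when_no_genes():
    cfg = SimulationConfig(replicon_lengths=(5000,), n_genes=0,
                           n_transcripts=0, rng_seed=0)
    genome, ann = generate_genome(cfg)
    assert ann.genes == []
    assert len(genome.replicons[0]) == 5000


def test_same_seed_is_byte_identical(tmp_path):
    from srnacall.io import write_fasta, write_gff3

    cfg = small_config(seed=3)
    for run in ("a", "b"):
        genome, ann = generate_genome(cfg)
        write_fasta(genome, tmp_path / f"{run}.fasta")
        write_gff3(ann, tmp_path / f"{run}.gff3")
    assert (tmp_path / "a.fasta").read_bytes() == (tmp_path / "b.fasta").read_bytes()
    assert (tmp_path / "a.gff3").read_bytes() == (tmp_path / "b.gff3").read_bytes()


def test_gc_content_close_to_configured():
    cfg = SimulationConfig(replicon_lengths=(100_000,), n_genes=0,
                           n_transcripts=0, gc_fraction=0.62, rng_seed=5)
    genome, _ = generate_genome(cfg)
    seq = genome.replicons[0].sequence
    gc = (seq.count("G") + seq.count("C")) / len(seq)
    assert abs(gc - 0.62) < 0.01


def test_gene_intervals_disjoint_with_min_gap():
    genome, ann = generate_genome(small_config(seed=11))
    for rep in genome.replicons:
        genes = ann.on_replicon(rep.id)
        for a, b in zip(genes, genes[1:]):
            assert b.start - a.end - 1 >= 150
        assert all(g.end <= len(rep) for g in genes)


def test_trans_only_mix_classifies_trans():
    cfg = small_config(seed=2, n_transcripts=15,
                       class_mix={"trans": 1.0, "antisense": 0, "leader": 0,
                                  "sense": 0, "orf_cover": 0})
    genome, ann = generate_genome(cfg)
    truth = plant_transcripts(genome, ann, cfg)
    assert len(truth) == 15
    for t in truth:
        res = classify_contig(make_contig(t.start, t.end, t.strand,
                                          t.replicon), ann)
        assert res.rna_class == "trans"


def test_zero_transcripts_gives_empty_truth():
    cfg = small_config(seed=2, n_transcripts=0)
    genome, ann = generate_genome(cfg)
    assert len(plant_transcripts(genome, ann, cfg)) == 0


def test_planted_leader_satisfies_interval_rule():
    """Leader placements: 5'-end within [start_codon - 40, start_codon + 1]
    and 3'-end strictly inside the CDS, by direct interval arithmetic."""
    cfg = small_config(seed=9)
    genome, ann = generate_genome(cfg)
    truth = plant_transcripts(genome, ann, cfg)
    genes = {g.gene_id: g for g in ann.genes}
    leaders = [t for t in truth if t.true_class == "leader"]
    assert leaders
    for t in leaders:
        g = genes[t.associated_gene]
        if g.strand == "+":
            assert g.start - 40 <= t.tss <= g.start + 1
            assert g.start < t.end3 < g.end
        else:
            assert g.end - 1 <= t.tss <= g.end + 40
            assert g.start < t.end3 < g.end


def test_planted_round_trip_through_classifier():
    """Placements run through the classifier with the planting UTR geometry
    reproduce the true class and subtype for all planted transcripts."""
    cfg = small_config(seed=13)
    genome, ann = generate_genome(cfg)
    truth = plant_transcripts(genome, ann, cfg)
    params = ClassifierParams(utr5=cfg.utr5, utr3=cfg.utr3,
                              leader_window=cfg.leader_window)
    mismatches = []
    for t in truth:
        res = classify_contig(make_contig(t.start, t.end, t.strand,
                                          t.replicon), ann, params)
        if res.rna_class != t.true_class or (t.true_subtype and
                                             res.subtype != t.true_subtype):
            mismatches.append((t, res))
    assert not mismatches
    assert Counter(t.true_class for t in truth)["sense"] > 0


def test_planted_lengths_within_protocol_bounds():
    cfg = small_config(seed=4)
    genome, ann = generate_genome(cfg)
    truth = plant_transcripts(genome, ann, cfg)
    assert all(50 <= len(t) <= 350 for t in truth)


def test_no_reads_when_depth_and_background_zero():
    cfg = small_config(seed=2, mean_depth=0.0, background_read_rate=0.0)
    genome, ann = generate_genome(cfg)
    truth = plant_transcripts(genome, ann, cfg)
    assert simulate_reads(truth, genome, cfg, SAMPLE_S1) == []
    assert simulate_reads(truth, genome, cfg, SAMPLE_S2) == []


def test_unknown_protocol_rejected(small_dataset):
    genome, ann, truth, _ = small_dataset
    with pytest.raises(ValueError, match="protocol"):
        simulate_reads(truth, genome, small_config(seed=7), "s3")


def test_s1_reads_share_tss_when_noise_zero(small_dataset):
    genome, ann, truth, libs = small_dataset
    primaries = {t.transcript_id: t for t in truth if t.is_primary}
    by_pos = {}
    for r in libs[SAMPLE_S1]:
        if r.read_id.startswith("s1_primary"):
            by_pos.setdefault((r.replicon, r.strand), []).append(r)
    for t in primaries.values():
        mine = [r for r in by_pos.get((t.replicon, t.strand), [])
                if min(t.start, t.end) - 1 <= r.start <= max(t.start, t.end)]
        # restrict to reads inside the transcript footprint: background reads
        # are excluded by requiring the exact 5' position
        fives = {r.start if t.strand == "+" else r.end for r in mine
                 if (r.start if t.strand == "+" else r.end) in
                 range(t.start - 2, t.end + 3)}
        if mine:
            assert t.tss in fives


def test_read_counts_poisson_distributed():
    """Per-transcript read counts follow Poisson(mean_depth): over seeded
    replicates the count stays within 3*sqrt(lambda) of lambda >= 99% of
    the time."""
    cfg = SimulationConfig(replicon_lengths=(4000,), n_genes=0,
                           n_transcripts=1, mean_depth=20.0,
                           background_read_rate=0.0,
                           class_mix={"trans": 1.0, "antisense": 0,
                                      "leader": 0, "sense": 0, "orf_cover": 0},
                           primary_prob={"trans": 1.0})
    genome, ann = generate_genome(cfg)
    ok = 0
    n_rep = 1000
    for seed in range(n_rep):
        cfg.rng_seed = seed
        truth = plant_transcripts(genome, ann, cfg)
        k = len(simulate_reads(truth, genome, cfg, SAMPLE_S1))
        if abs(k - 20.0) <= 3 * math.sqrt(20.0):
            ok += 1
    assert ok / n_rep >= 0.99


def test_reads_within_replicon_bounds(small_dataset):
    genome, _, _, libs = small_dataset
    lengths = genome.lengths()
    for reads in libs.values():
        for r in reads:
            assert 1 <= r.start <= r.end <= lengths[r.replicon]


def test_total_protocol_is_unstranded_and_short(small_dataset):
    _, _, _, libs = small_dataset
    total = libs[SAMPLE_TOTAL]
    assert total and all(r.strand is None for r in total)
    assert all(len(r) <= 36 for r in total)


def test_identical_config_identical_reads(small_dataset):
    genome, ann, truth, libs = small_dataset
    again = simulate_reads(truth, genome, small_config(seed=7), SAMPLE_S2)
    assert again == libs[SAMPLE_S2]
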