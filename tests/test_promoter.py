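"""Promoter PSSM: probabilities, exact P-values vs full enumeration,
scanning geometry on both strands, and literal consensus matching."""

import itertools

import numpy as np
import pytest

from srnacall.ends import EndCall, TranscriptEnds
from srnacall.promoter import (
    CONSENSUS_BOX10,
    CONSENSUS_BOX35,
    DEFAULT_PVALUE_CUTOFF,
    PromoterModel,
    Pssm,
    PssmError,
    build_pssm,
    genome_background,
    match_consensus,
    match_consensus_genome,
    scan_upstream,
    synthetic_sigma70_training,
)
from srnacall.types import Genome, Replicon, revcomp


def test_column_probability_formula():
    m = build_pssm(["A" * 6] * 25, pseudocount=0.01)
    assert m.probs[0, 0] == pytest.approx(25.01 / 25.04)
    assert m.probs[0, 1] == pytest.approx(0.01 / 25.04)


def test_zero_pseudocount_degenerate():
    m = build_pssm(["ACGT"], pseudocount=0.0)
    assert m.probs[0].tolist() == [1.0, 0.0, 0.0, 0.0]
    assert m.probs[1].tolist() == [0.0, 1.0, 0.0, 0.0]


def test_two_column_log_odds_hand_computed():
    # counts: col0 {A:2, C:1}, col1 {G:3}; pseudocount 1; uniform background
    m = build_pssm(["AG", "AG", "CG"], pseudocount=1.0)
    pa = (2 + 1) / (3 + 4)
    assert m.probs[0, 0] == pytest.approx(pa)
    assert m.log_odds[0, 0] == pytest.approx(np.log2(pa / 0.25), abs=1e-4)
    pg = (3 + 1) / (3 + 4)
    assert m.log_odds[1, 2] == pytest.approx(np.log2(pg / 0.25), abs=1e-4)


def test_ragged_or_bad_training_rejected():
    with pytest.raises(PssmError):
        build_pssm(["ACGT", "ACG"])
    with pytest.raises(PssmError):
        build_pssm(["ACNT"])


def test_pvalue_support_bounds():
    m = build_pssm(["ACGT", "AAGT", "ACGA"], pseudocount=0.5)
    assert m.pvalue(m.max_score() + 1.0) == 0.0
    assert m.pvalue(m.min_score()) == 1.0
    assert m.pvalue(m.min_score() - 5.0) == 1.0


@pytest.mark.parametrize("bg", [None, [0.19, 0.31, 0.31, 0.19]])
def test_width4_pvalues_match_enumeration(bg):
    rng = np.random.default_rng(1)
    training = ["".join(rng.choice(list("ACGT"), 4)) for _ in range(12)]
    m = build_pssm(training, 0.01, background=bg)
    probs = dict(zip("ACGT", m.background))
    words = ["".join(w) for w in itertools.product("ACGT", repeat=4)]
    scores = {w: m.score(w) for w in words}
    for w in words:
        p_enum = sum(np.prod([probs[b] for b in v])
                     for v in words if scores[v] >= scores[w] - 1e-12)
        assert m.pvalue(scores[w]) == pytest.approx(p_enum, rel=1e-9)


def test_pvalue_monotone_and_distribution_sums_to_one():
    m = build_pssm(synthetic_sigma70_training(), 0.01)
    offset, dist, _ = m._score_distribution()
    assert dist.sum() == pytest.approx(1.0)
    xs = np.linspace(m.min_score() - 1, m.max_score() + 1, 200)
    ps = [m.pvalue(x) for x in xs]
    assert all(a >= b - 1e-15 for a, b in zip(ps, ps[1:]))


def _genome_with_promoter(strand, spacer=17, gap=7, seed=0, n=600):
    rng = np.random.default_rng(seed)
    seq = list(rng.choice(list("ACGT"), n))
    word = CONSENSUS_BOX35 + "".join(rng.choice(list("ACGT"), spacer)) \
        + CONSENSUS_BOX10
    tss = 400
    if strand == "+":
        start = tss - gap - len(word) - 1
        seq[start:start + len(word)] = list(word)
    else:
        start = tss + gap
        seq[start:start + len(word)] = list(revcomp(word))
    genome = Genome([Replicon("chr", "".join(seq))])
    ends = [TranscriptEnds("RC1", "chr", strand,
                           [EndCall(tss, 30, frozenset({"s1"}), True)], [])]
    return genome, ends, tss


def test_two_box_consensus_placement_scores_maximally():
    model = PromoterModel.consensus_two_box(pvalue_cutoff=1e-6)
    genome, ends, tss = _genome_with_promoter("+", seed=3)
    hits = scan_upstream(model, genome, ends)
    best = max(hits, key=lambda h: h.score)
    assert best.spacer == 17
    assert best.score == pytest.approx(model.box35.max_score()
                                       + model.box10.max_score())
    assert best.tss == tss


def test_minus_strand_scan_mirrors_plus():
    model = PromoterModel.consensus_two_box(pvalue_cutoff=1e-6)
    plus_genome, plus_ends, tss = _genome_with_promoter("+", seed=5)
    minus_genome, minus_ends, _ = _genome_with_promoter("-", seed=5)
    hp = max(scan_upstream(model, plus_genome, plus_ends),
             key=lambda h: h.score)
    hm = max(scan_upstream(model, minus_genome, minus_ends),
             key=lambda h: h.score)
    assert hp.score == hm.score and hp.spacer == hm.spacer
    assert hp.tss - hp.box35_start == -(hm.tss - hm.box35_start)


def test_default_model_recovers_consensus_at_paper_cutoff():
    model = PromoterModel.default()
    word = model.consensus_word()
    rng = np.random.default_rng(11)
    seq = list(rng.choice(list("ACGT"), 500))
    tss = 300
    start = tss - 7 - len(word) - 1
    seq[start:start + len(word)] = list(word)
    genome = Genome([Replicon("chr", "".join(seq))])
    ends = [TranscriptEnds("RC1", "chr", "+",
                           [EndCall(tss, 30, frozenset({"s1"}), True)], [])]
    hits = scan_upstream(model, genome, ends)
    assert hits and all(h.pvalue <= DEFAULT_PVALUE_CUTOFF for h in hits)


def test_background_hit_rate_is_negligible():
    """On random GC-0.62 sequence the expected number of hits at the default
    cutoff is cutoff x positions scanned, i.e. far below one over 1,000
    windows."""
    model = PromoterModel.default([0.19, 0.31, 0.31, 0.19])
    rng = np.random.default_rng(23)
    n_hits = 0
    for i in range(1000):
        seq = "".join(rng.choice(list("ACGT"), 150,
                                 p=[0.19, 0.31, 0.31, 0.19]))
        genome = Genome([Replicon("chr", seq)])
        ends = [TranscriptEnds("RC1", "chr", "+",
                               [EndCall(145, 30, frozenset({"s1"}), True)],
                               [])]
        n_hits += len(scan_upstream(model, genome, ends, window=120))
    assert n_hits == 0


def test_match_consensus_examples():
    assert match_consensus("CTTGAC" + "A" * 17 + "CTATAT") == [1]
    assert match_consensus("CTTGAC" + "A" * 16 + "CTATAT") == []
    assert match_consensus("G" + "CTTGAC" + "T" * 17 + "CTATAT" + "GG") == [2]


def test_match_consensus_against_sliding_oracle():
    rng = np.random.default_rng(6)
    seq = "".join(rng.choice(list("ACGT"), 100_000,
                             p=[0.19, 0.31, 0.31, 0.19]))
    # plant a few
    seq = (seq[:5000] + "CTTGAC" + seq[5000:5017] + "CTATAT" + seq[5017:])
    got = match_consensus(seq)
    want = [i + 1 for i in range(len(seq) - 29 + 1)
            if seq[i:i + 6] == "CTTGAC" and seq[i + 23:i + 29] == "CTATAT"]
    assert got == want and 5001 in got


def test_match_consensus_minus_strand_roundtrip():
    word = "CTTGAC" + "ACGTA" * 3 + "CG" + "CTATAT"
    seq = "GGGG" + revcomp(word) + "TTTT"
    genome = Genome([Replicon("chr", seq)])
    pos = match_consensus_genome(genome, "chr", strand="-")
    assert len(pos) == 1


def test_every_consensus_match_is_a_max_score_scan_hit():
    model = PromoterModel.consensus_two_box(pvalue_cutoff=1e-6)
    rng = np.random.default_rng(9)
    spacer = "".join(rng.choice(list("ACGT"), 17))
    genome, ends, tss = _genome_with_promoter("+", seed=9)
    seq = genome.replicons[0].sequence
    for p in match_consensus(seq):
        if p + 29 + 7 - 1 == tss:   # the planted one ends 7 nt before the TSS
            hits = scan_upstream(model, genome, ends)
            assert any(h.box35_start == p and h.score ==
                       pytest.approx(model.box35.max_score()
                                     + model.box10.max_score())
                       for h in hits)


def test_genome_background_symmetric():
    genome = Genome([Replicon("chr", "GGGGCCCCAT")])
    bg = genome_background(genome)
    assert bg.sum() == pytest.approx(1.0)
    assert bg[1] == bg[2] and bg[0] == bg[3]


def test_model_json_roundtrip():
    m = build_pssm(synthetic_sigma70_training(5), 0.01)
    m2 = Pssm.from_json(m.to_json())
    assert np.allclose(m.log_odds, m2.log_odds)
    assert m2.pvalue(m2.max_score()) == m.pvalue(m.max_score())
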