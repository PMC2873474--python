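"""Positional classification: worked examples, an exhaustive sliding-contig
sweep against an independent decision-table oracle, clusters and summaries."""

import numpy as np
import pytest

from conftest import make_contig
from srnacall.classify import (
    ClassifierParams,
    classify_contig,
    filter_excluded,
    find_clusters,
    summarize,
)
from srnacall.types import Gene, GeneAnnotation

UTR5, UTR3, LEAD = 60, 20, 40


def oracle_classify(cs, ce, cstrand, genes):
    """Independent re-statement of the decision table on genomic intervals,
    with explicit plus/minus branches (no coordinate transform)."""
    c5 = cs if cstrand == "+" else ce
    c3 = ce if cstrand == "+" else cs

    def interval_overlap(a0, a1, b0, b1):
        return max(a0, b0) <= min(a1, b1)

    relations = []
    for g in genes:
        if g.strand == "+":
            mtu = (g.start - UTR5, g.end + UTR3)
            utr5_iv = (g.start - UTR5, g.start - 1)
            utr3_iv = (g.end + 1, g.end + UTR3)
        else:
            mtu = (g.start - UTR3, g.end + UTR5)
            utr5_iv = (g.end + 1, g.end + UTR5)
            utr3_iv = (g.start - UTR3, g.start - 1)
        if not interval_overlap(cs, ce, *mtu):
            continue
        if g.strand != cstrand:
            parts = set()
            if interval_overlap(cs, ce, *utr5_iv):
                parts.add(1)
            if interval_overlap(cs, ce, g.start, g.end):
                parts.add(2)
            if interval_overlap(cs, ce, *utr3_iv):
                parts.add(3)
            if parts <= {1, 2} and 1 in parts:
                sub = "1"
            elif parts <= {2, 3} and 3 in parts:
                sub = "3"
            elif parts == {2}:
                sub = "2"
            else:
                sub = "1/3"
            relations.append(("antisense", sub, g.gene_id))
            continue
        # same strand
        if g.strand == "+":
            covers = cs <= g.start and ce >= g.end
            in_leader = g.start - LEAD <= c5 <= g.start + 1
            three_inside = g.start < c3 < g.end
            sense1 = (g.start - UTR5 <= c5 <= g.start - LEAD - 1
                      and g.start <= c3 <= g.end)
            sense2 = cs >= g.start and ce <= g.end
            sense3 = interval_overlap(cs, ce, g.start, g.end) and c3 > g.end
            sense4 = c5 > g.end
            all_upstream = ce < g.start
        else:
            covers = cs <= g.start and ce >= g.end
            in_leader = g.end - 1 <= c5 <= g.end + LEAD
            three_inside = g.start < c3 < g.end
            sense1 = (g.end + LEAD + 1 <= c5 <= g.end + UTR5
                      and g.start <= c3 <= g.end)
            sense2 = cs >= g.start and ce <= g.end
            sense3 = interval_overlap(cs, ce, g.start, g.end) and c3 < g.start
            sense4 = c5 < g.start
            all_upstream = cs > g.end
        if covers:
            relations.append(("orf_cover", "", g.gene_id))
        elif in_leader and three_inside:
            relations.append(("leader", "", g.gene_id))
        elif sense1:
            relations.append(("sense", "1", g.gene_id))
        elif sense2:
            relations.append(("sense", "2", g.gene_id))
        elif sense3:
            relations.append(("sense", "3", g.gene_id))
        elif sense4:
            relations.append(("sense", "4", g.gene_id))
        elif all_upstream:
            relations.append(("sense", "1", g.gene_id))
        else:
            relations.append(("sense", "4", g.gene_id))

    if not relations:
        left = max((g for g in genes if g.end < cs), default=None,
                   key=lambda g: g.end)
        right = min((g for g in genes if g.start > ce), default=None,
                    key=lambda g: g.start)
        if (left and right and left.strand != cstrand
                and right.strand != cstrand):
            return ("trans", "1")
        return ("trans", "2")
    rank = {"orf_cover": 0, "leader": 1, "sense": 2, "antisense": 3}
    best = min(rank[r[0]] for r in relations)
    chosen = [r for r in relations if rank[r[0]] == best]
    subtype = "/".join(sorted({p for _, s, _ in chosen if s
                               for p in s.split("/")}, key=int))
    return (chosen[0][0], subtype)


def test_antisense_inside_cds_is_type_2():
    genes = GeneAnnotation([Gene("g1", "chr", "+", 1000, 1600)])
    res = classify_contig(make_contig(1200, 1300, strand="-"), genes)
    assert (res.rna_class, res.subtype) == ("antisense", "2")
    assert res.associated_genes == ["g1"]


def test_leader_example():
    genes = GeneAnnotation([Gene("g1", "chr", "+", 1000, 1600)])
    res = classify_contig(make_contig(965, 1200, strand="+"), genes)
    assert res.rna_class == "leader"


def test_orf_cover_beats_other_relations():
    genes = GeneAnnotation([Gene("g1", "chr", "+", 1000, 1180)])
    res = classify_contig(make_contig(990, 1195, strand="+"), genes)
    assert res.rna_class == "orf_cover"


def test_exhaustive_sweep_matches_decision_table():
    """A 100-nt contig slid base by base across a toy two-gene replicon in
    every strand configuration reproduces the independent decision table."""
    params = ClassifierParams()
    for s1 in "+-":
        for s2 in "+-":
            genes = [Gene("gA", "chr", s1, 601, 900),
                     Gene("gB", "chr", s2, 1601, 1900)]
            ann = GeneAnnotation(genes)
            for cstrand in "+-":
                for start in range(1, 2401, 1):
                    contig = make_contig(start, start + 99, strand=cstrand)
                    got = classify_contig(contig, ann, params)
                    want = oracle_classify(start, start + 99, cstrand, genes)
                    assert (got.rna_class, got.subtype) == want, (
                        s1, s2, cstrand, start, got, want)


def test_excluded_kinds_filtered_before_classification():
    ann = GeneAnnotation([Gene("r1", "chr", "+", 1000, 1100, kind="rRNA"),
                          Gene("g1", "chr", "+", 2000, 2500)])
    contigs = [make_contig(1050, 1150, contig_id="RC1"),
               make_contig(2100, 2200, contig_id="RC2")]
    kept, removed = filter_excluded(contigs, ann)
    assert [c.contig_id for c in kept] == ["RC2"]
    assert [c.contig_id for c in removed] == ["RC1"]


def test_transposase_noted_not_excluded():
    ann = GeneAnnotation([Gene("t1", "chr", "+", 1000, 1600,
                               kind="transposase")])
    contigs = [make_contig(1200, 1300, strand="-")]
    kept, removed = filter_excluded(contigs, ann)
    assert kept and not removed
    res = classify_contig(kept[0], ann)
    assert res.rna_class == "antisense"
    assert "transposable-element" in res.relation_notes


def _cluster_inputs(positions):
    contigs = [make_contig(s, e, contig_id=f"RC{i}")
               for i, (s, e) in enumerate(positions)]
    from srnacall.classify import ClassifiedTranscript

    transcripts = [ClassifiedTranscript(c.contig_id, "trans", "2")
                   for c in contigs]
    return transcripts, contigs


def test_cluster_gap_150_joins():
    transcripts, contigs = _cluster_inputs([(1000, 1100), (1251, 1350)])
    assert find_clusters(transcripts, contigs) == [["RC0", "RC1"]]


def test_cluster_gap_exactly_200_does_not_join():
    transcripts, contigs = _cluster_inputs([(1000, 1100), (1301, 1400)])
    assert find_clusters(transcripts, contigs) == []


def test_clusters_match_single_linkage_oracle():
    rng = np.random.default_rng(42)
    for _ in range(200):
        n = int(rng.integers(2, 12))
        starts = np.sort(rng.choice(5000, size=n, replace=False)) * 3
        positions = [(int(s) + 1, int(s) + int(rng.integers(50, 200)))
                     for s in starts]
        positions = [(s, e) for s, e in positions]
        # drop overlapping layouts
        ok = all(positions[i + 1][0] > positions[i][1]
                 for i in range(len(positions) - 1))
        if not ok:
            continue
        transcripts, contigs = _cluster_inputs(positions)
        got = find_clusters(transcripts, contigs)
        # oracle: single-linkage chaining on gaps < 200
        chains, cur = [], [0]
        for i in range(1, len(positions)):
            if positions[i][0] - positions[i - 1][1] - 1 < 200:
                cur.append(i)
            else:
                chains.append(cur)
                cur = [i]
        chains.append(cur)
        want = [[f"RC{i}" for i in ch] for ch in chains if len(ch) >= 2]
        assert got == want


def test_summary_singleton_and_quartiles():
    transcripts, contigs = _cluster_inputs([(1000, 1099)])
    counts, stats = summarize(transcripts, contigs)
    assert counts["count"].sum() == 1
    row = stats.iloc[0]
    assert row["min"] == row["q1"] == row["median"] == row["mean"] == \
        row["q3"] == row["max"] == 100


def test_summary_quartiles_match_sorted_list_oracle():
    rng = np.random.default_rng(8)
    lengths = rng.integers(53, 260, size=37)
    positions = [(1000 + i * 1000, 1000 + i * 1000 + int(l) - 1)
                 for i, l in enumerate(lengths)]
    transcripts, contigs = _cluster_inputs(positions)
    _counts, stats = summarize(transcripts, contigs)
    row = stats.iloc[0]
    q1, med, q3 = np.percentile(np.sort(lengths), [25, 50, 75])
    assert row["q1"] == pytest.approx(q1)
    assert row["median"] == pytest.approx(med)
    assert row["q3"] == pytest.approx(q3)
    assert row["mean"] == pytest.approx(lengths.mean())
    assert row["min"] == lengths.min() and row["max"] == lengths.max()


def test_summary_empty_input():
    counts, stats = summarize([], [])
    assert counts.empty and stats.empty


def test_counts_invariant_under_translation():
    genes = [Gene("gA", "chr", "+", 601, 900), Gene("gB", "chr", "-", 1601, 1900)]
    shift = 5000
    shifted = [Gene(g.gene_id, g.replicon, g.strand, g.start + shift,
                    g.end + shift) for g in genes]
    for start in range(400, 2200, 37):
        a = classify_contig(make_contig(start, start + 99),
                            GeneAnnotation(genes))
        b = classify_contig(make_contig(start + shift, start + shift + 99),
                            GeneAnnotation(shifted))
        assert (a.rna_class, a.subtype) == (b.rna_class, b.subtype)
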