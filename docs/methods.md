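# Methods

This note documents the models and procedures implemented in `srnacall`,
their assumptions, the parameters that matter, and the choices made where
the design was genuinely open. Nothing here states an empirical result that
the test suite or `scripts/acceptance.py` does not itself compute.

## Coordinates and conventions

All genomic coordinates are 1-based and inclusive (GFF3/SAM convention);
BED6 and bedGraph outputs are converted to 0-based half-open at the I/O
boundary, and a round-trip test pins the conversion. Biological 5'/3'-ends
are strand-aware: on the minus strand a read's 5'-end is its higher
coordinate. Unstranded (total-RNA) alignments carry no strand and by default
do not contribute to strand-specific contig calling; an explicit flag adds
them to both strands.

## Contig calling

A contig is defined by a seed — a maximal run of positions with pooled depth
≥ C containing at least L_min consecutive such positions — extended on both
sides while depth ≥ c. "Covered by at least C reads" is read as per-position
depth, not C distinct reads spanning the whole seed; positional depth is the
standard reading and is what makes extension by c well defined. Two presets
are provided: (L = 50–350, C = 10, c = 5) for variable-length long reads and
(L = 50, C = 5, c = 2) for short reads. Runs are maximal ≥c intervals; seeds
never merge across sub-c gaps. Contigs whose extended length exceeds L_max
are flagged over-length and dropped from default reports rather than
truncated: the emulated protocol size-fractionates RNA below ~350 nt, so an
over-length call signals misconfiguration, not biology. By default depth
pools the primary- and processed-enriched libraries; per-library means are
kept on every contig for provenance (S1 / S2 / S1&2) reporting.

One caller property worth noting: raising C can only remove calls, but
raising c can *split* one call into two when a bridging region drops below
the new threshold, so the call count is not monotone in c — the covered
territory is. The tests assert the monotone forms.

## Distinct ends and primary labels

A position is a distinct 5'-end when more than 5 reads (i.e. ≥ 6 — the
strict reading) share it and either it lies within the first two bases of
the contig (strand-aware) or its count reaches at least 10% of the contig's
mean coverage, where mean coverage is total depth over the contig divided by
its length, pooled over the samples used for the call. Symmetric rules apply
to 3'-ends on the 3'-end-count track. Ends are searched within the contig
± 2 nt, since reads may start just outside the called boundary.

Primary labelling compares per-library end calls: a 5'-end distinct in the
primary-enriched library is primary, regardless of its relative count in the
processed library (the screen has no quantitative criterion for mixed
support; presence in the enriched library's distinct list is taken as
sufficient). Ends one or two nucleotides apart are reported separately —
single-nucleotide TSS scatter is a real phenomenon — with an optional merge
radius (default 0) for compact reporting.

## Classification

The minimal transcription unit (MTU) of a gene is its CDS extended by an
assumed 60-nt 5'-UTR and 20-nt 3'-UTR; the same geometry drives the
trans-exclusion rule and the UTR-overlap subtypes so the classes partition
placements consistently. Decision order per overlapping gene, same strand
first: whole-ORF cover; mRNA leader (5'-end in [start_codon − 40,
start_codon + 1], 3'-end strictly inside the CDS); sense subtype 1 (5'-end
in the remaining 5'-UTR span −60…−41 with 3'-end in the CDS), 2 (fully
inside), 3 (CDS overlap extending past the stop), 4 (5'-end in the 3'-UTR).
Opposite strand: antisense subtype by overlapped part (5'-UTR → 1, CDS
interior → 2, 3'-UTR → 3). No MTU overlap on either strand → trans, type 1
when both nearest flanking genes (either strand) run antisense to the
contig, else type 2.

Open corners of this table required decisions: a same-strand contig confined
entirely upstream of the CDS (including leader-window starts whose 3'-end
never reaches the CDS) is sense type 1; one confined downstream is type 4;
antisense overlaps spanning a UTR and the CDS take the UTR's type, and only
contigs spanning both UTRs get the joined type "1/3". A leader may not
extend past the CDS 3'-end — such a placement covers the ORF and is
classified whole-ORF. Precedence orf_cover > leader > sense > antisense >
trans resolves multi-gene ambiguity; relations to several genes of the
winning class join their subtypes sorted ("1/3"). Contigs overlapping
annotated rRNA/tRNA/repeat features are removed before classification;
transposase associations are kept but noted for separate reporting. An
independent re-statement of the full table, written directly on genomic
intervals in the test suite, is checked against the implementation by
sliding a 100-nt contig base by base across a toy two-gene replicon in all
strand configurations.

Clusters are single-linkage chains of classified contigs with gaps strictly
below 200 nt, strand-agnostic, reported at size ≥ 2. Size summaries use
numpy's linear-interpolation percentiles.

## Promoter model

`build_pssm` smooths column counts with pseudocount 0.01:
P(b) = (count_b + 0.01) / (n + 0.04), log-odds = log2(P/background). The
background is the 0-order base composition of the input genome (strand-
symmetrized), the least-assuming choice. Score P-values are exact:
per-column score distributions are convolved on an integer lattice
(10⁻⁴ bits per bin) and the matrix's scores are themselves rationalized to
that lattice, so P(score) is exact for every score the scanner can emit; a
test checks full 256-word enumeration agreement on width-4 matrices.

Two scanner architectures exist. The two-box form (6-nt −35 box,
spacer 15–19 nt, 6-nt −10 box, combined P-value = product of box P-values)
is implemented and tested, but its combined P-value is bounded below by
P(best 6-mer)² ≈ 10⁻⁸ — twelve informative columns cannot reach the
historical cutoff 2.155343e-11, which presumes a full-width matrix trained
on complete promoter sequences. The default model therefore scans one
29-column PSSM (boxes plus spacer columns) whose training set is a
*synthetic* 25-sequence promoter compilation (`synthetic_sigma70_training`,
clearly labelled as such: near-consensus boxes with 8% per-position
degeneracy around an AT-rich spacer, the composition bacterial σ70 spacers
typically show); the real training compilation is not redistributable here.
The −10 box must end within 10 nt of the TSS (configurable; the positional
constraint is not otherwise fixed). The synthetic-data generator plants the
default model's maximum-likelihood word upstream of primary TSSs, so
promoter recovery at the cutoff tests the machinery rather than spacer luck.

## RNA structure and shape Z-scores

The energy model is a compact nearest-neighbour set: 36 stacking energies
over {AU, UA, CG, GC, GU, UG} pair stacks, affine hairpin penalty
5.4 + 0.25·(loop − 3) kcal/mol (minimum hairpin 3), affine interior/bulge
penalty 3.2 + 0.45·(unpaired) capped at 8 unpaired nt (larger interior
loops are outside the model space), and affine multiloops
3.4 + 0.4·(branches + 1) + 0.1·(unpaired), at 37 °C. It is deliberately
smaller than full thermodynamic parameter tables: the Z-score contract only
requires one consistent ensemble shared by transcript and background, and
the identical energy function drives four independent code paths — the
partition-function recursions, the stochastic sampler, a structure-level
energy evaluator, and an exhaustive structure enumerator — whose agreement
is tested (partition function equals the enumerated Boltzmann sum to
1e-9 relative at n ≤ 20).

Level-5 abstract shapes collapse helix nestings, drop unpaired regions and
reduce every hairpin to `[]`; a pair-free structure maps to `_`. Shape
probabilities are estimated as sample frequencies over k stochastic
tracebacks (default k = 1,000) from McCaskill-style inside matrices rather
than by a full shape-indexed partition DP: the estimator is unbiased, far
simpler, and its accuracy is certified against exhaustive enumeration
(±0.02 at k = 5,000 for n ≤ 20). Dominant-shape ties break toward the
lexicographically smaller shape string; the dominant shape's reported
representative structure is the lowest-energy sampled member. Matrices are
computed in extended precision (x87 longdouble) so long GC-rich helices
cannot overflow the Boltzmann weights.

Backgrounds iterate same-strand windows of the transcript's length under
three policies — all, strided, or a seeded random subsample (default 500
windows) since scanning every genome window is not desk-scale; a
subsampling-consistency test compares policies. Windows whose dominant
shape differs are discarded; fewer than two qualifying windows yield an
undefined-background error carried in the result. Z = (Prob(t,p) − E)/S.
Note that conditioning the background on sharing the dominant shape caps
attainable Z near (1 − E)/S, so well-structured transcripts show a clear
positive bias rather than arbitrarily large scores; leave-one-out self-Z
over the background windows is mean ≈ 0, sd ≈ 1, which the acceptance
suite checks over ≥ 200 windows.

The pipeline's structure stage folds a bounded, deterministic subset of
candidates by default (the shortest 5 at ≤ 140 nt, k = 300, 30 background
windows at k = 120) — the stage is quadratic-to-cubic in length and the
default keeps a full run interactive; all knobs are in `StructureSettings`.

## ORF and RBS screen

Complete ORFs only: a start codon ({ATG, GTG, TTG}, configurable) with an
in-frame stop inside the sequence, length measured start through stop codon
inclusive (the "at least 60 nt" bound is applied to that inclusive length;
the alternative exclusive reading is not used, and the boundary is tested
exactly). Nested starts sharing a stop are all reported. RBS detection
slides the anti-Shine-Dalgarno tail UCCUCCA ungapped across the window
[−20, −4] upstream of the start codon and sums stacking energies over runs
of consecutive complementary pairs (same stacking table as the folding
model; isolated single pairs contribute nothing); a site is called at
energy ≤ −3.4535 kcal/mol, a calibration treated as an opaque configurable
constant. ORFs beginning at the associated gene's own start codon are
excluded from reporting (they lack an in-frame stop on the sRNA); the rest
are related to the gene by mod-3 frame and stop-coordinate comparison
(shared-stop / other-frame / within-5'-UTR).

## Hybridization filters

M = log2(small/long), A = 0.5·log2(small·long) — "half the base-2 log of
the combined intensities" formalized as the standard MA-plot definition.
The M ≥ 3 candidate threshold is inclusive and equals 8-fold linear
enrichment. Intensities must be positive; lowess normalization and FDR
testing belong to array preprocessing and are out of scope — the module
consumes normalized intensities. The chip criterion chains probes with
signal ≥ 2× background (inclusive) within one intergenic region at
inter-probe gaps ≤ 200 nt, requiring ≥ 2 probes; a stricter 150-nt preset
is provided because both figures circulate for this screen, and the default
follows the laxer published criterion.

## Synthetic data: what it emulates and what it does not

The generator emulates the study design's *geometry and end structure*: a
GC-rich (default 0.62) three-replicon genome (300 + 120 + 80 kb — a
chromosome and two plasmid-like replicons at desk scale), 200
non-overlapping CDSs with ≥ 150 nt intergenic gaps and a small admixture of
rRNA/tRNA/repeat/transposase features to exercise the exclusion filter, and
120 planted transcripts drawn from the observed class mix (trans 0.16,
antisense 0.09, leader 0.34, sense 0.40, whole-ORF 0.01), each placed so
that its class rule holds by construction and separated from every other
planted transcript by ≥ 80 nt so that neither coverage nor planted promoter
words can collide. Each class's primary fraction follows the reported
per-class rates (0.74/0.46/0.60/0.18). Reads: per-transcript counts
Poisson(mean_depth = 25); the primary-enriched library covers only primary
transcripts, starting exactly at the TSS (plus optional rounded Gaussian end
noise, default 0); the processed-enriched library covers everything — a
non-primary transcript's reads start at its processed 5' boundary (its
recorded tss), while primary transcripts split 50/50 between the TSS and one
per-transcript internal cleavage site, producing the alternative-5'-end
phenomenon; 60% of reads reach the true 3'-end, the rest truncate uniformly.
The unstranded total-RNA library emits fixed 36-nt strandless reads.
Background "degradation" reads are uniform in position and length at 0.2
reads/kb/strand — the callers filter by coverage, so any low-rate noise
exercises the filter; the real libraries' background rates are unknown and
these are free parameters, not estimates.

Not emulated: sequencing errors, quality scores, adapters, enzymatic
efficiencies of the enrichment steps, operon structure, or expression
heterogeneity between transcripts. Passing the recovery tests therefore
shows that the callers and classifier implement their rules correctly under
the stated read model — not that the thresholds are optimal for any real
library.

Circular replicons are supported by splitting wrap-around reads into two
alignment segments; default replicons are linear.

## Determinism and problem sizes

Every random choice flows through `numpy.random.default_rng` seeded from a
single configuration seed (stage-specific children derive from it), and all
float output uses fixed formatting, so a repeated run is byte-identical —
the acceptance suite asserts this on the candidate tables. The test-suite
and acceptance problem sizes (500 random caller tracks, 300 end vectors,
the full 19,200-placement classifier sweep, k = 5,000 shape sampling at
n ≤ 20, 420 background windows at n = 40) were chosen as the smallest sizes
at which the corresponding statistical checks are stable, and run in well
under a minute each.

## Known limitations

The energy model's parameters are a compact published-style subset, not a
calibrated thermodynamic table; absolute folding energies are not
comparable to full-parameter tools, only ensemble-relative quantities
(shape probabilities, Z-scores) are meaningful. The exact-P-value lattice
introduces ≤ 1.5 × 10⁻³ bits of total rounding, which can in principle
merge two distinct word scores into one bin. The two-box promoter scanner's
product P-value is conservative and cannot reach full-matrix significance
levels (see above). The classifier assigns exactly one class per contig;
genuinely bicistronic or partially overlapping arrangements are reduced to
the highest-precedence relation with joined subtypes.
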