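# Methods

This note documents the models, parameter choices and numerical
conventions behind `viromine`, and what the synthetic-community tests
do and do not demonstrate about real data.

## Coordinates, identity, and the alignment engine

All coordinates are 0-based, half-open, on the forward strand;
1-based conversion happens only in report writers. Alignment identity
is defined once, everywhere, as *matches / alignment columns*, with gap
columns counting as non-matches and `N` matching nothing.

The aligner (`viromine.align`) is seed-and-extend: exact k-mer seeds
(k = 15 for DNA, 4–5-mer words under BLOSUM62 for protein), grouped by
diagonal, extended into maximal scoring gap-free segments by repeated
best-subarray extraction, then chained across nearby diagonals under
affine gap costs (open −5, extend −2, diagonal shift bounded by
`band = 16`). Scoring defaults (+1/−2, BLOSUM62 with word 5 and a
50-score HSP floor for translated comparisons) approximate
megablast/tblastx behaviour and are overridable through the parameter
dataclasses.

The package's mutation model is substitution-only (below), so the
gap-free extension is exact: on such data the top hit equals the full
Smith–Waterman optimum. This is not assumed but *asserted*: the test
suite and the acceptance script compare seed-extend scores and
identities against an independent affine-gap dynamic-programming
implementation (scikit-bio's `pair_align`) on hundreds of seeded pairs;
the observed score deviation is 0 and identity deviation ≤ 0.1 %.
Sequences with genuine indel divergence would engage the chaining path
and are outside what the tests certify.

Read mapping is best-hit-only (ties broken by lexicographic genome id)
so per-genome counts are comparable and conservation-safe
(Σ counts ≤ reads). A read is *recruited* at threshold *t* when some
alignment window covering ≥ 90 % of the read reaches identity ≥ *t*.
Recruitment subjects are linearised; reads spanning a circular origin
may fail to map — a known, accepted bias of order read-length/genome-
length (~0.3 % here).

## Synthetic communities and the planted truth

The generator emulates the study system: circular dsDNA phage genomes
(default 30–200 kb, GC 18–55 %), per-sample lognormal abundances
structured by planted distribution tags, per-sample contig sets with
≥ 99 %-identical cross-sample genome copies, exact terminal repeats on
"complete" contigs, and reads at controlled per-base identity. Every
output is a pure function of `(spec, seed)`.

Two deliberate design choices:

* **Substitution-only mutation.** Planted divergence, contig copy
  error and read error are all point substitutions at uniform
  positions; an indel mode is not enabled by default. This keeps
  identity targets exact and every alignment oracle simple.
* **Exact mutation counts, not rates.** A copy at target identity *p*
  receives exactly `round(L·(1−p))` substitutions. For reads this is
  what "controlled per-base identity" has to mean for threshold
  behaviour to be sharp: with binomially sampled errors a 100-bp read
  population at 96 % identity straddles both the 95 % and 99 %
  recruitment thresholds (≈ 21 % of reads fall below 95 %, ≈ 9 % reach
  99 %), and no threshold semantics separates the two regimes cleanly.
  With exact counts the separation is essentially total (measured
  ≥ 99.6 % recruited at 95 %, ≤ 0.1 % at 99 %).

Hallmark cassettes (terminase, portal, tail, major capsid) are planted
as stop-free ORFs whose codons are drawn at the genome's GC target, so
realised GC stays within binomial tolerance of the target. The truth
table records genome sources and intervals for every contig, per-sample
read counts, planted tRNA inserts, protospacer positions, pairwise
identities and distribution tags — sufficient to score every stage
without re-reading the genomes.

What the generator does **not** emulate: assembly artefacts and
chimeras, indel and quality-score error profiles, strain microdiversity
within a population, uneven coverage, or real genome composition
(planted genes are random ORFs, not homologs of real proteins).
Passing tests therefore certify the *logic* of each stage under its
stated model, not performance on real assemblies.

## Stage-level choices

**Screening.** "Several hallmark genes" is quantified as ≥ 2 distinct
hallmark labels (configurable); the paper-scale alternative — synteny
with a reference phage — requires ≥ 3 consecutive hit-bearing genes
best-hitting one reference with monotonic gene order on one strand.
Contigs without gene calls simply fail screening; no error.

**Terminal repeats.** Completeness requires an *identical* terminal
direct repeat, found as the longest exact prefix/suffix match with
length in [30, 1000]; a mismatch-tolerant mode exists only for the
post-merge MAVG test (below). Contigs deemed complete from gene order
alone (GF) require an explicit curator-supplied list — that judgment is
not heuristically reproduced.

**Viral clusters.** Edges demand strictly > 90 % weighted identity and
> 20 % coverage *of the shorter sequence* (the only reading under which
a 10-kb fragment can cluster with a 196-kb genome); clusters are
connected components — single linkage, the weakest assumption
consistent with pairwise cut-offs. The in-repo aligner is exactly
symmetric (exact seeds, gap-free extension), so the edge test is
computed once per pair; symmetry is asserted by a test rather than
enforced by symmetrising.

**MAVG merging.** Overlap edges are dovetail (or containment)
alignments ≥ 500 bp at ≥ 99 % identity; layout is greedy from the
longest contig, strongest overlap first, and any edge whose implied
placement disagrees with the layout by > 100 bp marks the component as
a conflict — except the circular-closure case, where one edge
disagreeing by approximately the genome length is exactly what a
fragment set tiling a full circle produces, and is taken as circularity
evidence. Consensus is per-column majority with ties resolved in favour
of the longest contributing contig. Because merged end copies carry
independent mutations, post-merge circularity uses a mismatch-tolerant
(≥ 99 % identity) suffix–prefix dovetail in addition to the exact
terminal-repeat test.

**Recruitment and classification.** RPKG is computed exactly, with no
pseudocounts; metagenome size is (reads × read length) in Gb. The
detection floor is strict (> 10 RPKG). Depth classes: detected at ≤ 2
contiguous sampled depths → stenobathic; at every photic depth →
eurybathic; anything else → intermediate (added because the two named
classes do not partition all cases); nothing above floor → undetected.
Geography: endemic = detections confined to the origin region;
widespread = ≥ 2 stations including ≥ 1 outside it. Sample comparison
uses Bray–Curtis, UPGMA average linkage, and classical metric PCoA
(double-centred squared distances; eigenvalue sum equals total centred
variance to ≤ 1e-8, asserted in tests). CCA is out of scope.

**Genome taxonomy.** The source transform behind the log-scaled Dice
dissimilarity is not fully specified by its provenance, so the package
uses `d = log10(1 + 9·(1 − dice))` — monotone, bounded on [0, 1],
zero-preserving — and documents it as its own choice; whether the log
is applied to similarity or dissimilarity is switchable. Neighbour
joining is canonical Saitou–Nei: Q-matrix minimisation with
lexicographic tie-breaks, standard branch-length formulas, negative
lengths clamped to zero with the deficit moved to the sister edge,
unrooted newick output at 12 significant digits (branch-length
round-trip error ≪ 1e-9). Maximum-likelihood trees are deliberately
replaced by NJ throughout: NJ is fully specifiable without external
tooling and is exact on additive matrices, which the tests exploit.
One empirical caveat, measured rather than assumed: over ~30-kb random
unrelated genome pairs the translated-score null is not strictly zero —
a chance ungapped HSP near the 50-score floor appears in a minority of
pairs — but it stays below 0.2 % of the self score, so Dice ≈ 0 and the
tree distance ≈ 1 regardless.

**Host prediction.** Evidence precedence is tRNA = CRISPR > best-hit >
AMG > cluster-neighbour; a label conflict at the decisive level yields
an explicit `ambiguous` call. AMG-only host assignment (e.g. psbA →
Cyanobacteria) is off by default; terminase-phylogeny placement is
realised as marker-tree neighbourhood and likewise off by default — the
weakest evidence classes are opt-in. The > 75 % identity / > 50 %
coverage best-hit rule is applied at nucleotide level against labelled
reference genomes.

## Problem sizes used by tests and the acceptance script

Chosen as the package's own benchmark conditions: 200 + 200 contigs for
terminal-repeat sensitivity/specificity; 20 seeded sets of 60 contigs
from 12 genomes (10–14 kb) for the clustering oracle; 20 seeded
shreddings of a 150-kb circular genome into 5 contigs over 3 samples
(0.2 % copy error) plus an unrelated decoy genome for MAVG recovery;
3 000 reads at 96 % identity for threshold recruitment; 55 genomes over
a six-depth photic profile plus 40 genomes over six stations
(~1 500 reads/sample) for distribution classification; 20 six-genome
duplication–divergence series (10 kb) for Dice/NJ topology recovery;
12 genomes with planted tRNAs/protospacers plus a hand-scored ten-gene
fixture for host prediction; 50 seeded pairs ≤ 2 kb at 1–8 % divergence
for the Smith–Waterman oracle; and two full runs of the 12-genome,
4-sample demonstration community for byte-level determinism.

## Known limitations

* Gap handling is limited to chaining collinear gap-free segments;
  long-indel or spliced alignment is out of scope.
* No E-value statistics; HSP retention is by raw score.
* The ORF caller is deliberately simple (start-to-stop, table 11,
  ≥ 60 codons) and is not expected to reproduce Prodigal gene models
  or counts.
* Circular subjects are linearised for read recruitment (origin-
  spanning reads may be lost).
* GF completeness and AMG host groups rely on supplied tables, not
  inference.
* Real-data performance is bounded by the generator's realism; see the
  generator section above.
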