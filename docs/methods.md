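# Methods

This note records the models, parameter choices and numerical
conventions behind `mitorrna`, in the spirit of a package methods
appendix: what is computed, under which assumptions, and where the
design was genuinely open.

## Coordinates and alphabets

Internal coordinates are 0-based half-open everywhere; every report and
file output is 1-based inclusive.  Sequences are stored DNA-style (U is
normalized to T on ingest) over the IUPAC nucleotide alphabet.
Ambiguity codes are preserved in records but treated as missing data by
all statistics — the simplest defensible policy, stated in each report.
Pairing is Watson-Crick plus G·U wobble (standard for rRNA; wobble can
be disabled per call).  Ambiguity codes never pair: a stem is extended
only through unambiguous evidence.

## Structure templates

A template describes one gene's reference model as an ordered list of
helices: CRW-style id, structural domain, 5′ and 3′ anchor motifs
(IUPAC, typically 6–12 nt), stem-length and loop-length ranges (base
pairs / nucleotides), a fractional expected center in the gene, and a
per-helix anchor mismatch budget.  Anchors operationalize the
comparative notion of "conserved regions shared across taxa": they are
the sequence evidence on which helix homology is anchored, and the
template states explicitly, per helix, what the reference model
expects.  Insect mitochondrial rrnL models lack domain III (a shortened
region between domains II and IV); templates declaring domain III for
rrnL are rejected at parse time.

Two example templates ship with the package: an 8-helix rrnS model
(domains I–IV; the helices commonly discussed for the 12S molecule:
H17, H47, H885, H921, H939, H1074, H1399, H1506) and a 44-helix rrnL
model (domains I–II and IV–VI).  Their anchor motifs are synthetic
stand-ins generated once with minimum pairwise Hamming distance 4
(against both motifs and their reverse complements) so that anchors are
mutually confusable only after several substitutions; helix ids without
a published CRW label are synthetic placeholders, marked as such in the
file header.  Real analyses should supply templates derived from
curated reference structures; the TSV format is one helix per line with
`#` comments, a `# gene:` declaration and an optional `# length:` hint.

## Annotation algorithm

For each helix, in template order:

1. The 5′ anchor is placed by exhaustive IUPAC-aware scan in a window
   around the expected center (half-width `max(20, 0.05 × L)` nt);
   the best placement minimizes mismatches, ties going to the leftmost
   position.  Placements overlapping previously resolved footprints are
   skipped, and all further work is confined to the free span
   containing the anchor.
2. The 3′ anchor is placed the same way, right of the 5′ anchor and
   within the maximal footprint plus the window slack.
3. Stem extension enumerates, over all diagonals between the two
   anchored regions, the maximal uninterrupted runs of complementary
   pairs (minimum run length 2; pairs must enclose at least 3 nt — the
   minimum hairpin loop).  The best run is chosen by (i) most base
   pairs, (ii) center closest to the expectation, (iii) 5′-most; up to
   `max_internal_break` (default 1) additional mutually nested runs are
   accepted, modelling bulged stems.
4. A helix with fewer than 3 pairs is reported missing; a result with
   more than half the template missing carries a degraded-annotation
   warning.  Inter-helix spans longer than 15 nt (tunable) are labeled
   hypervariable.

The procedure is greedy and deterministic; there is no hidden
randomness, and identical inputs yield identical annotations.  Element
counts follow the drawing conventions of comparative structure
diagrams: stems are maximal stacked-pair runs, loops are maximal
enclosed unpaired runs (terminal loop included), and the internal
unpaired length is the stretch enclosed by the innermost pair.

## Block alignment

Blocks are aligned with a three-state affine-gap aligner
(match +2, mismatch −1, gap open −4, gap extend −1), verified against
exhaustive enumeration on short strings.  Multiple rows are joined
progressively around the most central row (highest summed identity,
ties to input order), each new row aligned against the growing profile
with column scores summed over rows (gap characters neutral).
Traceback ties resolve match > gap-in-sequence > gap-in-profile, so the
output is deterministic.  For helix blocks the anchor prefix and suffix
columns are forced into register and only the enclosed part is aligned
freely; rows missing the helix are all-gap in that block (explicit
absence, not an error).  The consensus pairing line assigns a pair to a
column pair when at least 50% of the rows possessing the helix pair
those columns, then keeps a non-crossing subset by vote count.

Gap stripping removes a column when its gap fraction strictly exceeds
the tolerance — a 40% tolerance (the default) keeps columns with at
most 40% gaps.  The operation is idempotent and emits an old→new
column map.

## Diagnostics

**Iss.**  Per site, Shannon entropy (base 2) of the A/C/G/T frequencies
among non-missing residues; sites with fewer than two residues are
skipped.  The index divides the mean site entropy by the
full-saturation entropy computed from the global base frequencies, so
invariant data give 0 and data whose every site matches the global
composition at random give 1.  The index is invariant to row order,
column order and site duplication.

**Critical values.**  Rather than reproducing published fitted curves,
critical values are re-derived by simulation: JC69 evolution on a
balanced (symmetric) or pectinate (asymmetric) reference tree whose
every edge has the grid depth; at each depth the proportion of
replicates in which neighbor joining on p-distances recovers the true
topology (exact bipartition match) is measured, and Iss.c is linearly
interpolated at the 95% recovery crossing.  Neighbor joining uses
canonical Saitou–Nei updates with ties broken on the lowest taxon
label, and is cross-checked against an independent implementation in
the test suite.  Iss.cSym exceeds Iss.cAsym for trees of 8+ taxa (at 4
taxa the two unrooted shapes coincide); Iss.cSym grows with the number
of taxa, while Iss.cAsym falls — deep pectinate trees lose recoverable
signal sooner, which matches the published behaviour of these
critical values.  Two-sided p-values compare the observed index with
the replicate distribution pooled from the depths bracketing the
crossing.

**Composition.**  The per-taxon χ² compares each row's A/C/G/T counts
with expectations from the pooled composition (df 3); because the row
contributes to the pool, the test is slightly conservative (empirical
size ≈ 0.03–0.04 at nominal 0.05 with 10 rows — measured, and within
the tolerance the package tests for).  The overall test is the R×4
contingency χ² (df 3(R−1)).  A base absent from the pooled data drops
its cell with a df reduction and a warning.

## The simulator

The generator produces data with the statistical features the pipeline
assumes: conserved anchored stems, compensatory co-substitution,
hypervariable indel-rich linkers, and (optionally) one structurally
divergent lineage.  Defaults: paired-site substitution rate 0.3
relative to unpaired 1.0 (stems evolve under pairing constraint),
compensation probability 0.9, hypervariable indel rate 0.05 events per
site per unit branch length with geometric lengths (p = 0.5), tree
depth 0.05 substitutions/site for the canonical 11-taxon study, seed 11
for the canonical fixture.  Substitutions are Gillespie-style
(Poisson event counts per site, uniform replacement base, JC-like); a
compensated event sets the partner to the Watson-Crick complement.  An
optional per-lineage GC-bias knob (default off) injects compositional
heterogeneity.

Three constructions keep the ground truth exact:

- every alignment column carries an immutable key (a Fraction position
  plus creation serial); insertions take midpoint keys between their
  neighbors, so one global column order is consistent with every
  lineage's residue order and degapping any true-alignment row
  reproduces the leaf sequence verbatim;
- indels are confined to hypervariable linkers (real stems rarely gain
  indels, and this keeps stem pairing bookkeeping exact);
- root loops are drawn from a non-self-pairing alphabet (A/C), so the
  root's true structure is unambiguous — stems cannot extend into loops
  by chance.  Loop composition is therefore biased at the root; the
  composition statistics of simulated data should not be read as
  realistic base frequencies.

The divergent lineage has the 3′ strand of its designated helices
randomized and the enclosed loop doubled on its terminal branch,
mimicking a lineage whose helix geometry deviates from the rest of the
sample.

What the simulator does **not** emulate: covariance-model-like
context-dependent evolution, indels inside stems or loops, rate
variation across unpaired sites, realistic base composition, and
alignment ambiguity caused by repeated motifs.  Passing tests on this
generator therefore demonstrate the pipeline's correctness under its
own assumptions — anchored helices, localized indels — not performance
on arbitrary real data.

## Cross-taxon outlier rule

For one helix across taxa, a taxon is flagged when its (stems, loops)
pair differs from the modal pair, when its internal unpaired stretch
exceeds the modal value by more than 50% *and* by more than 3 nt, or
when the helix is missing.  The absolute guard exists because a bare
relative rule false-flags small helices on 1–3 nt of annotation jitter
(chance pairing at loop boundaries differs between taxa); 3 nt is below
any biologically discussed length contrast while comfortably above the
jitter.

## Problem sizes

The test suite and the acceptance script run the canonical 11-taxon,
790-nt rrnS study (depth 0.05), oracle comparisons at 500–1000 random
instances, Monte-Carlo critical values at 25–60 replicates over a
12-point depth grid, and the composition size check at 1000 simulated
10×500 alignments — sizes chosen so the whole suite completes in a few
minutes on one CPU while keeping Monte-Carlo noise well inside the
asserted margins.

## Known limitations

- Annotation quality is bounded by template quality; the shipped
  templates are worked examples with synthetic anchors, not curated
  reference models.
- Pseudoknots are not represented (dot-bracket output rejects crossing
  pairs), and thermodynamic folding is out of scope by design.
- The block aligner is a structure-aware progressive aligner, not an
  iterative refiner; for very divergent hypervariable blocks its
  columns are as ambiguous as any progressive method's.
- GenBank extraction falls back to inter-feature spans (trnL1→trnV,
  trnV→control region) when rRNA features are absent; records with
  unusual gene orders need explicit rRNA annotations.
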