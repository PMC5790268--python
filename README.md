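# mitorrna

Structure-guided analysis of insect mitochondrial ribosomal RNA genes
(`rrnS`/12S and `rrnL`/16S): template-based secondary-structure
annotation, structure-partitioned multiple alignment, per-helix
conservation and composition statistics, and alignment diagnostics
(substitution saturation, base-composition homogeneity).  A
structure-constrained sequence simulator with exact ground truth makes
every stage testable without any sequence download.

## Who this is for

Mitochondrial rRNA genes are among the most widely used phylogenetic
markers, but they are hard to align: indel-rich hypervariable regions
alternate with conserved helices, and automatic aligners misplace
homology in the variable parts.  The classical remedy is comparative:
realize a reference secondary-structure model (honeybee / fruit-fly
style, CRW helix numbering — H17, H47, H837, H1399, ...) on each
sequence, then align helix by helix so that columns correspond to
homologous structural positions.  This package turns that manual
procedure into a deterministic, tested pipeline for anyone preparing
rRNA alignments for phylogenetics or comparing rRNA structural motifs
across taxa.

## The method

**Annotation.**  A template lists each helix of the reference model as
a pair of conserved anchor motifs plus expected stem/loop geometry and
a fractional position in the gene.  For each helix, the annotator finds
the best IUPAC-aware anchor placements near the expected position, then
searches for uninterrupted antiparallel base pairing (Watson-Crick plus
G·U wobble) between the anchored regions — every diagonal is scanned
and maximal complementary runs are kept, with ties broken by run
length, closeness to the expected center, and 5′ position.  Helices are
resolved greedily in template order; resolved footprints are excluded
from later searches, so the result is deterministic.  Spans between
helices longer than 15 nt are labeled hypervariable.

**Alignment.**  Annotated sequences are cut into blocks (one per shared
helix, interleaved with linker/hypervariable blocks); each block is
aligned by a deterministic progressive aligner over an affine-gap core
(match +2, mismatch −1, gap open −4, gap extend −1), with anchor
columns of helix blocks forced into register.  Concatenating the
aligned blocks yields a Stockholm alignment with a majority-rule
`SS_cons` pairing line and per-column region labels.  Columns whose gap
fraction exceeds a tolerance (default 40%) can be stripped.

**Diagnostics.**  The substitution-saturation index is the entropy
index

    Iss = mean_site( −Σ_b p_b log2 p_b ) / ( −Σ_b f_b log2 f_b )

with per-site base frequencies `p_b` over non-missing residues and
global frequencies `f_b`; Iss is 0 for invariant data and 1 at full
saturation.  Critical values Iss.c are re-derived by Monte Carlo:
JC69 evolution is simulated on balanced (symmetric) and pectinate
(asymmetric) reference trees over a grid of depths, and Iss.c is the
index value at which neighbor joining on p-distances recovers the true
topology in 95% of replicates.  Base-composition homogeneity is tested
per taxon against the pooled composition (χ², df 3) and overall on the
taxa × bases contingency table (df 3(R−1)).

**Simulation.**  The generator emulates the statistical shape of a
mitochondrial rRNA gene: anchored stems kept paired by compensatory
substitution (paired-site rate 0.3× the unpaired rate, compensation
probability 0.9), hypervariable linkers accumulating geometric-length
indels, and an optional divergent lineage whose designated helices have
their 3′ strand randomized and loop doubled.  Column identities are
tracked exactly, so the true alignment and true structures are known.

## Worked example

```python
from mitorrna import annotate_sequence, load_example_template
from mitorrna.simulate import default_config, evolve, helix_recovery
from mitorrna.stats import classify_sites, compare_helix_across_taxa, helix_conservation
from mitorrna.structaln import build_struct_alignment, strip_struct_alignment

template = load_example_template("rrnS")
sim = evolve(default_config(template, depth=0.05, seed=11))
structures = {r.id: annotate_sequence(r, template) for r in sim.leaf_records}

print("recovery:", round(helix_recovery(sim, structures), 3))
saln = build_struct_alignment(sim.leaf_records, list(structures.values()), template)
stripped, _ = strip_struct_alignment(saln, 0.40)
print("columns:", saln.base.column_count, "->", stripped.base.column_count,
      "after 40% gap stripping")
sc = classify_sites(saln.base)
print("site classes:", sc.conserved, "conserved /", sc.variable, "variable /",
      sc.parsimony_informative, "parsimony-informative")
print("H1399 conserved: %.2f%%" % helix_conservation(saln, "H1399").percent_conserved)
flags = compare_helix_across_taxa(list(structures.values()), "H47")
print("H47 outliers:", sorted(flags[flags.flagged].taxon))
```

prints

```
recovery: 1.0
columns: 929 -> 791 after 40% gap stripping
site classes: 678 conserved / 141 variable / 80 parsimony-informative
H1399 conserved: 76.67%
H47 outliers: ['T01']
```

Eleven simulated taxa evolve at depth 0.05 substitutions/site; every
unperturbed helix is recovered (footprint Jaccard ≥ 0.8 against
truth), the structure alignment spans 929 columns (791 after 40% gap
stripping), and the engineered divergent lineage T01 — whose H47 helix
was structurally perturbed — is the only taxon flagged by the
cross-taxon H47 comparison.

The same stages are available from a shell:

```sh
mitorrna simulate --seed 11 --outdir fixtures
mitorrna annotate --fasta fixtures/fasta/leaves.fasta \
    --template fixtures/templates/rrns_helices.tsv --out annotations.txt
mitorrna pipeline --config run.cfg
```

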