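# Methods

This note documents the models, conventions and numerical choices behind
`neoprio`, in the order the pipeline applies them.

## Cohort model and burdens

A cohort is a set of patients, each contributing one or more sequenced
tumor *foci* (samples); a focus is staged pre-invasive or invasive.
Somatic variants carry a MAF-style classification (missense, nonsense,
nonstop, splice-site, frameshift insertion/deletion, in-frame
insertion/deletion, silent) and a coarse type (SNV / INS / DEL).
Coordinates are 1-based inclusive throughout (MAF convention); the
annotated-VCF reader strips the indel anchor base and shifts positions to
match on read. Silent variants are parsed and retained but excluded from
every tally, from TMB, and from peptide generation.

**TMB** is the count of non-silent mutations divided by the interrogated
capture size in megabases. The capture size is a configuration value with
default 38.0 Mb — a typical human whole-exome capture; there is no single
universal denominator, so it is always explicit. SNV- and InDel-derived
components are reported separately and sum to the total exactly.

**SNV spectrum.** Base substitutions are collapsed onto the six
pyrimidine-reference classes (C>A, C>G, C>T, T>A, T>C, T>G); a purine
reference is complemented (G>A reported as C>T). The collapse is
idempotent.

**Gene ranking.** "Mutation frequency" is defined as the number of samples
carrying a non-silent variant in the gene, with ties broken by total
variant count (descending) and then gene symbol. A cross-patient
consistency screen returns genes mutated in *every* patient whose pooled
variant-class set is a single class; "same kind of mutation" is interpreted
at the classification level, not the amino-acid-change level (both are
computable; classification is the default because identical protein changes
across unrelated patients are rare enough to make the stricter screen
nearly always empty).

## Peptide enumeration

Variants are applied to a coding sequence and the edit is re-translated
with the standard codon table (NCBI table 1; selenocysteine and stop
readthrough ignored). Frameshifts are translated from the shifted codon to
the first novel stop; a frameshift that never reaches a stop is flagged
stop-loss-like and translated to the end of the CDS. Splice-site variants
yield no peptides (no splicing model). The altered protein span is computed
by longest-common-prefix/suffix comparison of the wild-type and mutant
proteins; for a pure in-frame deletion the span marks the junction
residues, so enumeration windows cover the new sequence join.

Every mutant window of lengths 8–11 overlapping the altered span is paired
with the wild-type window **at the same start coordinate**. For
substitutions the members differ at exactly one residue; for frameshifts
and in-frame indels the wild-type window can be entirely unrelated — this
same-coordinate rule is a design choice (equal-length but dissimilar
wild-type controls are what one observes in practice for frameshift
neoantigens), and when the window would run past the shorter wild-type
terminus it is right-aligned to the terminus. Windows containing stops or
nonstandard residues, and windows whose mutant equals the wild-type, are
dropped before scoring. All windows are enumerated (not only a best window
per mutation); deduplication then keeps one pair per (gene, mutant
sequence), unions the foci sets of merged duplicates, and keeps the
best-scoring occurrence when scores are attached. Deduplication is
idempotent.

Only plus-strand, single-exon toy transcripts are modeled (one transcript
per gene, CDS starting at contig position 1). Mapping real spliced,
stranded annotation onto transcripts is out of scope; callers supplying
real data must provide transcript-relative coordinates.

## Binding and the first-round filter

Binding predictions are records of (peptide, allele, algorithm, pre-score
*a*). Affinity-type algorithms (NetMHCpan, IEDB-BA, the toy predictor)
report nM concentrations where lower is stronger; eluted-ligand and
SYFPEITHI scores are higher-is-stronger. Parsers are provided for three
tabular dialects with golden fixtures in `fixtures/`.

A pair is a **high binder** iff IC50(mut) < 500 nM and IC50(mut) <
IC50(wt), both strict. The filter is evaluated on a single IC50 source
(NetMHCpan preferred, then the toy predictor, then IEDB-BA) — mixing
concentrations from different models inside one inequality would be
meaningless. With multiple patient alleles a pair qualifies if the
condition holds for at least one allele; single-allele screening is the
default, matching the common situation where one allele (A*02:01) anchors
the validation assay. Pairs missing a score are skipped with a warning,
never silently counted as non-binders.

**TNB** for a sample is the number of distinct non-silent mutations with at
least one high-binder peptide, split by SNV/InDel origin (components sum to
the total). Class-II TNB flows through the same accounting from externally
parsed class-II calls; no class-II peptides are enumerated internally.

### Toy predictor

The built-in predictor exists so the full pipeline runs deterministically
offline; it does not approximate any published model's accuracy. The base
pseudo-IC50 is log-uniform over [100, 2000] nM, derived from a SHA-256 hash
of (peptide, allele, seed); each matched canonical A*02:01 anchor (L/M at
position 2, V/L/I at the C-terminus) divides the value by 25. The base span
(20×) is deliberately smaller than one anchor factor, so an additional
matched anchor outranks any hash draw — anchor ordering is a guaranteed
property, not a statistical one.

## Harmonization and ranking

Affinity pre-scores are transformed to *b* = 1/log *a* (log base 10 by
default; the base is configurable and cancels in the rank-preserving
rescale). The transform is singular at *a* = 1 nM, and sub-nM predictions
do occur; values ≤ 1 + ε (ε = 0.01) are clamped to 1 + ε with a logged
warning rather than rejected, so strong real predictions survive.
Eluted-ligand and SYFPEITHI scores need no transform. Fold change
FC = *a*(wt)/*a*(mut) is computed from the affinity source providing both
pair members; FC > 1 means the mutation improves predicted binding.

Each score column is min-max rescaled onto [1, 20] via
c = (b − min b)/(max b − min b) × 19 + 1, computed **within the displayed
candidate batch** (the top-*n* selection), so the batch minimum maps to 1
and the maximum to 20. A degenerate batch (all values equal) maps to the
midpoint 10.5 — an arbitrary but order-safe choice.

Selection is two-round: round 1 takes the *n* (default 30) candidates with
the lowest mutant IC50; round 2 attaches the per-algorithm *c* columns plus
the fold-change column and orders by **consensus**, the unweighted mean of
a candidate's available *c* values, with ties broken by mutant IC50 then
pair id. Unweighted mean is the default aggregation because nothing in the
problem privileges one predictor; subjective wet-lab criteria (synthesis
difficulty, solubility) are explicitly not modeled.

The multifocal screen returns candidates whose foci set has size ≥
`min_foci` (default 2), with the full pairs × foci presence matrix for
context; `min_foci = 1` is the identity.

## Synthetic cohorts

The generator emulates a small multifocal exome study. Defaults: 4
patients, each with 2 pre-invasive + 2 invasive foci; 120 genes with random
single-exon CDSs of 60–180 codons; ~216 expected mutations per focus
(Poisson) — matching a cohort of ~1500 mutations over 7 samples; a
missense-dominant class mix (missense 75.4%, frameshift deletions 8.8%,
in-frame deletions 5.6%, frameshift insertions 3.3%, remainder split over
nonsense 3.5%, splice-site 2.0%, in-frame insertions 1.0%, nonstop 0.4% —
the minor-class split is the package's own choice); trunk fraction 0.3;
planted-binder fraction 0.1.

Each patient draws a Poisson number of distinct mutation events; each event
is *trunk* with probability `trunk_fraction` (replicated into every focus
at identical coordinates) or private to one uniformly chosen focus. The
event rate is scaled by 1/(t + (1 − t)/F) so the expected per-focus burden
equals `mutations_per_focus` regardless of the trunk fraction. This makes
the trunk fraction directly recoverable as a binomial proportion over
distinct events.

Binding simulation plants high binders **per mutation**: with probability
`binder_fraction` a mutation's peptide set contains exactly one planted
pair, with IC50(mut) ~ U(10, 450) nM and IC50(wt) = IC50(mut) × U(1.5, 10)
— satisfying both filter conditions by construction — while all other
peptides draw IC50 ~ U(600, 20000) nM and fail the threshold. This
per-mutation semantics is what makes E[TNB] = q × (mutation count) exact.
Eluted-ligand and SYFPEITHI columns are rank-concordant with affinity plus
multiplicative noise. A single seed drives everything; rerunning a
configuration is byte-identical.

What the generator does **not** emulate: trinucleotide mutational
signatures, copy number, tumor purity/clonality, spliced or minus-strand
transcripts, expression filtering, or realistic binding-score
distributions. Tests passing on synthetic cohorts therefore demonstrate
correctness of the accounting and the screening logic under known ground
truth — not predictive performance on real tumors.

## Problem sizes used in checks

Recovery checks run at sizes chosen to make 3-standard-error bounds tight
while keeping the default suite fast: class-mix recovery at ~5000 mutations
in a single focus; TNB recovery at ~2000; the TMB–TNB correlation across
10 single-focus samples spanning a 10× burden range (expected means 30 to
300); the stage comparison on the default 4×4-focus layout; planted-binder
recall at ~150 mutations with q = 0.1, keeping the expected plant count
comfortably under the top-30 cut.

## Known limitations

- Genomic-to-transcript mapping is the caller's responsibility beyond the
  toy-genome convention; strand and splicing are not modeled.
- The first-round filter needs affinity-type scores for both pair members
  from one source; pure eluted-ligand screening is not supported.
- The consensus is a mean over whatever *c* columns exist; candidates
  scored by fewer algorithms are neither penalized nor imputed.
- Class-II presentation is accounting-only (external calls), never
  predicted.
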