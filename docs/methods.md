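# Methods

This note documents the models and procedures magpipe implements, the
parameters that matter, the numerical choices made where the design was
genuinely open, and what the synthetic-data generators do and do not
emulate.

## Scope and inputs

magpipe starts where assembly, binning, ORF prediction, read mapping,
HMM/BLAST searches, multiple alignment and tree inference end. Its
inputs are the tabular and text outputs of those tools: HMMER3
per-target tables (`--tblout`), 12-column BLAST tabular files, FASTA
(plain or aligned), Newick trees, and TSV coverage/count matrices.
Nothing in the package maps reads, infers alignments or builds trees.

## Bin quality control

A metagenome bin is scored against a conserved single-copy bacterial
marker set (default: the 31-gene set popularised by AMPHORA2; the HMMs
themselves are not bundled, hit tables are inputs). Each ORF is
assigned to at most one marker — the model of its lowest-E-value hit at
or below the cutoff (default 10⁻⁵, hmmsearch's `-E 0.00001`), ties
broken by bit score then model name — and

* completeness = fraction of markers with ≥ 1 assigned ORF,
* misbin (contamination) = fraction of markers with ≥ 2 assigned ORFs.

No standard arithmetic exists for "misbin"; the fraction-of-duplicated-
markers reading was chosen over excess-copies/total-copies because it is
the simplest statistic consistent with "multiple copies of single copy
genes" as evidence of mixed bins. Tier boundaries are half-open:
completeness ≤ 0.50 or misbin ≥ 0.10 → *rejected*; completeness ∈
[0.50, 0.90) → *incomplete*; completeness ∈ [0.90, 1] → *near_complete*.
Completeness exactly 0.90 counts as near-complete (the published tier
labels "NC > 90%" and "IC 50–89%" leave 89–90% undefined; a half-open
convention removes the gap deterministically).

Since completeness and misbin count markers, both are multiples of 1/31
and planted values on that grid are recovered exactly — the basis of
the bin-QC recovery tests.

## Marker-gene (rpS3) abundance

Ribosomal protein S3 is universal and single-copy, so per-sample rpS3
coverage approximates organism abundance.

**Pairwise identity.** Sequences are aligned globally with match +2,
mismatch −1, linear gap −2 and free terminal gaps (Biopython's
`PairwiseAligner` does the alignment). Identity is identical columns
over aligned columns, excluding terminal-gap columns. One guard was
added after analysis: with free end gaps, the *optimal* alignment of
two unrelated sequences collapses to a one-or-few-residue overlap,
whose excluded-terminal-gap identity is spuriously ~100%. The
denominator is therefore floored at the shorter sequence's ungapped
length (the same spirit as USEARCH's matches/shorter-sequence
definition). This changes nothing for homologous pairs — a shared core
with unaligned termini still scores by the core — and makes unrelated
pairs score near zero instead of near one. An
`include_terminal_gaps=True` mode gives the full-column denominator.
Symmetry is guaranteed by ordering each input pair canonically (by
length, then id) before aligning.

**Clustering.** Greedy centroid clustering: sequences sorted by
decreasing length (ties by id), each joining the first centroid, in
founding order, with identity ≥ threshold (default 0.99), else founding
a new cluster — the classic USEARCH/UCLUST scheme, made fully
deterministic by the explicit tie-breaks. The output is checked to be a
partition on every run.

**Abundance and taxonomy.** Per-cluster coverages (computed upstream)
are normalised to percentages summing to 100. Taxonomy per cluster is
the taxon of the best blastp hit (lowest E-value, ties by bit score
then subject id) at E ≤ 10⁻¹⁵; clusters with no qualifying hit are
`unassigned`. A subject id missing from the taxon map is an error, not
a silent drop.

## GH-family profiling

dbCAN emits multiple HMM hits per ORF; each ORF is resolved to the
single family with the lowest E-value at E ≤ 10⁻⁵ (ties by bit score
then family name). Counts are accumulated into a genome × family matrix
over a fixed universe (default GH1–GH135, shipped as an editable text
file) so that matrices from different runs are always column-compatible;
assignments outside the universe — including other CAZyme classes such
as GT/PL/CE — are dropped with a logged count. Presence/absence and
taxon-collapsed (row-sum) views support heatmap-style comparison;
collapse conserves total counts by construction. A coarse
family → substrate-class table (cellulolytic/starch/chitin/other) ships
for reporting only and carries no analytical weight. Counts are used
raw; a Hellinger or other transform before ordination is the caller's
choice.

## Ordination

**Bray-Curtis.** Computed vectorised via
Σₖ|xᵢₖ − xⱼₖ| / (Σₖxᵢₖ + Σₖxⱼₖ), which equals
1 − 2Σₖmin/(row sums). All-zero rows are rejected by name (the
dissimilarity is undefined for empty communities).

**NMDS.** Kruskal stress-1,
σ₁ = √(Σ(d̂ᵢⱼ − dᵢⱼ)² / Σdᵢⱼ²), minimised by SMACOF-style iterative
majorization: at each iteration the disparities d̂ are the isotonic
(monotone non-decreasing in the input dissimilarities) regression of
the current configuration distances (scikit-learn's
`IsotonicRegression`), rescaled to the distances' norm, followed by a
Guttman transform of the configuration. Start 1 is classical
(Torgerson) metric scaling — so exactly embeddable inputs converge
immediately — and the remaining starts (default 8 total) are uniform
random. The recorded stress sequence is non-increasing by construction:
an iteration that would raise stress restores the previous
configuration and stops that start. Default max 500 iterations,
convergence tolerance 10⁻¹²; the best start's configuration is centred,
rotated to principal axes, and sign-fixed for determinism under a given
seed. Any three points embed exactly in the plane under a monotone
transform, so n = 3 always reaches ~zero stress.

**RDA.** Response columns are centred; constraints are dummy-coded
(one indicator per level, drop-first) where categorical, centred, and
rank-reduced by pivoted QR (redundant columns dropped with a warning).
Least squares gives fitted values Ŷ = X(XᵀX)⁻Xᵀ Y; the SVD of Ŷ yields
the constrained eigenvalues sᵢ²/(n−1) and site scores; the constrained
variance fraction is ‖Ŷ‖²/‖Y꜀‖². By the Pythagorean property of least
squares, constrained + residual variance equals total variance, which
the tests assert. Variable loadings for biplot arrows are plain Pearson
correlations of each variable with each axis.

## Alignment trimming, concatenation, monophyly, phylum rule

Trimming is two-phase: columns are peeled from each end while their gap
fraction exceeds 0.5 (operationalising "unaligned ends" — no published
numeric exists, and 0.5 is configurable), then interior columns with
gap fraction strictly greater than 0.95 are dropped. The operation is
idempotent and errors if nothing survives.

Concatenation joins per-gene alignments (record ids = genome ids) in
input gene order, filling a genome's missing genes with all-gap blocks;
genomes present in fewer than half the genes (configurable) are dropped
— the 0.5 default is this package's choice where no published inclusion
criterion exists.

Monophyly on unrooted trees is the bipartition test: a tip set is a
clade iff some edge's removal splits the tips into exactly (set,
complement); on rooted trees (detected by a basal bifurcation, or
forced via `rooted=`), iff some node's descendant set equals it.
Singletons and the full set are trivially monophyletic. The test suite
checks agreement with an independent dendropy-based oracle on hundreds
of random trees.

The phylum rule: propose iff monophyletic AND n ≥ 2 genomes AND
(identity < 0.75, or identity ≤ 0.80 with the *strong clade* flag).
The "very obvious monophyletic clade" relaxation is a user-asserted
boolean, not inferred from support values, because no quantitative
criterion exists; the proposal record states which branch of the rule
fired.

## Residue conservation

Annotated reference positions (1-based, ungapped) are mapped through
the reference row's gap pattern to alignment columns; every other
sequence is scored `gap` / `match` / `mismatch` (exact membership in
the expected residue set; an optional substitution-group mode widens
the sets). The shipped NirK Cu-ligand table lists the canonical type 1
(2×His, Cys, Met) and type 2 (3×His) ligands with *placeholder*
positions — it is a synthetic template to be re-anchored on the user's
own reference, since no ground-truth coordinates are asserted.

## Synthetic data

Each generator takes explicit parameters plus a seed, drives all
randomness through one `numpy.random.default_rng(seed)`, and emits
machine-readable truth next to the data; recovery tests read truth only
from there. Defaults reflect the scales the recovery analyses use: bins
on the 1/31 marker grid; 10 clusters × 5 members of 200-aa proteins
with intra-cluster identity 0.995 (one substitution) and inter-centroid
identity ≤ 0.90 (verified at generation); GH signatures of 4 families
per taxon with Poisson(8) signature counts over Poisson(0.2)
background; trees built by grafting a random clade subtree onto a
random edge of a random background topology (monophyly by
construction); MSAs with a gapless reference, planted conserved sites
and explicit violations.

Limits worth knowing: sequences are uniform-random over the 20 amino
acids with point substitutions — no realistic evolutionary model, no
indel process, no compositional bias; trees have uniform-random
branch lengths and no clock; gap-rich columns are gapped in all
non-reference rows, so a >95% gap fraction with a gapless reference
needs ≥ 21 rows (the generator enforces this). Passing recovery tests
therefore demonstrates algorithmic correctness on data matching each
operation's assumptions, not robustness to real-data artefacts such as
fragmented ORFs, chimeric bins or alignment error.

## Problem sizes

The default verification runs use 200 synthetic bins, 20 clustering
fixtures of 50 sequences each, 500 random trees of ≤ 12 tips, 100
random count matrices for Bray-Curtis, 10-sample NMDS/RDA fixtures, a
9-genome GH fixture and a 20-sequence × 150-column MSA — sizes chosen
so the full suite and the acceptance script each complete in well under
a minute on a single CPU while exercising every code path.
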