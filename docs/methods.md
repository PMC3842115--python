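# Methods

## Pooled-reference integration of isobaric runs

Isobaric 8-plex labeling quantifies reporter-ion intensities for up to eight
channels per LC-MS/MS run, but intensities are only comparable within a run.
The pipeline assumes one channel of every run carries the same pooled
reference (a mixture of all study samples) and uses the within-run ratio to
that channel as the unit of quantification. Under a multiplicative error
model this cancels protein-specific ionization efficiency and run-level
offsets exactly; what remains is the sample's deviation from the pool
average plus channel noise. Records whose pool quantity is missing or zero
cannot be expressed on this scale and are dropped (counted in the manifest).

The identification filter retains proteins that passed the run-level FDR
cutoff and were identified by ≥ 2 peptides at ≥ 90 % confidence or a single
peptide at ≥ 99 %. It consumes the evidence fields as input metadata; decoy
FDR estimation is upstream of these tables and out of scope.

Merging runs is a pure union — no re-scaling — because the pool ratio *is*
the cross-run normalization. Missing values are explicit and never imputed;
the only missingness-handling mechanism is the common-protein filter (keep
rows quantified in every sample), after which each sample column is rescaled
to unit arithmetic mean. Equal means are both enforced (normalization) and
reported pre-normalization in the manifest as a labeling-equivalence QC
check.

## Clustering and PCA

Sample distances are ordinary Euclidean distances between paired protein
vectors, by default on log2 ratios so that 2-fold up and down are
equidistant from unity; a raw-ratio mode is kept for sensitivity analysis.
No per-protein standardization is applied. Linkage defaults to complete
(the common default of heatmap-ordering tools) and is configurable
(`complete`/`average`/`single`); agglomeration is delegated to
scipy.cluster.hierarchy and cross-checked in the tests against a naive
O(n³) re-agglomeration oracle. Group cohesion is quantified by cutting the
tree into k clusters and scoring majority-group purity.

PCA takes proteins as observations and samples as variables, so components
are directions in sample space: each sample has a loading, each protein a
score, and with column centering only (no unit-variance scaling — scaling
would equalize samples and distort the variance decomposition) the
variance fractions partition total between-sample variance. The solver is a
full deterministic SVD — no randomized approximation — with
`min(n_proteins − 1, n_samples)` components, which spans every nonzero
direction of the centered matrix, so fractions sum to 1. Signs are fixed by
a deterministic convention (largest-|loading| entry positive) and then
re-anchored to biology: PC1 positive on fresh adult hepatocytes (maturity),
PC2 positive on fresh fetal (cell-line axis points negative toward HepG2),
PC3 positive on ECM-sandwich cultures (dedifferentiation). Anchoring only
negates whole components; an exactly-zero anchor-group mean loading leaves
the component as computed, with a warning.

Whether the source analyses log-transformed ratios before the heatmap and
PCA is not determinable from their description; log2 is the default here
and both modes are exposed (`transform: log2|none`).

## Enrichment

The **detection test** is the one-sided hypergeometric tail: with N
annotated proteins in the background universe, K carrying a term, and a
foreground of n detected proteins of which k carry it, p = P(X ≥ k). The
universe is always an input (the annotation file), never hard-coded, and
the foreground defaults to the common-protein set.

The **PC score tests** compare a term's protein scores against all other
scored proteins: `absWilcox` is a one-sided Wilcoxon rank-sum on absolute
scores (alternative: annotated more extreme — extremeness is directional in
|score| by construction), `wilcox` a two-sided rank-sum on raw scores, `ks`
a two-sided two-sample Kolmogorov–Smirnov. Exact rank-null enumeration is
used when both groups have ≤ 8 members and there are no ties; otherwise a
tie-corrected normal approximation.

The **elimination algorithm** decorrelates the is_a DAG: terms are visited
in reverse topological order (children before parents, ties broken by term
id), each tested on its current annotation set if it has ≥ `min_size`
members (default 3 — smaller sets make rank tests meaningless); when a term
is significant at `elim_threshold`, its current proteins are removed from
all ancestors before those are tested. Both thresholds default to 0.001 and
equal the reporting threshold; they are independent configuration because
the source description fixes only the reporting cutoff. Raw p-values are
the primary output; a Benjamini–Hochberg q column is appended as a clearly
non-primary convenience. Overlapping significant terms are grouped by
single-linkage on Jaccard ≥ 0.5 of their post-elimination sets (the
"cluster of ribosomal terms" phenomenon), and per-term score distributions
with medians are exported for violin plots.

## Markers

Signatures intersect top-k lists (default k = 75) from two signed component
rankings; ties at the k-th rank are broken by accession lexicographic order
and logged, since any other convention is equally defensible and membership
near the boundary depends on it. Single extreme proteins (e.g. the most
negative PC1 score subject to positive PC2) are located by constrained
optimization over the score table with the same tie-break.

## Synthetic data: what it emulates and what it does not

The generator reproduces the study design: four 8-plex runs each with one
pool channel, 24 samples in six groups (8 fresh fetal, 4 fresh adult spread
one per run, 3 HepG2, 3 fetal ALI-3D, 3 adult ALI-3D, 3 adult ECM-sandwich),
~1,500 proteins. On the log2 scale a protein's channel value is
baseline + group effect + run offset + N(0, noise_sd); the pool channel
carries the equal-weight mean of the group means, so pool ratios cancel
baseline and run offset up to noise. Detection operates per (protein, run) —
a protein missed in a run is missing for all its samples, the regime in
which a "quantified in every sample" filter is meaningful — with logistic
abundance dependence; a core fraction is always detected. Dropout uniforms
are drawn from a dedicated stream so detection is monotone in the midpoint.

Default group effects are low-rank: four latent axes with per-protein
normal loadings — maturity (weight 1.0, adult-derived positive), cell line
(0.6, HepG2 negative), ECM dedifferentiation (0.45) and a weakest
membrane-culture signature (0.35). The fourth axis exists because the
emulated study observed cosegregation entirely by sample type with culture
formats clustering adjacent to, but separate from, their fresh parent
types; without a coherent culture-format shift the culture variants are
collinear with their parents and cannot form their own clusters. Two
simpler structures are available: `independent` (iid effects per group) and
`adult_vs_rest` (a single two-sided contrast). Planted score-enriched terms
give a term's member proteins a coordinated shift (2 × effect_sd by
default) on one axis; the truth object records baselines, the full
protein × group effect matrix, run offsets, the core set and planted terms.

Default dropout parameters (midpoint 2.0, slope 0.6 on the log2 baseline
scale, core fraction 0.28) were calibrated analytically against the
marginal of the logistic model so that roughly 430–460 of 1,500 proteins
are quantified in all 24 samples, matching the scale of the common set in
the emulated study. With run-independent dropout, the union of identified
proteins (~1,000) is necessarily smaller than a real study's identification
list at the same common-set size; the common matrix, which feeds every
downstream stage, is the prioritized quantity.

The generator does not model: peptide-to-protein inference, isotope
impurity or ratio compression (which shrinks true fold-changes in real
iTRAQ data), donor covariance (each sample is an independent draw),
correlated annotation structure beyond the random DAG, or
intensity-dependent noise. Passing tests therefore demonstrate correctness
of the statistical machinery under the stated generative model, not
robustness to these real-data artifacts.

## Numerical and engineering choices

Problem sizes in the test suite are chosen to keep the full suite in tens
of seconds: oracle comparisons use 6-sample/10×5 instances where exhaustive
computation is exact, recovery checks use 400 proteins × 24 samples over 20
seeds, and the null-calibration check uses 1,000 score vectors over a
30-term ontology. All randomness flows from explicit seeds through
`numpy.random.Generator`; independent named streams prevent one parameter
from perturbing unrelated draws. Pipeline outputs contain no timestamps and
all set-valued intermediates are sorted before serialization, so same-seed
runs are byte-identical (verified across interpreter hash seeds). Degenerate
inputs are contracts, not crashes: empty intersections are valid marker
sets, an all-constant matrix and an annotated-set-equals-universe test are
explicit errors, and a zero-mean anchor group leaves orientation unchanged
with a warning.

## Known limitations

Quantities are protein-level inputs; nothing upstream of the quantification
tables (spectrum matching, FDR estimation) is recomputed. The elimination
procedure's inferential properties are heuristic (as in its standard GO
usage): p-values after elimination are conditional on earlier removals and
are reported raw. The common-protein filter discards most of the proteome
and favors abundant proteins; conclusions about "absent" proteins are not
supported. Storey q-values are not implemented; the BH column is the only
multiplicity adjustment offered.
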