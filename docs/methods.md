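# Methods

This note documents the models, parameter choices and numerical decisions
behind `mycopan`, and what the synthetic-data validation does and does not
demonstrate about real data.

## Coordinate and data model

All intervals are 0-based half-open internally; GFF3 (1-based inclusive) and
BED (already half-open) are converted at the file boundary, and `write_gff3`
converts back, so `read → write` round-trips byte-identically in canonical
(scaffold, start, end, id) order.  A `GenomeAnnotation` bundles scaffolds,
genes and repeats for one species and validates referential integrity (every
feature on a known scaffold, within bounds, unique gene ids).

Allelic scaffold resolution: two scaffolds whose nucleotide similarity
exceeds 50% coverage and 90% identity form an allelic pair; pairs may chain,
and each connected component keeps its single longest scaffold (ties to the
lexicographically smaller id).  Whether secondary scaffolds should be
excluded before proximity analysis is genuinely open; the pipeline defaults
to primary-only and exposes `primary_scaffolds_only`.

## Orthology

Pairwise similarity is a local alignment (BLOSUM62, gap open −11, extend −1,
Biopython `PairwiseAligner`); identity = matches / alignment columns (gap
columns counted), coverage = aligned span of the shorter sequence / its
length.  The shorter-sequence denominator makes coverage symmetric and the
50% test well defined for unequal lengths; coverage-of-query is available by
swapping arguments.  An edge enters the similarity graph iff identity ≥ 0.50
and coverage ≥ 0.50; edge weight is identity (monotone in similarity, no
score calibration needed).  Within-species paralog pairs are aligned like
cross-species pairs, so orthogroups may contain paralogs.

A k-mer prescreen (4-mers, shared fraction ≥ 0.02 of the smaller set) skips
alignments between pairs that cannot approach 50% identity; it is a speed
device only, verified against exhaustive alignment in the tests, and can be
disabled (`kmer_prefilter=False`).

MCL: unit self-loops, column normalization, then alternating expansion
(matrix squaring) and inflation (entrywise power 3.0, renormalize), run per
connected component, until the maximum entry change is below 1e-6 or 100
iterations (non-convergence returns the current clustering with a flag).
Clusters are attractor systems (rows with positive diagonal, merged when
they flow into each other); a node attracted to several systems joins the
one with the larger total original edge weight, ties to the cluster with the
smallest member.  Orthogroup ids are assigned by each cluster's smallest
member, which together with sorted node order makes clustering invariant to
input order.

Partition: core = members in all species, specific = exactly one, accessory
otherwise.  Reported percentages are rounded to the nearest integer;
unrounded values are kept alongside.

## Synthetic pangenome

Families descend from a random ancestral peptide (length uniform on
120–450 aa) by i.i.d. substitutions over a 20-letter alphabet, no indels.
The divergence parameter `d` targets the *pairwise* identity between family
members: each member is mutated with per-site probability p solving
(1−p)² + p²/19 = 1 − d, so expected within-family identity is exactly 1 − d.
Indels are deliberately omitted: they would complicate the coverage
criterion without adding test power at the 50% identity threshold.
Between-family identity is that of unrelated random sequences (< 0.3).

## TE–gene proximity

Distance kernel: anchor = gene's leftmost coordinate regardless of strand
(the scaffold-absolute reading of "gene start"; a strand-aware mode is
available).  d_down = nearest repeat start ≥ anchor minus anchor; d_up =
anchor minus nearest repeat end ≤ anchor; distance = min of the defined
candidates, and any repeat whose span contains the anchor gives 0 — no
negative distances, so log-scale summaries stay defined.  Genes on
repeat-free scaffolds have undefined distance and are excluded from means in
observed and null models alike.  The kernel is exercised against a
brute-force all-repeats scan on 10,000 random fixtures.

Null model: every gene is re-placed on its own scaffold (preserving
per-scaffold gene content and length), without gene–gene overlap, repeats
fixed.  Placement uses the order-statistics gap construction — draw n
uniform points in [0, L − Σ lengths], sort, offset by cumulative lengths of
a random gene order — which is an exact uniform draw over non-overlapping
arrangements.  The generator's background gene placement uses the *same*
construction, so observed layouts are exchangeable with null models and the
permutation test is exact up to the +1/(N+1) smoothing; measured null
rejection at α = 0.05 was 50/1000.  When a proximity effect is planted, the
planted genes are anchored within `planted_proximity_max_dist` of a random
repeat edge first and the remaining genes are placed around them by bounded
rejection sampling (exact exchangeability is not needed for power studies).
Cross-scaffold shuffling is available as an option; the default preserves
per-scaffold gene density.

The p-value is one-sided towards "closer" by default (the direction of the
scientific claim); "farther" and two-sided are options.  "Close proximity"
means distance ≤ 4,500 bp, chosen because coding genes are mostly under
4 kb; `fraction_close` is monotone in this threshold by construction.

## Secretome

The five classes (secreted CAZyme, secreted lipase/protease, SSP, other
secreted, non-secreted) partition the gene set under the precedence
CAZyme > lipase/protease > SSP > other: an SSP-sized secreted enzyme is
counted as an enzyme where disjoint classes are required (e.g. proximity
analysis), but also in the SSP *subcategory* of secretome summaries, where
SSP is defined purely as "secreted and < 300 aa" (strict: 299 in, 300 out).
Secretion and enzyme flags are inputs produced by upstream annotation
pipelines, not computed here.

## Differential expression

Size factors are median-of-ratios: per-gene geometric mean over samples
(genes containing any zero excluded), per-sample median of count/reference
taken on the log scale (the DESeq2 convention; verified to match pydeseq2's
size factors exactly).  The per-gene test is a deliberately transparent
negative-binomial Wald test: log₂FC from pseudo-counted (+1) normalized
condition means; method-of-moments dispersion α = (s² − μ)/μ² pooled across
conditions and floored at 1e-8; delta-method standard error of the log₂
ratio; the statistic referred to a t distribution with pooled residual df
(the normal reference is anticonservative at 3–4 replicates).  BH-FDR across
tested genes; genes with all-zero counts are excluded from testing and
reported as non-significant.  Calls: up iff log₂FC > 1 and FDR < 0.05, down
symmetrically.  There is no dispersion shrinkage — the thresholds, not the
estimator, are what downstream summaries reuse — and a loader for externally
produced DE tables (`load_de_table`) provides real-data parity.

"Expressed" (for the SSP tables) is not standardized; the package uses
normalized mean count ≥ 5 in at least one condition, configurable via
`expression_floor`.

Reporting: percent-specific is rounded half-up to one decimal in the DEG
table and to the nearest integer in the SSP tables, matching the customary
printed precision of such tables.  UpSet counts are exclusive (each
orthogroup counted in its exact membership subset), so they sum to the size
of the union; an orthogroup with members regulated in both directions
appears in both the up and the down sets.

## Carbon transfer

The percent of fungal carbon acquired from the host is a two-end-member
mixing estimate, 100·(δ_ERM − δ_FLM)/(δ_leaf − δ_FLM), affine-invariant in
the δ values and undefined when the end members coincide.  Values outside
[0, 100] (possible under noise) are returned unclamped with a flag.  The
formula is isolated in `percent_c_acquired` so a variant with
isotope-enrichment corrections can be swapped in; published workflows cite
external calculation methods whose exact corrections are not restated here.
The leaf reference defaults to the mean over the replicate group.  Pearson
correlations report r with df = n − 2 and the two-sided t-transform p.

## Synthetic study conditions

Generator defaults are the desk-scale study conditions used throughout the
tests: 9 species; 25/35/45 core/accessory/specific families at d = 0.10;
four 400 kb scaffolds per genome with 15 repeats (0.5–5 kb) and genes of
1–4 kb; the SSP class planted within 2 kb of repeats; negative-binomial
counts (means 20–500, dispersion 0.05, planted |log₂FC| = 2, triplicates,
transcriptomes for 5 of the 9 species); δ¹³C triplets with leaf at +200‰,
FLM at −28‰, mixing fraction 0.35, noise 0.2‰, n = 6.  Validation runs use
the sizes stated in the test docstrings (e.g. 200 families for orthogroup
recovery, 200 genomes × 1,000 permutations for null calibration); these are
the package's chosen problem sizes for routine verification.

What the generator does *not* emulate — and hence what passing tests do not
show about real data: phylogenetically correlated gene gain/loss (family
membership is i.i.d. across species), indels and domain-level homology,
TE nesting and family structure, GC/codon composition, count outliers and
batch effects, or biological correlation between expression and genomic
context.  Results on real annotations depend on upstream calls (secretion
flags, repeat annotation, similarity search) that the pipeline consumes but
does not audit.

## Determinism

One master seed drives everything; synthetic sub-generators derive
independent streams by fixed offsets so stages can be re-run in isolation.
The pipeline writes a manifest (seed, configuration, input hashes) and its
outputs contain no timestamps; two runs with the same seed are byte-identical.
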