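# Methods

This note documents the models, defaults, numerical choices and known
limitations behind each stage of the pipeline.

## Synthetic data model

The simulators exist so that every downstream statistic can be checked
against a known ground truth without any external dataset.

**Tissue geometry.** A rectangular field (default 1000 × 1000 µm, image
convention: origin top-left, y downward) contains non-overlapping glomerular
discs (default 3, radius ~N(70, 10²) µm, floored at 20), large vessels as
axis-aligned rectangles, small vessels as small discs (radius 15 µm), and a
tubular mask built as a Boolean union of 45 µm discs oversampled by 30% to
offset overlap until the target coverage (default 35%) is approximately
reached. The interstitium is the complement. This is deliberately the
simplest geometry supporting point-in-polygon and distance queries; it makes
no attempt at nephron anatomy.

**Cytometry.** Default abundances mimic a cortical biopsy: tubular epithelium
~40%, endothelium 8%, the remainder split across eight immune types, for
1,500 cells per section (the scale of one annotated region). Placement is by
rejection sampling: a uniform candidate point is accepted with probability
proportional to the phenotype's odds multiplier for the compartment it falls
in, so an odds of w multiplies the in/out density ratio by exactly w (checked
by Monte-Carlo in the tests). Co-localization moves a stated fraction of an
attracted type to a random attractor cell plus an isotropic Gaussian(σ)
displacement — a single tunable effect size for power studies.

**Markers.** Raw MFI = exp(N(µ, σ²)) × region gain + region shift + Gaussian
noise, floored at zero. The default panel gives each phenotype two dedicated
high markers (log-mean 2.5 vs 0, log-sd 0.25), which yields inter-centroid
separation well above four within-phenotype standard deviations in trimmed-Z
space — the regime the accuracy checks assume. Region gain/shift emulate the
batch structure that per-region Z-scoring is designed to remove.

**Expression.** Counts are negative binomial with per-gene × per-type means
(shape θ, var = µ + µ²/θ; θ → ∞ recovers Poisson, used as a moment check)
scaled by a log-normal library factor. The default model (4,000 genes,
18 types, 40-fold-enriched disjoint marker blocks of 40 genes per type plus
mild global between-type variation) makes most genes differentially
expressed, so every type has ample barcode candidates. Optional injected
cells — low-complexity (exactly 300 expressed genes) and high-mitochondrial
(expected mito share 0.4) — exist solely to exercise the QC filter.

**What the simulators do not emulate:** segmentation errors, marker
spillover, spatially varying illumination beyond per-region gain/shift,
doublets, ambient RNA, or realistic gene-gene correlation. Passing tests
demonstrate correctness of the algorithms under the stated models, not
robustness to those artifacts.

## Normalization

Z-scores use the sample standard deviation (ddof = 1) within each
region × marker and are clipped to [0, 5]. A zero-spread region × marker
(or a single-cell region, which warns) stores z = 0: the cells stay usable
and the marker is simply uninformative there. The lower trim at 0 discards
the "below region mean" half of the signal by design — phenotypes are
recognized by the markers they express, not the ones they lack.

## Stratified sampling

Real quotas S·Nᵢ/M are rounded by the largest-remainder (Hamilton) method,
ties broken by sample order, so Σ Sᵢ = S exactly and every |Sᵢ − S·Nᵢ/M| < 1.
Draws are without replacement with a seeded generator.

## Clustering backends and consensus

The graph backend builds a k-nearest-neighbour graph (k = 30), weights each
edge by the Jaccard overlap of the two neighbourhoods, and runs Leiden with
the classic modularity objective (seeded). Modularity has a resolution
limit: on very small, well-separated groups it may subdivide a blob into
finer communities. This is harmless downstream because cluster → phenotype
annotation merges refined clusters, but it means the *number* of graph
communities should be read as an upper bound on phenotype count. An
RB-configuration partition with explicit resolution is available via the
`resolution` parameter.

The SOM backend is a small batch self-organizing map (default 10 × 10 grid,
10 epochs, Gaussian neighbourhood shrinking from half the grid to 0.5)
followed by Ward linkage of the codebook cut to k metaclusters; it is
written in-package (seeded, deterministic) because no SOM library is part
of the dependency set. k-means uses scikit-learn with a fixed seed. Both
receive k from the graph backend.

Annotation assigns each cluster the phenotype whose expected profile has the
highest Pearson correlation with the cluster's mean Z-profile; below the
minimum match score (default r = 0.3) the cluster is "NOS"; ties keep the
earlier signature. Automating this step replaces expert manual annotation,
which cannot be reproduced in software; the vote is taken at the phenotype
level (after annotation), because backend cluster ids are not comparable
across methods. A cell is labeled by majority when ≥2 backends agree and
"NOS" otherwise.

Label extrapolation fits a 2-D embedding on a template of ≤500 voted,
non-NOS cells per type and projects all cells into it; each receives the
modal label of its 100 nearest template cells, ties broken by smallest mean
neighbour distance, then label order. UMAP (seeded) is the default because
two PCA dimensions cannot keep ten or more mutually orthogonal phenotype
axes apart; the PCA fallback (`embedding="pca"`) exists for strictly
platform-independent determinism and for low-dimensional panels, and is
what most unit tests use for speed.

## Spatial statistics

Point-in-polygon is boundary-inclusive; overlapping polygons resolve by the
precedence glomerular > large vessel > small vessel > tubular, with the
interstitium as complement. Distances are Euclidean in µm in image
coordinates with no 3-D correction; distance to a glomerulus is zero inside
one. Neighborhood counts are ordered (each mixed pair contributes one
source → target pair; a same-type pair contributes two) with a symmetric
option, computed with a k-d tree but contractually equal to the brute-force
double loop (enforced by an oracle test).

The permutation null shuffles labels uniformly within each sample —
coordinates and the label multiset are preserved — and freezes structural
cells (tubular, endothelial) so tissue architecture cannot masquerade as
immune co-localization. Permutations are shared across the distance grid
(one shuffle per replicate), and per-sample seed streams are split from the
master seed. The empirical p uses the add-one estimator
p = (1 + #{perm ≥ obs})/(N + 1), which cannot return zero at finite N.

Because the count statistic is discrete, ties between permuted and observed
counts make the add-one p-value mildly conservative: under the null (1,000
simulated tissues, N = 200) the mean p is ≈0.55 rather than 0.50 and the
type-I error at α = 0.05 is ≈0.04. The p-value distribution is therefore
slightly super-uniform — a goodness-of-fit test against the exact uniform
can reject at large sample sizes even though the test never exceeds its
nominal error rate. The signed exceedance statistic reports n_lower when
the observation exceeds the permutation median and −n_higher otherwise;
both raw exceedance counts are kept because the plotting sign convention
is a presentation choice.

## Deconvolution

QC keeps cells with 400 ≤ detected genes ≤ 10000 and mitochondrial fraction
≤ 25% (the exclusion rules are strict inequalities, so boundary cells
survive). Probesets collapse to genes by highest mean expression, ties to
the lexicographically first probe id. All signature work is on linear-scale
("anti-logged") expression.

Signature construction: stratified-sample 10,000 labeled cells; per-type
mean expression; drop genes whose max per-type mean is < 0.1; per type,
candidate genes are those upregulated vs the rest with a Wilcoxon rank-sum
Benjamini-Hochberg q < 0.05, ranked by descending log₂ fold change. The
rank-sum test is computed by ranking the pooled matrix once and deriving
each one-vs-rest z from group rank sums with tie and continuity corrections
(verified to match scipy's asymptotic test to machine precision); this
avoids re-ranking the matrix once per type. For each G in [300, 500] the
union of top-G genes per type forms a candidate matrix; the G minimizing
the 2-norm condition number is kept. If a type has fewer than G_min
candidates the bound is relaxed with a warning.

Fraction estimation is NNLS (min‖Sf − b‖₂, f ≥ 0) on the gene intersection,
renormalized to the simplex, with the relative residual reported — a
documented, reproducible stand-in for the ν-SVR solver of reference
deconvolution pipelines, whose internals (and batch-correction modes) are
out of scope. Merged labels (e.g. pooling NK subsets whose estimated
fractions cannot be separated) are supported as a relabeling step before
fitting. Evaluation reports per-type Pearson r across samples with a median
over evaluable types; a type with zero variance in either vector is flagged
non-evaluable rather than contributing a meaningless coefficient.

## Reporting

Correlation CIs come from the Fisher z-transform: SE = 1/√(n−3) for Pearson
and the Bonett-Wright SE = √((1 + r²/2)/(n−3)) for Spearman. Two-sided
p-values are exhaustive-permutation for n ≤ 9 (n! ≤ 362,880 enumerations),
seeded Monte-Carlo permutation (10,000 resamples, add-one) for 9 < n ≤ 12,
and asymptotic beyond; full enumeration above n = 9 is computationally
disproportionate (12! ≈ 4.8 × 10⁸) for no practical gain in resolution.
Group comparisons use Kruskal-Wallis (scipy) and a hand-implemented Dunn
post-hoc (pooled-rank z with tie correction, Benjamini-Hochberg adjustment
by default, since the correction choice is open); single-observation groups
enter the omnibus test but are flagged in the pairwise table.

## Problem sizes in the acceptance studies

Calibration uses 200 null tissues (~1,500 cells) with N = 200 permutations
at d = 30 µm; power uses 100 tissues with the planted attraction
(σ = 15 µm, 60% attracted) at d ∈ {20, 30, 40}; oracle equivalence uses 20
instances of 500 cells; phenotyping uses 20,000 cells over 10 phenotypes
with a 5,000-cell clustering subsample; deconvolution uses 18 types ×
600 cells × 4,000 genes with 50 noisy mixtures. These sizes make the full
suite run in a few minutes on one CPU while keeping every Monte-Carlo
margin wide.

## Known limitations

* The consensus vote assumes the three backends' errors are not strongly
  correlated; on data where all three share a failure mode the vote gives
  false confidence.
* Signature construction assumes the bulk platform measures the same
  quantity as the single-cell reference up to gene intersection; no
  cross-platform batch correction is provided.
* The permutation test conditions on the observed cytometry per sample;
  it has no power against effects that only change composition.
* 2-D UMAP extrapolation can place rare, weakly separated types on top of
  each other; increasing template size or using more markers helps more
  than raising k_vote.
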