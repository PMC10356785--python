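# graftscape

Downstream computational analysis of kidney-allograft immune infiltrates:
consensus phenotyping of multiplexed-immunofluorescence single cells,
spatial compartment and neighborhood statistics with a permutation null,
and single-cell-derived signature-matrix deconvolution of bulk expression.

## Who this is for

Transplant-pathology and spatial-biology groups working with segmented
multiplex-IF cell tables (cell coordinates in µm plus one mean-fluorescence
intensity per marker), compartment annotations (glomeruli, vessels, tubular
masks as polygons), and labeled single-cell expression. The package starts
at the per-cell table — segmentation, registration and staining are out of
scope — and every stage can be exercised on synthetic data with known
ground truth, generated by the package itself.

## What it computes

**Consensus phenotyping.** MFIs are Z-scored within each staining region and
trimmed to [0, 5]. A stratified proportional subsample (quota
S·Nᵢ/M per sample, largest-remainder rounding) is clustered with three
backends: Leiden communities on a Jaccard-weighted kNN graph (k = 30), a
self-organizing map with Ward metaclustering, and k-means — the graph
backend's cluster count fixes k for the other two. Clusters are annotated
against expected marker signatures (best Pearson correlation, minimum match
score, else "NOS"), each cell gets the 2-of-3 majority phenotype ("NOS" if
all three disagree), and labels are extrapolated to the full dataset by a
100-nearest-template-neighbour vote in a 2-D UMAP built from ≤500 template
cells per type. Myeloid cells can be re-clustered on a 13-marker monocyte
panel with the same chain.

**Spatial statistics.** Cells are assigned to the glomerular, large-vessel,
small-vessel, tubular or interstitial compartment by boundary-inclusive
point-in-polygon with fixed precedence. The package reports compartment
compositions, per-phenotype glomerular in/out percentages (Mann-Whitney
across samples), distance-to-closest-glomerulus enrichment curves, and a
neighborhood enrichment test: ordered (source → target) cell pairs within
distance d are counted and compared with N label permutations that keep
every coordinate and the tissue's cytometry fixed while freezing structural
cells; p = (1 + #{perm ≥ obs})/(N + 1), with the signed exceedance count
(how many random tissues fall below/above the observation) per distance
d = 10…100 µm.

**Deconvolution.** From labeled linear-scale single-cell expression
(QC: cells with <400 or >10000 detected genes or >25% mitochondrial
transcripts are excluded) a genes × types signature matrix is built:
10,000 stratified cells, per-type mean expression, minimum-expression
filter at 0.1, per-type barcode genes gated by a Wilcoxon rank-sum
Benjamini-Hochberg q-value and ranked by log fold change, with the
barcode count G ∈ [300, 500] chosen to minimize the 2-norm condition
number. Bulk fractions solve min‖Sf − b‖₂ s.t. f ≥ 0 (NNLS) with
renormalization to the simplex, validated against pseudobulk mixtures of
known composition.

**Reporting.** Spearman/Pearson correlation of cell-type frequency with a
scalar inflammation severity (Fisher-z 95% CI; permutation p at small n)
and Kruskal-Wallis with Dunn's post-hoc pairwise z tests.

## Worked example

Simulate a tissue in which 60% of nonclassical monocytes are attracted to
FcγRIII⁺ NK cells at a 15 µm scale, then test that neighborhood:

```python
import graftscape as gs

spec = gs.default_tissue_spec(
    seed=7,
    colocalization=(("NK_FcgR3", "nonclassical_mono", 15.0, 0.6),),
)
cells, cmap, truth = gs.simulate_tissue(spec)
cells = gs.assign_compartments(cells, cmap)

cfg = gs.NeighborhoodConfig(
    distances=(20, 30, 40), n_permutations=1000,
    structural_types=("PT_cell", "distal_tubule", "endothelium"), seed=7,
)
res = gs.neighborhood_test(cells, cfg, "NK_FcgR3", "nonclassical_mono")
print(res[["d", "observed", "perm_mean", "p_enrich", "signed_exceedance"]].to_string(index=False))
```

prints

```
 d  observed  perm_mean  p_enrich  signed_exceedance
20        42     10.094  0.000999               1000
30        66     20.930  0.000999               1000
40        85     38.646  0.000999               1000
```

At every distance the observed NK→monocyte pair count (e.g. 66 at 30 µm)
far exceeds the permutation mean (≈21); all 1000 label-shuffled tissues
produced fewer pairs, so the signed exceedance is +1000 and the add-one
empirical p-value is 1/1001 ≈ 0.001 — the planted attraction is detected.

The same stages are available from the shell:

```bash
graftscape simulate tissue --seed 7 --out sim/
graftscape spatial neighborhood --cells sim/cells.csv \
    --source NK_FcgR3 --target nonclassical_mono --seed 7 --out nb.csv
graftscape phenotype --cells sim/cells.csv --signatures sim/signatures.tsv --out labeled.csv
```

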