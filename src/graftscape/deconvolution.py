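"""Signature-matrix construction and bulk cell-fraction deconvolution.

A signature matrix (genes x cell types, linear-scale mean expression) is
built from labeled single-cell expression: cells are stratified-sampled,
per-type means computed, low-expression genes dropped, per-type barcode
genes ranked by a differential statistic (Wilcoxon rank-sum q-value gate,
ranked by log fold change), and the per-type barcode count G chosen within
[gmin, gmax] to minimize the 2-norm condition number of the resulting
matrix.  Bulk fractions are then estimated by non-negative least squares
with renormalization to the simplex — a documented stand-in for the nu-SVR
solver of reference deconvolution pipelines, whose internals are out of
scope here.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.optimize import nnls
from scipy.stats import mannwhitneyu, pearsonr
from sklearn.base import BaseEstimator
from statsmodels.stats.multitest import multipletests

__all__ = [
    "SignatureConfig",
    "SignatureMatrix",
    "qc_filter",
    "collapse_probesets",
    "build_signature",
    "pseudobulk",
    "estimate_fractions",
    "evaluate_deconvolution",
    "SignatureDeconvolver",
]


# ----------------------------------------------------------------------- QC
def qc_filter(
    adata,
    min_genes: int = 400,
    max_genes: int = 10000,
    max_mito: float = 0.25,
    mito_col: str = "mito",
):
    """Remove low-quality cells from labeled counts.

    Cells with fewer than ``min_genes`` or more than ``max_genes`` detected
    genes, or with a mitochondrial transcript fraction strictly greater
    than ``max_mito``, are excluded.  Boundary cells (exactly ``min_genes``
    genes or exactly ``max_mito`` mito fraction) are kept: the exclusion
    rules are strict inequalities.
    """
    X = adata.X
    X = X.toarray() if hasattr(X, "toarray") else np.asarray(X)
    genes_detected = (X > 0).sum(axis=1)
    total = X.sum(axis=1)
    if mito_col in adata.var:
        mito_mask = adata.var[mito_col].to_numpy(dtype=bool)
        with np.errstate(invalid="ignore", divide="ignore"):
            mito_frac = np.where(total > 0, X[:, mito_mask].sum(axis=1) / total, 1.0)
    else:
        mito_frac = np.zeros(X.shape[0])
    keep = (genes_detected >= min_genes) & (genes_detected <= max_genes) & (mito_frac <= max_mito)
    return adata[keep].copy()


def collapse_probesets(expression: pd.DataFrame, probe_to_gene: pd.Series | dict) -> pd.DataFrame:
    """Collapse a probeset x sample matrix to gene level.

    For genes measured by several probesets, the probeset with the highest
    mean across samples is retained; ties break by lexicographically first
    probe id.  Probes without a gene mapping are dropped.
    """
    mapping = pd.Series(probe_to_gene)
    df = expression.loc[expression.index.intersection(mapping.index)]
    means = df.mean(axis=1)
    choice = (
        pd.DataFrame({"gene": mapping.loc[df.index], "mean": means, "probe": df.index})
        .sort_values(["gene", "mean", "probe"], ascending=[True, False, True])
        .drop_duplicates("gene", keep="first")
    )
    out = df.loc[choice["probe"]]
    out.index = choice["gene"].to_numpy()
    return out


# ------------------------------------------------------------- signature build
@dataclass
class SignatureConfig:
    """Parameters of signature-matrix construction."""

    n_cells: int = 10000
    min_expression: float = 0.1
    gmin: int = 300
    gmax: int = 500
    qvalue: float = 0.05
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0 < self.gmin <= self.gmax:
            raise ValueError("need 0 < gmin <= gmax")


@dataclass
class SignatureMatrix:
    """Genes x cell types linear mean expression with per-type barcode lists."""

    matrix: pd.DataFrame
    barcode_genes: dict = field(default_factory=dict)
    condition_number: float = np.nan
    g_selected: int = 0

    @property
    def genes(self) -> pd.Index:
        return self.matrix.index

    @property
    def cell_types(self) -> list[str]:
        return list(self.matrix.columns)


def _ranksum_pvalues(X: np.ndarray, group_masks: list[np.ndarray]) -> np.ndarray:
    """Two-sided Wilcoxon rank-sum p-values (normal approximation with tie and
    continuity corrections) for every gene and every one-vs-rest split.

    The pooled ranks are identical across the one-vs-rest splits, so the
    matrix is ranked once and each split only needs group rank sums.
    Matches scipy's asymptotic ``mannwhitneyu`` on shared inputs.
    """
    from scipy.stats import norm, rankdata

    N, G = X.shape
    pvals = np.empty((len(group_masks), G))
    step = 1000  # bound the rank-matrix working memory
    for lo in range(0, G, step):
        hi = min(lo + step, G)
        block = X[:, lo:hi]
        R = rankdata(block, axis=0)
        # per-gene tie term sum(t^3 - t) from sorted run lengths
        S = np.sort(block, axis=0)
        tie_term = np.zeros(hi - lo)
        for j in range(hi - lo):
            _, counts = np.unique(S[:, j], return_counts=True)
            tie_term[j] = float((counts.astype(float) ** 3 - counts).sum())
        for gi, mask in enumerate(group_masks):
            n1 = int(mask.sum())
            n2 = N - n1
            U = R[mask, :].sum(axis=0) - n1 * (n1 + 1) / 2.0
            mu = n1 * n2 / 2.0
            var = n1 * n2 / 12.0 * ((N + 1) - tie_term / (N * (N - 1.0)))
            sd = np.sqrt(np.maximum(var, 0))
            with np.errstate(divide="ignore", invalid="ignore"):
                z = (np.abs(U - mu) - 0.5) / sd  # continuity-corrected
            p = np.where(sd > 0, 2 * norm.sf(np.clip(z, 0, None)), 1.0)
            pvals[gi, lo:hi] = np.minimum(p, 1.0)
    return pvals


def _rank_barcode_genes(X: np.ndarray, labels: np.ndarray, genes: np.ndarray, qvalue: float) -> dict:
    """Per type: candidate genes upregulated vs rest (rank-sum q < cutoff),
    ranked by descending log fold change."""
    types = np.unique(labels)
    eps = 1e-9
    masks = [labels == t for t in types]
    pvals = _ranksum_pvalues(X, masks)
    ranked: dict = {}
    for k, t in enumerate(types):
        in_t = masks[k]
        a_mean = X[in_t].mean(axis=0)
        b_mean = X[~in_t].mean(axis=0)
        qvals = multipletests(pvals[k], method="fdr_bh")[1]
        lfc = np.log2((a_mean + eps) / (b_mean + eps))
        cand = np.flatnonzero((qvals < qvalue) & (lfc > 0))
        order = cand[np.argsort(-lfc[cand], kind="stable")]
        ranked[t] = genes[order]
    return ranked


def build_signature(X, labels, genes=None, cfg: SignatureConfig | None = None) -> SignatureMatrix:
    """Build a signature matrix from labeled linear-scale expression.

    Parameters
    ----------
    X : AnnData or (cells x genes) array
        Linear-scale ("anti-logged") expression.  If AnnData, labels default
        to ``obs["cell_type"]`` and genes to ``var_names``.
    labels : array-like or str
        Cell-type label per cell (or the obs column name for AnnData).
    genes : array-like, optional
        Gene names aligned with the columns of ``X``.
    cfg : SignatureConfig

    Procedure: stratified-sample ``cfg.n_cells`` cells; per-type linear mean
    expression; drop genes whose maximum per-type mean is below
    ``cfg.min_expression``; rank candidate genes per type (rank-sum q-gated
    log fold change); scan G in [gmin, gmax], forming the union of top-G
    genes per type, and keep the G minimizing the 2-norm condition number.
    """
    cfg = cfg or SignatureConfig()
    if hasattr(X, "obs"):  # AnnData
        adata = X
        lab_col = labels if isinstance(labels, str) else "cell_type"
        labels = adata.obs[lab_col].to_numpy()
        genes = adata.var_names.to_numpy()
        X = adata.X
    X = X.toarray() if hasattr(X, "toarray") else np.asarray(X, dtype=float)
    labels = np.asarray(labels)
    if genes is None:
        genes = np.array([f"g{i}" for i in range(X.shape[1])])
    genes = np.asarray(genes)
    types = np.unique(labels)
    if len(types) < 2:
        raise ValueError("need at least two cell types")

    # stratified sampling of cells (proportional, largest remainder)
    from .sampling import largest_remainder

    if cfg.n_cells < len(labels):
        sizes = np.array([(labels == t).sum() for t in types])
        quotas = largest_remainder(cfg.n_cells * sizes / sizes.sum(), cfg.n_cells)
        rng = np.random.default_rng(cfg.seed)
        keep = np.concatenate(
            [rng.choice(np.flatnonzero(labels == t), size=q, replace=False) for t, q in zip(types, quotas) if q > 0]
        )
        X, labels = X[keep], labels[keep]

    means = pd.DataFrame(
        {t: X[labels == t].mean(axis=0) for t in types}, index=genes
    )
    expressed = means.max(axis=1) >= cfg.min_expression
    means = means.loc[expressed]
    Xe = X[:, expressed.to_numpy()]
    genes_e = means.index.to_numpy()

    ranked = _rank_barcode_genes(Xe, labels, genes_e, cfg.qvalue)
    gmin, gmax = cfg.gmin, cfg.gmax
    shortest = min(len(v) for v in ranked.values())
    if shortest < gmin:
        warnings.warn(
            f"a type has only {shortest} candidate barcode genes; relaxing gmin from {gmin}"
        )
        gmin = max(1, shortest)
        gmax = max(gmax, gmin)

    best = None
    for G in range(gmin, gmax + 1):
        union: list = []
        for t in types:
            union.append(ranked[t][: min(G, len(ranked[t]))])
        sel = pd.Index(np.unique(np.concatenate(union)))
        M = means.loc[sel].to_numpy()
        cond = np.linalg.cond(M)
        if best is None or cond < best[0]:
            best = (cond, G, sel)
    cond, G, sel = best
    barcode = {t: list(ranked[t][: min(G, len(ranked[t]))]) for t in types}
    return SignatureMatrix(
        matrix=means.loc[sel].copy(),
        barcode_genes=barcode,
        condition_number=float(cond),
        g_selected=int(G),
    )


# ------------------------------------------------------------------ mixtures
def pseudobulk(X, labels, groups, genes=None, agg: str = "sum") -> tuple[pd.DataFrame, pd.DataFrame]:
    """Aggregate labeled single cells into bulk profiles with known fractions.

    ``groups`` assigns each cell to a pseudobulk sample.  Returns
    (genes x groups bulk matrix, groups x types true fraction matrix); the
    true fraction is the cell-count share of each type within the group.
    """
    if hasattr(X, "obs"):
        adata = X
        genes = adata.var_names.to_numpy()
        labels = adata.obs[labels].to_numpy() if isinstance(labels, str) else np.asarray(labels)
        X = adata.X
    X = X.toarray() if hasattr(X, "toarray") else np.asarray(X, dtype=float)
    labels = np.asarray(labels)
    groups = np.asarray(groups)
    if genes is None:
        genes = np.array([f"g{i}" for i in range(X.shape[1])])
    uniq_groups = pd.unique(groups)
    types = np.unique(labels)
    bulk = {}
    fracs = {}
    for g in uniq_groups:
        m = groups == g
        bulk[g] = X[m].sum(axis=0) if agg == "sum" else X[m].mean(axis=0)
        counts = np.array([(labels[m] == t).sum() for t in types], dtype=float)
        fracs[g] = counts / counts.sum()
    return (
        pd.DataFrame(bulk, index=genes),
        pd.DataFrame(fracs, index=types).T,
    )


def estimate_fractions(sig: SignatureMatrix | pd.DataFrame, bulk: pd.DataFrame) -> pd.DataFrame:
    """Estimate cell-type fractions per bulk sample by NNLS + renormalization.

    Signature and bulk are intersected on shared genes; per sample the
    solver minimizes ||S f - b||_2 subject to f >= 0 and the solution is
    renormalized to sum to 1.  The fit residual (relative 2-norm) is
    reported per sample.
    """
    S_df = sig.matrix if isinstance(sig, SignatureMatrix) else sig
    shared = S_df.index.intersection(bulk.index)
    if len(shared) == 0:
        raise ValueError("no shared genes between signature and bulk")
    S = S_df.loc[shared].to_numpy(dtype=float)
    B = bulk.loc[shared].to_numpy(dtype=float)
    rows = []
    for j, name in enumerate(bulk.columns):
        b = B[:, j]
        if not np.any(b):
            raise ValueError(f"all-zero bulk sample {name!r}")
        f, rnorm = nnls(S, b)
        total = f.sum()
        frac = f / total if total > 0 else np.full_like(f, 1.0 / len(f))
        rows.append(np.concatenate([frac, [rnorm / np.linalg.norm(b)]]))
    cols = list(S_df.columns) + ["residual"]
    return pd.DataFrame(rows, index=bulk.columns, columns=cols)


def evaluate_deconvolution(estimated: pd.DataFrame, truth: pd.DataFrame) -> pd.DataFrame:
    """Per-type Pearson r between estimated and true fractions across samples.

    Types with zero variance in either vector are flagged non-evaluable
    (r = NaN).  A ``median`` row over evaluable types is appended.
    """
    types = [c for c in truth.columns if c in estimated.columns]
    rows = []
    for t in types:
        a = estimated.loc[truth.index, t].to_numpy(dtype=float)
        b = truth[t].to_numpy(dtype=float)
        if np.std(a) == 0 or np.std(b) == 0:
            rows.append({"cell_type": t, "pearson_r": np.nan, "evaluable": False})
        else:
            rows.append({"cell_type": t, "pearson_r": float(pearsonr(a, b)[0]), "evaluable": True})
    df = pd.DataFrame(rows)
    med = df.loc[df["evaluable"], "pearson_r"].median()
    return pd.concat(
        [df, pd.DataFrame([{"cell_type": "median", "pearson_r": med, "evaluable": bool(df["evaluable"].any())}])],
        ignore_index=True,
    )


# ------------------------------------------------------------------ estimator
class SignatureDeconvolver(BaseEstimator):
    """Deconvolution estimator: fit a signature matrix, predict fractions.

    ``fit(adata)`` (or ``fit(X, labels)``) applies QC and builds the
    signature matrix; ``predict(bulk)`` returns the samples x types
    fraction matrix (plus a residual column).

    Parameters mirror :class:`SignatureConfig`; ``merge_types`` optionally
    maps raw labels onto merged ones (e.g. pooling NK subsets) before
    signature construction.
    """

    def __init__(
        self,
        n_cells: int = 10000,
        min_expression: float = 0.1,
        gmin: int = 300,
        gmax: int = 500,
        qvalue: float = 0.05,
        apply_qc: bool = True,
        min_genes: int = 400,
        max_genes: int = 10000,
        max_mito: float = 0.25,
        merge_types: dict | None = None,
        random_state: int = 0,
    ):
        self.n_cells = n_cells
        self.min_expression = min_expression
        self.gmin = gmin
        self.gmax = gmax
        self.qvalue = qvalue
        self.apply_qc = apply_qc
        self.min_genes = min_genes
        self.max_genes = max_genes
        self.max_mito = max_mito
        self.merge_types = merge_types
        self.random_state = random_state

    def fit(self, X, y=None):
        cfg = SignatureConfig(
            n_cells=self.n_cells,
            min_expression=self.min_expression,
            gmin=self.gmin,
            gmax=self.gmax,
            qvalue=self.qvalue,
            seed=self.random_state,
        )
        if hasattr(X, "obs"):
            adata = X
            if self.apply_qc:
                adata = qc_filter(adata, self.min_genes, self.max_genes, self.max_mito)
            labels = adata.obs["cell_type"].to_numpy()
            if self.merge_types:
                labels = np.array([self.merge_types.get(l, l) for l in labels], dtype=object)
            self.signature_ = build_signature(adata.X, labels, adata.var_names.to_numpy(), cfg)
        else:
            labels = np.asarray(y)
            if self.merge_types:
                labels = np.array([self.merge_types.get(l, l) for l in labels], dtype=object)
            self.signature_ = build_signature(X, labels, cfg=cfg)
        self.condition_number_ = self.signature_.condition_number
        return self

    def predict(self, bulk: pd.DataFrame) -> pd.DataFrame:
        if not hasattr(self, "signature_"):
            raise AttributeError("fit before predict")
        return estimate_fractions(self.signature_, bulk)
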