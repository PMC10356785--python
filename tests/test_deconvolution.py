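"""QC filtering, probeset collapse, signature building and NNLS estimation."""

import anndata as ad
import numpy as np
import pandas as pd
import pytest

import graftscape as gs
from graftscape.deconvolution import SignatureConfig, _ranksum_pvalues


# ------------------------------------------------------------------------- QC
def _toy_adata():
    """Six constructed cells with known QC violations.

    gene counts detected: c0=399 (fail <400), c1=400 (pass, boundary),
    c2=10000 (pass, boundary), c3=10001 (fail >10000), c4 mito 25.0% (pass),
    c5 mito 26% (fail).
    """
    n_genes = 10050
    X = np.zeros((6, n_genes), dtype=float)
    X[0, :399] = 1
    X[1, :400] = 1
    X[2, :10000] = 1
    X[3, :10001] = 1
    # mito genes are the last 100; give c4/c5 500 detected genes each
    X[4, :400] = 1.0
    X[4, -100:] = 4.0 / 3.0  # mito share = 133.33/(400+133.33) = 25.0%
    X[5, :400] = 1.0
    X[5, -100:] = 1.4054  # just above 25%
    var = pd.DataFrame({"mito": [False] * (n_genes - 100) + [True] * 100},
                       index=[f"g{i}" for i in range(n_genes)])
    obs = pd.DataFrame({"cell_type": list("abcdef")}, index=[f"c{i}" for i in range(6)])
    return ad.AnnData(X=X, obs=obs, var=var)


def test_qc_exact_survivor_set():
    filt = gs.qc_filter(_toy_adata())
    assert list(filt.obs_names) == ["c1", "c2", "c4"]


# ------------------------------------------------------------------ probesets
def test_collapse_probesets_rules():
    expr = pd.DataFrame(
        {"s1": [5.0, 7.0, 2.0, 3.0, 3.0], "s2": [5.0, 7.0, 2.0, 3.0, 3.0]},
        index=["pA1", "pA2", "pB1", "pC2", "pC1"],
    )
    mapping = {"pA1": "GA", "pA2": "GA", "pB1": "GB", "pC1": "GC", "pC2": "GC"}
    out = gs.collapse_probesets(expr, mapping)
    assert out.loc["GA", "s1"] == 7.0  # highest mean wins
    assert out.loc["GB", "s1"] == 2.0  # single probeset passes through
    # tied means resolve to the lexicographically first probe id (pC1)
    assert len(out) == 3 and out.loc["GC", "s1"] == 3.0


def test_collapse_tie_keeps_first_probe_id():
    # equal means (3.0) but distinguishable rows: pZ1 < pZ2 lexicographically
    expr = pd.DataFrame({"s1": [2.0, 4.0], "s2": [4.0, 2.0]}, index=["pZ2", "pZ1"])
    out = gs.collapse_probesets(expr, {"pZ1": "G", "pZ2": "G"})
    assert out.index.tolist() == ["G"]
    assert out.loc["G", "s1"] == 4.0  # the pZ1 row


# ------------------------------------------------------------------ rank test
def test_ranksum_matches_scipy_reference():
    from scipy.stats import mannwhitneyu

    rng = np.random.default_rng(1)
    X = rng.negative_binomial(3, 0.4, (80, 40)).astype(float)
    labels = np.array(["A"] * 30 + ["B"] * 50)
    ours = _ranksum_pvalues(X, [labels == "A", labels == "B"])
    for k, mask in enumerate([labels == "A", labels == "B"]):
        ref = mannwhitneyu(X[mask], X[~mask], alternative="two-sided",
                           method="asymptotic", axis=0).pvalue
        np.testing.assert_allclose(ours[k], ref, atol=1e-12)


# ------------------------------------------------------------------ signature
def test_orthogonal_types_condition_number_closed_form():
    """Two types expressed on disjoint gene sets give an orthogonal matrix whose
    2-norm condition number is the ratio of its column norms."""
    rng = np.random.default_rng(2)
    n_a, n_b = 8, 8
    genes = [f"g{i}" for i in range(16)]
    X = np.zeros((120, 16))
    X[:60, :n_a] = rng.lognormal(2.0, 0.2, (60, n_a))
    X[60:, n_a:] = rng.lognormal(0.5, 0.2, (60, n_b))
    labels = np.array(["A"] * 60 + ["B"] * 60)
    cfg = SignatureConfig(n_cells=120, gmin=n_a, gmax=n_a, qvalue=0.05)
    sig = gs.build_signature(X, labels, np.array(genes), cfg)
    assert set(sig.barcode_genes["A"]) == set(genes[:n_a])
    assert set(sig.barcode_genes["B"]) == set(genes[n_a:])
    M = sig.matrix[["A", "B"]].to_numpy()
    col_norms = np.linalg.norm(M, axis=0)
    expected = col_norms.max() / col_norms.min()
    assert sig.condition_number == pytest.approx(expected, rel=1e-9)


def test_min_expression_drops_low_genes():
    rng = np.random.default_rng(3)
    X = rng.lognormal(0, 0.2, (60, 5))
    X[:, 4] = 0.01  # below the 0.1 threshold in every type
    labels = np.array(["A"] * 30 + ["B"] * 30)
    X[:30, 0] *= 6
    X[30:, 1] *= 6
    cfg = SignatureConfig(n_cells=60, gmin=1, gmax=2, min_expression=0.1)
    sig = gs.build_signature(X, labels, np.array(list("vwxyz")), cfg)
    assert "z" not in sig.matrix.index


def test_fixed_g_selection_is_top_g(sc_adata):
    adata, spec = sc_adata
    cfg = SignatureConfig(n_cells=600, gmin=20, gmax=20, qvalue=0.05)
    sig = gs.build_signature(np.asarray(adata.X), adata.obs["cell_type"].to_numpy(),
                             adata.var_names.to_numpy(), cfg)
    assert sig.g_selected == 20
    assert all(len(v) == 20 for v in sig.barcode_genes.values())


def test_relaxed_gmin_warns():
    rng = np.random.default_rng(4)
    X = rng.lognormal(0, 0.3, (40, 6))
    X[:20, 0] *= 8
    X[20:, 1] *= 8
    labels = np.array(["A"] * 20 + ["B"] * 20)
    with pytest.warns(UserWarning, match="relaxing gmin"):
        sig = gs.build_signature(X, labels, cfg=SignatureConfig(n_cells=40, gmin=50, gmax=60))
    assert sig.g_selected >= 1


def test_condition_scan_returns_the_scanned_minimum(sc_adata):
    adata, _ = sc_adata
    X = np.asarray(adata.X)
    labels = adata.obs["cell_type"].to_numpy()
    genes = adata.var_names.to_numpy()
    cfg = SignatureConfig(n_cells=600, gmin=10, gmax=30)
    sig = gs.build_signature(X, labels, genes, cfg)
    for G in (10, 15, 20, 25, 30):
        alt = gs.build_signature(X, labels, genes, SignatureConfig(n_cells=600, gmin=G, gmax=G))
        assert sig.condition_number <= alt.condition_number + 1e-9


# ------------------------------------------------------------------ pseudobulk
def test_pseudobulk_fractions_and_single_cell_group(sc_adata):
    adata, _ = sc_adata
    X = np.asarray(adata.X)
    labels = adata.obs["cell_type"].to_numpy()
    groups = np.array(["g1"] + ["g2"] * (len(labels) - 1))
    bulk, frac = gs.pseudobulk(X, labels, groups, genes=adata.var_names.to_numpy())
    np.testing.assert_allclose(frac.sum(axis=1), 1.0)
    np.testing.assert_allclose(bulk["g1"].to_numpy(), X[0])


def test_pseudobulk_known_shares():
    X = np.ones((10, 3))
    labels = np.array(["A"] * 7 + ["B"] * 3)
    bulk, frac = gs.pseudobulk(X, labels, np.array(["g"] * 10))
    assert frac.loc["g", "A"] == pytest.approx(0.7)


# ------------------------------------------------------------------- fractions
def test_pure_column_recovers_unit_fraction():
    rng = np.random.default_rng(5)
    sig = pd.DataFrame(rng.lognormal(1, 1, (50, 3)), columns=list("ABC"),
                       index=[f"g{i}" for i in range(50)])
    bulk = sig[["B"]].rename(columns={"B": "s1"})
    est = gs.estimate_fractions(sig, bulk)
    np.testing.assert_allclose(est.loc["s1", list("ABC")], [0, 1, 0], atol=1e-9)


def test_even_blend_recovered():
    rng = np.random.default_rng(6)
    sig = pd.DataFrame(rng.lognormal(1, 1, (50, 3)), columns=list("ABC"),
                       index=[f"g{i}" for i in range(50)])
    bulk = pd.DataFrame({"s1": 0.5 * sig["A"] + 0.5 * sig["B"]})
    est = gs.estimate_fractions(sig, bulk)
    np.testing.assert_allclose(est.loc["s1", list("ABC")], [0.5, 0.5, 0.0], atol=1e-6)


def test_no_shared_genes_raises():
    sig = pd.DataFrame(np.ones((3, 2)), index=list("abc"), columns=["A", "B"])
    bulk = pd.DataFrame(np.ones((3, 1)), index=list("xyz"))
    with pytest.raises(ValueError, match="shared genes"):
        gs.estimate_fractions(sig, bulk)


def test_all_zero_bulk_sample_raises():
    sig = pd.DataFrame(np.ones((3, 2)), index=list("abc"), columns=["A", "B"])
    bulk = pd.DataFrame({"s": [0.0, 0.0, 0.0]}, index=list("abc"))
    with pytest.raises(ValueError, match="all-zero"):
        gs.estimate_fractions(sig, bulk)


# ------------------------------------------------------------------ evaluation
def test_perfect_estimates_give_r_one():
    truth = pd.DataFrame(np.random.default_rng(7).dirichlet([1, 1, 1], 20),
                         columns=list("ABC"))
    res = gs.evaluate_deconvolution(truth.copy(), truth)
    np.testing.assert_allclose(res.loc[res["cell_type"] != "median", "pearson_r"], 1.0)
    assert res.loc[res["cell_type"] == "median", "pearson_r"].iloc[0] == pytest.approx(1.0)


def test_absent_type_flagged_non_evaluable():
    truth = pd.DataFrame({"A": [0.5, 0.6, 0.7], "B": [0.5, 0.4, 0.3], "C": [0.0, 0.0, 0.0]})
    est = truth.copy()
    res = gs.evaluate_deconvolution(est, truth)
    c = res[res["cell_type"] == "C"].iloc[0]
    assert not c["evaluable"] and np.isnan(c["pearson_r"])


def test_random_estimates_median_r_near_zero():
    rng = np.random.default_rng(8)
    truth = pd.DataFrame(rng.dirichlet(np.ones(5), 100), columns=list("ABCDE"))
    est = pd.DataFrame(rng.dirichlet(np.ones(5), 100), columns=list("ABCDE"),
                       index=truth.index)
    res = gs.evaluate_deconvolution(est, truth)
    med = res.loc[res["cell_type"] == "median", "pearson_r"].iloc[0]
    assert abs(med) < 0.25


# ------------------------------------------------------------------- estimator
def test_deconvolver_estimator_roundtrip(sc_adata):
    adata, _ = sc_adata
    dec = gs.SignatureDeconvolver(n_cells=600, gmin=10, gmax=15, apply_qc=False,
                                  random_state=0)
    dec.fit(adata)
    assert dec.signature_.matrix.shape[1] == 6
    bulk, frac = gs.simulate_mixtures(dec.signature_.matrix, n_mixtures=8, seed=0)
    est = dec.predict(bulk)
    err = np.abs(est[dec.signature_.cell_types].to_numpy() - frac.to_numpy()).max()
    assert err < 1e-6
    # sklearn param plumbing
    assert dec.get_params()["gmin"] == 10
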