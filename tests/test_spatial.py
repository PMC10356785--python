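"""Compartment geometry, distance curves and the permutation neighborhood test."""

import numpy as np
import pandas as pd
import pytest
from shapely.geometry import Point, box

import graftscape as gs
from graftscape.spatial import CompartmentMap, neighborhood_counts

STRUCTURAL = ("PT_cell", "distal_tubule", "endothelium")


def _map(sample="S1"):
    return CompartmentMap(
        sample_id=sample,
        polygons={
            "glomerular": [Point(100, 100).buffer(50, quad_segs=64)],
            "tubular": [Point(100, 100).buffer(80, quad_segs=64), box(300, 300, 400, 400)],
            "large_vessel": [box(200, 0, 240, 500)],
        },
        boundary=box(0, 0, 500, 500),
    )


def _cells(points, sample="S1", types=None):
    df = pd.DataFrame(points, columns=["x", "y"])
    df["sample_id"] = sample
    df["phenotype"] = types if types is not None else "T"
    return df


# ------------------------------------------------------------ compartments
def test_precedence_and_interstitial_fallback():
    cells = _cells([(100, 100), (350, 350), (220, 450), (450, 100)])
    out = gs.assign_compartments(cells, _map())
    # disc center is inside both glomerulus and tubule: glomerular wins
    assert out["compartment"].tolist() == ["glomerular", "tubular", "large_vessel", "interstitial"]


def test_outside_field_flagged():
    cells = _cells([(600, 600), (10, 10)])
    out = gs.assign_compartments(cells, _map())
    assert out["outside_field"].tolist() == [True, False]
    assert out["compartment"].tolist() == ["", "interstitial"]


def test_geojson_roundtrip(tmp_path):
    cm = _map()
    path = tmp_path / "map.geojson"
    cm.write_geojson(path)
    back = CompartmentMap.from_geojson(str(path))
    assert back.sample_id == cm.sample_id
    assert set(back.polygons) == set(cm.polygons)
    assert back.union("glomerular").area == pytest.approx(cm.union("glomerular").area)


def test_composition_partitions_phenotype_share():
    cells = _cells([(100, 100), (350, 350), (450, 450), (450, 100)],
                   types=["T", "T", "B", "B"])
    out = gs.assign_compartments(cells, _map())
    comp = gs.compartment_composition(out)
    # per phenotype, shares across compartments sum to its overall share
    for p, share in (("T", 50.0), ("B", 50.0)):
        assert comp.loc[comp["phenotype"] == p, "pct_of_total"].sum() == pytest.approx(share)


def test_glomerular_inout_pure_phenotype():
    cells = _cells([(100, 100), (110, 110), (400, 100), (450, 450)],
                   types=["NK", "NK", "B", "B"])
    out = gs.assign_compartments(cells, _map())
    res = gs.glomerular_inout(out)
    nk = res[res["phenotype"] == "NK"].iloc[0]
    assert nk["pct_inside"] == 100.0 and nk["pct_outside"] == 0.0
    b = res[res["phenotype"] == "B"].iloc[0]
    assert b["pct_inside"] == 0.0 and b["pct_outside"] == 100.0


# ---------------------------------------------------------------- distances
def test_distance_zero_inside_glomerulus():
    cells = _cells([(100, 100)])
    assert gs.distance_to_glomerulus(cells, _map())[0] == 0.0


def test_distance_to_disc_boundary():
    # disc radius 50 at (100, 100); cell 80 um from the center is 30 from the rim
    cells = _cells([(180, 100)])
    assert gs.distance_to_glomerulus(cells, _map())[0] == pytest.approx(30.0, abs=0.05)


def _brute_force_distance(px, py, polygons):
    """Min distance to any polygon boundary segment; 0 if inside any polygon."""
    best = np.inf
    for poly in polygons:
        if poly.covers(Point(px, py)):
            return 0.0
        coords = np.asarray(poly.exterior.coords)
        for (x1, y1), (x2, y2) in zip(coords[:-1], coords[1:]):
            dx, dy = x2 - x1, y2 - y1
            t = np.clip(((px - x1) * dx + (py - y1) * dy) / (dx * dx + dy * dy), 0, 1)
            best = min(best, np.hypot(px - (x1 + t * dx), py - (y1 + t * dy)))
    return best


def test_distance_matches_all_edges_oracle():
    rng = np.random.default_rng(9)
    cm = _map()
    pts = rng.uniform(0, 500, (100, 2))
    cells = _cells(list(map(tuple, pts)))
    fast = gs.distance_to_glomerulus(cells, cm)
    slow = [_brute_force_distance(x, y, cm.polygons["glomerular"]) for x, y in pts]
    np.testing.assert_allclose(fast, slow, atol=1e-9)


def test_enrichment_curve_monotone_and_saturates(null_tissue):
    cells, cmap, _ = null_tissue
    dist = gs.distance_to_glomerulus(cells, cmap)
    curve = gs.enrichment_curve(cells, "CD8_Teff", dist, grid=np.arange(0, 2001, 50))
    vals = curve["pct_of_total"].to_numpy()
    assert np.all(np.diff(vals) >= 0)
    overall = 100.0 * (cells["phenotype"] == "CD8_Teff").mean()
    assert vals[-1] == pytest.approx(overall)
    assert np.all(vals <= overall + 1e-12)


# ------------------------------------------------------------ neighborhoods
def test_pair_within_distance_counted():
    cells = _cells([(0, 0), (3, 4)], types=["A", "B"])  # 5 um apart
    assert neighborhood_counts(cells, 10, "A", "B") == 1
    assert neighborhood_counts(cells, 4, "A", "B") == 0


def test_same_type_pairs_double_when_ordered():
    cells = _cells([(0, 0), (1, 0), (100, 100)], types=["A", "A", "A"])
    assert neighborhood_counts(cells, 5, "A", "A", ordered=True) == 2
    assert neighborhood_counts(cells, 5, "A", "A", ordered=False) == 1


def _brute_force_count(cells, d, source, target):
    xy = cells[["x", "y"]].to_numpy()
    lab = cells["phenotype"].to_numpy()
    n = 0
    for i in range(len(xy)):
        for j in range(len(xy)):
            if i != j and lab[i] == source and lab[j] == target:
                if np.hypot(*(xy[i] - xy[j])) <= d:
                    n += 1
    return n


def test_counts_equal_brute_force_oracle():
    rng = np.random.default_rng(4)
    cells = _cells(
        list(map(tuple, rng.uniform(0, 300, (200, 2)))),
        types=rng.choice(["A", "B", "C"], 200),
    )
    for d in (10, 25, 50):
        for s, t in (("A", "B"), ("B", "A"), ("A", "A")):
            assert neighborhood_counts(cells, d, s, t) == _brute_force_count(cells, d, s, t)


def test_exceedance_counts_partition_permutations(null_tissue):
    cells, _, _ = null_tissue
    cfg = gs.NeighborhoodConfig(distances=(20, 40), n_permutations=37,
                                structural_types=STRUCTURAL, seed=1)
    res = gs.neighborhood_test(cells, cfg, "NK_FcgR3", "macrophage")
    assert ((res["n_higher"] + res["n_lower"] + res["n_tied"]) == 37).all()
    assert ((res["p_enrich"] > 0) & (res["p_enrich"] <= 1)).all()


def test_constant_labels_give_p_one():
    rng = np.random.default_rng(5)
    cells = _cells(list(map(tuple, rng.uniform(0, 100, (60, 2)))), types=["A"] * 60)
    cfg = gs.NeighborhoodConfig(distances=(15,), n_permutations=25, seed=0)
    res = gs.neighborhood_test(cells, cfg, "A", "A")
    assert res["p_enrich"].iloc[0] == 1.0
    assert res["p_deplete"].iloc[0] == 1.0
    assert res["n_tied"].iloc[0] == 25


def test_structural_freeze_preserves_structural_pair_counts(null_tissue):
    """Permuting only immune labels must keep immune-structural counts at the
    values obtained by permuting all labels restricted to immune positions."""
    cells, _, _ = null_tissue
    labels = cells["phenotype"].to_numpy()
    free = ~np.isin(labels, STRUCTURAL)
    rng = np.random.default_rng(0)
    permuted = labels.copy()
    permuted[free] = rng.permutation(labels[free])
    # structural labels are untouched by construction of the scheme
    assert np.array_equal(permuted[~free], labels[~free])
    assert sorted(permuted[free]) == sorted(labels[free])


def test_absent_type_flagged_non_evaluable():
    rng = np.random.default_rng(6)
    cells = _cells(list(map(tuple, rng.uniform(0, 100, (40, 2)))),
                   types=rng.choice(["A", "B"], 40))
    cfg = gs.NeighborhoodConfig(distances=(20,), n_permutations=9, seed=0)
    res = gs.neighborhood_test(cells, cfg, "A", "Z")
    assert not res["evaluable"].iloc[0]
    assert np.isnan(res["p_enrich"].iloc[0])


def test_structural_source_rejected(null_tissue):
    cells, _, _ = null_tissue
    cfg = gs.NeighborhoodConfig(structural_types=STRUCTURAL)
    with pytest.raises(ValueError):
        gs.neighborhood_test(cells, cfg, "PT_cell", "NK_FcgR3")


def test_neighborhood_test_deterministic(null_tissue):
    cells, _, _ = null_tissue
    cfg = gs.NeighborhoodConfig(distances=(30,), n_permutations=20,
                                structural_types=STRUCTURAL, seed=123)
    r1 = gs.neighborhood_test(cells, cfg, "NK_FcgR3", "nonclassical_mono")
    r2 = gs.neighborhood_test(cells, cfg, "NK_FcgR3", "nonclassical_mono")
    pd.testing.assert_frame_equal(r1, r2)
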