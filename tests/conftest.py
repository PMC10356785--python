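import numpy as np
import pandas as pd
import pytest

import graftscape as gs

STRUCTURAL = ("PT_cell", "distal_tubule", "endothelium")


@pytest.fixture(scope="session")
def null_tissue():
    """One reference tissue with neutral odds and no co-localization."""
    cells, cmap, truth = gs.simulate_tissue(gs.default_tissue_spec(seed=11))
    return cells, cmap, truth


@pytest.fixture(scope="session")
def ten_blob_cells():
    """4,000 cells over 10 well-separated phenotypes with marker MFIs."""
    phen = [f"P{i}" for i in range(10)]
    model = gs.default_marker_model(phenotypes=phen, seed=3)
    spec = gs.default_tissue_spec(seed=3, n_cells=4000, abundance={p: 0.1 for p in phen})
    cells, _, _ = gs.simulate_tissue(spec)
    cells = gs.simulate_markers(cells, model)
    return cells, model, gs.default_signatures(model)


@pytest.fixture(scope="session")
def sc_adata():
    """Small labeled single-cell counts (6 types) for deconvolution units."""
    spec = gs.default_expression_spec(n_genes=600, n_types=6, markers_per_type=25, seed=5)
    return gs.simulate_sc_counts(spec, n_cells_per_type=150), spec
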