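"""Readers and writers for the pipeline's on-disk formats.

Cell tables travel as CSV (one row per cell) with a JSON sidecar schema;
compartment maps as GeoJSON FeatureCollections (one feature per polygon,
``compartment`` property); single-cell counts as MatrixMarket MTX plus
gene/cell TSVs; signature matrices and fraction tables as TSV.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd
from scipy.io import mmread, mmwrite
from scipy.sparse import csr_matrix

CORE_COLUMNS = {
    "cell_id": "unique cell identifier",
    "sample_id": "biopsy / sample identifier",
    "region_id": "staining region (normalization stratum)",
    "x": "x coordinate, micrometres, origin top-left",
    "y": "y coordinate, micrometres, y increases downward",
    "nuclear_size": "nuclear area, square micrometres",
    "phenotype": "ground-truth or assigned phenotype",
    "compartment": "tissue compartment (spatial stage)",
}


def write_cell_table(cells: pd.DataFrame, path) -> None:
    """Write a cell table CSV plus a ``.schema.json`` column-description sidecar."""
    path = Path(path)
    cells.to_csv(path, index=False)
    schema = {}
    for col in cells.columns:
        if col in CORE_COLUMNS:
            schema[col] = CORE_COLUMNS[col]
        elif col.endswith("_z"):
            schema[col] = f"trimmed per-region Z-score of marker {col[:-2]!r}"
        else:
            schema[col] = "raw marker MFI or pipeline annotation"
    path.with_suffix(path.suffix + ".schema.json").write_text(json.dumps(schema, indent=1))


def read_cell_table(path) -> pd.DataFrame:
    return pd.read_csv(path)


def write_counts_mtx(adata, outdir) -> None:
    """Write AnnData counts as matrix.mtx + genes.tsv + cells.tsv."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    X = adata.X
    mmwrite(str(outdir / "matrix.mtx"), csr_matrix(X))
    pd.Series(adata.var_names).to_csv(outdir / "genes.tsv", sep="\t", index=False, header=False)
    adata.obs.reset_index().rename(columns={"index": "cell_id"}).to_csv(
        outdir / "cells.tsv", sep="\t", index=False
    )


def read_counts_mtx(outdir):
    """Read counts written by :func:`write_counts_mtx` back into AnnData."""
    import anndata as ad

    outdir = Path(outdir)
    X = mmread(str(outdir / "matrix.mtx")).tocsr()
    genes = pd.read_csv(outdir / "genes.tsv", sep="\t", header=None)[0].astype(str)
    obs = pd.read_csv(outdir / "cells.tsv", sep="\t")
    obs = obs.set_index(obs.columns[0])
    obs.index = obs.index.astype(str)
    adata = ad.AnnData(X=np.asarray(X.todense()), obs=obs)
    adata.var_names = genes
    return adata
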