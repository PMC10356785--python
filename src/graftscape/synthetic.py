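"""Synthetic tissues, marker intensities, single-cell counts and bulk mixtures.

Every downstream stage of the pipeline (phenotyping, spatial statistics,
deconvolution, reporting) is exercisable on data generated here with known
ground truth.  The generators emulate:

* segmented multiplex-IF cell tables over a kidney-like section — glomeruli
  as non-overlapping discs, large vessels as rectangles, tubules as a union
  of discs, interstitium as the complement (the simplest geometry that
  supports point-in-polygon and distance queries);
* per-cell marker intensities as log-normal draws with per-region gain and
  shift (removed downstream by per-region Z-scoring);
* labeled single-cell counts as negative binomials with library-size
  scaling, plus optional low-complexity / high-mitochondrial cells for QC
  testing;
* bulk mixtures as signature x fractions with multiplicative noise.

Coordinates are in micrometres, origin top-left, y increasing downward
(image convention).  All generators are bit-reproducible for a fixed seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import anndata as ad
import numpy as np
import pandas as pd
import shapely
from shapely.geometry import Point, Polygon, box

from .spatial import CompartmentMap, PRECEDENCE

__all__ = [
    "TissueSpec",
    "MarkerModel",
    "ExpressionSpec",
    "simulate_tissue",
    "simulate_markers",
    "simulate_sc_counts",
    "simulate_mixtures",
    "default_tissue_spec",
    "default_marker_model",
    "default_signatures",
    "default_expression_spec",
]

# default cytometry of a simulated section: three structural types
# (frozen in the neighborhood permutation) and eight immune types
DEFAULT_ABUNDANCE = {
    "PT_cell": 0.30,
    "distal_tubule": 0.10,
    "endothelium": 0.08,
    "NK_FcgR3": 0.06,
    "CD8_Teff": 0.10,
    "CD4_Teff": 0.08,
    "B_cell": 0.05,
    "macrophage": 0.08,
    "neutrophil": 0.04,
    "classical_mono": 0.06,
    "nonclassical_mono": 0.05,
}
STRUCTURAL_TYPES = ("PT_cell", "distal_tubule", "endothelium")


@dataclass
class TissueSpec:
    """Geometry, cytometry and spatial effects of one simulated section."""

    sample_id: str = "S1"
    width: float = 1000.0
    height: float = 1000.0
    n_cells: int = 1500
    n_glomeruli: int = 3
    glom_radius_mean: float = 70.0
    glom_radius_sd: float = 10.0
    # each large vessel: (x, y, width, height) rectangle
    large_vessels: tuple = ((620.0, 100.0, 80.0, 320.0),)
    n_small_vessels: int = 8
    small_vessel_radius: float = 15.0
    tubule_fraction: float = 0.35
    tubule_disc_radius: float = 45.0
    abundance: dict = field(default_factory=lambda: dict(DEFAULT_ABUNDANCE))
    # phenotype -> {compartment: odds multiplier}; unlisted odds are 1
    compartment_odds: dict = field(default_factory=dict)
    # (attractor phenotype, attracted phenotype, sigma um, fraction attracted)
    colocalization: tuple = ()
    n_regions: int = 2
    seed: int = 0

    def __post_init__(self) -> None:
        total = sum(self.abundance.values())
        if abs(total - 1.0) > 1e-9:
            raise ValueError(f"abundances must sum to 1 (got {total})")
        for v in (self.width, self.height, self.glom_radius_mean, self.small_vessel_radius, self.tubule_disc_radius):
            if v <= 0:
                raise ValueError("geometric parameters must be positive")
        for _, _, sigma, frac in self.colocalization:
            if sigma <= 0:
                raise ValueError("co-localization sigma must be > 0")
            if not 0 <= frac <= 1:
                raise ValueError("attracted fraction must lie in [0, 1]")


def _disc(cx: float, cy: float, r: float) -> Polygon:
    return Point(cx, cy).buffer(r, quad_segs=32)


def _build_geometry(spec: TissueSpec, rng: np.random.Generator) -> CompartmentMap:
    boundary = box(0, 0, spec.width, spec.height)
    polygons: dict = {}

    gloms = []
    attempts = 0
    while len(gloms) < spec.n_glomeruli and attempts < 1000:
        attempts += 1
        r = max(20.0, rng.normal(spec.glom_radius_mean, spec.glom_radius_sd))
        cx = rng.uniform(r, spec.width - r)
        cy = rng.uniform(r, spec.height - r)
        cand = _disc(cx, cy, r)
        if all(not cand.intersects(g) for g in gloms):
            gloms.append(cand)
    if gloms:
        polygons["glomerular"] = gloms

    if spec.large_vessels:
        polygons["large_vessel"] = [box(x, y, x + w, y + h) for x, y, w, h in spec.large_vessels]

    if spec.n_small_vessels:
        polygons["small_vessel"] = [
            _disc(rng.uniform(0, spec.width), rng.uniform(0, spec.height), spec.small_vessel_radius)
            for _ in range(spec.n_small_vessels)
        ]

    if spec.tubule_fraction > 0:
        area = spec.width * spec.height
        disc_area = np.pi * spec.tubule_disc_radius**2
        # oversample to offset overlap between discs
        n_discs = int(np.ceil(1.3 * spec.tubule_fraction * area / disc_area))
        polygons["tubular"] = [
            _disc(rng.uniform(0, spec.width), rng.uniform(0, spec.height), spec.tubule_disc_radius)
            for _ in range(n_discs)
        ]

    return CompartmentMap(sample_id=spec.sample_id, polygons=polygons, boundary=boundary)


def _compartment_of_points(cmap: CompartmentMap, xs: np.ndarray, ys: np.ndarray) -> np.ndarray:
    pts = shapely.points(xs, ys)
    comp = np.full(len(xs), "interstitial", dtype=object)
    assigned = np.zeros(len(xs), dtype=bool)
    for label in PRECEDENCE:
        union = cmap.union(label)
        if union is None:
            continue
        inside = shapely.covers(union, pts) & ~assigned
        comp[inside] = label
        assigned |= inside
    return comp


def simulate_tissue(spec: TissueSpec) -> tuple[pd.DataFrame, CompartmentMap, pd.Series]:
    """Simulate one tissue section.

    Cells are placed by rejection sampling: a uniform candidate point in the
    field is accepted with probability proportional to the phenotype's odds
    multiplier for the compartment it falls in, so a phenotype with odds w
    in a compartment has its in/out density ratio multiplied by w.  After
    placement, for each co-localization effect a stated fraction of the
    attracted phenotype is moved to a random attractor cell plus an
    isotropic Gaussian(sigma) displacement.

    Returns (cell table, compartment map, ground-truth phenotype labels).
    """
    rng = np.random.default_rng(spec.seed)
    cmap = _build_geometry(spec, rng)

    phenotypes = list(spec.abundance)
    probs = np.array([spec.abundance[p] for p in phenotypes])
    counts = rng.multinomial(spec.n_cells, probs)

    xs_all, ys_all, phen_all = [], [], []
    for ptype, n_needed in zip(phenotypes, counts):
        odds = {c: 1.0 for c in ("glomerular", "large_vessel", "small_vessel", "tubular", "interstitial")}
        odds.update(spec.compartment_odds.get(ptype, {}))
        max_odds = max(odds.values())
        got_x: list[np.ndarray] = []
        got_y: list[np.ndarray] = []
        n_got = 0
        while n_got < n_needed:
            batch = max(256, 2 * (n_needed - n_got))
            cx = rng.uniform(0, spec.width, batch)
            cy = rng.uniform(0, spec.height, batch)
            comp = _compartment_of_points(cmap, cx, cy)
            accept_p = np.array([odds[c] / max_odds for c in comp])
            keep = rng.random(batch) < accept_p
            got_x.append(cx[keep])
            got_y.append(cy[keep])
            n_got += int(keep.sum())
        gx = np.concatenate(got_x)[:n_needed]
        gy = np.concatenate(got_y)[:n_needed]
        xs_all.append(gx)
        ys_all.append(gy)
        phen_all.extend([ptype] * n_needed)

    xs = np.concatenate(xs_all)
    ys = np.concatenate(ys_all)
    phen = np.array(phen_all, dtype=object)

    # co-localization: move a fraction of the attracted type next to attractors
    for attractor, attracted, sigma, frac in spec.colocalization:
        a_idx = np.flatnonzero(phen == attractor)
        b_idx = np.flatnonzero(phen == attracted)
        if len(a_idx) == 0 or len(b_idx) == 0:
            continue
        n_move = int(round(frac * len(b_idx)))
        moved = rng.choice(b_idx, size=n_move, replace=False)
        anchors = rng.choice(a_idx, size=n_move, replace=True)
        xs[moved] = np.clip(xs[anchors] + rng.normal(0, sigma, n_move), 0, spec.width)
        ys[moved] = np.clip(ys[anchors] + rng.normal(0, sigma, n_move), 0, spec.height)

    order = rng.permutation(spec.n_cells)
    xs, ys, phen = xs[order], ys[order], phen[order]
    region = np.where(xs < spec.width / 2, f"{spec.sample_id}_R1", f"{spec.sample_id}_R2")
    if spec.n_regions == 1:
        region = np.full(spec.n_cells, f"{spec.sample_id}_R1", dtype=object)
    cells = pd.DataFrame(
        {
            "cell_id": [f"{spec.sample_id}_c{i}" for i in range(spec.n_cells)],
            "sample_id": spec.sample_id,
            "region_id": region,
            "x": xs,
            "y": ys,
            "nuclear_size": rng.lognormal(np.log(35.0), 0.25, spec.n_cells),
            "phenotype": phen,
        }
    )
    return cells, cmap, cells["phenotype"].copy()


# ----------------------------------------------------------------- marker MFI
@dataclass
class MarkerModel:
    """Log-normal marker intensity model with per-region batch effects."""

    log_mean: pd.DataFrame  # phenotype x marker
    log_sd: pd.DataFrame  # phenotype x marker, all > 0 (0 allowed for degenerate tests)
    region_gain: dict = field(default_factory=dict)  # region -> multiplicative gain
    region_shift: dict = field(default_factory=dict)  # region -> additive shift
    noise_sd: float = 0.05
    seed: int = 0

    def __post_init__(self) -> None:
        if not self.log_mean.index.equals(self.log_sd.index) or not self.log_mean.columns.equals(self.log_sd.columns):
            raise ValueError("log_mean and log_sd must share phenotype/marker axes")
        if (self.log_sd.to_numpy() < 0).any():
            raise ValueError("log-intensity sds must be >= 0")
        if self.noise_sd < 0:
            raise ValueError("noise sd must be >= 0")
        self._check_separation()

    def _check_separation(self) -> None:
        mu = self.log_mean.to_numpy()
        sd = self.log_sd.to_numpy()
        for i in range(mu.shape[0]):
            ok = False
            for j in range(mu.shape[1]):
                gaps = np.abs(mu[:, j] - mu[i, j])
                pooled = sd[:, j] + sd[i, j]
                others = np.delete(np.arange(mu.shape[0]), i)
                if np.all(gaps[others] >= np.maximum(pooled[others], 1e-12)):
                    ok = True
                    break
            if not ok:
                raise ValueError(
                    f"phenotype {self.log_mean.index[i]!r} has no marker separating it from all others"
                )

    @property
    def markers(self) -> list[str]:
        return list(self.log_mean.columns)

    @property
    def phenotypes(self) -> list[str]:
        return list(self.log_mean.index)


def simulate_markers(cells: pd.DataFrame, model: MarkerModel) -> pd.DataFrame:
    """Attach raw MFI columns: exp(Normal(mu, sd)) * gain + shift + noise, floored at 0."""
    unknown = set(cells["phenotype"]) - set(model.phenotypes)
    if unknown:
        raise ValueError(f"phenotypes missing from marker model: {sorted(unknown)}")
    rng = np.random.default_rng(model.seed)
    out = cells.copy()
    mu = model.log_mean.loc[out["phenotype"]].to_numpy()
    sd = model.log_sd.loc[out["phenotype"]].to_numpy()
    mfi = np.exp(rng.normal(mu, sd))
    gain = out["region_id"].map(lambda r: model.region_gain.get(r, 1.0)).to_numpy()[:, None]
    shift = out["region_id"].map(lambda r: model.region_shift.get(r, 0.0)).to_numpy()[:, None]
    mfi = mfi * gain + shift
    if model.noise_sd > 0:
        mfi = mfi + rng.normal(0, model.noise_sd, mfi.shape)
    mfi = np.maximum(mfi, 0.0)
    for j, m in enumerate(model.markers):
        out[m] = mfi[:, j]
    return out


# --------------------------------------------------------- default MIF panels
def default_tissue_spec(**overrides) -> TissueSpec:
    """The package's reference tissue: neutral odds, no co-localization."""
    return TissueSpec(**overrides)


def default_marker_model(
    phenotypes: list[str] | None = None,
    n_markers: int = 20,
    markers_per_type: int = 2,
    mu_high: float = 2.5,
    mu_low: float = 0.0,
    log_sd: float = 0.25,
    noise_sd: float = 0.05,
    regions: dict | None = None,
    seed: int = 0,
) -> MarkerModel:
    """Separable marker panel: each phenotype high on its own marker block.

    With the defaults the inter-centroid separation in intensity space
    exceeds four within-phenotype standard deviations, which is the regime
    the consensus-phenotyping accuracy checks assume.
    """
    if phenotypes is None:
        phenotypes = [f"P{i}" for i in range(10)]
    need = len(phenotypes) * markers_per_type
    if n_markers < need:
        n_markers = need
    markers = [f"M{j}" for j in range(n_markers)]
    mu = pd.DataFrame(mu_low, index=phenotypes, columns=markers, dtype=float)
    for i, p in enumerate(phenotypes):
        for k in range(markers_per_type):
            mu.loc[p, markers[i * markers_per_type + k]] = mu_high
    sd = pd.DataFrame(log_sd, index=phenotypes, columns=markers, dtype=float)
    region_gain = {}
    region_shift = {}
    if regions:
        region_gain = {r: g for r, (g, _) in regions.items()}
        region_shift = {r: s for r, (_, s) in regions.items()}
    return MarkerModel(
        log_mean=mu, log_sd=sd, region_gain=region_gain, region_shift=region_shift,
        noise_sd=noise_sd, seed=seed,
    )


def default_signatures(model: MarkerModel) -> pd.DataFrame:
    """One-hot expected marker profiles (phenotype x marker) from a marker model.

    A marker is coded 1 for the phenotypes whose log-mean on it is within
    10% of the panel maximum, else 0 — the numeric form of a +/./- profile.
    """
    mu = model.log_mean
    hi = mu.to_numpy() >= mu.to_numpy().max() - 0.1 * (mu.to_numpy().max() - mu.to_numpy().min())
    return pd.DataFrame(hi.astype(float), index=mu.index, columns=mu.columns)


# ------------------------------------------------------------- expression data
@dataclass
class ExpressionSpec:
    """Negative-binomial single-cell expression model with known labels."""

    mean: pd.DataFrame  # genes x cell types, linear-scale NB means
    theta: float = 2.0  # NB shape; var = mu + mu^2/theta, theta -> inf is Poisson
    marker_sets: dict = field(default_factory=dict)  # type -> list of marker genes
    mito_genes: tuple = ()
    libsize_log_sd: float = 0.25
    seed: int = 0

    def __post_init__(self) -> None:
        if (self.mean.to_numpy() < 0).any():
            raise ValueError("negative NB means")
        if self.theta <= 0:
            raise ValueError("dispersion parameter must be > 0")
        seen: set = set()
        for t, genes in self.marker_sets.items():
            overlap = seen & set(genes)
            if overlap:
                raise ValueError(f"marker-gene sets must be disjoint (duplicated: {sorted(overlap)[:3]}...)")
            seen |= set(genes)

    @property
    def genes(self) -> list[str]:
        return list(self.mean.index)

    @property
    def cell_types(self) -> list[str]:
        return list(self.mean.columns)


def default_expression_spec(
    n_genes: int = 4000,
    n_types: int = 18,
    markers_per_type: int = 40,
    marker_fold: float = 8.0,
    between_type_log_sd: float = 0.4,
    mito_fraction_of_genes: float = 0.01,
    theta: float = 2.0,
    seed: int = 0,
) -> ExpressionSpec:
    """Reference expression model: per-type marker blocks plus mild global
    between-type variation so that most genes are differentially expressed."""
    rng = np.random.default_rng(seed)
    genes = [f"G{g}" for g in range(n_genes)]
    types = [f"T{t}" for t in range(n_types)]
    base = rng.lognormal(mean=-0.5, sigma=1.0, size=n_genes)
    mean = np.outer(base, np.ones(n_types)) * rng.lognormal(0.0, between_type_log_sd, (n_genes, n_types))
    marker_sets = {}
    for t in range(n_types):
        lo, hi = t * markers_per_type, (t + 1) * markers_per_type
        if hi > n_genes:
            break
        mean[lo:hi, t] *= marker_fold
        marker_sets[types[t]] = genes[lo:hi]
    n_mito = max(1, int(mito_fraction_of_genes * n_genes))
    mito = tuple(genes[-n_mito:])
    return ExpressionSpec(
        mean=pd.DataFrame(mean, index=genes, columns=types),
        theta=theta,
        marker_sets=marker_sets,
        mito_genes=mito,
        seed=seed,
    )


def simulate_sc_counts(
    spec: ExpressionSpec,
    n_cells_per_type: int | dict = 500,
    n_low_complexity: int = 0,
    n_high_mito: int = 0,
    mito_fraction: float = 0.4,
    low_complexity_genes: int = 300,
) -> ad.AnnData:
    """Simulate labeled single-cell counts (cells x genes AnnData).

    Counts are NB(mean * library factor, theta).  Optionally injects
    low-complexity cells (exactly ``low_complexity_genes`` expressed genes)
    and high-mitochondrial cells (expected mito fraction ``mito_fraction``)
    labeled ``qc_low_complexity`` / ``qc_high_mito`` for QC testing.
    """
    rng = np.random.default_rng(spec.seed)
    mean = spec.mean.to_numpy()
    n_genes = mean.shape[0]
    if isinstance(n_cells_per_type, int):
        n_per = {t: n_cells_per_type for t in spec.cell_types}
    else:
        n_per = dict(n_cells_per_type)

    blocks, labels = [], []
    for t_idx, t in enumerate(spec.cell_types):
        n = n_per.get(t, 0)
        if n == 0:
            continue
        lib = np.exp(rng.normal(0.0, spec.libsize_log_sd, n))
        mu = mean[:, t_idx][None, :] * lib[:, None]
        p = spec.theta / (spec.theta + mu)
        counts = rng.negative_binomial(spec.theta, p)
        blocks.append(counts)
        labels.extend([t] * n)

    mito_idx = np.array([spec.genes.index(g) for g in spec.mito_genes], dtype=int)
    if n_low_complexity:
        lc = np.zeros((n_low_complexity, n_genes), dtype=np.int64)
        for i in range(n_low_complexity):
            on = rng.choice(n_genes, size=low_complexity_genes, replace=False)
            lc[i, on] = rng.poisson(3.0, low_complexity_genes) + 1
        blocks.append(lc)
        labels.extend(["qc_low_complexity"] * n_low_complexity)
    if n_high_mito:
        hm = rng.poisson(1.0, (n_high_mito, n_genes))
        non_mito_total = hm.sum(axis=1) - hm[:, mito_idx].sum(axis=1)
        # scale mito counts so expected mito share is mito_fraction
        target = mito_fraction / (1 - mito_fraction) * non_mito_total
        per_gene = np.maximum(target / max(len(mito_idx), 1), 0)
        hm[:, mito_idx] = rng.poisson(per_gene[:, None], (n_high_mito, len(mito_idx)))
        blocks.append(hm)
        labels.extend(["qc_high_mito"] * n_high_mito)

    X = np.vstack(blocks).astype(np.float32)
    adata = ad.AnnData(
        X=X,
        obs=pd.DataFrame({"cell_type": pd.Categorical(labels)}, index=[f"cell{i}" for i in range(X.shape[0])]),
        var=pd.DataFrame({"mito": [g in set(spec.mito_genes) for g in spec.genes]}, index=spec.genes),
    )
    return adata


def simulate_mixtures(
    signature_truth: pd.DataFrame,
    n_mixtures: int = 50,
    dirichlet_alpha: float | np.ndarray = 1.0,
    noise_sd: float = 0.0,
    seed: int = 0,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Simulate bulk profiles as signature x fractions with relative noise.

    fractions ~ Dirichlet(alpha) on the simplex; bulk_j = (S @ f_j) * (1 + sd*z)
    floored at 0.  Returns (genes x mixtures bulk, mixtures x types fractions).
    """
    rng = np.random.default_rng(seed)
    types = list(signature_truth.columns)
    alpha = np.full(len(types), dirichlet_alpha) if np.isscalar(dirichlet_alpha) else np.asarray(dirichlet_alpha)
    fractions = rng.dirichlet(alpha, size=n_mixtures)
    S = signature_truth.to_numpy(dtype=float)
    bulk = S @ fractions.T
    if noise_sd > 0:
        bulk = np.maximum(bulk * (1 + rng.normal(0, noise_sd, bulk.shape)), 0.0)
    mix_names = [f"mix{i}" for i in range(n_mixtures)]
    return (
        pd.DataFrame(bulk, index=signature_truth.index, columns=mix_names),
        pd.DataFrame(fractions, index=mix_names, columns=types),
    )
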