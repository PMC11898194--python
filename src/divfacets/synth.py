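"""Synthetic study system generator.

Emulates, at reduced scale and fully determined by one seed, the structure
the downstream analysis assumes: spatially autocorrelated environmental
surfaces on a regular grid, an east-to-west richness gradient injected
through range placement, log-normal correlated mammal traits with a
configurable fraction of incomplete species, a Yule phylogeny, per-GCM
Last Glacial Maximum climate layers, compositional land-use proportions,
and a per-species habitat-suitability thinning mask that ties realized
richness to forest (positive) and cropland (negative) cover so that the
injected effects are recoverable by the spatial regression.

One root seed; every component draws from its own child stream derived by
a fixed component id, so changing one component's draw count never
perturbs the others.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from pathlib import Path

import dendropy
import numpy as np
import pandas as pd
import yaml
from scipy.ndimage import gaussian_filter, generic_filter
from shapely.geometry import box

from .assembly import SpeciesRange, ranges_to_geojson
from .grid import Grid
from .spatial import lgm_anomaly
from .traits import TRAIT_NAMES, TraitTable

# fixed component ids for child seed derivation
_CID_SURFACE = 11
_CID_TREE = 23
_CID_TRAITS = 31
_CID_RANGES = 41
_CID_SUITABILITY = 53

#: value ranges the raw smoothed fields are rescaled to, per surface
SURFACE_RANGES: dict[str, tuple[float, float]] = {
    "elevation": (500.0, 4500.0),
    "MAT": (-2.0, 18.0),
    "AP": (400.0, 1600.0),
}

#: land-use classes (proportions per cell); cropland/forest/UGS are the
#: classes the regression uses
LANDUSE_CLASSES = [
    "bare", "cropland", "forest", "grassland", "impervious",
    "shrubland", "snow_ice", "ugs", "water", "wetland",
]

_SURFACE_IDS = {name: i for i, name in enumerate(
    list(SURFACE_RANGES) + [f"landuse_{c}" for c in LANDUSE_CLASSES]
    + [f"lgm_mat_gcm{g}" for g in (1, 2, 3)]
    + [f"lgm_ap_gcm{g}" for g in (1, 2, 3)]
)}


@dataclass
class LandscapeConfig:
    """Knobs of the synthetic study system (defaults = study conditions)."""

    n_rows: int = 20
    n_cols: int = 20
    cell_size_km: float = 5.0
    n_species: int = 30
    autocorr_length_cells: float = 1.5
    richness_gradient_strength: float = 1.0
    trait_corr: float = 0.6
    yule_birth_rate: float = 1.0
    trait_missing_fraction: float = 0.2
    forest_effect: float = 2.0
    cropland_effect: float = -2.0
    suitability_baseline: float = 0.5
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_rows * self.n_cols < 4:
            raise ValueError("grid must have at least 4 cells")
        if self.n_species < 3:
            raise ValueError("need at least 3 species")
        if not -1.0 < self.trait_corr < 1.0:
            raise ValueError("trait_corr must be in (-1, 1)")
        if not self.yule_birth_rate > 0:
            raise ValueError("yule_birth_rate must be positive")
        if not 0.0 <= self.trait_missing_fraction < 1.0:
            raise ValueError("trait_missing_fraction must be in [0, 1)")
        if not self.autocorr_length_cells >= 0:
            raise ValueError("autocorr_length_cells must be >= 0")
        if not self.cell_size_km > 0:
            raise ValueError("cell_size_km must be positive")

    @property
    def grid(self) -> Grid:
        return Grid(self.n_rows, self.n_cols, self.cell_size_km)

    def to_yaml(self, path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(asdict(self), fh, sort_keys=True)

    @classmethod
    def from_yaml(cls, path) -> "LandscapeConfig":
        with open(path) as fh:
            d = yaml.safe_load(fh)
        return cls.from_dict(d)

    @classmethod
    def from_dict(cls, d: dict) -> "LandscapeConfig":
        known = {f for f in cls.__dataclass_fields__}
        unknown = set(d) - known
        if unknown:
            raise ValueError(f"unknown landscape config keys: {sorted(unknown)}")
        return cls(**d)


def _rng(config: LandscapeConfig, component: int, extra: int = 0) -> np.random.Generator:
    return np.random.default_rng(
        np.random.SeedSequence((config.seed, component, extra))
    )


# ---------------------------------------------------------------------------
# Surfaces


def generate_surface(config: LandscapeConfig, which: str) -> np.ndarray:
    """One spatially autocorrelated per-cell surface, flattened row-major.

    Seeded white noise smoothed with an isotropic Gaussian kernel of scale
    ``autocorr_length_cells`` and min-max rescaled to the surface's value
    range (proportion-like surfaces go to [0, 1]).
    """
    if which not in _SURFACE_IDS:
        raise ValueError(
            f"unknown surface {which!r}; valid surfaces: {sorted(_SURFACE_IDS)}"
        )
    rng = _rng(config, _CID_SURFACE, _SURFACE_IDS[which])
    noise = rng.standard_normal((config.n_rows, config.n_cols))
    if config.autocorr_length_cells > 0:
        field_ = gaussian_filter(noise, sigma=config.autocorr_length_cells,
                                 mode="reflect")
    else:
        field_ = noise
    lo, hi = SURFACE_RANGES.get(which, (0.0, 1.0))
    fmin, fmax = field_.min(), field_.max()
    if fmax == fmin:  # pathological flat field
        return np.full(config.n_rows * config.n_cols, (lo + hi) / 2.0)
    scaled = lo + (field_ - fmin) / (fmax - fmin) * (hi - lo)
    return scaled.ravel()


def habitat_from_elevation(elevation: np.ndarray) -> np.ndarray:
    """Habitat raster: elevation terciles -> codes 0 (low), 1 (mid), 2 (high)."""
    q1, q2 = np.quantile(elevation, [1 / 3, 2 / 3])
    return np.digitize(elevation, [q1, q2]).astype(int)


def _local_stat(grid_vals: np.ndarray, shape: tuple[int, int], fn) -> np.ndarray:
    arr = grid_vals.reshape(shape)
    return generic_filter(arr, fn, size=3, mode="reflect").ravel()


# ---------------------------------------------------------------------------
# Phylogeny


def generate_phylogeny(config: LandscapeConfig) -> dendropy.Tree:
    """Rooted bifurcating ultrametric Yule tree with n_species tips.

    Forward simulation: start from the root's two daughter lineages, wait
    Exp(k * lambda) between speciation events, split a uniformly chosen
    lineage; after the last split the present is one further Exp(n * lambda)
    ahead, so every pendant branch has positive length.
    """
    n = config.n_species
    if n < 2:
        raise ValueError("need at least 2 species for a phylogeny")
    lam = config.yule_birth_rate
    rng = _rng(config, _CID_TREE)

    taxa = dendropy.TaxonNamespace()
    tree = dendropy.Tree(taxon_namespace=taxa)
    t = 0.0
    root = tree.seed_node
    active: list[tuple[dendropy.Node, float]] = []  # (node, birth time)
    for _ in range(2):
        child = root.new_child()
        active.append((child, 0.0))
    while len(active) < n:
        t += rng.exponential(1.0 / (lam * len(active)))
        idx = rng.integers(len(active))
        node, birth = active.pop(idx)
        node.edge.length = t - birth
        active.append((node.new_child(), t))
        active.append((node.new_child(), t))
    t_end = t + rng.exponential(1.0 / (lam * n))
    # deterministic tip labelling: left-to-right leaf order
    for node, birth in active:
        node.edge.length = t_end - birth
    for i, leaf in enumerate(tree.leaf_node_iter()):
        leaf.taxon = taxa.new_taxon(f"sp{i + 1:04d}")
    root.edge.length = 0.0
    return tree


def write_newick(tree: dendropy.Tree, path) -> None:
    tree.write(path=str(path), schema="newick", suppress_rooting=True,
               real_value_format_specifier=".12g")


def read_newick(path) -> dendropy.Tree:
    return dendropy.Tree.get(path=str(path), schema="newick")


# ---------------------------------------------------------------------------
# Traits


# log10-scale means and SDs for the nine canonical traits (mammal-like
# magnitudes: lengths in mm, mass in g, ages in days)
_TRAIT_LOG_MEAN = np.array([1.5, 2.0, 2.2, 2.5, 0.2, 0.45, 2.3, 2.9, 1.8])
_TRAIT_LOG_SD = np.array([0.3, 0.35, 0.3, 0.5, 0.15, 0.2, 0.3, 0.25, 0.2])

#: designated correlated trait pairs (log-scale correlation = trait_corr)
TRAIT_PAIRS = [(0, 1), (2, 3), (4, 5), (6, 7)]


def generate_traits(config: LandscapeConfig) -> TraitTable:
    """Multivariate log-normal traits; designated pairs correlated.

    A ``trait_missing_fraction`` share of species (in expectation) gets one
    missing value to exercise the completeness filter.
    """
    if config.n_species < 2:
        raise ValueError("need at least 2 species")
    rng = _rng(config, _CID_TRAITS)
    k = len(TRAIT_NAMES)
    R = np.eye(k)
    for i, j in TRAIT_PAIRS:
        R[i, j] = R[j, i] = config.trait_corr
    L = np.linalg.cholesky(R)
    z = rng.standard_normal((config.n_species, k)) @ L.T
    vals = 10.0 ** (_TRAIT_LOG_MEAN + _TRAIT_LOG_SD * z)
    species = [f"sp{i + 1:04d}" for i in range(config.n_species)]
    df = pd.DataFrame(vals, index=species, columns=TRAIT_NAMES)
    incomplete = rng.random(config.n_species) < config.trait_missing_fraction
    for i in np.flatnonzero(incomplete):
        df.iloc[i, int(rng.integers(k))] = np.nan
    return TraitTable(df)


# ---------------------------------------------------------------------------
# Ranges and suitability


def generate_ranges(
    config: LandscapeConfig, elevation: np.ndarray
) -> list[SpeciesRange]:
    """Rectangular extents of occurrence with elevation/habitat tolerances.

    Range centres are biased eastward (toward high column index) with
    strength ``richness_gradient_strength``, so assembled richness declines
    westward.  Elevation intervals are drawn from pooled elevation
    quantiles; tolerated habitat codes are a random 2- or 3-band subset.
    """
    rng = _rng(config, _CID_RANGES)
    g = config.richness_gradient_strength
    if g < 0:
        raise ValueError("richness_gradient_strength must be >= 0")
    grid = config.grid
    x0, y0, x1, y1 = grid.extent
    W, H = x1 - x0, y1 - y0
    out = []
    for i in range(config.n_species):
        fx = rng.random() ** (1.0 / (1.0 + g))  # biased toward 1 (east) if g > 0
        cx = x0 + fx * W
        cy = y0 + rng.random() * H
        w = rng.uniform(0.5, 0.95) * W
        h = rng.uniform(0.5, 0.95) * H
        rect = box(
            max(x0, cx - w / 2), max(y0, cy - h / 2),
            min(x1, cx + w / 2), min(y1, cy + h / 2),
        )
        lo = float(np.quantile(elevation, rng.uniform(0.0, 0.25)))
        hi = float(np.quantile(elevation, rng.uniform(0.75, 1.0)))
        if not lo < hi:
            hi = lo + 1.0
        n_bands = int(rng.integers(2, 4))
        bands = frozenset(rng.choice(3, size=n_bands, replace=False).tolist())
        out.append(
            SpeciesRange(
                species_id=f"sp{i + 1:04d}",
                polygon=rect,
                elev_lo=lo,
                elev_hi=hi,
                habitat_codes=bands,
            )
        )
    return out


def generate_suitability(
    config: LandscapeConfig, forest: np.ndarray, cropland: np.ndarray
) -> np.ndarray:
    """Per-species x per-cell Bernoulli keep mask from land-use suitability.

    Keep probability is logistic in the standardized forest and cropland
    proportions with the configured effects, so realized richness responds
    positively to forest and negatively to cropland cover.
    """
    rng = _rng(config, _CID_SUITABILITY)
    zf = (forest - forest.mean()) / forest.std(ddof=1)
    zc = (cropland - cropland.mean()) / cropland.std(ddof=1)
    eta = (
        config.suitability_baseline
        + config.forest_effect * zf
        + config.cropland_effect * zc
    )
    keep_p = 1.0 / (1.0 + np.exp(-eta))
    return rng.random((config.n_species, keep_p.size)) < keep_p


def apply_suitability(presence, suitability: np.ndarray):
    """Thin a presence matrix by the generator's ground-truth keep mask.

    Row order of ``suitability`` follows sp0001..; rows are matched to the
    matrix's species by id.
    """
    from .assembly import PresenceMatrix

    out = presence.data.copy()
    for i, sid in enumerate(presence.species):
        sp_idx = int(sid[2:]) - 1
        out[i] &= suitability[sp_idx].astype(np.int8)
    return PresenceMatrix(list(presence.species), presence.cells.copy(), out)


# ---------------------------------------------------------------------------
# Predictors and full study


def generate_predictors(config: LandscapeConfig, elevation: np.ndarray) -> pd.DataFrame:
    """Per-cell predictor table: climate, LGM layers/anomalies, land use,
    topographic heterogeneity.  Land-use proportions are compositional
    (each in [0, 1], summing to 0.95 per cell)."""
    mat = generate_surface(config, "MAT")
    ap = generate_surface(config, "AP")
    # per-GCM LGM layers: current + smoothed perturbation per model
    lgm_mat = []
    lgm_ap = []
    for gcm in (1, 2, 3):
        pert_m = generate_surface(config, f"lgm_mat_gcm{gcm}")  # in [0, 1]
        pert_a = generate_surface(config, f"lgm_ap_gcm{gcm}")
        lgm_mat.append(mat - 6.0 * pert_m)          # LGM colder by 0-6 C
        lgm_ap.append(ap - 400.0 * pert_a)          # LGM drier by 0-400 mm
    raw = {c: generate_surface(config, f"landuse_{c}") for c in LANDUSE_CLASSES}
    total = np.sum(list(raw.values()), axis=0)
    landuse = {c: 0.95 * raw[c] / total for c in LANDUSE_CLASSES}

    shape = (config.n_rows, config.n_cols)
    df = pd.DataFrame({"cell_id": np.arange(config.n_rows * config.n_cols)})
    df["MAT"] = mat
    df["AP"] = ap
    for gcm, (lm, la) in enumerate(zip(lgm_mat, lgm_ap), start=1):
        df[f"lgm_mat_gcm{gcm}"] = lm
        df[f"lgm_ap_gcm{gcm}"] = la
    df["lgm_mat_anomaly"] = lgm_anomaly(mat, lgm_mat)
    df["lgm_ap_anomaly"] = lgm_anomaly(ap, lgm_ap)
    for c in LANDUSE_CLASSES:
        df[f"prop_{c}"] = landuse[c]
    df["elev_sd"] = _local_stat(elevation, shape, np.std)
    df["elev_range"] = _local_stat(elevation, shape, np.ptp)
    return df


#: the full pre-screen predictor set (climate + anomalies + 10 land-use
#: classes + topography), mirroring a 16-variable candidate pool
CANDIDATE_PREDICTORS = (
    ["MAT", "AP", "lgm_mat_anomaly", "lgm_ap_anomaly"]
    + [f"prop_{c}" for c in LANDUSE_CLASSES]
    + ["elev_sd", "elev_range"]
)

#: the eight predictors the regressions use by default
DEFAULT_PREDICTORS = [
    "MAT", "AP", "lgm_mat_anomaly", "lgm_ap_anomaly",
    "prop_cropland", "prop_forest", "prop_ugs", "elev_sd",
]


def assign_regions(grid: Grid, n_row_blocks: int = 2, n_col_blocks: int = 3) -> np.ndarray:
    """Contiguous block labels ("M1".."M6") standing in for mountain ranges."""
    rows, cols = np.divmod(np.arange(grid.n_cells), grid.n_cols)
    rb = np.minimum(rows * n_row_blocks // grid.n_rows, n_row_blocks - 1)
    cb = np.minimum(cols * n_col_blocks // grid.n_cols, n_col_blocks - 1)
    return np.array([f"M{r * n_col_blocks + c + 1}" for r, c in zip(rb, cb)])


@dataclass
class SyntheticStudy:
    """A complete generated study system."""

    config: LandscapeConfig
    grid: Grid
    elevation: np.ndarray
    habitat: np.ndarray
    ranges: list[SpeciesRange]
    traits: TraitTable
    tree: dendropy.Tree
    predictors: pd.DataFrame
    suitability: np.ndarray
    regions: np.ndarray

    def __post_init__(self) -> None:
        tips = {l.taxon.label for l in self.tree.leaf_node_iter()}
        sp = {r.species_id for r in self.ranges}
        if not sp <= tips:
            raise ValueError("range species missing from tree tips")
        if not sp <= set(self.traits.species):
            raise ValueError("range species missing from trait table")


def generate_study(config: LandscapeConfig) -> SyntheticStudy:
    """Generate the full synthetic study system from one config/seed."""
    elevation = generate_surface(config, "elevation")
    habitat = habitat_from_elevation(elevation)
    predictors = generate_predictors(config, elevation)
    return SyntheticStudy(
        config=config,
        grid=config.grid,
        elevation=elevation,
        habitat=habitat,
        ranges=generate_ranges(config, elevation),
        traits=generate_traits(config),
        tree=generate_phylogeny(config),
        predictors=predictors,
        suitability=generate_suitability(
            config,
            predictors["prop_forest"].to_numpy(),
            predictors["prop_cropland"].to_numpy(),
        ),
        regions=assign_regions(config.grid),
    )


def _write_raster_csv(values: np.ndarray, grid: Grid, path, fmt: str = "%.10g") -> None:
    np.savetxt(path, values.reshape(grid.n_rows, grid.n_cols),
               delimiter=",", fmt=fmt)


def write_study(study: SyntheticStudy, out_dir) -> None:
    """Serialize every component as plain-text files (row 0 = northernmost)."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    study.config.to_yaml(out / "config.yaml")
    with open(out / "grid.json", "w") as fh:
        json.dump(study.grid.to_dict(), fh, indent=1)
    _write_raster_csv(study.elevation, study.grid, out / "elevation.csv")
    _write_raster_csv(study.habitat.astype(float), study.grid,
                      out / "habitat.csv", fmt="%d")
    ranges_to_geojson(study.ranges, out / "ranges.geojson")
    study.traits.to_csv(out / "traits.csv")
    write_newick(study.tree, out / "tree.nwk")
    study.predictors.to_csv(out / "predictors.csv", index=False,
                            float_format="%.10g")
    np.savetxt(out / "suitability.csv", study.suitability.astype(int),
               delimiter=",", fmt="%d")
    pd.DataFrame(
        {"cell_id": np.arange(study.grid.n_cells), "region": study.regions}
    ).to_csv(out / "regions.csv", index=False)
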