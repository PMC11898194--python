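"""Community assembly: from range polygons to a binary presence matrix.

A species is scored present in a grid cell when its extent-of-occurrence
polygon overlaps the cell square with strictly positive area (a boundary
touch does not count).  The raw matrix is then refined with per-species
elevation limits and tolerated habitat types: a cell whose elevation falls
outside the species' interval, or whose habitat code the species does not
tolerate, is set to absence.  Finally species with incomplete trait data are
dropped — the remaining pool is the one used for richness, functional and
phylogenetic diversity alike.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import shapely
from shapely.geometry import Polygon, mapping, shape

from .grid import Grid
from .traits import TraitTable


@dataclass
class SpeciesRange:
    """Extent-of-occurrence range with IUCN-style refinement attributes."""

    species_id: str
    polygon: Polygon
    elev_lo: float
    elev_hi: float
    habitat_codes: frozenset[int]

    def __post_init__(self) -> None:
        if not isinstance(self.polygon, Polygon):
            self.polygon = Polygon(self.polygon)
        if len(self.polygon.exterior.coords) < 4:  # closed ring: 3 distinct + repeat
            raise ValueError(f"{self.species_id}: polygon needs >= 3 distinct vertices")
        if not self.elev_lo < self.elev_hi:
            raise ValueError(f"{self.species_id}: elev_lo must be < elev_hi")
        self.habitat_codes = frozenset(int(h) for h in self.habitat_codes)
        if not self.habitat_codes:
            raise ValueError(f"{self.species_id}: habitat_codes must be non-empty")


class PresenceMatrix:
    """Binary species x cell occurrence matrix with fixed orderings.

    Rows are species (ids recorded in ``species``), columns are grid cells
    (ids in ``cells``).  Row sums are species occupancies; column sums are
    per-cell richness and are the single source of truth for richness
    downstream.
    """

    def __init__(self, species: list[str], cells: np.ndarray, data: np.ndarray):
        data = np.asarray(data)
        if not np.isin(data, (0, 1)).all():
            raise ValueError("presence matrix entries must be 0 or 1")
        if data.shape != (len(species), len(cells)):
            raise ValueError("presence matrix shape does not match labels")
        if len(set(species)) != len(species):
            raise ValueError("duplicate species ids")
        self.species = list(species)
        self.cells = np.asarray(cells, dtype=int)
        self.data = data.astype(np.int8)

    @property
    def shape(self) -> tuple[int, int]:
        return self.data.shape

    @property
    def occupancy(self) -> np.ndarray:
        """Per-species number of occupied cells (row sums)."""
        return self.data.sum(axis=1)

    @property
    def richness(self) -> np.ndarray:
        """Per-cell species richness (column sums)."""
        return self.data.sum(axis=0).astype(int)

    def species_in_cell(self, cell_id: int) -> list[str]:
        j = int(np.flatnonzero(self.cells == cell_id)[0])
        return [self.species[i] for i in np.flatnonzero(self.data[:, j])]

    def subset_species(self, keep: list[str]) -> "PresenceMatrix":
        idx = {s: i for i, s in enumerate(self.species)}
        missing = [s for s in keep if s not in idx]
        if missing:
            raise KeyError(f"species not in matrix: {missing}")
        rows = [idx[s] for s in keep]
        return PresenceMatrix(list(keep), self.cells.copy(), self.data[rows].copy())

    def copy(self) -> "PresenceMatrix":
        return PresenceMatrix(list(self.species), self.cells.copy(), self.data.copy())

    def to_dataframe(self) -> pd.DataFrame:
        return pd.DataFrame(self.data, index=self.species, columns=self.cells)

    def to_csv(self, path) -> None:
        self.to_dataframe().to_csv(path, index_label="species_id")

    @classmethod
    def from_csv(cls, path) -> "PresenceMatrix":
        df = pd.read_csv(path, index_col="species_id")
        return cls(list(df.index), df.columns.astype(int).to_numpy(), df.to_numpy())

    def to_triplets(self, path) -> None:
        """Sparse triplet TSV: species_id, cell_id, 1 per occurrence."""
        rows, cols = np.nonzero(self.data)
        with open(path, "w") as fh:
            fh.write("species_id\tcell_id\tpresence\n")
            for r, c in zip(rows, cols):
                fh.write(f"{self.species[r]}\t{self.cells[c]}\t1\n")

    def __eq__(self, other) -> bool:
        return (
            isinstance(other, PresenceMatrix)
            and self.species == other.species
            and np.array_equal(self.cells, other.cells)
            and np.array_equal(self.data, other.data)
        )


def rasterize_range(rng: SpeciesRange, grid: Grid) -> set[int]:
    """Cells whose square overlaps the range polygon with positive area.

    A polygon that only touches a cell boundary (zero-area intersection)
    does not confer presence.
    """
    poly = rng.polygon
    if poly.area <= 0:
        raise ValueError(f"{rng.species_id}: degenerate polygon with zero area")
    if not poly.is_valid:
        raise ValueError(f"{rng.species_id}: invalid (self-intersecting?) polygon")
    # bounding-box prefilter, then exact area test
    px0, py0, px1, py1 = poly.bounds
    out: set[int] = set()
    cand = []
    for cid in range(grid.n_cells):
        x0, y0, x1, y1 = grid.cell_bounds(cid)
        if x1 <= px0 or x0 >= px1 or y1 <= py0 or y0 >= py1:
            continue
        cand.append(cid)
    if not cand:
        return out
    boxes = shapely.box(
        *np.array([grid.cell_bounds(c) for c in cand]).T
    )
    areas = shapely.area(shapely.intersection(poly, boxes))
    for cid, a in zip(cand, areas):
        if a > 0:
            out.add(cid)
    return out


def build_presence(ranges: list[SpeciesRange], grid: Grid) -> PresenceMatrix:
    """Rasterize every range onto the grid into a raw presence matrix."""
    species = [r.species_id for r in ranges]
    data = np.zeros((len(ranges), grid.n_cells), dtype=np.int8)
    for i, r in enumerate(ranges):
        for cid in rasterize_range(r, grid):
            data[i, cid] = 1
    return PresenceMatrix(species, np.arange(grid.n_cells), data)


def refine_occurrences(
    presence: PresenceMatrix,
    ranges: dict[str, SpeciesRange] | list[SpeciesRange],
    elevation: np.ndarray,
    habitat: np.ndarray,
) -> tuple[PresenceMatrix, dict[str, int]]:
    """Zero out occurrences outside a species' elevation limits or habitats.

    Never converts absence to presence; elevation comparison is inclusive on
    both ends.  Returns the refined matrix and a per-species count of
    removed cells.
    """
    if not isinstance(ranges, dict):
        ranges = {r.species_id: r for r in ranges}
    missing = [s for s in presence.species if s not in ranges]
    if missing:
        raise KeyError(f"species missing elevation/habitat constraints: {missing}")
    elevation = np.asarray(elevation, dtype=float)
    habitat = np.asarray(habitat)
    if elevation.shape[0] != presence.shape[1] or habitat.shape[0] != presence.shape[1]:
        raise ValueError("elevation/habitat rasters do not match the grid")

    out = presence.data.copy()
    removed: dict[str, int] = {}
    for i, sid in enumerate(presence.species):
        r = ranges[sid]
        ok = (
            (elevation >= r.elev_lo)
            & (elevation <= r.elev_hi)
            & np.isin(habitat, list(r.habitat_codes))
        )
        before = int(out[i].sum())
        out[i] &= ok.astype(np.int8)
        removed[sid] = before - int(out[i].sum())
    return PresenceMatrix(list(presence.species), presence.cells.copy(), out), removed


def filter_trait_complete(
    presence: PresenceMatrix, traits: TraitTable
) -> tuple[PresenceMatrix, list[str]]:
    """Drop species with any missing trait value.

    Returns the filtered matrix and the list of excluded species.  Raises if
    the trait table does not cover the matrix, or if no species would
    remain.
    """
    uncovered = [s for s in presence.species if s not in traits.df.index]
    if uncovered:
        raise KeyError(f"species missing from trait table: {uncovered}")
    flags = traits.complete
    keep = [s for s in presence.species if flags[s]]
    dropped = [s for s in presence.species if not flags[s]]
    if not keep:
        raise ValueError("no species remain after excluding incomplete trait data")
    return presence.subset_species(keep), dropped


# ---------------------------------------------------------------------------
# GeoJSON I/O


def ranges_to_geojson(ranges: list[SpeciesRange], path) -> None:
    features = []
    for r in ranges:
        features.append(
            {
                "type": "Feature",
                "geometry": mapping(r.polygon),
                "properties": {
                    "species_id": r.species_id,
                    "elev_lo": r.elev_lo,
                    "elev_hi": r.elev_hi,
                    "habitat_codes": sorted(r.habitat_codes),
                },
            }
        )
    with open(path, "w") as fh:
        json.dump({"type": "FeatureCollection", "features": features}, fh, indent=1)


def ranges_from_geojson(path) -> list[SpeciesRange]:
    with open(path) as fh:
        fc = json.load(fh)
    out = []
    for feat in fc["features"]:
        props = feat["properties"]
        out.append(
            SpeciesRange(
                species_id=props["species_id"],
                polygon=shape(feat["geometry"]),
                elev_lo=float(props["elev_lo"]),
                elev_hi=float(props["elev_hi"]),
                habitat_codes=frozenset(props["habitat_codes"]),
            )
        )
    return out
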