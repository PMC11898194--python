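"""Per-cell diversity metrics: richness, functional richness, Faith's PD.

Functional richness (FRic) is the volume of the convex hull of an
assemblage's species in a standardized trait space.  Size traits are
log10-transformed, every trait is z-scored across the full retained species
pool (never per cell, so cells are comparable), and when an assemblage has
no more species than trait dimensions the points are projected onto the
pool's leading principal components, d = min(S_cell - 1, max_dim), so the
hull volume is well defined.  Faith's PD is the total branch length of the
minimal subtree connecting an assemblage's tips to the root (root-inclusive
convention).

Both metrics are undefined for cells below their minimum richness (2 for
PD, 3 for FRic) and are reported as NaN there.
"""

from __future__ import annotations

from dataclasses import dataclass

import dendropy
import numpy as np
import pandas as pd
from scipy.spatial import ConvexHull, QhullError

from .assembly import PresenceMatrix
from .traits import LOG_TRAITS, TraitTable

# ---------------------------------------------------------------------------
# Faith's phylogenetic diversity


def branch_incidence(
    tree: dendropy.Tree, species: list[str]
) -> tuple[np.ndarray, np.ndarray]:
    """Tip x branch incidence of root-ward paths.

    Returns ``(lengths, A)`` where ``lengths[j]`` is the length of branch j
    and ``A[i, j]`` is True when branch j lies on the path from tip
    ``species[i]`` to the root.  Branches with no length (the root edge)
    contribute zero length.
    """
    tips = {leaf.taxon.label: leaf for leaf in tree.leaf_node_iter()}
    missing = [s for s in species if s not in tips]
    if missing:
        raise KeyError(f"tip labels not in tree: {missing}")
    edges = [e for e in tree.preorder_edge_iter() if e.head_node is not tree.seed_node]
    lengths = np.array([e.length if e.length is not None else 0.0 for e in edges])
    edge_index = {id(e): j for j, e in enumerate(edges)}
    A = np.zeros((len(species), len(edges)), dtype=bool)
    for i, s in enumerate(species):
        node = tips[s]
        while node is not tree.seed_node:
            A[i, edge_index[id(node.edge)]] = True
            node = node.parent_node
    return lengths, A


def faith_pd(tree: dendropy.Tree, species) -> float:
    """Faith's phylogenetic diversity of a species set (root-inclusive).

    Sum of branch lengths of the union of root-to-tip paths over the set.
    Undefined (NaN) for fewer than two species; unknown tip labels raise.
    """
    species = sorted(set(species))
    if len(species) < 2:
        lengths, A = branch_incidence(tree, species)  # still validate labels
        return float("nan")
    lengths, A = branch_incidence(tree, species)
    return float(lengths[A.any(axis=0)].sum())


def faith_pd_cells(
    tree: dendropy.Tree, presence: PresenceMatrix
) -> np.ndarray:
    """Vectorized per-cell Faith's PD for every column of a presence matrix.

    Cells with fewer than two species get NaN.
    """
    lengths, A = branch_incidence(tree, presence.species)
    covered = A.T.astype(np.int32) @ presence.data.astype(np.int32) > 0
    pd_vals = lengths @ covered
    pd_vals = pd_vals.astype(float)
    pd_vals[presence.richness < 2] = np.nan
    return pd_vals


def total_tree_length(tree: dendropy.Tree) -> float:
    return sum(
        e.length or 0.0
        for e in tree.preorder_edge_iter()
        if e.head_node is not tree.seed_node
    )


# ---------------------------------------------------------------------------
# Functional richness


def hull_volume(points: np.ndarray) -> tuple[float, bool]:
    """Convex-hull volume of a point cloud.

    Returns ``(volume, degenerate)``; degenerate (coplanar or too few
    distinct points for the dimensionality) point sets get volume 0.0 with
    the flag set rather than an error, because randomized assemblages can
    legitimately be degenerate.
    """
    points = np.asarray(points, dtype=float)
    if points.ndim != 2:
        raise ValueError("points must be a 2-D array")
    n, d = points.shape
    if d == 1:
        lo, hi = points.min(), points.max()
        return (float(hi - lo), bool(hi == lo))
    if n < d + 1:
        return 0.0, True
    try:
        return float(ConvexHull(points).volume), False
    except QhullError:
        return 0.0, True


@dataclass
class TraitSpace:
    """Pooled trait-space transform shared by every cell (and every null).

    Fitting records the log-transform, the pool means/SDs for z-scoring and
    the pool PCA rotation.  Cell-level functional richness then projects the
    cell's species into this fixed space; the basis is never re-fit per cell
    or per null community, so the null model varies composition only.
    """

    traits: TraitTable
    log_transform: bool = True
    standardize: bool = True
    max_dim: int = 9

    def __post_init__(self) -> None:
        df = self.traits.df.loc[self.traits.complete]
        if df.isna().any().any():
            raise ValueError("trait space must be fit on complete species only")
        X = df.to_numpy(dtype=float).copy()
        if self.log_transform:
            for j, name in enumerate(df.columns):
                if name in LOG_TRAITS:
                    if (X[:, j] <= 0).any():
                        raise ValueError(f"non-positive values in log trait {name}")
                    X[:, j] = np.log10(X[:, j])
        self._mean = X.mean(axis=0)
        sd = (
            X.std(axis=0, ddof=1) if X.shape[0] > 1 else np.ones(X.shape[1])
        )
        if self.standardize and X.shape[0] > 1:
            if (sd == 0).any():
                bad = [df.columns[j] for j in np.flatnonzero(sd == 0)]
                raise ValueError(f"constant trait column(s): {bad}")
            Z = (X - self._mean) / sd
        else:
            Z = X - self._mean
        self._sd = sd
        # pool PCA rotation; volumes are rotation-invariant, truncation uses
        # the leading axes
        _, _, Vt = np.linalg.svd(Z - Z.mean(axis=0), full_matrices=False)
        self._rotation = Vt.T
        self._scores = pd.DataFrame(
            (Z - Z.mean(axis=0)) @ self._rotation, index=df.index
        )

    @property
    def species(self) -> list[str]:
        return list(self._scores.index)

    def cell_scores(self, species: list[str], d: int) -> np.ndarray:
        return self._scores.loc[list(species)].to_numpy()[:, :d]

    def cell_dim(self, n_species: int) -> int:
        return min(n_species - 1, self.max_dim, self._scores.shape[1])

    def volume(self, species) -> tuple[float, bool]:
        """Functional richness of a species set in this space.

        NaN for fewer than 3 species (undefined); otherwise the convex-hull
        volume in the leading d = min(S-1, max_dim) pool axes.
        """
        species = list(species)
        missing = [s for s in species if s not in self._scores.index]
        if missing:
            raise KeyError(f"species without (complete) traits: {missing}")
        if len(species) < 3:
            return float("nan"), False
        d = self.cell_dim(len(species))
        return hull_volume(self.cell_scores(species, d))


def functional_richness(
    traits: TraitTable,
    species,
    *,
    log_transform: bool = True,
    standardize: bool = True,
    max_dim: int = 9,
    space: TraitSpace | None = None,
) -> float:
    """Convex-hull functional richness of a species set.

    Degenerate hulls give 0.0; fewer than 3 species give NaN.  Pass a
    pre-fit ``space`` to reuse a pooled standardization/PCA basis.
    """
    if space is None:
        space = TraitSpace(
            traits, log_transform=log_transform, standardize=standardize, max_dim=max_dim
        )
    vol, _ = space.volume(species)
    return vol


# ---------------------------------------------------------------------------
# Per-cell profile


def species_richness(presence: PresenceMatrix) -> np.ndarray:
    """Per-cell species richness (column sums of the presence matrix)."""
    return presence.richness


def fric_cells(space: TraitSpace, presence: PresenceMatrix) -> tuple[np.ndarray, np.ndarray]:
    """Per-cell functional richness and degeneracy flags for a matrix."""
    vols = np.full(presence.shape[1], np.nan)
    degen = np.zeros(presence.shape[1], dtype=bool)
    scores_all = space._scores.loc[presence.species].to_numpy()
    for j in range(presence.shape[1]):
        idx = np.flatnonzero(presence.data[:, j])
        if idx.size < 3:
            continue
        d = space.cell_dim(idx.size)
        vols[j], degen[j] = hull_volume(scores_all[idx, :d])
    return vols, degen


def diversity_profile(
    presence: PresenceMatrix,
    traits: TraitTable,
    tree: dendropy.Tree,
    *,
    log_transform: bool = True,
    standardize: bool = True,
    max_dim: int = 9,
) -> pd.DataFrame:
    """Per-cell table of richness, functional richness and Faith's PD.

    Expects a trait-complete presence matrix.  Columns: cell_id, richness,
    FD, PD, fd_degenerate.  FD/PD are NaN where undefined.
    """
    space = TraitSpace(
        traits.subset(presence.species),
        log_transform=log_transform,
        standardize=standardize,
        max_dim=max_dim,
    )
    fd, degen = fric_cells(space, presence)
    pd_vals = faith_pd_cells(tree, presence)
    return pd.DataFrame(
        {
            "cell_id": presence.cells,
            "richness": presence.richness,
            "FD": fd,
            "PD": pd_vals,
            "fd_degenerate": degen,
        }
    )


def profile_summary(profile: pd.DataFrame, groups: pd.Series | None = None) -> pd.DataFrame:
    """Mean +/- SD of each facet over cells where it is defined.

    With ``groups`` (per-cell labels aligned to profile rows) also returns
    one row per group, mirroring per-mountain summaries.
    """
    def _one(sub: pd.DataFrame, label: str) -> dict:
        row: dict = {"group": label, "n_cells": len(sub)}
        for m in ("richness", "FD", "PD"):
            vals = sub[m].dropna()
            row[f"{m}_mean"] = vals.mean()
            row[f"{m}_sd"] = vals.std(ddof=1)
            row[f"{m}_n"] = len(vals)
        return row

    rows = [_one(profile, "all")]
    if groups is not None:
        groups = pd.Series(np.asarray(groups), index=profile.index)
        for g in sorted(groups.unique()):
            rows.append(_one(profile[groups == g], str(g)))
    return pd.DataFrame(rows)
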