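"""Species trait table.

The canonical table carries nine numeric traits common to all mammals
(hindfoot length, tail length, body length, body mass, litters per year,
litter size, age at maturity, generation length, gestation length).  A table
may also carry an arbitrary set of numeric trait columns, which is useful
for toy examples and for testing the convex-hull machinery on raw point
sets.  A species is *complete* when none of its trait values is missing;
only complete species enter diversity calculations.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

#: Canonical mammal trait columns, in fixed order.
TRAIT_NAMES = [
    "hindfoot_length_mm",
    "tail_length_mm",
    "body_length_mm",
    "body_mass_g",
    "litters_per_year",
    "litter_size",
    "maturity_d",
    "generation_length_d",
    "gestation_length_d",
]

#: Size traits that are log10-transformed before standardization by default.
LOG_TRAITS = [
    "hindfoot_length_mm",
    "tail_length_mm",
    "body_length_mm",
    "body_mass_g",
]


class TraitTable:
    """Species x trait matrix with per-species completeness flags.

    Parameters
    ----------
    df : DataFrame
        Indexed by species id; numeric trait columns.  NaN marks a missing
        value.
    """

    def __init__(self, df: pd.DataFrame):
        if df.index.has_duplicates:
            dups = df.index[df.index.duplicated()].unique().tolist()
            raise ValueError(f"duplicate species ids in trait table: {dups}")
        self.df = df.astype(float)

    @property
    def species(self) -> list[str]:
        return list(self.df.index)

    @property
    def trait_names(self) -> list[str]:
        return list(self.df.columns)

    @property
    def complete(self) -> pd.Series:
        """Boolean per-species flag: True when no trait value is missing."""
        return ~self.df.isna().any(axis=1)

    @property
    def complete_species(self) -> list[str]:
        return list(self.df.index[self.complete])

    @property
    def incomplete_species(self) -> list[str]:
        return list(self.df.index[~self.complete])

    def subset(self, species: list[str]) -> "TraitTable":
        missing = [s for s in species if s not in self.df.index]
        if missing:
            raise KeyError(f"species not in trait table: {missing}")
        return TraitTable(self.df.loc[species])

    def values(self, species: list[str] | None = None) -> np.ndarray:
        if species is None:
            return self.df.to_numpy()
        return self.subset(species).df.to_numpy()

    def to_csv(self, path) -> None:
        self.df.to_csv(path, index_label="species_id", float_format="%.10g")

    @classmethod
    def from_csv(cls, path) -> "TraitTable":
        return cls(pd.read_csv(path, index_col="species_id"))

    def __len__(self) -> int:
        return len(self.df)

    def __repr__(self) -> str:
        n_inc = int((~self.complete).sum())
        return (
            f"TraitTable({len(self)} species x {len(self.trait_names)} traits, "
            f"{n_inc} incomplete)"
        )
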