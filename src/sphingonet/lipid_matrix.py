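"""Subjects x species abundance container with raw / log / z-score views.

Abundances are nonnegative with missing values (below the detection limit)
stored as NaN. The log view is the natural log of the raw abundances; the
z-score view standardizes each species' log values to mean 0, SD 1 over its
non-missing entries. Missing stays missing through every view.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd


@dataclass
class LipidMatrix:
    abundances: pd.DataFrame  # subjects x species, raw scale, NaN = missing
    class_map: pd.Series  # species -> class

    def __post_init__(self) -> None:
        missing_map = [s for s in self.abundances.columns if s not in self.class_map.index]
        if missing_map:
            raise ValueError(f"species without class assignment: {missing_map}")
        self.class_map = self.class_map.loc[self.abundances.columns]
        vals = self.abundances.to_numpy(dtype=float)
        if np.nanmin(vals, initial=np.inf) < 0:
            raise ValueError("abundances must be nonnegative")

    @property
    def species(self) -> list[str]:
        return list(self.abundances.columns)

    @property
    def subjects(self) -> pd.Index:
        return self.abundances.index

    @property
    def n_subjects(self) -> int:
        return len(self.abundances)

    @property
    def raw(self) -> pd.DataFrame:
        return self.abundances

    @property
    def log(self) -> pd.DataFrame:
        vals = self.abundances.to_numpy(dtype=float)
        if np.nanmin(vals, initial=np.inf) <= 0:
            bad = self.abundances.columns[(self.abundances <= 0).any(axis=0)].tolist()
            raise ValueError(f"log view requires strictly positive abundances; offending species: {bad}")
        return np.log(self.abundances)

    @property
    def zscore(self) -> pd.DataFrame:
        logged = self.log
        mean = logged.mean(axis=0, skipna=True)
        sd = logged.std(axis=0, ddof=1, skipna=True)  # sample SD
        constant = sd.index[(sd == 0) | sd.isna()].tolist()
        if constant:
            raise ValueError(f"zero variance (constant) species: {constant}")
        return (logged - mean) / sd

    def missing_fraction(self) -> pd.Series:
        return self.abundances.isna().mean(axis=0)

    def select_species(self, species: list[str]) -> "LipidMatrix":
        return LipidMatrix(self.abundances[species].copy(), self.class_map.loc[species])

    def select_subjects(self, subjects) -> "LipidMatrix":
        return LipidMatrix(self.abundances.loc[subjects].copy(), self.class_map)

    def class_totals(self, classes: list[str] | None = None) -> pd.DataFrame:
        """Per-subject raw totals per class, summing non-missing species only."""
        classes = classes or list(dict.fromkeys(self.class_map))
        out = {}
        for cls in classes:
            cols = self.class_map.index[self.class_map == cls]
            if len(cols) == 0:
                raise ValueError(f"no species in class {cls!r}")
            out[cls] = self.abundances[cols].sum(axis=1, skipna=True, min_count=1)
        return pd.DataFrame(out, index=self.subjects)

    # -- I/O (plain TSV; missing cells empty) --------------------------------

    def to_tsv(self, abundance_path, class_map_path=None) -> None:
        self.abundances.to_csv(abundance_path, sep="\t", index_label="subject_id")
        if class_map_path is not None:
            self.class_map.rename("class_id").to_csv(
                class_map_path, sep="\t", index_label="species_id"
            )

    @classmethod
    def from_tsv(cls, abundance_path, class_map_path) -> "LipidMatrix":
        abund = pd.read_csv(abundance_path, sep="\t", index_col="subject_id")
        cmap = pd.read_csv(class_map_path, sep="\t", index_col="species_id")["class_id"]
        return cls(abund, cmap)
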