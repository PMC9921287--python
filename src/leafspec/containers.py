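"""In-memory containers shared across the pipeline.

A :class:`SpectrumSet` holds an ``n x bands`` matrix of relative reflectance
together with the wavelength grid, sample identifiers and the leaf surface
each row was imaged from.  A :class:`NutrientTable` holds per-sample
concentrations for one or more mineral nutrients, with the measurement unit
recorded per nutrient (percent of dry mass for macronutrients, mg/kg for
trace elements).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = ["SpectrumSet", "NutrientTable", "SURFACES"]

SURFACES = ("adaxial", "abaxial")


@dataclass
class SpectrumSet:
    """Matrix of relative reflectance spectra on a common wavelength grid."""

    wavelengths: np.ndarray          # (bands,) nm, strictly increasing
    reflectance: np.ndarray          # (n, bands) relative reflectance
    sample_ids: list[str]
    surfaces: list[str]              # per-sample surface label

    def __post_init__(self) -> None:
        self.wavelengths = np.asarray(self.wavelengths, dtype=float)
        self.reflectance = np.atleast_2d(np.asarray(self.reflectance, dtype=float))
        self.sample_ids = [str(s) for s in self.sample_ids]
        self.surfaces = [str(s) for s in self.surfaces]
        n, bands = self.reflectance.shape
        if bands != self.wavelengths.size:
            raise ValueError(
                f"band count mismatch: {bands} columns against a "
                f"{self.wavelengths.size}-band grid"
            )
        if len(self.sample_ids) != n or len(self.surfaces) != n:
            raise ValueError("sample_ids/surfaces length must match row count")
        if len(set(self.sample_ids)) != n:
            dupes = sorted({s for s in self.sample_ids if self.sample_ids.count(s) > 1})
            raise ValueError(f"duplicate sample IDs: {', '.join(dupes)}")
        if not np.all(np.isfinite(self.reflectance)):
            raise ValueError("reflectance contains missing or non-finite values")
        for s in self.surfaces:
            if s not in SURFACES:
                raise ValueError(f"unknown surface label: {s!r}")

    @property
    def n_samples(self) -> int:
        return self.reflectance.shape[0]

    @property
    def n_bands(self) -> int:
        return self.reflectance.shape[1]

    def subset(self, ids: list[str]) -> "SpectrumSet":
        """Row subset by sample id, preserving the given order."""
        index = {s: i for i, s in enumerate(self.sample_ids)}
        rows = [index[s] for s in ids]
        return SpectrumSet(
            wavelengths=self.wavelengths,
            reflectance=self.reflectance[rows],
            sample_ids=[self.sample_ids[i] for i in rows],
            surfaces=[self.surfaces[i] for i in rows],
        )


@dataclass
class NutrientTable:
    """Per-sample nutrient concentrations with units per nutrient."""

    data: pd.DataFrame               # index = sample_id, columns = nutrients
    units: dict[str, str] = field(default_factory=dict)  # nutrient -> unit

    def __post_init__(self) -> None:
        if self.data.index.has_duplicates:
            dupes = self.data.index[self.data.index.duplicated()].unique().tolist()
            raise ValueError(f"duplicate sample IDs: {', '.join(map(str, dupes))}")
        self.data = self.data.astype(float)

    @property
    def nutrients(self) -> list[str]:
        return list(self.data.columns)

    @property
    def sample_ids(self) -> list[str]:
        return [str(s) for s in self.data.index]

    def values_for(self, nutrient: str, ids: list[str] | None = None) -> np.ndarray:
        col = self.data[nutrient]
        if ids is not None:
            col = col.loc[ids]
        return col.to_numpy(dtype=float)

    def subset(self, ids: list[str]) -> "NutrientTable":
        return NutrientTable(data=self.data.loc[ids].copy(), units=dict(self.units))
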