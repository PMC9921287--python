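"""Reflectance calibration, ROI extraction and delimited/ENVI-style IO.

Raw digital numbers from a line-scanner camera are converted to relative
reflectance against dark-current and white-reference frames,

    R = (R0 - D) / (W - D)   per band,

then averaged over a region-of-interest mask to give one spectrum per
sample.  Spectral matrices travel as comma-separated text with a
``sample_id,surface,<wavelength...>`` header; cube fixtures use a minimal
ENVI-style band-sequential layout (text header + float32 binary).
"""

from __future__ import annotations

import csv
import warnings
from dataclasses import dataclass
from pathlib import Path

import numpy as np

from .containers import NutrientTable, SpectrumSet

__all__ = [
    "ReferencePair",
    "SpectralCube",
    "correct_reflectance",
    "extract_roi_mean",
    "read_spectrum_table",
    "write_spectrum_table",
    "read_nutrient_table",
    "write_nutrient_table",
    "read_envi_cube",
    "write_envi_cube",
]

# corrected reflectance outside this range suggests a calibration problem
_PLAUSIBLE = (-0.05, 1.5)


@dataclass
class ReferencePair:
    """Dark and white reference frames, per band or per pixel-and-band.

    Frame-averaged per-band vectors are the default convention; full
    per-pixel arrays of the same shape as the cube are also accepted for
    per-pixel calibration.
    """

    dark: np.ndarray
    white: np.ndarray

    def __post_init__(self) -> None:
        self.dark = np.asarray(self.dark, dtype=float)
        self.white = np.asarray(self.white, dtype=float)
        if self.dark.shape != self.white.shape:
            raise ValueError("dark and white frames must have the same shape")
        if np.any(self.white == self.dark):
            raise ValueError("degenerate white reference: W = D on some band")


@dataclass
class SpectralCube:
    """Raw intensity cube, lines x samples x bands, with its wavelength grid."""

    data: np.ndarray
    wavelengths: np.ndarray
    bit_depth: int = 12

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=float)
        self.wavelengths = np.asarray(self.wavelengths, dtype=float)
        if self.data.ndim != 3:
            raise ValueError("cube must be 3-D (lines x samples x bands)")
        if self.data.shape[2] != self.wavelengths.size:
            raise ValueError(
                f"band count mismatch: cube has {self.data.shape[2]} bands, "
                f"grid has {self.wavelengths.size}"
            )
        if np.any(self.data < 0):
            raise ValueError("raw intensities must be non-negative")


def correct_reflectance(raw: np.ndarray, refs: ReferencePair) -> np.ndarray:
    """Dark/white reflectance correction, elementwise per band.

    ``raw`` may be a single spectrum, a matrix of spectra, or a cube with
    bands on the last axis; the references broadcast against it.  Values
    outside the plausible reflectance range trigger a warning, not an error
    (negative excursions carry real signal for scatter correction and are
    never clipped).
    """
    raw = np.asarray(raw, dtype=float)
    denom = refs.white - refs.dark
    out = (raw - refs.dark) / denom
    lo, hi = _PLAUSIBLE
    if np.any(out < lo) or np.any(out > hi):
        warnings.warn(
            f"corrected reflectance outside [{lo}, {hi}]: check references",
            stacklevel=2,
        )
    return out


def extract_roi_mean(cube: SpectralCube | np.ndarray, mask: np.ndarray) -> np.ndarray:
    """Per-band arithmetic mean spectrum over the masked pixels."""
    data = cube.data if isinstance(cube, SpectralCube) else np.asarray(cube, dtype=float)
    mask = np.asarray(mask, dtype=bool)
    if mask.shape != data.shape[:2]:
        raise ValueError(
            f"mask shape {mask.shape} does not match cube spatial "
            f"dimensions {data.shape[:2]}"
        )
    if not mask.any():
        raise ValueError("empty ROI: mask selects no pixels")
    return data[mask].mean(axis=0)


# ---------------------------------------------------------------------------
# delimited spectral / nutrient tables

def write_spectrum_table(spectra: SpectrumSet, path: str | Path) -> None:
    """Write as CSV: header ``sample_id,surface,<wavelength values...>``."""
    path = Path(path)
    with path.open("w", newline="") as fh:
        writer = csv.writer(fh)
        writer.writerow(
            ["sample_id", "surface"] + [f"{w:.10g}" for w in spectra.wavelengths]
        )
        for sid, surf, row in zip(
            spectra.sample_ids, spectra.surfaces, spectra.reflectance
        ):
            writer.writerow([sid, surf] + [f"{v:.10g}" for v in row])


def read_spectrum_table(
    path: str | Path, wavelengths: np.ndarray | None = None
) -> SpectrumSet:
    """Read a spectral CSV; optionally validate against an expected grid."""
    path = Path(path)
    with path.open(newline="") as fh:
        reader = csv.reader(fh)
        try:
            header = next(reader)
        except StopIteration:
            raise ValueError(f"{path}: empty file") from None
        if len(header) < 3 or header[0] != "sample_id" or header[1] != "surface":
            raise ValueError(f"{path}: malformed header")
        try:
            grid = np.array([float(w) for w in header[2:]])
        except ValueError:
            raise ValueError(f"{path}: non-numeric wavelength in header") from None
        if wavelengths is not None and (
            grid.size != np.asarray(wavelengths).size
            or not np.allclose(grid, wavelengths)
        ):
            raise ValueError(
                f"{path}: band count mismatch: file has {grid.size} bands, "
                f"expected {np.asarray(wavelengths).size}"
            )
        ids: list[str] = []
        surfaces: list[str] = []
        rows: list[list[float]] = []
        for lineno, row in enumerate(reader, start=2):
            if not row:
                continue
            if len(row) != len(header):
                raise ValueError(
                    f"{path}: row {lineno} ({row[0] if row else '?'}) has "
                    f"{len(row)} fields, expected {len(header)}"
                )
            try:
                rows.append([float(v) for v in row[2:]])
            except ValueError:
                raise ValueError(
                    f"{path}: non-numeric cell in row {lineno} ({row[0]})"
                ) from None
            ids.append(row[0])
            surfaces.append(row[1])
    seen: set[str] = set()
    for sid in ids:
        if sid in seen:
            raise ValueError(f"{path}: duplicate sample ID {sid!r}")
        seen.add(sid)
    return SpectrumSet(
        wavelengths=grid,
        reflectance=np.array(rows, dtype=float),
        sample_ids=ids,
        surfaces=surfaces,
    )


def write_nutrient_table(table: NutrientTable, path: str | Path) -> None:
    """Write as CSV: header ``sample_id,<nutrient names...>``."""
    df = table.data.copy()
    df.index.name = "sample_id"
    df.to_csv(path, float_format="%.10g")


def read_nutrient_table(
    path: str | Path, units: dict[str, str] | None = None
) -> NutrientTable:
    import pandas as pd

    df = pd.read_csv(path, index_col="sample_id")
    if df.index.has_duplicates:
        dupes = df.index[df.index.duplicated()].unique().tolist()
        raise ValueError(f"{path}: duplicate sample ID {dupes[0]!r}")
    try:
        df = df.astype(float)
    except ValueError as exc:
        raise ValueError(f"{path}: non-numeric cell ({exc})") from None
    return NutrientTable(data=df, units=dict(units or {}))


# ---------------------------------------------------------------------------
# ENVI-style band-sequential cube fixtures

def write_envi_cube(
    cube: SpectralCube, path_prefix: str | Path
) -> tuple[Path, Path]:
    """Write ``<prefix>.hdr`` (text) and ``<prefix>.bsq`` (float32, BSQ)."""
    prefix = Path(path_prefix)
    hdr, raw = prefix.with_suffix(".hdr"), prefix.with_suffix(".bsq")
    lines, samples, bands = cube.data.shape
    wl = ", ".join(f"{w:.6f}" for w in cube.wavelengths)
    hdr.write_text(
        "ENVI\n"
        f"lines = {lines}\n"
        f"samples = {samples}\n"
        f"bands = {bands}\n"
        "interleave = bsq\n"
        "data type = float32\n"
        f"bit depth = {cube.bit_depth}\n"
        f"wavelength = {{ {wl} }}\n"
    )
    # BSQ: band-major on disk
    np.ascontiguousarray(
        np.moveaxis(cube.data, 2, 0), dtype=np.float32
    ).tofile(raw)
    return hdr, raw


def read_envi_cube(path_prefix: str | Path) -> SpectralCube:
    prefix = Path(path_prefix)
    hdr, raw = prefix.with_suffix(".hdr"), prefix.with_suffix(".bsq")
    fields: dict[str, str] = {}
    for line in hdr.read_text().splitlines():
        if "=" in line:
            key, _, value = line.partition("=")
            fields[key.strip().lower()] = value.strip()
    try:
        lines = int(fields["lines"])
        samples = int(fields["samples"])
        bands = int(fields["bands"])
    except KeyError as exc:
        raise ValueError(f"{hdr}: missing header key {exc}") from None
    wl_text = fields.get("wavelength", "").strip("{} ")
    wavelengths = np.array([float(w) for w in wl_text.split(",") if w.strip()])
    data = np.fromfile(raw, dtype=np.float32)
    if data.size != lines * samples * bands:
        raise ValueError(f"{raw}: size does not match header dimensions")
    cube = np.moveaxis(
        data.reshape(bands, lines, samples).astype(float), 0, 2
    )
    return SpectralCube(
        data=cube,
        wavelengths=wavelengths,
        bit_depth=int(fields.get("bit depth", 12)),
    )
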