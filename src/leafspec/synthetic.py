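"""Synthetic Vis-NIR leaf reflectance, nutrient tables and raw image cubes.

The generator is a phenomenological stand-in for laboratory hyperspectral
images of tree leaves (macadamia in the motivating study): it emulates the
empirical structure of leaf reflectance in 400-1000 nm rather than simulating
leaf optics from first principles.  Each spectrum is a surface-specific
baseline (green peak near 560 nm, chlorophyll absorption well near 670 nm,
red-edge rise between ~690 and 740 nm, NIR plateau) perturbed by a small
number of latent physiological components, multiplicative/additive scatter
and band noise.  Nutrient concentrations are affine functions of the same
latent component scores plus independent noise, so a scatter-corrected PLSR
is the correct estimator and downstream recovery tests are meaningful.

The two leaf surfaces differ the way real leaves do: the abaxial (lower)
surface reflects more than the adaxial (upper) surface throughout the
visible, with the largest gap near 567 nm, the ordering reversing once
between 730 and 740 nm so the adaxial surface is brighter in the NIR.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .containers import SURFACES, NutrientTable, SpectrumSet

__all__ = [
    "NutrientConfig",
    "SurfaceProfile",
    "make_wavelength_grid",
    "default_nutrient_configs",
    "surface_profile",
    "latent_components",
    "generate_spectra",
    "generate_cube",
    "to_integer_scale",
    "N_BANDS",
    "WAVELENGTH_MIN",
    "WAVELENGTH_MAX",
]

N_BANDS = 462
WAVELENGTH_MIN = 400.0
WAVELENGTH_MAX = 1000.0

#: units used for foliar nutrient concentrations
UNIT_PERCENT = "percent"
UNIT_MG_PER_KG = "mg_per_kg"

# generator defaults: per-sample multiplicative/additive scatter and band
# noise, on the [0, 1] reflectance scale
DEFAULT_SCATTER_MULT_SD = 0.05
DEFAULT_SCATTER_ADD_SD = 0.01
DEFAULT_BAND_NOISE_SD = 0.002


def make_wavelength_grid() -> np.ndarray:
    """Uniform 462-band wavelength grid spanning 400-1000 nm (~1.3 nm step)."""
    return np.linspace(WAVELENGTH_MIN, WAVELENGTH_MAX, N_BANDS)


@dataclass(frozen=True)
class NutrientConfig:
    """Statistical description of one foliar nutrient.

    ``mean``/``sd`` describe the marginal concentration distribution and
    ``minimum``/``maximum`` its physiological range (values are clipped to
    it, which slightly thins the tails).  ``weights`` couple the nutrient to
    the latent spectral components; ``noise_sd`` is the residual sd of the
    concentration given the spectrum, so the analytic ceiling on a predictive
    model's R^2 is ``1 - (noise_sd / sd)**2``.
    """

    name: str
    unit: str
    minimum: float
    maximum: float
    mean: float
    sd: float
    weights: tuple[float, ...]
    noise_sd: float

    def __post_init__(self) -> None:
        if self.unit not in (UNIT_PERCENT, UNIT_MG_PER_KG):
            raise ValueError(f"unknown unit {self.unit!r}")
        if not self.minimum < self.maximum:
            raise ValueError(f"{self.name}: min must be < max")
        if self.sd <= 0:
            raise ValueError(f"{self.name}: sd must be positive")
        if not 0 <= self.noise_sd < self.sd:
            raise ValueError(f"{self.name}: noise_sd must lie in [0, sd)")
        if not any(w != 0 for w in self.weights):
            raise ValueError(f"{self.name}: at least one linkage weight must be nonzero")

    @property
    def signal_sd(self) -> float:
        """SD of the spectrum-explained part; signal^2 + noise^2 = sd^2."""
        return float(np.sqrt(self.sd**2 - self.noise_sd**2))

    @property
    def analytic_r2(self) -> float:
        """Best attainable prediction R^2 given the injected noise."""
        return 1.0 - (self.noise_sd / self.sd) ** 2


def _rho(r2: float) -> float:
    # noise fraction that yields an analytic R^2 ceiling of r2
    return float(np.sqrt(1.0 - r2))


def default_nutrient_configs() -> list[NutrientConfig]:
    """The 13 foliar nutrients with macadamia-leaf ranges and dispersions.

    Ranges, means and SDs follow published descriptive statistics for
    macadamia cv. '816' leaves (e.g. N spans 1.03-2.89% of dry mass).  The
    noise fractions are set so the analytic R^2 ceilings echo the relative
    predictability observed for leaf spectra: structural/chlorophyll-bound
    nutrients (N, P, K, Ca, Cu, Zn) are well coupled to the spectrum while
    Al, B, Fe and Na are mostly spectrally silent.
    """

    def cfg(name, unit, lo, hi, mean, sd, weights, r2):
        return NutrientConfig(name, unit, lo, hi, mean, sd, weights, _rho(r2) * sd)

    pct, mg = UNIT_PERCENT, UNIT_MG_PER_KG
    return [
        cfg("N", pct, 1.03, 2.89, 1.68, 0.41, (1.0, 0.3, 0.6, 0.1), 0.55),
        cfg("P", pct, 0.04, 0.21, 0.10, 0.04, (0.2, 1.0, 0.3, 0.2), 0.77),
        cfg("K", pct, 0.29, 1.11, 0.53, 0.16, (0.1, 0.4, 0.2, 1.0), 0.77),
        cfg("Ca", pct, 0.15, 0.69, 0.38, 0.14, (0.5, 0.1, 1.0, 0.3), 0.75),
        cfg("Al", mg, 26.4, 196.6, 69.2, 39.7, (0.3, 0.2, 0.1, 0.5), 0.33),
        cfg("B", mg, 13.0, 357.8, 86.2, 66.4, (0.2, 0.5, 0.3, 0.1), 0.22),
        cfg("Cu", mg, 3.08, 67.14, 17.89, 15.49, (0.7, 0.2, 0.8, 0.2), 0.80),
        cfg("Fe", mg, 40.1, 125.1, 67.1, 19.0, (0.4, 0.4, 0.4, 0.4), 0.05),
        cfg("Mg", mg, 736.0, 2056.0, 1162.0, 246.0, (0.8, 0.6, 0.2, 0.1), 0.64),
        cfg("Mn", mg, 19.2, 286.4, 86.3, 48.1, (0.3, 0.7, 0.5, 0.2), 0.56),
        cfg("Na", mg, 53.1, 402.7, 120.3, 48.8, (0.1, 0.2, 0.4, 0.6), 0.29),
        cfg("S", mg, 1015.0, 3607.0, 1908.0, 426.0, (0.6, 0.3, 0.3, 0.7), 0.49),
        cfg("Zn", mg, 6.51, 30.91, 15.09, 5.27, (0.9, 0.1, 0.5, 0.6), 0.85),
    ]


def _gauss(wl: np.ndarray, center: float, width: float) -> np.ndarray:
    return np.exp(-(((wl - center) / width) ** 2))


def _sigmoid(wl: np.ndarray, center: float, scale: float) -> np.ndarray:
    return 1.0 / (1.0 + np.exp(-(wl - center) / scale))


def _adaxial_baseline(wl: np.ndarray) -> np.ndarray:
    """Leaf-like reflectance: green peak, pigment wells, red edge, NIR plateau."""
    base = (
        0.08
        + 0.10 * _gauss(wl, 560.0, 28.0)          # green reflectance peak
        + 0.01 * _gauss(wl, 600.0, 10.0)          # two small secondary peaks
        + 0.01 * _gauss(wl, 640.0, 10.0)
        - 0.030 * _gauss(wl, 670.0, 18.0)         # chlorophyll-a absorption well
        - 0.025 * _gauss(wl, 445.0, 22.0)         # blue absorption
        + 0.38 * _sigmoid(wl, 715.0, 12.0)        # red edge -> NIR plateau
    )
    return np.maximum(base, 1e-3)


def _surface_difference(wl: np.ndarray) -> np.ndarray:
    """abaxial minus adaxial reflectance: positive below the 735 nm crossing
    with its maximum near 567 nm, negative (adaxial brighter) in the NIR."""
    amplitude = 0.035 * _gauss(wl, 567.0, 110.0) + 0.012
    return amplitude * np.tanh((735.0 - wl) / 8.0)


@dataclass(frozen=True)
class SurfaceProfile:
    """Baseline optical behaviour of one leaf surface."""

    surface: str
    baseline: np.ndarray                 # (bands,) reflectance on [0, 1]
    scatter_mult_sd: float = DEFAULT_SCATTER_MULT_SD
    scatter_add_sd: float = DEFAULT_SCATTER_ADD_SD
    band_noise_sd: float = DEFAULT_BAND_NOISE_SD

    def __post_init__(self) -> None:
        if self.surface not in SURFACES:
            raise ValueError(f"unknown surface label: {self.surface!r}")
        if np.any(self.baseline < 0):
            raise ValueError("baseline reflectance must be non-negative")


def surface_profile(surface: str, wavelengths: np.ndarray | None = None,
                    **kwargs) -> SurfaceProfile:
    """Baseline profile for one surface on the given (default) grid."""
    if surface not in SURFACES:
        raise ValueError(f"unknown surface label: {surface!r}")
    wl = make_wavelength_grid() if wavelengths is None else np.asarray(wavelengths)
    base = _adaxial_baseline(wl)
    if surface == "abaxial":
        base = base + _surface_difference(wl)
    return SurfaceProfile(surface=surface, baseline=np.maximum(base, 1e-3), **kwargs)


def latent_components(wavelengths: np.ndarray | None = None) -> np.ndarray:
    """The four latent spectral components, rows = components x bands.

    Components: chlorophyll absorption depth (670 nm), green-peak height
    (560 nm), red-edge position/steepness (bump near 715 nm), NIR plateau
    amplitude.  Amplitudes are in reflectance units per unit latent score.
    """
    wl = make_wavelength_grid() if wavelengths is None else np.asarray(wavelengths)
    chlorophyll = -0.020 * _gauss(wl, 670.0, 20.0)
    green = 0.020 * _gauss(wl, 560.0, 25.0)
    red_edge = 0.020 * _gauss(wl, 715.0, 15.0)
    nir = 0.030 * _sigmoid(wl, 715.0, 12.0)
    return np.vstack([chlorophyll, green, red_edge, nir])


def generate_spectra(
    n: int,
    surface: str,
    nutrient_configs: list[NutrientConfig] | None = None,
    seed: int = 0,
    scatter_mult_sd: float = DEFAULT_SCATTER_MULT_SD,
    scatter_add_sd: float = DEFAULT_SCATTER_ADD_SD,
    band_noise_sd: float = DEFAULT_BAND_NOISE_SD,
) -> tuple[SpectrumSet, NutrientTable]:
    """Draw ``n`` leaf spectra of one surface and linked nutrient values.

    Each sample i gets latent scores z_i ~ N(0, I4); its spectrum is

        baseline * (1 + m_i) + sum_k z_ik * component_k + a_i + noise

    with multiplicative scatter m_i, additive offset a_i and per-band noise.
    Each nutrient is mean + signal_sd * (w.z_i / ||w||) + N(0, noise_sd),
    clipped to its configured range.  The same seed reproduces the same
    output bit for bit.
    """
    if n < 4:
        raise ValueError("insufficient samples: n must be >= 4")
    if surface not in SURFACES:
        raise ValueError(f"unknown surface label: {surface!r}")
    configs = default_nutrient_configs() if nutrient_configs is None else nutrient_configs

    wl = make_wavelength_grid()
    profile = surface_profile(
        surface, wl,
        scatter_mult_sd=scatter_mult_sd,
        scatter_add_sd=scatter_add_sd,
        band_noise_sd=band_noise_sd,
    )
    components = latent_components(wl)
    n_comp = components.shape[0]

    rng = np.random.default_rng(seed)
    z = rng.standard_normal((n, n_comp))
    mult = rng.normal(0.0, scatter_mult_sd, size=n)
    add = rng.normal(0.0, scatter_add_sd, size=n)
    noise = rng.normal(0.0, band_noise_sd, size=(n, wl.size))

    spectra = (
        profile.baseline[None, :] * (1.0 + mult[:, None])
        + z @ components
        + add[:, None]
        + noise
    )

    ids = [f"{surface}_{i + 1:03d}" for i in range(n)]
    values: dict[str, np.ndarray] = {}
    units: dict[str, str] = {}
    for cfg in configs:
        w = np.asarray(cfg.weights, dtype=float)
        if w.size != n_comp:
            raise ValueError(
                f"{cfg.name}: expected {n_comp} linkage weights, got {w.size}"
            )
        u = z @ w / np.linalg.norm(w)
        y = cfg.mean + cfg.signal_sd * u + rng.normal(0.0, cfg.noise_sd, size=n)
        values[cfg.name] = np.clip(y, cfg.minimum, cfg.maximum)
        units[cfg.name] = cfg.unit

    spectrum_set = SpectrumSet(
        wavelengths=wl, reflectance=spectra, sample_ids=ids, surfaces=[surface] * n
    )
    table = NutrientTable(
        data=pd.DataFrame(values, index=pd.Index(ids, name="sample_id")),
        units=units,
    )
    return spectrum_set, table


def generate_cube(
    height: int,
    width: int,
    spectrum: np.ndarray,
    seed: int = 0,
    noise_sd: float = 0.0,
    bit_depth: int = 12,
    background_reflectance: float = 0.05,
    roi: tuple[slice, slice] | None = None,
) -> tuple[np.ndarray, np.ndarray, np.ndarray, np.ndarray]:
    """Raw line-scanner cube with dark/white reference frames and ROI mask.

    Returns ``(cube, dark, white, mask)`` where the cube is height x width x
    bands of raw digital numbers, ``dark`` and ``white`` are per-band
    reference vectors (white ~99% of the sensor's full scale), and ``mask``
    marks the leaf region.  Inside the ROI the raw signal is
    ``D + R*(W - D) + noise``; outside it a dark tray background.  Applying
    the dark/white reflectance correction and averaging over the ROI
    recovers ``spectrum`` up to the pixel noise.
    """
    if height < 2 or width < 2:
        raise ValueError("cube must be at least 2 x 2 pixels")
    spectrum = np.asarray(spectrum, dtype=float)
    n_bands = spectrum.size
    grid_len = N_BANDS
    if n_bands != grid_len:
        raise ValueError(
            f"spectrum length {n_bands} does not match the {grid_len}-band grid"
        )

    full_scale = float(2**bit_depth - 1)
    rng = np.random.default_rng(seed)
    wl = make_wavelength_grid()
    # dark current: low, slowly varying across bands
    dark = full_scale * (0.02 + 0.005 * np.sin(2 * np.pi * (wl - wl[0]) / 600.0))
    white = np.full(n_bands, 0.99 * full_scale)

    if roi is None:
        roi = (slice(height // 4, height - height // 4),
               slice(width // 4, width - width // 4))
    mask = np.zeros((height, width), dtype=bool)
    mask[roi] = True

    gain = white - dark
    cube = np.empty((height, width, n_bands), dtype=float)
    cube[:] = dark + background_reflectance * gain
    n_roi = int(mask.sum())
    pixel_noise = rng.normal(0.0, 1.0, size=(n_roi, n_bands)) if noise_sd > 0 else 0.0
    cube[mask] = dark + spectrum * gain + noise_sd * gain * pixel_noise
    return cube, dark, white, mask


def to_integer_scale(reflectance: np.ndarray, full: int = 10_000) -> np.ndarray:
    """Scale [0, 1] relative reflectance to the 10,000-integer convention."""
    return np.rint(np.asarray(reflectance, dtype=float) * full).astype(np.int64)
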