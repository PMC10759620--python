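"""Synthetic visual-pigment absorbance scans.

Ground truth is the A1 (retinal) pigment absorbance template of
Govardovskii et al. (2000): an alpha band whose shape depends only on
lambda_max, plus an optional beta band. Simulated scans add a 280-nm
protein peak, a linear baseline and white replicate noise; photobleaching
converts a fraction of the pigment into a short-wave product.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from opsinkit.spectra.core import Spectrum, SpectralMeasurement

PROTEIN_PEAK_NM = 280.0
PROTEIN_PEAK_WIDTH_NM = 28.0
DEFAULT_BLEACH_PRODUCT_NM = 380.0
BLEACH_PRODUCT_WIDTH_NM = 32.0

TEMPLATE_LAMBDA_RANGE = (330.0, 600.0)


def govardovskii_template(
    lambda_max: float,
    wavelengths: np.ndarray,
    include_beta_band: bool | None = None,
) -> np.ndarray:
    """A1 pigment absorbance template, normalized to peak at 1.0.

    Parameters
    ----------
    lambda_max : float
        Peak wavelength in nm; must lie in [330, 600].
    wavelengths : array-like
        Strictly increasing evaluation grid, nm.
    include_beta_band : bool, optional
        Add the short-wave beta band. Default: on for lambda_max < 500 nm.
    """
    lo, hi = TEMPLATE_LAMBDA_RANGE
    if not lo <= lambda_max <= hi:
        raise ValueError(
            f"lambda_max={lambda_max} outside supported range [{lo}, {hi}]"
        )
    wl = np.asarray(wavelengths, dtype=float)
    if wl.ndim != 1 or wl.size < 2 or np.any(np.diff(wl) <= 0):
        raise ValueError("wavelengths must be a strictly increasing 1-D grid")
    if include_beta_band is None:
        include_beta_band = lambda_max < 500.0

    x = lambda_max / wl
    a = 0.8795 + 0.0459 * np.exp(-((lambda_max - 300.0) ** 2) / 11940.0)
    alpha = 1.0 / (
        np.exp(69.7 * (a - x))
        + np.exp(28.0 * (0.922 - x))
        + np.exp(-14.9 * (1.104 - x))
        + 0.674
    )
    s = alpha
    if include_beta_band:
        lm_beta = 189.0 + 0.315 * lambda_max
        band = -40.5 + 0.195 * lambda_max
        beta = 0.26 * np.exp(-(((wl - lm_beta) / band) ** 2))
        s = alpha + beta
    peak = s.max()
    return s / peak


def _gaussian_peak(wl: np.ndarray, center: float, width: float) -> np.ndarray:
    return np.exp(-0.5 * ((wl - center) / width) ** 2)


@dataclass
class PigmentTemplateParams:
    """Parameters of a simulated spectrophotometric measurement."""

    lambda_max: float
    alpha_amplitude: float = 0.05
    beta_band_included: bool | None = None
    protein_peak_amplitude: float = 0.5
    baseline_offset: float = 0.02
    baseline_slope: float = -1e-5
    bleach_product_lambda_max: float = DEFAULT_BLEACH_PRODUCT_NM
    bleach_fraction: float = 1.0
    noise_sd: float = 0.002
    n_replicates: int = 8
    wavelength_grid: np.ndarray = field(
        default_factory=lambda: np.arange(250.0, 701.0, 1.0)
    )
    seed: int = 0

    def __post_init__(self) -> None:
        self.wavelength_grid = np.asarray(self.wavelength_grid, dtype=float)
        wl = self.wavelength_grid
        if wl.ndim != 1 or wl.size < 2 or np.any(np.diff(wl) <= 0):
            raise ValueError("wavelength_grid must be strictly increasing")
        if not wl[0] <= self.lambda_max <= wl[-1]:
            raise ValueError("lambda_max outside the wavelength grid")
        if not 0.0 <= self.bleach_fraction <= 1.0:
            raise ValueError("bleach_fraction must lie in [0, 1]")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be >= 0")
        if self.n_replicates < 1:
            raise ValueError("n_replicates must be >= 1")


def pigment_component(params: PigmentTemplateParams) -> np.ndarray:
    """Noise-free pigment alpha/beta-band absorbance (dark state)."""
    return params.alpha_amplitude * govardovskii_template(
        params.lambda_max, params.wavelength_grid, params.beta_band_included
    )


def bleach_component(params: PigmentTemplateParams) -> np.ndarray:
    """Noise-free absorbance of the fully bleached product."""
    return params.alpha_amplitude * _gaussian_peak(
        params.wavelength_grid,
        params.bleach_product_lambda_max,
        BLEACH_PRODUCT_WIDTH_NM,
    )


def _background(params: PigmentTemplateParams) -> np.ndarray:
    wl = params.wavelength_grid
    baseline = params.baseline_offset + params.baseline_slope * (wl - wl[0])
    protein = params.protein_peak_amplitude * _gaussian_peak(
        wl, PROTEIN_PEAK_NM, PROTEIN_PEAK_WIDTH_NM
    )
    return baseline + protein


def simulate_measurement(
    params: PigmentTemplateParams, pigment_label: str = "synthetic"
) -> SpectralMeasurement:
    """Simulate replicated dark scans and post-bleach (light) scans.

    Dark scans: baseline + protein peak + pigment template + noise.
    Light scans: the bleached fraction of the pigment is replaced by the
    bleach-product template. Bit-reproducible for a fixed seed.
    """
    rng = np.random.default_rng(params.seed)
    wl = params.wavelength_grid
    background = _background(params)
    pigment = pigment_component(params)
    bleached = bleach_component(params)
    f = params.bleach_fraction

    dark_mean = background + pigment
    light_mean = background + (1.0 - f) * pigment + f * bleached

    dark_scans, light_scans = [], []
    for rep in range(1, params.n_replicates + 1):
        noise = rng.normal(0.0, params.noise_sd, size=wl.size)
        dark_scans.append(Spectrum(wl, dark_mean + noise, "dark", rep))
    for rep in range(1, params.n_replicates + 1):
        noise = rng.normal(0.0, params.noise_sd, size=wl.size)
        light_scans.append(Spectrum(wl, light_mean + noise, "light", rep))
    return SpectralMeasurement(pigment_label, dark_scans, light_scans)
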