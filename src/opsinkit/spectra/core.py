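"""Spectrum containers, replicate arithmetic and lambda-max estimation.

The estimation protocol mirrors standard dark/difference-spectrum
spectrophotometry of reconstructed visual pigments: per replicate scan
(or positionally paired dark-minus-light difference), a heavily smoothed
cubic spline is fitted with knots at every observation, and lambda-max is
the argmax of the fitted curve on a 0.1-nm grid restricted to a search
window that excludes the 280-nm protein peak. The replicate mean and
sample SD summarize the estimate.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np

from opsinkit.spectra._spline import SmoothingSpline, smoothing_spline

#: Default lambda-max search windows (nm) by opsin class.
DEFAULT_SEARCH_WINDOWS: dict[str, tuple[float, float]] = {
    "LWS": (450.0, 650.0),
    "SWS2": (380.0, 520.0),
    "RH1": (420.0, 570.0),
}

PEAK_GRID_STEP_NM = 0.1

CONDITIONS = ("dark", "light", "difference")


class GridMismatchError(ValueError):
    """Spectra do not share a wavelength grid."""


@dataclass
class Spectrum:
    """A single absorbance scan on a strictly increasing wavelength grid."""

    wavelengths: np.ndarray
    absorbances: np.ndarray
    condition: str = "dark"
    replicate_id: int | None = None

    def __post_init__(self) -> None:
        self.wavelengths = np.asarray(self.wavelengths, dtype=float)
        self.absorbances = np.asarray(self.absorbances, dtype=float)
        if self.wavelengths.shape != self.absorbances.shape:
            raise ValueError("wavelengths and absorbances differ in length")
        if self.wavelengths.ndim != 1 or self.wavelengths.size < 2:
            raise ValueError("a spectrum needs >= 2 points")
        if np.any(np.diff(self.wavelengths) <= 0):
            raise ValueError("wavelengths must be strictly increasing")
        if np.any(~np.isfinite(self.absorbances)):
            raise ValueError("absorbances contain missing values")
        if self.condition not in CONDITIONS:
            raise ValueError(f"condition must be one of {CONDITIONS}")

    def same_grid(self, other: "Spectrum") -> bool:
        return (
            self.wavelengths.size == other.wavelengths.size
            and bool(np.all(self.wavelengths == other.wavelengths))
        )


@dataclass
class SpectralMeasurement:
    """Replicated dark scans and optional post-bleach (light) scans."""

    pigment_label: str
    dark_scans: list[Spectrum]
    light_scans: list[Spectrum] = field(default_factory=list)

    def __post_init__(self) -> None:
        if not self.dark_scans:
            raise ValueError("at least one dark scan is required")
        ref = self.dark_scans[0]
        for s in [*self.dark_scans, *self.light_scans]:
            if not ref.same_grid(s):
                raise GridMismatchError("all scans must share one grid")

    @property
    def wavelengths(self) -> np.ndarray:
        return self.dark_scans[0].wavelengths


@dataclass
class LambdaMaxEstimate:
    """Per-replicate lambda-max peaks with their mean and sample SD."""

    method: str
    per_replicate_peaks: np.ndarray
    mean_nm: float
    sd_nm: float
    n: int
    search_window: tuple[float, float]
    boundary_peak: bool = False  # a fitted curve was monotone on the window

    @classmethod
    def from_peaks(cls, method, peaks, window, boundary_peak=False):
        peaks = np.asarray(peaks, dtype=float)
        sd = float(np.std(peaks, ddof=1)) if peaks.size > 1 else 0.0
        return cls(
            method=method,
            per_replicate_peaks=peaks,
            mean_nm=float(np.mean(peaks)),
            sd_nm=sd,
            n=int(peaks.size),
            search_window=(float(window[0]), float(window[1])),
            boundary_peak=boundary_peak,
        )

    def to_dict(self) -> dict:
        return {
            "method": self.method,
            "per_replicate_peaks": self.per_replicate_peaks.tolist(),
            "mean_nm": self.mean_nm,
            "sd_nm": self.sd_nm,
            "n": self.n,
            "search_window": list(self.search_window),
            "boundary_peak": self.boundary_peak,
        }


def average_spectra(scans: list[Spectrum]) -> Spectrum:
    """Pointwise arithmetic mean of scans sharing one grid."""
    if not scans:
        raise ValueError("cannot average an empty list of scans")
    ref = scans[0]
    for s in scans[1:]:
        if not ref.same_grid(s):
            raise GridMismatchError("scans are on different grids")
    mean = np.mean([s.absorbances for s in scans], axis=0)
    return Spectrum(ref.wavelengths.copy(), mean, ref.condition)


def difference_spectrum(dark: Spectrum, light: Spectrum) -> Spectrum:
    """Dark minus light, pointwise."""
    if not dark.same_grid(light):
        raise GridMismatchError("dark and light scans are on different grids")
    if dark.condition != "dark" or light.condition != "light":
        raise ValueError("expected a dark and a light spectrum, in that order")
    return Spectrum(
        dark.wavelengths.copy(),
        dark.absorbances - light.absorbances,
        "difference",
        dark.replicate_id,
    )


def fit_smoothing_spline(
    spectrum: Spectrum,
    smoothness: float | None = None,
    edf: float | None = None,
) -> SmoothingSpline:
    """Cubic smoothing spline with knots at every observation.

    ``smoothness`` in [0, 1] maps linearly onto an effective-df target
    (0 -> interpolation-like, 1 -> a straight line); alternatively pass
    ``edf`` directly. The default (edf = 10% of the point count)
    approximates heavy R-style spar=1 smoothing; the mapping is monotone
    in the roughness penalty but is not a bit-exact port of spar.
    """
    n = spectrum.wavelengths.size
    if smoothness is not None:
        if edf is not None:
            raise ValueError("give either smoothness or edf, not both")
        if not 0.0 <= smoothness <= 1.0:
            raise ValueError("smoothness must lie in [0, 1]")
        edf = 2.0 + (1.0 - smoothness) * (n - 2.0)
    return smoothing_spline(spectrum.wavelengths, spectrum.absorbances, edf=edf)


def _peak_of_curve(
    curve: SmoothingSpline, window: tuple[float, float]
) -> tuple[float, bool]:
    lo, hi = window
    grid = np.arange(lo, hi + PEAK_GRID_STEP_NM / 2, PEAK_GRID_STEP_NM)
    values = curve(grid)
    idx = int(np.argmax(values))  # ties -> lowest wavelength
    at_boundary = idx == 0 or idx == grid.size - 1
    return float(grid[idx]), at_boundary


def estimate_lambda_max(
    measurement: SpectralMeasurement,
    method: str = "dark_spectrum",
    search_window: tuple[float, float] | None = None,
    smoothness: float | None = None,
    edf: float | None = None,
) -> LambdaMaxEstimate:
    """Per-replicate spline-fitted lambda-max with mean and sample SD.

    method="dark_spectrum" fits each dark scan; "difference_spectrum"
    fits the positionally paired dark-minus-light difference of each
    replicate. A curve that is monotone over the window (no interior
    peak) is flagged via ``boundary_peak`` and contributes the window
    argmax.
    """
    if method not in ("dark_spectrum", "difference_spectrum"):
        raise ValueError(f"unknown method {method!r}")
    wl = measurement.wavelengths
    if search_window is None:
        search_window = (float(wl[0]), float(wl[-1]))
    lo, hi = search_window
    if lo >= hi or lo < wl[0] or hi > wl[-1]:
        raise ValueError("search_window must be a subinterval of the grid")

    if method == "dark_spectrum":
        targets = list(measurement.dark_scans)
    else:
        if not measurement.light_scans:
            raise ValueError(
                "difference_spectrum requires light scans in the measurement"
            )
        targets = [
            difference_spectrum(d, l)
            for d, l in zip(measurement.dark_scans, measurement.light_scans)
        ]

    peaks, any_boundary = [], False
    for spec in targets:
        curve = fit_smoothing_spline(spec, smoothness=smoothness, edf=edf)
        peak, at_boundary = _peak_of_curve(curve, search_window)
        peaks.append(peak)
        any_boundary = any_boundary or at_boundary
    if any_boundary:
        warnings.warn(
            "fitted curve had no interior peak in the search window for at "
            "least one replicate; window argmax reported",
            stacklevel=2,
        )
    return LambdaMaxEstimate.from_peaks(
        method, peaks, search_window, boundary_peak=any_boundary
    )
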