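"""Publication-style spectrum plots (mean scans, fitted curve, peak marker)."""

from __future__ import annotations

import matplotlib

matplotlib.use("Agg")
import matplotlib.pyplot as plt
import numpy as np

from opsinkit.spectra.core import (
    SpectralMeasurement,
    LambdaMaxEstimate,
    average_spectra,
    difference_spectrum,
    fit_smoothing_spline,
)


def plot_measurement(
    measurement: SpectralMeasurement,
    estimate: LambdaMaxEstimate | None = None,
    smoothness: float | None = None,
    edf: float | None = None,
    out: str | None = None,
):
    """Plot mean dark (and, if present, light and difference) spectra with
    their fitted smoothing splines; mark the estimated lambda-max."""
    fig, ax = plt.subplots(figsize=(7, 4.5))
    wl = measurement.wavelengths
    panels = [("dark", average_spectra(measurement.dark_scans))]
    if measurement.light_scans:
        light = average_spectra(measurement.light_scans)
        panels.append(("light", light))
        diff = difference_spectrum(panels[0][1], light)
        panels.append(("difference", diff))
    for name, spec in panels:
        ax.plot(wl, spec.absorbances, lw=0.7, alpha=0.5, label=f"{name} (mean)")
        curve = fit_smoothing_spline(spec, smoothness=smoothness, edf=edf)
        ax.plot(wl, curve(wl), lw=1.5, label=f"{name} (spline)")
    if estimate is not None:
        ax.axvline(estimate.mean_nm, color="k", ls="--", lw=1)
        ax.annotate(
            f"$\\lambda_{{max}}$ = {estimate.mean_nm:.1f} "
            f"$\\pm$ {estimate.sd_nm:.1f} nm",
            xy=(estimate.mean_nm, ax.get_ylim()[1]),
            xytext=(5, -12),
            textcoords="offset points",
            fontsize=9,
        )
    ax.set_xlabel("wavelength (nm)")
    ax.set_ylabel("absorbance (AU)")
    ax.set_title(measurement.pigment_label)
    ax.legend(fontsize=8)
    fig.tight_layout()
    if out is not None:
        fig.savefig(out, dpi=150)
        plt.close(fig)
        return None
    return fig
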