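"""CSV I/O for replicated spectral measurements.

The canonical dialect has columns wavelength_nm, absorbance, condition
(dark|light), replicate (1-based). A bare two-column wavelength,absorbance
file is also accepted, with condition/replicate supplied by the caller.
"""

from __future__ import annotations

from pathlib import Path

import pandas as pd

from opsinkit.spectra.core import Spectrum, SpectralMeasurement

CANONICAL_COLUMNS = ["wavelength_nm", "absorbance", "condition", "replicate"]


def write_measurement_csv(measurement: SpectralMeasurement, path) -> None:
    rows = []
    for scan in [*measurement.dark_scans, *measurement.light_scans]:
        rep = scan.replicate_id if scan.replicate_id is not None else 1
        rows.append(
            pd.DataFrame(
                {
                    "wavelength_nm": scan.wavelengths,
                    "absorbance": scan.absorbances,
                    "condition": scan.condition,
                    "replicate": rep,
                }
            )
        )
    pd.concat(rows, ignore_index=True).to_csv(path, index=False)


def read_measurement_csv(
    path,
    pigment_label: str | None = None,
    condition: str = "dark",
    replicate: int = 1,
) -> SpectralMeasurement:
    """Read a measurement CSV (canonical or bare two-column dialect)."""
    path = Path(path)
    df = pd.read_csv(path)
    label = pigment_label or path.stem
    if not set(CANONICAL_COLUMNS) <= set(df.columns):
        if df.shape[1] < 2:
            raise ValueError(f"{path}: expected at least two columns")
        df = df.iloc[:, :2].copy()
        df.columns = ["wavelength_nm", "absorbance"]
        df["condition"] = condition
        df["replicate"] = replicate
    dark, light = [], []
    for (cond, rep), grp in df.groupby(["condition", "replicate"]):
        grp = grp.sort_values("wavelength_nm")
        spec = Spectrum(
            grp["wavelength_nm"].to_numpy(),
            grp["absorbance"].to_numpy(),
            str(cond),
            int(rep),
        )
        (dark if cond == "dark" else light).append(spec)
    dark.sort(key=lambda s: s.replicate_id)
    light.sort(key=lambda s: s.replicate_id)
    return SpectralMeasurement(label, dark, light)
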