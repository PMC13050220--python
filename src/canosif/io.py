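"""CSV readers and writers for the interface schemas.

Spectrum scans are one CSV per observation (columns wavelength_nm,
irradiance, radiance) named ``<plot>_<datetime>.csv`` and listed in a
``scans.csv`` manifest with plot and timestamp; tabular inputs (weather,
chamber records, field measurements) are plain CSV handled by pandas.
"""

from __future__ import annotations

from datetime import datetime
from pathlib import Path

import pandas as pd

from .spectra import SpectrumPair

SPECTRUM_COLUMNS = ("wavelength_nm", "irradiance", "radiance")


def read_spectrum_csv(
    path: str | Path,
    timestamp: datetime | None = None,
    plot_id: str | None = None,
) -> SpectrumPair:
    """Read one scan CSV into a SpectrumPair.

    When metadata are not given they are parsed from the
    ``<plot>_<datetime>.csv`` filename pattern where possible.
    """
    path = Path(path)
    df = pd.read_csv(path)
    missing = [c for c in SPECTRUM_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"{path.name}: missing columns {missing}")
    if plot_id is None or timestamp is None:
        stem = path.stem
        if "_" in stem:
            plot_part, _, stamp_part = stem.rpartition("_")
            plot_id = plot_id or plot_part
            if timestamp is None:
                try:
                    timestamp = datetime.strptime(stamp_part, "%Y%m%dT%H%M%S")
                except ValueError:
                    timestamp = None
    return SpectrumPair(
        df["wavelength_nm"].to_numpy(),
        df["irradiance"].to_numpy(),
        df["radiance"].to_numpy(),
        timestamp=timestamp,
        plot_id=plot_id,
    )


def write_spectrum_csv(pair: SpectrumPair, path: str | Path) -> None:
    """Write one SpectrumPair to the scan CSV schema."""
    pd.DataFrame(
        {
            "wavelength_nm": pair.wavelengths,
            "irradiance": pair.irradiance,
            "radiance": pair.radiance,
        }
    ).to_csv(path, index=False, float_format="%.10g")


def read_scan_directory(directory: str | Path) -> list[SpectrumPair]:
    """Read every scan listed in ``scans.csv`` (or all ``*_*.csv`` files)."""
    directory = Path(directory)
    manifest_path = directory / "scans.csv"
    pairs = []
    if manifest_path.exists():
        manifest = pd.read_csv(manifest_path)
        for _, row in manifest.iterrows():
            pairs.append(
                read_spectrum_csv(
                    directory / row["file"],
                    timestamp=pd.to_datetime(row["timestamp"]).to_pydatetime(),
                    plot_id=str(row["plot_id"]),
                )
            )
        return pairs
    for path in sorted(directory.glob("*_*.csv")):
        pairs.append(read_spectrum_csv(path))
    return pairs
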