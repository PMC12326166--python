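"""Reading and writing ImageJ "Results"-style measurement tables.

The upstream measurements come from Fiji/ImageJ "Analyze Particles" or
"Measure" exports: a CSV with an unnamed leading index column and at least an
``Area`` column, optionally ``Major``/``Minor`` (ellipse-fit full axes) and a
``Label`` column naming the source image.  Areas may be in px^2 or um^2
depending on whether the image was spatially calibrated, so the reader takes
an explicit um-per-px calibration (1.0 = already in um) — there is no default,
because silently mis-scaled areas are the worst failure mode of this kind of
pipeline.

Tables are held as a pandas DataFrame with canonical columns plus the sample
metadata (composition tag, condition tag, calibration) alongside.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from .geometry import diameter_from_area

__all__ = [
    "MeasurementTable",
    "read_imagej_csv",
    "write_imagej_csv",
    "write_processed_csv",
    "read_processed_csv",
    "COMPOSITIONS",
]

#: DOPC:cholesterol molar ratios used throughout (lipid-solution tags).
COMPOSITIONS = ("100:0", "85:15", "71:29", "60:40")

#: canonical column order of the in-memory table
_COLUMNS = ["particle_id", "label", "area_um2", "major_um", "minor_um"]

#: stable column order of processed CSV output
_PROCESSED_COLUMNS = [
    "id",
    "label",
    "composition",
    "condition",
    "area_um2",
    "diameter_um",
    "surface_um2",
    "major_um",
    "minor_um",
]


@dataclass(frozen=True)
class MeasurementTable:
    """Per-vesicle measurements for one sample (composition x condition).

    ``data`` holds one row per vesicle with columns ``particle_id``,
    ``label``, ``area_um2``, ``major_um``, ``minor_um`` (the axis columns are
    NaN when the export had no ellipse fit).  All lengths are um after
    calibration.
    """

    data: pd.DataFrame
    composition: str
    condition: str
    calibration: float = 1.0

    def __post_init__(self) -> None:
        if not (self.calibration > 0.0):
            raise ValueError(f"calibration must be positive, got {self.calibration}")
        missing = [c for c in _COLUMNS if c not in self.data.columns]
        if missing:
            raise ValueError(f"measurement table missing columns: {missing}")
        bad = np.flatnonzero(~(self.data["area_um2"].to_numpy(dtype=float) > 0.0))
        if bad.size:
            raise ValueError(f"non-positive area in rows {bad.tolist()}")

    def __len__(self) -> int:
        return len(self.data)

    @property
    def areas(self) -> np.ndarray:
        return self.data["area_um2"].to_numpy(dtype=float)

    @property
    def diameters(self) -> np.ndarray:
        """Equivalent circular diameters (um) of all rows."""
        return np.asarray(diameter_from_area(self.areas))

    @property
    def has_axes(self) -> bool:
        ax = self.data[["major_um", "minor_um"]]
        return len(ax) > 0 and bool(ax.notna().all().all())


def _sniff_delimiter(header_line: str) -> str:
    # locale exports use ';'; prefer whichever separator dominates the header
    return ";" if header_line.count(";") > header_line.count(",") else ","


def _find_column(columns: list[str], name: str) -> str | None:
    for c in columns:
        if c.strip().lower() == name:
            return c
    return None


def read_imagej_csv(
    path: str | Path,
    calibration: float,
    composition: str,
    condition: str,
) -> MeasurementTable:
    """Read an ImageJ Results export and return a calibrated table.

    Parameters
    ----------
    path : path
        CSV with a header naming at least an ``Area`` column
        (case-insensitive); ``Major``/``Minor``/``Label`` optional; a leading
        unnamed index column is accepted and used as the particle id.
    calibration : float
        um per px.  Areas are multiplied by ``calibration**2`` and axes by
        ``calibration``; pass 1.0 when the export is already in um.
    composition, condition : str
        Sample tags attached to the table (e.g. "60:40", "t0", "H3").

    Raises
    ------
    ValueError
        If no Area column exists (the error names the columns found) or any
        area is non-positive (the error names the row indices).
    """
    path = Path(path)
    if not (calibration > 0.0):
        raise ValueError(f"calibration must be positive, got {calibration}")
    with open(path, encoding="utf-8-sig") as fh:
        header = fh.readline()
    sep = _sniff_delimiter(header)
    df = pd.read_csv(path, sep=sep, encoding="utf-8-sig", float_precision="round_trip")

    cols = list(df.columns)
    area_col = _find_column(cols, "area")
    if area_col is None:
        raise ValueError(
            f"{path.name}: no Area column found; columns present: {cols}"
        )
    major_col = _find_column(cols, "major")
    minor_col = _find_column(cols, "minor")
    label_col = _find_column(cols, "label")
    # ImageJ writes the particle index as an unnamed leading column
    id_col = cols[0] if cols[0].startswith("Unnamed") or cols[0].strip() in ("", " ") else None

    area = df[area_col].to_numpy(dtype=float) * calibration**2
    bad = np.flatnonzero(~(area > 0.0))
    if bad.size:
        raise ValueError(
            f"{path.name}: non-positive area in data rows {bad.tolist()}"
        )

    n = len(df)
    out = pd.DataFrame(
        {
            "particle_id": (
                df[id_col].to_numpy() if id_col is not None else np.arange(1, n + 1)
            ),
            "label": df[label_col].astype(str).to_numpy() if label_col else [""] * n,
            "area_um2": area,
            "major_um": (
                df[major_col].to_numpy(dtype=float) * calibration
                if major_col
                else np.full(n, np.nan)
            ),
            "minor_um": (
                df[minor_col].to_numpy(dtype=float) * calibration
                if minor_col
                else np.full(n, np.nan)
            ),
        }
    )

    # repair axis misordering (ellipse-fit rounding) by swapping, with a warning
    both = out["major_um"].notna() & out["minor_um"].notna()
    swapped = both & (out["major_um"] < out["minor_um"])
    if swapped.any():
        warnings.warn(
            f"{path.name}: swapped major/minor axes in {int(swapped.sum())} rows",
            stacklevel=2,
        )
        maj = out.loc[swapped, "major_um"].copy()
        out.loc[swapped, "major_um"] = out.loc[swapped, "minor_um"]
        out.loc[swapped, "minor_um"] = maj

    return MeasurementTable(
        data=out, composition=composition, condition=condition, calibration=calibration
    )


def write_imagej_csv(table: MeasurementTable, path: str | Path) -> None:
    """Write a table back in the ImageJ Results dialect (um-calibrated).

    Emits the unnamed leading index column and ``Label,Area,Major,Minor``
    headers so the file is readable by :func:`read_imagej_csv` with
    calibration 1.0.  Axis columns are omitted when the table has none.
    """
    out = pd.DataFrame(
        {
            " ": table.data["particle_id"].to_numpy(),
            "Label": table.data["label"].to_numpy(),
            "Area": table.areas,
        }
    )
    if table.has_axes:
        out["Major"] = table.data["major_um"].to_numpy()
        out["Minor"] = table.data["minor_um"].to_numpy()
    out.to_csv(path, index=False, float_format="%.17g")


def write_processed_csv(table: MeasurementTable, path: str | Path) -> pd.DataFrame:
    """Write the tidy processed CSV (um-calibrated, with derived geometry).

    Adds the equivalent circular diameter and the spherical surface area
    ``4 pi (d/2)^2`` per vesicle.  Column order is stable
    (``id,label,composition,condition,area_um2,diameter_um,surface_um2,
    major_um,minor_um``) and floats are written with 17 significant digits so
    a re-read reproduces every value to full double precision.

    Returns the DataFrame that was written.
    """
    d = table.diameters if len(table) else np.empty(0)
    out = pd.DataFrame(
        {
            "id": table.data["particle_id"].to_numpy(),
            "label": table.data["label"].to_numpy(),
            "composition": table.composition,
            "condition": table.condition,
            "area_um2": table.areas,
            "diameter_um": d,
            "surface_um2": np.pi * d**2,
            "major_um": table.data["major_um"].to_numpy(),
            "minor_um": table.data["minor_um"].to_numpy(),
        },
        columns=_PROCESSED_COLUMNS,
    )
    out.to_csv(path, index=False, float_format="%.17g")
    return out


def read_processed_csv(path: str | Path) -> MeasurementTable:
    """Read back a processed CSV written by :func:`write_processed_csv`."""
    df = pd.read_csv(path, float_precision="round_trip")
    missing = [c for c in ("area_um2", "composition", "condition") if c not in df.columns]
    if missing:
        raise ValueError(f"{Path(path).name}: not a processed table, missing {missing}")
    composition = str(df["composition"].iloc[0]) if len(df) else ""
    condition = str(df["condition"].iloc[0]) if len(df) else ""
    n = len(df)
    data = pd.DataFrame(
        {
            "particle_id": df["id"].to_numpy() if "id" in df else np.arange(1, n + 1),
            "label": df["label"].astype(str).to_numpy() if "label" in df and n else [""] * n,
            "area_um2": df["area_um2"].to_numpy(dtype=float),
            "major_um": df["major_um"].to_numpy(dtype=float) if "major_um" in df else np.full(n, np.nan),
            "minor_um": df["minor_um"].to_numpy(dtype=float) if "minor_um" in df else np.full(n, np.nan),
        }
    )
    return MeasurementTable(
        data=data, composition=composition, condition=condition, calibration=1.0
    )
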