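"""Localization-table and segment-ROI input/output.

Localization tables are plain :class:`pandas.DataFrame` objects with canonical
columns ``x_nm, y_nm[, z_nm], channel, frame[, photons]`` — nanometres
throughout. Files written by other software are adapted at load time through a
*dialect*: a mapping from canonical names to file column names, optionally with
a unit declaration (``unit: "px"`` plus ``pixel_size_nm``) so pixel-based
tables are converted to nm on the way in.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .errors import AnalysisError, FormatError

#: canonical column order; z and photons are optional
CANONICAL_COLUMNS = ("x_nm", "y_nm", "z_nm", "channel", "frame", "photons")
_REQUIRED = ("x_nm", "y_nm")
_COORD_COLUMNS = ("x_nm", "y_nm", "z_nm")


@dataclass(frozen=True)
class SegmentROI:
    """A straight axon-segment region of interest, endpoints in global nm."""

    endpoint_a: tuple[float, float]
    endpoint_b: tuple[float, float]
    half_width: float
    label: str = ""

    def __post_init__(self) -> None:
        if self.endpoint_a == self.endpoint_b:
            raise ValueError("SegmentROI endpoints must be distinct")
        if not self.half_width > 0:
            raise ValueError("SegmentROI half_width must be > 0")

    @property
    def length(self) -> float:
        ax, ay = self.endpoint_a
        bx, by = self.endpoint_b
        return math.hypot(bx - ax, by - ay)

    @property
    def axis(self) -> np.ndarray:
        """Unit vector from endpoint_a to endpoint_b."""
        a = np.asarray(self.endpoint_a, float)
        b = np.asarray(self.endpoint_b, float)
        return (b - a) / np.linalg.norm(b - a)


def validate_localizations(table: pd.DataFrame, allow_empty: bool = True) -> None:
    """Check canonical schema: required columns, finite coordinates, channel >= 1."""
    for col in _REQUIRED:
        if col not in table.columns:
            raise FormatError(f"localization table is missing required column {col!r}")
    if len(table) == 0:
        if allow_empty:
            return
        raise AnalysisError("localization table is empty")
    for col in _COORD_COLUMNS:
        if col in table.columns and not np.isfinite(table[col].to_numpy(float)).all():
            raise FormatError(f"non-finite values in column {col!r}")
    if "channel" in table.columns and (table["channel"].to_numpy() < 1).any():
        raise FormatError("channel indices must be >= 1")


def read_localizations(path, dialect: dict | None = None) -> pd.DataFrame:
    """Read a delimited localization table (comma or tab, autodetected).

    Parameters
    ----------
    path
        Delimited text file with a header row.
    dialect
        Optional mapping from canonical names (``x``, ``y``, ``z``, ``channel``,
        ``frame``, ``photons``) to the file's column names, plus optionally
        ``unit`` (``"nm"``, the default, or ``"px"``) and ``pixel_size_nm``
        for pixel-based coordinates.
    """
    df = pd.read_csv(path, sep=None, engine="python")
    dialect = dict(dialect or {})
    unit = dialect.pop("unit", "nm")
    pixel_size = float(dialect.pop("pixel_size_nm", 1.0))
    if unit not in ("nm", "px"):
        raise FormatError(f"unknown coordinate unit {unit!r} (expected 'nm' or 'px')")
    if unit == "px" and "pixel_size_nm" not in dialect and pixel_size == 1.0:
        # pixel dialects must declare the physical pixel size explicitly
        raise FormatError("pixel-unit dialect requires 'pixel_size_nm'")

    rename: dict[str, str] = {}
    for canonical, source in dialect.items():
        target = canonical if canonical.endswith("_nm") or canonical in ("channel", "frame", "photons") else f"{canonical}_nm"
        if canonical in ("channel", "frame", "photons"):
            target = canonical
        if source not in df.columns:
            raise FormatError(f"dialect maps {canonical!r} to missing column {source!r}")
        rename[source] = target
    df = df.rename(columns=rename)

    for col in _REQUIRED:
        if col not in df.columns:
            raise FormatError(f"localization table is missing required column {col!r}")

    for col in _COORD_COLUMNS:
        if col not in df.columns:
            continue
        values = pd.to_numeric(df[col], errors="coerce")
        bad = values.isna() & df[col].notna()
        if bad.any():
            raise FormatError(
                f"non-numeric coordinate in column {col!r} at row {int(np.flatnonzero(bad)[0])}"
            )
        df[col] = values.astype(float)
        if unit == "px":
            df[col] = df[col] * pixel_size

    if "channel" not in df.columns:
        df["channel"] = 1
    if "frame" not in df.columns:
        df["frame"] = 0
    df["channel"] = df["channel"].astype(int) if len(df) else df.get("channel", pd.Series(dtype=int))
    df["frame"] = df["frame"].astype(int) if len(df) else df["frame"]

    ordered = [c for c in CANONICAL_COLUMNS if c in df.columns]
    df = df[ordered + [c for c in df.columns if c not in ordered]]
    validate_localizations(df)
    return df


def write_localizations(table: pd.DataFrame, path) -> None:
    """Write a table with the canonical header; optional columns absent are omitted."""
    validate_localizations(table)
    columns = [c for c in CANONICAL_COLUMNS if c in table.columns]
    table[columns].to_csv(path, index=False)


def read_rois(path) -> list[SegmentROI]:
    """Read segment ROIs, one per line: ax,ay,bx,by,half_width,label."""
    rois = []
    df = pd.read_csv(path, header=None, names=["ax", "ay", "bx", "by", "half_width", "label"])
    for _, row in df.iterrows():
        rois.append(
            SegmentROI(
                (float(row.ax), float(row.ay)),
                (float(row.bx), float(row.by)),
                float(row.half_width),
                "" if pd.isna(row.label) else str(row.label),
            )
        )
    return rois


def write_rois(rois: list[SegmentROI], path) -> None:
    rows = [
        (r.endpoint_a[0], r.endpoint_a[1], r.endpoint_b[0], r.endpoint_b[1], r.half_width, r.label)
        for r in rois
    ]
    pd.DataFrame(rows).to_csv(path, index=False, header=False)


def write_mask(mask, path) -> None:
    """Write a mask/grayscale image as TIFF with a JSON sidecar for the pixel size."""
    import json

    import tifffile

    from .simulate import MaskImage

    if isinstance(mask, MaskImage):
        data, pixel_size = mask.data.astype(np.uint8), mask.pixel_size
    else:
        raise FormatError("write_mask expects a MaskImage")
    tifffile.imwrite(path, data)
    with open(f"{path}.meta.json", "w") as fh:
        json.dump({"pixel_size_nm": pixel_size}, fh)


def read_mask(path):
    """Read a mask written by :func:`write_mask` (TIFF + pixel-size sidecar)."""
    import json

    import tifffile

    from .simulate import MaskImage

    data = tifffile.imread(path)
    with open(f"{path}.meta.json") as fh:
        meta = json.load(fh)
    return MaskImage(data.astype(bool), float(meta["pixel_size_nm"]))


def extract_segment(table: pd.DataFrame, roi: SegmentROI) -> pd.DataFrame:
    """Return localizations inside the ROI, in segment-local coordinates.

    Local x is the axial coordinate (0 at ``endpoint_a``), local y the signed
    perpendicular offset. Points are kept when ``|local y| <= half_width`` and
    ``0 <= local x <= |b - a|`` (closed intervals).
    """
    validate_localizations(table)
    a = np.asarray(roi.endpoint_a, float)
    u = roi.axis
    n = np.array([-u[1], u[0]])
    xy = table[["x_nm", "y_nm"]].to_numpy(float) - a
    t = xy @ u
    s = xy @ n
    keep = (np.abs(s) <= roi.half_width) & (t >= 0.0) & (t <= roi.length)
    out = table.loc[keep].copy()
    out["x_nm"] = t[keep]
    out["y_nm"] = s[keep]
    return out.reset_index(drop=True)
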