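"""Localization tables and image stacks: containers and file I/O.

Conventions used throughout the package:

* Coordinates are continuous positions in nanometres, in a Cartesian frame
  whose origin is the top-left corner of camera pixel (0, 0).  The centre of
  raster pixel ``(r, c)`` at pixel size ``p`` is ``((c + 0.5) p, (r + 0.5) p)``.
* Frame indices are 0-based and ranges are half-open.

Three delimited-text dialects are supported for localization tables:

``thunderstorm_csv``
    Comma-separated with bracketed units in the header
    (``"x [nm]","y [nm]","frame","intensity [photon]"``).
``rapidstorm_txt``
    Whitespace-separated values preceded by a ``#`` comment line declaring the
    columns as ``<field identifier="..." unit="..." />`` entries.  The exact
    export schema varies between versions; parsing is best-effort on the
    documented identifier prefixes (``Position-0``, ``Position-1``,
    ``ImageNumber``, ``Amplitude``).
``generic_csv``
    Case-insensitive header matching on ``x``, ``y``, ``frame``,
    ``intensity`` (optionally with bracketed units); the delimiter is sniffed
    from comma, semicolon and tab.

Dialects whose positions are in pixel units are converted to nanometres on
read using the caller-supplied pixel size.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Optional

import numpy as np
import pandas as pd
import tifffile

__all__ = [
    "FormatError",
    "LocalizationTable",
    "ImageStack",
    "read_localizations",
    "write_localizations",
    "read_image_stack",
    "write_image_stack",
]

DIALECTS = ("thunderstorm_csv", "rapidstorm_txt", "generic_csv")

#: default camera pixel size (nm) of the acquisition setup
CAMERA_PIXEL_SIZE_NM = 129.0


class FormatError(ValueError):
    """A localization/image file does not conform to its declared dialect."""


@dataclass
class LocalizationTable:
    """One record per detected single-molecule event.

    Positions are in nm; ``frame`` is a 0-based integer index; ``intensity``
    is in photons or ADU (arbitrary but consistent within a table).
    ``track_id`` is absent (``None``) until tracking has been run.
    """

    x: np.ndarray
    y: np.ndarray
    frame: np.ndarray
    intensity: np.ndarray
    track_id: Optional[np.ndarray] = None

    def __post_init__(self) -> None:
        self.x = np.asarray(self.x, dtype=float)
        self.y = np.asarray(self.y, dtype=float)
        self.frame = np.asarray(self.frame, dtype=np.int64)
        self.intensity = np.asarray(self.intensity, dtype=float)
        if self.track_id is not None:
            self.track_id = np.asarray(self.track_id, dtype=np.int64)
        n = len(self.x)
        for name in ("y", "frame", "intensity"):
            if len(getattr(self, name)) != n:
                raise ValueError(f"column {name!r} has length "
                                 f"{len(getattr(self, name))}, expected {n}")
        if self.track_id is not None and len(self.track_id) != n:
            raise ValueError("track_id length mismatch")
        if n:
            if not (np.isfinite(self.x).all() and np.isfinite(self.y).all()):
                raise ValueError("non-finite coordinates")
            if self.frame.min() < 0:
                raise ValueError("negative frame index")

    def __len__(self) -> int:
        return len(self.x)

    @property
    def n_frames(self) -> int:
        """Number of frames implied by the table (max frame + 1)."""
        return int(self.frame.max()) + 1 if len(self) else 0

    @property
    def xy(self) -> np.ndarray:
        """(n, 2) array of positions, nm."""
        return np.column_stack([self.x, self.y])

    def sort_by_frame(self) -> "LocalizationTable":
        order = np.argsort(self.frame, kind="stable")
        return self.select(order)

    def select(self, index) -> "LocalizationTable":
        """Row subset (mask or integer index array)."""
        return LocalizationTable(
            self.x[index], self.y[index], self.frame[index],
            self.intensity[index],
            None if self.track_id is None else self.track_id[index],
        )

    def with_positions(self, xy: np.ndarray) -> "LocalizationTable":
        xy = np.asarray(xy, dtype=float)
        return replace(self, x=xy[:, 0].copy(), y=xy[:, 1].copy())

    def to_dataframe(self) -> pd.DataFrame:
        data = {"x": self.x, "y": self.y, "frame": self.frame,
                "intensity": self.intensity}
        if self.track_id is not None:
            data["track_id"] = self.track_id
        return pd.DataFrame(data)

    @classmethod
    def from_dataframe(cls, df: pd.DataFrame) -> "LocalizationTable":
        return cls(
            df["x"].to_numpy(float), df["y"].to_numpy(float),
            df["frame"].to_numpy(np.int64), df["intensity"].to_numpy(float),
            df["track_id"].to_numpy(np.int64) if "track_id" in df else None,
        )

    @classmethod
    def empty(cls) -> "LocalizationTable":
        z = np.empty(0)
        return cls(z, z, z.astype(np.int64), z)

    def allclose(self, other: "LocalizationTable", tol: float = 1e-6) -> bool:
        if len(self) != len(other):
            return False
        ok = (np.allclose(self.x, other.x, atol=tol)
              and np.allclose(self.y, other.y, atol=tol)
              and np.array_equal(self.frame, other.frame)
              and np.allclose(self.intensity, other.intensity,
                              atol=tol, rtol=1e-9))
        if (self.track_id is None) != (other.track_id is None):
            return False
        if self.track_id is not None:
            ok = ok and np.array_equal(self.track_id, other.track_id)
        return bool(ok)


@dataclass
class ImageStack:
    """3-D raster (frame, row, col) with acquisition metadata."""

    pixels: np.ndarray
    pixel_size: float = CAMERA_PIXEL_SIZE_NM  # nm per pixel
    exposure_ms: Optional[float] = None

    def __post_init__(self) -> None:
        self.pixels = np.asarray(self.pixels)
        if self.pixels.ndim == 2:
            self.pixels = self.pixels[None]
        if self.pixels.ndim != 3:
            raise ValueError("pixels must be (frame, row, col)")
        if self.pixel_size <= 0:
            raise ValueError("pixel_size must be > 0")
        if self.pixels.size and np.issubdtype(self.pixels.dtype, np.floating):
            if self.pixels.min() < 0:
                raise ValueError("negative intensities in image stack")

    @property
    def n_frames(self) -> int:
        return self.pixels.shape[0]

    @property
    def frame_shape(self) -> tuple:
        return self.pixels.shape[1:]


# ---------------------------------------------------------------------------
# localization table I/O

_MANDATORY = ("x", "y", "frame")
_HEADER_RE = re.compile(r"^\s*(?P<name>.*?)\s*(?:\[(?P<unit>[^\]]*)\])?\s*$")

_RAPIDSTORM_FIELDS = {
    # identifier prefix -> (column, unit attribute written on export)
    "Position-0": ("x", "nanometer"),
    "Position-1": ("y", "nanometer"),
    "ImageNumber": ("frame", "frame"),
    "Amplitude": ("intensity", "A/D count"),
    "TrackID": ("track_id", "dimensionless"),
}

_PX_UNITS = {"px", "pixel", "pixels"}
_NM_UNITS = {"", "nm", "nanometer", "nanometers", "nanometre", "nanometres"}


def _split_header_token(token: str) -> tuple[str, str]:
    m = _HEADER_RE.match(token.strip().strip('"'))
    name = m.group("name").strip().lower()
    unit = (m.group("unit") or "").strip().lower()
    return name, unit


def _sniff_delimiter(header_line: str) -> str:
    counts = {d: header_line.count(d) for d in (",", ";", "\t")}
    best = max(counts, key=counts.get)
    return best if counts[best] > 0 else ","


def _to_nm(values: np.ndarray, unit: str, pixel_size: Optional[float],
           column: str) -> np.ndarray:
    if unit in _NM_UNITS:
        return values
    if unit in _PX_UNITS:
        if pixel_size is None:
            raise FormatError(
                f"column {column!r} is in pixel units but no pixel_size "
                "was supplied")
        return values * float(pixel_size)
    raise FormatError(f"unsupported unit {unit!r} for column {column!r}")


def _numeric(df: pd.DataFrame, col: str, path) -> np.ndarray:
    raw = df[col]
    values = pd.to_numeric(raw, errors="coerce")
    bad = values.isna() & raw.notna()
    if bad.any():
        row = int(np.flatnonzero(bad.to_numpy())[0])
        raise FormatError(
            f"{path}: unparsable value {raw.iloc[row]!r} in column "
            f"{col!r} at data row {row + 1}")
    if values.isna().any():
        row = int(np.flatnonzero(values.isna().to_numpy())[0])
        raise FormatError(f"{path}: missing value in column {col!r} "
                          f"at data row {row + 1}")
    return values.to_numpy(float)


def _assemble(df: pd.DataFrame, colmap: dict, units: dict,
              pixel_size: Optional[float], path) -> LocalizationTable:
    for col in _MANDATORY:
        if col not in colmap:
            raise FormatError(f"{path}: mandatory column {col!r} not found "
                              "in header")
    data = {}
    for col, src in colmap.items():
        values = _numeric(df, src, path)
        if col in ("x", "y"):
            values = _to_nm(values, units.get(col, ""), pixel_size, col)
        data[col] = values
    frame = data["frame"]
    if np.any(frame != np.round(frame)):
        row = int(np.flatnonzero(frame != np.round(frame))[0])
        raise FormatError(f"{path}: non-integer frame at data row {row + 1}")
    intensity = data.get("intensity", np.zeros(len(frame)))
    track = data.get("track_id")
    return LocalizationTable(
        data["x"], data["y"], frame.astype(np.int64), intensity,
        None if track is None else track.astype(np.int64))


def _read_delimited(path, delimiter: Optional[str],
                    pixel_size: Optional[float]) -> LocalizationTable:
    with open(path, "r", encoding="utf-8") as fh:
        header_line = fh.readline()
    if not header_line.strip():
        raise FormatError(f"{path}: empty file")
    sep = delimiter or _sniff_delimiter(header_line)
    df = pd.read_csv(path, sep=sep, dtype=str, skipinitialspace=True)
    colmap, units = {}, {}
    for src in df.columns:
        name, unit = _split_header_token(src)
        if name in ("x", "y", "frame", "intensity", "track_id", "id"):
            key = "track_id" if name == "id" else name
            colmap.setdefault(key, src)
            units[key] = unit
    return _assemble(df, colmap, units, pixel_size, path)


def _read_rapidstorm(path, pixel_size: Optional[float]) -> LocalizationTable:
    with open(path, "r", encoding="utf-8") as fh:
        first = fh.readline()
    if not first.startswith("#"):
        raise FormatError(f"{path}: missing rapidstorm column comment line")
    colmap, units = {}, {}
    for idx, attrs in enumerate(re.findall(r"<field\b(.*?)/?>", first)):
        ident = re.search(r'identifier="([^"]+)"', attrs)
        unit = re.search(r'unit="([^"]+)"', attrs)
        if ident is None:
            continue
        for prefix, (col, _) in _RAPIDSTORM_FIELDS.items():
            if ident.group(1).startswith(prefix):
                colmap.setdefault(col, idx)
                u = (unit.group(1).lower() if unit else "")
                units[col] = "" if u in ("frame", "a/d count",
                                         "dimensionless") else u
                break
    try:
        df = pd.read_csv(path, sep=r"\s+", comment="#", header=None,
                         dtype=str)
    except pd.errors.EmptyDataError:
        df = pd.DataFrame(columns=range(max(colmap.values(),
                                            default=-1) + 1))
    n_cols = df.shape[1] if len(df) else max(colmap.values(), default=-1) + 1
    if len(df) and max(colmap.values(), default=-1) >= n_cols:
        raise FormatError(f"{path}: header declares more fields than data "
                          "columns")
    df.columns = list(range(n_cols))
    return _assemble(df, colmap, units, pixel_size, path)


def read_localizations(path, dialect: str = "generic_csv", *,
                       pixel_size: Optional[float] = None,
                       ) -> LocalizationTable:
    """Read a localization table, returning positions in nm.

    Parameters
    ----------
    path : path-like
        Input file.
    dialect : {"thunderstorm_csv", "rapidstorm_txt", "generic_csv"}
        Table layout, see module docstring.
    pixel_size : float, optional
        nm per pixel; required when the file declares pixel-unit positions.

    Raises
    ------
    FormatError
        If a mandatory column (x, y, frame) is missing, a row is unparsable
        (the error names the row), or units cannot be resolved.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    if dialect == "rapidstorm_txt":
        return _read_rapidstorm(path, pixel_size)
    if dialect == "thunderstorm_csv":
        return _read_delimited(path, ",", pixel_size)
    if dialect == "generic_csv":
        return _read_delimited(path, None, pixel_size)
    raise ValueError(f"unknown dialect {dialect!r}; expected one of {DIALECTS}")


def write_localizations(table: LocalizationTable, path,
                        dialect: str = "generic_csv") -> None:
    """Write ``table`` so that :func:`read_localizations` round-trips it
    (coordinates to better than 1e-6 nm)."""
    path = Path(path)
    df = table.to_dataframe()
    fmt = {"x": "%.9f", "y": "%.9f", "intensity": "%.9f"}
    if dialect == "thunderstorm_csv":
        rename = {"x": "x [nm]", "y": "y [nm]", "frame": "frame",
                  "intensity": "intensity [photon]", "track_id": "track_id"}
        out = df.rename(columns=rename)
        out.to_csv(path, index=False, float_format="%.9f")
    elif dialect == "generic_csv":
        df.to_csv(path, index=False, float_format="%.9f")
    elif dialect == "rapidstorm_txt":
        order = ["x", "y", "frame", "intensity"]
        if table.track_id is not None:
            order.append("track_id")
        inverse = {col: prefix for prefix, (col, _) in
                   _RAPIDSTORM_FIELDS.items()}
        fields = []
        for col in order:
            prefix = inverse[col]
            unit = _RAPIDSTORM_FIELDS[prefix][1]
            fields.append(f'<field identifier="{prefix}-0" unit="{unit}" />')
        with open(path, "w", encoding="utf-8") as fh:
            fh.write("# " + " ".join(fields) + "\n")
            cols = []
            for col in order:
                v = df[col]
                cols.append(v.map(lambda s: format(s, ".9f"))
                            if col in fmt else v.astype(str))
            for row in zip(*cols):
                fh.write(" ".join(row) + "\n")
    else:
        raise ValueError(f"unknown dialect {dialect!r}; expected one of "
                         f"{DIALECTS}")


# ---------------------------------------------------------------------------
# image stack I/O

def read_image_stack(path, pixel_size: float = CAMERA_PIXEL_SIZE_NM,
                     exposure_ms: Optional[float] = None) -> ImageStack:
    """Read a multi-page TIFF as an :class:`ImageStack`.

    Pixel size and exposure are acquisition metadata not reliably stored in
    plain TIFF; they are supplied by the caller (camera default 129 nm).
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    with tifffile.TiffFile(path) as tf:
        shapes = {page.shape for page in tf.pages}
        if len(shapes) > 1:
            raise FormatError(
                f"{path}: non-uniform page shapes {sorted(shapes)}")
        data = tf.asarray()
    return ImageStack(data, pixel_size=pixel_size, exposure_ms=exposure_ms)


def write_image_stack(stack: ImageStack, path) -> None:
    """Write an :class:`ImageStack` as multi-page TIFF (lossless for
    integer rasters)."""
    tifffile.imwrite(path, stack.pixels, photometric="minisblack")
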