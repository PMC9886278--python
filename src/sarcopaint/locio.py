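"""Localization-table, pick-region and band-table I/O.

Coordinate convention: ``x``/``y`` are continuous camera-pixel coordinates
with the origin at the top-left pixel corner and pixel centres at
half-integers; conversion to nanometres multiplies by ``pixel_size_nm``.

On disk, localization tables follow the widespread SMLM (Picasso-style)
convention: an HDF5 file with a single structured dataset named ``locs``
carrying at least ``frame, x, y, photons, sx, sy``, accompanied by a YAML
sidecar (same basename, ``.yaml``) with ``pixel_size_nm`` and
``channel_label``.  A CSV alternative with identical columns is supported.
Pick regions are YAML lists of rotated rectangles.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import h5py
import numpy as np
import pandas as pd
import yaml

from .errors import FormatError, ValidationError

#: camera pixel pitch used throughout unless overridden (nm / pixel)
DEFAULT_PIXEL_SIZE_NM = 130.0

LOC_COLUMNS = ("frame", "x", "y", "photons", "sx", "sy")

BAND_COLUMNS = (
    "myofibril_id",
    "zdisc_id",
    "channel_label",
    "epitope_label",
    "side",
    "center_nm",
    "sigma_nm",
    "amplitude",
    "n_localizations",
)


# ---------------------------------------------------------------------------
# containers
# ---------------------------------------------------------------------------

@dataclass(eq=False)
class LocalizationTable:
    """Per-molecule detections with sub-pixel positions and PSF-fit widths.

    All planar quantities are in camera pixels; ``pixel_size_nm`` converts
    them to physical units.  ``sx``/``sy`` are the standard deviations of the
    per-spot Gaussian fit and feed the multi-emitter filter.
    """

    frame: np.ndarray
    x: np.ndarray
    y: np.ndarray
    photons: np.ndarray
    sx: np.ndarray
    sy: np.ndarray
    pixel_size_nm: float = DEFAULT_PIXEL_SIZE_NM
    channel_label: str = ""

    def __post_init__(self) -> None:
        self.frame = np.asarray(self.frame, dtype=np.int64)
        for name in ("x", "y", "photons", "sx", "sy"):
            setattr(self, name, np.asarray(getattr(self, name), dtype=np.float64))
        n = len(self.frame)
        for name in ("x", "y", "photons", "sx", "sy"):
            if len(getattr(self, name)) != n:
                raise ValidationError(f"column '{name}' has length "
                                      f"{len(getattr(self, name))}, expected {n}")
        if self.pixel_size_nm <= 0:
            raise ValidationError("pixel_size_nm must be positive")
        if n:
            bad = np.flatnonzero((self.sx <= 0) | (self.sy <= 0))
            if bad.size:
                raise ValidationError(
                    f"non-positive sx/sy at row indices {bad[:20].tolist()}")
            if np.any(self.frame < 0):
                raise ValidationError("negative frame index")
            if not (np.all(np.isfinite(self.x)) and np.all(np.isfinite(self.y))):
                raise ValidationError("non-finite x/y coordinate")

    def __len__(self) -> int:
        return len(self.frame)

    @property
    def x_nm(self) -> np.ndarray:
        return self.x * self.pixel_size_nm

    @property
    def y_nm(self) -> np.ndarray:
        return self.y * self.pixel_size_nm

    def select(self, mask_or_index: np.ndarray) -> "LocalizationTable":
        """Row subset preserving relative order and metadata."""
        return LocalizationTable(
            frame=self.frame[mask_or_index],
            x=self.x[mask_or_index],
            y=self.y[mask_or_index],
            photons=self.photons[mask_or_index],
            sx=self.sx[mask_or_index],
            sy=self.sy[mask_or_index],
            pixel_size_nm=self.pixel_size_nm,
            channel_label=self.channel_label,
        )

    def to_dataframe(self) -> pd.DataFrame:
        return pd.DataFrame({c: getattr(self, c) for c in LOC_COLUMNS})

    def equals(self, other: "LocalizationTable", atol_px: float = 1e-9) -> bool:
        if len(self) != len(other) or self.channel_label != other.channel_label:
            return False
        if abs(self.pixel_size_nm - other.pixel_size_nm) > 1e-9:
            return False
        if not np.array_equal(self.frame, other.frame):
            return False
        return all(
            np.allclose(getattr(self, c), getattr(other, c), atol=atol_px, rtol=0)
            for c in ("x", "y", "photons", "sx", "sy")
        )


def _normalize_angle(angle: float) -> float:
    """Fold an orientation into (-pi/2, pi/2]; a line has no direction."""
    a = angle % math.pi
    if a > math.pi / 2:
        a -= math.pi
    return a


@dataclass
class PickRegion:
    """Rotated rectangle selecting one myofibril.

    ``angle`` is the long-axis orientation versus +x, counter-clockwise
    positive, normalized to (-pi/2, pi/2].  ``length`` >= ``width``; a pick
    read with the two swapped is corrected with a warning.
    """

    center_x: float
    center_y: float
    length: float
    width: float
    angle: float = 0.0

    def __post_init__(self) -> None:
        if self.length <= 0 or self.width <= 0:
            raise ValidationError("pick length and width must be positive")
        if self.width > self.length:
            warnings.warn("pick width > length; swapping axes", stacklevel=2)
            self.length, self.width = self.width, self.length
            self.angle = self.angle + math.pi / 2
        self.angle = _normalize_angle(self.angle)


# ---------------------------------------------------------------------------
# localization files
# ---------------------------------------------------------------------------

def _infer_format(path: Path, format: str | None) -> str:
    if format is not None:
        return format
    suffix = path.suffix.lower()
    if suffix in (".h5", ".hdf5"):
        return "hdf5"
    if suffix in (".csv", ".txt"):
        return "csv"
    raise FormatError(f"cannot infer localization format from '{path.name}'")


def _sidecar_path(path: Path) -> Path:
    return path.with_suffix(".yaml")


def read_localizations(
    path: str | Path,
    format: str | None = None,
    pixel_size_nm: float = DEFAULT_PIXEL_SIZE_NM,
    channel_label: str | None = None,
) -> LocalizationTable:
    """Load a localization table from HDF5 (``locs`` dataset) or CSV.

    A YAML sidecar next to an HDF5 file supplies ``pixel_size_nm`` and
    ``channel_label`` and takes precedence over the arguments.  Extra
    columns (background, precision, ...) are tolerated and ignored; a
    missing required column raises :class:`FormatError` naming it.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    fmt = _infer_format(path, format)

    if fmt == "hdf5":
        with h5py.File(path, "r") as f:
            if "locs" not in f:
                raise FormatError("HDF5 file lacks a 'locs' dataset")
            locs = f["locs"][()]
        names = locs.dtype.names or ()
        for col in LOC_COLUMNS:
            if col not in names:
                raise FormatError(col)
        cols = {c: locs[c] for c in LOC_COLUMNS}
        sidecar = _sidecar_path(path)
        if sidecar.exists():
            meta = yaml.safe_load(sidecar.read_text()) or {}
            pixel_size_nm = float(meta.get("pixel_size_nm", pixel_size_nm))
            channel_label = meta.get("channel_label", channel_label)
    elif fmt == "csv":
        df = pd.read_csv(path)
        for col in LOC_COLUMNS:
            if col not in df.columns:
                raise FormatError(col)
        cols = {c: df[c].to_numpy() for c in LOC_COLUMNS}
    else:
        raise FormatError(f"unknown localization format '{fmt}'")

    return LocalizationTable(
        pixel_size_nm=pixel_size_nm,
        channel_label=channel_label or "",
        **cols,
    )


def write_localizations(
    path: str | Path, table: LocalizationTable, format: str | None = None
) -> None:
    """Write a localization table as HDF5 (+ YAML sidecar) or CSV."""
    path = Path(path)
    fmt = _infer_format(path, format)
    if fmt == "hdf5":
        dtype = np.dtype(
            [("frame", "i8"), ("x", "f8"), ("y", "f8"),
             ("photons", "f8"), ("sx", "f8"), ("sy", "f8")]
        )
        rec = np.empty(len(table), dtype=dtype)
        for c in LOC_COLUMNS:
            rec[c] = getattr(table, c)
        with h5py.File(path, "w") as f:
            f.create_dataset("locs", data=rec)
        _sidecar_path(path).write_text(
            yaml.safe_dump(
                {"pixel_size_nm": float(table.pixel_size_nm),
                 "channel_label": table.channel_label},
                sort_keys=False,
            )
        )
    elif fmt == "csv":
        table.to_dataframe().to_csv(path, index=False)
    else:
        raise FormatError(f"unknown localization format '{fmt}'")


# ---------------------------------------------------------------------------
# pick files
# ---------------------------------------------------------------------------

def _pick_from_corners(corners: Sequence[Sequence[float]]) -> PickRegion:
    pts = np.asarray(corners, dtype=float)
    if pts.shape != (4, 2):
        raise FormatError("corner picks need exactly four [x, y] points")
    center = pts.mean(axis=0)
    e1 = pts[1] - pts[0]
    e2 = pts[3] - pts[0]
    l1, l2 = np.hypot(*e1), np.hypot(*e2)
    if l1 >= l2:
        long_vec, length, width = e1, l1, l2
    else:
        long_vec, length, width = e2, l2, l1
    angle = math.atan2(long_vec[1], long_vec[0])
    return PickRegion(center_x=float(center[0]), center_y=float(center[1]),
                      length=float(length), width=float(width), angle=angle)


def read_picks(path: str | Path) -> list[PickRegion]:
    """Read a YAML list of rotated-rectangle picks, order preserved.

    Each entry is either ``{center_x, center_y, length, width, angle_rad}``
    or ``{corners: [[x, y] * 4]}`` (converted internally).
    """
    path = Path(path)
    entries = yaml.safe_load(path.read_text())
    if not isinstance(entries, list):
        raise FormatError("pick file must contain a YAML list")
    picks: list[PickRegion] = []
    for i, entry in enumerate(entries):
        try:
            if "corners" in entry:
                picks.append(_pick_from_corners(entry["corners"]))
            else:
                picks.append(
                    PickRegion(
                        center_x=float(entry["center_x"]),
                        center_y=float(entry["center_y"]),
                        length=float(entry["length"]),
                        width=float(entry["width"]),
                        angle=float(entry.get("angle_rad", 0.0)),
                    )
                )
        except (KeyError, TypeError, ValueError) as exc:
            raise FormatError(f"malformed pick entry {i}: {exc}") from exc
    return picks


def write_picks(path: str | Path, picks: Sequence[PickRegion]) -> None:
    Path(path).write_text(
        yaml.safe_dump(
            [
                {"center_x": float(p.center_x), "center_y": float(p.center_y),
                 "length": float(p.length), "width": float(p.width),
                 "angle_rad": float(p.angle)}
                for p in picks
            ],
            sort_keys=False,
        )
    )


# ---------------------------------------------------------------------------
# band tables
# ---------------------------------------------------------------------------

def validate_band_table(table: pd.DataFrame) -> None:
    for col in BAND_COLUMNS:
        if col not in table.columns:
            raise FormatError(col)
    if len(table) == 0:
        return
    if (table["sigma_nm"] <= 0).any():
        raise ValidationError("sigma_nm must be positive")
    if (table["n_localizations"] < 1).any():
        raise ValidationError("n_localizations must be >= 1")
    if not table["side"].isin(["left", "right"]).all():
        raise ValidationError("side must be 'left' or 'right'")
    key = ["myofibril_id", "zdisc_id", "channel_label", "epitope_label", "side"]
    if table.duplicated(key).any():
        raise ValidationError("duplicate (zdisc, channel, epitope, side) rows")


def write_band_table(path: str | Path, table: pd.DataFrame) -> None:
    """Write fitted bands as CSV; nm floats keep >= 3 decimal places."""
    validate_band_table(table)
    table.to_csv(path, index=False, columns=list(BAND_COLUMNS),
                 float_format="%.6f")


def read_band_table(path: str | Path) -> pd.DataFrame:
    table = pd.read_csv(Path(path))
    validate_band_table(table)
    return table
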