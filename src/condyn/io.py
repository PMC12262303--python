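"""Trajectory tables and mask images.

The tracking-CSV dialect follows the conventions of common spot-tracking
exporters (TrackMate in particular): one row per localization with columns
for track id, frame index, x, y and an optional quality score, preceded by
up to three non-numeric sub-header rows (column names / units / shorthand)
which are auto-detected and skipped.

Conventions fixed here once, to avoid off-by-half errors downstream:
coordinates are pixel-centered with the origin at the top-left corner,
x increasing rightward and y downward; frame indices are 0-based; pixel
coordinates convert to micrometres as ``x_um = x_px * pixel_size_nm / 1000``.
"""
from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
import tifffile
import yaml

from .errors import FormatError, InvalidParameterError

logger = logging.getLogger(__name__)

#: Default column mapping: TrackMate "spots" export dialect.
DEFAULT_COLUMNS = {
    "track_id": "TRACK_ID",
    "frame": "FRAME",
    "x": "POSITION_X",
    "y": "POSITION_Y",
    "quality": "QUALITY",
}


@dataclass(frozen=True)
class AcquisitionMeta:
    """Physical calibration of an acquisition.

    Parameters
    ----------
    pixel_size : float
        Camera pixel size in nm/pixel.
    frame_rate : float
        Acquisition frequency in Hz; the frame interval is ``1 / frame_rate``.
    """

    pixel_size: float
    frame_rate: float

    def __post_init__(self) -> None:
        if not (self.pixel_size > 0):
            raise InvalidParameterError(f"pixel_size must be > 0, got {self.pixel_size}")
        if not (self.frame_rate > 0):
            raise InvalidParameterError(f"frame_rate must be > 0, got {self.frame_rate}")

    @property
    def dt(self) -> float:
        """Frame interval in seconds."""
        return 1.0 / self.frame_rate


@dataclass(frozen=True)
class Trajectory:
    """One particle's time-ordered 2D positions in physical units.

    Attributes
    ----------
    track_id : str or int
        Identifier of the track.
    frames : ndarray of int
        Strictly increasing 0-based frame indices. Gaps are retained: a
        missed detection leaves a hole in ``frames`` and time lags computed
        downstream honour the true elapsed time.
    x, y : ndarray of float
        Positions in micrometres.
    dt : float
        Frame interval in seconds (constant within a trajectory).
    quality : ndarray or None
        Optional per-localization quality score (arbitrary units).
    """

    track_id: object
    frames: np.ndarray
    x: np.ndarray
    y: np.ndarray
    dt: float
    quality: np.ndarray | None = None

    def __post_init__(self) -> None:
        frames = np.asarray(self.frames, dtype=np.int64)
        x = np.asarray(self.x, dtype=float)
        y = np.asarray(self.y, dtype=float)
        object.__setattr__(self, "frames", frames)
        object.__setattr__(self, "x", x)
        object.__setattr__(self, "y", y)
        if self.quality is not None:
            object.__setattr__(self, "quality", np.asarray(self.quality, dtype=float))
        if len(frames) < 2:
            raise InvalidParameterError(
                f"track {self.track_id!r}: a trajectory needs >= 2 localizations"
            )
        if not (len(frames) == len(x) == len(y)):
            raise InvalidParameterError(f"track {self.track_id!r}: field lengths differ")
        if np.any(np.diff(frames) <= 0):
            raise FormatError(f"track {self.track_id!r}: frames are not strictly increasing")
        if not (np.all(np.isfinite(x)) and np.all(np.isfinite(y))):
            raise InvalidParameterError(f"track {self.track_id!r}: non-finite positions")
        if not (self.dt > 0):
            raise InvalidParameterError(f"dt must be > 0, got {self.dt}")

    def __len__(self) -> int:
        return len(self.frames)

    @property
    def times(self) -> np.ndarray:
        """Acquisition times in seconds (``frames * dt``)."""
        return self.frames * self.dt

    @property
    def positions(self) -> np.ndarray:
        """(N, 2) array of positions in micrometres."""
        return np.column_stack([self.x, self.y])

    def slice_frames(self, start: int, stop: int) -> "Trajectory":
        """Sub-trajectory with frame indices in ``[start, stop]`` (inclusive)."""
        keep = (self.frames >= start) & (self.frames <= stop)
        return replace(
            self,
            frames=self.frames[keep],
            x=self.x[keep],
            y=self.y[keep],
            quality=None if self.quality is None else self.quality[keep],
        )


def _detect_subheader_rows(path, sep: str = ",", max_check: int = 5) -> int:
    """Count leading rows (after the header) whose frame/x fields are non-numeric.

    TrackMate prepends up to three such rows (readable names, units, shorthand).
    """
    head = pd.read_csv(path, sep=sep, nrows=max_check, dtype=str)
    n_skip = 0
    for _, row in head.iterrows():
        numeric = True
        for v in row.values:
            if v is None or (isinstance(v, float) and np.isnan(v)):
                continue
            try:
                float(v)
            except (TypeError, ValueError):
                numeric = False
                break
        if numeric:
            break
        n_skip += 1
    return n_skip


def read_tracking_csv(
    path,
    meta: AcquisitionMeta,
    units_in: str = "pixel",
    columns: dict | None = None,
    drop_gapped: bool = False,
) -> list[Trajectory]:
    """Read a tracking CSV into a list of :class:`Trajectory`.

    Parameters
    ----------
    path : path-like
        CSV file with at least track-id, frame, x and y columns.
    meta : AcquisitionMeta
        Pixel size (nm) and frame rate (Hz) of the acquisition.
    units_in : {"pixel", "um"}
        Units of the x/y columns. Pixel inputs are converted to micrometres
        via ``pixel_size``.
    columns : dict, optional
        Override of the column mapping (keys: track_id, frame, x, y, quality).
    drop_gapped : bool
        If True, tracks with missing frames are dropped instead of retained.

    Returns
    -------
    list of Trajectory
        One per track id with >= 2 rows; single-row tracks are dropped and
        their count logged.
    """
    if units_in not in ("pixel", "um"):
        raise InvalidParameterError(f"units_in must be 'pixel' or 'um', got {units_in!r}")
    colmap = dict(DEFAULT_COLUMNS)
    if columns:
        colmap.update(columns)

    n_skip = _detect_subheader_rows(path)
    df = pd.read_csv(path, skiprows=range(1, 1 + n_skip) if n_skip else None)
    for key in ("track_id", "frame", "x", "y"):
        if colmap[key] not in df.columns:
            raise FormatError(f"required column {colmap[key]!r} ({key}) missing from {path}")
    has_quality = colmap["quality"] in df.columns

    if df.empty:
        logger.warning("%s: empty data section, returning no trajectories", path)
        return []

    scale = meta.pixel_size / 1000.0 if units_in == "pixel" else 1.0
    dt = meta.dt
    trajectories: list[Trajectory] = []
    n_dropped_short = 0
    n_dropped_gapped = 0
    for track_id, grp in df.groupby(colmap["track_id"], sort=True):
        grp = grp.sort_values(colmap["frame"])
        frames = grp[colmap["frame"]].to_numpy(dtype=np.int64)
        if len(frames) < 2:
            n_dropped_short += 1
            continue
        if np.any(np.diff(frames) <= 0):
            raise FormatError(f"track {track_id!r}: non-monotone frames")
        if drop_gapped and np.any(np.diff(frames) != 1):
            n_dropped_gapped += 1
            continue
        trajectories.append(
            Trajectory(
                track_id=track_id,
                frames=frames,
                x=grp[colmap["x"]].to_numpy(dtype=float) * scale,
                y=grp[colmap["y"]].to_numpy(dtype=float) * scale,
                dt=dt,
                quality=grp[colmap["quality"]].to_numpy(dtype=float) if has_quality else None,
            )
        )
    if n_dropped_short:
        logger.info("%s: dropped %d single-row tracks", path, n_dropped_short)
    if n_dropped_gapped:
        logger.info("%s: dropped %d gapped tracks", path, n_dropped_gapped)
    return trajectories


def write_tracking_csv(trajectories: list[Trajectory], path) -> None:
    """Write trajectories in the package's tracking-CSV dialect (positions in um).

    Round-trips through :func:`read_tracking_csv` (``units_in="um"``) to
    <= 1e-9 um.
    """
    rows = []
    for t in trajectories:
        for i in range(len(t)):
            row = {
                "TRACK_ID": t.track_id,
                "FRAME": int(t.frames[i]),
                "POSITION_X": repr(float(t.x[i])),
                "POSITION_Y": repr(float(t.y[i])),
            }
            if t.quality is not None:
                row["QUALITY"] = repr(float(t.quality[i]))
            rows.append(row)
    cols = ["TRACK_ID", "FRAME", "POSITION_X", "POSITION_Y"]
    if any(t.quality is not None for t in trajectories):
        cols.append("QUALITY")
    pd.DataFrame(rows, columns=cols).to_csv(path, index=False)


@dataclass(frozen=True)
class MaskImage:
    """A binary segmentation mask with attached physical scale."""

    data: np.ndarray  # bool, True = foreground
    pixel_size: float  # nm/pixel

    @property
    def extent_um(self) -> tuple[float, float]:
        """(width, height) of the field of view in micrometres."""
        h, w = self.data.shape
        return (w * self.pixel_size / 1000.0, h * self.pixel_size / 1000.0)


def read_mask_tiff(path, pixel_size: float) -> MaskImage:
    """Read a single-page integer TIFF as a binary mask; nonzero = foreground."""
    if not (pixel_size > 0):
        raise InvalidParameterError(f"pixel_size must be > 0, got {pixel_size}")
    img = tifffile.imread(path)
    if img.ndim != 2:
        raise FormatError(f"{path}: expected a 2D single-page image, got shape {img.shape}")
    if not np.issubdtype(img.dtype, np.integer) and img.dtype != bool:
        raise FormatError(f"{path}: expected an integer or boolean image, got {img.dtype}")
    return MaskImage(data=img != 0, pixel_size=pixel_size)


def load_config(path) -> dict:
    """Load a YAML config holding a column map and/or AcquisitionMeta fields."""
    with open(path) as fh:
        cfg = yaml.safe_load(fh) or {}
    if not isinstance(cfg, dict):
        raise FormatError(f"{path}: config must be a mapping")
    return cfg
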