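"""Accessibility mapping, boundary geometry, colocalization and
Stokes-Einstein transforms.

Space accessible to mobile probe particles is reconstructed as a density
map of trajectory-representative localizations on a fine grid (default
58.5 nm, half the 117 nm camera pixel). Membrane boundaries come from
binary segmentation masks: contours are traced at sub-pixel (half-pixel
marching-squares) resolution and distances are measured to contour
segments, not vertices, because distances of interest (~100 nm) are
comparable to the pixel size. Containment uses the even-odd rule with
on-contour points counted as inside (a condensate centre sitting on the
membrane trace is membrane-associated).

The Stokes-Einstein relation D = k_B T / (6 pi eta r) links the diffusion
coefficient of an inert spherical probe of radius r to the viscosity eta
of the surrounding medium; both directions are provided and are exact
inverses. Default temperature is 310.15 K (37 degrees C live-cell imaging).
"""
from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
from shapely.geometry import LineString, Point, Polygon
from skimage import filters, measure

from .classify import MOBILE, ClassifierConfig, classify_immobile
from .errors import InvalidParameterError, UndefinedDistanceError
from .io import MaskImage, Trajectory

logger = logging.getLogger(__name__)

K_B = 1.380649e-23  # J/K
DEFAULT_TEMPERATURE = 310.15  # K, 37 degrees C

# Unit table: single point of truth for the conversions this module mixes.
UM_PER_NM = 1e-3
M_PER_UM = 1e-6
M_PER_NM = 1e-9
M2_PER_UM2 = 1e-12


@dataclass(frozen=True)
class BoundarySet:
    """Contour polylines extracted from a segmentation mask.

    Vertices are (x, y) in micrometres; ``closed[i]`` says whether contour
    i is a ring; ``is_hole[i]`` whether it bounds a hole (background
    enclosed by foreground). Containment queries use the even-odd rule over
    closed contours, so holes are handled without special-casing.
    """

    contours: tuple[np.ndarray, ...]  # each (N, 2) of x, y in um
    closed: tuple[bool, ...]
    is_hole: tuple[bool, ...]
    pixel_size: float  # nm/pixel of the source mask

    def __len__(self) -> int:
        return len(self.contours)


@dataclass(frozen=True)
class DensityMap:
    """Grid of trajectory-representative localization counts."""

    origin: tuple[float, float]  # um, lower (x, y) corner of cell (0, 0)
    spacing: float  # nm
    counts: np.ndarray  # (ny, nx) non-negative ints
    rule: str  # "trajectory-mean" or "per-frame"

    @property
    def total(self) -> int:
        return int(self.counts.sum())


@dataclass(frozen=True)
class ColocalizationResult:
    """Thresholded Manders' coefficients M1 and M2.

    M1 is the fraction of channel-1 foreground intensity that lies where
    channel 2 is also above threshold (and symmetrically M2); both in
    [0, 1]. An all-background channel leaves the corresponding coefficient
    undefined (NaN), not 0.
    """

    m1: float
    m2: float
    threshold1: float
    threshold2: float


@dataclass(frozen=True)
class ViscosityEstimate:
    """Stokes-Einstein viscosity from a probe diffusion coefficient."""

    viscosity: float  # Pa s
    D: float  # um^2/s
    radius: float  # nm
    temperature: float  # K


def density_map(
    trajectories: list[Trajectory],
    spacing: float = 58.5,
    rule: str = "trajectory-mean",
    origin: tuple[float, float] | None = None,
    shape: tuple[int, int] | None = None,
) -> DensityMap:
    """Bin trajectory-representative points on a regular grid.

    Parameters
    ----------
    spacing : float
        Grid cell size in nm (58.5 nm = half a 117 nm camera pixel by
        default, giving 2x2 grid cells per pixel).
    rule : {"trajectory-mean", "per-frame"}
        "trajectory-mean" bins one representative (the mean position) per
        trajectory — the accessibility-map readout for fast probes;
        "per-frame" bins every localization.
    origin, shape : optional
        Fix the grid instead of deriving it from the data. Cells are
        half-open ``[edge, edge + spacing)``: a point exactly on an edge
        belongs to the higher cell.
    """
    if not trajectories:
        raise InvalidParameterError("need at least one trajectory")
    if not (spacing > 0):
        raise InvalidParameterError(f"spacing must be > 0, got {spacing}")
    if rule == "trajectory-mean":
        pts = np.array([[t.x.mean(), t.y.mean()] for t in trajectories])
    elif rule == "per-frame":
        pts = np.vstack([t.positions for t in trajectories])
    else:
        raise InvalidParameterError(f"unknown rule {rule!r}")
    sp_um = spacing * UM_PER_NM
    if origin is None:
        origin = (
            float(np.floor(pts[:, 0].min() / sp_um) * sp_um),
            float(np.floor(pts[:, 1].min() / sp_um) * sp_um),
        )
    ix = np.floor((pts[:, 0] - origin[0]) / sp_um).astype(int)
    iy = np.floor((pts[:, 1] - origin[1]) / sp_um).astype(int)
    if shape is None:
        shape = (int(iy.max()) + 1, int(ix.max()) + 1)
    counts = np.zeros(shape, dtype=np.int64)
    keep = (ix >= 0) & (ix < shape[1]) & (iy >= 0) & (iy < shape[0])
    if not keep.all():
        logger.warning("density_map: %d representatives fall outside the grid",
                       int(np.sum(~keep)))
    np.add.at(counts, (iy[keep], ix[keep]), 1)
    return DensityMap(origin=origin, spacing=spacing, counts=counts, rule=rule)


def extract_boundaries(mask: MaskImage) -> BoundarySet:
    """Trace foreground-component borders of a binary mask at sub-pixel
    resolution.

    Uses marching squares at the 0.5 iso-level, so vertices interpolate
    half-way between foreground and background pixel centres. Vertices are
    converted to micrometres with the mask's pixel size (pixel-centred
    coordinates, origin top-left). Holes appear as separate contours,
    flagged by winding orientation. An empty mask yields an empty set.
    """
    arr = mask.data.astype(float)
    if not mask.data.any():
        return BoundarySet(contours=(), closed=(), is_hole=(), pixel_size=mask.pixel_size)
    # pad so foreground touching the image border still yields closed rings
    padded = np.pad(arr, 1, constant_values=0.0)
    raw = measure.find_contours(padded, 0.5, positive_orientation="high")
    scale = mask.pixel_size * UM_PER_NM
    contours, closed, holes = [], [], []
    for c in raw:
        rc = c - 1.0  # undo padding
        xy = np.column_stack([rc[:, 1], rc[:, 0]]) * scale
        is_closed = bool(np.allclose(xy[0], xy[-1]))
        # shoelace signed area; in image coordinates (y down) with
        # positive_orientation="high", outer foreground borders come out
        # with negative signed area and hole borders positive
        x, y = xy[:, 0], xy[:, 1]
        signed = 0.5 * float(np.sum(x[:-1] * y[1:] - x[1:] * y[:-1]))
        contours.append(xy)
        closed.append(is_closed)
        holes.append(is_closed and signed > 0)
    return BoundarySet(
        contours=tuple(contours), closed=tuple(closed), is_hole=tuple(holes),
        pixel_size=mask.pixel_size,
    )


_ON_CONTOUR_TOL_UM = 1e-9


def point_in_boundary(point: tuple[float, float], boundaries: BoundarySet) -> str:
    """Even-odd containment of a point (um) in a boundary set.

    Returns ``"inside"`` or ``"outside"``. Points exactly on a contour
    count as inside. If the set has no closed contour every point is
    outside (with a warning).
    """
    closed_polys = [
        Polygon(c) for c, cl in zip(boundaries.contours, boundaries.closed) if cl
    ]
    if not closed_polys:
        logger.warning("point_in_boundary: no closed contours; everything is outside")
        return "outside"
    p = Point(point)
    crossings = 0
    for poly in closed_polys:
        if poly.exterior.distance(p) <= _ON_CONTOUR_TOL_UM:
            return "inside"
        if poly.contains(p):
            crossings += 1
    return "inside" if crossings % 2 == 1 else "outside"


def distance_to_boundary(point: tuple[float, float], boundaries: BoundarySet) -> float:
    """Minimal Euclidean distance (nm) from a point (um) to any contour segment."""
    if len(boundaries) == 0:
        raise UndefinedDistanceError("distance to an empty boundary set is undefined")
    p = Point(point)
    d_um = min(LineString(c).distance(p) for c in boundaries.contours)
    return d_um / UM_PER_NM


def center_of_trajectory(traj: Trajectory, interval: float = 50.0) -> tuple[float, float]:
    """Mean position (um) over the first ``interval`` seconds of a trajectory.

    Restricting to a fixed early interval limits photobleaching bias for
    long acquisitions. If the trajectory is shorter than the interval the
    full span is used with a warning.
    """
    if not (interval > 0):
        raise InvalidParameterError(f"interval must be > 0, got {interval}")
    rel_t = (traj.frames - traj.frames[0]) * traj.dt
    if rel_t[-1] < interval:
        logger.warning(
            "track %r spans %.1f s < interval %.1f s; using full span",
            traj.track_id, rel_t[-1], interval,
        )
        sel = slice(None)
    else:
        sel = rel_t <= interval
    return (float(np.mean(traj.x[sel])), float(np.mean(traj.y[sel])))


def manders_coefficients(
    img1: np.ndarray,
    img2: np.ndarray,
    threshold_policy="otsu",
) -> ColocalizationResult:
    """Thresholded Manders' overlap coefficients of two channels.

    ``M1 = sum img1 over (img1 > t1 and img2 > t2) / sum img1 over (img1 > t1)``
    and symmetrically M2. ``threshold_policy`` is ``"otsu"`` (per-channel
    automatic foreground threshold), ``"zero"`` (foreground = strictly
    positive), or an explicit ``(t1, t2)`` pair. A channel with no
    foreground leaves its coefficient NaN.
    """
    img1 = np.asarray(img1, dtype=float)
    img2 = np.asarray(img2, dtype=float)
    if img1.shape != img2.shape:
        raise InvalidParameterError("channel images must have equal shapes")
    if threshold_policy == "otsu":
        t1 = filters.threshold_otsu(img1) if img1.max() > img1.min() else np.inf
        t2 = filters.threshold_otsu(img2) if img2.max() > img2.min() else np.inf
    elif threshold_policy == "zero":
        t1 = t2 = 0.0
    else:
        t1, t2 = threshold_policy
    fg1 = img1 > t1
    fg2 = img2 > t2
    denom1 = float(img1[fg1].sum())
    denom2 = float(img2[fg2].sum())
    m1 = float(img1[fg1 & fg2].sum() / denom1) if denom1 > 0 else float("nan")
    m2 = float(img2[fg1 & fg2].sum() / denom2) if denom2 > 0 else float("nan")
    return ColocalizationResult(m1=m1, m2=m2, threshold1=float(t1), threshold2=float(t2))


def estimate_viscosity(
    D: float, r: float, T: float = DEFAULT_TEMPERATURE
) -> ViscosityEstimate:
    """Stokes-Einstein viscosity (Pa s) from a probe diffusion coefficient.

    ``eta = k_B T / (6 pi D r)`` with D in um^2/s and probe radius r in nm.
    """
    if not (D > 0 and r > 0 and T > 0):
        raise InvalidParameterError("D, r and T must all be > 0")
    eta = K_B * T / (6.0 * np.pi * (D * M2_PER_UM2) * (r * M_PER_NM))
    return ViscosityEstimate(viscosity=float(eta), D=D, radius=r, temperature=T)


def predict_diffusion(r: float, eta: float, T: float = DEFAULT_TEMPERATURE) -> float:
    """Theoretical Stokes-Einstein diffusion coefficient (um^2/s).

    ``D = k_B T / (6 pi eta r)`` for probe radius r (nm) in a medium of
    viscosity eta (Pa s). Exact inverse of :func:`estimate_viscosity`.
    """
    if not (r > 0 and eta > 0 and T > 0):
        raise InvalidParameterError("r, eta and T must all be > 0")
    return float(K_B * T / (6.0 * np.pi * eta * (r * M_PER_NM)) / M2_PER_UM2)


def boundary_records(boundaries: BoundarySet) -> list[dict]:
    """GeoJSON-style polygon/polyline records of a boundary set (um units)."""
    records = []
    for c, closed, hole in zip(boundaries.contours, boundaries.closed,
                               boundaries.is_hole):
        records.append({
            "type": "Polygon" if closed else "LineString",
            "coordinates": [[float(x), float(y)] for x, y in c],
            "closed": closed,
            "is_hole": hole,
            "pixel_size_nm": boundaries.pixel_size,
        })
    return records


def mobile_fraction(
    trajectories: list[Trajectory], cfg: ClassifierConfig = ClassifierConfig()
) -> dict:
    """Fraction of trajectories classified mobile, with counts."""
    if not trajectories:
        raise InvalidParameterError("empty trajectory set")
    n_mobile = sum(1 for t in trajectories if classify_immobile(t, cfg) == MOBILE)
    return {
        "fraction": n_mobile / len(trajectories),
        "n_mobile": n_mobile,
        "n_total": len(trajectories),
    }
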