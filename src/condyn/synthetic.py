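"""Synthetic trajectories, masks and image stacks with known ground truth.

Every downstream stage of the pipeline (diffusion profiling, event
detection, spatial analysis) is tested against data from this module,
because the motions it emulates have closed-form statistics:

* Brownian motion — independent Gaussian increments, ensemble
  MSD(tau) = 4 D tau in 2D.
* Fractional Brownian motion (fBm) — stationary-increment Gaussian process
  with Hurst index H = alpha/2, scaled so MSD(tau) = 4 D tau^alpha; the
  model for sub-diffusive (alpha < 1) and super-diffusive (alpha > 1)
  regimes.
* Tethered motion — per-axis Ornstein-Uhlenbeck (OU) relaxation about an
  anchor with stationary standard deviation sigma_c; ensemble
  MSD(tau) = 4 sigma_c^2 (1 - exp(-tau / relaxation_time)), plateauing at
  4 sigma_c^2. This emulates constrained (tether-limited, not corralled)
  diffusion of membrane-attached condensates.
* Directed runs — constant-velocity translocation (~0.1-0.3 um/s, the
  motor-protein range) with optional Brownian jitter.

Reproducibility contract: every generator is deterministic given
(seed, parameters). A single global seed expands to per-trajectory
sub-seeds through ``numpy.random.SeedSequence(seed).spawn(n)``, so
trajectory i of a batch is identical no matter the batch size.

fBm synthesis uses exact covariance factorization of the fractional
Gaussian noise, which is O(n^2) memory and O(n^3) time — exactness over
speed, intended for trajectories up to a few thousand frames.
"""
from __future__ import annotations

import logging
from dataclasses import dataclass, field
from functools import lru_cache

import numpy as np
from scipy import ndimage

from .errors import InvalidParameterError
from .io import Trajectory

logger = logging.getLogger(__name__)

STATE_NAMES = ("brownian", "subdiffusive", "tethered", "directed")


@dataclass(frozen=True)
class NoiseModel:
    """Static localization error, i.i.d. Gaussian per axis per frame.

    sigma_loc is the per-axis standard deviation in nm (16 nm is a typical
    static localization error for immobilized single emitters).
    """

    sigma_loc: float = 16.0

    def __post_init__(self) -> None:
        if self.sigma_loc < 0:
            raise InvalidParameterError(f"sigma_loc must be >= 0, got {self.sigma_loc}")


@dataclass
class MotionGroundTruth:
    """Per-frame generating state and parameters of a synthetic trajectory.

    ``states`` labels every frame exactly once (frame 0 carries the label of
    the first segment; frame k > 0 carries the label of the segment that
    generated the step into it). ``params`` records the generating
    parameters per segment.
    """

    states: np.ndarray  # dtype '<U12', one label per frame
    params: list[dict] = field(default_factory=list)
    seed: int | None = None

    def __post_init__(self) -> None:
        self.states = np.asarray(self.states)
        bad = set(np.unique(self.states)) - set(STATE_NAMES)
        if bad:
            raise InvalidParameterError(f"unknown state labels {sorted(bad)}")


def _rng(seed) -> np.random.Generator:
    return np.random.default_rng(seed)


def spawn_seeds(seed: int, n: int) -> list[np.random.SeedSequence]:
    """Expand a single global seed into ``n`` independent per-trajectory seeds."""
    return np.random.SeedSequence(seed).spawn(n)


def _make_traj(x, y, dt, track_id=0) -> Trajectory:
    n = len(x)
    return Trajectory(track_id=track_id, frames=np.arange(n), x=x, y=y, dt=dt)


def simulate_brownian(
    n_frames: int,
    D_gen: float,
    dt: float,
    start: tuple[float, float] = (0.0, 0.0),
    seed=0,
    track_id=0,
) -> tuple[Trajectory, MotionGroundTruth]:
    """Simulate 2D Brownian motion.

    Increments are independent Gaussian with per-axis variance ``2 D dt``,
    so the ensemble time-averaged MSD converges to ``4 D tau``.
    """
    if n_frames < 2:
        raise InvalidParameterError(f"n_frames must be >= 2, got {n_frames}")
    if not (D_gen > 0):
        raise InvalidParameterError(f"D_gen must be > 0, got {D_gen}")
    if not (dt > 0):
        raise InvalidParameterError(f"dt must be > 0, got {dt}")
    rng = _rng(seed)
    sigma = np.sqrt(2.0 * D_gen * dt)
    steps = rng.normal(0.0, sigma, size=(n_frames - 1, 2))
    pos = np.vstack([np.asarray(start, dtype=float), steps]).cumsum(axis=0)
    gt = MotionGroundTruth(
        states=np.full(n_frames, "brownian"),
        params=[{"state": "brownian", "D_gen": D_gen, "dt": dt}],
        seed=seed if isinstance(seed, int) else None,
    )
    return _make_traj(pos[:, 0], pos[:, 1], dt, track_id), gt


@lru_cache(maxsize=4)
def _fgn_cholesky(n_steps: int, alpha: float, D_gen: float, dt: float) -> np.ndarray:
    """Lower Cholesky factor of the fractional-Gaussian-noise covariance.

    The increment process has per-axis variance 2 D dt^alpha at lag 1 and
    autocovariance gamma(k) = D dt^alpha (|k+1|^a - 2|k|^a + |k-1|^a)
    with a = alpha (= 2H), which makes the per-axis positional MSD exactly
    2 D tau^alpha and the 2D MSD 4 D tau^alpha.
    """
    k = np.arange(n_steps, dtype=float)
    gamma = D_gen * dt**alpha * (
        np.abs(k + 1) ** alpha - 2 * np.abs(k) ** alpha + np.abs(k - 1) ** alpha
    )
    cov = gamma[np.abs(np.subtract.outer(np.arange(n_steps), np.arange(n_steps)))]
    try:
        return np.linalg.cholesky(cov)
    except np.linalg.LinAlgError:
        # near-singular at alpha -> 2: fall back to symmetric eigen square root
        w, v = np.linalg.eigh(cov)
        w = np.clip(w, 0.0, None)
        return v * np.sqrt(w)


def simulate_fbm(
    n_frames: int,
    alpha_gen: float,
    D_gen: float,
    dt: float,
    start: tuple[float, float] = (0.0, 0.0),
    seed=0,
    track_id=0,
) -> tuple[Trajectory, MotionGroundTruth]:
    """Simulate 2D fractional Brownian motion with ensemble MSD = 4 D tau^alpha.

    Increments are fractional Gaussian noise with Hurst index
    ``alpha_gen / 2``, synthesized by exact covariance factorization
    (O(n^3); intended for trajectories up to a few thousand frames).
    ``alpha_gen = 1`` reduces to :func:`simulate_brownian` statistics;
    ``alpha_gen = 2`` is ballistic (perfectly correlated increments).
    """
    if n_frames < 2:
        raise InvalidParameterError(f"n_frames must be >= 2, got {n_frames}")
    if not (0 < alpha_gen <= 2):
        raise InvalidParameterError(f"alpha_gen must be in (0, 2], got {alpha_gen}")
    if not (D_gen > 0):
        raise InvalidParameterError(f"D_gen must be > 0, got {D_gen}")
    if not (dt > 0):
        raise InvalidParameterError(f"dt must be > 0, got {dt}")
    rng = _rng(seed)
    n_steps = n_frames - 1
    z = rng.standard_normal(size=(n_steps, 2))
    if alpha_gen == 1.0:
        # fGn covariance is diagonal: exactly independent Brownian steps
        steps = np.sqrt(2.0 * D_gen * dt) * z
    elif alpha_gen == 2.0:
        # ballistic limit: one Gaussian velocity per axis, shared by all steps
        sigma = np.sqrt(2.0 * D_gen * dt**2)
        steps = np.broadcast_to(sigma * z[:1], (n_steps, 2))
    else:
        L = _fgn_cholesky(n_steps, alpha_gen, D_gen, dt)
        steps = L @ z
    pos = np.vstack([np.asarray(start, dtype=float), steps]).cumsum(axis=0)
    gt = MotionGroundTruth(
        states=np.full(n_frames, "subdiffusive" if alpha_gen < 1 else "brownian"),
        params=[{"state": "fbm", "alpha_gen": alpha_gen, "D_gen": D_gen, "dt": dt}],
        seed=seed if isinstance(seed, int) else None,
    )
    return _make_traj(pos[:, 0], pos[:, 1], dt, track_id), gt


def _ou_segment(rng, n_steps, start, anchor, relaxation_time, sigma_c, dt):
    """Exact-transition-density OU path of n_steps steps from ``start``."""
    phi = np.exp(-dt / relaxation_time)
    innov_sd = sigma_c * np.sqrt(1.0 - phi**2)
    pos = np.empty((n_steps + 1, 2))
    pos[0] = start
    anchor = np.asarray(anchor, dtype=float)
    for i in range(n_steps):
        pos[i + 1] = anchor + phi * (pos[i] - anchor) + innov_sd * rng.standard_normal(2)
    return pos


def simulate_tethered(
    n_frames: int,
    anchor: tuple[float, float],
    relaxation_time: float,
    sigma_c: float,
    dt: float,
    seed=0,
    track_id=0,
) -> tuple[Trajectory, MotionGroundTruth]:
    """Simulate tether-constrained motion as a per-axis OU process.

    Uses the exact OU transition density (not an Euler scheme), initialized
    at stationarity, so the ensemble MSD is exactly
    ``4 sigma_c^2 (1 - exp(-tau / relaxation_time))`` with plateau
    ``4 sigma_c^2``.
    """
    if n_frames < 2:
        raise InvalidParameterError(f"n_frames must be >= 2, got {n_frames}")
    if not (relaxation_time > 0):
        raise InvalidParameterError(f"relaxation_time must be > 0, got {relaxation_time}")
    if not (sigma_c > 0):
        raise InvalidParameterError(f"sigma_c must be > 0, got {sigma_c}")
    if not (dt > 0):
        raise InvalidParameterError(f"dt must be > 0, got {dt}")
    rng = _rng(seed)
    anchor = np.asarray(anchor, dtype=float)
    start = anchor + sigma_c * rng.standard_normal(2)  # stationary initial condition
    pos = _ou_segment(rng, n_frames - 1, start, anchor, relaxation_time, sigma_c, dt)
    gt = MotionGroundTruth(
        states=np.full(n_frames, "tethered"),
        params=[{
            "state": "tethered", "anchor": tuple(anchor),
            "relaxation_time": relaxation_time, "sigma_c": sigma_c, "dt": dt,
        }],
        seed=seed if isinstance(seed, int) else None,
    )
    return _make_traj(pos[:, 0], pos[:, 1], dt, track_id), gt


def simulate_switching(
    schedule: list[tuple[str, float, dict]],
    dt: float,
    start: tuple[float, float] = (0.0, 0.0),
    seed=0,
    track_id=0,
) -> tuple[Trajectory, MotionGroundTruth]:
    """Simulate mode-switching motion from a (state, duration_s, params) schedule.

    Position is continuous across switches. Segment i contributes
    ``round(duration / dt)`` steps; frame 0 carries the first segment's
    label and each later frame the label of the segment generating the step
    into it. Directed segments move at constant velocity ``v`` (um/s) along
    ``direction`` (unit vector, default +x) plus optional Brownian jitter
    ``D_jitter`` (default 0, i.e. clean geometry). Tethered segments anchor
    at the segment's start position unless ``anchor`` is given.
    """
    if not schedule:
        raise InvalidParameterError("schedule must be non-empty")
    if not (dt > 0):
        raise InvalidParameterError(f"dt must be > 0, got {dt}")
    rng = _rng(seed)
    pos_chunks = [np.asarray(start, dtype=float)[None, :]]
    labels = []
    params_log = []
    current = np.asarray(start, dtype=float)
    first = True
    for state, duration, p in schedule:
        if state not in STATE_NAMES:
            raise InvalidParameterError(f"unknown state {state!r}; expected one of {STATE_NAMES}")
        if not (duration > 0):
            raise InvalidParameterError(f"segment duration must be > 0, got {duration}")
        n_steps = max(1, int(round(duration / dt)))
        p = dict(p)
        if state == "brownian":
            sigma = np.sqrt(2.0 * p["D_gen"] * dt)
            steps = rng.normal(0.0, sigma, size=(n_steps, 2))
            seg = current + steps.cumsum(axis=0)
        elif state == "subdiffusive":
            L = _fgn_cholesky(n_steps, p["alpha_gen"], p["D_gen"], dt)
            steps = L @ rng.standard_normal(size=(n_steps, 2))
            seg = current + steps.cumsum(axis=0)
        elif state == "tethered":
            anchor = np.asarray(p.get("anchor", current), dtype=float)
            seg = _ou_segment(
                rng, n_steps, current, anchor, p["relaxation_time"], p["sigma_c"], dt
            )[1:]
        else:  # directed
            v = float(p["v"])
            direction = np.asarray(p.get("direction", (1.0, 0.0)), dtype=float)
            direction = direction / np.linalg.norm(direction)
            drift = v * dt * direction
            seg = current + np.outer(np.arange(1, n_steps + 1), drift)
            D_jitter = float(p.get("D_jitter", 0.0))
            if D_jitter > 0:
                jitter = rng.normal(0.0, np.sqrt(2 * D_jitter * dt), size=(n_steps, 2))
                seg = seg + jitter.cumsum(axis=0)
        pos_chunks.append(seg)
        current = seg[-1]
        if first:
            labels.append(np.full(n_steps + 1, state))
            first = False
        else:
            labels.append(np.full(n_steps, state))
        params_log.append({"state": state, "duration": duration, **p})
    pos = np.vstack(pos_chunks)
    gt = MotionGroundTruth(
        states=np.concatenate(labels),
        params=params_log,
        seed=seed if isinstance(seed, int) else None,
    )
    return _make_traj(pos[:, 0], pos[:, 1], dt, track_id), gt


def add_localization_noise(traj: Trajectory, sigma_loc: float, seed=0) -> Trajectory:
    """Return a copy of ``traj`` with i.i.d. Gaussian localization error added.

    ``sigma_loc`` is the per-axis standard deviation in nm. The input
    trajectory is unmodified; ``sigma_loc = 0`` returns an exact copy.
    """
    if sigma_loc < 0:
        raise InvalidParameterError(f"sigma_loc must be >= 0, got {sigma_loc}")
    if sigma_loc == 0:
        return traj
    rng = _rng(seed)
    s_um = sigma_loc / 1000.0
    noise = rng.normal(0.0, s_um, size=(len(traj), 2))
    return Trajectory(
        track_id=traj.track_id,
        frames=traj.frames.copy(),
        x=traj.x + noise[:, 0],
        y=traj.y + noise[:, 1],
        dt=traj.dt,
        quality=None if traj.quality is None else traj.quality.copy(),
    )


def generate_er_mask(
    shape_px: tuple[int, int],
    pixel_size: float,
    n_tubules: int,
    tubule_width: float,
    seed=0,
    step_px: int = 4,
    persistence: float = 0.85,
):
    """Generate an ER-like tubular network mask.

    The network is built from ``n_tubules`` random persistent paths: the
    first starts near the centre of the field, each subsequent one branches
    from a random point of the existing skeleton, so the foreground is one
    connected component. The skeleton is then dilated with a Euclidean disk
    of radius ``tubule_width / 2`` (every foreground pixel lies within
    ``tubule_width / 2`` of the skeleton by construction).

    Returns
    -------
    (MaskImage, BoundarySet)
    """
    from .io import MaskImage
    from .spatial import extract_boundaries

    if not (pixel_size > 0):
        raise InvalidParameterError(f"pixel_size must be > 0, got {pixel_size}")
    if n_tubules < 0:
        raise InvalidParameterError(f"n_tubules must be >= 0, got {n_tubules}")
    if n_tubules > 0 and tubule_width < pixel_size:
        raise InvalidParameterError(
            f"tubule_width ({tubule_width} nm) must be >= pixel_size ({pixel_size} nm)"
        )
    rng = _rng(seed)
    h, w = shape_px
    skeleton = np.zeros((h, w), dtype=bool)
    anchor_points: list[tuple[int, int]] = []
    for i in range(n_tubules):
        if i == 0 or not anchor_points:
            r = h // 2 + int(rng.integers(-h // 8, h // 8 + 1))
            c = w // 2 + int(rng.integers(-w // 8, w // 8 + 1))
        else:
            r, c = anchor_points[int(rng.integers(len(anchor_points)))]
        theta = rng.uniform(0, 2 * np.pi)
        n_segs = int(rng.integers(max(h, w) // (2 * step_px), max(h, w) // step_px + 1))
        for _ in range(n_segs):
            theta = persistence * theta + (1 - persistence) * rng.uniform(0, 2 * np.pi) \
                + rng.normal(0, 0.3)
            r2 = int(np.clip(round(r + step_px * np.sin(theta)), 0, h - 1))
            c2 = int(np.clip(round(c + step_px * np.cos(theta)), 0, w - 1))
            rr, cc = _line_px(r, c, r2, c2)
            skeleton[rr, cc] = True
            for rr_i, cc_i in zip(rr, cc):
                anchor_points.append((int(rr_i), int(cc_i)))
            r, c = r2, c2
    if n_tubules == 0:
        mask = MaskImage(data=skeleton, pixel_size=pixel_size)
        return mask, extract_boundaries(mask)
    radius_px = (tubule_width / 2.0) / pixel_size
    mask_arr = _dilate_euclidean(skeleton, radius_px)
    mask = MaskImage(data=mask_arr, pixel_size=pixel_size)
    return mask, extract_boundaries(mask)


def _line_px(r0, c0, r1, c1):
    from skimage.draw import line

    return line(r0, c0, r1, c1)


def _dilate_euclidean(skeleton: np.ndarray, radius_px: float) -> np.ndarray:
    """Dilate a skeleton to all pixels within Euclidean distance radius_px."""
    if not skeleton.any():
        return skeleton.copy()
    dist = ndimage.distance_transform_edt(~skeleton)
    return dist <= radius_px


def render_spot_stack(
    trajectories: list[Trajectory],
    shape_px: tuple[int, int],
    psf_sigma: float,
    pixel_size: float,
    n_frames: int | None = None,
    amplitudes: list[float] | None = None,
    trajectories_b: list[Trajectory] | None = None,
    amplitudes_b: list[float] | None = None,
    alternation: str | None = None,
    background: float = 0.0,
    seed=0,
) -> np.ndarray:
    """Render trajectories as diffraction-limited Gaussian spots.

    Each localization is drawn as a 2D Gaussian of standard deviation
    ``psf_sigma`` (nm) on a grid of ``pixel_size`` (nm). With
    ``alternation="odd_has_both"`` a two-species cross-excitation scheme is
    rendered: 0-based even frames contain species A (``trajectories``) plus
    species B (``trajectories_b``), 0-based odd frames contain species B
    only; frame pair i samples both species at time index i. Spots whose
    centre falls outside the field of view are clipped silently and the
    count is logged.
    """
    if not (psf_sigma > 0):
        raise InvalidParameterError(f"psf_sigma must be > 0, got {psf_sigma}")
    if not (pixel_size > 0):
        raise InvalidParameterError(f"pixel_size must be > 0, got {pixel_size}")
    if alternation is not None and alternation != "odd_has_both":
        raise InvalidParameterError(f"unknown alternation scheme {alternation!r}")

    h, w = shape_px
    if n_frames is None:
        sources = trajectories + (trajectories_b or [])
        n_frames = 1 + max((int(t.frames.max()) for t in sources), default=0)
    if alternation is None:
        stack = np.full((n_frames, h, w), background, dtype=float)
        _render_species(stack, trajectories, amplitudes, psf_sigma, pixel_size, lambda f: f)
        return stack
    stack = np.full((2 * n_frames, h, w), background, dtype=float)
    _render_species(stack, trajectories, amplitudes, psf_sigma, pixel_size,
                    lambda f: 2 * f)  # A: even frames only
    for parity in (0, 1):  # B: every frame
        _render_species(stack, trajectories_b or [], amplitudes_b, psf_sigma, pixel_size,
                        lambda f, p=parity: 2 * f + p)
    return stack


def _render_species(stack, trajectories, amplitudes, psf_sigma, pixel_size, frame_map):
    n_total, h, w = stack.shape
    sigma_px = psf_sigma / pixel_size
    half = max(3, int(np.ceil(4 * sigma_px)))
    n_clipped = 0
    for j, t in enumerate(trajectories):
        amp = 1.0 if amplitudes is None else amplitudes[j]
        for i in range(len(t)):
            fr = frame_map(int(t.frames[i]))
            if fr >= n_total:
                continue
            cx = t.x[i] * 1000.0 / pixel_size
            cy = t.y[i] * 1000.0 / pixel_size
            if not (0 <= cx < w and 0 <= cy < h):
                n_clipped += 1
                continue
            c0, c1 = int(max(0, np.floor(cx - half))), int(min(w, np.ceil(cx + half) + 1))
            r0, r1 = int(max(0, np.floor(cy - half))), int(min(h, np.ceil(cy + half) + 1))
            cols = np.arange(c0, c1)
            rows = np.arange(r0, r1)
            gx = np.exp(-((cols - cx) ** 2) / (2 * sigma_px**2))
            gy = np.exp(-((rows - cy) ** 2) / (2 * sigma_px**2))
            stack[fr, r0:r1, c0:c1] += amp * np.outer(gy, gx)
    if n_clipped:
        logger.info("render_spot_stack: clipped %d out-of-field localizations", n_clipped)
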