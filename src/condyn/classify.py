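"""Immobility filtering, rule-based super-diffusion event detection and
population fractions.

A trajectory is immobile when its mean consecutive-frame step size falls
below a threshold set just above the localization-noise floor (a static
emitter with 16 nm per-axis error shows an apparent mean step of
16 * sqrt(pi) ~ 28.4 nm, hence a 30 nm threshold). Immobile trajectories
are excluded before diffusion profiling and event detection.

Super-diffusive events are detected by a conjunction of rules on the raw
steps and on the running-window diffusion fits:

1. candidate steps — a step is a candidate when it and its immediate
   successor both exceed ``step_threshold`` (2 pixels = 234 nm at 117
   nm/px); an event is a maximal run of candidate steps;
2. the run's start-to-end net displacement (not summed path length) must
   reach ``total_displacement_threshold`` (5 pixels = 585 nm);
3. at least one running window overlapping the run must satisfy
   alpha > 1, D > 0.01 um^2/s and R^2 > 0.6.

The nm thresholds are coupled to the acquisition rate they were derived at
(a 2 s step at 0.5 Hz); rescale them when analysing other frame rates.
Event velocity is net displacement over duration (directional transport,
not path speed).
"""
from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .diffusion import WindowProfile, running_window_profile
from .errors import InvalidParameterError
from .io import Trajectory

MOBILE = "mobile"
IMMOBILE = "immobile"


@dataclass(frozen=True)
class ClassifierConfig:
    """Thresholds of the immobility filter and the super-diffusion detector.

    Defaults correspond to a 117 nm/px camera at 0.5 Hz: 234 nm = 2 px and
    585 nm = 5 px.
    """

    immobile_mean_step_threshold: float = 30.0  # nm
    step_threshold: float = 234.0  # nm
    consecutive_steps_required: int = 2
    total_displacement_threshold: float = 585.0  # nm
    alpha_min: float = 1.0
    D_min: float = 0.01  # um^2/s
    r2_min: float = 0.6

    def __post_init__(self) -> None:
        for name in ("immobile_mean_step_threshold", "step_threshold",
                     "total_displacement_threshold", "alpha_min", "D_min", "r2_min"):
            if not (getattr(self, name) > 0):
                raise InvalidParameterError(f"{name} must be > 0")
        if self.r2_min > 1:
            raise InvalidParameterError("r2_min must be <= 1")
        if self.consecutive_steps_required < 1:
            raise InvalidParameterError("consecutive_steps_required must be >= 1")


@dataclass(frozen=True)
class MotionEvent:
    """A detected super-diffusive segment of one trajectory."""

    track_id: object
    start_frame: int
    end_frame: int  # inclusive; end_frame > start_frame
    net_displacement: float  # um, start-to-end
    duration: float  # s
    velocity: float  # um/s = net_displacement / duration
    window_indices: tuple[int, ...] = ()  # running windows supporting the event

    def __post_init__(self) -> None:
        if self.end_frame <= self.start_frame:
            raise InvalidParameterError("end_frame must exceed start_frame")


def classify_immobile(traj: Trajectory, cfg: ClassifierConfig = ClassifierConfig()) -> str:
    """Classify a trajectory as ``"mobile"`` or ``"immobile"``.

    Immobile iff the mean consecutive-localization step size is below
    ``immobile_mean_step_threshold`` (nm).
    """
    steps_um = np.linalg.norm(np.diff(traj.positions, axis=0), axis=1)
    mean_step_nm = float(np.mean(steps_um)) * 1000.0
    return IMMOBILE if mean_step_nm < cfg.immobile_mean_step_threshold else MOBILE


def detect_super_events(
    traj: Trajectory,
    profile: WindowProfile | None = None,
    cfg: ClassifierConfig = ClassifierConfig(),
) -> list[MotionEvent]:
    """Detect super-diffusive events in one trajectory.

    ``profile`` must be the running-window profile of the same trajectory;
    if omitted it is computed (when the trajectory is long enough; shorter
    trajectories are screened on the step rules alone with no window
    support, hence return no events).
    """
    if profile is not None:
        if profile.track_id != traj.track_id or len(profile) + profile.window_length - 1 != len(traj):
            raise InvalidParameterError("profile does not match trajectory")
    elif len(traj) >= 20:
        profile = running_window_profile(traj)
    else:
        return []

    pos = traj.positions
    frames = traj.frames
    steps_nm = np.linalg.norm(np.diff(pos, axis=0), axis=1) * 1000.0
    n_steps = len(steps_nm)
    if n_steps < cfg.consecutive_steps_required:
        return []
    big = steps_nm > cfg.step_threshold
    # candidate step k: it and its (consecutive_steps_required - 1) successors all big
    m = cfg.consecutive_steps_required
    candidate = np.zeros(n_steps, dtype=bool)
    for k in range(n_steps - m + 1):
        if big[k : k + m].all():
            candidate[k : k + m] = True

    events: list[MotionEvent] = []
    W = profile.window_length
    k = 0
    while k < n_steps:
        if not candidate[k]:
            k += 1
            continue
        j = k
        while j + 1 < n_steps and candidate[j + 1]:
            j += 1
        # run of candidate steps k..j spans localizations k..j+1
        start_loc, end_loc = k, j + 1
        net_nm = float(np.linalg.norm(pos[end_loc] - pos[start_loc])) * 1000.0
        if net_nm >= cfg.total_displacement_threshold:
            supporting = _supporting_windows(profile, start_loc, end_loc, W, cfg)
            if supporting:
                start_frame = int(frames[start_loc])
                end_frame = int(frames[end_loc])
                duration = (end_frame - start_frame) * traj.dt
                events.append(MotionEvent(
                    track_id=traj.track_id,
                    start_frame=start_frame,
                    end_frame=end_frame,
                    net_displacement=net_nm / 1000.0,
                    duration=duration,
                    velocity=net_nm / 1000.0 / duration,
                    window_indices=tuple(supporting),
                ))
        k = j + 1
    return events


def _supporting_windows(profile, start_loc, end_loc, W, cfg):
    """Running windows overlapping localizations [start_loc, end_loc] that
    pass all three fit criteria."""
    lo = max(0, start_loc - W + 1)
    hi = min(len(profile) - 1, end_loc)
    out = []
    for s in range(lo, hi + 1):
        if profile.degenerate[s]:
            continue
        if (profile.alpha[s] > cfg.alpha_min
                and profile.D[s] > cfg.D_min
                and profile.r_squared[s] > cfg.r2_min):
            out.append(s)
    return out


def event_velocity(event: MotionEvent) -> float:
    """Net start-to-end displacement over duration, in um/s."""
    if event.duration <= 0:
        raise InvalidParameterError("event duration must be > 0")
    return event.net_displacement / event.duration


def superdiffusive_fraction(
    trajectories: list[Trajectory], events: dict[object, list[MotionEvent]]
) -> dict:
    """Fraction of trajectories with >= 1 event and fraction of steps inside events.

    ``events`` maps track_id -> event list (as from
    :func:`detect_super_events` per trajectory). Returns both fractions and
    their denominators.
    """
    if not trajectories:
        raise InvalidParameterError("empty trajectory set")
    n_traj_with = 0
    n_steps_total = 0
    n_steps_in = 0
    for t in trajectories:
        evs = events.get(t.track_id, [])
        n_steps_total += len(t) - 1
        if evs:
            n_traj_with += 1
        frames = t.frames
        for ev in evs:
            in_span = (frames[:-1] >= ev.start_frame) & (frames[1:] <= ev.end_frame)
            n_steps_in += int(np.sum(in_span))
    return {
        "trajectory_fraction": n_traj_with / len(trajectories),
        "step_fraction": n_steps_in / n_steps_total if n_steps_total else 0.0,
        "n_trajectories": len(trajectories),
        "n_steps": n_steps_total,
    }


def segment_by_label(
    trajectories: list[Trajectory], events: dict[object, list[MotionEvent]]
) -> tuple[list[Trajectory], list[Trajectory]]:
    """Partition trajectories into super-diffusive and sub-diffusive segments.

    Event frame spans become "super" segments; the complementary spans
    become "sub" segments. Every frame of every trajectory lands in exactly
    one segment; segments shorter than 2 localizations are dropped (no
    displacement to analyse). Feeds :func:`condyn.diffusion.ensemble_msd`.
    """
    super_segments: list[Trajectory] = []
    sub_segments: list[Trajectory] = []
    for t in trajectories:
        evs = sorted(events.get(t.track_id, []), key=lambda e: e.start_frame)
        cursor = int(t.frames[0])
        last = int(t.frames[-1])
        for ev in evs:
            if ev.start_frame - 1 >= cursor:
                seg = _maybe_slice(t, cursor, ev.start_frame - 1)
                if seg is not None:
                    sub_segments.append(seg)
            seg = _maybe_slice(t, ev.start_frame, ev.end_frame)
            if seg is not None:
                super_segments.append(seg)
            cursor = ev.end_frame + 1
        if cursor <= last:
            seg = _maybe_slice(t, cursor, last)
            if seg is not None:
                sub_segments.append(seg)
    return super_segments, sub_segments


def _maybe_slice(traj, start, stop):
    keep = (traj.frames >= start) & (traj.frames <= stop)
    if int(np.sum(keep)) < 2:
        return None
    return traj.slice_frames(start, stop)


def events_table(events: dict[object, list[MotionEvent]]) -> pd.DataFrame:
    """Flatten an events mapping into the standard events table."""
    rows = [
        {
            "track_id": ev.track_id,
            "start_frame": ev.start_frame,
            "end_frame": ev.end_frame,
            "net_disp_um": ev.net_displacement,
            "duration_s": ev.duration,
            "velocity_um_s": ev.velocity,
        }
        for evs in events.values()
        for ev in evs
    ]
    return pd.DataFrame(
        rows,
        columns=["track_id", "start_frame", "end_frame",
                 "net_disp_um", "duration_s", "velocity_um_s"],
    )
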