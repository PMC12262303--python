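"""MSD computation, anomalous-exponent fitting and running-window profiling.

The quantitative core of the pipeline. A particle's time-averaged mean
squared displacement,

    MSD(tau) = < |r(t + tau) - r(t)|^2 >_t ,

is fitted on a log-log scale to the anomalous-diffusion law

    log MSD = alpha log tau + log(2 n D),      n = 2 dimensions,

so the slope is the anomalous exponent alpha (alpha < 1 sub-diffusion,
alpha = 1 Brownian, alpha > 1 super-diffusion, alpha = 2 ballistic) and the
intercept yields the generalized diffusion coefficient D (um^2/s^alpha,
conventionally quoted as um^2/s). Natural logarithms are used throughout;
the base cancels in alpha and D is recovered as exp(intercept) / (2 n).

Running-window profiling slides a 20-frame window along the trajectory with
stride 1, fitting alpha, D and R^2 per window and recording the mean step
size, which resolves transient mode switches (e.g. a directed run inside an
otherwise tethered trajectory). Windows with R^2 < 0.6 are flagged as
excluded but kept on the timeline; windows with a zero MSD lag (static
segments) are flagged degenerate rather than raising.
"""
from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .errors import (
    DegenerateInputError,
    InvalidParameterError,
    ShortTrajectoryError,
)
from .io import Trajectory

N_DIMS = 2
R2_EXCLUSION = 0.6


@dataclass(frozen=True)
class MSDCurve:
    """Time-averaged MSD versus lag time."""

    lags: np.ndarray  # s, strictly increasing multiples of dt
    msd: np.ndarray  # um^2
    n_pairs: np.ndarray  # displacement pairs averaged per lag

    def __post_init__(self) -> None:
        object.__setattr__(self, "lags", np.asarray(self.lags, dtype=float))
        object.__setattr__(self, "msd", np.asarray(self.msd, dtype=float))
        object.__setattr__(self, "n_pairs", np.asarray(self.n_pairs, dtype=np.int64))
        if len(self.lags) and np.any(np.diff(self.lags) <= 0):
            raise InvalidParameterError("lags must be strictly increasing")
        if np.any(self.msd < 0):
            raise InvalidParameterError("msd must be non-negative")

    def __len__(self) -> int:
        return len(self.lags)


@dataclass(frozen=True)
class DiffusionFit:
    """Result of the log-log anomalous-diffusion fit."""

    alpha: float
    D: float  # um^2/s (generalized; um^2/s^alpha strictly)
    r_squared: float
    n_fit_points: int
    n_dims: int = N_DIMS
    excluded: bool = False  # True when r_squared < 0.6 (poor-fit rule)


@dataclass
class WindowProfile:
    """Running-window readout of a single trajectory.

    One row per window of ``window_length`` frames at stride 1
    (``len(trajectory) - window_length + 1`` windows). Degenerate windows
    (a zero MSD lag, e.g. a perfectly static stretch) carry NaN fits and
    ``degenerate=True``; windows with R^2 < 0.6 carry ``excluded=True``
    but stay on the timeline.
    """

    track_id: object
    window_starts: np.ndarray  # index into trajectory localizations
    start_frames: np.ndarray  # frame number at each window start
    alpha: np.ndarray
    D: np.ndarray
    r_squared: np.ndarray
    mean_step: np.ndarray  # um
    excluded: np.ndarray  # bool
    degenerate: np.ndarray  # bool
    window_length: int
    dt: float

    def __len__(self) -> int:
        return len(self.window_starts)

    def to_frame(self) -> pd.DataFrame:
        """Tabular view: track_id, window_start, alpha, D, r2, mean_step, excluded."""
        return pd.DataFrame({
            "track_id": self.track_id,
            "window_start": self.start_frames,
            "alpha": self.alpha,
            "D": self.D,
            "r2": self.r_squared,
            "mean_step": self.mean_step,
            "excluded": self.excluded,
            "degenerate": self.degenerate,
        })


@dataclass(frozen=True)
class StepStats:
    """Consecutive-frame step sizes and turning angles of a trajectory.

    ``angles`` are undirected, in degrees in [0, 180]: 0 means no
    directional change between successive steps, 180 a complete reversal.
    A trajectory of L localizations has L-1 steps and up to L-2 angles;
    angles involving a zero-length step are undefined and skipped
    (``n_undefined_angles`` counts them).
    """

    steps: np.ndarray  # um
    angles: np.ndarray  # degrees
    n_undefined_angles: int = 0


def time_averaged_msd(traj: Trajectory, max_lag: int | None = None) -> MSDCurve:
    """Time-averaged MSD of one trajectory.

    ``MSD(k dt) = mean_i |r(frame i + k) - r(frame i)|^2`` over all ordered
    pairs separated by exactly k frames. Gapped tracks are handled by frame
    arithmetic, so lag times are honest; lags with zero pairs are omitted.
    """
    L = len(traj)
    if max_lag is None:
        max_lag = L - 1
    if not (1 <= max_lag < L):
        raise InvalidParameterError(
            f"max_lag must be in [1, len-1]; got {max_lag} for length {L}"
        )
    frames = traj.frames
    pos = traj.positions
    span = int(frames[-1] - frames[0])
    max_lag_frames = min(max_lag, span)
    # lay positions out on the frame axis (NaN for gaps) so each lag is a
    # single vectorized shift-and-subtract with honest time lags
    grid = np.full((span + 1, 2), np.nan)
    grid[frames - frames[0]] = pos
    lags, msds, counts = [], [], []
    for k in range(1, max_lag_frames + 1):
        d = grid[k:] - grid[:-k]
        sq = d[:, 0] ** 2 + d[:, 1] ** 2
        valid = ~np.isnan(sq)
        n = int(np.sum(valid))
        if n:
            lags.append(k * traj.dt)
            msds.append(float(np.mean(sq[valid])))
            counts.append(n)
    return MSDCurve(lags=np.array(lags), msd=np.array(msds), n_pairs=np.array(counts))


def fit_alpha_loglog(msd: MSDCurve, n_fit_points: int | None = None) -> DiffusionFit:
    """Fit ``log MSD = alpha log tau + log(2 n D)`` over the first lags.

    ``n_fit_points`` defaults to half the available lags (the usual
    "fit roughly the first half of the curve" rule). Raises
    :class:`DegenerateInputError` if any retained MSD value is zero.
    Fits with R^2 < 0.6 are returned with ``excluded=True``.
    """
    if len(msd) < 2:
        raise InvalidParameterError("need at least 2 MSD points to fit")
    if n_fit_points is None:
        n_fit_points = max(2, len(msd) // 2)
    if n_fit_points < 2:
        raise InvalidParameterError(f"n_fit_points must be >= 2, got {n_fit_points}")
    n_fit_points = min(n_fit_points, len(msd))
    tau = msd.lags[:n_fit_points]
    m = msd.msd[:n_fit_points]
    if np.any(m == 0):
        raise DegenerateInputError("zero MSD value in fit range (log undefined)")
    res = stats.linregress(np.log(tau), np.log(m))
    alpha = float(res.slope)
    D = float(np.exp(res.intercept) / (2 * N_DIMS))
    r2 = float(res.rvalue**2)
    return DiffusionFit(
        alpha=alpha, D=D, r_squared=r2, n_fit_points=n_fit_points,
        excluded=r2 < R2_EXCLUSION,
    )


def fit_d_powerlaw(msd: MSDCurve, alpha: float, n_fit_points: int | None = None) -> float:
    """Least-squares D for the one-parameter model ``MSD = 2 n D tau^alpha``.

    With alpha fixed the model is linear in D:
    ``D = sum(MSD * tau^alpha) / (2 n sum(tau^(2 alpha)))``. On a noiseless
    power law this equals the D from :func:`fit_alpha_loglog` exactly.
    """
    if len(msd) == 0:
        raise InvalidParameterError("empty MSD curve")
    if n_fit_points is None:
        n_fit_points = len(msd)
    tau = msd.lags[:n_fit_points]
    m = msd.msd[:n_fit_points]
    ta = tau**alpha
    return float((m @ ta) / (2 * N_DIMS * (ta @ ta)))


def steps_and_angles(traj: Trajectory) -> StepStats:
    """Step sizes and undirected turning angles of a trajectory.

    Step k is ``|r(k+1) - r(k)|``; the angle between steps k and k+1 is the
    arccos of their normalized dot product, in degrees in [0, 180].
    """
    if len(traj) < 2:
        raise InvalidParameterError("need >= 2 localizations for steps")
    vec = np.diff(traj.positions, axis=0)
    steps = np.linalg.norm(vec, axis=1)
    angles = np.array([])
    n_undef = 0
    if len(traj) >= 3:
        a, b = vec[:-1], vec[1:]
        na, nb = steps[:-1], steps[1:]
        ok = (na > 0) & (nb > 0)
        n_undef = int(np.sum(~ok))
        cosang = np.einsum("ij,ij->i", a[ok], b[ok]) / (na[ok] * nb[ok])
        angles = np.degrees(np.arccos(np.clip(cosang, -1.0, 1.0)))
    return StepStats(steps=steps, angles=angles, n_undefined_angles=n_undef)


def running_window_profile(
    traj: Trajectory, window_length: int = 20, n_fit_points: int | None = None
) -> WindowProfile:
    """Sliding-window alpha/D/R^2/mean-step profile of one trajectory.

    Windows of ``window_length`` localizations at stride 1; per-window MSD
    uses lags up to ``window_length // 2`` (10 by default) and the fit uses
    all of them. Raises :class:`ShortTrajectoryError` if the trajectory is
    shorter than one window.
    """
    L = len(traj)
    W = window_length
    if W < 4:
        raise InvalidParameterError(f"window_length must be >= 4, got {W}")
    if L < W:
        raise ShortTrajectoryError(f"trajectory length {L} < window length {W}")
    max_lag = W // 2
    if n_fit_points is None:
        n_fit_points = max_lag
    n_win = L - W + 1
    pos = traj.positions
    frames = traj.frames
    gapless = bool(np.all(np.diff(frames) == 1))
    if gapless:
        alpha, D, r2, mean_step, excluded, degenerate = _profile_gapless(
            pos, W, max_lag, n_fit_points, traj.dt
        )
    else:
        alpha = np.full(n_win, np.nan)
        D = np.full(n_win, np.nan)
        r2 = np.full(n_win, np.nan)
        mean_step = np.full(n_win, np.nan)
        excluded = np.zeros(n_win, dtype=bool)
        degenerate = np.zeros(n_win, dtype=bool)
        for s in range(n_win):
            sub = Trajectory(
                track_id=traj.track_id,
                frames=frames[s : s + W],
                x=pos[s : s + W, 0],
                y=pos[s : s + W, 1],
                dt=traj.dt,
            )
            curve = time_averaged_msd(sub, max_lag=max_lag)
            step_vec = np.diff(pos[s : s + W], axis=0)
            mean_step[s] = float(np.mean(np.linalg.norm(step_vec, axis=1)))
            try:
                fit = fit_alpha_loglog(curve, n_fit_points=min(n_fit_points, len(curve)))
            except (DegenerateInputError, InvalidParameterError):
                degenerate[s] = True
                excluded[s] = True
                continue
            alpha[s], D[s], r2[s] = fit.alpha, fit.D, fit.r_squared
            excluded[s] = fit.excluded
    return WindowProfile(
        track_id=traj.track_id,
        window_starts=np.arange(n_win),
        start_frames=frames[:n_win].copy(),
        alpha=alpha, D=D, r_squared=r2, mean_step=mean_step,
        excluded=excluded, degenerate=degenerate,
        window_length=W, dt=traj.dt,
    )


def _profile_gapless(pos, W, max_lag, n_fit_points, dt):
    """Vectorized sliding-window profile for contiguous-frame trajectories.

    Produces the same per-window MSDs and log-log fits as the generic path
    (sliding sums via cumsum; one closed-form OLS across all windows).
    """
    L = len(pos)
    n_win = L - W + 1
    nfit = min(n_fit_points, max_lag)
    msd_w = np.empty((n_win, max_lag))
    for k in range(1, max_lag + 1):
        d = pos[k:] - pos[:-k]
        sq = d[:, 0] ** 2 + d[:, 1] ** 2
        c = np.concatenate([[0.0], np.cumsum(sq)])
        m = W - k  # pairs per window at lag k
        msd_w[:, k - 1] = (c[m : m + n_win] - c[:n_win]) / m
    steps = np.linalg.norm(np.diff(pos, axis=0), axis=1)
    cs = np.concatenate([[0.0], np.cumsum(steps)])
    mean_step = (cs[W - 1 : W - 1 + n_win] - cs[:n_win]) / (W - 1)

    alpha = np.full(n_win, np.nan)
    D = np.full(n_win, np.nan)
    r2 = np.full(n_win, np.nan)
    Y = msd_w[:, :nfit]
    degenerate = np.any(Y <= 0, axis=1)
    ok = ~degenerate
    if np.any(ok):
        x = np.log(np.arange(1, nfit + 1) * dt)
        xc = x - x.mean()
        sxx = float(xc @ xc)
        ylog = np.log(Y[ok])
        ybar = ylog.mean(axis=1)
        yc = ylog - ybar[:, None]
        sxy = yc @ xc
        syy = np.einsum("ij,ij->i", yc, yc)
        slope = sxy / sxx
        alpha[ok] = slope
        D[ok] = np.exp(ybar - slope * x.mean()) / (2 * N_DIMS)
        with np.errstate(divide="ignore", invalid="ignore"):
            r2[ok] = np.where(syy > 0, sxy**2 / (sxx * syy), 0.0)
    excluded = degenerate.copy()
    excluded[ok] = r2[ok] < R2_EXCLUSION
    return alpha, D, r2, mean_step, excluded, degenerate


def ensemble_msd(
    segments: list[Trajectory], max_lag: int | None = None, n_fit_points: int | None = None
) -> tuple[MSDCurve, DiffusionFit]:
    """Pair-count-weighted ensemble MSD over trajectory segments, plus its fit.

    All segments must share the same frame interval. A single segment
    reduces to its own :func:`time_averaged_msd`.
    """
    if not segments:
        raise InvalidParameterError("need at least one segment")
    dts = {float(s.dt) for s in segments}
    if len(dts) > 1:
        raise InvalidParameterError(f"segments mix frame intervals: {sorted(dts)}")
    acc: dict[float, tuple[float, int]] = {}
    for seg in segments:
        curve = time_averaged_msd(seg, max_lag=min(max_lag, len(seg) - 1) if max_lag else None)
        for lag, m, n in zip(curve.lags, curve.msd, curve.n_pairs):
            tot, cnt = acc.get(lag, (0.0, 0))
            acc[lag] = (tot + m * n, cnt + int(n))
    lags = np.array(sorted(acc))
    msd = np.array([acc[l][0] / acc[l][1] for l in lags])
    n_pairs = np.array([acc[l][1] for l in lags])
    curve = MSDCurve(lags=lags, msd=msd, n_pairs=n_pairs)
    fit = fit_alpha_loglog(curve, n_fit_points=n_fit_points)
    return curve, fit


def summary_histograms(
    profiles: list[WindowProfile],
    step_stats: list[StepStats] | None = None,
    bins: int = 50,
    include_excluded: bool = False,
) -> dict[str, pd.DataFrame]:
    """Histogram tables for alpha, log10 D, step size and turning angle.

    Excluded/degenerate windows are pooled only when ``include_excluded``
    is set. Returns a mapping of quantity name to a (bin_left, bin_right,
    count) table.
    """
    table = profile_table(profiles)
    if not include_excluded and len(table):
        table = table[~table["excluded"]]
    out = {}
    series = {
        "alpha": table["alpha"].dropna().to_numpy(),
        "log10_D": np.log10(table["D"].dropna().to_numpy().clip(min=1e-300)),
        "mean_step": table["mean_step"].dropna().to_numpy(),
    }
    if step_stats is not None:
        series["angle"] = np.concatenate([s.angles for s in step_stats]) \
            if step_stats else np.array([])
    for name, vals in series.items():
        if len(vals) == 0:
            out[name] = pd.DataFrame(columns=["bin_left", "bin_right", "count"])
            continue
        rng = (0.0, 180.0) if name == "angle" else None
        counts, edges = np.histogram(vals, bins=bins, range=rng)
        out[name] = pd.DataFrame({
            "bin_left": edges[:-1], "bin_right": edges[1:], "count": counts,
        })
    return out


def profile_table(profiles: list[WindowProfile]) -> pd.DataFrame:
    """Concatenate per-trajectory window profiles into one table."""
    if not profiles:
        return pd.DataFrame(
            columns=["track_id", "window_start", "alpha", "D", "r2",
                     "mean_step", "excluded", "degenerate"]
        )
    return pd.concat([p.to_frame() for p in profiles], ignore_index=True)
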