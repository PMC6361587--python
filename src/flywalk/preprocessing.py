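"""Trajectory preprocessing: loading, smoothing, and kinematic observables.

A fly's centroid track, sampled at 30 frames/s in a circular arena, is
normalized so that the arena boundary is the unit circle.  The model
observables are the components of the per-frame displacement parallel
(``v_par``) and perpendicular (``v_perp``) to the displacement at the
previous frame; straight motion gives ``v_perp = 0`` and counterclockwise
(left) turns give ``v_perp < 0``.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
import pywt
from statsmodels.nonparametric.smoothers_lowess import lowess

__all__ = [
    "TrajectoryRecord",
    "ObservableSeries",
    "SmoothingConfig",
    "TrajectoryFormatError",
    "DataQualityError",
    "load_trajectory",
    "write_trajectory",
    "smooth_trajectory",
    "compute_observables",
    "clip_outliers",
    "speed_curvature",
    "write_observables",
]

FPS = 30
DEFAULT_ARENA_RADIUS_CM = 3.2
DEFAULT_ODOR_ZONE_RADIUS_CM = 1.5
DEFAULT_ODOR_ON_FRAME = 3 * 60 * FPS  # odor valve opens at minute 3

# Displacements below this magnitude (normalized units) define a
# stationary frame; the decomposition axis is then carried forward.
STATIONARY_EPS = 1e-12


class TrajectoryFormatError(ValueError):
    """Raised for malformed trajectory files (non-monotone/duplicate frames)."""


class DataQualityError(ValueError):
    """Raised when a trajectory has too many missing frames."""


@dataclass
class TrajectoryRecord:
    """One fly's centroid trajectory in normalized arena coordinates.

    ``x``/``y`` are in units of the arena radius, so the wall is at
    radius 1 and the odor zone at radius
    ``odor_zone_radius_cm / arena_radius_cm`` (0.46875 by default).
    """

    fly_id: str
    t: np.ndarray  # frame indices, strictly increasing, uniform spacing
    x: np.ndarray
    y: np.ndarray
    arena_radius_cm: float = DEFAULT_ARENA_RADIUS_CM
    odor_zone_radius_cm: float = DEFAULT_ODOR_ZONE_RADIUS_CM
    odor_on_frame: int = DEFAULT_ODOR_ON_FRAME
    n_missing: int = 0

    def __post_init__(self) -> None:
        self.t = np.asarray(self.t, dtype=np.int64)
        self.x = np.asarray(self.x, dtype=float)
        self.y = np.asarray(self.y, dtype=float)

    @property
    def n_frames(self) -> int:
        return self.t.size

    @property
    def zone_radius(self) -> float:
        """Odor-zone radius in normalized arena units."""
        return self.odor_zone_radius_cm / self.arena_radius_cm

    def radius(self) -> np.ndarray:
        return np.hypot(self.x, self.y)


@dataclass
class ObservableSeries:
    """Per-frame kinematic observables derived from a trajectory.

    The series is two frames shorter than the trajectory: the first
    two positions are needed to define the first decomposition axis.
    ``frames`` holds the trajectory frame index each sample refers to.
    """

    v_par: np.ndarray
    v_perp: np.ndarray
    frames: np.ndarray | None = None
    speed: np.ndarray | None = None
    curvature: np.ndarray | None = None
    curvature_valid: np.ndarray | None = None
    fly_id: str = ""

    def __len__(self) -> int:
        return self.v_par.size

    def as_matrix(self) -> np.ndarray:
        """(T, 2) observation matrix in (v_par, v_perp) order."""
        return np.column_stack([self.v_par, self.v_perp])


@dataclass
class SmoothingConfig:
    """Wavelet-then-lowess smoothing parameters.

    Soft-threshold wavelet denoising (universal threshold, per level)
    followed by a locally weighted regression with a short span.  Both
    stages use the full track (no causality constraint).
    """

    wavelet: str = "sym4"
    wavelet_level: int = 4
    lowess_span_frames: int = 7


def load_trajectory(
    path,
    fly_id: str = "",
    arena_radius_cm: float = DEFAULT_ARENA_RADIUS_CM,
    odor_zone_radius_cm: float = DEFAULT_ODOR_ZONE_RADIUS_CM,
    odor_on_frame: int = DEFAULT_ODOR_ON_FRAME,
    coordinates_in_cm: bool = True,
    max_missing_frac: float = 0.01,
) -> TrajectoryRecord:
    """Read a delimited ``frame,x,y`` file and normalize to the unit circle.

    Raises
    ------
    TrajectoryFormatError
        If frame indices are duplicated or non-monotone.
    DataQualityError
        If more than ``max_missing_frac`` of the frame range is missing.
    """
    df = pd.read_csv(path)
    if df.shape[1] < 3:
        raise TrajectoryFormatError(f"{path}: expected columns frame,x,y")
    frames = df.iloc[:, 0].to_numpy(dtype=np.int64)
    x = df.iloc[:, 1].to_numpy(dtype=float)
    y = df.iloc[:, 2].to_numpy(dtype=float)
    if frames.size >= 2 and np.any(np.diff(frames) <= 0):
        raise TrajectoryFormatError(f"{path}: frame indices not strictly increasing")
    span = int(frames[-1] - frames[0]) + 1 if frames.size else 0
    n_missing = span - frames.size
    if span and n_missing / span > max_missing_frac:
        raise DataQualityError(
            f"{path}: {n_missing}/{span} frames missing "
            f"(> {max_missing_frac:.1%} allowed)"
        )
    if coordinates_in_cm:
        x = x / arena_radius_cm
        y = y / arena_radius_cm
    return TrajectoryRecord(
        fly_id=fly_id or str(path),
        t=frames,
        x=x,
        y=y,
        arena_radius_cm=arena_radius_cm,
        odor_zone_radius_cm=odor_zone_radius_cm,
        odor_on_frame=odor_on_frame,
        n_missing=n_missing,
    )


def write_trajectory(rec: TrajectoryRecord, path, coordinates_in_cm: bool = True) -> None:
    """Write a trajectory as ``frame,x,y`` CSV (inverse of :func:`load_trajectory`)."""
    scale = rec.arena_radius_cm if coordinates_in_cm else 1.0
    pd.DataFrame(
        {"frame": rec.t, "x": rec.x * scale, "y": rec.y * scale}
    ).to_csv(path, index=False)


def smooth_trajectory(
    rec: TrajectoryRecord, config: SmoothingConfig | None = None
) -> TrajectoryRecord:
    """Denoise a track with wavelet soft-thresholding followed by lowess."""
    config = config or SmoothingConfig()
    n = rec.n_frames
    if n < 2 * config.lowess_span_frames:
        raise ValueError(
            f"track of {n} frames is shorter than the smoothing window"
        )
    x = _wavelet_denoise(rec.x, config)
    y = _wavelet_denoise(rec.y, config)
    frac = min(1.0, config.lowess_span_frames / n)
    tt = np.arange(n, dtype=float)
    x = lowess(x, tt, frac=frac, return_sorted=False)
    y = lowess(y, tt, frac=frac, return_sorted=False)
    return replace(rec, x=x, y=y)


def _wavelet_denoise(sig: np.ndarray, config: SmoothingConfig) -> np.ndarray:
    level = min(
        config.wavelet_level, pywt.dwt_max_level(sig.size, config.wavelet)
    )
    if level < 1:
        return sig.copy()
    coeffs = pywt.wavedec(sig, config.wavelet, level=level, mode="smooth")
    # Universal threshold with the noise scale from the finest detail level.
    detail = coeffs[-1]
    sigma = np.median(np.abs(detail - np.median(detail))) / 0.6745
    thresh = sigma * np.sqrt(2.0 * np.log(sig.size))
    coeffs = [coeffs[0]] + [
        pywt.threshold(c, thresh, mode="soft") for c in coeffs[1:]
    ]
    out = pywt.waverec(coeffs, config.wavelet, mode="smooth")
    return out[: sig.size]


def compute_observables(rec: TrajectoryRecord) -> ObservableSeries:
    """Decompose per-frame displacements into (v_par, v_perp).

    v_par(t) = (dx_t dx_{t-1} + dy_t dy_{t-1}) / |d_{t-1}|
    v_perp(t) = (dy_{t-1} dx_t - dy_t dx_{t-1}) / |d_{t-1}|

    so a left (counterclockwise) turn yields negative v_perp.  When the
    previous displacement is (numerically) zero the last valid heading
    defines the axis; before any valid heading exists, v_par is set to
    the step length and v_perp to zero.
    """
    if rec.n_frames < 3:
        raise ValueError("need at least 3 frames to define v_par/v_perp")
    dx = np.diff(rec.x)
    dy = np.diff(rec.y)
    n = dx.size - 1  # observables for steps 1..n
    v_par = np.empty(n)
    v_perp = np.empty(n)
    ux, uy = np.nan, np.nan  # unit heading carried across stationary frames
    for i in range(n):
        px, py = dx[i], dy[i]
        norm = np.hypot(px, py)
        if norm > STATIONARY_EPS:
            ux, uy = px / norm, py / norm
        cx, cy = dx[i + 1], dy[i + 1]
        if np.isnan(ux):
            v_par[i] = np.hypot(cx, cy)
            v_perp[i] = 0.0
        else:
            v_par[i] = cx * ux + cy * uy
            v_perp[i] = uy * cx - cy * ux
    return ObservableSeries(
        v_par=v_par,
        v_perp=v_perp,
        frames=rec.t[2:].copy(),
        fly_id=rec.fly_id,
    )


def clip_outliers(obs: ObservableSeries, seed: int) -> ObservableSeries:
    """Pull extreme observables back to the 4-SD mark.

    Values further than 4 standard deviations from the mean of their
    series are replaced by draws from a normal centered at the (signed)
    4-SD mark with unit variance *on the standardized scale* (i.e. an SD
    equal to one SD of the series — a fixed raw-unit variance would
    dwarf observables measured in arena units per frame).  The SD is
    computed per fly and per observable over the full track.
    """
    rng = np.random.default_rng(seed)
    out = replace(obs)
    out.v_par = _clip_series(obs.v_par, rng)
    out.v_perp = _clip_series(obs.v_perp, rng)
    return out


def _clip_series(v: np.ndarray, rng: np.random.Generator) -> np.ndarray:
    mu = v.mean()
    sd = v.std()
    if sd == 0.0:
        return v.copy()
    out = v.copy()
    dev = (v - mu) / sd
    for sign in (1.0, -1.0):
        mask = sign * dev > 4.0
        if mask.any():
            out[mask] = mu + sd * (
                sign * 4.0 + rng.standard_normal(mask.sum())
            )
    return out


def speed_curvature(obs: ObservableSeries, rec: TrajectoryRecord) -> ObservableSeries:
    """Fill in speed and curvature from the observables.

    Speed = sqrt(v_par^2 + v_perp^2); curvature = v_perp / |d_{t-1}|^2.
    Curvature is undefined (flagged invalid) on frames whose previous
    displacement is zero.
    """
    dx = np.diff(rec.x)
    dy = np.diff(rec.y)
    prev_sq = dx[:-1] ** 2 + dy[:-1] ** 2
    if prev_sq.size != len(obs):
        raise ValueError("observable series does not match trajectory length")
    out = replace(obs)
    out.speed = np.hypot(obs.v_par, obs.v_perp)
    valid = prev_sq > STATIONARY_EPS**2
    curv = np.full(len(obs), np.nan)
    curv[valid] = obs.v_perp[valid] / prev_sq[valid]
    out.curvature = curv
    out.curvature_valid = valid
    return out


def write_observables(obs: ObservableSeries, path) -> None:
    """Write per-frame observables as CSV."""
    cols = {"frame": obs.frames, "v_par": obs.v_par, "v_perp": obs.v_perp}
    if obs.speed is not None:
        cols["speed"] = obs.speed
    if obs.curvature is not None:
        cols["curvature"] = obs.curvature
    pd.DataFrame(cols).to_csv(path, index=False)
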