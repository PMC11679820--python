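"""Feature pipeline: frame standardization, Kalman smoothing, central point,
instantaneous speeds and min-max normalization.

The pipeline turns variable-length keypoint clips into fixed-size numeric
sequences:

1. every clip is randomly subsampled (order-preserving, without replacement)
   to the dataset's minimum frame count;
2. the tracked points used for velocities — torso central point (derived from
   shoulders and hips), nose, and both knees — are denoised with a per-axis
   constant-velocity Kalman filter;
3. instantaneous speed of each tracked point is the Euclidean distance
   between consecutive smoothed positions, with the first frame's speed
   defined as 0 (no movement assumed at the initial state);
4. coordinate and speed channels are min-max rescaled with statistics fitted
   on the training split only.

The torso central point is the midpoint of the two cross-body midpoints
(left shoulder <-> right hip, right shoulder <-> left hip); algebraically it
is the mean of the four landmarks.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .schema import (
    LANDMARK_NAMES,
    LEFT_HIP,
    LEFT_KNEE,
    LEFT_SHOULDER,
    N_LANDMARKS,
    NOSE,
    RIGHT_HIP,
    RIGHT_KNEE,
    RIGHT_SHOULDER,
    Clip,
    ClipDataset,
    PoseFrame,
)

SPEED_CHANNEL_NAMES = ("Central_Body_Speed", "Left_Knee_Speed", "Right_Knee_Speed")
NOSE_SPEED_CHANNEL = "Nose_Speed"


# ---------------------------------------------------------------------------
# frame standardization


def standard_frame_count(ds: ClipDataset) -> int:
    """The dataset-wide standard sequence length: the minimum clip length."""
    if not ds.clips:
        raise ValueError("empty dataset has no standard frame count")
    return min(len(clip) for clip in ds.clips)


def subsample_frames(clip: Clip, n: int, rng: np.random.Generator) -> Clip:
    """Keep a uniformly random size-``n`` subset of frames, in original order.

    Sampling is without replacement and the retained frames keep their
    original ``frame_index``, so temporal order (and gaps) remain visible.
    Upsampling is refused: ``n`` may not exceed the clip length.
    """
    if n < 2:
        raise ValueError(f"cannot subsample to {n} frames; need at least 2")
    if n > len(clip):
        raise ValueError(f"cannot subsample clip {clip.clip_id!r} of length {len(clip)} to {n} frames")
    keep = np.sort(rng.choice(len(clip), size=n, replace=False))
    return Clip(
        clip_id=clip.clip_id,
        label=clip.label,
        frames=[clip.frames[i] for i in keep],
        fps=clip.fps,
    )


# ---------------------------------------------------------------------------
# central point


def central_point(frame: PoseFrame) -> np.ndarray:
    """Torso center: midpoint of the shoulder<->opposite-hip midpoints."""
    c = frame.coords()
    m1 = (c[LEFT_SHOULDER] + c[RIGHT_HIP]) / 2.0
    m2 = (c[RIGHT_SHOULDER] + c[LEFT_HIP]) / 2.0
    return (m1 + m2) / 2.0


def central_point_series(coords: np.ndarray) -> np.ndarray:
    """Vectorized central point for a (T, 33, 3) coordinate array -> (T, 3)."""
    m1 = (coords[:, LEFT_SHOULDER] + coords[:, RIGHT_HIP]) / 2.0
    m2 = (coords[:, RIGHT_SHOULDER] + coords[:, LEFT_HIP]) / 2.0
    return (m1 + m2) / 2.0


# ---------------------------------------------------------------------------
# Kalman smoothing


@dataclass
class KalmanParams:
    """Linear-Gaussian filter matrices, applied independently to each data column.

    The default is a constant-velocity model per coordinate axis: state is
    (position, velocity), ``A = [[1, 1], [0, 1]]``, ``H = [1, 0]``.  The
    control term of the textbook update is fixed to zero — tracked body
    points are passively observed, there is no actuation input.  ``Q`` uses
    the discrete white-noise-acceleration form scaled by ``q``; ``R`` is the
    observation-noise variance.  ``initial_state=None`` seeds the position
    component from the first observation (velocity 0).
    """

    A: np.ndarray
    H: np.ndarray
    Q: np.ndarray
    R: np.ndarray
    initial_state: np.ndarray | None = None
    initial_covariance: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.A = np.atleast_2d(np.asarray(self.A, dtype=float))
        self.H = np.atleast_2d(np.asarray(self.H, dtype=float))
        self.Q = np.atleast_2d(np.asarray(self.Q, dtype=float))
        self.R = np.atleast_2d(np.asarray(self.R, dtype=float))
        n = self.A.shape[0]
        if self.A.shape != (n, n) or self.Q.shape != (n, n) or self.H.shape[1] != n:
            raise ValueError("inconsistent Kalman matrix dimensions")
        m = self.H.shape[0]
        if self.R.shape != (m, m):
            raise ValueError("R dimension does not match H")
        for name, mat in (("Q", self.Q), ("R", self.R)):
            if not np.allclose(mat, mat.T):
                raise ValueError(f"{name} must be symmetric")
            if np.min(np.linalg.eigvalsh(mat)) < -1e-12:
                raise ValueError(f"{name} must be positive semi-definite")
        if self.initial_covariance is None:
            self.initial_covariance = np.eye(n)
        else:
            self.initial_covariance = np.atleast_2d(np.asarray(self.initial_covariance, dtype=float))


def default_kalman_params(q: float = 1e-4, r: float = 2.5e-5) -> KalmanParams:
    """Constant-velocity defaults; ``r`` matches the generator's default noise variance."""
    A = np.array([[1.0, 1.0], [0.0, 1.0]])
    H = np.array([[1.0, 0.0]])
    Q = q * np.array([[0.25, 0.5], [0.5, 1.0]])
    R = np.array([[r]])
    return KalmanParams(A=A, H=H, Q=Q, R=R, initial_covariance=np.eye(2) * 1.0)


def kalman_smooth(series: np.ndarray, params: KalmanParams | None = None) -> np.ndarray:
    """Causal Kalman filtering of a (T,) or (T, d) series, column by column.

    Each output element is the filtered position estimate after assimilating
    the observation at that time step; the gain is recomputed every step from
    the propagated covariance.  Output has the same shape as the input.
    """
    params = params or default_kalman_params()
    z = np.asarray(series, dtype=float)
    squeeze = z.ndim == 1
    if squeeze:
        z = z[:, None]
    if z.ndim != 2:
        raise ValueError("series must be (T,) or (T, d)")
    if params.H.shape[0] != 1:
        raise ValueError("per-column filtering requires a single observation dimension")
    T, d = z.shape
    n = params.A.shape[0]
    out = np.empty_like(z)
    eye = np.eye(n)
    for col in range(d):
        if params.initial_state is None:
            x = np.zeros(n)
            x[np.argmax(params.H[0] != 0)] = z[0, col] / params.H[0][np.argmax(params.H[0] != 0)]
        else:
            x = np.asarray(params.initial_state, dtype=float).copy()
        P = params.initial_covariance.copy()
        for t in range(T):
            # predict
            x = params.A @ x
            P = params.A @ P @ params.A.T + params.Q
            # update
            S = params.H @ P @ params.H.T + params.R
            K = P @ params.H.T @ np.linalg.inv(S)
            innov = z[t, col] - params.H @ x
            x = x + (K @ innov.reshape(1))
            P = (eye - K @ params.H) @ P
            out[t, col] = (params.H @ x)[0]
    return out[:, 0] if squeeze else out


# ---------------------------------------------------------------------------
# speed


def speed_series(positions: np.ndarray) -> np.ndarray:
    """Per-frame instantaneous speed: Euclidean distance between consecutive
    positions, with the first element defined as 0."""
    p = np.asarray(positions, dtype=float)
    if p.ndim == 1:
        p = p[:, None]
    if len(p) == 0:
        raise ValueError("need at least one position")
    out = np.zeros(len(p))
    if len(p) > 1:
        out[1:] = np.linalg.norm(np.diff(p, axis=0), axis=1)
    return out


# ---------------------------------------------------------------------------
# feature assembly


@dataclass
class FeatureMatrix:
    """A clip rendered as a T x D numeric sequence with named channels."""

    clip_id: str
    label: str
    values: np.ndarray
    channel_names: list[str]

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 2 or self.values.shape[1] != len(self.channel_names):
            raise ValueError("values shape does not match channel_names")
        if not np.all(np.isfinite(self.values)):
            raise ValueError("feature matrix contains non-finite values")


def _coordinate_channel_names(include_visibility: bool) -> list[str]:
    names = []
    for i in range(N_LANDMARKS):
        for ax in ("x", "y", "z"):
            names.append(f"{i}_{ax}_({LANDMARK_NAMES[i]})")
        if include_visibility:
            names.append(f"{i}_v_({LANDMARK_NAMES[i]})")
    return names


def feature_channel_names(include_visibility: bool = False, include_nose_speed: bool = False) -> list[str]:
    names = _coordinate_channel_names(include_visibility)
    names.extend(SPEED_CHANNEL_NAMES)
    if include_nose_speed:
        names.append(NOSE_SPEED_CHANNEL)
    return names


def build_features(
    clip: Clip,
    n_frames: int,
    kalman: KalmanParams | None = None,
    rng: np.random.Generator | None = None,
    include_visibility: bool = False,
    include_nose_speed: bool = False,
    smooth_all: bool = False,
    use_2d_speed: bool = False,
) -> FeatureMatrix:
    """Subsample, smooth, differentiate and assemble one clip's channels.

    Channel layout: 33 x (x, y, z[, visibility]) landmark channels in
    landmark order, then the speed channels (central point, left knee, right
    knee[, nose]).  Speeds are computed from Kalman-smoothed positions; the
    central point is derived from smoothed shoulders/hips.  Positional
    channels stay raw unless ``smooth_all`` is set.
    """
    rng = rng or np.random.default_rng(0)
    sub = subsample_frames(clip, n_frames, rng) if n_frames < len(clip) else clip
    coords = sub.coords()  # (T, 33, 3)

    tracked = {NOSE, LEFT_SHOULDER, RIGHT_SHOULDER, LEFT_HIP, RIGHT_HIP, LEFT_KNEE, RIGHT_KNEE}
    smoothed = coords.copy()
    to_smooth = range(N_LANDMARKS) if smooth_all else sorted(tracked)
    for i in to_smooth:
        smoothed[:, i, :] = kalman_smooth(coords[:, i, :], kalman)

    dims = slice(0, 2) if use_2d_speed else slice(0, 3)
    central = central_point_series(smoothed)
    speed_sources = [central[:, dims], smoothed[:, LEFT_KNEE, dims], smoothed[:, RIGHT_KNEE, dims]]
    if include_nose_speed:
        speed_sources.append(smoothed[:, NOSE, dims])
    speeds = np.column_stack([speed_series(src) for src in speed_sources])

    pos = smoothed if smooth_all else coords
    T = pos.shape[0]
    if include_visibility:
        vis = sub.visibilities()[:, :, None]  # (T, 33, 1)
        coord_block = np.concatenate([pos, vis], axis=2).reshape(T, N_LANDMARKS * 4)
    else:
        coord_block = pos.reshape(T, N_LANDMARKS * 3)
    values = np.column_stack([coord_block, speeds])
    names = feature_channel_names(include_visibility, include_nose_speed)
    return FeatureMatrix(clip_id=clip.clip_id, label=clip.label, values=values, channel_names=names)


def prepare_features(
    ds: ClipDataset,
    n_frames: int | None = None,
    kalman: KalmanParams | None = None,
    seed: int = 0,
    **kwargs,
) -> list[FeatureMatrix]:
    """Standardize frame counts across a dataset and build every clip's features.

    ``n_frames=None`` uses the dataset minimum.  Each clip gets its own
    random stream spawned from ``seed`` so the subsampling is reproducible
    and independent of processing order.
    """
    if n_frames is None:
        n_frames = standard_frame_count(ds)
    children = np.random.SeedSequence(seed).spawn(len(ds.clips))
    return [
        build_features(clip, n_frames, kalman, np.random.default_rng(child), **kwargs)
        for clip, child in zip(ds.clips, children)
    ]


# ---------------------------------------------------------------------------
# min-max normalization


@dataclass
class NormalizationParams:
    """Per-channel min and max of the fitted (training) data."""

    x_min: np.ndarray
    x_max: np.ndarray
    channel_names: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.x_min = np.asarray(self.x_min, dtype=float)
        self.x_max = np.asarray(self.x_max, dtype=float)
        if self.x_min.shape != self.x_max.shape:
            raise ValueError("x_min and x_max must have the same shape")
        if np.any(self.x_max < self.x_min):
            raise ValueError("x_max must be >= x_min per channel")


def fit_minmax(train: list[FeatureMatrix]) -> NormalizationParams:
    """Per-channel min/max over every frame of every training clip."""
    if not train:
        raise ValueError("cannot fit normalization on an empty list")
    names = train[0].channel_names
    for m in train:
        if m.channel_names != names:
            raise ValueError("all feature matrices must share channel_names")
    stacked = np.vstack([m.values for m in train])
    return NormalizationParams(stacked.min(axis=0), stacked.max(axis=0), list(names))


def apply_minmax(m: FeatureMatrix, p: NormalizationParams) -> FeatureMatrix:
    """Affine rescale each channel by its fitted range: (x - min) / (max - min).

    Constant channels map to 0.  Values outside the fitted range are *not*
    clipped; on held-out data they can fall outside [0, 1].
    """
    if p.channel_names and m.channel_names != p.channel_names:
        raise ValueError("feature channels do not match normalization params")
    span = p.x_max - p.x_min
    safe = np.where(span > 0, span, 1.0)
    values = (m.values - p.x_min) / safe
    values[:, span == 0] = 0.0
    return FeatureMatrix(m.clip_id, m.label, values, list(m.channel_names))


def invert_minmax(m: FeatureMatrix, p: NormalizationParams) -> FeatureMatrix:
    """Inverse of :func:`apply_minmax` on non-constant channels."""
    span = p.x_max - p.x_min
    values = m.values * np.where(span > 0, span, 0.0) + p.x_min
    return FeatureMatrix(m.clip_id, m.label, values, list(m.channel_names))


def minmax_from_pairs(raw: tuple[float, float], normalized: tuple[float, float]) -> tuple[float, float]:
    """Recover (x_min, x_max) of the min-max map from two (raw, normalized) pairs.

    Given x_norm = (x - x_min) / (x_max - x_min) evaluated at two distinct raw
    values, the slope is s = dn/dr, so x_min = r1 - n1/s and x_max = x_min + 1/s.
    """
    (r1, r2), (n1, n2) = raw, normalized
    if r1 == r2:
        raise ValueError("raw values must be distinct")
    s = (n2 - n1) / (r2 - r1)
    if s <= 0:
        raise ValueError("normalized values must increase with raw values")
    x_min = r1 - n1 / s
    return x_min, x_min + 1.0 / s
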