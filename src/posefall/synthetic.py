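"""Synthetic labeled skeleton-motion clips in the 33-landmark pose schema.

The generator produces the class-conditional kinematic signatures a
speed-aware posture classifier must separate: a fast torso descent for
falls, slow descents for deliberate transitions (sit down, lie down), a
near-static body for sleeping/standing, and an ascent for standing up.
Dynamics are parametric sigmoidal transitions of torso-center height and
body inclination — not a physics simulation; the goal is controllable,
reproducible class structure, not photorealism.

Each frame is realized as a stick figure: all 33 landmarks are placed by a
fixed articulated offset table relative to the torso center, rotated by the
body inclination (0 = upright, pi/2 = horizontal/supine).  The mean of the
two shoulders and two hips equals the torso center exactly by construction,
so the central-point trajectory of a generated clip is the template's center
path plus observation noise.

Image conventions follow the pose-estimator output: coordinates are
normalized to the frame, and y grows downward, so falling *increases* y.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace

import numpy as np

from .schema import (
    CLASS_VOCABULARY,
    N_LANDMARKS,
    Clip,
    ClipDataset,
    Landmark,
    PoseFrame,
)

#: Peak-speed unit: one unit of ``peak_speed_scale`` corresponds to this
#: torso-center displacement per frame (image-normalized units).
BASE_PEAK_SPEED = 0.08

# Articulated offset table: (axial, lateral, depth) per landmark, in units of
# the body scale.  Axial is along the body axis (+ toward the head), lateral
# is + toward the subject's left, depth perturbs z.  Shoulders and hips are
# axially and laterally symmetric so their mean is exactly the torso center.
_OFFSETS: dict[int, tuple[float, float, float]] = {
    0: (0.30, 0.00, -0.05),   # nose
    1: (0.32, 0.02, -0.04),   # left eye inner
    2: (0.32, 0.03, -0.04),   # left eye
    3: (0.32, 0.04, -0.04),   # left eye outer
    4: (0.32, -0.02, -0.04),  # right eye inner
    5: (0.32, -0.03, -0.04),  # right eye
    6: (0.32, -0.04, -0.04),  # right eye outer
    7: (0.31, 0.06, -0.01),   # left ear
    8: (0.31, -0.06, -0.01),  # right ear
    9: (0.28, 0.015, -0.045),  # mouth left
    10: (0.28, -0.015, -0.045),  # mouth right
    11: (0.15, 0.11, 0.00),   # left shoulder
    12: (0.15, -0.11, 0.00),  # right shoulder
    13: (0.00, 0.16, 0.01),   # left elbow
    14: (0.00, -0.16, 0.01),  # right elbow
    15: (-0.14, 0.17, 0.01),  # left wrist
    16: (-0.14, -0.17, 0.01),  # right wrist
    17: (-0.18, 0.18, 0.01),  # left pinky
    18: (-0.18, -0.18, 0.01),  # right pinky
    19: (-0.18, 0.175, 0.00),  # left index
    20: (-0.18, -0.175, 0.00),  # right index
    21: (-0.17, 0.165, 0.00),  # left thumb
    22: (-0.17, -0.165, 0.00),  # right thumb
    23: (-0.15, 0.06, 0.00),  # left hip
    24: (-0.15, -0.06, 0.00),  # right hip
    25: (-0.42, 0.07, 0.00),  # left knee
    26: (-0.42, -0.07, 0.00),  # right knee
    27: (-0.68, 0.08, 0.00),  # left ankle
    28: (-0.68, -0.08, 0.00),  # right ankle
    29: (-0.71, 0.08, 0.02),  # left heel
    30: (-0.71, -0.08, 0.02),  # right heel
    31: (-0.70, 0.085, -0.04),  # left foot index
    32: (-0.70, -0.085, -0.04),  # right foot index
}


@dataclass
class MotionTemplate:
    """Parametric torso-center path and inclination transition for one class.

    ``peak_speed_scale`` sets the peak per-frame torso-center displacement in
    units of :data:`BASE_PEAK_SPEED`; the sigmoid sharpness is derived from
    it so the peak is attained regardless of clip duration.  Static postures
    use ``peak_speed_scale = 0`` (no deterministic center motion).
    """

    label: str
    duration_frames_range: tuple[int, int]
    start_height: float
    end_height: float
    start_inclination: float
    end_inclination: float
    transition_midpoint: float = 0.5
    peak_speed_scale: float = 0.0
    sway_amplitude: float = 0.0

    def __post_init__(self) -> None:
        lo, hi = self.duration_frames_range
        if not (2 <= lo <= hi):
            raise ValueError(f"empty or invalid duration range {self.duration_frames_range}")
        if self.peak_speed_scale < 0:
            raise ValueError("peak_speed_scale must be >= 0")


def default_templates() -> dict[str, MotionTemplate]:
    """One template per posture class.

    Falls are short and sharp; deliberate transitions are long and gentle;
    sleeping/standing are static postures.  `lie` descends from standing to
    supine, `lie_down` from a seated start, `sit_down` stops at a seated
    height, `stand_up` ascends from supine back to upright.
    """
    t = {
        "falling": MotionTemplate(
            "falling", (18, 28), 0.35, 0.72, 0.0, math.pi / 2, peak_speed_scale=1.0
        ),
        "lie": MotionTemplate(
            "lie", (45, 65), 0.35, 0.72, 0.0, math.pi / 2, peak_speed_scale=0.15
        ),
        "lie_down": MotionTemplate(
            "lie_down", (40, 60), 0.55, 0.72, 0.25, math.pi / 2, peak_speed_scale=0.15
        ),
        "sit_down": MotionTemplate(
            "sit_down", (35, 55), 0.35, 0.55, 0.0, 0.25, peak_speed_scale=0.12
        ),
        "sleeping": MotionTemplate(
            "sleeping", (50, 70), 0.72, 0.72, math.pi / 2, math.pi / 2, peak_speed_scale=0.0
        ),
        "standing": MotionTemplate(
            "standing", (40, 60), 0.35, 0.35, 0.0, 0.0, peak_speed_scale=0.0, sway_amplitude=0.003
        ),
        "stand_up": MotionTemplate(
            "stand_up", (45, 65), 0.72, 0.35, math.pi / 2, 0.0, peak_speed_scale=0.18
        ),
    }
    _check_separability(t)
    return t


def _check_separability(templates: dict[str, MotionTemplate]) -> None:
    # The class-separating assumption: falls are kinematically faster than
    # the deliberate descents the classifier must not confuse them with.
    fall = templates["falling"].peak_speed_scale
    for other in ("sit_down", "lie"):
        if other in templates and not fall > templates[other].peak_speed_scale:
            raise ValueError(
                f"falling peak_speed_scale ({fall}) must exceed {other}'s "
                f"({templates[other].peak_speed_scale})"
            )


@dataclass
class GeneratorConfig:
    """Study-condition knobs for the synthetic dataset.

    Defaults emulate a balanced collection of 100 clips per posture class
    with mild observation noise (sd 0.005 image units) and occasional
    low-visibility occlusions.
    """

    clips_per_class: int = 100
    templates: dict[str, MotionTemplate] = field(default_factory=default_templates)
    coordinate_noise_sd: float = 0.005
    occlusion_rate: float = 0.02
    seed: int = 0
    body_scale: float = 0.35
    fps: float = 30.0

    def __post_init__(self) -> None:
        if self.clips_per_class < 1:
            raise ValueError("clips_per_class must be >= 1")
        if self.coordinate_noise_sd < 0:
            raise ValueError("coordinate_noise_sd must be >= 0")
        if not (0.0 <= self.occlusion_rate < 1.0):
            raise ValueError("occlusion_rate must be in [0, 1)")
        _check_separability(self.templates)


def skeleton_from_pose_state(
    torso_center: np.ndarray, inclination: float, scale: float, frame_index: int = 1
) -> PoseFrame:
    """Realize all 33 landmarks from a torso center, inclination and body scale.

    Upright (inclination 0) puts the nose above the hips (smaller y); supine
    (inclination pi/2) lays the body axis horizontal so shoulder and hip y
    coincide.  The mean of landmarks 11, 12, 23, 24 equals ``torso_center``
    exactly.
    """
    if scale <= 0:
        raise ValueError("scale must be > 0")
    cx, cy, cz = (float(v) for v in torso_center)
    # body-axis direction (toward the head) and lateral direction in (x, y)
    ux, uy = math.sin(inclination), -math.cos(inclination)
    vx, vy = math.cos(inclination), math.sin(inclination)
    landmarks = []
    for i in range(N_LANDMARKS):
        a, l, d = _OFFSETS[i]
        a, l, d = a * scale, l * scale, d * scale
        landmarks.append(
            Landmark(
                index=i,
                x=cx + a * ux + l * vx,
                y=cy + a * uy + l * vy,
                z=cz + d,
                visibility=1.0,
            )
        )
    return PoseFrame(frame_index=frame_index, landmarks=landmarks)


def _ramp(phase: np.ndarray, midpoint: float, sharpness: float) -> np.ndarray:
    """Sigmoid transition rescaled to run exactly from 0 at phase 0 to 1 at phase 1."""
    if sharpness <= 0:
        return phase  # linear fallback; unused by the default templates
    s = 1.0 / (1.0 + np.exp(-sharpness * (phase - midpoint)))
    s0 = 1.0 / (1.0 + np.exp(sharpness * midpoint))
    s1 = 1.0 / (1.0 + np.exp(-sharpness * (1.0 - midpoint)))
    return (s - s0) / (s1 - s0)


def generate_clip(
    label: str,
    cfg: GeneratorConfig,
    rng: np.random.Generator,
    clip_id: str | None = None,
) -> Clip:
    """Draw one labeled clip from the class template plus observation noise.

    Frame count is drawn uniformly from the template's duration range; the
    torso center and inclination follow the sigmoid transition; every
    coordinate gets additive Gaussian noise; occluded frame-landmarks get
    visibility below 0.5 and inflated noise.
    """
    if label not in cfg.templates:
        raise ValueError(f"unknown label {label!r}")
    tpl = cfg.templates[label]
    lo, hi = tpl.duration_frames_range
    n = int(rng.integers(lo, hi + 1))
    phase = np.arange(n) / max(n - 1, 1)

    delta_h = tpl.end_height - tpl.start_height
    delta_incl = tpl.end_inclination - tpl.start_inclination
    travel = max(abs(delta_h), 1e-12)
    if tpl.peak_speed_scale > 0:
        # sharpness chosen so the peak per-frame center displacement is
        # peak_speed_scale * BASE_PEAK_SPEED, independent of duration
        sharpness = 4.0 * n * tpl.peak_speed_scale * BASE_PEAK_SPEED / travel
        ramp = _ramp(phase, tpl.transition_midpoint, sharpness)
    else:
        ramp = np.zeros(n)

    base_x = 0.5 + rng.uniform(-0.05, 0.05)
    base_z = rng.uniform(-0.02, 0.02)
    sway = tpl.sway_amplitude * np.sin(2 * np.pi * phase * rng.uniform(0.8, 1.2))
    center = np.column_stack(
        [
            np.full(n, base_x) + sway,
            tpl.start_height + delta_h * ramp,
            np.full(n, base_z),
        ]
    )
    inclination = tpl.start_inclination + delta_incl * ramp

    frames = []
    for t in range(n):
        frame = skeleton_from_pose_state(center[t], float(inclination[t]), cfg.body_scale, frame_index=t + 1)
        if cfg.coordinate_noise_sd > 0 or cfg.occlusion_rate > 0:
            noise = rng.normal(0.0, cfg.coordinate_noise_sd, size=(N_LANDMARKS, 3))
            occluded = rng.random(N_LANDMARKS) < cfg.occlusion_rate
            if occluded.any():
                noise[occluded] += rng.normal(0.0, 5 * cfg.coordinate_noise_sd, size=(int(occluded.sum()), 3))
            for i, lm in enumerate(frame.landmarks):
                lm.x += noise[i, 0]
                lm.y += noise[i, 1]
                lm.z += noise[i, 2]
                if occluded[i]:
                    lm.visibility = float(rng.uniform(0.05, 0.45))
        frames.append(frame)
    return Clip(clip_id=clip_id or f"{label}-0", label=label, frames=frames, fps=cfg.fps)


def generate_dataset(cfg: GeneratorConfig) -> ClipDataset:
    """Generate ``clips_per_class`` clips for each of the seven classes.

    Fully deterministic given the config (including its seed): per-clip
    random streams are spawned from one root seed sequence in a fixed order,
    and the final clip order is a seeded shuffle.
    """
    root = np.random.SeedSequence(cfg.seed)
    labels = [label for label in CLASS_VOCABULARY if label in cfg.templates]
    children = root.spawn(len(labels) * cfg.clips_per_class + 1)
    clips: list[Clip] = []
    k = 0
    for label in labels:
        for j in range(cfg.clips_per_class):
            rng = np.random.default_rng(children[k])
            k += 1
            clips.append(generate_clip(label, cfg, rng, clip_id=f"{label}_{j + 1:03d}"))
    shuffle_rng = np.random.default_rng(children[-1])
    order = shuffle_rng.permutation(len(clips))
    return ClipDataset(clips=[clips[i] for i in order], class_vocabulary=CLASS_VOCABULARY)
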