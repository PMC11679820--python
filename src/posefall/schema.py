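"""Pose data model: landmarks, frames, clips and dataset-level validation.

The schema mirrors the MediaPipe Pose output: 33 named landmarks per frame,
each with image-normalized ``x``/``y`` coordinates, a relative depth ``z``
and a ``visibility`` confidence in [0, 1].  ``y`` grows downward (image
convention), so a falling body *increases* its ``y`` coordinates.

Frames are 1-based in serialized files and kept as-is on the ``frame_index``
attribute; positional access into a clip is ordinary 0-based indexing.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

#: The 33 MediaPipe Pose landmark names, in landmark-index order.
LANDMARK_NAMES: tuple[str, ...] = (
    "Nose",
    "Left_Eye_Inner",
    "Left_Eye",
    "Left_Eye_Outer",
    "Right_Eye_Inner",
    "Right_Eye",
    "Right_Eye_Outer",
    "Left_Ear",
    "Right_Ear",
    "Mouth_Left",
    "Mouth_Right",
    "Left_Shoulder",
    "Right_Shoulder",
    "Left_Elbow",
    "Right_Elbow",
    "Left_Wrist",
    "Right_Wrist",
    "Left_Pinky",
    "Right_Pinky",
    "Left_Index",
    "Right_Index",
    "Left_Thumb",
    "Right_Thumb",
    "Left_Hip",
    "Right_Hip",
    "Left_Knee",
    "Right_Knee",
    "Left_Ankle",
    "Right_Ankle",
    "Left_Heel",
    "Right_Heel",
    "Left_Foot_Index",
    "Right_Foot_Index",
)

N_LANDMARKS = 33

# Landmark indices used by the feature pipeline.
NOSE = 0
LEFT_SHOULDER = 11
RIGHT_SHOULDER = 12
LEFT_HIP = 23
RIGHT_HIP = 24
LEFT_KNEE = 25
RIGHT_KNEE = 26

#: The seven posture classes, in vocabulary (output) order.
CLASS_VOCABULARY: tuple[str, ...] = (
    "falling",
    "lie",
    "lie_down",
    "sit_down",
    "sleeping",
    "standing",
    "stand_up",
)

FALL_CLASS = "falling"


@dataclass
class Landmark:
    """A single tracked anatomical point in one frame."""

    index: int
    x: float
    y: float
    z: float
    visibility: float = 1.0

    @property
    def name(self) -> str:
        return LANDMARK_NAMES[self.index]

    def as_array(self) -> np.ndarray:
        return np.array([self.x, self.y, self.z], dtype=float)


@dataclass
class PoseFrame:
    """One time step: 33 landmarks ordered by landmark index."""

    frame_index: int
    landmarks: list[Landmark]

    def coords(self) -> np.ndarray:
        """(33, 3) array of x, y, z in landmark order."""
        return np.array([[lm.x, lm.y, lm.z] for lm in self.landmarks], dtype=float)

    def visibilities(self) -> np.ndarray:
        return np.array([lm.visibility for lm in self.landmarks], dtype=float)


@dataclass
class Clip:
    """An ordered pose-frame sequence with a posture label — the unit of classification."""

    clip_id: str
    label: str
    frames: list[PoseFrame]
    fps: float = 30.0
    #: Speed columns carried through from an input table, keyed by column
    #: name; informational — the feature pipeline recomputes speeds itself.
    precomputed_speeds: dict[str, list[float]] = field(default_factory=dict)

    def __len__(self) -> int:
        return len(self.frames)

    def coords(self) -> np.ndarray:
        """(T, 33, 3) array of all frame coordinates."""
        return np.stack([f.coords() for f in self.frames])

    def visibilities(self) -> np.ndarray:
        """(T, 33) array of visibilities."""
        return np.stack([f.visibilities() for f in self.frames])


@dataclass
class ClipDataset:
    """A labeled collection of clips sharing one class vocabulary."""

    clips: list[Clip]
    class_vocabulary: tuple[str, ...] = CLASS_VOCABULARY

    def __len__(self) -> int:
        return len(self.clips)

    def labels(self) -> list[str]:
        return [c.label for c in self.clips]

    def counts_per_class(self) -> dict[str, int]:
        counts = {label: 0 for label in self.class_vocabulary}
        for clip in self.clips:
            counts[clip.label] = counts.get(clip.label, 0) + 1
        return counts


@dataclass
class Violation:
    """One schema-invariant breach, locating the clip/frame and naming the rule."""

    clip_id: str | None
    frame_index: int | None
    rule: str

    def __str__(self) -> str:  # pragma: no cover - cosmetic
        loc = []
        if self.clip_id is not None:
            loc.append(f"clip {self.clip_id!r}")
        if self.frame_index is not None:
            loc.append(f"frame {self.frame_index}")
        where = ", ".join(loc) or "dataset"
        return f"{where}: {self.rule}"


def _validate_frame(clip_id: str, frame: PoseFrame, out: list[Violation]) -> None:
    if len(frame.landmarks) != N_LANDMARKS:
        out.append(
            Violation(clip_id, frame.frame_index, f"expected {N_LANDMARKS} landmarks, found {len(frame.landmarks)}")
        )
    indices = [lm.index for lm in frame.landmarks]
    if sorted(indices) != list(range(len(frame.landmarks))) or indices != sorted(indices):
        out.append(Violation(clip_id, frame.frame_index, "landmark indices must be 0..32 in order with no gaps"))
    for lm in frame.landmarks:
        if not (0 <= lm.index <= 32):
            out.append(Violation(clip_id, frame.frame_index, f"landmark index {lm.index} outside [0, 32]"))
        if not (0.0 <= lm.visibility <= 1.0):
            out.append(
                Violation(clip_id, frame.frame_index, f"landmark {lm.index} visibility {lm.visibility} outside [0, 1]")
            )
        for axis in ("x", "y", "z"):
            v = getattr(lm, axis)
            if not np.isfinite(v):
                out.append(Violation(clip_id, frame.frame_index, f"landmark {lm.index} non-finite {axis}"))


def validate_clip(clip: Clip) -> list[Violation]:
    out: list[Violation] = []
    if len(clip.frames) < 2:
        out.append(Violation(clip.clip_id, None, f"clip has {len(clip.frames)} frames, need >= 2"))
    last = None
    for frame in clip.frames:
        if last is not None and frame.frame_index <= last:
            out.append(Violation(clip.clip_id, frame.frame_index, "frame_index not strictly increasing"))
        last = frame.frame_index
        _validate_frame(clip.clip_id, frame, out)
    if clip.fps <= 0:
        out.append(Violation(clip.clip_id, None, f"fps {clip.fps} must be > 0"))
    return out


def validate_dataset(ds: ClipDataset) -> list[Violation]:
    """Report every schema-invariant breach; an empty list means the dataset conforms."""
    out: list[Violation] = []
    seen_ids: set[str] = set()
    vocab = set(ds.class_vocabulary)
    for clip in ds.clips:
        if clip.clip_id in seen_ids:
            out.append(Violation(clip.clip_id, None, "duplicate clip_id"))
        seen_ids.add(clip.clip_id)
        if clip.label not in vocab:
            out.append(Violation(clip.clip_id, None, f"label {clip.label!r} not in class vocabulary"))
        out.extend(validate_clip(clip))
    return out
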