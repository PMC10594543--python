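"""Core in-memory containers shared across the pipeline.

All images are numpy arrays in (row, column[, channel]) order with a fixed
R, G, B channel order; binary masks hold exactly {0, 255} as uint8.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from . import device


def _as_uint8_rgb(frame: np.ndarray) -> np.ndarray:
    frame = np.asarray(frame)
    if frame.ndim != 3 or frame.shape[2] != 3:
        raise ValueError(f"expected an HxWx3 RGB image, got shape {frame.shape}")
    if frame.dtype != np.uint8:
        raise ValueError(f"expected uint8 pixels, got dtype {frame.dtype}")
    return frame


def validate_binary_mask(mask: np.ndarray) -> np.ndarray:
    """Check a mask is single-channel uint8 with values in {0, 255}."""
    mask = np.asarray(mask)
    if mask.ndim != 2:
        raise ValueError(f"mask must be 2-D, got shape {mask.shape}")
    bad = np.setdiff1d(np.unique(mask), [0, 255])
    if bad.size:
        raise ValueError(f"mask contains values outside {{0, 255}}: {bad.tolist()}")
    return mask.astype(np.uint8, copy=False)


@dataclass
class FrameStack:
    """Ordered same-shape 8-bit RGB frames with physical metadata.

    Parameters
    ----------
    frames : ndarray, shape (n_frames, H, W, 3), uint8
    um_per_px : float
        Physical pixel pitch in micrometres (1.85 for the device).
    fps : float
        Acquisition frame rate.
    """

    frames: np.ndarray
    um_per_px: float = device.UM_PER_PX
    fps: float = device.FRAME_RATE_FPS

    def __post_init__(self) -> None:
        self.frames = np.asarray(self.frames)
        if self.frames.ndim != 4 or self.frames.shape[3] != 3:
            raise ValueError(
                f"frames must have shape (n, H, W, 3), got {self.frames.shape}")
        if self.frames.shape[0] < 1:
            raise ValueError("a FrameStack needs at least one frame")
        if self.frames.dtype != np.uint8:
            raise ValueError(f"frames must be uint8, got {self.frames.dtype}")

    @classmethod
    def from_list(cls, frames: list[np.ndarray], um_per_px: float = device.UM_PER_PX,
                  fps: float = device.FRAME_RATE_FPS) -> "FrameStack":
        if not frames:
            raise ValueError("empty frame list")
        shapes = {f.shape for f in frames}
        if len(shapes) != 1:
            raise ValueError(f"frames have non-uniform shapes: {sorted(shapes)}")
        return cls(np.stack([_as_uint8_rgb(f) for f in frames]), um_per_px, fps)

    @property
    def n_frames(self) -> int:
        return self.frames.shape[0]

    @property
    def frame_shape(self) -> tuple[int, int]:
        return self.frames.shape[1], self.frames.shape[2]


@dataclass
class CompositeImage:
    """A still distilled from a stack by per-pixel minimum-G frame selection.

    ``source_frame_index[y, x]`` records which frame supplied pixel (y, x);
    ``image[y, x]`` equals that frame's full RGB value exactly.
    """

    image: np.ndarray
    source_frame_index: np.ndarray
    um_per_px: float = device.UM_PER_PX

    def __post_init__(self) -> None:
        self.image = _as_uint8_rgb(self.image)
        if self.source_frame_index.shape != self.image.shape[:2]:
            raise ValueError("source_frame_index grid must match the image grid")


@dataclass
class StabilizationResult:
    """Aligned frames plus the per-frame template-match locations.

    ``offsets[k]`` is the (x, y) top-left pixel of the best-matching window
    of frame k; the aligned frame is the crop at that location.
    """

    aligned: FrameStack
    offsets: list[tuple[int, int]]
    template_size: tuple[int, int]  # (w, h)

    def __post_init__(self) -> None:
        w, h = self.template_size
        if self.aligned.frame_shape != (h, w):
            raise ValueError("aligned frames must equal the template size")
        if len(self.offsets) != self.aligned.n_frames:
            raise ValueError("one offset per frame required")


@dataclass
class SceneGroundTruth:
    """Full ground truth emitted alongside a synthetic scene.

    The capillary mask lives in the coordinates of the un-jittered scene
    (frame 0 is rendered at zero offset).
    """

    capillary_mask: np.ndarray
    region_count: int
    jitter_offsets: list[tuple[int, int]]
    per_vessel_intermittent: list[bool] = field(default_factory=list)
    # per vessel: ((y, x) probe pixel on the centerline, frames covering it)
    probes: list[tuple[tuple[int, int], list[int]]] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.capillary_mask = validate_binary_mask(self.capillary_mask)
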