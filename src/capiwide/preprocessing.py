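"""Raw video -> contrast-enhanced still.

Four stages, applied in order:

1. **Stabilization** — the central crop of the first frame is the template;
   every frame is searched exhaustively for the window with the highest
   zero-mean normalized cross-correlation and cropped there. Integer-pixel
   body/operator motion up to the margin is removed exactly.
2. **Minimum-G compositing** — per pixel, the frame with the lowest green
   value is selected and its full RGB value copied. RBCs absorb green, so
   this accumulates every moment an RBC passed and closes the gaps a single
   frame would show.
3. **Flat-fielding** — each channel is divided by a heavily mean-filtered
   copy of itself to remove vignetting, then rescaled back to 8 bits.
4. **Contrast enhancement** — per-channel histogram equalization followed by
   gamma correction (default gamma = 0.3).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Literal

import numpy as np
from scipy import ndimage
from skimage.feature import match_template

from .datatypes import CompositeImage, FrameStack, StabilizationResult

__all__ = [
    "FlatFieldConfig", "ContrastConfig", "stabilize", "min_green_composite",
    "flatten_illumination", "enhance_contrast", "preprocess_video",
]


@dataclass
class FlatFieldConfig:
    """Mean-filter flat-fielding parameters.

    ``kernel_radius_px`` is the mean-filter radius (window edge 2r+1); 300 px
    matches the scale of the device's vignetting. ``rescale`` controls how
    the dimensionless ratio returns to 8 bits: multiply by the channel's
    global mean (default, leaves a constant image untouched) or by mid-gray
    128.
    """

    kernel_radius_px: int = 300
    border_mode: Literal["reflect", "replicate"] = "reflect"
    rescale: Literal["global_channel_mean", "fixed_midgray"] = "global_channel_mean"

    def validate(self) -> None:
        if self.kernel_radius_px < 1:
            raise ValueError("kernel_radius_px must be >= 1")
        if self.border_mode not in ("reflect", "replicate"):
            raise ValueError(f"unknown border_mode {self.border_mode!r}")
        if self.rescale not in ("global_channel_mean", "fixed_midgray"):
            raise ValueError(f"unknown rescale {self.rescale!r}")


@dataclass
class ContrastConfig:
    gamma: float = 0.3
    apply_equalization: bool = True

    def validate(self) -> None:
        if not self.gamma > 0:
            raise ValueError("gamma must be positive")


def _check_rgb(image: np.ndarray) -> np.ndarray:
    image = np.asarray(image)
    if image.ndim != 3 or image.shape[2] != 3 or image.dtype != np.uint8:
        raise ValueError("expected an 8-bit HxWx3 RGB image")
    return image


def stabilize(stack: FrameStack, template_margin_px: int = 50) -> StabilizationResult:
    """Align all frames to the central crop of the first frame.

    The template is the central (W-2m) x (H-2m) crop of frame 0. For each
    frame the location maximizing the zero-mean normalized cross-correlation
    (the normalized-coefficient statistic) is found over every valid integer
    position; ties resolve to the smallest (y, x). Matching runs on the
    channel-mean intensity. Drift up to +-m px is correctable.
    """
    m = int(template_margin_px)
    if m < 1:
        raise ValueError("template_margin_px must be >= 1")
    h, w = stack.frame_shape
    if h <= 2 * m or w <= 2 * m:
        raise ValueError(
            f"frames of {w}x{h} px cannot host a 2x{m} px stabilization margin")
    gray = stack.frames.mean(axis=3)
    template = gray[0, m:h - m, m:w - m]
    if np.ptp(template) == 0:
        raise ValueError("untextured template: zero variance in the central crop")

    th, tw = template.shape
    offsets: list[tuple[int, int]] = []
    aligned = np.empty((stack.n_frames, th, tw, 3), dtype=np.uint8)
    for k in range(stack.n_frames):
        # response grid covers all (2m+1)^2 valid top-left positions
        response = match_template(gray[k], template, pad_input=False)
        y, x = np.unravel_index(np.argmax(response), response.shape)
        offsets.append((int(x), int(y)))
        aligned[k] = stack.frames[k, y:y + th, x:x + tw]

    return StabilizationResult(
        aligned=FrameStack(aligned, stack.um_per_px, stack.fps),
        offsets=offsets,
        template_size=(tw, th),
    )


def min_green_composite(stack: FrameStack) -> CompositeImage:
    """Per-pixel minimum-green frame selection.

    For each pixel, the frame whose G value is lowest supplies the full RGB
    value; ties go to the earliest frame.
    """
    green = stack.frames[..., 1]
    src = np.argmin(green, axis=0)  # first occurrence = earliest frame
    idx = src[None, ..., None]
    image = np.take_along_axis(stack.frames, idx, axis=0)[0]
    return CompositeImage(image=image, source_frame_index=src,
                          um_per_px=stack.um_per_px)


_SCIPY_MODE = {"reflect": "mirror", "replicate": "nearest"}


def flatten_illumination(image: CompositeImage | np.ndarray,
                         cfg: FlatFieldConfig | None = None) -> np.ndarray:
    """Remove smooth brightness unevenness by mean-filter division.

    Each channel is divided by its mean-filtered copy (denominator floored
    at 1 count to guard dark corners) and the ratio rescaled to 8 bits per
    ``cfg.rescale``; a constant image is a fixed point under the default
    rescale.
    """
    cfg = cfg or FlatFieldConfig()
    cfg.validate()
    arr = image.image if isinstance(image, CompositeImage) else image
    arr = _check_rgb(arr)
    size = 2 * cfg.kernel_radius_px + 1
    mode = _SCIPY_MODE[cfg.border_mode]
    out = np.empty_like(arr)
    for c in range(3):
        ch = arr[..., c].astype(np.float64)
        smooth = ndimage.uniform_filter(ch, size=size, mode=mode)
        ratio = ch / np.maximum(smooth, 1.0)
        gain = ch.mean() if cfg.rescale == "global_channel_mean" else 128.0
        out[..., c] = np.clip(np.floor(ratio * gain + 0.5), 0, 255).astype(np.uint8)
    return out


def _equalize_channel(ch: np.ndarray) -> np.ndarray:
    """256-bin histogram equalization with min-bin normalisation.

    The LUT maps the lowest occupied bin to 0 and the cumulative histogram
    above it linearly to [0, 255]; a constant channel is returned unchanged.
    """
    hist = np.bincount(ch.ravel(), minlength=256)
    i0 = int(np.flatnonzero(hist)[0])
    total = ch.size
    if hist[i0] == total:
        return ch.copy()
    cum = np.cumsum(hist)
    scale = 255.0 / (total - hist[i0])
    lut = np.zeros(256, dtype=np.uint8)
    lut[i0 + 1:] = np.clip(np.round((cum[i0 + 1:] - cum[i0]) * scale),
                           0, 255).astype(np.uint8)
    return lut[ch]


def gamma_lut(gamma: float) -> np.ndarray:
    """8-bit gamma LUT: v -> round(255 * (v/255)**gamma); fixes 0 and 255."""
    if not gamma > 0:
        raise ValueError("gamma must be positive")
    v = np.arange(256) / 255.0
    return np.clip(np.round(255.0 * v ** gamma), 0, 255).astype(np.uint8)


def enhance_contrast(image: np.ndarray, cfg: ContrastConfig | None = None) -> np.ndarray:
    """Per-channel histogram equalization followed by gamma correction."""
    cfg = cfg or ContrastConfig()
    cfg.validate()
    arr = _check_rgb(image)
    lut = gamma_lut(cfg.gamma)
    out = np.empty_like(arr)
    for c in range(3):
        ch = arr[..., c]
        if cfg.apply_equalization:
            ch = _equalize_channel(ch)
        out[..., c] = lut[ch]
    return out


def preprocess_video(stack: FrameStack,
                     flat: FlatFieldConfig | None = None,
                     con: ContrastConfig | None = None,
                     template_margin_px: int = 50) -> np.ndarray:
    """Full pipeline: stabilize -> min-G composite -> flat-field -> contrast.

    A margin of 0 skips stabilization (already-aligned input).
    """
    if template_margin_px == 0:
        aligned = stack
    else:
        aligned = stabilize(stack, template_margin_px).aligned
    composite = min_green_composite(aligned)
    flattened = flatten_illumination(composite, flat)
    return enhance_contrast(flattened, con)
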