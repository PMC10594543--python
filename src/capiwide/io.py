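"""Readers and writers for frames, stills, masks and offsets.

Frames live on disk as zero-padded numbered PNGs in a directory, a
multi-page TIFF, or a common video container; masks as single-channel PNGs
with exactly {0, 255}. Everything is normalized to (R, G, B) channel order
in memory. Video containers are supported but discouraged: lossy codecs
perturb the per-pixel minimum-G selection.
"""

from __future__ import annotations

import hashlib
import json
import logging
from pathlib import Path

import imageio.v3 as iio
import numpy as np
import pandas as pd
import tifffile
import yaml

from . import device
from .datatypes import FrameStack, validate_binary_mask

log = logging.getLogger("capiwide")

_FRAME_EXTS = (".png", ".tif", ".tiff")
_VIDEO_EXTS = (".mp4", ".avi", ".mov", ".mkv")


def _normalize_frame(frame: np.ndarray, origin: str) -> np.ndarray:
    frame = np.asarray(frame)
    if frame.ndim == 2:
        frame = np.stack([frame] * 3, axis=-1)
    if frame.ndim == 3 and frame.shape[2] == 4:
        frame = frame[..., :3]  # drop alpha
    if frame.ndim != 3 or frame.shape[2] != 3:
        raise ValueError(f"{origin}: cannot interpret shape {frame.shape} as RGB")
    if frame.dtype != np.uint8:
        raise ValueError(f"{origin}: expected 8-bit pixels, got {frame.dtype}")
    return frame


def read_frames(path: str | Path, um_per_px: float = device.UM_PER_PX,
                fps: float = device.FRAME_RATE_FPS) -> FrameStack:
    """Load a frame directory, a multi-page TIFF, or a video container."""
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(f"frame source does not exist: {path}")
    if path.is_dir():
        files = sorted(p for p in path.iterdir()
                       if p.suffix.lower() in _FRAME_EXTS)
        if not files:
            raise FileNotFoundError(f"no frame files in {path}")
        frames = []
        for f in files:
            frames.append(_normalize_frame(iio.imread(f), str(f)))
        shapes = {fr.shape for fr in frames}
        if len(shapes) != 1:
            ref = frames[0].shape
            for f, fr in zip(files, frames):
                if fr.shape != ref:
                    raise ValueError(
                        f"frame {f} has shape {fr.shape}, expected {ref}")
        return FrameStack(np.stack(frames), um_per_px, fps)
    if path.suffix.lower() in (".tif", ".tiff"):
        arr = tifffile.imread(path)
        if arr.ndim == 3 and arr.shape[-1] == 3:
            arr = arr[None]
        frames = [_normalize_frame(fr, f"{path}[{i}]") for i, fr in enumerate(arr)]
        return FrameStack(np.stack(frames), um_per_px, fps)
    if path.suffix.lower() in _VIDEO_EXTS:
        log.warning("reading lossy video container %s: compression may alter "
                    "minimum-G composites", path)
        arr = iio.imread(path)
        frames = [_normalize_frame(fr, f"{path}[{i}]") for i, fr in enumerate(arr)]
        return FrameStack(np.stack(frames), um_per_px, fps)
    raise ValueError(f"unsupported frame source: {path}")


def write_frames(stack: FrameStack, out_dir: str | Path) -> list[Path]:
    """Write frames as frame_0000.png ... in a directory."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    paths = []
    for i, frame in enumerate(stack.frames):
        p = out_dir / f"frame_{i:04d}.png"
        iio.imwrite(p, frame)
        paths.append(p)
    return paths


def write_still(image: np.ndarray, path: str | Path) -> Path:
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    iio.imwrite(path, image)
    return path


def read_still(path: str | Path) -> np.ndarray:
    return _normalize_frame(iio.imread(path), str(path))


def write_mask(mask: np.ndarray, path: str | Path) -> Path:
    """Write a {0, 255} mask as a single-channel PNG."""
    mask = validate_binary_mask(mask)
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    iio.imwrite(path, mask)
    return path


def read_mask(path: str | Path) -> np.ndarray:
    """Read a mask PNG; a 3-channel mask with consistent channels collapses."""
    arr = np.asarray(iio.imread(path))
    if arr.ndim == 3:
        if arr.shape[2] == 4:
            arr = arr[..., :3]
        if not (arr[..., 0] == arr[..., 1:].transpose(2, 0, 1)).all():
            raise ValueError(f"{path}: 3-channel mask with inconsistent channels")
        arr = arr[..., 0]
    return validate_binary_mask(arr)


def write_offsets_csv(offsets: list[tuple[int, int]], path: str | Path) -> Path:
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    pd.DataFrame([{"frame": i, "dx": dx, "dy": dy}
                  for i, (dx, dy) in enumerate(offsets)]).to_csv(path, index=False)
    return path


def read_offsets_csv(path: str | Path) -> list[tuple[int, int]]:
    df = pd.read_csv(path)
    return [(int(r.dx), int(r.dy)) for r in df.itertuples()]


def write_probability_map(prob: np.ndarray, path: str | Path) -> Path:
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    tifffile.imwrite(path, prob.astype(np.float32))
    return path


def load_yaml(path: str | Path) -> dict:
    with open(path) as fh:
        data = yaml.safe_load(fh)
    return data or {}


def save_yaml(data: dict, path: str | Path) -> Path:
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    path.write_text(yaml.safe_dump(data, sort_keys=True))
    return path


def write_provenance(artifact: str | Path, config: dict, seed: int | None,
                     stage: str) -> Path:
    """JSON sidecar recording how an artifact was produced."""
    digest = hashlib.sha256(
        json.dumps(config, sort_keys=True, default=str).encode()).hexdigest()
    sidecar = {
        "stage": stage,
        "seed": seed,
        "config_sha256": digest,
        "config": config,
        "package": "capiwide 0.1.0",
    }
    p = Path(str(artifact) + ".provenance.json")
    p.write_text(json.dumps(sidecar, indent=2, default=str))
    return p
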