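"""Shared fixtures and independent brute-force oracles.

The oracles here are deliberately naive (per-pixel loops, stack flood fill,
exhaustive SSD search) so they stay independent of the vectorized
implementations they check.
"""

from __future__ import annotations

import numpy as np
import pytest

import capiwide as cw


# ---------------------------------------------------------------------------
# oracles


def naive_min_green(frames: np.ndarray) -> np.ndarray:
    """Per-pixel loop: earliest frame with minimal G supplies the pixel."""
    n, h, w, _ = frames.shape
    out = np.empty((h, w, 3), dtype=np.uint8)
    for y in range(h):
        for x in range(w):
            best, best_g = 0, frames[0, y, x, 1]
            for k in range(1, n):
                g = frames[k, y, x, 1]
                if g < best_g:
                    best, best_g = k, g
            out[y, x] = frames[best, y, x]
    return out


def ssd_match(image: np.ndarray, template: np.ndarray) -> tuple[int, int]:
    """Exhaustive sum-of-squared-differences search; returns (x, y)."""
    ih, iw = image.shape
    th, tw = template.shape
    best, best_pos = None, None
    for y in range(ih - th + 1):
        for x in range(iw - tw + 1):
            win = image[y:y + th, x:x + tw].astype(np.float64)
            ssd = ((win - template) ** 2).sum()
            if best is None or ssd < best:
                best, best_pos = ssd, (x, y)
    return best_pos


def flood_fill_regions(mask: np.ndarray, connectivity: int = 8) -> list[int]:
    """Stack-based flood fill; returns sorted component areas."""
    fg = mask > 0
    seen = np.zeros_like(fg)
    if connectivity == 8:
        nbrs = [(dy, dx) for dy in (-1, 0, 1) for dx in (-1, 0, 1)
                if (dy, dx) != (0, 0)]
    else:
        nbrs = [(-1, 0), (1, 0), (0, -1), (0, 1)]
    areas = []
    h, w = fg.shape
    for sy in range(h):
        for sx in range(w):
            if not fg[sy, sx] or seen[sy, sx]:
                continue
            stack, area = [(sy, sx)], 0
            seen[sy, sx] = True
            while stack:
                y, x = stack.pop()
                area += 1
                for dy, dx in nbrs:
                    ny, nx = y + dy, x + dx
                    if 0 <= ny < h and 0 <= nx < w and fg[ny, nx] and not seen[ny, nx]:
                        seen[ny, nx] = True
                        stack.append((ny, nx))
            areas.append(area)
    return sorted(areas)


def loop_pixel_confusion(pred: np.ndarray, gt: np.ndarray) -> tuple[int, int, int, int]:
    """Per-pixel loop cross-tabulation -> (tp, tn, fp, fn)."""
    tp = tn = fp = fn = 0
    for y in range(pred.shape[0]):
        for x in range(pred.shape[1]):
            p, g = pred[y, x] > 0, gt[y, x] > 0
            if p and g:
                tp += 1
            elif p:
                fp += 1
            elif g:
                fn += 1
            else:
                tn += 1
    return tp, tn, fp, fn


# ---------------------------------------------------------------------------
# fixtures


@pytest.fixture(scope="session")
def small_scene():
    """A seeded small scene reused across read-only tests."""
    cfg = cw.SceneConfig(width_px=160, height_px=120, n_frames=20,
                         n_capillaries=5, seed=3, jitter_max_px=2,
                         n_distractors=2)
    stack, gt = cw.generate_scene(cfg)
    return cfg, stack, gt


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)


def textured_stack(rng: np.random.Generator, n=5, h=48, w=64,
                   shifts=None) -> tuple[cw.FrameStack, list[tuple[int, int]]]:
    """Frames that are integer-shifted views of one textured scene."""
    pad = 10
    scene = rng.integers(0, 256, (h + 2 * pad, w + 2 * pad, 3), dtype=np.uint8)
    if shifts is None:
        shifts = [(0, 0)] + [tuple(rng.integers(-4, 5, 2)) for _ in range(n - 1)]
    frames = []
    for dx, dy in shifts:
        frames.append(scene[pad - dy:pad - dy + h, pad - dx:pad - dx + w])
    return cw.FrameStack(np.stack(frames)), shifts
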