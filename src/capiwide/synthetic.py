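"""Seeded synthetic capillaroscopy scenes with full ground truth.

Skin capillaries are invisible under reflected light until red blood cells
(RBCs) pass through them: an RBC packet absorbs green strongly, so a perfused
segment shows up as a local G-channel depression. The generator emulates the
device's output at that level of realism: tortuous sub-10-px vessels on a
textured skin-coloured background, RBC packets advancing along each vessel
frame to frame, multiplicative vignetting, integer camera jitter with
replicate-edge fill, and static non-vessel distractors (stains, sweat-gland
spots, hairs). Everything is driven by one integer seed and the ground truth
(vessel mask, region count, per-frame jitter) is emitted alongside the video.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage

from . import device
from .datatypes import FrameStack, SceneGroundTruth

_EIGHT = np.ones((3, 3), dtype=bool)


@dataclass
class SceneConfig:
    """Parameters of one synthetic scene.

    ``vessel_width_px`` spans the outer-diameter scale of skin capillaries
    (~10 um ~ 5.4 px at 1.85 um/px). ``perfusion_fraction`` is the fraction
    of vessels with intermittent RBC traffic; the rest are filled in every
    frame. ``rbc_contrast`` is the G-channel depression (8-bit counts) under
    an RBC packet — the device's actual contrast is not documented, so it is
    a free parameter rather than a constant.
    """

    width_px: int = 256
    height_px: int = 192
    n_frames: int = device.N_ANALYSIS_FRAMES
    fps: float = device.FRAME_RATE_FPS
    um_per_px: float = device.UM_PER_PX
    n_capillaries: int = 8
    vessel_width_px: tuple[float, float] = (2.0, 6.0)
    perfusion_fraction: float = 0.5
    rbc_speed_px_per_frame: tuple[float, float] = (2.0, 6.0)
    rbc_contrast: float = 60.0
    vignette_strength: float = 0.35
    jitter_max_px: int = 3
    n_distractors: int = 4
    noise_sigma: float = 2.0
    seed: int = 0

    def validate(self) -> None:
        if self.width_px <= 0 or self.height_px <= 0:
            raise ValueError("zero-area canvas")
        if self.n_frames < 1:
            raise ValueError("n_frames must be >= 1")
        if self.n_capillaries < 0 or self.n_distractors < 0:
            raise ValueError("counts must be non-negative")
        if not (0.0 <= self.perfusion_fraction <= 1.0):
            raise ValueError("perfusion_fraction must lie in [0, 1]")
        if not (0.0 <= self.vignette_strength < 1.0):
            raise ValueError("vignette_strength must lie in [0, 1)")
        if self.jitter_max_px < 0:
            raise ValueError("jitter_max_px must be non-negative")
        if 2 * self.jitter_max_px >= min(self.width_px, self.height_px):
            raise ValueError("jitter would shift content fully out of frame")
        for name in ("vessel_width_px", "rbc_speed_px_per_frame"):
            lo, hi = getattr(self, name)
            if not (0 < lo <= hi):
                raise ValueError(f"{name} range is empty or non-positive")


def default_device_config(width_px: int = device.SENSOR_WIDTH_PX,
                          height_px: int = device.SENSOR_HEIGHT_PX,
                          **overrides) -> SceneConfig:
    """Scene config matching the device: 1.85 um/px, 30 fps, 150 frames.

    The canvas defaults to the full 4000x3000 sensor; pass a smaller size
    for desk-scale runs.
    """
    cfg = SceneConfig(width_px=width_px, height_px=height_px,
                      n_frames=device.N_ANALYSIS_FRAMES,
                      fps=device.FRAME_RATE_FPS,
                      um_per_px=device.UM_PER_PX)
    for key, val in overrides.items():
        if not hasattr(cfg, key):
            raise TypeError(f"unknown SceneConfig field {key!r}")
        setattr(cfg, key, val)
    cfg.validate()
    return cfg


@dataclass
class _Vessel:
    centerline: np.ndarray          # (L, 2) float (y, x), unit arc step
    width_px: float
    intermittent: bool
    speed: float = 0.0              # px / frame
    packet_len: float = 0.0         # arc-length px
    phase: float = 0.0

    def covered_arcs(self, t: int) -> list[tuple[float, float]]:
        """Arc-length intervals occupied by RBCs at frame t (wrapping)."""
        L = float(len(self.centerline))
        if not self.intermittent:
            return [(0.0, L)]
        s0 = (self.phase + self.speed * t) % L
        s1 = s0 + self.packet_len
        if s1 <= L:
            return [(s0, s1)]
        return [(s0, L), (0.0, s1 - L)]


def _random_centerline(rng: np.random.Generator, cfg: SceneConfig,
                       margin: float) -> np.ndarray:
    """Smoothed 2-D random walk: unit steps, bounded curvature, border reflect."""
    h, w = cfg.height_px, cfg.width_px
    length = int(rng.uniform(0.35, 0.7) * min(h, w))
    length = max(length, 12)
    y = rng.uniform(margin, h - margin)
    x = rng.uniform(margin, w - margin)
    theta = rng.uniform(0, 2 * np.pi)
    pts = np.empty((length, 2))
    for i in range(length):
        pts[i] = (y, x)
        theta += np.clip(rng.normal(0.0, 0.18), -0.35, 0.35)
        y += np.sin(theta)
        x += np.cos(theta)
        if not (margin <= y <= h - margin):
            theta = -theta
            y = np.clip(y, margin, h - margin)
        if not (margin <= x <= w - margin):
            theta = np.pi - theta
            x = np.clip(x, margin, w - margin)
    return pts


def _stamp_disks(mask: np.ndarray, points: np.ndarray, radius: float) -> None:
    """Set True in ``mask`` on a disk of ``radius`` around each point."""
    r = max(int(np.ceil(radius)), 1)
    dy, dx = np.mgrid[-r:r + 1, -r:r + 1]
    disk = dy * dy + dx * dx <= max(radius, 0.5) ** 2
    oy, ox = np.nonzero(disk)
    oy, ox = oy - r, ox - r
    h, w = mask.shape
    ys = (np.round(points[:, 0]).astype(int)[:, None] + oy[None, :]).ravel()
    xs = (np.round(points[:, 1]).astype(int)[:, None] + ox[None, :]).ravel()
    keep = (ys >= 0) & (ys < h) & (xs >= 0) & (xs < w)
    mask[ys[keep], xs[keep]] = True


def _footprint(vessel: _Vessel, shape: tuple[int, int],
               arcs: list[tuple[float, float]] | None = None) -> np.ndarray:
    mask = np.zeros(shape, dtype=bool)
    if arcs is None:
        pts = vessel.centerline
    else:
        idx = np.arange(len(vessel.centerline))
        keep = np.zeros(len(idx), dtype=bool)
        for s0, s1 in arcs:
            keep |= (idx >= s0) & (idx < s1)
        pts = vessel.centerline[keep]
    if len(pts):
        _stamp_disks(mask, pts, vessel.width_px / 2.0)
    return mask


def _build_vessels(rng: np.random.Generator, cfg: SceneConfig) -> list[_Vessel]:
    vessels: list[_Vessel] = []
    occupied = np.zeros((cfg.height_px, cfg.width_px), dtype=bool)
    n_intermittent = int(round(cfg.perfusion_fraction * cfg.n_capillaries))
    flags = rng.permutation(
        [True] * n_intermittent + [False] * (cfg.n_capillaries - n_intermittent))
    for i in range(cfg.n_capillaries):
        width = rng.uniform(*cfg.vessel_width_px)
        margin = max(8.0, width + 2 + cfg.jitter_max_px)
        # keep vessels disjoint when the canvas allows it: retry placements
        # whose footprint (padded by 2 px) touches an existing vessel
        for _ in range(20):
            cl = _random_centerline(rng, cfg, margin)
            v = _Vessel(cl, width, bool(flags[i]))
            foot = _footprint(v, occupied.shape)
            if not (ndimage.binary_dilation(foot, _EIGHT, iterations=2)
                    & occupied).any():
                break
        occupied |= foot
        v.speed = rng.uniform(*cfg.rbc_speed_px_per_frame)
        L = len(v.centerline)
        v.packet_len = rng.uniform(0.15, 0.3) * L
        v.phase = rng.uniform(0, L)
        vessels.append(v)
    return vessels


def _background(rng: np.random.Generator, cfg: SceneConfig) -> np.ndarray:
    """Skin-like base: smooth colour field plus fine static texture."""
    h, w = cfg.height_px, cfg.width_px
    base = np.array([205.0, 165.0, 155.0])
    img = np.empty((h, w, 3))
    sigma = max(min(h, w) / 6.0, 4.0)
    for c in range(3):
        low = ndimage.gaussian_filter(rng.normal(0, 1, (h, w)), sigma)
        span = max(np.ptp(low), 1e-9)
        img[..., c] = base[c] + 12.0 * (low - low.mean()) / span * 2
    img += rng.normal(0, 3.0, (h, w, 3))  # static fine texture
    return img


def _add_distractors(rng: np.random.Generator, cfg: SceneConfig,
                     img: np.ndarray) -> None:
    """Static stains, sweat-gland spots and hairs; none affect the GT mask."""
    h, w = cfg.height_px, cfg.width_px
    kinds = rng.integers(0, 3, size=cfg.n_distractors)
    for kind in kinds:
        y = rng.uniform(5, h - 5)
        x = rng.uniform(5, w - 5)
        if kind == 0:  # stain: broad mild darkening, colour-neutral
            r = rng.uniform(4, 10)
            m = np.zeros((h, w), dtype=bool)
            _stamp_disks(m, np.array([[y, x]]), r)
            img[m] *= 0.88
        elif kind == 1:  # sweat-gland spot: small bright dot
            m = np.zeros((h, w), dtype=bool)
            _stamp_disks(m, np.array([[y, x]]), rng.uniform(1, 2.5))
            img[m] = np.minimum(img[m] * 1.18, 255.0)
        else:  # hair: thin dark near-straight line
            theta = rng.uniform(0, 2 * np.pi)
            length = int(rng.uniform(0.2, 0.5) * min(h, w))
            t = np.arange(length)
            pts = np.stack([np.clip(y + t * np.sin(theta), 0, h - 1),
                            np.clip(x + t * np.cos(theta), 0, w - 1)], axis=1)
            m = np.zeros((h, w), dtype=bool)
            _stamp_disks(m, pts, 0.8)
            img[m] *= 0.6


def _vignette(cfg: SceneConfig) -> np.ndarray:
    h, w = cfg.height_px, cfg.width_px
    yy, xx = np.mgrid[0:h, 0:w]
    cy, cx = (h - 1) / 2.0, (w - 1) / 2.0
    r2 = ((yy - cy) / max(cy, 0.5)) ** 2 + ((xx - cx) / max(cx, 0.5)) ** 2
    return 1.0 - cfg.vignette_strength * np.clip(r2 / 2.0, 0.0, 1.0)


def _shift_frame(img: np.ndarray, dx: int, dy: int) -> np.ndarray:
    """Translate by (dx, dy) with replicate-edge fill (content moves right/down
    for positive offsets)."""
    h, w = img.shape[:2]
    pad = max(abs(dx), abs(dy))
    if pad == 0:
        return img.copy()
    padded = np.pad(img, ((pad, pad), (pad, pad), (0, 0)), mode="edge")
    y0 = pad - dy
    x0 = pad - dx
    return padded[y0:y0 + h, x0:x0 + w]


def generate_scene(config: SceneConfig) -> tuple[FrameStack, SceneGroundTruth]:
    """Render a seeded capillaroscopy video and its ground truth.

    Frame 0 is rendered at zero jitter, so the ground-truth mask lives in
    frame-0 (template) coordinates. Deterministic: the same config yields a
    bit-identical stack.

    Returns
    -------
    (FrameStack, SceneGroundTruth)
        The ground truth additionally carries, per vessel, one probe pixel on
        the centerline together with the frames in which an RBC packet covers
        it (used by intermittency checks).
    """
    config.validate()
    rng = np.random.default_rng(config.seed)

    background = _background(rng, config)
    _add_distractors(rng, config, background)
    vessels = _build_vessels(rng, config)
    vignette = _vignette(config)

    gt_mask = np.zeros((config.height_px, config.width_px), dtype=bool)
    for v in vessels:
        gt_mask |= _footprint(v, gt_mask.shape)
    n_regions = int(ndimage.label(gt_mask, structure=_EIGHT)[1])

    jitter = [(0, 0)]
    for _ in range(1, config.n_frames):
        jitter.append((int(rng.integers(-config.jitter_max_px,
                                        config.jitter_max_px + 1)),
                       int(rng.integers(-config.jitter_max_px,
                                        config.jitter_max_px + 1))))

    # one probe pixel per vessel (mid-centerline) plus its covered frames;
    # coverage is checked on the rendered footprint, not the arc index, so
    # disks stamped by neighbouring centerline points count too
    probes: list[tuple[tuple[int, int], list[int]]] = []
    probe_yx = [tuple(np.round(v.centerline[len(v.centerline) // 2]).astype(int))
                for v in vessels]

    depression = np.array([0.15, 1.0, 0.5]) * config.rbc_contrast

    frames = np.empty((config.n_frames, config.height_px, config.width_px, 3),
                      dtype=np.uint8)
    covered_frames: list[list[int]] = [[] for _ in vessels]
    for t in range(config.n_frames):
        scene = background.copy()
        for vi, v in enumerate(vessels):
            arcs = v.covered_arcs(t)
            foot = _footprint(v, gt_mask.shape, arcs)
            scene[foot] -= depression
            if foot[probe_yx[vi]]:
                covered_frames[vi].append(t)
        scene *= vignette[..., None]
        scene += rng.normal(0, config.noise_sigma, scene.shape)
        dx, dy = jitter[t]
        frames[t] = np.clip(np.round(_shift_frame(scene, dx, dy)),
                            0, 255).astype(np.uint8)

    for vi in range(len(vessels)):
        py, px = probe_yx[vi]
        probes.append(((int(py), int(px)), covered_frames[vi]))

    gt = SceneGroundTruth(
        capillary_mask=(gt_mask.astype(np.uint8) * 255),
        region_count=n_regions,
        jitter_offsets=jitter,
        per_vessel_intermittent=[v.intermittent for v in vessels],
        probes=probes,
    )
    stack = FrameStack(frames, um_per_px=config.um_per_px, fps=config.fps)
    return stack, gt
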