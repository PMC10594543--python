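"""U-Net capillary segmentation: patch sampling, training, tiled inference.

The network is the classic encoder/decoder with skip connections, built here
as a self-contained numpy implementation (im2col 3x3 convolutions, 2x2 max
pooling, nearest-neighbour upsampling followed by a convolution, channel
concatenation, a 1x1 output convolution and a sigmoid head) trained with
Adam on binary cross-entropy (optionally Dice or their sum). Convolutions
are size-preserving, so the output probability grid equals the input grid
and the net is fully convolutional: any input whose sides are divisible by
2**(depth-1) works.

Inference on large stills runs as a sliding window (default 512 px window,
50 px stride) whose overlapping predictions are merged per pixel (mean by
default) and thresholded to a binary mask.

Everything is seeded: patch sampling, weight initialization and batch
shuffling derive from the config seed, and a saved checkpoint reloads to
bit-identical predictions.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Literal, NamedTuple, Sequence

import numpy as np

from .datatypes import validate_binary_mask

__all__ = [
    "AnnotationPair", "TrainConfig", "TileConfig", "SegmenterModel",
    "sample_patches", "train", "predict_tiled",
]


# ---------------------------------------------------------------------------
# configuration and data containers


@dataclass
class AnnotationPair:
    """A still image and its manual capillary annotation (255=capillary)."""

    image: np.ndarray
    mask: np.ndarray

    def __post_init__(self) -> None:
        self.image = np.asarray(self.image)
        self.mask = validate_binary_mask(self.mask)
        if self.image.shape[:2] != self.mask.shape:
            raise ValueError(
                f"image grid {self.image.shape[:2]} != mask grid {self.mask.shape}")


@dataclass
class TrainConfig:
    """Training hyper-parameters.

    Defaults mirror the full-scale protocol (512 px patches, 150 patches,
    batch 16, 50 epochs); desk-scale runs shrink patch size, depth and
    epochs. The optimizer (Adam) and learning rate are this package's
    defaults — they are not documented for the original experiment.
    """

    patch_size_px: int = 512
    n_patches: int = 150
    batch_size: int = 16
    epochs: int = 50
    seed: int = 0
    loss: Literal["bce", "dice", "bce_dice"] = "bce"
    learning_rate: float = 1e-3
    depth: int = 4
    base_channels: int = 64

    def validate(self) -> None:
        if self.patch_size_px < 1 or self.n_patches < 1:
            raise ValueError("patch_size_px and n_patches must be positive")
        if self.n_patches < self.batch_size:
            raise ValueError("n_patches must be >= batch_size")
        if self.depth < 1 or self.base_channels < 1:
            raise ValueError("depth and base_channels must be positive")
        if self.loss not in ("bce", "dice", "bce_dice"):
            raise ValueError(f"unknown loss {self.loss!r}")
        if self.patch_size_px % (1 << (self.depth - 1)) != 0:
            raise ValueError(
                f"patch size {self.patch_size_px} not divisible by "
                f"2**(depth-1) = {1 << (self.depth - 1)}")


@dataclass
class TileConfig:
    """Sliding-window inference parameters (512 px window, 50 px stride)."""

    window_px: int = 512
    stride_px: int = 50
    merge: Literal["mean", "max"] = "mean"
    threshold: float = 0.5

    def validate(self) -> None:
        if not (0 < self.stride_px <= self.window_px):
            raise ValueError("stride must satisfy 0 < stride <= window")
        if not (0.0 < self.threshold < 1.0):
            raise ValueError("threshold must lie in (0, 1)")
        if self.merge not in ("mean", "max"):
            raise ValueError(f"unknown merge {self.merge!r}")


class Patch(NamedTuple):
    """A congruent image/mask crop with its provenance."""

    image: np.ndarray
    mask: np.ndarray
    source_index: int
    y: int
    x: int


def sample_patches(pairs: Sequence[AnnotationPair], cfg: TrainConfig) -> list[Patch]:
    """Draw ``cfg.n_patches`` seeded random crops from annotated stills.

    Each draw picks a source image uniformly, then a uniform valid top-left
    corner; image and mask are cut congruently and the provenance recorded.
    """
    cfg.validate()
    if not pairs:
        raise ValueError("no annotation pairs given")
    p = cfg.patch_size_px
    for i, pair in enumerate(pairs):
        h, w = pair.mask.shape
        if h < p or w < p:
            raise ValueError(
                f"annotation pair {i} ({w}x{h} px) is smaller than the "
                f"{p}x{p} px patch size")
    rng = np.random.default_rng(cfg.seed)
    out: list[Patch] = []
    for _ in range(cfg.n_patches):
        i = int(rng.integers(len(pairs)))
        h, w = pairs[i].mask.shape
        y = int(rng.integers(h - p + 1))
        x = int(rng.integers(w - p + 1))
        out.append(Patch(pairs[i].image[y:y + p, x:x + p].copy(),
                         pairs[i].mask[y:y + p, x:x + p].copy(), i, y, x))
    return out


# ---------------------------------------------------------------------------
# numpy layers (float32 throughout; NHWC layout)


def _conv3x3(x: np.ndarray, w: np.ndarray, b: np.ndarray):
    """Same-padded 3x3 convolution. w: (Cout, Cin, 3, 3)."""
    n, h, wd, cin = x.shape
    cout = w.shape[0]
    xp = np.pad(x, ((0, 0), (1, 1), (1, 1), (0, 0)))
    cols = np.lib.stride_tricks.sliding_window_view(xp, (3, 3), axis=(1, 2))
    # (n, h, w, cin, 3, 3) -> (n*h*w, cin*9)
    cols = cols.reshape(n * h * wd, cin * 9)
    y = cols @ w.reshape(cout, cin * 9).T + b
    return y.reshape(n, h, wd, cout), cols


def _conv3x3_bwd(dy: np.ndarray, cols: np.ndarray, x_shape, w: np.ndarray):
    n, h, wd, cin = x_shape
    cout = w.shape[0]
    dyf = dy.reshape(n * h * wd, cout)
    dw = (cols.T @ dyf).reshape(cin, 3, 3, cout).transpose(3, 0, 1, 2)
    db = dyf.sum(axis=0)
    # full correlation of dy with 180deg-rotated kernels
    dyp = np.pad(dy, ((0, 0), (1, 1), (1, 1), (0, 0)))
    dcols = np.lib.stride_tricks.sliding_window_view(dyp, (3, 3), axis=(1, 2))
    dcols = dcols.reshape(n * h * wd, cout * 9)
    wrot = w[:, :, ::-1, ::-1].transpose(0, 2, 3, 1).reshape(cout * 9, cin)
    dx = (dcols @ wrot).reshape(n, h, wd, cin)
    return dx, dw, db


def _maxpool2(x: np.ndarray):
    n, h, w, c = x.shape
    xr = x.reshape(n, h // 2, 2, w // 2, 2, c).transpose(0, 1, 3, 5, 2, 4)
    xr = xr.reshape(n, h // 2, w // 2, c, 4)
    arg = xr.argmax(axis=-1)
    return np.take_along_axis(xr, arg[..., None], axis=-1)[..., 0], (arg, x.shape)


def _maxpool2_bwd(dy: np.ndarray, cache):
    arg, (n, h, w, c) = cache
    dxr = np.zeros((n, h // 2, w // 2, c, 4), dtype=dy.dtype)
    np.put_along_axis(dxr, arg[..., None], dy[..., None], axis=-1)
    dxr = dxr.reshape(n, h // 2, w // 2, c, 2, 2).transpose(0, 1, 4, 2, 5, 3)
    return dxr.reshape(n, h, w, c)


def _upsample2(x: np.ndarray) -> np.ndarray:
    return x.repeat(2, axis=1).repeat(2, axis=2)


def _upsample2_bwd(dy: np.ndarray) -> np.ndarray:
    n, h, w, c = dy.shape
    return dy.reshape(n, h // 2, 2, w // 2, 2, c).sum(axis=(2, 4))


def _sigmoid(z: np.ndarray) -> np.ndarray:
    out = np.empty_like(z)
    pos = z >= 0
    out[pos] = 1.0 / (1.0 + np.exp(-z[pos]))
    ez = np.exp(z[~pos])
    out[~pos] = ez / (1.0 + ez)
    return out


# ---------------------------------------------------------------------------
# the model


class SegmenterModel:
    """A trained U-Net with serializable parameters.

    ``depth`` is the number of resolution levels, ``base_channels`` the
    width of the first level (doubling per level down). Probabilities are
    emitted on the input grid; inputs are 8-bit RGB, normalized to [0, 1]
    internally.
    """

    def __init__(self, depth: int, base_channels: int,
                 params: dict[str, np.ndarray] | None = None,
                 rng: np.random.Generator | None = None) -> None:
        self.depth = depth
        self.base_channels = base_channels
        self.loss_history: list[float] = []
        if params is not None:
            self.params = params
        else:
            rng = rng or np.random.default_rng(0)
            self.params = self._init_params(rng)

    # -- construction ------------------------------------------------------

    def _channels(self, level: int) -> int:
        return self.base_channels * (1 << level)

    def _init_params(self, rng: np.random.Generator) -> dict[str, np.ndarray]:
        p: dict[str, np.ndarray] = {}

        def conv(name: str, cin: int, cout: int, k: int = 3) -> None:
            std = np.sqrt(2.0 / (cin * k * k))  # He initialization
            p[f"{name}.w"] = rng.normal(0, std, (cout, cin, k, k)).astype(np.float32)
            p[f"{name}.b"] = np.zeros(cout, dtype=np.float32)

        cin = 3
        for lv in range(self.depth):
            c = self._channels(lv)
            conv(f"enc{lv}a", cin, c)
            conv(f"enc{lv}b", c, c)
            cin = c
        for lv in range(self.depth - 2, -1, -1):
            c = self._channels(lv)
            conv(f"up{lv}", self._channels(lv + 1), c)
            conv(f"dec{lv}a", 2 * c, c)
            conv(f"dec{lv}b", c, c)
        std = np.sqrt(2.0 / self.base_channels)
        p["out.w"] = rng.normal(0, std, (1, self.base_channels, 1, 1)).astype(np.float32)
        p["out.b"] = np.zeros(1, dtype=np.float32)
        return p

    # -- forward / backward ------------------------------------------------

    def _forward(self, x: np.ndarray, need_cache: bool):
        p = self.params
        cache: dict = {"acts": {}}
        skips = {}
        h = x
        for lv in range(self.depth):
            for tag in ("a", "b"):
                name = f"enc{lv}{tag}"
                z, cols = _conv3x3(h, p[f"{name}.w"], p[f"{name}.b"])
                a = np.maximum(z, 0.0)
                if need_cache:
                    cache[name] = (cols, h.shape, z > 0)
                h = a
            if lv < self.depth - 1:
                skips[lv] = h
                h, pc = _maxpool2(h)
                if need_cache:
                    cache[f"pool{lv}"] = pc
        for lv in range(self.depth - 2, -1, -1):
            u = _upsample2(h)
            name = f"up{lv}"
            z, cols = _conv3x3(u, p[f"{name}.w"], p[f"{name}.b"])
            a = np.maximum(z, 0.0)
            if need_cache:
                cache[name] = (cols, u.shape, z > 0)
            h = np.concatenate([skips[lv], a], axis=-1)
            if need_cache:
                cache[f"cat{lv}"] = skips[lv].shape[-1]
            for tag in ("a", "b"):
                name = f"dec{lv}{tag}"
                z, cols = _conv3x3(h, p[f"{name}.w"], p[f"{name}.b"])
                a = np.maximum(z, 0.0)
                if need_cache:
                    cache[name] = (cols, h.shape, z > 0)
                h = a
        # 1x1 output convolution -> logits
        n, hh, ww, c = h.shape
        logits = (h.reshape(-1, c) @ p["out.w"].reshape(1, c).T
                  + p["out.b"]).reshape(n, hh, ww)
        if need_cache:
            cache["out"] = h
        return logits, cache

    def _backward(self, dlogits: np.ndarray, cache: dict) -> dict[str, np.ndarray]:
        p = self.params
        grads: dict[str, np.ndarray] = {}
        hout = cache["out"]
        n, hh, ww, c = hout.shape
        dflat = dlogits.reshape(-1, 1)
        grads["out.w"] = (hout.reshape(-1, c).T @ dflat).T.reshape(1, c, 1, 1)
        grads["out.b"] = dflat.sum(axis=0)
        dh = (dflat @ p["out.w"].reshape(1, c)).reshape(n, hh, ww, c)

        def conv_bwd(name: str, d: np.ndarray) -> np.ndarray:
            cols, xshape, relu_mask = cache[name]
            d = d * relu_mask
            dx, dw, db = _conv3x3_bwd(d, cols, xshape, p[f"{name}.w"])
            grads[f"{name}.w"] = dw
            grads[f"{name}.b"] = db
            return dx

        dskip: dict[int, np.ndarray] = {}
        for lv in range(0, self.depth - 1):
            dh = conv_bwd(f"dec{lv}b", dh)
            dh = conv_bwd(f"dec{lv}a", dh)
            csk = cache[f"cat{lv}"]
            dskip[lv] = dh[..., :csk]
            dh = conv_bwd(f"up{lv}", dh[..., csk:])
            dh = _upsample2_bwd(dh)
        for lv in range(self.depth - 1, -1, -1):
            if lv < self.depth - 1:
                dh = _maxpool2_bwd(dh, cache[f"pool{lv}"]) + dskip[lv]
            dh = conv_bwd(f"enc{lv}b", dh)
            dh = conv_bwd(f"enc{lv}a", dh)
        return grads

    # -- public API --------------------------------------------------------

    def predict(self, images: np.ndarray) -> np.ndarray:
        """Per-pixel capillary probabilities for a batch of RGB images.

        ``images``: (n, H, W, 3) or (H, W, 3), uint8 or float in [0, 255];
        H and W must be divisible by 2**(depth-1).
        """
        single = images.ndim == 3
        x = np.asarray(images, dtype=np.float32)
        if single:
            x = x[None]
        if x.max() > 1.0:
            x = x / 255.0
        div = 1 << (self.depth - 1)
        if x.shape[1] % div or x.shape[2] % div:
            raise ValueError(
                f"input sides must be divisible by {div} for depth {self.depth}")
        logits, _ = self._forward(x, need_cache=False)
        probs = _sigmoid(logits)
        return probs[0] if single else probs

    def save(self, path: str | Path) -> Path:
        """Write parameters (npz) plus a JSON architecture sidecar."""
        path = Path(path)
        np.savez(path, **self.params)
        path = path if path.suffix == ".npz" else path.with_suffix(path.suffix + ".npz")
        sidecar = {"depth": self.depth, "base_channels": self.base_channels,
                   "loss_history": self.loss_history,
                   "input_contract": "HxWx3 uint8 -> HxW probability in [0,1]"}
        Path(str(path) + ".json").write_text(json.dumps(sidecar, indent=2))
        return path

    @classmethod
    def load(cls, path: str | Path) -> "SegmenterModel":
        path = Path(path)
        if path.suffix != ".npz":
            path = path.with_suffix(path.suffix + ".npz")
        sidecar = json.loads(Path(str(path) + ".json").read_text())
        with np.load(path) as npz:
            params = {k: npz[k] for k in npz.files}
        model = cls(sidecar["depth"], sidecar["base_channels"], params=params)
        model.loss_history = list(sidecar.get("loss_history", []))
        return model


# ---------------------------------------------------------------------------
# training


def _loss_and_grad(logits: np.ndarray, target: np.ndarray, kind: str):
    """Loss value and d(loss)/d(logits). target in {0,1} float32."""
    npx = logits.size
    p = _sigmoid(logits)
    loss = 0.0
    dlogits = np.zeros_like(logits)
    if kind in ("bce", "bce_dice"):
        # softplus(z) - y*z, numerically stable; overflow from a diverged
        # model yields inf/nan, caught by the caller's finiteness check
        with np.errstate(over="ignore", invalid="ignore"):
            sp = np.logaddexp(0.0, logits)
            loss += float((sp - target * logits).mean())
        dlogits += (p - target) / npx
    if kind in ("dice", "bce_dice"):
        eps = 1.0
        inter = float((p * target).sum())
        denom = float(p.sum() + target.sum()) + eps
        dice = (2.0 * inter + eps) / denom
        loss += 1.0 - dice
        dp = -(2.0 * target * denom - (2.0 * inter + eps)) / denom ** 2
        dlogits += dp * p * (1.0 - p)
    return loss, dlogits


def train(patches: Sequence[Patch] | Sequence[tuple], cfg: TrainConfig) -> SegmenterModel:
    """Train a U-Net on image/mask patches with seeded Adam.

    Records the mean loss per epoch in ``model.loss_history`` (entry 0 is
    the pre-training loss on all patches). Aborts with a diagnostic if the
    loss turns non-finite.
    """
    cfg.validate()
    if not patches:
        raise ValueError("empty patch list")
    x = np.stack([np.asarray(p[0], dtype=np.float32) / 255.0 for p in patches])
    y = np.stack([np.asarray(p[1], dtype=np.float32) / 255.0 for p in patches])
    if not np.isin(y, (0.0, 1.0)).all():
        raise ValueError("masks must be binary {0, 255}")

    rng = np.random.default_rng(cfg.seed)
    model = SegmenterModel(cfg.depth, cfg.base_channels, rng=rng)

    logits, _ = model._forward(x[: min(len(x), cfg.batch_size)], need_cache=False)
    init_loss, _ = _loss_and_grad(logits, y[: logits.shape[0]], cfg.loss)
    model.loss_history.append(init_loss)

    mom = {k: np.zeros_like(v) for k, v in model.params.items()}
    vel = {k: np.zeros_like(v) for k, v in model.params.items()}
    beta1, beta2, eps = 0.9, 0.999, 1e-8
    step = 0
    bs = min(cfg.batch_size, len(x))
    for epoch in range(cfg.epochs):
        order = rng.permutation(len(x))
        epoch_losses = []
        for s in range(0, len(order) - bs + 1, bs):
            idx = order[s:s + bs]
            logits, cache = model._forward(x[idx], need_cache=True)
            loss, dlogits = _loss_and_grad(logits, y[idx], cfg.loss)
            if not np.isfinite(loss):
                raise RuntimeError(
                    f"non-finite loss at epoch {epoch}, step {step}: {loss!r}; "
                    "lower the learning rate or check the input scaling")
            grads = model._backward(dlogits.astype(np.float32), cache)
            step += 1
            for k, g in grads.items():
                mom[k] = beta1 * mom[k] + (1 - beta1) * g
                vel[k] = beta2 * vel[k] + (1 - beta2) * g * g
                mhat = mom[k] / (1 - beta1 ** step)
                vhat = vel[k] / (1 - beta2 ** step)
                model.params[k] -= (cfg.learning_rate * mhat
                                    / (np.sqrt(vhat) + eps)).astype(np.float32)
            epoch_losses.append(loss)
        model.loss_history.append(float(np.mean(epoch_losses)))
    return model


# ---------------------------------------------------------------------------
# tiled inference


def _tile_starts(extent: int, window: int, stride: int) -> list[int]:
    starts = list(range(0, extent - window + 1, stride))
    if starts[-1] != extent - window:
        starts.append(extent - window)  # clamp the last window to the edge
    return starts


def predict_tiled(model, image: np.ndarray,
                  cfg: TileConfig | None = None) -> tuple[np.ndarray, np.ndarray]:
    """Sliding-window segmentation of a full still.

    Windows tile the image row-major at the configured stride, the last
    window per row/column clamped to the image edge so every pixel is
    covered; overlapping window predictions are merged per ``cfg.merge``
    and the merged probability map thresholded to a {0, 255} mask.

    ``model`` needs only a ``predict(window) -> probability`` method.
    """
    cfg = cfg or TileConfig()
    cfg.validate()
    image = np.asarray(image)
    if image.ndim != 3 or image.shape[2] != 3:
        raise ValueError("expected an HxWx3 RGB image")
    h, w = image.shape[:2]
    win = cfg.window_px
    if h < win or w < win:
        raise ValueError(
            f"image {w}x{h} px is smaller than the {win} px window; pad the "
            "image or reduce window_px")
    if cfg.merge == "mean":
        acc = np.zeros((h, w), dtype=np.float64)
        cov = np.zeros((h, w), dtype=np.int32)
    else:
        acc = np.full((h, w), -np.inf)
    for y0 in _tile_starts(h, win, cfg.stride_px):
        for x0 in _tile_starts(w, win, cfg.stride_px):
            prob = np.asarray(model.predict(image[y0:y0 + win, x0:x0 + win]))
            if cfg.merge == "mean":
                acc[y0:y0 + win, x0:x0 + win] += prob
                cov[y0:y0 + win, x0:x0 + win] += 1
            else:
                np.maximum(acc[y0:y0 + win, x0:x0 + win], prob,
                           out=acc[y0:y0 + win, x0:x0 + win])
    prob_map = acc / cov if cfg.merge == "mean" else acc
    mask = np.where(prob_map >= cfg.threshold, 255, 0).astype(np.uint8)
    return prob_map, mask
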