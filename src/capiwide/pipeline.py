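"""End-to-end pipeline orchestration driven by a YAML-style config dict.

Canonical stage order: simulate -> preprocess -> train -> predict ->
quantify -> evaluate. Each stage writes its artifacts plus a JSON
provenance sidecar (config hash, seed, stage); re-running with the same
config and seed reproduces deterministic artifacts byte-identically.
"""

from __future__ import annotations

import dataclasses
import logging
import time
from pathlib import Path

import numpy as np

from . import io as cio
from . import synthetic, preprocessing, unet, quantify, evaluate
from .datatypes import FrameStack

log = logging.getLogger("capiwide")

STAGE_ORDER = ("simulate", "preprocess", "train", "predict", "quantify", "evaluate")


def _subconfig(cls, block: dict | None, **extra):
    block = dict(block or {})
    block.update(extra)
    fields = {f.name for f in dataclasses.fields(cls)}
    unknown = set(block) - fields
    if unknown:
        raise ValueError(f"unknown {cls.__name__} fields: {sorted(unknown)}")
    return cls(**block)


class PipelineConfig:
    """Validated stage blocks plus global seed and output directory."""

    def __init__(self, raw: dict):
        self.raw = dict(raw)
        self.seed = int(raw.get("seed", 0))
        self.out_dir = Path(raw.get("out_dir", "capiwide_out"))
        self.margin = int(raw.get("stabilize", {}).get("template_margin_px", 50))
        self.scene = _subconfig(synthetic.SceneConfig, raw.get("scene"),
                                seed=self.seed)
        self.flat = _subconfig(preprocessing.FlatFieldConfig, raw.get("flatfield"))
        self.contrast = _subconfig(preprocessing.ContrastConfig, raw.get("contrast"))
        self.train = _subconfig(unet.TrainConfig, raw.get("train"), seed=self.seed)
        self.tile = _subconfig(unet.TileConfig, raw.get("tile"))
        self.evaluate = dict(raw.get("evaluate", {}))
        self.io = dict(raw.get("io", {}))

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        return cls(cio.load_yaml(path))


def run_pipeline(config: PipelineConfig | dict,
                 stages: set[str] | list[str]) -> dict[str, Path]:
    """Run the requested stages in canonical order; returns artifact paths.

    Stages not requested read their inputs from disk via the ``io`` config
    block (or from artifacts written earlier in the same run).
    """
    cfg = config if isinstance(config, PipelineConfig) else PipelineConfig(config)
    stages = set(stages)
    unknown = stages - set(STAGE_ORDER)
    if unknown:
        raise ValueError(f"unknown stages: {sorted(unknown)}")
    out = cfg.out_dir
    out.mkdir(parents=True, exist_ok=True)
    artifacts: dict[str, Path] = {}

    stack: FrameStack | None = None
    gt = None
    still: np.ndarray | None = None
    model = None
    mask: np.ndarray | None = None

    for stage in STAGE_ORDER:
        if stage not in stages:
            continue
        t0 = time.perf_counter()

        if stage == "simulate":
            stack, gt = synthetic.generate_scene(cfg.scene)
            frames_dir = out / "frames"
            cio.write_frames(stack, frames_dir)
            cio.write_mask(gt.capillary_mask, out / "gt_mask.png")
            cio.write_offsets_csv(gt.jitter_offsets, out / "jitter.csv")
            cio.save_yaml(dataclasses.asdict(cfg.scene), out / "scene.yaml")
            cio.write_provenance(frames_dir, cfg.raw, cfg.seed, stage)
            artifacts["frames"] = frames_dir
            artifacts["gt_mask"] = out / "gt_mask.png"

        elif stage == "preprocess":
            if stack is None:
                src = cfg.io.get("frames", out / "frames")
                stack = cio.read_frames(src)
            stab = preprocessing.stabilize(stack, cfg.margin)
            composite = preprocessing.min_green_composite(stab.aligned)
            flat = preprocessing.flatten_illumination(composite, cfg.flat)
            still = preprocessing.enhance_contrast(flat, cfg.contrast)
            cio.write_still(still, out / "still.png")
            cio.write_offsets_csv(stab.offsets, out / "stabilization_offsets.csv")
            cio.write_provenance(out / "still.png", cfg.raw, cfg.seed, stage)
            artifacts["still"] = out / "still.png"
            if gt is not None:
                # ground truth cropped to the stabilized (template) grid
                m = cfg.margin
                h, w = gt.capillary_mask.shape
                cio.write_mask(gt.capillary_mask[m:h - m, m:w - m],
                               out / "gt_still_mask.png")
                artifacts["gt_still_mask"] = out / "gt_still_mask.png"

        elif stage == "train":
            pairs = []
            if still is not None and (out / "gt_still_mask.png").exists():
                pairs.append(unet.AnnotationPair(
                    still, cio.read_mask(out / "gt_still_mask.png")))
            for item in cfg.io.get("annotations", []):
                pairs.append(unet.AnnotationPair(
                    cio.read_still(item["image"]), cio.read_mask(item["mask"])))
            if not pairs:
                raise FileNotFoundError(
                    "train stage needs annotation pairs (io.annotations or a "
                    "preceding simulate+preprocess run)")
            patches = unet.sample_patches(pairs, cfg.train)
            model = unet.train(patches, cfg.train)
            model.save(out / "model")
            cio.write_provenance(out / "model.npz", cfg.raw, cfg.seed, stage)
            artifacts["model"] = out / "model.npz"

        elif stage == "predict":
            if model is None:
                model = unet.SegmenterModel.load(cfg.io.get("model", out / "model"))
            if still is None:
                still = cio.read_still(cfg.io.get("still", out / "still.png"))
            prob, mask = unet.predict_tiled(model, still, cfg.tile)
            cio.write_probability_map(prob, out / "probability.tif")
            cio.write_mask(mask, out / "pred_mask.png")
            cio.write_provenance(out / "pred_mask.png", cfg.raw, cfg.seed, stage)
            artifacts["pred_mask"] = out / "pred_mask.png"

        elif stage == "quantify":
            if mask is None:
                mask = cio.read_mask(cfg.io.get("mask", out / "pred_mask.png"))
            table = quantify.label_regions(
                mask, connectivity=int(cfg.evaluate.get("connectivity", 8)))
            variables = quantify.capillary_variables(
                table, um_per_px=cfg.raw.get("um_per_px"))
            table.to_frame().to_csv(out / "regions.csv", index=False)
            (out / "capillary_variables.json").write_text(variables.to_json())
            cio.write_provenance(out / "capillary_variables.json",
                                 cfg.raw, cfg.seed, stage)
            artifacts["variables"] = out / "capillary_variables.json"

        elif stage == "evaluate":
            if mask is None:
                mask = cio.read_mask(cfg.io.get("mask", out / "pred_mask.png"))
            gt_path = cfg.io.get("gt_mask", out / "gt_still_mask.png")
            gt_mask = cio.read_mask(gt_path)
            conn = int(cfg.evaluate.get("connectivity", 8))
            pix = evaluate.pixel_metrics(evaluate.pixel_confusion(mask, gt_mask))
            reg = evaluate.region_confusion(mask, gt_mask, connectivity=conn)
            report = {"pixel": dataclasses.asdict(pix),
                      "region": dataclasses.asdict(reg)}
            import json as _json
            (out / "evaluation.json").write_text(_json.dumps(report, indent=2))
            cio.write_provenance(out / "evaluation.json", cfg.raw, cfg.seed, stage)
            artifacts["evaluation"] = out / "evaluation.json"

        log.info("stage %-10s done in %.2f s", stage, time.perf_counter() - t0)

    return artifacts
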