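"""End-to-end phantom pipeline: simulate -> train -> segment -> morph
-> evaluate, with a single serializable run configuration.

Every stage is seeded from the global run seed, logs what it consumed,
and writes its outputs under the run directory (config copy included),
so an identical config + seed reproduces byte-identical CSV/JSON
reports.
"""

from __future__ import annotations

import dataclasses
import json
import logging
import time
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import evaluation, morphometry, phantom
from .segmentation import UNetSegmenter

log = logging.getLogger("meiboseg")

ALL_STAGES = ("simulate", "train", "segment", "morph", "evaluate")


@dataclass
class RunConfig:
    """Nested configuration for a full phantom-pipeline run."""

    seed: int = 0
    out_dir: str = "runs/phantom"
    stages: tuple[str, ...] = ALL_STAGES
    n_train: int = 30
    n_val: int = 10
    n_test: int = 10
    phantom: phantom.PhantomConfig = field(default_factory=phantom.PhantomConfig)
    segmenter: dict = field(
        default_factory=lambda: {
            "depth": 2,
            "base_channels": 8,
            "epochs": 15,
            "batch_size": 5,
            "learning_rate": 1e-3,
            "input_size": (64, 64),
        }
    )
    min_area: int = morphometry.DEFAULT_MIN_AREA
    length_mode: str = "path"
    resample_step: int = morphometry.DEFAULT_RESAMPLE_STEP

    def to_dict(self) -> dict:
        def listify(obj):
            if isinstance(obj, (list, tuple)):
                return [listify(v) for v in obj]
            if isinstance(obj, dict):
                return {k: listify(v) for k, v in obj.items()}
            return obj

        return listify(dataclasses.asdict(self))

    def to_yaml(self, path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(self.to_dict(), fh, sort_keys=True)

    @classmethod
    def from_dict(cls, d: dict) -> "RunConfig":
        d = dict(d)
        if "phantom" in d and isinstance(d["phantom"], dict):
            ph = dict(d["phantom"])
            for key in ("length_range", "half_width_range", "amplitude_range",
                        "wavelength_range", "specular_spot_radius"):
                if key in ph and ph[key] is not None:
                    ph[key] = tuple(ph[key])
            d["phantom"] = phantom.PhantomConfig(**ph)
        if "stages" in d:
            d["stages"] = tuple(d["stages"])
        if "segmenter" in d and "input_size" in d["segmenter"]:
            d["segmenter"] = dict(d["segmenter"])
            d["segmenter"]["input_size"] = tuple(d["segmenter"]["input_size"])
        return cls(**d)

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        with open(path) as fh:
            return cls.from_dict(yaml.safe_load(fh) or {})


def _morph_frame(summaries, tag: str) -> pd.DataFrame:
    rows = []
    for i, s in enumerate(summaries):
        for g in s.per_gland:
            rows.append(
                {
                    "image": i,
                    "kind": "gland",
                    "source": tag,
                    "gland_id": g.label,
                    "length_px": g.length,
                    "width_px": g.width,
                    "tortuosity": g.tortuosity,
                }
            )
        rows.append(
            {
                "image": i,
                "kind": "summary",
                "source": tag,
                "gland_id": s.gland_count,
                "length_px": s.mean_length,
                "width_px": s.mean_width,
                "tortuosity": s.mean_tortuosity,
            }
        )
    return pd.DataFrame(rows)


def run_pipeline(config: RunConfig) -> dict:
    """Execute the configured stages in order; returns a report dict.

    Stage outputs land under ``config.out_dir`` with the config copied
    in. Per-image segment+morph wall time is logged for information.
    """
    t0 = time.time()
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    config.to_yaml(out / "config.yaml")
    report: dict = {"out_dir": str(out)}
    unknown = set(config.stages) - set(ALL_STAGES)
    if unknown:
        raise ValueError(f"unknown pipeline stages: {sorted(unknown)}")

    samples = test_samples = None
    est = None
    if "simulate" in config.stages:
        t = time.time()
        base = dataclasses.replace(config.phantom, seed=config.seed)
        samples = phantom.generate_dataset(base, config.n_train + config.n_val, seed=config.seed)
        test_samples = phantom.generate_dataset(base, config.n_test, seed=config.seed + 1)
        phantom.write_dataset(test_samples, out / "phantoms_test")
        log.info("simulate: %d train+val, %d test phantoms in %.1fs",
                 len(samples), len(test_samples), time.time() - t)
        report["n_phantoms"] = len(samples) + len(test_samples)
    if "train" in config.stages:
        if samples is None:
            raise ValueError("stage 'train' needs stage 'simulate' (no dataset available)")
        t = time.time()
        tr = samples[: config.n_train]
        va = samples[config.n_train :]
        est = UNetSegmenter(random_state=config.seed, **config.segmenter)
        est.fit(
            [s.image for s in tr],
            [s.mask for s in tr],
            validation_data=([s.image for s in va], [s.mask for s in va]) if va else None,
        )
        pd.DataFrame(est.history_).to_csv(out / "history.csv", index=False)
        est.save(out / "model.npz")
        log.info("train: %d epochs on %d pairs in %.1fs", est.epochs, len(tr), time.time() - t)
        report["final_train_loss"] = est.history_[-1]["train_loss"]
        if va:
            report["final_val_dice"] = est.history_[-1]["val_dice"]
    pred_masks = probs = None
    if "segment" in config.stages:
        if est is None or test_samples is None:
            raise ValueError("stage 'segment' needs stages 'simulate' and 'train'")
        t = time.time()
        probs = est.predict_proba([s.image for s in test_samples])
        pred_masks = [p >= est.binarize_threshold for p in probs]
        (out / "pred_masks").mkdir(exist_ok=True)
        from .manifest import imwrite_mask

        for i, m in enumerate(pred_masks):
            imwrite_mask(m, out / "pred_masks" / f"phantom_{i:04d}.png")
        dt = time.time() - t
        log.info("segment: %d images, %.2f s/image", len(pred_masks), dt / len(pred_masks))
        report["seconds_per_image"] = dt / len(pred_masks)
    morph_auto = None
    if "morph" in config.stages:
        if pred_masks is None:
            raise ValueError("stage 'morph' needs stage 'segment'")
        t = time.time()
        kw = dict(min_area=config.min_area, resample_step=config.resample_step,
                  length_mode=config.length_mode)
        morph_auto = [morphometry.analyze_mask(m, **kw) for m in pred_masks]
        morph_gt = [morphometry.analyze_mask(s.mask, **kw) for s in test_samples]
        df = pd.concat([_morph_frame(morph_auto, "auto"), _morph_frame(morph_gt, "ground_truth")])
        df.to_csv(out / "morphometry.csv", index=False)
        log.info("morph: %d masks in %.1fs", len(morph_auto), time.time() - t)
        # relative name: report files must not depend on the run location
        report["morphometry_csv"] = "morphometry.csv"
    if "evaluate" in config.stages:
        if pred_masks is None:
            raise ValueError("stage 'evaluate' needs stage 'segment'")
        gts = [s.mask for s in test_samples]
        metrics = evaluation.evaluate_masks(pred_masks, gts, probs=probs)
        report["metrics"] = metrics.to_dict()
        if morph_auto is not None:
            counts_auto = [m.gland_count for m in morph_auto]
            counts_gt = [s.expected.gland_count for s in test_samples]
            if len(counts_auto) >= 3:
                ba = evaluation.bland_altman(counts_gt, counts_auto)
                report["bland_altman_count"] = {
                    "mean_diff": ba.mean_diff,
                    "loa": [ba.loa_lower, ba.loa_upper],
                    "fraction_within_loa": ba.fraction_within_loa,
                    "p_value_paired_t": ba.p_value_paired_t,
                }
        with open(out / "metrics.json", "w") as fh:
            json.dump(report.get("metrics", {}), fh, indent=1)
    log.info("pipeline finished in %.1fs", time.time() - t0)
    # timing is logged, never persisted: report files must be reproducible
    persisted = {k: v for k, v in report.items() if k not in ("out_dir", "seconds_per_image")}
    with open(out / "report.json", "w") as fh:
        json.dump(persisted, fh, indent=1, default=float)
    return report
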