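"""Pipeline orchestration, configuration and run manifests.

``run_all`` executes the full identification pipeline — synthesize (or
load) grain images, segment, extract two deep-feature views, fuse,
select, classify — writing every intermediate table as CSV and recording
a manifest of per-stage inputs, outputs and dimensions.

One global seed fans out to per-stage seeds through a fixed
``SeedSequence`` splitting rule, so each stage is independently
reproducible and two runs with the same config produce identical
artifacts (timestamps aside).
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
import time
from dataclasses import dataclass, field, fields
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import backbones, boa, evaluation, fusion, segmentation, synthetic

logger = logging.getLogger(__name__)

__all__ = ["PipelineConfig", "RunManifest", "run_all", "stage_seed"]

_STAGES = ("synth", "segment", "extract_dar", "extract_squ", "fuse", "select", "classify")


def stage_seed(global_seed: int, stage: str) -> int:
    """Derive a per-stage seed (< 2^31) from the global seed."""
    idx = _STAGES.index(stage)
    seq = np.random.SeedSequence(global_seed, spawn_key=(idx,))
    return int(seq.generate_state(1)[0] % (2**31))


@dataclass
class PipelineConfig:
    """Serializable configuration for the whole pipeline.

    Desk-scale defaults: 5 classes x 40 synthetic images at 128 px,
    128-dim mock extractors per view, 40 selection iterations.
    """

    seed: int = 1
    out_dir: str = "runs/latest"
    synthetic: bool = True
    input_dir: str | None = None
    n_per_class: int = 40
    n_classes: int = 5
    hw: int = 128
    n_segments: int = 200
    alpha: float = 0.99
    sigma_c: float = 10.0
    sigma_s: float = 0.1
    dar_dim: int = 128
    squ_dim: int = 128
    tau_high: float = 0.90
    tau_low: float = 0.05
    pop_size: int = 30
    n_iters: int = 40
    lam: float = 0.01
    split: float = 0.5
    cv_folds: int = 10
    use_cv: bool = False
    panel: list[str] = field(default_factory=lambda: list(evaluation.FULL_PANEL))

    @classmethod
    def from_dict(cls, data: dict) -> "PipelineConfig":
        known = {f.name for f in fields(cls)}
        unknown = set(data) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        return cls(**data)

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        with open(path) as fh:
            return cls.from_dict(yaml.safe_load(fh) or {})

    def to_yaml(self, path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(dataclasses.asdict(self), fh, sort_keys=True)

    def config_hash(self) -> str:
        blob = json.dumps(dataclasses.asdict(self), sort_keys=True).encode()
        return hashlib.sha256(blob).hexdigest()[:16]


@dataclass
class RunManifest:
    config_hash: str
    seed: int
    stages: list[dict] = field(default_factory=list)

    def record(self, name: str, **info) -> None:
        if any(s["stage"] == name for s in self.stages):
            raise ValueError(f"stage {name} already recorded")
        self.stages.append({"stage": name, "timestamp": time.time(), **info})

    def to_json(self, path) -> None:
        with open(path, "w") as fh:
            json.dump(dataclasses.asdict(self), fh, indent=2)

    def comparable(self) -> dict:
        """Manifest content with timestamps stripped, for determinism checks."""
        return {
            "config_hash": self.config_hash,
            "seed": self.seed,
            "stages": [
                {k: v for k, v in s.items() if k != "timestamp"} for s in self.stages
            ],
        }


def _masked_rgb(image: np.ndarray, mask: np.ndarray) -> np.ndarray:
    return image * mask.astype(image.dtype)[..., None]


def run_all(config: PipelineConfig) -> RunManifest:
    """Execute every stage in order; abort with the stage name on failure.

    The partial manifest is persisted even when a stage fails, so the
    failure point and all completed dimensions stay on disk.
    """
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    manifest = RunManifest(config_hash=config.config_hash(), seed=config.seed)
    config.to_yaml(out / "config.yaml")
    current = None
    try:
        # --- synth / load -------------------------------------------------
        current = "synth"
        if config.synthetic:
            samples = synthetic.gen_grain_images(
                config.n_per_class, config.n_classes, config.hw,
                seed=stage_seed(config.seed, "synth"),
            )
        else:
            if not config.input_dir or not Path(config.input_dir).is_dir():
                raise FileNotFoundError(f"input_dir not found: {config.input_dir}")
            samples = _load_image_dir(Path(config.input_dir))
        labels = np.array([s.label for s in samples])
        manifest.record("synth", n_samples=len(samples), n_classes=int(labels.max()) + 1,
                        hw=config.hw, source="synthetic" if config.synthetic else config.input_dir)

        # --- segment ------------------------------------------------------
        current = "segment"
        masked, seg_rows = [], []
        for i, s in enumerate(samples):
            res = segmentation.segment_image(
                s.image, n_segments=config.n_segments, alpha=config.alpha,
                sigma_c=config.sigma_c, sigma_s=config.sigma_s,
            )
            masked.append(_masked_rgb(s.image, res.mask))
            seg_rows.append(
                {"sample_id": f"s_{i:05d}", "threshold": res.threshold,
                 "mask_area_px": int(res.mask.sum())}
            )
        seg_log = pd.DataFrame(seg_rows).set_index("sample_id")
        seg_log.to_csv(out / "segmentation_log.csv")
        manifest.record("segment", n_images=len(masked),
                        mean_mask_area=float(seg_log.mask_area_px.mean()))

        # --- extract two views -------------------------------------------
        feats = {}
        for view, dim in (("dar", config.dar_dim), ("squ", config.squ_dim)):
            current = f"extract_{view}"
            extractor = backbones.MockFeatureExtractor(
                out_dim=dim, seed=stage_seed(config.seed, f"extract_{view}"),
                descriptor=f"{'darknet19' if view == 'dar' else 'squeezenet'}-mock",
            )
            frame = backbones.extract_features(extractor, masked)
            frame.insert(0, "label", labels)
            frame.to_csv(out / f"features_{view}.csv")
            feats[view] = frame.drop(columns="label")
            manifest.record(f"extract_{view}", out_dim=dim, n_rows=len(frame))

        # --- fuse ---------------------------------------------------------
        current = "fuse"
        fused, report = fusion.fuse_features(
            feats["dar"], feats["squ"],
            fusion.FusionConfig(tau_high=config.tau_high, tau_low=config.tau_low),
        )
        fused_out = fused.copy()
        fused_out.insert(0, "label", labels)
        fused_out.to_csv(out / "features_fused.csv")
        with open(out / "fusion_report.json", "w") as fh:
            json.dump(report.to_dict(), fh, indent=2)
        manifest.record("fuse", fused_dim=report.fused_dim,
                        dropped_redundant=len(report.dropped_redundant),
                        dropped_low=len(report.dropped_low))

        # --- select -------------------------------------------------------
        current = "select"
        sel = boa.run_improved_boa(
            fused, labels,
            boa.BOAConfig(pop_size=config.pop_size, n_iters=config.n_iters,
                          seed=stage_seed(config.seed, "select")),
            lam=config.lam,
        )
        selected = fused[sel.selected_ids]
        selected_out = selected.copy()
        selected_out.insert(0, "label", labels)
        selected_out.to_csv(out / "features_selected.csv")
        pd.DataFrame({"best_fitness": sel.best_fitness_trace}).to_csv(
            out / "selection_trace.csv", index_label="iteration"
        )
        manifest.record("select", selected_dim=sel.n_selected,
                        best_fitness=sel.best_fitness_trace[-1])

        # --- classify -----------------------------------------------------
        current = "classify"
        results = evaluation.evaluate_panel(
            selected, labels, specs=config.panel,
            cfg=evaluation.EvalConfig(split=config.split, cv_folds=config.cv_folds,
                                      seed=stage_seed(config.seed, "classify")),
            use_cv=config.use_cv,
        )
        table = evaluation.results_frame(results)
        table.to_csv(out / "results.csv")
        cm_dir = out / "confusion_matrices"
        cm_dir.mkdir(exist_ok=True)
        for row, cm in results:
            pd.DataFrame(cm).to_csv(cm_dir / f"{row.classifier}.csv", index=False)
        manifest.record("classify", n_classifiers=len(results),
                        best_accuracy=float(table.accuracy.max()),
                        metrics={r.classifier: round(r.accuracy, 4) for r, _ in results})
    except Exception:
        logger.exception("pipeline failed at stage %r", current)
        manifest.to_json(out / "manifest.json")
        raise
    manifest.to_json(out / "manifest.json")
    return manifest


def _load_image_dir(root: Path) -> list[synthetic.GrainImageSample]:
    """Read a one-directory-per-class image tree (PNG/JPEG/TIFF)."""
    import imageio.v3 as iio

    samples = []
    class_dirs = sorted(d for d in root.iterdir() if d.is_dir())
    if not class_dirs:
        raise FileNotFoundError(f"no class directories under {root}")
    for label, cls_dir in enumerate(class_dirs):
        for path in sorted(cls_dir.glob("*")):
            if path.suffix.lower() not in (".png", ".jpg", ".jpeg", ".tif", ".tiff"):
                continue
            if path.stem.endswith("_mask"):
                continue
            image = np.asarray(iio.imread(path))
            if image.ndim == 2:
                image = np.stack([image] * 3, axis=-1)
            placeholder = np.zeros(image.shape[:2], dtype=np.uint8)
            placeholder[0, 0] = 1  # unknown ground truth; not used downstream
            samples.append(
                synthetic.GrainImageSample(image=image[..., :3], mask=placeholder, label=label)
            )
    return samples
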