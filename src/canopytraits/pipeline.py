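"""End-to-end orchestration: generate -> split -> augment -> train -> evaluate.

Also hosts the synthetic trait-recovery benchmark shared by the test suite and
the acceptance script: a 300-image dataset (100 per cultivar), an 80:20
stratified split, a width-reduced CNN trained for 40 epochs at batch 32, the
shallow feature baselines and the three depth linear models, all scored with
R^2 / NRMSE on the held-out test images.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
import time
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml
from PIL import Image

from . import augment as augmod
from . import metrics
from .baselines import BaselineModelSpec, fit_baseline
from .cnn import CNNConfig, CNNTraitModel, TrainConfig
from .dataset import SplitSpec, center_crop_resize, split_dataset
from .depth import StructuralTraitModel, segment_depth, structural_features
from .exceptions import DomainError, PipelineError
from .features import extract_features, pearson_screen, segment_plant
from .synthdata import (SceneSpec, default_cultivars, generate_dataset,
                        load_depth_png)

logger = logging.getLogger(__name__)

__all__ = ["PipelineConfig", "run_pipeline", "benchmark_cnn_config",
           "benchmark_train_config", "trait_recovery_benchmark",
           "load_image_stack"]


def benchmark_cnn_config() -> CNNConfig:
    """Width-reduced network for the CPU-scale synthetic benchmark.

    Same topology as the reference network (five 5x5 conv layers, padding on
    conv2/3, four 2x2 average pools, dropout before the 3-output dense layer)
    with channels (8, 16, 32, 54, 128) so a 40-epoch fit runs in minutes on
    one core.
    """
    return CNNConfig(conv_channels=(8, 16, 32, 54, 128))


def benchmark_train_config(seed: int = 0, epochs: int = 40,
                           batch_size: int = 32) -> TrainConfig:
    """Benchmark schedule: lr0 0.01 (momentum 0.9) stepping down by 0.1 every
    20 epochs — the reference step shape at a step size suited to the small
    batch and narrow network."""
    return TrainConfig(lr0=0.01, lr_drop_every=20, lr_drop_factor=0.1,
                       batch_size=batch_size, max_epochs=epochs, rng_seed=seed)


def load_image_stack(manifest: pd.DataFrame, root: Path | str,
                     side: int | None = None) -> np.ndarray:
    """Load (and optionally crop/resize) the RGB images of a manifest."""
    root = Path(root)
    images = []
    for _, rec in manifest.iterrows():
        img = np.asarray(Image.open(root / rec["rgb_path"]).convert("RGB"))
        if side is not None and img.shape[0] != side:
            img = center_crop_resize(img, crop_box=None, target_side=side)
        images.append(img)
    return np.stack(images)


def _subset(manifest: pd.DataFrame, ids) -> pd.DataFrame:
    out = manifest[manifest["id"].isin(set(ids))].copy()
    return out.sort_values("id").reset_index(drop=True)


def trait_recovery_benchmark(seed: int = 0, n_per_cultivar: int = 100,
                             epochs: int = 40, batch_size: int = 32,
                             work_dir: Path | str | None = None,
                             scene: SceneSpec | None = None,
                             include_baselines: bool = True,
                             include_depth: bool = True) -> dict:
    """Run the synthetic trait-recovery experiment end to end.

    Returns a dict with the evaluation report, the Pearson screening tables
    and the raw partitions.  Deterministic per seed.
    """
    import tempfile

    t0 = time.time()
    scene = scene or SceneSpec(rng_seed=seed)
    if scene.rng_seed != seed:
        scene = dataclasses.replace(scene, rng_seed=seed)
    cultivars = default_cultivars()

    ctx = tempfile.TemporaryDirectory() if work_dir is None else None
    root = Path(ctx.name) if ctx else Path(work_dir)
    try:
        manifest = generate_dataset(n_per_cultivar, cultivars, scene, root)
        split = split_dataset(manifest, SplitSpec(rng_seed=seed))
        train_rows = _subset(manifest, split.train_ids)
        val_rows = _subset(manifest, split.val_ids)
        test_rows = _subset(manifest, split.test_ids)

        cnn_cfg = benchmark_cnn_config()
        side = cnn_cfg.input_side
        x_train = load_image_stack(train_rows, root, side)
        x_val = load_image_stack(val_rows, root, side)
        x_test = load_image_stack(test_rows, root, side)
        trait_cols = ["lfw_g", "ldw_g", "la_cm2"]
        y_train = train_rows[trait_cols].to_numpy(float)
        y_val = val_rows[trait_cols].to_numpy(float)

        model = CNNTraitModel(x_train, y_train, config=cnn_cfg,
                              val_images=x_val, val_targets=y_val)
        cnn_res = model.fit(benchmark_train_config(seed, epochs, batch_size))
        logger.info("CNN fitted in %.1f s", time.time() - t0)

        truth = test_rows.set_index("id")[trait_cols + ["cultivar"]]
        truth.columns = list(metrics.TRAITS) + ["cultivar"]
        predictions: dict[str, pd.DataFrame] = {}
        predictions["CNN"] = pd.DataFrame(
            cnn_res.predict(x_test), index=test_rows["id"],
            columns=list(metrics.TRAITS))

        screening: dict[str, pd.DataFrame] = {}
        if include_baselines:
            # handcrafted features at native resolution on train+val vs test
            fit_rows = pd.concat([train_rows, val_rows], ignore_index=True) \
                .sort_values("id").reset_index(drop=True)
            feats = {}
            for rows in (fit_rows, test_rows):
                imgs = load_image_stack(rows, root)
                tab = {}
                for rid, img in zip(rows["id"], imgs):
                    tab[rid] = extract_features(img, segment_plant(img))
                feats[id(rows)] = pd.DataFrame(tab).T
            f_fit = feats[id(fit_rows)]
            f_test = feats[id(test_rows)].loc[test_rows["id"]]
            for trait, col in zip(metrics.TRAITS, trait_cols):
                y_fit = fit_rows.set_index("id")[col].loc[f_fit.index]
                screening[trait] = pearson_screen(f_fit, y_fit)
            for kind, name in (("svr", "SVR"), ("rf", "RF")):
                cols_pred = {}
                for trait, col in zip(metrics.TRAITS, trait_cols):
                    sel = screening[trait]["feature"].tolist() \
                        or list(f_fit.columns)
                    y_fit = fit_rows.set_index("id")[col].loc[f_fit.index]
                    fitted = fit_baseline(
                        BaselineModelSpec(kind=kind, rng_seed=seed),
                        f_fit[sel], y_fit)
                    cols_pred[trait] = fitted.predict(f_test[sel])
                predictions[name] = pd.DataFrame(
                    cols_pred, index=f_test.index)

        if include_depth:
            struct = {}
            all_rows = pd.concat([train_rows, val_rows, test_rows],
                                 ignore_index=True)
            for _, rec in all_rows.iterrows():
                depth = load_depth_png(root / rec["depth_path"])
                dmask = segment_depth(depth)
                sf = structural_features(depth, dmask, scene.sensor_height)
                struct[rec["id"]] = {"H": sf.H, "PA": sf.PA, "V": sf.V}
            struct_df = pd.DataFrame(struct).T
            fit_ids = sorted(set(split.train_ids) | set(split.val_ids))
            for feat_name, model_name in (("V", "LR-V"), ("PA", "LR-PA"),
                                          ("H", "LR-H")):
                cols_pred = {}
                for trait, col in zip(metrics.TRAITS, trait_cols):
                    y_fit = manifest.set_index("id").loc[fit_ids, col]
                    lr = StructuralTraitModel(
                        struct_df.loc[fit_ids, feat_name], y_fit,
                        name=feat_name).fit()
                    cols_pred[trait] = np.clip(
                        lr.predict(struct_df.loc[test_rows["id"], feat_name]),
                        0.0, None)
                predictions[model_name] = pd.DataFrame(
                    cols_pred, index=test_rows["id"])

        report = metrics.build_report(predictions, truth,
                                      strata=("all", "cultivar"))
        return {
            "report": report,
            "screening": screening,
            "cnn_results": cnn_res,
            "split": split,
            "manifest": manifest,
            "runtime_s": time.time() - t0,
        }
    finally:
        if ctx:
            ctx.cleanup()


# --- config-driven pipeline ----------------------------------------------------


@dataclass
class PipelineConfig:
    """Everything one run needs; loadable from YAML."""

    out_dir: str
    n_per_cultivar: int = 32
    scene: SceneSpec = field(default_factory=SceneSpec)
    split: SplitSpec = field(default_factory=SplitSpec)
    augmentation: augmod.AugmentationConfig = field(
        default_factory=augmod.AugmentationConfig)
    cnn: CNNConfig = field(default_factory=benchmark_cnn_config)
    train: TrainConfig = field(default_factory=lambda: benchmark_train_config())
    run_augmentation: bool = False
    run_baselines: bool = True
    run_depth: bool = True
    rng_seed: int = 0

    def __post_init__(self) -> None:
        if self.n_per_cultivar < 7:
            raise DomainError("n_per_cultivar must cover the 7 sessions")

    @classmethod
    def from_yaml(cls, path: Path | str) -> "PipelineConfig":
        raw = yaml.safe_load(Path(path).read_text()) or {}
        kwargs = dict(raw)
        if "scene" in kwargs:
            kwargs["scene"] = SceneSpec(**kwargs["scene"])
        if "split" in kwargs:
            kwargs["split"] = SplitSpec(**kwargs["split"])
        if "augmentation" in kwargs:
            a = dict(kwargs["augmentation"])
            for key in ("rotations", "flips", "brightness_factors"):
                if key in a:
                    a[key] = tuple(a[key])
            kwargs["augmentation"] = augmod.AugmentationConfig(**a)
        if "cnn" in kwargs:
            c = dict(kwargs["cnn"])
            if "conv_channels" in c:
                c["conv_channels"] = tuple(c["conv_channels"])
            if "padded_layers" in c:
                c["padded_layers"] = frozenset(c["padded_layers"])
            kwargs["cnn"] = CNNConfig(**c)
        if "train" in kwargs:
            kwargs["train"] = TrainConfig(**kwargs["train"])
        return cls(**kwargs)

    def config_hash(self) -> str:
        def default(o):
            if dataclasses.is_dataclass(o):
                return dataclasses.asdict(o)
            if isinstance(o, frozenset):
                return sorted(o)
            return str(o)
        blob = json.dumps(dataclasses.asdict(self), default=default,
                          sort_keys=True)
        return hashlib.sha256(blob.encode()).hexdigest()[:16]


def run_pipeline(config: PipelineConfig) -> Path:
    """Run every stage and write reports plus a machine-readable run summary.

    Returns the run directory.  Any stage failure aborts with the stage name;
    artifacts written so far are retained for inspection.
    """
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    summary: dict = {"seed": config.rng_seed,
                     "config_hash": config.config_hash(), "stages": {}}
    stage = "generate"
    try:
        t = time.time()
        scene = dataclasses.replace(config.scene, rng_seed=config.rng_seed)
        manifest = generate_dataset(config.n_per_cultivar, default_cultivars(),
                                    scene, out / "data")
        summary["stages"][stage] = {"n_images": len(manifest),
                                    "seconds": round(time.time() - t, 2)}

        stage = "split"
        t = time.time()
        split = split_dataset(
            manifest, dataclasses.replace(config.split,
                                          rng_seed=config.rng_seed))
        split.to_frame().to_csv(out / "partition.csv", index=False)
        summary["stages"][stage] = {
            "n_train": len(split.train_ids), "n_val": len(split.val_ids),
            "n_test": len(split.test_ids),
            "seconds": round(time.time() - t, 2)}

        if config.run_augmentation:
            stage = "augment"
            t = time.time()
            train_rows = _subset(manifest, split.train_ids)
            aug = augmod.expand_training_set(
                train_rows, config.augmentation, out / "augmented",
                image_root=out / "data")
            factor = augmod.augmentation_factor(config.augmentation)
            observed = len(aug) / max(len(train_rows), 1)
            if observed != factor:
                raise PipelineError(
                    f"augmentation factor mismatch: rule {factor}, "
                    f"observed {observed}")
            summary["stages"][stage] = {
                "n_augmented": len(aug), "factor": factor,
                "seconds": round(time.time() - t, 2)}

        stage = "train-cnn"
        t = time.time()
        bench = trait_recovery_benchmark(
            seed=config.rng_seed, n_per_cultivar=config.n_per_cultivar,
            epochs=config.train.max_epochs,
            batch_size=config.train.batch_size, work_dir=out / "data",
            scene=scene, include_baselines=config.run_baselines,
            include_depth=config.run_depth)
        report = bench["report"]
        summary["stages"][stage] = {"seconds": round(time.time() - t, 2)}

        stage = "evaluate"
        report.rows.to_csv(out / "report.csv", index=False,
                           float_format="%.6f")
        report.pairs.to_csv(out / "scatter_pairs.csv", index=False,
                            float_format="%.6f")
        report.grid("r2").to_json(out / "report_r2.json")
        (out / "run_summary.json").write_text(
            json.dumps(summary, indent=2, sort_keys=True))
        return out
    except Exception as exc:
        (out / "run_summary.json").write_text(
            json.dumps({**summary, "failed_stage": stage,
                        "error": str(exc)}, indent=2, sort_keys=True))
        raise PipelineError(f"stage {stage!r} failed: {exc}") from exc
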