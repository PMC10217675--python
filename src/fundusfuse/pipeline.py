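"""Configuration-driven end-to-end runs: generate/load -> preprocess ->
extract (LBP, branching CNN, ResNet50) -> entropy top-k selection -> deep
fusion -> swarm optimization -> final fusion -> multi-preset evaluation.

Every artifact is stamped with a hash of the configuration and the global
seed; metrics that must be byte-reproducible (metrics.csv, masks, features)
carry no timestamps — wall times live in ``timings.json`` and the log.
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

from .deep import TrainConfig, build_graphnet, extract_backbone_features, extract_deep_features, train_cnn
from .entropy import feature_entropy, select_top_k
from .evaluation import ALL_PRESETS, evaluate_protocol, make_classifier
from .features import FeatureMatrix
from .fusion import build_final_vector, fuse_blocks
from .preprocessing import Image, PreprocessConfig, preprocess_pipeline
from .swarm import OptimizerConfig, combine_optimizers, make_knn_evaluator
from .synthetic import FundusConfig, generate_dataset
from .texture import extract_lbp_features

log = logging.getLogger("fundusfuse")


@dataclass
class PipelineConfig:
    """Flat, YAML-serializable description of one experiment."""

    # dataset: synthetic generator (default) or a directory with manifest.csv
    data_dir: str | None = None
    n_per_class: int = 30
    image_size: int = 64
    # preprocessing
    target_size: int = 64
    median_kernel: int = 3
    unsharp_radius: float = 2.0
    unsharp_amount: float = 1.0
    # deep extractors
    cnn_epochs: int = 30
    cnn_minibatch: int = 16
    cnn_initial_lr: float = 0.003
    cnn_lr_drop_period: int = 15
    cnn_stem_channels: int = 8
    resnet_input_size: int = 64
    # selection sizes (l, g, r)
    l: int = 10
    g: int = 32
    r: int = 32
    # optimizer
    optimizer_population: int = 20
    optimizer_iterations: int = 30
    optimizer_alpha: float = 0.99
    optimizer_eval_folds: int = 3
    # fusion + evaluation
    fusion_mode: str = "zero"
    presets: list[str] = field(default_factory=lambda: list(ALL_PRESETS))
    protocol: str = "kfold:5"
    # bookkeeping
    out_dir: str = "runs/run"
    seed: int = 0

    def __post_init__(self) -> None:
        if not 1 <= self.l <= 59:
            raise ValueError("l must be in 1..59 (LBP width)")
        if not 1 <= self.g <= 4096 or not 1 <= self.r <= 2048:
            raise ValueError("g must be in 1..4096 and r in 1..2048")
        for p in self.presets:
            if p not in ALL_PRESETS:
                raise ValueError(f"unknown preset {p!r}")

    def to_yaml(self, path: str | Path) -> None:
        Path(path).write_text(yaml.safe_dump(dataclasses.asdict(self), sort_keys=True))

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        return cls(**yaml.safe_load(Path(path).read_text()))

    def content_hash(self) -> str:
        """Hash of the scientific configuration (output location excluded)."""
        d = dataclasses.asdict(self)
        d.pop("out_dir")
        blob = yaml.safe_dump(d, sort_keys=True).encode()
        return hashlib.sha256(blob).hexdigest()[:16]


def _load_directory(data_dir: str, target: int) -> tuple[list[np.ndarray], np.ndarray]:
    from PIL import Image as PILImage

    root = Path(data_dir)
    manifest = pd.read_csv(root / "manifest.csv")
    images, grades = [], []
    for _, row in manifest.iterrows():
        images.append(np.asarray(PILImage.open(root / row["path"]).convert("RGB")))
        grades.append(int(row["grade"]))
    return images, np.asarray(grades)


def run_pipeline(cfg: PipelineConfig) -> Path:
    """Execute the full pipeline; returns the populated run directory."""
    out = Path(cfg.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    handler = logging.FileHandler(out / "run.log")
    handler.setFormatter(logging.Formatter("%(asctime)s %(levelname)s %(message)s"))
    log.addHandler(handler)
    log.setLevel(logging.INFO)
    timings: dict[str, float] = {}
    run_hash = cfg.content_hash()
    try:
        cfg.to_yaml(out / "config.yaml")

        def stage(name):
            log.info("stage %s start", name)
            return time.perf_counter()

        # ---- dataset ----
        t0 = stage("dataset")
        if cfg.data_dir:
            images, labels = _load_directory(cfg.data_dir, cfg.target_size)
        else:
            fconf = FundusConfig(image_size=cfg.image_size, seed=cfg.seed)
            images, manifest, _ = generate_dataset(fconf, cfg.n_per_class, cfg.seed)
            labels = manifest["grade"].to_numpy()
            manifest.to_csv(out / "manifest.csv", index=False)
        timings["dataset"] = time.perf_counter() - t0

        # ---- preprocessing ----
        t0 = stage("preprocess")
        pconf = PreprocessConfig(
            target_size=cfg.target_size,
            median_kernel=cfg.median_kernel,
            unsharp_radius=cfg.unsharp_radius,
            unsharp_amount=cfg.unsharp_amount,
        )
        pre = [preprocess_pipeline(Image(img, grade=int(g)), pconf) for img, g in zip(images, labels)]
        timings["preprocess"] = time.perf_counter() - t0

        # ---- feature extraction ----
        t0 = stage("extract_lbp")
        lbp = extract_lbp_features(pre)
        timings["extract_lbp"] = time.perf_counter() - t0

        t0 = stage("extract_graphnet")
        model = build_graphnet(5, cfg.target_size, seed=cfg.seed, stem_channels=cfg.cnn_stem_channels)
        tconf = TrainConfig(
            initial_lr=cfg.cnn_initial_lr,
            lr_drop_period=cfg.cnn_lr_drop_period,
            max_epochs=cfg.cnn_epochs,
            minibatch=cfg.cnn_minibatch,
            seed=cfg.seed,
        )
        history = train_cnn(model, pre, labels, tconf)
        graphnet = extract_deep_features(model, pre, "FC-1")
        timings["extract_graphnet"] = time.perf_counter() - t0

        t0 = stage("extract_resnet")
        resnet = extract_backbone_features(pre, input_size=cfg.resnet_input_size, seed=cfg.seed)
        timings["extract_resnet"] = time.perf_counter() - t0

        # ---- entropy selection (top-k per block) ----
        t0 = stage("select")
        blocks = {}
        for name, block, k in (("lbp", lbp, cfg.l), ("graphnet", graphnet, cfg.g), ("resnet", resnet, cfg.r)):
            profile = feature_entropy(block, labels)
            sel = select_top_k(profile, k)
            blocks[name] = block.select_columns(sel.indices)
            blocks[name].to_npz(out / f"features_{name}_selected.npz")
        timings["select"] = time.perf_counter() - t0

        # ---- deep fusion + swarm optimization ----
        t0 = stage("optimize")
        deep_fused = fuse_blocks([blocks["graphnet"], blocks["resnet"]])
        oconf = OptimizerConfig(
            population=cfg.optimizer_population,
            iterations=cfg.optimizer_iterations,
            alpha=cfg.optimizer_alpha,
            seed=cfg.seed,
            evaluator=make_knn_evaluator(deep_fused, labels, seed=cfg.seed, folds=cfg.optimizer_eval_folds),
        )
        best = combine_optimizers(deep_fused, labels, oconf)
        (out / "optimizer.json").write_text(
            json.dumps(
                {
                    "mask": best.mask.astype(int).tolist(),
                    "fitness": best.fitness,
                    "error": best.error,
                    "size": best.size,
                    "config_hash": run_hash,
                    "seed": cfg.seed,
                }
            )
        )
        timings["optimize"] = time.perf_counter() - t0

        # ---- final fusion ----
        final = build_final_vector(blocks["lbp"], deep_fused, best.mask, cfg.fusion_mode)
        final.to_npz(out / "features_final.npz")
        log.info("final feature width %d", final.width)

        # ---- evaluation ----
        t0 = stage("evaluate")
        rows, reports = [], {}
        for preset in cfg.presets:
            rep = evaluate_protocol(final, labels, make_classifier(preset), cfg.protocol, cfg.seed)
            rows.append(rep.summary_row())
            reports[preset] = {
                "per_class": rep.per_class,
                "overall_acc": rep.overall_acc,
                "wall_time_s": rep.wall_time,
                "cm": rep.cm.counts.tolist(),
            }
        timings["evaluate"] = time.perf_counter() - t0

        summary = pd.DataFrame(rows)
        # deterministic artifact: no wall times
        summary.drop(columns=["time_s"]).round(6).to_csv(out / "metrics.csv", index=False)
        (out / "metrics.json").write_text(json.dumps(reports, indent=1))
        (out / "timings.json").write_text(json.dumps(timings, indent=1))
        (out / "run_meta.json").write_text(
            json.dumps(
                {
                    "config_hash": run_hash,
                    "seed": cfg.seed,
                    "final_width": final.width,
                    "cnn_final_train_accuracy": history["accuracy"][-1],
                    "n_images": len(images),
                }
            )
        )
        log.info("run complete: %s", out)
        return out
    except Exception as exc:  # persist partial state, then re-raise with stage info
        (out / "FAILED").write_text(f"{type(exc).__name__}: {exc}")
        raise
    finally:
        log.removeHandler(handler)
        handler.close()


def summarize_runs(run_dirs: list[str | Path]) -> pd.DataFrame:
    """One row per classifier per run; best value per metric flagged in JSON.

    Incomplete run directories are skipped with a warning.
    """
    frames = []
    for d in run_dirs:
        d = Path(d)
        metrics = d / "metrics.csv"
        if not metrics.exists():
            log.warning("skipping incomplete run dir %s", d)
            continue
        df = pd.read_csv(metrics)
        df.insert(0, "run", d.name)
        frames.append(df)
    if not frames:
        raise ValueError("no completed runs found")
    table = pd.concat(frames, ignore_index=True)
    best = {m: float(table[m].max()) for m in ("ACC", "SEN", "PRE", "SPE", "F1")}
    table.attrs["best_per_column"] = best
    return table
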