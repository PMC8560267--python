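"""Pipeline configuration, seed derivation and the end-to-end study runner.

A single YAML file (or :class:`PipelineConfig` object) drives the whole
study: phantom generation, training of the baseline CNN, the four
per-modality CNNs and the FCN, segmentation of a held-out evaluation set by
the three algorithms (CNN, FCN[+CRF], multimodal), and the benchmark report.
One global seed deterministically derives every stage seed by hashing
``(global_seed, stage_name)``, so two runs of the same config are
byte-identical.
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
import yaml

from vesselseg import __version__
from vesselseg.cnn import TrainConfig, segment_cnn, train_cnn_on_phantoms
from vesselseg.crf import crf_refine
from vesselseg.fcn import fcn_forward, train_fcn
from vesselseg.filters import FilterBankConfig, build_modality_stack
from vesselseg.fusion import (
    FCMParams,
    FusionConfig,
    GMMParams,
    fit_fusion_weights_end_to_end,
    run_multimodal_pipeline,
)
from vesselseg.metrics import evaluate_masks
from vesselseg.io import file_checksum
from vesselseg.metrics import benchmark_report
from vesselseg.phantom import PRESETS, PhantomConfig, generate_dataset

logger = logging.getLogger(__name__)


class ConfigError(ValueError):
    pass


def derive_stage_seed(global_seed: int, stage: str) -> int:
    """Deterministic per-stage seed: blake2s of ``"<seed>:<stage>"`` mod 2^31."""
    digest = hashlib.blake2s(f"{global_seed}:{stage}".encode()).digest()
    return int.from_bytes(digest[:4], "little") % (2**31)


@dataclass
class CRFConfig:
    weight: float = 0.5
    max_iter: int = 20
    apply_to: str = "fcn"  # none | fcn | all


@dataclass
class PipelineConfig:
    """Everything one study run needs; round-trips losslessly through YAML."""

    phantom: PhantomConfig = field(default_factory=lambda: PRESETS["easy"])
    n_train: int = 14
    n_eval: int = 6
    filters: FilterBankConfig = field(default_factory=FilterBankConfig)
    cnn_train: TrainConfig = field(default_factory=TrainConfig)
    fcn_train: TrainConfig = field(
        default_factory=lambda: TrainConfig(learning_rate=0.2, epochs=40, batch_size=1)
    )
    crf: CRFConfig = field(default_factory=CRFConfig)
    fusion: FusionConfig = field(default_factory=lambda: FusionConfig(rule="weighted", weights=None))
    gmm: GMMParams = field(default_factory=lambda: GMMParams(covariance="tied"))
    fcm: FCMParams = field(default_factory=FCMParams)
    patch_size: int = 17
    stride: int = 1
    seed: int = 0
    log_level: str = "INFO"

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d["phantom"] = self.phantom.to_dict()
        for key in ("gmm", "fcm"):
            d[key] = {
                k: (v.tolist() if isinstance(v, np.ndarray) else v)
                for k, v in d[key].items()
                if k not in ("means", "variances", "mixing_weights", "centers", "membership")
                or v is None
            }
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "PipelineConfig":
        d = dict(d)
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(d) - known
        if unknown:
            raise ConfigError(f"unknown config fields: {sorted(unknown)}")
        if "phantom" in d:
            d["phantom"] = PhantomConfig.from_dict(d["phantom"])
        if "filters" in d:
            d["filters"] = FilterBankConfig.from_dict(d["filters"])
        for key, typ in (
            ("cnn_train", TrainConfig),
            ("fcn_train", TrainConfig),
            ("crf", CRFConfig),
            ("gmm", GMMParams),
            ("fcm", FCMParams),
        ):
            if key in d and isinstance(d[key], dict):
                d[key] = typ(**d[key])
        if "fusion" in d and isinstance(d["fusion"], dict):
            f = dict(d["fusion"])
            if f.get("weights") is not None:
                f["weights"] = tuple(f["weights"])
            d["fusion"] = FusionConfig(**f)
        return cls(**d)

    def config_hash(self) -> str:
        return hashlib.sha256(json.dumps(self.to_dict(), sort_keys=True).encode()).hexdigest()[:16]


def load_config(path: str | Path) -> PipelineConfig:
    """Parse a YAML pipeline configuration, validating field names eagerly."""
    with open(path) as fh:
        data = yaml.safe_load(fh)
    if not isinstance(data, dict):
        raise ConfigError(f"{path}: expected a mapping at top level")
    return PipelineConfig.from_dict(data)


@dataclass
class RunManifest:
    """Record of one ``run_all`` execution: config, checksums, timing, stages."""

    config: dict
    version: str
    config_hash: str
    started: float
    finished: float | None = None
    stages: list[dict] = field(default_factory=list)
    artifacts: dict[str, str] = field(default_factory=dict)

    def record_stage(self, name: str, seed: int | None, status: str = "ok") -> None:
        self.stages.append({"stage": name, "seed": seed, "status": status, "time": time.time()})

    def record_artifact(self, path: str | Path) -> None:
        self.artifacts[str(path)] = file_checksum(path)

    def write(self, path: str | Path) -> None:
        Path(path).parent.mkdir(parents=True, exist_ok=True)
        Path(path).write_text(json.dumps(dataclasses.asdict(self), indent=2) + "\n")


def train_all_models(config: PipelineConfig, train_images, train_masks):
    """Train the per-modality CNNs and the FCN for one study run.

    Returns ``(modality_models, fcn_model, fusion_config)``; the CNN baseline
    is the modality-0 (original-channel) model, since the baseline *is* a
    single-modality CNN on the unfiltered image.  When the fusion rule is
    ``weighted`` with no explicit weights, per-modality weights are estimated
    from each model's Dice on a few training images by the log-odds rule.
    """
    stacks = [build_modality_stack(img, config.filters) for img in train_images]
    # hold out ~30% of the images from patch training; the fusion combiner is
    # fit on these so it sees generalization, not memorization, per modality
    n_holdout = max(1, len(stacks) * 3 // 10) if len(stacks) > 1 else 0
    n_fit = len(stacks) - n_holdout
    modality_models = []
    probe_maps: list[list[np.ndarray]] = [[] for _ in range(n_holdout)]
    for ch in range(4):
        seed = derive_stage_seed(config.seed, f"cnn_modality_{ch}")
        tcfg = dataclasses.replace(config.cnn_train, seed=seed)
        imgs = [s.channels[ch] for s in stacks]
        model, history = train_cnn_on_phantoms(
            imgs[:n_fit], train_masks[:n_fit], tcfg, patch_size=config.patch_size
        )
        logger.info("modality %d CNN trained: loss %.4f -> %.4f", ch, history[0], history[-1])
        for i in range(n_holdout):
            probe_maps[i].append(segment_cnn(imgs[n_fit + i], model, stride=config.stride))
        modality_models.append(model)

    fusion_config = config.fusion
    if fusion_config.rule == "weighted" and fusion_config.weights is None:
        if n_holdout == 0:
            fusion_config = FusionConfig(rule="mean")
        else:
            weights = fit_fusion_weights_end_to_end(
                probe_maps,
                train_masks[n_fit:],
                gmm=dataclasses.replace(config.gmm, seed=derive_stage_seed(config.seed, "gmm")),
                fcm=dataclasses.replace(config.fcm, seed=derive_stage_seed(config.seed, "fcm")),
            )
            fusion_config = FusionConfig(rule="weighted", weights=weights)
            logger.info("stacked fusion weights: %s", np.round(weights, 3))

    fcn_seed = derive_stage_seed(config.seed, "fcn")
    fcfg = dataclasses.replace(config.fcn_train, seed=fcn_seed)
    fcn_model, fhistory = train_fcn(train_images, train_masks, fcfg)
    logger.info("FCN trained: loss %.4f -> %.4f", fhistory[0], fhistory[-1])
    return modality_models, fcn_model, fusion_config


def make_algorithms(config: PipelineConfig, modality_models, fcn_model, fusion_config=None):
    """The three compared segmenters as name → (image → binary mask)."""
    fusion_config = fusion_config or config.fusion

    def seg_cnn(image):
        prob = segment_cnn(image, modality_models[0], stride=config.stride)
        if config.crf.apply_to == "all":
            return crf_refine(prob, config.crf.weight, config.crf.max_iter)
        return (prob[1] > 0.5).astype(np.uint8)

    def seg_fcn(image):
        prob = fcn_forward(image, fcn_model)
        if config.crf.apply_to in ("fcn", "all"):
            return crf_refine(prob, config.crf.weight, config.crf.max_iter)
        return (prob[1] > 0.5).astype(np.uint8)

    def seg_multimodal(image):
        return run_multimodal_pipeline(
            image,
            modality_models,
            filter_config=config.filters,
            fusion_config=fusion_config,
            gmm=dataclasses.replace(config.gmm, seed=derive_stage_seed(config.seed, "gmm")),
            fcm=dataclasses.replace(config.fcm, seed=derive_stage_seed(config.seed, "fcm")),
            stride=config.stride,
        )

    return {"cnn": seg_cnn, "fcn": seg_fcn, "multimodal": seg_multimodal}


def phantom_benchmark(seed: int, n_eval: int = 20, config: PipelineConfig | None = None):
    """Train all models and evaluate the three algorithms on fresh phantoms.

    Returns the benchmark summary table (one row per algorithm with
    mean ± SD of Dice/precision/recall over ``n_eval`` evaluation phantoms).
    Training data, evaluation data and all stage seeds derive from ``seed``.
    """
    config = config or PipelineConfig()
    config = dataclasses.replace(config, seed=seed)
    train, _ = generate_dataset(
        config.phantom, config.n_train, seed=derive_stage_seed(seed, "phantom_train"), val_fraction=0.0
    )
    evals, _ = generate_dataset(
        config.phantom, n_eval, seed=derive_stage_seed(seed, "phantom_eval"), val_fraction=0.0
    )
    models, fcn_model, fusion_config = train_all_models(
        config, [p.image for p in train], [p.mask for p in train]
    )
    algorithms = make_algorithms(config, models, fcn_model, fusion_config)
    return benchmark_report(algorithms, [p.image for p in evals], [p.mask for p in evals])


def run_all(config: PipelineConfig, out_dir: str | Path) -> RunManifest:
    """Execute the full study and write ``report.csv``/``report.json`` + manifest.

    The report files depend only on (config, seed); the manifest additionally
    records wall-clock timestamps and artifact checksums.
    """
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    logging.basicConfig(level=getattr(logging, config.log_level.upper(), logging.INFO))
    manifest = RunManifest(
        config=config.to_dict(),
        version=__version__,
        config_hash=config.config_hash(),
        started=time.time(),
    )
    logger.info("run_all: config hash %s, global seed %d", config.config_hash(), config.seed)

    data_seed = derive_stage_seed(config.seed, "phantom_train")
    train, _ = generate_dataset(config.phantom, config.n_train, seed=data_seed, val_fraction=0.0)
    eval_seed = derive_stage_seed(config.seed, "phantom_eval")
    evals, _ = generate_dataset(config.phantom, config.n_eval, seed=eval_seed, val_fraction=0.0)
    manifest.record_stage("phantom_generation", data_seed)

    train_images = [p.image for p in train]
    train_masks = [p.mask for p in train]
    try:
        modality_models, fcn_model, fusion_config = train_all_models(config, train_images, train_masks)
        manifest.record_stage("training", config.seed)
    except Exception as exc:
        manifest.record_stage("training", config.seed, status=f"failed: {exc}")
        manifest.finished = time.time()
        manifest.write(out_dir / "manifest.json")
        raise

    algorithms = make_algorithms(config, modality_models, fcn_model, fusion_config)
    report_csv = out_dir / "report.csv"
    report_json = out_dir / "report.json"
    table = benchmark_report(
        algorithms,
        [p.image for p in evals],
        [p.mask for p in evals],
        out_csv=report_csv,
        out_json=report_json,
    )
    manifest.record_stage("benchmark", eval_seed)
    manifest.record_artifact(report_csv)
    manifest.record_artifact(report_json)
    manifest.finished = time.time()
    manifest.write(out_dir / "manifest.json")
    logger.info("benchmark summary:\n%s", table.to_string(index=False))
    return manifest
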