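"""End-to-end orchestration: extract -> register -> train -> predict -> evaluate.

Each stage writes its artifacts under the run directory and is skipped on
rerun when its outputs already exist, so interrupted runs resume.  The fully
resolved configuration (defaults filled in) and all seeds are echoed next to
the outputs.
"""

from __future__ import annotations

import logging
import time
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np

from . import io as ir2_io
from .errors import FormatError, InvalidConfigError
from .metrics import SpectralEntropyConfig, evaluate_patchwise, surface_patch_selector
from .registration import register_pairs
from .restoration import TrainedModel, TrainingConfig, UNetConfig, predict_volume, train_model
from .sampling import SamplingConfig, extract_training_set
from .phantom import PairedVolume
from .volume import Volume

log = logging.getLogger("ir2")


@dataclass
class PipelineConfig:
    """Everything a full run needs, loadable from YAML."""

    degraded_path: str = ""
    truth_path: str = ""
    voxel_spacing_um: tuple[float, float, float] = (1.0, 0.5, 0.5)
    sampling: SamplingConfig = field(default_factory=SamplingConfig)
    registration_radius: tuple[int, int, int] = (2, 10, 10)
    unet: UNetConfig = field(default_factory=UNetConfig)
    training: TrainingConfig = field(default_factory=TrainingConfig)
    entropy: SpectralEntropyConfig = field(default_factory=SpectralEntropyConfig)
    tile_overlap: tuple[int, int, int] = (4, 8, 8)
    eval_patches: int = 50
    eval_max_distance_um: float | None = None
    seed: int = 0

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        raw = ir2_io.read_yaml(path)
        return cls.from_dict(raw)

    @classmethod
    def from_dict(cls, raw: dict) -> "PipelineConfig":
        kwargs = dict(raw)
        for key, sub in (("sampling", SamplingConfig), ("unet", UNetConfig),
                         ("training", TrainingConfig),
                         ("entropy", SpectralEntropyConfig)):
            if key in kwargs and isinstance(kwargs[key], dict):
                sect = {
                    k: tuple(v) if isinstance(v, list) else v
                    for k, v in kwargs[key].items()
                }
                kwargs[key] = sub(**sect)
        for key in ("voxel_spacing_um", "registration_radius", "tile_overlap"):
            if key in kwargs and isinstance(kwargs[key], list):
                kwargs[key] = tuple(kwargs[key])
        return cls(**kwargs)

    def to_dict(self) -> dict:
        return asdict(self)


def _stage(name: str):
    def deco(fn):
        def wrapper(*args, **kwargs):
            t0 = time.perf_counter()
            log.info("stage %s: start", name)
            try:
                out = fn(*args, **kwargs)
            except Exception:
                log.exception("stage %s: FAILED", name)
                raise
            log.info("stage %s: done in %.1fs", name, time.perf_counter() - t0)
            return out
        return wrapper
    return deco


def run_pipeline(config: PipelineConfig, outdir) -> dict:
    """Execute the full restoration workflow and return artifact paths.

    Stages whose artifacts already exist under ``outdir`` are skipped, which
    makes reruns resume after a failure.  Reports are CSV/JSON, volumes TIFF.
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    handler = logging.FileHandler(outdir / "run.log")
    handler.setFormatter(logging.Formatter("%(asctime)s %(levelname)s %(message)s"))
    log.addHandler(handler)
    log.setLevel(logging.INFO)
    try:
        return _run_pipeline_inner(config, outdir)
    finally:
        log.removeHandler(handler)
        handler.close()


def _run_pipeline_inner(config: PipelineConfig, outdir: Path) -> dict:
    ir2_io.write_yaml(config.to_dict(), outdir / "config_resolved.yaml")
    log.info("seed=%d sampling.seed=%d training.seed=%d", config.seed,
             config.sampling.seed, config.training.seed)

    if not Path(config.degraded_path).exists():
        raise FormatError(f"degraded volume not found: {config.degraded_path}")
    if not Path(config.truth_path).exists():
        raise FormatError(f"truth volume not found: {config.truth_path}")
    degraded = ir2_io.read_volume(config.degraded_path, config.voxel_spacing_um,
                                  "degraded")
    truth = ir2_io.read_volume(config.truth_path, config.voxel_spacing_um,
                               "ground_truth")
    if degraded.shape != truth.shape:
        raise InvalidConfigError("degraded and truth volumes differ in shape")

    from .sampling import otsu_threshold
    mask = truth.data > otsu_threshold(truth.data)
    paired = PairedVolume(ground_truth=truth, degraded=degraded, mask=mask,
                          depth_map=np.zeros(truth.shape))

    patches_dir = outdir / "patches"
    extract = _stage("extract")(_extract)
    if not (patches_dir / "manifest.csv").exists():
        extract(paired, config, patches_dir)
    pairs = ir2_io.read_patches(patches_dir)

    model_dir = outdir / "model"
    if not (model_dir / "model.json").exists():
        register = _stage("register")(register_pairs)
        pairs = register(pairs, config.registration_radius, truth.data)
        ir2_io.write_patches(pairs, patches_dir)
        train = _stage("train")(train_model)
        run = train(pairs, config.unet, config.training)
        run.model.save(model_dir)
        ir2_io.write_json({"train_loss": run.train_loss,
                           "val_loss": run.val_loss,
                           "train_indices": run.train_indices,
                           "val_indices": run.val_indices},
                          model_dir / "training_log.json")
    model = TrainedModel.load(model_dir)

    restored_path = outdir / "restored.tif"
    if not restored_path.exists():
        predict = _stage("predict")(predict_volume)
        tile = tuple(np.minimum(config.sampling.patch_shape,
                                _divisible_floor(degraded.shape,
                                                 2 ** config.unet.depth)))
        restored = predict(model, degraded.data, tile, config.tile_overlap)
        ir2_io.write_volume(Volume(restored, config.voxel_spacing_um, "restored"),
                            restored_path)
    restored = ir2_io.read_volume(restored_path, config.voxel_spacing_um,
                                  "restored")

    report_path = outdir / "report.csv"
    if not report_path.exists():
        evaluate = _stage("evaluate")(_evaluate)
        evaluate(degraded, truth, restored, config, outdir)
    return {
        "patches": patches_dir,
        "model": model_dir,
        "restored": restored_path,
        "report": report_path,
        "log": outdir / "run.log",
        "config": outdir / "config_resolved.yaml",
    }


def _divisible_floor(shape, k):
    return tuple(max(k, (s // k) * k) for s in shape)


def _extract(paired, config, patches_dir):
    result = extract_training_set(paired, config.sampling)
    log.info("extracted %d pairs, coverage %.3f, status=%s",
             len(result.pairs), result.coverage, result.status)
    ir2_io.write_patches(result.pairs, patches_dir)
    ir2_io.write_json({"coverage_trace": result.coverage_trace,
                       "threshold": result.threshold,
                       "status": result.status},
                      patches_dir / "extraction.json")


def _evaluate(degraded, truth, restored, config, outdir):
    patch_shape = config.sampling.patch_shape
    max_dist = config.eval_max_distance_um
    if max_dist is None:
        max_dist = float("inf")
    centers = surface_patch_selector(
        truth.data, None, max_dist, patch_shape,
        n=config.eval_patches, seed=config.seed,
        spacing_um=config.voxel_spacing_um,
    )
    records, summary = evaluate_patchwise(
        {"degraded": degraded.data, "truth": truth.data,
         "restored": restored.data},
        centers, patch_shape, config.entropy, config.voxel_spacing_um,
    )
    records.to_csv(outdir / "report.csv", index=False)
    ir2_io.write_json(
        {"overall": summary["overall"].to_dict(),
         "n_patches": int(len(records))},
        outdir / "report_summary.json",
    )
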