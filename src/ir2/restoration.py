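"""Supervised restoration: percentile normalization, U-Net training, tiled
whole-volume prediction.

Patch pairs from the sampler (degraded input, ground-truth target) are
normalized with the 0.3/99.9 percentile convention used throughout the
pipeline, split 9:1 into training and validation sets, and fed to the
volumetric U-Net with a mean-squared-error loss; training runs for a fixed
number of epochs (full-scale default 100, batch 8) with Adam.  Full volumes
are restored by tiled inference with linear feather blending in the overlap
zones, then mapped back to the intensity scale of the training targets.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass
from pathlib import Path

import numpy as np

from .errors import (
    DegenerateInputError,
    DivergenceError,
    GeometryError,
    InvalidConfigError,
)
from .nn import Adam, UNet3D
from .sampling import PatchPair


@dataclass
class UNetConfig:
    """Architecture of the restoration network (one channel in, one out)."""

    depth: int = 2
    base_channels: int = 16
    kernel: int = 3
    input_channels: int = 1
    output_channels: int = 1
    output_activation: str = "linear"

    def __post_init__(self):
        if self.depth < 1:
            raise InvalidConfigError("depth must be >= 1")
        if self.input_channels != 1 or self.output_channels != 1:
            raise InvalidConfigError("only single-channel input/output supported")
        if self.output_activation != "linear":
            raise InvalidConfigError("only linear output activation supported")


@dataclass
class TrainingConfig:
    """Optimization schedule and data handling."""

    epochs: int = 100
    batch_size: int = 8
    split_ratio: tuple[int, int] = (9, 1)
    learning_rate: float = 4e-4
    seed: int = 0
    normalization_percentiles: tuple[float, float] = (0.3, 99.9)

    def __post_init__(self):
        if self.epochs < 1:
            raise InvalidConfigError("epochs must be >= 1")
        if self.batch_size < 1:
            raise InvalidConfigError("batch_size must be >= 1")
        if min(self.split_ratio) <= 0:
            raise InvalidConfigError("split_ratio parts must be positive")
        lo, hi = self.normalization_percentiles
        if not (0 <= lo < hi <= 100):
            raise InvalidConfigError("percentiles must satisfy 0 <= low < high <= 100")


@dataclass
class TrainingRun:
    """Result of :func:`train_model`."""

    model: "TrainedModel"
    train_loss: list[float]
    val_loss: list[float]
    train_indices: list[int]
    val_indices: list[int]


def split_train_val(pairs, ratio=(9, 1), seed: int = 0):
    """Random disjoint train/validation partition at the given ratio.

    With the default 9:1 ratio, ``len(train) = round(0.9 * n)``.  Both sides
    must be nonempty.
    """
    n = len(pairs)
    if n < 2:
        raise InvalidConfigError("need at least 2 pairs to split")
    frac = ratio[0] / (ratio[0] + ratio[1])
    n_train = int(round(n * frac))
    if n_train == 0 or n_train == n:
        raise InvalidConfigError(
            f"ratio {ratio} leaves an empty side for n={n}"
        )
    rng = np.random.default_rng(seed)
    perm = rng.permutation(n)
    train_idx = sorted(int(i) for i in perm[:n_train])
    val_idx = sorted(int(i) for i in perm[n_train:])
    return ([pairs[i] for i in train_idx], [pairs[i] for i in val_idx],
            train_idx, val_idx)


def normalize_percentile(volume: np.ndarray, p_low: float = 0.3,
                         p_high: float = 99.9):
    """Scale intensities by the (p_low, p_high) percentiles of their support.

    Percentiles are computed over nonzero voxels (zero is the padding /
    empty-space value in this pipeline); the affine map sends ``q_low`` to 0
    and ``q_high`` to 1.  Returns ``(normalized, q_low, q_high)``.
    """
    if p_low >= p_high:
        raise InvalidConfigError("p_low must be < p_high")
    v = np.asarray(volume, dtype=np.float64)
    support = v[v != 0]
    if support.size == 0:
        support = v.ravel()
    q_low, q_high = np.percentile(support, [p_low, p_high])
    if q_high == q_low:
        raise DegenerateInputError("degenerate percentiles: constant volume")
    return (v - q_low) / (q_high - q_low), float(q_low), float(q_high)


class TrainedModel:
    """A U-Net together with the normalization that defines its input scale.

    Callable on raw-intensity patches: normalizes with the training-set input
    percentiles, applies the network, and maps the prediction back through
    the training-target percentiles.
    """

    def __init__(self, net: UNet3D, unet_config: UNetConfig,
                 training_config: TrainingConfig,
                 input_refs: tuple[float, float],
                 target_refs: tuple[float, float]):
        self.net = net
        self.unet_config = unet_config
        self.training_config = training_config
        self.input_refs = tuple(float(r) for r in input_refs)
        self.target_refs = tuple(float(r) for r in target_refs)

    def __call__(self, patch: np.ndarray) -> np.ndarray:
        lo_i, hi_i = self.input_refs
        lo_t, hi_t = self.target_refs
        x = (np.asarray(patch, dtype=np.float32) - lo_i) / (hi_i - lo_i)
        y = self.net(x)
        return np.asarray(y, dtype=np.float64) * (hi_t - lo_t) + lo_t

    def save(self, path):
        """Weights as an .npz archive plus a JSON sidecar."""
        path = Path(path)
        path.mkdir(parents=True, exist_ok=True)
        np.savez(path / "weights.npz", **self.net.state_dict())
        sidecar = {
            "unet": asdict(self.unet_config),
            "training": asdict(self.training_config),
            "input_refs": list(self.input_refs),
            "target_refs": list(self.target_refs),
            "seed": self.training_config.seed,
        }
        (path / "model.json").write_text(json.dumps(sidecar, indent=2))

    @classmethod
    def load(cls, path) -> "TrainedModel":
        path = Path(path)
        sidecar = json.loads((path / "model.json").read_text())
        unet_cfg = UNetConfig(**{k: tuple(v) if isinstance(v, list) else v
                                 for k, v in sidecar["unet"].items()})
        tr = sidecar["training"]
        tr["split_ratio"] = tuple(tr["split_ratio"])
        tr["normalization_percentiles"] = tuple(tr["normalization_percentiles"])
        train_cfg = TrainingConfig(**tr)
        net = UNet3D(base_channels=unet_cfg.base_channels, depth=unet_cfg.depth,
                     seed=train_cfg.seed)
        with np.load(path / "weights.npz") as state:
            net.load_state_dict(dict(state))
        return cls(net, unet_cfg, train_cfg,
                   tuple(sidecar["input_refs"]), tuple(sidecar["target_refs"]))


def _stack_patches(pairs: list[PatchPair]):
    x = np.stack([np.asarray(p.degraded_patch, dtype=np.float32) for p in pairs])
    y = np.stack([np.asarray(p.truth_patch, dtype=np.float32) for p in pairs])
    return x, y


def train_model(pairs: list[PatchPair], unet: UNetConfig | None = None,
                cfg: TrainingConfig | None = None) -> TrainingRun:
    """Fit the U-Net to registered patch pairs with MSE loss.

    Normalization percentiles are computed once over the pooled training
    inputs and targets respectively; the same constants are used at
    prediction time.  Loss traces carry one entry per epoch.
    """
    unet = unet or UNetConfig()
    cfg = cfg or TrainingConfig()
    if len(pairs) < 2:
        raise InvalidConfigError("need at least 2 patch pairs")
    shape = np.asarray(pairs[0].degraded_patch).shape
    if any(np.asarray(p.degraded_patch).shape != shape
           or np.asarray(p.truth_patch).shape != shape for p in pairs):
        raise GeometryError("all patches must share one shape")
    if any(s % (2 ** unet.depth) for s in shape):
        raise GeometryError(
            f"patch shape {shape} not divisible by 2^{unet.depth}"
        )

    x_raw, y_raw = _stack_patches(pairs)
    _, in_lo, in_hi = normalize_percentile(x_raw, *cfg.normalization_percentiles)
    _, tg_lo, tg_hi = normalize_percentile(y_raw, *cfg.normalization_percentiles)
    x = (x_raw - in_lo) / (in_hi - in_lo)
    y = (y_raw - tg_lo) / (tg_hi - tg_lo)

    train_p, _, train_idx, val_idx = split_train_val(
        list(range(len(pairs))), cfg.split_ratio, cfg.seed)
    train_idx = np.asarray(train_idx)
    val_idx = np.asarray(val_idx)

    net = UNet3D(base_channels=unet.base_channels, depth=unet.depth,
                 seed=cfg.seed)
    opt = Adam(net, lr=cfg.learning_rate)
    rng = np.random.default_rng(cfg.seed + 1)

    train_loss: list[float] = []
    val_loss: list[float] = []
    for epoch in range(cfg.epochs):
        order = rng.permutation(train_idx)
        epoch_losses = []
        for start in range(0, len(order), cfg.batch_size):
            batch = order[start:start + cfg.batch_size]
            # accumulate gradients over the batch sample by sample
            grads = None
            batch_loss = 0.0
            for i in batch:
                pred = net.forward(x[i])
                resid = pred[0] - y[i]
                batch_loss += float(np.mean(resid ** 2))
                dy = (2.0 / resid.size) * resid[None] / len(batch)
                net.backward(dy.astype(np.float32))
                step_grads = {name: (getattr(conv, gattr).copy())
                              for name, conv, _, gattr in net.parameters()}
                if grads is None:
                    grads = step_grads
                else:
                    for k in grads:
                        grads[k] += step_grads[k]
            for name, conv, _, gattr in net.parameters():
                setattr(conv, gattr, grads[name])
            opt.step()
            epoch_losses.append(batch_loss / len(batch))
        train_loss.append(float(np.mean(epoch_losses)))
        v = [float(np.mean((net.forward(x[i])[0] - y[i]) ** 2)) for i in val_idx]
        val_loss.append(float(np.mean(v)))
        if not (np.isfinite(train_loss[-1]) and np.isfinite(val_loss[-1])):
            raise DivergenceError(
                f"non-finite loss at epoch {epoch}", epoch=epoch
            )

    model = TrainedModel(net, unet, cfg, (in_lo, in_hi), (tg_lo, tg_hi))
    return TrainingRun(model=model, train_loss=train_loss, val_loss=val_loss,
                       train_indices=[int(i) for i in train_idx],
                       val_indices=[int(i) for i in val_idx])


def _tile_positions(size: int, tile: int, step: int) -> list[int]:
    if tile >= size:
        return [0]
    pos = list(range(0, size - tile + 1, step))
    if pos[-1] != size - tile:
        pos.append(size - tile)
    return pos


def _feather_weight(tile: int, overlap: int) -> np.ndarray:
    w = np.ones(tile, dtype=np.float64)
    if overlap > 0:
        ramp = np.linspace(1.0 / (overlap + 1), 1.0, overlap)
        w[:overlap] = ramp
        w[-overlap:] = np.minimum(w[-overlap:], ramp[::-1])
    return w


def predict_volume(model, volume: np.ndarray, tile_shape=(16, 64, 64),
                   overlap: tuple[int, int, int] | int = 4) -> np.ndarray:
    """Restore a whole volume by overlapped tiling with feather blending.

    ``model`` is any callable mapping a raw-intensity tile to a same-shape
    restored tile (a :class:`TrainedModel` handles normalization internally).
    Axes smaller than the tile are reflect-padded and cropped back.  Overlap
    zones are blended with a linear ramp, so tile seams are exactly invisible
    for constant predictors and agree to high accuracy for smooth ones.
    """
    vol = np.asarray(volume, dtype=np.float64)
    if vol.ndim != 3:
        raise GeometryError("volume must be 3D")
    tile_shape = tuple(int(t) for t in tile_shape)
    if isinstance(overlap, int):
        overlap = (overlap,) * 3
    overlap = tuple(int(o) for o in overlap)
    if any(o < 0 or 2 * o >= t for o, t in zip(overlap, tile_shape)):
        raise InvalidConfigError("overlap must satisfy 0 <= overlap < tile/2")

    pad = [max(0, t - s) for t, s in zip(tile_shape, vol.shape)]
    if any(pad):
        vol_p = np.pad(vol, [(0, p) for p in pad], mode="reflect")
    else:
        vol_p = vol

    steps = [t - o for t, o in zip(tile_shape, overlap)]
    positions = [
        _tile_positions(s, t, st)
        for s, t, st in zip(vol_p.shape, tile_shape, steps)
    ]
    weights = [_feather_weight(t, o) for t, o in zip(tile_shape, overlap)]
    w_tile = (weights[0][:, None, None] * weights[1][None, :, None]
              * weights[2][None, None, :])

    out = np.zeros(vol_p.shape, dtype=np.float64)
    wsum = np.zeros(vol_p.shape, dtype=np.float64)
    for z0 in positions[0]:
        for y0 in positions[1]:
            for x0 in positions[2]:
                sl = (slice(z0, z0 + tile_shape[0]),
                      slice(y0, y0 + tile_shape[1]),
                      slice(x0, x0 + tile_shape[2]))
                pred = np.asarray(model(vol_p[sl]), dtype=np.float64)
                if pred.ndim == 4:
                    pred = pred[0]
                if pred.shape != tile_shape:
                    raise GeometryError(
                        f"model returned shape {pred.shape}, expected {tile_shape}"
                    )
                out[sl] += pred * w_tile
                wsum[sl] += w_tile
    out /= wsum
    return out[tuple(slice(0, s) for s in vol.shape)]
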