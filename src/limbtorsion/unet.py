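"""Modified 3D U-net for multi-class bone segmentation, with training loop.

The network follows the classic encoder-decoder layout with skip connections,
with three departures from the original recipe that suit anisotropic axial MRI
at batch size one:

* instance normalization instead of batch normalization,
* trilinear upsampling followed by a 1x1x1 convolution instead of transposed
  convolutions,
* 3D convolutions throughout.

Each level applies two 3x3x3 convolutions with instance norm and ReLU; filter
counts start at ``base_filters`` and double at every pooling step (16, 32, 64,
128, 256, 512 at the default depth of 6).  The final layer is a per-voxel
softmax over the four classes.  Because the stacks hold only ~29 slices while
the in-plane matrix is large, the pooling plan is anisotropic: a level pools
the z axis only while the z extent is at least ``min_z_pool`` and even, and
always pools in-plane (so in-plane dimensions must be divisible by
``2**(depth-1)``).

Training uses the sum of the soft Dice loss over the foreground classes
present in the target and voxel-averaged categorical cross-entropy over all
classes, optimized with Adam at batch size one.  The learning rate is halved
whenever the moving average of the training loss stops improving (relative
tolerance over a patience window) and never increases.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import ndimage
from sklearn.base import BaseEstimator

from . import autograd as ag
from .artifacts import ARTIFACT_FAMILIES, apply_artifact
from .volume import (LabelMask, PreprocessSpec, Volume, crop_or_pad,
                     normalize_intensity, resample, restore_native)

__all__ = [
    "NetConfig", "TrainConfig", "AugmentSpec", "UNet3D", "build_unet",
    "combined_loss", "Adam", "PlateauHalving", "train", "predict_mask",
    "UNet3DSegmenter",
]

DICE_EPS = 1e-5


@dataclass
class NetConfig:
    depth: int = 6
    base_filters: int = 16
    classes: int = 4
    in_channels: int = 1
    min_z_pool: int = 8

    def __post_init__(self) -> None:
        if self.depth < 2:
            raise ValueError("depth must be >= 2")
        if self.base_filters < 1:
            raise ValueError("base_filters must be >= 1")

    @property
    def filters(self) -> list[int]:
        return [self.base_filters * 2 ** k for k in range(self.depth)]


@dataclass
class TrainConfig:
    batch_size: int = 1
    initial_lr: float = 1e-3
    lr_decay_factor: float = 2.0
    plateau_window: int = 50
    plateau_patience: int = 100
    plateau_rel_tol: float = 1e-3
    min_lr: float = 1e-6
    max_iterations: int = 300
    seed: int = 0

    def __post_init__(self) -> None:
        if self.batch_size < 1 or self.initial_lr <= 0:
            raise ValueError("batch_size must be >= 1 and initial_lr > 0")


@dataclass
class AugmentSpec:
    """Per-sample random artifact choice: none with ``none_probability``,
    otherwise a uniform draw among the listed families."""

    families: tuple[str, ...] = ARTIFACT_FAMILIES
    none_probability: float = 0.5
    params: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        unknown = set(self.families) - set(ARTIFACT_FAMILIES)
        if unknown:
            raise ValueError(f"unknown artifact families: {sorted(unknown)}")
        if not 0.0 <= self.none_probability <= 1.0:
            raise ValueError("none_probability must be in [0, 1]")


# ---------------------------------------------------------------------------
# model


def _he_init(rng: np.random.Generator, shape: tuple[int, ...], fan_in: int) -> ag.Tensor:
    w = rng.normal(0.0, np.sqrt(2.0 / fan_in), size=shape).astype(np.float32)
    t = ag.Tensor(w, requires_grad=True)
    return t


def _zeros(shape) -> ag.Tensor:
    return ag.Tensor(np.zeros(shape, np.float32), requires_grad=True)


def _ones(shape) -> ag.Tensor:
    return ag.Tensor(np.ones(shape, np.float32), requires_grad=True)


class _ConvBlock:
    """Two (conv 3x3x3 -> instance norm -> ReLU) stages."""

    def __init__(self, rng, in_ch: int, out_ch: int):
        self.w1 = _he_init(rng, (out_ch, in_ch, 3, 3, 3), in_ch * 27)
        self.b1 = _zeros(out_ch)
        self.g1, self.be1 = _ones(out_ch), _zeros(out_ch)
        self.w2 = _he_init(rng, (out_ch, out_ch, 3, 3, 3), out_ch * 27)
        self.b2 = _zeros(out_ch)
        self.g2, self.be2 = _ones(out_ch), _zeros(out_ch)

    def __call__(self, x: ag.Tensor) -> ag.Tensor:
        x = ag.relu(ag.instance_norm(ag.conv3x3(x, self.w1, self.b1), self.g1, self.be1))
        x = ag.relu(ag.instance_norm(ag.conv3x3(x, self.w2, self.b2), self.g2, self.be2))
        return x

    def parameters(self):
        return [self.w1, self.b1, self.g1, self.be1,
                self.w2, self.b2, self.g2, self.be2]


class UNet3D:
    """Encoder-decoder segmentation network producing per-voxel log-probabilities."""

    def __init__(self, config: NetConfig | None = None, seed: int = 0):
        self.config = config or NetConfig()
        self.seed = seed
        rng = np.random.default_rng(seed)
        f = self.config.filters
        self.encoder = []
        in_ch = self.config.in_channels
        for k in range(self.config.depth):
            self.encoder.append(_ConvBlock(rng, in_ch, f[k]))
            in_ch = f[k]
        self.up_w = []   # 1x1x1 conv after trilinear upsampling
        self.up_b = []
        self.decoder = []
        for k in range(self.config.depth - 2, -1, -1):
            self.up_w.append(ag.Tensor(
                rng.normal(0, np.sqrt(2.0 / f[k + 1]), size=(f[k], f[k + 1])
                           ).astype(np.float32), requires_grad=True))
            self.up_b.append(_zeros(f[k]))
            self.decoder.append(_ConvBlock(rng, 2 * f[k], f[k]))
        self.head_w = ag.Tensor(
            rng.normal(0, 0.01, size=(self.config.classes, f[0])).astype(np.float32),
            requires_grad=True)
        # prior-initialized output bias: start the softmax near realistic
        # class frequencies (background-dominant) so rare foreground classes
        # receive strong loss gradients from the first iteration
        priors = np.full(self.config.classes, 0.02, dtype=np.float32)
        priors[0] = 1.0 - 0.02 * (self.config.classes - 1)
        self.head_b = ag.Tensor(np.log(priors), requires_grad=True)

    # -- plumbing

    def parameters(self) -> list[ag.Tensor]:
        params: list[ag.Tensor] = []
        for blk in self.encoder + self.decoder:
            params.extend(blk.parameters())
        for w, b in zip(self.up_w, self.up_b):
            params.extend([w, b])
        params.extend([self.head_w, self.head_b])
        return params

    def pooling_plan(self, shape: Sequence[int]) -> list[tuple[int, int, int]]:
        """Per-level pooling factors for a given spatial input shape."""
        X, Y, Z = shape
        plan = []
        inplane = 2 ** (self.config.depth - 1)
        for axis, n in zip("xy", (X, Y)):
            if n % inplane:
                raise ValueError(
                    f"axis {axis} has extent {n}, not divisible by the cumulative "
                    f"in-plane pooling factor {inplane}")
        z = Z
        for _ in range(self.config.depth - 1):
            fz = 2 if (z >= self.config.min_z_pool and z % 2 == 0) else 1
            plan.append((2, 2, fz))
            z //= fz
        return plan

    def forward(self, x: np.ndarray) -> ag.Tensor:
        """Log-probabilities of shape ``(classes, X, Y, Z)`` for one sample."""
        if x.ndim == 3:
            x = x[None]
        plan = self.pooling_plan(x.shape[1:])
        t = ag.Tensor(np.ascontiguousarray(x, dtype=np.float32))
        skips = []
        for k, blk in enumerate(self.encoder):
            t = blk(t)
            if k < self.config.depth - 1:
                skips.append(t)
                t = ag.maxpool(t, plan[k])
        for i, blk in enumerate(self.decoder):
            level = self.config.depth - 2 - i
            t = ag.upsample_linear(t, plan[level])
            t = ag.conv1x1(t, self.up_w[i], self.up_b[i])
            t = ag.concat([skips[level], t], axis=0)
            t = blk(t)
        logits = ag.conv1x1(t, self.head_w, self.head_b)
        return ag.log_softmax(logits, axis=0)

    def predict_proba(self, x: np.ndarray) -> np.ndarray:
        return np.exp(self.forward(x).data)

    # -- checkpointing

    def save(self, path: str | Path) -> None:
        arrays = {f"p{i}": p.data for i, p in enumerate(self.parameters())}
        np.savez(path, config=json.dumps(asdict(self.config)),
                 seed=self.seed, **arrays)

    @classmethod
    def load(cls, path: str | Path) -> "UNet3D":
        with np.load(path, allow_pickle=False) as npz:
            cfg = NetConfig(**json.loads(str(npz["config"])))
            model = cls(cfg, seed=int(npz["seed"]))
            for i, p in enumerate(model.parameters()):
                p.data = npz[f"p{i}"].astype(np.float32)
        return model


def build_unet(config: NetConfig | None = None, seed: int = 0) -> UNet3D:
    return UNet3D(config, seed=seed)


# ---------------------------------------------------------------------------
# loss


def combined_loss(log_probs: ag.Tensor, target: np.ndarray) -> ag.Tensor:
    """Soft Dice over foreground classes present in the target + voxel-mean CE.

    ``log_probs`` is ``(classes, X, Y, Z)`` (per-voxel log-softmax) and
    ``target`` an integer class grid of the same spatial shape.
    """
    n_classes = log_probs.data.shape[0]
    if log_probs.data.shape[1:] != target.shape:
        raise ValueError(
            f"probability grid {log_probs.data.shape[1:]} does not match "
            f"target grid {target.shape}")
    target = np.asarray(target)
    onehot = np.zeros(log_probs.data.shape, dtype=np.float32)
    for c in range(n_classes):
        onehot[c] = target == c
    n_vox = float(target.size)
    ce = ag.mul(ag.tsum(ag.mul(log_probs, onehot)), -1.0 / n_vox)
    loss = ce
    probs = ag.exp(log_probs)
    for c in range(1, n_classes):
        t_c = onehot[c]
        if not t_c.any():
            continue
        p_c = ag.tsum(ag.mul(probs, _class_selector(n_classes, c)), axis=0)
        inter = ag.tsum(ag.mul(p_c, t_c))
        denom = ag.add(ag.tsum(p_c), float(t_c.sum() + DICE_EPS))
        dice = ag.div(ag.mul(inter, 2.0), denom)
        loss = ag.add(loss, ag.sub(1.0, dice))
    return loss


def _class_selector(n_classes: int, c: int) -> np.ndarray:
    sel = np.zeros((n_classes, 1, 1, 1), dtype=np.float32)
    sel[c] = 1.0
    return sel


# ---------------------------------------------------------------------------
# optimization


try:  # single fused pass over each parameter; numpy fallback keeps results close
    from numba import njit

    @njit(cache=True, fastmath=False)
    def _adam_kernel(p, g, m, v, lr, b1, b2, eps, bc1, bc2):  # pragma: no cover
        for i in range(p.size):
            m[i] = b1 * m[i] + (1.0 - b1) * g[i]
            v[i] = b2 * v[i] + (1.0 - b2) * g[i] * g[i]
            p[i] -= lr * (m[i] / bc1) / (np.sqrt(v[i] / bc2) + eps)
except ImportError:  # pragma: no cover
    def _adam_kernel(p, g, m, v, lr, b1, b2, eps, bc1, bc2):
        m *= b1
        m += (1.0 - b1) * g
        v *= b2
        v += (1.0 - b2) * g * g
        p -= lr * (m / bc1) / (np.sqrt(v / bc2) + eps)


class Adam:
    """Adam with bias correction; ``lr`` may be lowered between steps."""

    def __init__(self, params: Sequence[ag.Tensor], lr: float = 1e-3,
                 betas: tuple[float, float] = (0.9, 0.999), eps: float = 1e-8):
        self.params = list(params)
        self.lr = float(lr)
        self.b1, self.b2 = betas
        self.eps = eps
        self.t = 0
        self.m = [np.zeros_like(p.data) for p in self.params]
        self.v = [np.zeros_like(p.data) for p in self.params]

    def step(self) -> None:
        self.t += 1
        bc1 = 1.0 - self.b1 ** self.t
        bc2 = 1.0 - self.b2 ** self.t
        for p, m, v in zip(self.params, self.m, self.v):
            if p.grad is None:
                continue
            g = p.grad.ravel()
            if g.dtype != np.float32:
                g = g.astype(np.float32)
            _adam_kernel(p.data.ravel(), g, m.ravel(), v.ravel(),
                         np.float32(self.lr), np.float32(self.b1),
                         np.float32(self.b2), np.float32(self.eps),
                         np.float32(bc1), np.float32(bc2))

    def zero_grad(self) -> None:
        for p in self.params:
            p.grad = None


class PlateauHalving:
    """Halve the learning rate when the moving training-loss average plateaus.

    The moving average over the last ``window`` iterations is compared against
    its own value ``patience`` iterations earlier; if it has not improved by
    ``rel_tol`` (relative) over that span, the learning rate is divided by
    ``factor`` (never below ``min_lr``), and at least ``patience`` further
    iterations must pass before the next drop.  Comparing against the lagged
    average (rather than a running minimum) keeps single-sample loss noise —
    large at batch size one, where per-region losses differ widely — from
    triggering drops while the trend is still downward.
    """

    def __init__(self, initial_lr: float, *, window: int = 50, patience: int = 100,
                 rel_tol: float = 1e-3, factor: float = 2.0, min_lr: float = 1e-6):
        self.lr = float(initial_lr)
        self.window = window
        self.patience = patience
        self.rel_tol = rel_tol
        self.factor = factor
        self.min_lr = min_lr
        self._losses: list[float] = []
        self._ma_hist: list[float] = []
        self._last_drop = 0

    def update(self, loss: float) -> tuple[float, float]:
        """Record a loss; returns ``(moving_average, lr)`` after the update."""
        self._losses.append(float(loss))
        ma = float(np.mean(self._losses[-self.window:]))
        self._ma_hist.append(ma)
        t = len(self._ma_hist)
        # compare only once the lagged reference is itself a full-window mean;
        # partial-window averages early in training are single-sample noise
        if (t > self.window + self.patience
                and t - self._last_drop > self.patience
                and ma > self._ma_hist[t - 1 - self.patience] * (1.0 - self.rel_tol)
                and self.lr / self.factor >= self.min_lr):
            self.lr = self.lr / self.factor  # exact factor only, never clamped
            self._last_drop = t
        return ma, self.lr


# ---------------------------------------------------------------------------
# training and prediction


def train(model: UNet3D, dataset: Sequence[tuple[Volume, LabelMask]],
          train_config: TrainConfig | None = None,
          augment_spec: AugmentSpec | None = None):
    """Train on (volume, mask) pairs; returns ``(model, history)``.

    Volumes are expected on the network grid already (resampled and padded per
    the preprocessing spec).  Each iteration draws one sample, optionally
    corrupts it with one artifact family, z-scores the intensities, and takes
    one Adam step on the combined loss.  Fully reproducible given the seed.
    """
    cfg = train_config or TrainConfig()
    if len(dataset) == 0:
        raise ValueError("training requires a nonempty dataset")
    rng = np.random.default_rng(cfg.seed)
    opt = Adam(model.parameters(), lr=cfg.initial_lr)
    sched = PlateauHalving(cfg.initial_lr, window=cfg.plateau_window,
                           patience=cfg.plateau_patience,
                           rel_tol=cfg.plateau_rel_tol,
                           factor=cfg.lr_decay_factor, min_lr=cfg.min_lr)
    rows = []
    for it in range(cfg.max_iterations):
        idx = int(rng.integers(0, len(dataset)))
        vol, mask = dataset[idx]
        x = vol.data
        if augment_spec is not None and augment_spec.families:
            if rng.random() >= augment_spec.none_probability:
                family = augment_spec.families[int(rng.integers(0, len(augment_spec.families)))]
                params = dict(augment_spec.params.get(family, {}))
                if family == "motion":
                    params.setdefault("spacing", vol.spacing)
                x = apply_artifact(x, family, seed=int(rng.integers(0, 2 ** 31)),
                                   **params)
        sd = x.std()
        x = (x - x.mean()) / sd if sd > 0 else np.zeros_like(x)
        opt.zero_grad()
        log_probs = model.forward(x.astype(np.float32))
        loss = combined_loss(log_probs, mask.data)
        ag.backward(loss)
        opt.lr = sched.lr
        opt.step()
        ma, lr = sched.update(loss.item())
        rows.append((it, loss.item(), ma, lr))
    history = pd.DataFrame(rows, columns=["iteration", "loss", "moving_avg", "lr"])
    return model, history


def predict_mask(model: UNet3D, volume: Volume,
                 spec: PreprocessSpec | None = None) -> LabelMask:
    """Segment a native-grid volume: preprocess, argmax-decode, map back.

    Ties in the per-voxel argmax resolve to the lower class code.  The
    predicted mask is un-padded and nearest-neighbour resampled back onto the
    input's native grid.
    """
    spec = spec or PreprocessSpec()
    work = resample(volume, spec.target_spacing, mode="intensity")
    if spec.normalize:
        work = normalize_intensity(work)
    padded, record = crop_or_pad(work, spec.pad_multiple)
    probs = model.predict_proba(padded.data)
    labels = probs.argmax(axis=0).astype(np.uint8)  # first max -> lowest class
    pred = LabelMask(data=labels, spacing=padded.spacing, region=volume.region)
    pred = restore_native(pred, record)
    native = _resample_labels_to_shape(pred, volume.shape, volume.spacing)
    return LabelMask(data=native, spacing=volume.spacing, region=volume.region)


def _resample_labels_to_shape(mask: LabelMask, out_shape: tuple[int, int, int],
                              out_spacing: tuple[float, float, float]) -> np.ndarray:
    if mask.shape == out_shape and all(
            abs(a - b) < 1e-9 for a, b in zip(mask.spacing, out_spacing)):
        return mask.data.copy()
    coords = np.meshgrid(
        *[(np.arange(m) + 0.5) * (t / s) - 0.5
          for m, s, t in zip(out_shape, mask.spacing, out_spacing)],
        indexing="ij")
    return ndimage.map_coordinates(mask.data, np.stack(coords), order=0,
                                   mode="nearest").astype(np.uint8)


# ---------------------------------------------------------------------------
# estimator facade


class UNet3DSegmenter(BaseEstimator):
    """Scikit-learn style facade over the 3D U-net segmentation pipeline.

    ``fit`` takes lists of :class:`Volume` and :class:`LabelMask` (native
    grids), handles preprocessing, and trains the network; ``predict`` returns
    native-grid masks.  Fitted attributes: ``model_``, ``history_``,
    ``preprocess_spec_``.
    """

    def __init__(self, depth: int = 6, base_filters: int = 16, classes: int = 4,
                 min_z_pool: int = 8,
                 target_spacing: tuple[float, float, float] = (0.6, 0.6, 6.5),
                 pad_multiple: tuple[int, int, int] = (32, 32, 1),
                 initial_lr: float = 1e-3, max_iterations: int = 300,
                 plateau_window: int = 50, plateau_patience: int = 100,
                 plateau_rel_tol: float = 1e-3, min_lr: float = 1e-6,
                 augment: bool = True, none_probability: float = 0.5,
                 random_state: int = 0):
        self.depth = depth
        self.base_filters = base_filters
        self.classes = classes
        self.min_z_pool = min_z_pool
        self.target_spacing = target_spacing
        self.pad_multiple = pad_multiple
        self.initial_lr = initial_lr
        self.max_iterations = max_iterations
        self.plateau_window = plateau_window
        self.plateau_patience = plateau_patience
        self.plateau_rel_tol = plateau_rel_tol
        self.min_lr = min_lr
        self.augment = augment
        self.none_probability = none_probability
        self.random_state = random_state

    def _preprocess_pair(self, vol: Volume, mask: LabelMask):
        spec = self.preprocess_spec_
        v = resample(vol, spec.target_spacing, mode="intensity")
        m = resample(mask, spec.target_spacing, mode="label")
        v, _ = crop_or_pad(v, spec.pad_multiple)
        m, _ = crop_or_pad(m, spec.pad_multiple)
        return v, m

    def fit(self, X: Sequence[Volume], y: Sequence[LabelMask]) -> "UNet3DSegmenter":
        if len(X) != len(y) or len(X) == 0:
            raise ValueError("X and y must be nonempty and the same length")
        self.preprocess_spec_ = PreprocessSpec(
            target_spacing=self.target_spacing, normalize=True,
            pad_multiple=self.pad_multiple)
        dataset = [self._preprocess_pair(v, m) for v, m in zip(X, y)]
        cfg = NetConfig(depth=self.depth, base_filters=self.base_filters,
                        classes=self.classes, min_z_pool=self.min_z_pool)
        tcfg = TrainConfig(initial_lr=self.initial_lr,
                           max_iterations=self.max_iterations,
                           plateau_window=self.plateau_window,
                           plateau_patience=self.plateau_patience,
                           plateau_rel_tol=self.plateau_rel_tol,
                           min_lr=self.min_lr, seed=self.random_state)
        aug = AugmentSpec(none_probability=self.none_probability) if self.augment else None
        model = build_unet(cfg, seed=self.random_state)
        self.model_, self.history_ = train(model, dataset, tcfg, aug)
        return self

    def predict(self, X: Sequence[Volume]) -> list[LabelMask]:
        if not hasattr(self, "model_"):
            raise RuntimeError("estimator is not fitted")
        return [predict_mask(self.model_, v, self.preprocess_spec_) for v in X]

    def score(self, X: Sequence[Volume], y: Sequence[LabelMask]) -> float:
        """Mean foreground Dice over samples and classes present in ``y``."""
        from .agreement import dice_coefficient

        preds = self.predict(X)
        scores = []
        for pred, truth in zip(preds, y):
            for c in range(1, self.classes):
                if (truth.data == c).any():
                    scores.append(dice_coefficient(pred.data == c, truth.data == c))
        return float(np.mean(scores)) if scores else float("nan")
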