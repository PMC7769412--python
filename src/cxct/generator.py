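"""Correction network G and its training loop.

G maps a scatter-corrupted CBCT-like slice to a planning-CT-like slice.
The stated design — a five-layer CNN of 3x3 kernels, stride-2
downsampling, ReLU activations and an adaptive channel width (512 for
inputs of width >= 128, else 1024) — underdetermines a shape-preserving
network, since a pure stride-2 stack cannot return the input resolution.
We therefore implement a symmetric encoder-decoder: the encoder is the
described stack of stride-2 3x3 convolutions (spatial size halved per
stage until it reaches ``min_spatial``; any remaining layers become
stride-1 bottleneck convolutions), and the decoder mirrors it with
nearest-neighbour upsampling followed by 3x3 convolutions.  By default G
predicts a *residual* added to its input, which keeps the body contour of
the output anchored to the input image.

Training follows the published recipe: Adam, learning rate 1e-4, ReLU,
batch size 1, the combined contextual objective (or a comparison loss),
over a configurable number of epochs (300 at full scale).
"""

from __future__ import annotations

import csv
import json
import math
from dataclasses import dataclass, field, asdict
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np

from ._autodiff import Tensor, as_tensor, conv2d, upsample2
from .cx_core import (
    CXParams,
    LossWeights,
    _sample_indices,
    _take_rows,
    cx_loss,
    l2_loss,
    style_layer_seed,
)
from .features import DEFAULT_HU_WINDOW, ExtractorConfig, FeatureExtractor

__all__ = [
    "GeneratorConfig",
    "TrainConfig",
    "LossHistory",
    "CorrectionNet",
    "build_generator",
    "train",
    "correct_image",
    "load_model",
]


@dataclass(frozen=True)
class GeneratorConfig:
    """Architecture of the correction network.

    ``base_width=None`` applies the adaptive rule (512 channels when the
    input side is >= 128 pixels, else 1024); smaller explicit widths are
    the practical choice for desk-scale experiments.
    """

    n_layers: int = 5
    base_width: Optional[int] = None
    min_spatial: int = 4
    residual: bool = True
    seed: int = 0

    def __post_init__(self):
        if self.n_layers < 2:
            raise ValueError("n_layers must be >= 2")
        if self.min_spatial < 1:
            raise ValueError("min_spatial must be >= 1")


@dataclass
class TrainConfig:
    learning_rate: float = 1e-4
    epochs: int = 300
    batch_size: int = 1
    seed: int = 0
    loss: str = "cx"  # cx | l2 | perceptual | cx_l2
    loss_weights: LossWeights = field(default_factory=LossWeights)
    cx_params: CXParams = field(default_factory=CXParams)
    mode: str = "feedforward"  # feedforward | single_image
    perceptual_layer: str = "conv4_2"
    l2_term_weight: float = 1.0  # for the cx_l2 variant, on windowed images
    # keep the checkpoint with the lowest validation MAE (early stopping);
    # requires a validation set and has no effect without one
    select_best_val: bool = True

    def __post_init__(self):
        if self.learning_rate <= 0:
            raise ValueError("learning_rate must be > 0")
        if self.epochs < 1:
            raise ValueError("epochs must be >= 1")
        if self.loss not in ("cx", "l2", "perceptual", "cx_l2"):
            raise ValueError(f"unknown loss {self.loss!r}")
        if self.mode not in ("feedforward", "single_image"):
            raise ValueError(f"unknown mode {self.mode!r}")


@dataclass
class LossHistory:
    """Per-epoch mean training loss (and optional validation MAE in HU)."""

    losses: List[float] = field(default_factory=list)
    content: List[float] = field(default_factory=list)
    style: List[float] = field(default_factory=list)
    val_mae: List[float] = field(default_factory=list)
    best_epoch: Optional[int] = None  # 1-based epoch of the selected checkpoint
    # weights at the last epoch, kept when checkpoint selection rewinds the
    # model, so the end of the optimisation trajectory stays inspectable
    final_weights: Optional[List[np.ndarray]] = None

    def write_csv(self, path) -> None:
        with open(path, "w", newline="") as f:
            w = csv.writer(f)
            header = ["epoch", "loss", "content", "style"]
            if self.val_mae:
                header.append("val_mae")
            w.writerow(header)
            for i, loss in enumerate(self.losses):
                row = [i + 1, loss,
                       self.content[i] if self.content else "",
                       self.style[i] if self.style else ""]
                if self.val_mae:
                    row.append(self.val_mae[i])
                w.writerow(row)


class CorrectionNet:
    """Symmetric encoder-decoder CNN operating on windowed [0, 1] images."""

    def __init__(self, config: GeneratorConfig, side: int,
                 hu_window: Tuple[float, float] = DEFAULT_HU_WINDOW):
        if side < 16 or side & (side - 1):
            raise ValueError(
                f"input side must be a power of two >= 16, got {side}; "
                "pad the image to the next power of two first"
            )
        self.config = config
        self.side = side
        self.hu_window = hu_window
        width = config.base_width
        if width is None:
            width = 512 if side >= 128 else 1024
        self.width = width
        self.n_down = min(config.n_layers, int(math.log2(side // config.min_spatial)))
        self.n_extra = config.n_layers - self.n_down

        rng = np.random.default_rng(config.seed)
        self.params: List[Tensor] = []
        self._enc, self._mid, self._dec = [], [], []
        c_in = 1
        for _ in range(self.n_down):
            self._enc.append(self._conv_init(rng, c_in, width))
            c_in = width
        for _ in range(self.n_extra):
            self._mid.append(self._conv_init(rng, c_in, width))
            c_in = width
        for _ in range(self.n_down):
            self._dec.append(self._conv_init(rng, c_in, width))
            c_in = width
        # final projection: near-zero init so training starts at (approximately)
        # the identity mapping in residual mode
        self._out = self._conv_init(rng, c_in, 1, std=1e-3)

    def _conv_init(self, rng, c_in, c_out, std=None):
        if std is None:
            std = math.sqrt(2.0 / (c_in * 9))
        w = Tensor(rng.normal(0, std, (c_out, c_in, 3, 3)).astype(np.float32),
                   requires_grad=True)
        b = Tensor(np.zeros(c_out, dtype=np.float32), requires_grad=True)
        self.params.extend([w, b])
        return (w, b)

    def forward(self, x: Tensor) -> Tensor:
        """x: (1, H, W) windowed image tensor -> (1, H, W) output."""
        h = x
        for w, b in self._enc:
            h = conv2d(h, w, b, stride=2, pad=1).relu()
        for w, b in self._mid:
            h = conv2d(h, w, b, stride=1, pad=1).relu()
        for w, b in self._dec:
            h = conv2d(upsample2(h), w, b, stride=1, pad=1).relu()
        w, b = self._out
        delta = conv2d(h, w, b, stride=1, pad=1)
        return x + delta if self.config.residual else delta

    # -- persistence -------------------------------------------------------
    def save(self, path) -> None:
        meta = {
            "format": "cxct-checkpoint-v1",
            "config": asdict(self.config),
            "side": self.side,
            "hu_window": list(self.hu_window),
        }
        arrays = {f"param_{i}": p.data for i, p in enumerate(self.params)}
        np.savez(path, meta=json.dumps(meta), **arrays)


def load_model(path) -> CorrectionNet:
    with np.load(path, allow_pickle=False) as npz:
        meta = json.loads(str(npz["meta"]))
        if meta.get("format") != "cxct-checkpoint-v1":
            raise ValueError(f"unrecognised checkpoint format in {path}")
        cfg = GeneratorConfig(**meta["config"])
        model = CorrectionNet(cfg, meta["side"], tuple(meta["hu_window"]))
        for i, p in enumerate(model.params):
            p.data = npz[f"param_{i}"].astype(np.float32)
    return model


def build_generator(config: GeneratorConfig, input_shape: Tuple[int, int],
                    hu_window: Tuple[float, float] = DEFAULT_HU_WINDOW) -> CorrectionNet:
    """Construct the correction network for square power-of-two inputs."""
    h, w = input_shape
    if h != w:
        raise ValueError(f"input must be square, got {h}x{w}")
    return CorrectionNet(config, h, hu_window)


class _Adam:
    def __init__(self, params: Sequence[Tensor], lr: float,
                 beta1=0.9, beta2=0.999, eps=1e-8):
        self.params = list(params)
        self.lr, self.b1, self.b2, self.eps = lr, beta1, beta2, eps
        self.m = [np.zeros_like(p.data) for p in self.params]
        self.v = [np.zeros_like(p.data) for p in self.params]
        self.t = 0

    def step(self) -> None:
        self.t += 1
        for i, p in enumerate(self.params):
            if p.grad is None:
                continue
            g = p.grad
            self.m[i] = self.b1 * self.m[i] + (1 - self.b1) * g
            self.v[i] = self.b2 * self.v[i] + (1 - self.b2) * g * g
            mhat = self.m[i] / (1 - self.b1**self.t)
            vhat = self.v[i] / (1 - self.b2**self.t)
            p.data = p.data - self.lr * mhat / (np.sqrt(vhat) + self.eps)
            p.grad = None


def _unit(img: np.ndarray, window) -> np.ndarray:
    lo, hi = window
    return ((np.asarray(img, np.float64) - lo) / (hi - lo)).astype(np.float32)


def _hu(unit: np.ndarray, window) -> np.ndarray:
    lo, hi = window
    return np.asarray(unit, np.float64) * (hi - lo) + lo


class _CXObjective:
    """Combined CX objective with per-sample precomputed target features.

    Source/label features never change during training, so they are
    extracted (and style-subsampled, with one seeded draw per layer per
    run) once up front.
    """

    def __init__(self, extractor: FeatureExtractor, weights: LossWeights,
                 params: CXParams, add_l2: bool = False, l2_weight: float = 1.0):
        self.ext = extractor
        self.w = weights
        self.p = params
        self.add_l2 = add_l2
        self.l2_weight = l2_weight
        self.layers = list(dict.fromkeys([weights.content_layer, *weights.style_layers]))
        self.style_idx: Dict[str, Optional[np.ndarray]] = {}

    def prepare(self, sample_units: Sequence[Tuple[np.ndarray, np.ndarray]]):
        """sample_units: list of (source_unit, label_unit) windowed images."""
        targets = []
        for src_u, lab_u in sample_units:
            src_sets = self.ext.feature_sets(as_tensor(src_u[None]), [self.w.content_layer])
            lab_sets = self.ext.feature_sets(as_tensor(lab_u[None]), list(self.w.style_layers))
            content_t = np.ascontiguousarray(src_sets[self.w.content_layer].data)
            style_t = {}
            for layer in self.w.style_layers:
                t = np.ascontiguousarray(lab_sets[layer].data)
                if layer not in self.style_idx:
                    n_avail = t.shape[0]
                    if self.w.style_sample_n < n_avail:
                        self.style_idx[layer] = _sample_indices(
                            n_avail, self.w.style_sample_n,
                            style_layer_seed(self.w.sample_seed, layer))
                    else:
                        self.style_idx[layer] = None
                idx = self.style_idx[layer]
                style_t[layer] = t if idx is None else t[idx]
            targets.append((content_t, style_t, lab_u))
        return targets

    def loss(self, out_unit: Tensor, target) -> Tuple[Tensor, float, float]:
        content_t, style_t, lab_u = target
        gen_sets = self.ext.feature_sets(out_unit, self.layers)
        content = cx_loss(gen_sets[self.w.content_layer], content_t, self.p)
        style = None
        for layer in self.w.style_layers:
            g = gen_sets[layer]
            idx = self.style_idx.get(layer)
            if idx is not None:
                g = _take_rows(g, idx)
            term = cx_loss(g, style_t[layer], self.p)
            style = term if style is None else style + term
        total = content + style * self.w.lambda_weight
        if self.add_l2:
            total = total + l2_loss(out_unit, lab_u[None]) * self.l2_weight
        return total, float(content.data), float(style.data)


def _check_finite(value: float, term: str):
    if not math.isfinite(value):
        raise RuntimeError(f"non-finite training loss in term '{term}'")


def train(
    dataset: Sequence,
    gen_config: GeneratorConfig = GeneratorConfig(),
    train_config: TrainConfig = TrainConfig(),
    extractor_config: ExtractorConfig = ExtractorConfig(),
    val_set: Optional[Sequence] = None,
    checkpoint_path=None,
    log_csv=None,
) -> Tuple[CorrectionNet, LossHistory]:
    """Train the correction network on (input, label) slice pairs.

    ``dataset`` is a sequence of objects with ``input_image`` and
    ``label_image`` attributes in HU (the phantom simulator's
    ``PairedSlice`` qualifies).  Returns the trained model and the
    per-epoch loss history.  When ``val_set`` is given, per-epoch
    validation MAE against its ``clean_truth`` is recorded and (under
    ``select_best_val``, the default) the returned model carries the
    weights of the epoch with the lowest validation MAE — ordinary early
    stopping, which matters here because every loss is optimised against
    *misaligned* labels and prolonged optimisation eventually drifts away
    from pixel fidelity to the underlying anatomy.
    """
    if len(dataset) == 0:
        raise ValueError("dataset is empty")
    shapes = {s.input_image.shape for s in dataset}
    if len(shapes) != 1:
        raise ValueError("all training slices must share one shape")
    if train_config.mode == "single_image" and len(dataset) != 1:
        raise ValueError("single_image mode optimises exactly one pair")

    window = extractor_config.hu_window
    side = dataset[0].input_image.shape[0]
    model = build_generator(gen_config, dataset[0].input_image.shape, window)

    units = [(_unit(s.input_image, window), _unit(s.label_image, window)) for s in dataset]

    needs_ext = train_config.loss in ("cx", "cx_l2", "perceptual")
    extractor = FeatureExtractor(extractor_config) if needs_ext else None

    objective = None
    targets: List = []
    if train_config.loss in ("cx", "cx_l2"):
        objective = _CXObjective(
            extractor, train_config.loss_weights, train_config.cx_params,
            add_l2=(train_config.loss == "cx_l2"),
            l2_weight=train_config.l2_term_weight,
        )
        targets = objective.prepare(units)
    elif train_config.loss == "perceptual":
        layer = train_config.perceptual_layer
        for _, lab_u in units:
            fmap = extractor.feature_maps(as_tensor(lab_u[None]), [layer])[layer]
            targets.append(np.ascontiguousarray(fmap.data))
    else:
        targets = [lab_u for _, lab_u in units]

    if train_config.mode == "single_image":
        return _train_single_image(dataset[0], units[0], targets[0], objective,
                                   extractor, train_config, window, side)

    opt = _Adam(model.params, train_config.learning_rate)
    rng = np.random.default_rng(train_config.seed)
    history = LossHistory()
    best_snapshot = None  # (val_mae, epoch, weights) under select_best_val

    for _epoch in range(train_config.epochs):
        order = rng.permutation(len(dataset))
        ep_loss, ep_content, ep_style = [], [], []
        for i in order:
            src_u, _ = units[i]
            out = model.forward(as_tensor(src_u[None]))
            if train_config.loss in ("cx", "cx_l2"):
                loss, c_val, s_val = objective.loss(out, targets[i])
                _check_finite(c_val, "content CX")
                _check_finite(s_val, "style CX")
                ep_content.append(c_val)
                ep_style.append(s_val)
            elif train_config.loss == "perceptual":
                fmap = extractor.feature_maps(out, [train_config.perceptual_layer])
                loss = (fmap[train_config.perceptual_layer] - targets[i]).abs().sum()
            else:
                loss = l2_loss(out, targets[i][None])
            _check_finite(float(loss.data), train_config.loss)
            loss.backward(np.ones((), dtype=np.float32))
            opt.step()
            ep_loss.append(float(loss.data))
        history.losses.append(float(np.mean(ep_loss)))
        if ep_content:
            history.content.append(float(np.mean(ep_content)))
            history.style.append(float(np.mean(ep_style)))
        if val_set is not None:
            maes = [
                float(np.abs(correct_image(model, s.input_image) - s.clean_truth).mean())
                for s in val_set
            ]
            history.val_mae.append(float(np.mean(maes)))
            if train_config.select_best_val and (
                    best_snapshot is None or history.val_mae[-1] < best_snapshot[0]):
                best_snapshot = (history.val_mae[-1], _epoch + 1,
                                 [p.data.copy() for p in model.params])

    if best_snapshot is not None:
        _, history.best_epoch, weights = best_snapshot
        history.final_weights = [p.data.copy() for p in model.params]
        for p, w in zip(model.params, weights):
            p.data = w
    if checkpoint_path is not None:
        model.save(checkpoint_path)
    if log_csv is not None:
        history.write_csv(log_csv)
    return model, history


class SingleImageResult:
    """Result of single-image iterative optimisation: a fixed corrected slice."""

    def __init__(self, image_hu: np.ndarray, side: int, hu_window):
        self.image_hu = image_hu
        self.side = side
        self.hu_window = hu_window

    def forward(self, x):  # mirrors CorrectionNet's interface for correct_image
        return as_tensor(_unit(self.image_hu, self.hu_window)[None])


def _train_single_image(pair, unit_pair, target, objective, extractor,
                        train_config, window, side):
    """Iterative-optimisation reading: optimise the output pixels directly."""
    src_u, _ = unit_pair
    pixels = Tensor(src_u.copy()[None], requires_grad=True)
    opt = _Adam([pixels], train_config.learning_rate)
    history = LossHistory()
    for _epoch in range(train_config.epochs):
        out = pixels * 1.0  # re-enter the graph each step
        if objective is not None:
            loss, c_val, s_val = objective.loss(out, target)
            history.content.append(c_val)
            history.style.append(s_val)
        elif train_config.loss == "perceptual":
            fmap = extractor.feature_maps(out, [train_config.perceptual_layer])
            loss = (fmap[train_config.perceptual_layer] - target).abs().sum()
        else:
            loss = l2_loss(out, target[None])
        _check_finite(float(loss.data), train_config.loss)
        loss.backward(np.ones((), dtype=np.float32))
        opt.step()
        history.losses.append(float(loss.data))
    corrected = np.clip(_hu(pixels.data[0], window), *window)
    return SingleImageResult(corrected, side, window), history


def correct_image(model, cbct: np.ndarray, clamp: bool = True) -> np.ndarray:
    """Run inference: corrected slice in HU, same shape as the input.

    The output is clamped to the model's HU window (inference only).
    """
    cbct = np.asarray(cbct, dtype=np.float64)
    if cbct.shape != (model.side, model.side):
        raise ValueError(
            f"input shape {cbct.shape} does not match the trained size "
            f"({model.side}x{model.side})"
        )
    out = model.forward(as_tensor(_unit(cbct, model.hu_window)[None]))
    hu = _hu(np.asarray(out.data[0], np.float64), model.hu_window)
    if clamp:
        hu = np.clip(hu, *model.hu_window)
    return hu
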