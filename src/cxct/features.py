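"""Deep feature extraction with a VGG-19-topology convolutional network.

The contextual and perceptual losses compare images in the feature space of
a fixed convolutional network with the VGG-19 layout: five blocks of
(2, 2, 4, 4, 4) 3x3 convolutions with 64/128/256/512/512 channels, ReLU
after every convolution, and 2x2 max pooling between blocks.  Layers are
addressed as ``conv{block}_{index}`` (e.g. ``conv4_2``).  Only the
convolutional part is ever materialised; the fully connected head plays no
role in any loss.

Two weight backends are provided:

``surrogate``
    Fixed, seeded, He-initialised random weights.  Random convolutional
    features still induce a meaningful feature geometry for the CX loss,
    and the backend is fully self-contained and deterministic, so the
    whole package trains and tests without any weight file.

``pretrained``
    Loads VGG-19 convolution weights from a local ``.npz`` file with
    arrays ``conv{b}_{i}_w`` of shape (Cout, Cin, 3, 3) and
    ``conv{b}_{i}_b`` of shape (Cout,).  No downloading is performed.

Images arrive as 2-D HU slices; they are affinely windowed into [0, 1]
(default window [-1000, 1500] HU) and replicated to three channels before
entering the network.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Dict, Iterable, List, Optional, Tuple

import numpy as np

from ._autodiff import Tensor, as_tensor, conv2d, maxpool2
from .cx_core import FeatureSet

__all__ = [
    "VGG19_BLOCKS",
    "ExtractorConfig",
    "FeatureExtractor",
    "parse_layer_name",
    "replicate_channels",
    "extract_features",
    "hu_to_unit",
    "unit_to_hu",
]

#: convolutions per block and output channels per block (VGG-19)
VGG19_BLOCKS: Tuple[Tuple[int, int], ...] = ((2, 64), (2, 128), (4, 256), (4, 512), (4, 512))

DEFAULT_HU_WINDOW: Tuple[float, float] = (-1000.0, 1500.0)


def parse_layer_name(name: str) -> Tuple[int, int]:
    """Validate ``conv{block}_{index}`` against the VGG-19 topology."""
    try:
        head, idx = name.split("_")
        if not head.startswith("conv"):
            raise ValueError
        block, index = int(head[4:]), int(idx)
    except Exception:
        raise ValueError(f"malformed layer name {name!r}; expected e.g. 'conv4_2'") from None
    if not 1 <= block <= len(VGG19_BLOCKS):
        raise ValueError(f"layer {name!r}: block {block} outside VGG-19 topology")
    n_convs, _ = VGG19_BLOCKS[block - 1]
    if not 1 <= index <= n_convs:
        raise ValueError(
            f"layer {name!r}: block {block} has {n_convs} convolutions, index {index} invalid"
        )
    return block, index


def hu_to_unit(image: np.ndarray, window: Tuple[float, float] = DEFAULT_HU_WINDOW) -> np.ndarray:
    """Affinely map HU values from ``window`` to [0, 1] (no clipping)."""
    lo, hi = window
    if hi <= lo:
        raise ValueError("window must satisfy hi > lo")
    return (np.asarray(image, dtype=np.float64) - lo) / (hi - lo)


def unit_to_hu(image: np.ndarray, window: Tuple[float, float] = DEFAULT_HU_WINDOW) -> np.ndarray:
    lo, hi = window
    return np.asarray(image, dtype=np.float64) * (hi - lo) + lo


def replicate_channels(
    image: np.ndarray, window: Tuple[float, float] = DEFAULT_HU_WINDOW
) -> np.ndarray:
    """Window a single-channel HU slice and replicate it to three channels."""
    image = np.asarray(image)
    if image.ndim != 2:
        raise ValueError(f"expected a single-channel 2-D image, got shape {image.shape}")
    unit = hu_to_unit(image, window)
    return np.broadcast_to(unit, (3, *unit.shape)).copy()


@dataclass(frozen=True)
class ExtractorConfig:
    """Extractor backend selection and input normalisation.

    ``lowpass_mix`` shapes the surrogate's random filters: each kernel is a
    convex mix of a random local-average (low-pass) component and white
    noise.  Pure white-noise kernels yield noise-dominated deep features
    whose matching optima are poorly aligned with pixel fidelity; the
    low-pass component gives features the local-intensity content that
    trained convolutional filters possess.
    """

    backend: str = "surrogate"
    seed: int = 0
    weights_path: Optional[str] = None
    hu_window: Tuple[float, float] = DEFAULT_HU_WINDOW
    dtype: str = "float32"
    lowpass_mix: float = 0.5

    def __post_init__(self):
        if self.backend not in ("surrogate", "pretrained"):
            raise ValueError(f"unknown backend {self.backend!r}")
        if self.backend == "pretrained" and not self.weights_path:
            raise ValueError("pretrained backend requires weights_path")
        if not 0.0 <= self.lowpass_mix <= 1.0:
            raise ValueError("lowpass_mix must lie in [0, 1]")


class FeatureExtractor:
    """Frozen VGG-19-topology network exposing per-layer feature maps.

    Weights are constants; gradients flow through the network to the input
    image, which is what training the correction network requires.
    """

    def __init__(self, config: ExtractorConfig = ExtractorConfig()):
        self.config = config
        self._weights: Dict[str, Tuple[np.ndarray, np.ndarray]] = {}
        if config.backend == "pretrained":
            self._load_pretrained(config.weights_path)

    # -- weights -----------------------------------------------------------
    def _layer_io(self, block: int, index: int) -> Tuple[int, int]:
        c_out = VGG19_BLOCKS[block - 1][1]
        if index > 1:
            c_in = c_out
        elif block == 1:
            c_in = 3
        else:
            c_in = VGG19_BLOCKS[block - 2][1]
        return c_in, c_out

    def _get_weights(self, name: str) -> Tuple[np.ndarray, np.ndarray]:
        if name not in self._weights:
            if self.config.backend == "pretrained":
                raise KeyError(f"pretrained weights file lacks layer {name}")
            block, index = parse_layer_name(name)
            c_in, c_out = self._layer_io(block, index)
            rng = np.random.default_rng([self.config.seed, block, index])
            noise = rng.normal(size=(c_out, c_in, 3, 3))
            lowpass = rng.normal(size=(c_out, c_in, 1, 1)) * np.full((3, 3), 1.0 / 3.0)
            mix = self.config.lowpass_mix
            w = mix * lowpass + (1.0 - mix) * noise
            w *= np.sqrt(2.0 / (c_in * 9)) / w.std()  # He-scale overall gain
            b = np.zeros(c_out, dtype=self.config.dtype)
            self._weights[name] = (w.astype(self.config.dtype), b)
        return self._weights[name]

    def _load_pretrained(self, path: str) -> None:
        with np.load(path) as npz:
            for block, (n_convs, _) in enumerate(VGG19_BLOCKS, start=1):
                for index in range(1, n_convs + 1):
                    name = f"conv{block}_{index}"
                    wk, bk = f"{name}_w", f"{name}_b"
                    if wk not in npz:
                        continue
                    w = npz[wk].astype(self.config.dtype)
                    b = npz[bk].astype(self.config.dtype)
                    c_in, c_out = self._layer_io(block, index)
                    if w.shape != (c_out, c_in, 3, 3):
                        raise ValueError(
                            f"{name}: weight shape {w.shape} != {(c_out, c_in, 3, 3)}"
                        )
                    self._weights[name] = (w, b)

    # -- forward -----------------------------------------------------------
    def _check_input(self, h: int, w: int, deepest_block: int) -> None:
        factor = 2 ** (deepest_block - 1)
        if h % factor or w % factor or h < factor or w < factor:
            raise ValueError(
                f"input {h}x{w} too small or not divisible by {factor} for "
                f"block {deepest_block} features (one 2x pooling per block boundary)"
            )

    def feature_maps(self, x, layers: Iterable[str]) -> Dict[str, Tensor]:
        """Run the network and return ``layer -> (C, H, W)`` tensors.

        ``x`` is a windowed [0, 1] image tensor/array of shape (1, H, W) or
        (3, H, W); a single channel is broadcast to three.
        """
        layers = list(layers)
        parsed = {name: parse_layer_name(name) for name in layers}
        deepest = max(b for b, _ in parsed.values())
        xt = as_tensor(x)
        if xt.data.ndim != 3 or xt.data.shape[0] not in (1, 3):
            raise ValueError(f"expected (1|3, H, W) input, got shape {xt.data.shape}")
        self._check_input(xt.data.shape[1], xt.data.shape[2], deepest)
        if xt.data.shape[0] == 1:
            xt = xt * np.ones((3, 1, 1), dtype=xt.data.dtype)
        dtype = np.dtype(self.config.dtype)
        if xt.data.dtype != dtype and not xt.requires_grad:
            xt = as_tensor(xt.data.astype(dtype))

        out: Dict[str, Tensor] = {}
        cur = xt
        for block in range(1, deepest + 1):
            if block > 1:
                cur = maxpool2(cur)
            n_convs = VGG19_BLOCKS[block - 1][0]
            remaining = [i for (b, i) in parsed.values() if b == block]
            last_needed = max(remaining) if block == deepest else n_convs
            for index in range(1, last_needed + 1):
                name = f"conv{block}_{index}"
                w, b = self._get_weights(name)
                cur = conv2d(cur, as_tensor(w), as_tensor(b), stride=1, pad=1).relu()
                if name in parsed:
                    out[name] = cur
        return out

    def hu_feature_maps(self, image, layers: Iterable[str]) -> Dict[str, Tensor]:
        """Feature maps of a 2-D HU slice (array or tensor), windowing it first."""
        t = as_tensor(image)
        if t.data.ndim != 2:
            raise ValueError(f"expected a 2-D HU slice, got shape {t.data.shape}")
        lo, hi = self.config.hu_window
        unit = (t - lo) * (1.0 / (hi - lo))
        h, w = t.data.shape
        return self.feature_maps(unit.reshape(1, h, w), layers)

    def hu_feature_sets(self, image, layers: Iterable[str]) -> Dict[str, Tensor]:
        """Flattened (N, D) feature sets of a 2-D HU slice."""
        maps = self.hu_feature_maps(image, layers)
        return {name: f.reshape(f.data.shape[0], -1).T for name, f in maps.items()}

    def feature_sets(self, x, layers: Iterable[str]) -> Dict[str, Tensor]:
        """Feature maps flattened to ``layer -> (N, D)`` tensors.

        Every spatial position of a layer's activation map becomes one
        feature vector of dimension equal to the channel count.
        """
        maps = self.feature_maps(x, layers)
        sets: Dict[str, Tensor] = {}
        for name, fmap in maps.items():
            c, h, w = fmap.data.shape
            sets[name] = fmap.reshape(c, h * w).T
        return sets


def extract_features(
    image: np.ndarray,
    layers: List[str],
    config: ExtractorConfig = ExtractorConfig(),
    extractor: Optional[FeatureExtractor] = None,
) -> Dict[str, FeatureSet]:
    """Extract per-layer feature sets from a 2-D HU slice.

    Returns ``layer -> FeatureSet`` with N = spatial size of the layer's
    activation map.  Deterministic given (backend, seed, input).
    """
    image = np.asarray(image)
    if image.ndim != 2 or image.size == 0:
        raise ValueError(f"expected a non-empty 2-D HU slice, got shape {image.shape}")
    ext = extractor if extractor is not None else FeatureExtractor(config)
    x = replicate_channels(image, ext.config.hu_window).astype(ext.config.dtype)
    sets = ext.feature_sets(as_tensor(x), layers)
    return {
        name: FeatureSet(np.asarray(t.data, dtype=np.float64), layer_tag=name)
        for name, t in sets.items()
    }
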