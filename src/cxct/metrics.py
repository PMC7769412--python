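"""Image-quality evaluation in Hounsfield units: MAE, PSNR, SSIM, std, ROI means.

All metrics operate on raw HU values (no rescaling), are mask-aware and
deterministic.  Variances are population variances (divide by the pixel
count), matching the printed definitions these metrics reproduce.  PSNR
uses a configurable bit depth, default 12 (a ~4096-level range suits HU
images; natural 8-bit images use 255).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Dict, List, Optional, Sequence

import numpy as np

__all__ = [
    "SSIMParams",
    "EvalReport",
    "mae",
    "psnr",
    "ssim",
    "image_std",
    "roi_mean",
    "evaluate",
    "dice",
    "body_mask_of",
]


@dataclass(frozen=True)
class SSIMParams:
    """SSIM stabilisation constants and dynamic range.

    ``c1 = (k1 L)^2`` and ``c2 = (k2 L)^2`` with the customary
    ``k1 = 0.01``, ``k2 = 0.03``; ``L`` is the dynamic range of the pixel
    values (255 for 8-bit images; default 4095 for 12-bit-range HU data).
    ``window='global'`` evaluates the single-formula SSIM over whole-image
    statistics; ``window='sliding'`` uses the common local-window variant.
    """

    k1: float = 0.01
    k2: float = 0.03
    dynamic_range: float = 4095.0
    window: str = "global"
    sliding_win_size: int = 7

    def __post_init__(self):
        if self.dynamic_range <= 0:
            raise ValueError("dynamic_range must be > 0")
        if self.window not in ("global", "sliding"):
            raise ValueError("window must be 'global' or 'sliding'")


@dataclass
class EvalReport:
    """Aggregate metrics for a corrected test set (means over slices)."""

    mae: float
    mae_std: float
    psnr: float
    ssim: float
    std_whole: float
    roi_means: Dict[str, float] = field(default_factory=dict)
    roi_stds: Dict[str, float] = field(default_factory=dict)
    per_slice: List[Dict[str, float]] = field(default_factory=list)

    def to_dict(self) -> dict:
        return {
            "mae": self.mae,
            "mae_std": self.mae_std,
            "psnr": self.psnr,
            "ssim": self.ssim,
            "std_whole": self.std_whole,
            "roi_means": dict(self.roi_means),
            "roi_stds": dict(self.roi_stds),
        }


def _masked(a: np.ndarray, mask: Optional[np.ndarray]) -> np.ndarray:
    a = np.asarray(a, dtype=np.float64)
    if mask is None:
        return a.ravel()
    mask = np.asarray(mask, dtype=bool)
    if mask.shape != a.shape:
        raise ValueError("mask shape differs from image shape")
    if not mask.any():
        raise ValueError("mask selects no pixels")
    return a[mask]


def _check_shapes(x, y):
    x, y = np.asarray(x, dtype=np.float64), np.asarray(y, dtype=np.float64)
    if x.shape != y.shape:
        raise ValueError(f"shape mismatch: {x.shape} vs {y.shape}")
    return x, y


def mae(reference: np.ndarray, evaluated: np.ndarray,
        mask: Optional[np.ndarray] = None) -> float:
    """Mean absolute HU difference over the mask (default: whole image)."""
    reference, evaluated = _check_shapes(reference, evaluated)
    diff = np.abs(reference - evaluated)
    return float(_masked(diff, mask).mean())


def psnr(target: np.ndarray, predicted: np.ndarray, n_bits: int = 12,
         mask: Optional[np.ndarray] = None) -> float:
    """Peak signal-to-noise ratio, ``10 log10((2^n - 1)^2 / MSE)`` in dB.

    Raises for identical images (MSE = 0 means infinite PSNR).
    """
    if n_bits < 1:
        raise ValueError("n_bits must be >= 1")
    target, predicted = _check_shapes(target, predicted)
    mse = float(_masked((target - predicted) ** 2, mask).mean())
    if mse == 0:
        raise ZeroDivisionError("MSE is zero: PSNR is infinite for identical images")
    peak = float(2**n_bits - 1)
    return float(10.0 * math.log10(peak * peak / mse))


def ssim(x: np.ndarray, y: np.ndarray, params: SSIMParams = SSIMParams()) -> float:
    """Structural similarity with global statistics (default) or sliding window.

    Global mode evaluates
    ``(2 mu_x mu_y + c1)(2 sigma_xy + c2) /
    ((mu_x^2 + mu_y^2 + c1)(sigma_x^2 + sigma_y^2 + c2))``
    over whole-image (population) moments.  Sliding mode defers to the
    standard local-window implementation for comparability with common
    practice.
    """
    x, y = _check_shapes(x, y)
    if params.window == "sliding":
        from skimage.metrics import structural_similarity

        return float(structural_similarity(
            x, y, data_range=params.dynamic_range, win_size=params.sliding_win_size,
            gaussian_weights=False, use_sample_covariance=False,
            K1=params.k1, K2=params.k2,
        ))
    c1 = (params.k1 * params.dynamic_range) ** 2
    c2 = (params.k2 * params.dynamic_range) ** 2
    mu_x, mu_y = x.mean(), y.mean()
    var_x, var_y = x.var(), y.var()  # population variance
    cov = ((x - mu_x) * (y - mu_y)).mean()
    return float(
        (2 * mu_x * mu_y + c1) * (2 * cov + c2)
        / ((mu_x**2 + mu_y**2 + c1) * (var_x + var_y + c2))
    )


def image_std(image: np.ndarray, mask: Optional[np.ndarray] = None) -> float:
    """Population standard deviation of HU over the mask."""
    vals = _masked(np.asarray(image, dtype=np.float64), mask)
    return float(vals.std(ddof=0))


def roi_mean(image: np.ndarray, roi_mask: np.ndarray) -> float:
    """Mean CT number (HU) over a region of interest."""
    return float(_masked(np.asarray(image, dtype=np.float64), roi_mask).mean())


def dice(mask_a: np.ndarray, mask_b: np.ndarray) -> float:
    """Dice overlap of two boolean masks."""
    a, b = np.asarray(mask_a, bool), np.asarray(mask_b, bool)
    if a.shape != b.shape:
        raise ValueError("mask shapes differ")
    denom = a.sum() + b.sum()
    if denom == 0:
        return 1.0
    return float(2.0 * (a & b).sum() / denom)


def body_mask_of(image_hu: np.ndarray, threshold: float = -400.0) -> np.ndarray:
    """Extract the body contour mask: threshold air out, fill internal holes."""
    from scipy import ndimage as ndi

    mask = np.asarray(image_hu, dtype=np.float64) > threshold
    mask = ndi.binary_fill_holes(mask)
    labels, n = ndi.label(mask)
    if n > 1:  # keep the largest connected component
        sizes = ndi.sum(mask, labels, index=range(1, n + 1))
        mask = labels == (1 + int(np.argmax(sizes)))
    return mask


def evaluate(
    corrected: Sequence[np.ndarray],
    reference: Sequence[np.ndarray],
    rois: Optional[Sequence[Dict[str, np.ndarray]]] = None,
    ssim_params: SSIMParams = SSIMParams(),
    psnr_bits: int = 12,
    mask: Optional[Sequence[np.ndarray]] = None,
) -> EvalReport:
    """Per-slice metrics plus across-slice means for a corrected test set.

    ``mae_std`` is the population standard deviation of the per-slice MAE
    values.  PSNR of an identical pair is recorded as ``inf`` and
    propagates to the mean.  ``rois`` supplies per-slice ROI masks
    (e.g. bone marrow, skin) for mean/std CT-number reporting.
    """
    if len(corrected) != len(reference):
        raise ValueError("corrected and reference sets differ in length")
    if len(corrected) == 0:
        raise ValueError("empty evaluation set")
    if rois is not None and len(rois) != len(corrected):
        raise ValueError("rois must align with the slice sets")

    per_slice: List[Dict[str, float]] = []
    roi_vals: Dict[str, List[float]] = {}
    roi_sds: Dict[str, List[float]] = {}
    for i, (c, r) in enumerate(zip(corrected, reference)):
        m = None if mask is None else mask[i]
        row = {
            "mae": mae(r, c, m),
            "ssim": ssim(c, r, ssim_params),
            "std_whole": image_std(c, m),
        }
        try:
            row["psnr"] = psnr(r, c, psnr_bits, m)
        except ZeroDivisionError:
            row["psnr"] = math.inf
        if rois is not None:
            for name, roi in rois[i].items():
                if not np.asarray(roi, bool).any():
                    continue
                roi_vals.setdefault(name, []).append(roi_mean(c, roi))
                roi_sds.setdefault(name, []).append(image_std(c, roi))
        per_slice.append(row)

    maes = np.array([p["mae"] for p in per_slice])
    return EvalReport(
        mae=float(maes.mean()),
        mae_std=float(maes.std(ddof=0)),
        psnr=float(np.mean([p["psnr"] for p in per_slice])),
        ssim=float(np.mean([p["ssim"] for p in per_slice])),
        std_whole=float(np.mean([p["std_whole"] for p in per_slice])),
        roi_means={k: float(np.mean(v)) for k, v in roi_vals.items()},
        roi_stds={k: float(np.mean(v)) for k, v in roi_sds.items()},
        per_slice=per_slice,
    )
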