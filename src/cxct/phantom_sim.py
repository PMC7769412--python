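"""Synthetic pelvis-phantom simulator for CBCT/planning-CT training pairs.

Real paired data for this problem are a patient's CBCT (scatter-corrupted,
treatment position) and their planning CT deformably registered onto it
(clean intensities, but residually misaligned by a few pixels).  The
simulator emulates exactly that triplet per slice:

``clean_truth``  an elliptical soft-tissue body with a skin rim, two
                 cortical-bone ellipses with marrow cores and optional air
                 cavities, at fixed HU per tissue class;
``input_image``  the clean slice corrupted inside the body by a radial
                 cupping bias, oriented streaks and Gaussian noise — the
                 CBCT stand-in;
``label_image``  the clean slice warped by a smooth random displacement
                 field bounded by a few pixels — the imperfectly
                 registered planning-CT stand-in.

Everything is seeded and byte-reproducible.  The simulator models the
*appearance* of scatter artifacts (grayscale nonuniformity, streaks,
noise), not their projection-domain physics.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np
from scipy import ndimage

__all__ = [
    "PhantomSpec",
    "ArtifactSpec",
    "DeformationSpec",
    "PairedSlice",
    "SliceDataset",
    "generate_phantom",
    "corrupt",
    "artifact_field",
    "deform",
    "displacement_field",
    "make_dataset",
]

# Default tissue HU: skin and marrow follow published pelvic ROI means;
# air, soft tissue and cortical bone are standard CT values.
DEFAULT_TISSUE_HU: Dict[str, float] = {
    "air": -1000.0,
    "soft": 40.0,
    "skin": -140.0,
    "bone_marrow": 232.0,
    "bone_cortical": 700.0,
}


@dataclass(frozen=True)
class PhantomSpec:
    """Geometry and tissue intensities of one clean phantom slice."""

    size: int = 64
    body_half_axes: Tuple[float, float] = (0.42, 0.34)  # fraction of size
    tissue_hu: Dict[str, float] = field(default_factory=lambda: dict(DEFAULT_TISSUE_HU))
    n_air_cavities: int = 1
    skin_thickness: float = 0.04  # fraction of size
    seed: int = 0

    def __post_init__(self):
        hu = self.tissue_hu
        if not (hu["air"] < hu["soft"] < hu["bone_cortical"]):
            raise ValueError("tissue HU must satisfy air < soft < cortical bone")
        ax, ay = self.body_half_axes
        if ax >= 0.5 or ay >= 0.5:
            raise ValueError("body half-axes must fit inside the frame (< 0.5 of size)")


@dataclass(frozen=True)
class ArtifactSpec:
    """Scatter-artifact model: cupping bias + streaks + noise (all in HU)."""

    cupping_amplitude: float = 80.0
    n_streaks: int = 6
    streak_amplitude: float = 60.0
    streak_width: float = 1.5
    noise_sigma: float = 15.0
    seed: int = 0

    def __post_init__(self):
        for name in ("cupping_amplitude", "streak_amplitude", "streak_width", "noise_sigma"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")
        if self.n_streaks < 0:
            raise ValueError("n_streaks must be >= 0")


@dataclass(frozen=True)
class DeformationSpec:
    """Smooth random warp standing in for residual registration error."""

    grid_spacing: int = 16
    max_displacement: float = 4.0
    seed: int = 0

    def __post_init__(self):
        if self.max_displacement < 0:
            raise ValueError("max_displacement must be >= 0")
        if self.grid_spacing < 2:
            raise ValueError("grid_spacing must be >= 2")


@dataclass
class PairedSlice:
    """One training example: CBCT stand-in, CT stand-in, hidden truth, masks."""

    input_image: np.ndarray
    label_image: np.ndarray
    clean_truth: np.ndarray
    body_mask: np.ndarray
    roi_masks: Dict[str, np.ndarray]

    def __post_init__(self):
        shapes = {self.input_image.shape, self.label_image.shape, self.clean_truth.shape,
                  self.body_mask.shape} | {m.shape for m in self.roi_masks.values()}
        if len(shapes) != 1:
            raise ValueError("all images and masks of a PairedSlice must share one shape")


@dataclass
class SliceDataset:
    train: List[PairedSlice]
    val: List[PairedSlice]
    test: List[PairedSlice]
    master_seed: int = 0

    def __iter__(self):
        return iter(self.train + self.val + self.test)


# ---------------------------------------------------------------------------
# Clean phantom
# ---------------------------------------------------------------------------

def _ellipse_mask(size: int, cx: float, cy: float, ax: float, ay: float,
                  angle: float = 0.0) -> np.ndarray:
    yy, xx = np.mgrid[0:size, 0:size].astype(np.float64)
    x, y = xx - cx, yy - cy
    if angle:
        c, s = np.cos(angle), np.sin(angle)
        x, y = c * x + s * y, -s * x + c * y
    return (x / ax) ** 2 + (y / ay) ** 2 <= 1.0


def generate_phantom(spec: PhantomSpec = PhantomSpec()):
    """Build one clean slice; returns ``(image, body_mask, roi_masks)``.

    ROI masks mark bone marrow and skin.  Geometry (bone placement, cavity
    position) is jittered from ``spec.seed`` so repeated calls with
    different seeds give plausible anatomical variation.
    """
    n = spec.size
    hu = spec.tissue_hu
    rng = np.random.default_rng(spec.seed)
    c = (n - 1) / 2.0
    ax, ay = spec.body_half_axes[0] * n, spec.body_half_axes[1] * n

    body = _ellipse_mask(n, c, c, ax, ay)
    if not body[1:-1, 1:-1].any() or body[0, :].any() or body[-1, :].any() \
            or body[:, 0].any() or body[:, -1].any():
        raise ValueError("body ellipse does not fit inside the frame")
    rim = spec.skin_thickness * n
    interior = _ellipse_mask(n, c, c, ax - rim, ay - rim)
    skin = body & ~interior

    image = np.full((n, n), hu["air"], dtype=np.float64)
    image[body] = hu["skin"]
    image[interior] = hu["soft"]

    # two symmetric femoral-head-like bone structures: cortical shell + marrow core
    bone_r = 0.11 * n * rng.uniform(0.9, 1.1)
    bx_off = 0.22 * n * rng.uniform(0.9, 1.1)
    by = c + 0.05 * n * rng.uniform(-1.0, 1.0)
    marrow = np.zeros((n, n), dtype=bool)
    cortical = np.zeros((n, n), dtype=bool)
    for sign in (-1.0, 1.0):
        outer = _ellipse_mask(n, c + sign * bx_off, by, bone_r, bone_r * 0.85)
        inner = _ellipse_mask(n, c + sign * bx_off, by, bone_r * 0.6, bone_r * 0.5)
        cortical |= outer & ~inner
        marrow |= inner
    image[cortical & interior] = hu["bone_cortical"]
    marrow &= interior
    image[marrow] = hu["bone_marrow"]

    for _ in range(spec.n_air_cavities):
        rc = 0.06 * n * rng.uniform(0.7, 1.3)
        cav_cx = c + 0.08 * n * rng.uniform(-1.0, 1.0)
        cav_cy = c + 0.18 * n * rng.uniform(0.6, 1.0)
        cav = _ellipse_mask(n, cav_cx, cav_cy, rc, rc * 0.8)
        cav &= interior & ~cortical & ~marrow
        image[cav] = hu["air"]

    roi_masks = {"bone_marrow": marrow, "skin": skin & ~marrow}
    return image, body, roi_masks


# ---------------------------------------------------------------------------
# Artifact corruption
# ---------------------------------------------------------------------------

def artifact_field(shape: Tuple[int, int], body_mask: np.ndarray,
                   spec: ArtifactSpec) -> np.ndarray:
    """Total additive artifact field (HU), zero outside the body mask.

    Cupping: ``-A * (1 - (r/R)^2)`` on the normalised elliptical body
    radius, i.e. the body centre is depressed by exactly A and the body
    edge is untouched.  Streaks: oriented lines of alternating sign with a
    Gaussian cross-profile.  Noise: i.i.d. Gaussian.
    """
    n_y, n_x = shape
    rng = np.random.default_rng(spec.seed)
    field_total = np.zeros(shape, dtype=np.float64)
    yy, xx = np.mgrid[0:n_y, 0:n_x].astype(np.float64)

    if body_mask.any():
        ys, xs = np.nonzero(body_mask)
        cy, cx = ys.mean(), xs.mean()
        ry = max((ys.max() - ys.min()) / 2.0, 1.0)
        rx = max((xs.max() - xs.min()) / 2.0, 1.0)
        r2 = ((xx - cx) / rx) ** 2 + ((yy - cy) / ry) ** 2
        field_total -= spec.cupping_amplitude * np.clip(1.0 - r2, 0.0, None)

        for k in range(spec.n_streaks):
            theta = rng.uniform(0.0, np.pi)
            offset = rng.uniform(-0.8, 0.8)
            sign = 1.0 if k % 2 == 0 else -1.0
            # signed distance to the line through the body centre
            dist = (xx - cx) * np.sin(theta) - (yy - cy) * np.cos(theta) - offset * min(rx, ry)
            profile = np.exp(-0.5 * (dist / max(spec.streak_width, 1e-9)) ** 2)
            field_total += sign * spec.streak_amplitude * profile

        if spec.noise_sigma > 0:
            field_total += rng.normal(0.0, spec.noise_sigma, size=shape)

    field_total[~body_mask] = 0.0
    return field_total


def corrupt(clean: np.ndarray, body_mask: np.ndarray,
            spec: ArtifactSpec = ArtifactSpec()) -> np.ndarray:
    """Apply the artifact field inside the body; identity outside.

    With all amplitudes zero the output equals the input bit-exactly.
    """
    clean = np.asarray(clean, dtype=np.float64)
    if clean.shape != body_mask.shape:
        raise ValueError("image and body mask shapes differ")
    if spec.cupping_amplitude == 0 and spec.noise_sigma == 0 and (
            spec.n_streaks == 0 or spec.streak_amplitude == 0):
        return clean.copy()
    return clean + artifact_field(clean.shape, np.asarray(body_mask, bool), spec)


# ---------------------------------------------------------------------------
# Residual-misalignment warp
# ---------------------------------------------------------------------------

def displacement_field(shape: Tuple[int, int], spec: DeformationSpec) -> np.ndarray:
    """Smooth per-pixel displacement (2, H, W), |each component| <= bound.

    Random displacements are drawn on a coarse control grid and bilinearly
    interpolated; linear interpolation cannot overshoot the node values,
    so the bound holds exactly everywhere.
    """
    n_y, n_x = shape
    rng = np.random.default_rng(spec.seed)
    gs = spec.grid_spacing
    gy = int(np.ceil(n_y / gs)) + 1
    gx = int(np.ceil(n_x / gs)) + 1
    coarse = rng.uniform(-spec.max_displacement, spec.max_displacement, size=(2, gy, gx))
    node_y = np.linspace(0, n_y - 1, gy)
    node_x = np.linspace(0, n_x - 1, gx)
    yy, xx = np.mgrid[0:n_y, 0:n_x].astype(np.float64)
    iy = np.clip(np.searchsorted(node_y, yy.ravel(), side="right") - 1, 0, gy - 2)
    ix = np.clip(np.searchsorted(node_x, xx.ravel(), side="right") - 1, 0, gx - 2)
    ty = ((yy.ravel() - node_y[iy]) / (node_y[iy + 1] - node_y[iy])).reshape(shape)
    tx = ((xx.ravel() - node_x[ix]) / (node_x[ix + 1] - node_x[ix])).reshape(shape)
    iy, ix = iy.reshape(shape), ix.reshape(shape)
    out = np.empty((2, n_y, n_x), dtype=np.float64)
    for c in range(2):
        f = coarse[c]
        out[c] = ((1 - ty) * (1 - tx) * f[iy, ix] + (1 - ty) * tx * f[iy, ix + 1]
                  + ty * (1 - tx) * f[iy + 1, ix] + ty * tx * f[iy + 1, ix + 1])
    return out


def deform(image: np.ndarray, spec: DeformationSpec = DeformationSpec(),
           order: int = 1, is_mask: bool = False) -> np.ndarray:
    """Warp an image (or mask) by the spec's smooth displacement field."""
    image = np.asarray(image)
    if spec.max_displacement == 0:
        return image.astype(bool if is_mask else np.float64).copy()
    disp = displacement_field(image.shape, spec)
    yy, xx = np.mgrid[0 : image.shape[0], 0 : image.shape[1]].astype(np.float64)
    coords = np.stack([yy + disp[0], xx + disp[1]])
    if is_mask:
        warped = ndimage.map_coordinates(image.astype(np.float64), coords, order=0,
                                         mode="nearest")
        return warped > 0.5
    return ndimage.map_coordinates(image.astype(np.float64), coords, order=order,
                                   mode="nearest")


# ---------------------------------------------------------------------------
# Dataset assembly
# ---------------------------------------------------------------------------

def _rotate_slice(s: PairedSlice, angle: float) -> PairedSlice:
    def rot(img, order):
        return ndimage.rotate(img.astype(np.float64), angle, reshape=False, order=order,
                              mode="constant", cval=float(img.min()))
    return PairedSlice(
        input_image=rot(s.input_image, 1),
        label_image=rot(s.label_image, 1),
        clean_truth=rot(s.clean_truth, 1),
        body_mask=rot(s.body_mask, 0) > 0.5,
        roi_masks={k: rot(m, 0) > 0.5 for k, m in s.roi_masks.items()},
    )


def _split_counts(n: int, fractions: Sequence[float]) -> Tuple[int, int, int]:
    if len(fractions) != 3 or abs(sum(fractions) - 1.0) > 1e-9:
        raise ValueError("split must be three fractions summing to 1")
    counts = [int(np.floor(f * n)) for f in fractions]
    counts[0] += n - sum(counts)
    for f, c in zip(fractions, counts):
        if f > 0 and c == 0:
            raise ValueError(f"split fraction {f} yields an empty split for n={n}")
    return tuple(counts)


def make_paired_slice(phantom: PhantomSpec, artifact: ArtifactSpec,
                      deformation: DeformationSpec) -> PairedSlice:
    """Generate one (input, label, truth, masks) example from three specs."""
    clean, body, rois = generate_phantom(phantom)
    corrupted = corrupt(clean, body, artifact)
    label = deform(clean, deformation)
    return PairedSlice(input_image=corrupted, label_image=label, clean_truth=clean,
                       body_mask=body, roi_masks=rois)


def make_dataset(
    n: int,
    phantom: PhantomSpec = PhantomSpec(),
    artifact: ArtifactSpec = ArtifactSpec(),
    deformation: DeformationSpec = DeformationSpec(),
    split: Tuple[float, float, float] = (5 / 7, 1 / 7, 1 / 7),
    augment_rotations: Sequence[float] = (),
    master_seed: int = 0,
) -> SliceDataset:
    """Generate ``n`` paired slices with seeded per-slice jitter and splits.

    Each slice draws fresh phantom geometry, artifact and warp seeds from
    ``master_seed``.  Rotation augmentation (applied consistently to
    input/label/truth/masks) expands the *training* split only.  The whole
    dataset is byte-reproducible from its arguments.
    """
    if n < 1:
        raise ValueError("n must be >= 1")
    n_train, n_val, n_test = _split_counts(n, split)
    seed_rng = np.random.default_rng(master_seed)
    slices = []
    for _ in range(n):
        s_ph, s_ar, s_de = (int(s) for s in seed_rng.integers(2**31, size=3))
        slices.append(make_paired_slice(
            replace(phantom, seed=s_ph),
            replace(artifact, seed=s_ar),
            replace(deformation, seed=s_de),
        ))
    train = slices[:n_train]
    val = slices[n_train : n_train + n_val]
    test = slices[n_train + n_val :]
    for angle in augment_rotations:
        train = train + [_rotate_slice(s, angle) for s in slices[:n_train]]
    return SliceDataset(train=train, val=val, test=test, master_seed=master_seed)
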