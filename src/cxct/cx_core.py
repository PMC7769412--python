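"""Contextual-similarity (CX) loss mathematics and comparison losses.

The contextual loss treats each image as a *set* of deep feature vectors and
scores how well every feature of one image can find a contextually similar
feature in the other, rather than comparing pixels at corresponding
locations.  This makes it robust to the residual misalignment left by
deformable registration of CBCT/planning-CT pairs, which is exactly the
regime the correction network is trained in.

Pipeline, for feature sets ``S = {s_i}`` (rows) and ``T = {t_j}`` (columns):

1. ``d_ij`` — cosine distance between ``s_i - mu_t`` and ``t_j - mu_t``,
   where ``mu_t`` is the mean of the *target* features only.
2. ``d~_ij = d_ij / (min_k d_ik + eps)`` — per-row scale normalisation.
3. ``w_ij = exp((1 - d~_ij) / h)`` — distances turned into affinities with
   bandwidth ``h``.
4. ``CX_ij = w_ij / sum_k w_ik`` — row-normalised contextual similarity.
5. ``CX(S, T) = (1/N_t) * sum_j max_i CX_ij`` — global similarity, and the
   contextual loss is ``-log CX(S, T)``.

Every function below is written against the internal autodiff tensor, so the
same code path serves both plain numerical evaluation (arrays in, arrays
out) and gradient-based training (tensors in, tensors out).
"""

from __future__ import annotations

import zlib
from dataclasses import dataclass

import numpy as np

from ._autodiff import Tensor, as_tensor

__all__ = [
    "FeatureSet",
    "CXParams",
    "LossWeights",
    "cosine_distances",
    "cx_from_distances",
    "global_similarity",
    "cx_loss",
    "combined_loss",
    "l2_loss",
    "perceptual_loss",
    "sample_features",
]

#: floor applied to the global similarity before -log, so that totally
#: dissimilar feature sets give a large finite loss instead of +inf.
SIMILARITY_FLOOR = 1e-12


@dataclass(frozen=True)
class FeatureSet:
    """N feature vectors of dimension D drawn from one extractor layer."""

    vectors: np.ndarray
    layer_tag: str = ""

    def __post_init__(self):
        v = np.asarray(self.vectors)
        if v.ndim != 2 or v.shape[0] < 1 or v.shape[1] < 1:
            raise ValueError(f"feature set must be (N>=1, D>=1), got shape {v.shape}")
        if not np.all(np.isfinite(v)):
            raise ValueError("feature set contains non-finite entries")
        object.__setattr__(self, "vectors", v)

    @property
    def n(self) -> int:
        return self.vectors.shape[0]

    @property
    def dim(self) -> int:
        return self.vectors.shape[1]


@dataclass(frozen=True)
class CXParams:
    """Numerical parameters of the similarity transform.

    ``epsilon`` guards the row-minimum in the distance normalisation (and
    the norm of a zero centered feature); ``bandwidth_h`` controls how
    sharply the affinity decays with normalised distance.
    """

    epsilon: float = 1e-5
    bandwidth_h: float = 0.5

    def __post_init__(self):
        if self.epsilon <= 0:
            raise ValueError("epsilon must be > 0")
        if self.bandwidth_h <= 0:
            raise ValueError("bandwidth_h must be > 0")


@dataclass(frozen=True)
class LossWeights:
    """Configuration of the combined training objective.

    total = CX(G(s), s @ content_layer) + lambda_weight * sum over
    style_layers of CX(G(s), t @ layer), each style layer's feature set
    subsampled to at most ``style_sample_n`` vectors (seeded, drawn once).
    """

    lambda_weight: float = 5.0
    content_layer: str = "conv4_2"
    style_layers: tuple = ("conv2_2", "conv3_2", "conv4_2")
    style_sample_n: int = 6400  # 80 x 80
    sample_seed: int = 0

    def __post_init__(self):
        if self.lambda_weight < 0:
            raise ValueError("lambda_weight must be >= 0")
        if self.style_sample_n < 1:
            raise ValueError("style_sample_n must be >= 1")


def _vectors(x) -> "Tensor | np.ndarray":
    if isinstance(x, FeatureSet):
        return x.vectors
    return x


def _as_matrix_tensor(x, name: str) -> Tensor:
    t = as_tensor(_vectors(x))
    if t.data.ndim != 2:
        raise ValueError(f"{name} must be a 2-D (N, D) array, got shape {t.data.shape}")
    return t


# ---------------------------------------------------------------------------
# Core similarity chain (tensor-generic)
# ---------------------------------------------------------------------------

def cosine_distances(source, target, norm_eps: float = 1e-5):
    """Matrix of cosine distances between target-centered feature vectors.

    Entry ``(i, j)`` is ``1 - cos(s_i - mu_t, t_j - mu_t)`` with ``mu_t``
    the mean of the target vectors.  The norm of a centered vector is
    floored at ``norm_eps`` (the floor only ever bites at zero norm, so
    joint rescaling of S and T leaves the matrix exactly unchanged); if
    *both* members of a pair are zero after centering they are identical
    and the distance is defined as 0.

    Accepts :class:`FeatureSet`, arrays or autodiff tensors; returns an
    ``(N_s, N_t)`` array (or tensor, if either input carries gradients).
    """
    s = _as_matrix_tensor(source, "source")
    t = _as_matrix_tensor(target, "target")
    if s.data.shape[1] != t.data.shape[1]:
        raise ValueError(
            f"feature dimension mismatch: source D={s.data.shape[1]}, "
            f"target D={t.data.shape[1]}"
        )
    mu_t = t.mean(axis=0, keepdims=True)
    sc = s - mu_t
    tc = t - mu_t
    sn = (sc * sc).sum(axis=1, keepdims=True).sqrt()  # (Ns, 1)
    tn = (tc * tc).sum(axis=1, keepdims=True).sqrt()  # (Nt, 1)
    denom = sn.clamp_min(norm_eps) @ tn.clamp_min(norm_eps).T
    d = 1.0 - (sc @ tc.T) / denom
    both_zero = (sn.data == 0.0) & (tn.data == 0.0).T
    if both_zero.any():
        d = d * (~both_zero).astype(d.data.dtype)
    return d if d.requires_grad else d.data


def cx_from_distances(d, params: CXParams = CXParams()):
    """Row-normalised contextual-similarity matrix from cosine distances.

    Normalises each row by its minimum (plus ``epsilon``), maps distances to
    affinities through ``exp((1 - d~)/h)`` and normalises rows to sum to 1.
    The exponent is shifted by its row maximum before ``exp``; the shift
    cancels in the row normalisation and prevents overflow for the very
    large normalised distances (~1e5/h) that dissimilar features produce.
    """
    dt_in = as_tensor(d)
    if dt_in.data.ndim != 2 or dt_in.data.shape[1] < 1 or dt_in.data.shape[0] < 1:
        raise ValueError(f"distance matrix must be non-empty 2-D, got shape {dt_in.data.shape}")
    dmin = dt_in.min(axis=1, keepdims=True)
    d_norm = dt_in / (dmin + params.epsilon)
    a = (1.0 - d_norm) * (1.0 / params.bandwidth_h)
    a = a - a.max(axis=1, keepdims=True)
    w = a.exp()
    cx = w / w.sum(axis=1, keepdims=True)
    return cx if cx.requires_grad else cx.data


def global_similarity(cx):
    """Global contextual similarity: mean over columns of the column max.

    Each target feature ``t_j`` contributes its best match
    ``max_i CX_ij``; identical sets give 1, uniformly dissimilar N x N
    sets give exactly 1/N.
    """
    t = as_tensor(cx)
    if t.data.ndim != 2 or t.data.size == 0:
        raise ValueError("CX matrix must be non-empty 2-D")
    g = t.max(axis=0).mean()
    return g if g.requires_grad else float(g.data)


def cx_loss(source_feats, target_feats, params: CXParams = CXParams()):
    """Contextual loss: ``-log CX(S, T)`` through the full Eq. chain.

    Non-negative up to floating error; exactly 0 when the sets coincide.
    The similarity is floored at ``SIMILARITY_FLOOR`` so the loss stays
    finite for completely dissimilar sets.
    """
    d = cosine_distances(source_feats, target_feats, norm_eps=params.epsilon)
    cx = cx_from_distances(d, params)
    g = global_similarity(cx)
    gt = as_tensor(g).clamp_min(SIMILARITY_FLOOR)
    loss = -(gt.log())
    return loss if loss.requires_grad else float(loss.data)


# ---------------------------------------------------------------------------
# Comparison losses
# ---------------------------------------------------------------------------

def l2_loss(x, y, normalized: bool = False):
    """Euclidean norm of the pixel-wise difference, ``||x - y||_2``.

    With ``normalized=True`` the norm is divided by sqrt(number of pixels)
    (a root-mean-square variant), useful when comparing across image sizes.
    """
    xt, yt = as_tensor(x), as_tensor(y)
    if xt.data.shape != yt.data.shape:
        raise ValueError(f"shape mismatch: {xt.data.shape} vs {yt.data.shape}")
    diff = xt - yt
    sq = (diff * diff).sum()
    # guard the sqrt at 0 (gradient of ||.|| is undefined there)
    out = (sq + 1e-24).sqrt()
    if normalized:
        out = out * (1.0 / np.sqrt(xt.data.size))
    return out if out.requires_grad else float(out.data)


def perceptual_loss(x, y, layer: str, extractor):
    """L1 distance between the layer-``layer`` feature maps of two images."""
    xt, yt = as_tensor(x), as_tensor(y)
    if xt.data.shape != yt.data.shape:
        raise ValueError(f"shape mismatch: {xt.data.shape} vs {yt.data.shape}")
    fx = extractor.hu_feature_maps(xt, [layer])[layer]
    fy = extractor.hu_feature_maps(yt, [layer])[layer]
    out = (fx - fy).abs().sum()
    return out if out.requires_grad else float(out.data)


def sample_features(feats: FeatureSet, n: int, seed: int) -> FeatureSet:
    """Keep ``n`` features drawn uniformly without replacement (seeded).

    Returns the set unchanged when ``n >= N``.  Sampling makes the CX
    matrices of wide shallow layers tractable; the same index draw is
    applied to both sides of a comparison so positions stay aligned.
    """
    if n < 1:
        raise ValueError("n must be >= 1")
    if n >= feats.n:
        return feats
    idx = _sample_indices(feats.n, n, seed)
    return FeatureSet(feats.vectors[idx], feats.layer_tag)


def _sample_indices(n_total: int, n_keep: int, seed: int) -> np.ndarray:
    rng = np.random.default_rng(seed)
    return np.sort(rng.choice(n_total, size=n_keep, replace=False))


# ---------------------------------------------------------------------------
# Combined training objective
# ---------------------------------------------------------------------------

def _take_rows(t: Tensor, idx: np.ndarray) -> Tensor:
    out = Tensor._make(t.data[idx], (t,), None)
    if out.requires_grad:
        def back(g):
            full = np.zeros_like(t.data)
            full[idx] = g  # idx is unique by construction
            t._accum(full)
        out._backward = back
    return out


def style_layer_seed(sample_seed: int, layer: str) -> int:
    """Deterministic per-layer sampling seed derived from the run seed."""
    tag = zlib.crc32(layer.encode("utf-8"))
    return int(np.random.default_rng([sample_seed, tag]).integers(2**31))


def combined_loss(
    generated,
    source,
    label,
    weights: LossWeights = LossWeights(),
    params: CXParams = CXParams(),
    extractor=None,
    return_terms: bool = False,
):
    """Combined objective: content CX to the input + lambda * style CX to the label.

    ``L(G) = L_CX(G(s), s, l_s) + lambda * sum_{l in l_t} L_CX(G(s), t, l)``

    The content layer compares the generated image against the *source*
    (the CBCT input), anchoring structure to the treatment-position
    anatomy; the style layers compare against the *label* (the planning
    CT), pulling intensities toward artifact-free values.  Style feature
    sets larger than ``style_sample_n`` are subsampled once with a seeded
    draw, identically on both sides of each comparison.
    """
    if extractor is None:
        raise ValueError("an extractor must be provided")
    gt = as_tensor(generated)
    st, lt = as_tensor(source), as_tensor(label)
    if not (gt.data.shape == st.data.shape == lt.data.shape):
        raise ValueError("generated, source and label must share one shape")

    layers = list(dict.fromkeys([weights.content_layer, *weights.style_layers]))
    gen_sets = extractor.hu_feature_sets(gt, layers)
    src_sets = extractor.hu_feature_sets(st, [weights.content_layer])
    lab_sets = extractor.hu_feature_sets(lt, list(weights.style_layers))

    content = cx_loss(gen_sets[weights.content_layer], src_sets[weights.content_layer], params)
    style = 0.0
    for layer in weights.style_layers:
        g_l, t_l = gen_sets[layer], lab_sets[layer]
        n_avail = g_l.data.shape[0] if isinstance(g_l, Tensor) else _vectors(g_l).shape[0]
        if weights.style_sample_n < n_avail:
            idx = _sample_indices(n_avail, weights.style_sample_n,
                                  style_layer_seed(weights.sample_seed, layer))
            g_l = _take_rows(as_tensor(_vectors(g_l)), idx)
            t_l = as_tensor(_vectors(t_l)).data[idx]
        style = style + cx_loss(g_l, t_l, params)

    total = content + as_tensor(style) * weights.lambda_weight if isinstance(style, Tensor) \
        else content + weights.lambda_weight * style
    if not isinstance(total, Tensor):
        total = float(total)
    if return_terms:
        return total, content, style
    return total
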