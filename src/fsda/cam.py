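"""Class activation maps through the discriminant-reduced feature space.

Standard CAM weights the last-conv feature-map channels by the classifier
weights of the predicted class.  After discriminant reduction the
classifier no longer sees channels directly, so the relevant weight block
is first back-projected through the transpose of the projection matrix;
the resulting channel weights are then applied to the flattened feature
map and the spatial map interpolated up to image size.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from matplotlib import colormaps
from PIL import Image

from .core_da import DiscriminantBasis
from .errors import ValidationError
from .evaluate import LinearClassifier, predict_scores

__all__ = ["FeatureMap", "CamResult", "compute_cam", "resize_map", "overlay"]

GAP_TOLERANCE = 1e-5


@dataclass(frozen=True)
class FeatureMap:
    """Channels x height x width activation tensor from a conv backbone."""

    tensor: np.ndarray  # (M, H, W)
    source_image_size: tuple[int, int] | None = None

    def __post_init__(self) -> None:
        tensor = np.asarray(self.tensor, dtype=float)
        if tensor.ndim != 3:
            raise ValidationError("feature map must be 3-D (channels, height, width)")
        if not np.isfinite(tensor).all():
            raise ValidationError("feature map contains non-finite values")
        object.__setattr__(self, "tensor", tensor)

    @property
    def n_channels(self) -> int:
        return self.tensor.shape[0]

    @property
    def spatial_shape(self) -> tuple[int, int]:
        return self.tensor.shape[1:]

    @property
    def flattened(self) -> np.ndarray:
        """(M, H*W) view used by the CAM weighting."""
        return self.tensor.reshape(self.n_channels, -1)

    @property
    def pooled(self) -> np.ndarray:
        """Channel-wise global average pooling -> the backbone feature vector."""
        return self.tensor.mean(axis=(1, 2))


@dataclass(frozen=True)
class CamResult:
    """Raw and image-sized relevance maps plus bookkeeping scalars.

    ``clinical_contribution`` is the part of the winning-class score that
    came from the clinical block and therefore cannot appear in the map.
    """

    weight_back: np.ndarray  # (M,) back-projected channel weights
    raw_map: np.ndarray  # (H, W)
    resized_map: np.ndarray | None
    predicted_class: object
    class_index: int
    scores: np.ndarray
    image_contribution: float
    clinical_contribution: float
    normalization: tuple[float, float]


def compute_cam(
    fmap: FeatureMap,
    basis: DiscriminantBasis,
    classifier: LinearClassifier,
    clinical: np.ndarray | None = None,
    class_index: int | None = None,
    interp: str = "bilinear",
    expected_pooled: np.ndarray | None = None,
) -> CamResult:
    """Relevance map for the predicted (or requested) class.

    Pools the feature map to recover the backbone vector, projects and
    fuses it, scores it with the linear classifier, back-projects the
    image-block weights of the winning class through the projection
    transpose, and applies them to the flattened feature map.  Only the
    linear classifier kind is supported; margin classifiers carry no
    per-class weight columns.
    """
    if not isinstance(classifier, LinearClassifier):
        raise ValidationError(
            "CAM requires the linear classifier kind (explicit weight matrix)"
        )
    if fmap.n_channels != basis.n_features:
        raise ValidationError(
            f"feature map has {fmap.n_channels} channels but basis expects "
            f"{basis.n_features}"
        )
    n_dir = basis.n_directions
    clinical = np.zeros(0) if clinical is None else np.asarray(clinical, dtype=float)
    if n_dir + clinical.size != classifier.input_dim:
        raise ValidationError(
            f"classifier input dim {classifier.input_dim} does not match "
            f"{n_dir} reduced features + {clinical.size} clinical values"
        )
    y = fmap.pooled
    if expected_pooled is not None:
        drift = float(np.max(np.abs(y - np.asarray(expected_pooled, dtype=float))))
        if drift > GAP_TOLERANCE:
            warnings.warn(
                f"pooled feature map deviates from the backbone vector by "
                f"{drift:.2e}; backbone adapter may be inconsistent",
                RuntimeWarning,
            )
    y_reduced = basis.projection @ y
    z = np.concatenate([y_reduced, clinical])
    scores, predicted = predict_scores(classifier, z)
    idx = int(np.argmax(scores)) if class_index is None else int(class_index)
    w_class = classifier.weights[:, idx]
    w_image = w_class[:n_dir]
    w_back = basis.projection.T @ w_image
    # weighted channel sum == flattened-map transpose times w_back; the
    # explicit reduction keeps the result reproducible across BLAS builds
    raw = (w_back[:, None, None] * fmap.tensor).sum(axis=0)
    resized = None
    if fmap.source_image_size is not None:
        resized = resize_map(raw, fmap.source_image_size, method=interp)
    lo, hi = float(raw.min()), float(raw.max())
    return CamResult(
        weight_back=w_back,
        raw_map=raw,
        resized_map=resized,
        predicted_class=classifier.classes[idx],
        class_index=idx,
        scores=scores,
        image_contribution=float(w_image @ y_reduced),
        clinical_contribution=float(w_class[n_dir:] @ clinical),
        normalization=(lo, hi),
    )


def _axis_coords(n_src: int, n_dst: int) -> np.ndarray:
    # corner-aligned grid so constant maps and corner values are preserved
    if n_src == 1:
        return np.zeros(n_dst)
    return np.linspace(0.0, n_src - 1.0, n_dst)


def resize_map(
    raw: np.ndarray, target: tuple[int, int], method: str = "bilinear"
) -> np.ndarray:
    """Interpolate a spatial map to ``target`` (height, width).

    Bilinear interpolation is corner-aligned (preserves constants and
    corner values, never overshoots); nearest uses pixel-center mapping so
    integer-factor upscaling replicates each cell exactly.
    """
    raw = np.asarray(raw, dtype=float)
    if raw.ndim != 2:
        raise ValidationError("map must be 2-D")
    th, tw = int(target[0]), int(target[1])
    if th < 1 or tw < 1:
        raise ValidationError(f"invalid target size: {target!r}")
    h, w = raw.shape
    if method == "nearest":
        rows = np.minimum(((np.arange(th) + 0.5) * h / th).astype(int), h - 1)
        cols = np.minimum(((np.arange(tw) + 0.5) * w / tw).astype(int), w - 1)
        return raw[np.ix_(rows, cols)]
    if method != "bilinear":
        raise ValidationError(f"unknown interpolation method: {method!r}")
    ry = _axis_coords(h, th)
    rx = _axis_coords(w, tw)
    y0 = np.minimum(np.floor(ry).astype(int), h - 1)
    x0 = np.minimum(np.floor(rx).astype(int), w - 1)
    y1 = np.minimum(y0 + 1, h - 1)
    x1 = np.minimum(x0 + 1, w - 1)
    fy = (ry - y0)[:, None]
    fx = (rx - x0)[None, :]
    top = raw[np.ix_(y0, x0)] * (1 - fx) + raw[np.ix_(y0, x1)] * fx
    bot = raw[np.ix_(y1, x0)] * (1 - fx) + raw[np.ix_(y1, x1)] * fx
    return top * (1 - fy) + bot * fy


def overlay(
    relevance: np.ndarray,
    image: np.ndarray | Image.Image,
    alpha: float = 0.5,
    cmap: str = "jet",
) -> Image.Image:
    """Blend a min-max-normalized heat map onto an image.

    ``alpha=0`` returns the original image bytes; ``alpha=1`` the pure
    colour-mapped heat layer.  A constant map normalizes to all-zeros with
    a warning.
    """
    if not 0.0 <= alpha <= 1.0:
        raise ValidationError("alpha must lie in [0, 1]")
    relevance = np.asarray(relevance, dtype=float)
    if isinstance(image, Image.Image):
        img_arr = np.asarray(image.convert("RGB"), dtype=np.uint8)
    else:
        img_arr = np.asarray(image)
        if img_arr.ndim == 2:
            img_arr = np.repeat(img_arr[:, :, None], 3, axis=2)
        if img_arr.dtype != np.uint8:
            img_arr = np.clip(img_arr, 0, 255).astype(np.uint8)
    if relevance.shape != img_arr.shape[:2]:
        raise ValidationError(
            f"map shape {relevance.shape} does not match image {img_arr.shape[:2]}"
        )
    lo, hi = float(relevance.min()), float(relevance.max())
    if hi > lo:
        norm = (relevance - lo) / (hi - lo)
    else:
        warnings.warn("constant relevance map; rendering all-zeros", RuntimeWarning)
        norm = np.zeros_like(relevance)
    heat = (colormaps[cmap](norm)[:, :, :3] * 255.0).astype(np.float64)
    blended = (1.0 - alpha) * img_arr.astype(np.float64) + alpha * heat
    return Image.fromarray(np.round(blended).astype(np.uint8), mode="RGB")
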