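"""Pluggable frozen feature extractors mapping images to pooled vectors.

Deep backbones are optional extras; the core package ships a deterministic
synthetic backbone so every downstream stage is testable without model
downloads.  All adapters honour one contract: when a conv feature map is
provided, its channel-wise spatial mean equals the pooled feature vector.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from PIL import Image

from .cam import FeatureMap
from .core_da import LabelledFeatures
from .errors import MissingDependencyError, ValidationError

__all__ = [
    "BackboneSpec",
    "SyntheticBackbone",
    "get_backbone",
    "extract",
    "load_manifest",
]

# Published input sizes for the named architectures.
_NAMED_SPECS = {
    "resnet18": dict(input_size=(512, 512), feature_dim=512, provides_feature_map=True),
    "vgg16": dict(input_size=(224, 224), feature_dim=4096, provides_feature_map=False),
    "vit": dict(input_size=(384, 384), feature_dim=768, provides_feature_map=False),
}


@dataclass(frozen=True)
class BackboneSpec:
    """Description of a frozen feature extractor."""

    name: str
    input_size: tuple[int, int]
    feature_dim: int
    provides_feature_map: bool
    preprocessing: dict = field(default_factory=dict)


class SyntheticBackbone:
    """Deterministic toy extractor: pooled grey patches times fixed filters.

    The image is average-pooled onto an H x W grid; channel m is that grid
    scaled by a fixed per-channel coefficient drawn from a seeded stream.
    A blank image therefore yields an all-zero map and vector, and pooled
    vectors equal the channel-wise spatial mean of the map by construction.
    """

    def __init__(
        self,
        feature_dim: int = 64,
        map_shape: tuple[int, int] = (7, 7),
        input_size: tuple[int, int] = (56, 56),
        seed: int = 7,
    ):
        self.spec = BackboneSpec(
            name="synthetic",
            input_size=input_size,
            feature_dim=feature_dim,
            provides_feature_map=True,
            preprocessing={"mode": "grayscale", "range": "[0,1]"},
        )
        rng = np.random.default_rng(seed)
        self._filters = rng.normal(size=feature_dim)

    def _to_array(self, image) -> np.ndarray:
        if isinstance(image, Image.Image):
            arr = np.asarray(image.convert("L"), dtype=float) / 255.0
        else:
            arr = np.asarray(image, dtype=float)
            if arr.ndim == 3:
                arr = arr.mean(axis=2)
        if arr.ndim != 2:
            raise ValidationError("image must be 2-D grayscale or RGB")
        return arr

    def feature_map(self, image) -> FeatureMap:
        arr = self._to_array(image)
        h, w = self.spec.input_size
        gh, gw = 7, 7
        # average-pool onto the grid via corner-aligned block means
        rows = np.array_split(np.arange(arr.shape[0]), gh)
        cols = np.array_split(np.arange(arr.shape[1]), gw)
        pooled = np.array([[arr[np.ix_(r, c)].mean() for c in cols] for r in rows])
        tensor = self._filters[:, None, None] * pooled[None, :, :]
        return FeatureMap(tensor=tensor, source_image_size=arr.shape)

    def features(self, image) -> np.ndarray:
        return self.feature_map(image).pooled

    def __call__(self, image) -> np.ndarray:
        return self.features(image)


def _deep_backbone_stub(name: str):
    try:
        import torch  # noqa: F401
        import torchvision  # noqa: F401
    except ImportError as exc:
        raise MissingDependencyError(
            f"backbone {name!r} requires the optional deep-learning extras; "
            f"install them with: pip install 'fsda[torch]'"
        ) from exc
    raise MissingDependencyError(
        f"adapter for backbone {name!r} is not bundled in this build"
    )


def get_backbone(name: str, **kwargs):
    """Look up a backbone adapter by name."""
    if name == "synthetic":
        return SyntheticBackbone(**kwargs)
    if name in _NAMED_SPECS:
        return _deep_backbone_stub(name)
    raise ValidationError(
        f"unknown backbone {name!r}; available: synthetic, {', '.join(_NAMED_SPECS)}"
    )


def named_spec(name: str) -> BackboneSpec:
    """Spec of a named deep architecture (usable without its weights)."""
    if name not in _NAMED_SPECS:
        raise ValidationError(f"unknown backbone {name!r}")
    return BackboneSpec(name=name, **_NAMED_SPECS[name])


def load_manifest(path) -> pd.DataFrame:
    """Read a (sample_id, path) delimited manifest of images."""
    table = pd.read_csv(path, sep=None, engine="python")
    for col in ("sample_id", "path"):
        if col not in table.columns:
            raise ValidationError(f"manifest must have a {col!r} column")
    return table


def extract(
    backbone,
    images,
    labels=None,
    continue_on_error: bool = False,
) -> tuple[np.ndarray, list[FeatureMap | None]]:
    """Run a frozen backbone over a batch of images.

    Returns the pooled feature matrix and, for map-capable backbones, the
    per-image feature maps.  With ``continue_on_error`` a corrupt image
    yields a None map and a NaN feature row instead of aborting the batch.
    """
    vectors: list[np.ndarray] = []
    maps: list[FeatureMap | None] = []
    for i, image in enumerate(images):
        try:
            if getattr(backbone.spec, "provides_feature_map", False):
                fmap = backbone.feature_map(image)
                maps.append(fmap)
                vectors.append(fmap.pooled)
            else:
                maps.append(None)
                vectors.append(np.asarray(backbone.features(image), dtype=float))
        except Exception as exc:
            if not continue_on_error:
                raise ValidationError(f"failed to extract image #{i}: {exc}") from exc
            maps.append(None)
            vectors.append(np.full(backbone.spec.feature_dim, np.nan))
    return np.vstack(vectors), maps
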