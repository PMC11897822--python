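"""Synthetic data generators for every pipeline input.

Emulates the statistical regime the method targets — many more features
than samples, a handful of discriminative directions, weakly informative
clinical variables — plus conv-style feature maps with class-dependent
"hot" regions at known locations for localization scoring.  All randomness
derives from one seed through spawned child streams, so each generator is
independently reproducible.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .cam import FeatureMap
from .core_da import LabelledFeatures
from .errors import ValidationError
from .fusion import ClinicalSchema

__all__ = ["SynthConfig", "gen_features", "gen_clinical", "gen_feature_maps"]


@dataclass(frozen=True)
class SynthConfig:
    """Knobs for the synthetic generators.

    ``delta`` is the class-mean separation per informative dimension in
    within-class standard deviations; ``clinical_effect`` in [0, 1] scales
    the label association of the clinical variables from independent (0)
    to deterministic (1).
    """

    n_per_class: int = 50
    n_features: int = 512
    informative_dims: tuple[int, ...] = (0,)
    delta: float = 2.0
    covariance: str = "identity"  # "identity", "random_spd" or "spiked"
    condition_number: float = 10.0
    spike_count: int = 10
    spike_scale: float = 30.0
    clinical_effect: float = 0.5
    # feature-map synthesis
    map_channels: int = 32
    map_shape: tuple[int, int] = (7, 7)
    hot_channels: int = 12
    blob_size: int = 3
    blob_locations: tuple[tuple[int, int], tuple[int, int]] = ((0, 0), (4, 4))
    noise_sigma: float = 1.0
    snr: float = 3.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_per_class < 1:
            raise ValidationError("n_per_class must be >= 1")
        if self.delta < 0:
            raise ValidationError("delta must be non-negative")
        if not 0.0 <= self.clinical_effect <= 1.0:
            raise ValidationError("clinical_effect must lie in [0, 1]")
        if any(d < 0 or d >= self.n_features for d in self.informative_dims):
            raise ValidationError("informative_dims out of range")
        h, w = self.map_shape
        if self.blob_size > min(h, w):
            raise ValidationError("blob larger than the feature map")
        for r, c in self.blob_locations:
            if r + self.blob_size > h or c + self.blob_size > w:
                raise ValidationError("blob placement exceeds the feature map")


def _streams(cfg: SynthConfig) -> dict[str, np.random.Generator]:
    children = np.random.SeedSequence(cfg.seed).spawn(3)
    names = ("features", "clinical", "maps")
    return {n: np.random.default_rng(s) for n, s in zip(names, children)}


def _covariance(cfg: SynthConfig, rng: np.random.Generator) -> np.ndarray | None:
    if cfg.covariance == "identity":
        return None
    if cfg.covariance == "random_spd":
        m = cfg.n_features
        q, _ = np.linalg.qr(rng.normal(size=(m, m)))
        eigs = np.geomspace(1.0, cfg.condition_number, m)
        eigs /= eigs.mean()
        return (q * eigs) @ q.T
    raise ValidationError(f"unknown covariance kind: {cfg.covariance!r}")


def gen_features(cfg: SynthConfig) -> LabelledFeatures:
    """Class-conditional Gaussian features; only informative dims differ in mean.

    The mean gap on an informative dimension is ``delta`` times that
    dimension's within-class standard deviation.
    """
    rng = _streams(cfg)["features"]
    n, m = cfg.n_per_class, cfg.n_features
    if cfg.covariance == "spiked":
        # isotropic floor plus a few dominant variance directions, mimicking
        # the correlated high-variance structure of pooled conv activations
        k = min(cfg.spike_count, m)
        q, _ = np.linalg.qr(rng.normal(size=(m, k)))
        x = rng.normal(size=(2 * n, m))
        x += (rng.normal(size=(2 * n, k)) * cfg.spike_scale) @ q.T
        marginal_sd = np.sqrt(1.0 + cfg.spike_scale**2 * (q**2).sum(axis=1))
    else:
        cov = _covariance(cfg, rng)
        if cov is None:
            x = rng.normal(size=(2 * n, m))
            marginal_sd = np.ones(m)
        else:
            chol = np.linalg.cholesky(cov)
            x = rng.normal(size=(2 * n, m)) @ chol.T
            marginal_sd = np.sqrt(np.diag(cov))
    labels = np.repeat([1, 2], n)
    shift = np.zeros(m)
    dims = np.asarray(cfg.informative_dims, dtype=int)
    if dims.size:
        shift[dims] = cfg.delta * marginal_sd[dims]
    x[labels == 2] += shift
    names = tuple(f"f{i}" for i in range(m))
    return LabelledFeatures(matrix=x, labels=labels, feature_names=names)


def gen_clinical(
    cfg: SynthConfig, labels: np.ndarray
) -> tuple[pd.DataFrame, ClinicalSchema]:
    """Clinical table with one numeric and one categorical label-linked field.

    numeric: effect * s + (1 - effect) * noise, with s = -1/+1 by class, so
    effect 1 is perfectly separable and effect 0 pure noise.  categorical:
    agrees with the class with probability (1 + effect) / 2.
    """
    labels = np.asarray(labels)
    rng = _streams(cfg)["clinical"]
    sign = np.where(labels == np.unique(labels)[1], 1.0, -1.0)
    e = cfg.clinical_effect
    marker = e * sign + (1.0 - e) * rng.normal(size=labels.size)
    agree = rng.random(labels.size) < (1.0 + e) / 2.0
    group = np.where(agree == (sign > 0), "b", "a")
    table = pd.DataFrame(
        {
            "sample_id": [f"s{i:04d}" for i in range(labels.size)],
            "marker": marker,
            "group": group,
        }
    )
    schema = ClinicalSchema(
        fields={"marker": "numeric", "group": "categorical"},
        id_column="sample_id",
    )
    return table, schema


def gen_feature_maps(
    cfg: SynthConfig, labels: np.ndarray
) -> tuple[list[FeatureMap], np.ndarray, LabelledFeatures]:
    """Noisy feature maps with a class-located hot square in some channels.

    The hot channels are split into two groups, one per class: a sample's
    blob appears only in its class's group, at its class's location.  The
    channel groups make the pooled features class-separable (pooling alone
    would erase a purely spatial difference) while the locations give the
    relevance map a known target.  Returns the maps, boolean ground-truth
    blob masks (N, H, W) for localization scoring, and the pooled features
    (channel-wise spatial means), keeping the pooling consistency the CAM
    derivation assumes.
    """
    labels = np.asarray(labels)
    rng = _streams(cfg)["maps"]
    h, w = cfg.map_shape
    order = np.unique(labels)
    # amplitude is snr in units of the noise std; with zero noise snr is
    # taken as the absolute blob height
    amp = cfg.snr * cfg.noise_sigma if cfg.noise_sigma > 0 else cfg.snr
    half = max(cfg.hot_channels // 2, 1)
    groups = (np.arange(0, half), np.arange(half, cfg.hot_channels))
    maps: list[FeatureMap] = []
    masks = np.zeros((labels.size, h, w), dtype=bool)
    pooled = np.zeros((labels.size, cfg.map_channels))
    for i, lab in enumerate(labels):
        cls = int(np.where(order == lab)[0][0])
        r, c = cfg.blob_locations[cls]
        tensor = rng.normal(scale=cfg.noise_sigma, size=(cfg.map_channels, h, w))
        tensor[groups[cls], r : r + cfg.blob_size, c : c + cfg.blob_size] += amp
        fmap = FeatureMap(tensor=tensor, source_image_size=(8 * h, 8 * w))
        maps.append(fmap)
        masks[i, r : r + cfg.blob_size, c : c + cfg.blob_size] = True
        pooled[i] = fmap.pooled
    names = tuple(f"c{i}" for i in range(cfg.map_channels))
    features = LabelledFeatures(matrix=pooled, labels=labels, feature_names=names)
    return maps, masks, features
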