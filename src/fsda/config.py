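"""Run configuration and the end-to-end pipeline driver."""

from __future__ import annotations

import json
import logging
from dataclasses import asdict, dataclass, field, fields
from pathlib import Path

import yaml

from .core_da import LabelledFeatures
from .errors import ConfigError, ValidationError
from .evaluate import ARMS, EvaluationReport, cross_validate
from .fusion import ClinicalSchema
from .io import load_clinical, load_features

__all__ = ["RunConfig", "run_pipeline"]

logger = logging.getLogger("fsda")


@dataclass
class RunConfig:
    """Declarative description of an evaluation run.

    Loads from YAML with strict key checking; every problem found is
    reported at once rather than one at a time.
    """

    features_path: str | None = None
    clinical_path: str | None = None
    schema_path: str | None = None
    output_dir: str = "fsda_out"
    arms: list[str] = field(default_factory=lambda: ["DA", "DA+CV"])
    n_directions: int = 10
    folds: int = 5
    seed: int = 0
    classifier: str = "margin"
    within_mode: str = "as_printed"
    ridge: float | None = None
    label_column: str = "label"

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        if not isinstance(raw, dict):
            raise ConfigError(f"config file {path} must hold a mapping")
        known = {f.name for f in fields(cls)}
        unknown = sorted(set(raw) - known)
        if unknown:
            raise ConfigError(f"unknown config keys: {', '.join(unknown)}")
        cfg = cls(**raw)
        cfg.validate()
        return cfg

    def to_yaml(self, path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(asdict(self), fh, sort_keys=True)

    def validate(self) -> None:
        problems: list[str] = []
        if self.features_path is None:
            problems.append("features_path is required")
        for arm in self.arms:
            if arm not in ARMS:
                problems.append(f"unknown arm {arm!r}; valid: {', '.join(ARMS)}")
        needs_clinical = any(arm.endswith("+CV") for arm in self.arms)
        if needs_clinical and not self.clinical_path:
            problems.append("clinical_path is required by a +CV arm")
        if needs_clinical and not self.schema_path:
            problems.append("schema_path is required by a +CV arm")
        if self.folds < 2:
            problems.append("folds must be >= 2")
        if self.n_directions < 1:
            problems.append("n_directions must be >= 1")
        if self.classifier not in ("margin", "linear"):
            problems.append(f"unknown classifier kind {self.classifier!r}")
        if self.within_mode not in ("as_printed", "pooled"):
            problems.append(f"unknown within_mode {self.within_mode!r}")
        if self.ridge is not None and self.ridge < 0:
            problems.append("ridge must be non-negative")
        if problems:
            raise ConfigError("; ".join(problems))


def run_pipeline(config: RunConfig) -> EvaluationReport:
    """Load inputs, run the requested arms under cross-validation, persist reports.

    Writes ``report.json`` and ``report.tsv`` under ``output_dir`` and
    returns the in-memory report.
    """
    config.validate()
    features: LabelledFeatures = load_features(
        config.features_path, label_column=config.label_column
    )
    logger.info(
        "loaded features: %d samples x %d features",
        features.n_samples,
        features.n_features,
    )
    clinical = schema = None
    if any(arm.endswith("+CV") for arm in config.arms):
        clinical = load_clinical(config.clinical_path)
        schema = ClinicalSchema.from_yaml(config.schema_path)
        if len(clinical) != features.n_samples:
            raise ValidationError(
                f"clinical table has {len(clinical)} rows for "
                f"{features.n_samples} samples"
            )
    report = cross_validate(
        features,
        clinical=clinical,
        schema=schema,
        arms=tuple(config.arms),
        folds=config.folds,
        seed=config.seed,
        n_directions=config.n_directions,
        classifier=config.classifier,
        within_mode=config.within_mode,
        ridge=config.ridge,
    )
    out = Path(config.output_dir)
    out.mkdir(parents=True, exist_ok=True)
    (out / "report.json").write_text(report.to_json())
    report.to_table().to_csv(out / "report.tsv", sep="\t", index=False)
    logger.info("report written to %s", out)
    return report
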