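"""Analysis configuration: one YAML/TOML file driving the full pipeline.

CLI flags override config values; the fully resolved configuration is
echoed into the output manifest (via its hash) for provenance.
"""

from __future__ import annotations

from dataclasses import asdict, dataclass, field
from pathlib import Path
from typing import Any

from .patterns import ValidationError
from .tracking import METRIC_POLARITY

__all__ = ["AnalysisConfig"]

_SCHEMES = ("group_sign_flip", "trial_label_shuffle")
_ALTERNATIVES = ("greater", "less", "two-sided")
_NORMALIZATIONS = ("none", "univariate", "multivariate")


@dataclass
class AnalysisConfig:
    seed: int = 0
    n_subjects: int = 8
    output_dir: str | None = None
    simulate: dict[str, Any] = field(default_factory=dict)
    paths: dict[str, str] = field(default_factory=dict)
    extraction: dict[str, Any] = field(default_factory=dict)
    tracking: dict[str, Any] = field(default_factory=dict)
    inference: dict[str, Any] = field(default_factory=dict)
    verbosity: str = "INFO"

    def __post_init__(self) -> None:
        if int(self.n_subjects) < 1:
            raise ValidationError("n_subjects must be >= 1")
        metric = self.tracking.get("metric", "pearson")
        if metric not in METRIC_POLARITY:
            raise ValidationError(
                f"tracking.metric {metric!r} not one of {sorted(METRIC_POLARITY)}")
        scheme = self.inference.get("scheme", "group_sign_flip")
        if scheme not in _SCHEMES:
            raise ValidationError(f"inference.scheme must be one of {_SCHEMES}")
        alt = self.inference.get("alternative", "greater")
        if alt not in _ALTERNATIVES:
            raise ValidationError(f"inference.alternative must be one of {_ALTERNATIVES}")
        norm = self.extraction.get("normalization", "none")
        if norm not in _NORMALIZATIONS:
            raise ValidationError(
                f"extraction.normalization must be one of {_NORMALIZATIONS}")
        if not self.simulate and not self.paths:
            raise ValidationError("config needs a 'simulate' block or input 'paths'")
        for key, p in self.paths.items():
            if not Path(p).exists():
                raise ValidationError(f"paths.{key}: {p} does not exist")

    @classmethod
    def from_file(cls, path, **overrides) -> "AnalysisConfig":
        path = Path(path)
        text = path.read_text()
        if path.suffix in (".yaml", ".yml"):
            import yaml

            raw = yaml.safe_load(text)
        elif path.suffix == ".toml":
            import tomllib

            raw = tomllib.loads(text)
        else:
            raise ValidationError(
                f"unsupported config format {path.suffix!r} (use .yaml or .toml)")
        if not isinstance(raw, dict):
            raise ValidationError("config file must contain a mapping")
        raw.update({k: v for k, v in overrides.items() if v is not None})
        known = set(cls.__dataclass_fields__)
        unknown = set(raw) - known
        if unknown:
            raise ValidationError(f"unknown config keys: {sorted(unknown)}")
        return cls(**raw)

    def as_dict(self) -> dict:
        return asdict(self)
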