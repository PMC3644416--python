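"""Pipeline configuration: schema-validated YAML/JSON settings.

The configuration document has four sections (all optional, all keys typed and
defaulted); unknown keys anywhere are rejected so typos fail loudly.  The
machine-readable schema shipped at ``splinodule/data/config.schema.json``
documents every field; validation itself is done by the small checker below.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import asdict, dataclass, field
from pathlib import Path

import yaml

from .detect import DetectionConfig
from .errors import ConfigurationError

__all__ = ["CompressSettings", "DenoiseSettings", "IOSettings", "PipelineConfig"]


@dataclass
class DenoiseSettings:
    enabled: bool = True
    family: str = "biorthogonal_spline"
    degree: int = 3
    dual_order: int = 2
    levels: int = 3
    mode: str = "soft"
    threshold_policy: str = "per_level"
    threshold: float | None = None


@dataclass
class CompressSettings:
    enabled: bool = False
    family: str = "biorthogonal_spline"
    degree: int = 1
    dual_order: int = 2
    levels: int = 4
    ratio: float = 10.0
    quantization_step: float = 0.0


@dataclass
class IOSettings:
    bit_depth: int = 8
    output_dir: str = "."


@dataclass
class PipelineConfig:
    denoise: DenoiseSettings = field(default_factory=DenoiseSettings)
    compress: CompressSettings = field(default_factory=CompressSettings)
    detect: DetectionConfig = field(default_factory=DetectionConfig)
    io: IOSettings = field(default_factory=IOSettings)
    detect_family: str = "biorthogonal_spline"
    detect_degree: int = 3
    detect_dual_order: int = 2
    seed: int = 0

    @classmethod
    def from_dict(cls, doc: dict) -> "PipelineConfig":
        if not isinstance(doc, dict):
            raise ConfigurationError("configuration root must be a mapping")
        sections = {
            "denoise": DenoiseSettings,
            "compress": CompressSettings,
            "detect": DetectionConfig,
            "io": IOSettings,
        }
        scalars = {"detect_family", "detect_degree", "detect_dual_order", "seed"}
        unknown = set(doc) - set(sections) - scalars
        if unknown:
            raise ConfigurationError(f"unknown configuration keys: {sorted(unknown)}")
        kwargs = {}
        for name, klass in sections.items():
            sub = doc.get(name, {})
            if not isinstance(sub, dict):
                raise ConfigurationError(f"section {name!r} must be a mapping")
            allowed = set(klass.__dataclass_fields__)
            bad = set(sub) - allowed
            if bad:
                raise ConfigurationError(f"unknown keys in {name!r}: {sorted(bad)}")
            try:
                kwargs[name] = klass(**sub)
            except (TypeError, ValueError) as exc:
                raise ConfigurationError(f"invalid {name!r} settings: {exc}") from exc
        for key in scalars:
            if key in doc:
                kwargs[key] = doc[key]
        return cls(**kwargs)

    @classmethod
    def from_file(cls, path) -> "PipelineConfig":
        path = Path(path)
        text = path.read_text()
        try:
            if path.suffix.lower() == ".json":
                doc = json.loads(text)
            else:
                doc = yaml.safe_load(text)
        except (json.JSONDecodeError, yaml.YAMLError) as exc:
            raise ConfigurationError(f"cannot parse {path}: {exc}") from exc
        return cls.from_dict(doc or {})

    def to_dict(self) -> dict:
        return asdict(self)

    def config_hash(self) -> str:
        """Stable digest of the full configuration, for provenance blocks."""
        blob = json.dumps(self.to_dict(), sort_keys=True).encode()
        return hashlib.sha256(blob).hexdigest()[:16]
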