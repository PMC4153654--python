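"""Pipeline configuration: nested dataclasses with a YAML front end.

Every run logs the fully resolved configuration, so a result can always be
traced back to the exact thresholds that produced it.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from pathlib import Path

import yaml

from .filtering import FilterConfig


@dataclass
class IoConfig:
    dialect: str = "tsv"
    decimal_comma: bool = False
    columns: dict[str, str] = field(default_factory=dict)


@dataclass
class LocalizationConfig:
    cutoff_pct: float = 75.0
    inclusive: bool = True


@dataclass
class QuantificationConfig:
    aggregate: str = "mean"  # or "median"
    sig_log2: float = 1.0
    min_nonphospho: int = 10


@dataclass
class AnnotationConfig:
    matrix: str = "BLOSUM62"
    gap_open: float = 11.0
    gap_extend: float = 1.0


@dataclass
class PipelineConfig:
    io: IoConfig = field(default_factory=IoConfig)
    filters: FilterConfig = field(default_factory=FilterConfig)
    localization: LocalizationConfig = field(default_factory=LocalizationConfig)
    quantification: QuantificationConfig = field(
        default_factory=QuantificationConfig
    )
    annotation: AnnotationConfig = field(default_factory=AnnotationConfig)
    seed: int = 0

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)

    @classmethod
    def from_dict(cls, data: dict) -> "PipelineConfig":
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(data) - known
        if unknown:
            raise ValueError(f"unknown config sections: {sorted(unknown)}")
        sections = {}
        for f in dataclasses.fields(cls):
            if f.name not in data:
                continue
            value = data[f.name]
            if f.name == "seed":
                sections["seed"] = int(value)
            else:
                section_cls = {
                    "io": IoConfig,
                    "filters": FilterConfig,
                    "localization": LocalizationConfig,
                    "quantification": QuantificationConfig,
                    "annotation": AnnotationConfig,
                }[f.name]
                valid = {sf.name for sf in dataclasses.fields(section_cls)}
                bad = set(value) - valid
                if bad:
                    raise ValueError(
                        f"unknown keys in [{f.name}]: {sorted(bad)}"
                    )
                sections[f.name] = section_cls(**value)
        return cls(**sections)

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        return cls.from_dict(data)

    def to_yaml(self) -> str:
        return yaml.safe_dump(self.to_dict(), sort_keys=False)
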