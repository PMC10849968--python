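"""Pipeline configuration: one YAML file driving every stage."""

from __future__ import annotations

from dataclasses import asdict, dataclass, field
from pathlib import Path

import yaml

from .dea import DegParams
from .drive import DriveParams
from .jtk import JtkParams
from .preprocess import QcParams
from .transfer import TransferParams

__all__ = ["PipelineConfig"]


@dataclass
class PipelineConfig:
    """Aggregate settings for all stages, YAML round-trippable."""

    qc: QcParams = field(default_factory=QcParams)
    jtk: JtkParams = field(default_factory=JtkParams)
    dea: DegParams = field(default_factory=DegParams)
    drive: DriveParams = field(default_factory=DriveParams)
    transfer: TransferParams = field(default_factory=TransferParams)
    run_effect_alpha: float = 0.001
    run_effect_exclude: list[str] = field(default_factory=list)
    seed: int = 0

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        raw = yaml.safe_load(Path(path).read_text()) or {}
        kwargs = {}
        sections = {
            "qc": QcParams, "jtk": JtkParams, "dea": DegParams,
            "drive": DriveParams, "transfer": TransferParams,
        }
        for key, klass in sections.items():
            if key in raw:
                section = dict(raw[key])
                if key == "qc" and "excluded_conditions" in section:
                    section["excluded_conditions"] = frozenset(section["excluded_conditions"])
                for tup in ("timepoints", "lags"):
                    if key == "jtk" and tup in section:
                        section[tup] = tuple(section[tup])
                kwargs[key] = klass(**section)
        for key in ("run_effect_alpha", "run_effect_exclude", "seed"):
            if key in raw:
                kwargs[key] = raw[key]
        return cls(**kwargs)

    def to_yaml(self, path: str | Path) -> None:
        data = asdict(self)
        data["qc"]["excluded_conditions"] = sorted(self.qc.excluded_conditions)
        data["jtk"]["timepoints"] = list(self.jtk.timepoints)
        data["jtk"]["lags"] = list(self.jtk.lags)
        Path(path).write_text(yaml.safe_dump(data, sort_keys=False))
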