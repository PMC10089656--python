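"""Pipeline configuration: a flat, YAML-serializable record of every choice.

Every stochastic stage carries an explicit seed; a config round-trips
losslessly through ``to_yaml``/``from_yaml``.
"""

from __future__ import annotations

from dataclasses import asdict, dataclass, field
from pathlib import Path

import yaml

from .observer import DEFAULT_SFS

__all__ = ["PipelineConfig"]


@dataclass
class PipelineConfig:
    # data source: simulate, or read an existing tidy table
    simulate: bool = True
    trials_path: str | None = None
    n_observers: int = 1
    scenario: str = "paper-like"
    sfs: tuple[float, ...] = DEFAULT_SFS
    trials_per_sf_hm: int = 160
    trials_per_sf_vm: int = 140
    trials_per_sf_mscale: int = 84
    include_mscale: bool = True

    # model options
    csf_models: tuple[str, ...] = ("LP", "dEXP", "aLP", "DoG", "MS", "HmH", "HmG", "EmG", "YQM")
    n_starts: int = 20
    half_max_on: str = "log"

    # CRF constants
    kappa: float = 11.8
    pl: float = 0.5
    pu: float = 0.99
    pt: float = 0.75

    # seeds (every stochastic stage has one)
    sim_seed: int = 0
    fit_seed: int = 0
    bootstrap_seed: int = 0

    out_dir: str = "vfcsf_out"
    extra: dict = field(default_factory=dict)

    def to_yaml(self, path) -> None:
        payload = asdict(self)
        payload["sfs"] = list(self.sfs)
        payload["csf_models"] = list(self.csf_models)
        Path(path).write_text(yaml.safe_dump(payload, sort_keys=True))

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        payload = yaml.safe_load(Path(path).read_text()) or {}
        if "sfs" in payload:
            payload["sfs"] = tuple(payload["sfs"])
        if "csf_models" in payload:
            payload["csf_models"] = tuple(payload["csf_models"])
        return cls(**payload)
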