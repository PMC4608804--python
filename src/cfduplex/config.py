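"""Run configuration: one YAML file drives every pipeline stage.

The config carries an explicit seed for every stochastic stage and
round-trips losslessly through YAML.
"""
from __future__ import annotations

import dataclasses
from pathlib import Path

import yaml

from .cnv import REPORTABLE_PLASMA_CN, Z_AMPLIFICATION
from .digitize import DEFAULT_SUPERMAJORITY
from .noise import DEFAULT_K, DEFAULT_MIN_SUPPORT
from .qc import QcThresholds
from .simulate import SimParams
from .snv import SnvCallParams


@dataclasses.dataclass
class ConsensusParams:
    min_base_quality: int = 20
    supermajority: float = DEFAULT_SUPERMAJORITY


@dataclasses.dataclass
class NoiseParams:
    k: float = DEFAULT_K
    min_support: int = DEFAULT_MIN_SUPPORT
    germline_exclude_fraction: float = 0.25
    n_normals: int = 5


@dataclasses.dataclass
class CnvParams:
    z_threshold: float = Z_AMPLIFICATION
    reportable_cn: float = REPORTABLE_PLASMA_CN


@dataclasses.dataclass
class RunConfig:
    """Complete run configuration for the CLI pipeline."""

    seed: int = 0
    simulator: SimParams = dataclasses.field(default_factory=SimParams)
    consensus: ConsensusParams = dataclasses.field(default_factory=ConsensusParams)
    noise: NoiseParams = dataclasses.field(default_factory=NoiseParams)
    snv: SnvCallParams = dataclasses.field(default_factory=SnvCallParams)
    cnv: CnvParams = dataclasses.field(default_factory=CnvParams)
    qc: QcThresholds = dataclasses.field(default_factory=QcThresholds)

    def to_yaml(self, path: str | Path) -> None:
        data = dataclasses.asdict(self)
        # tuples become lists in YAML; normalized on load
        with open(path, "w") as fh:
            yaml.safe_dump(data, fh, sort_keys=False)

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        with open(path) as fh:
            data = yaml.safe_load(fh)
        return cls(
            seed=data.get("seed", 0),
            simulator=_build(SimParams, data.get("simulator", {})),
            consensus=_build(ConsensusParams, data.get("consensus", {})),
            noise=_build(NoiseParams, data.get("noise", {})),
            snv=_build(SnvCallParams, data.get("snv", {})),
            cnv=_build(CnvParams, data.get("cnv", {})),
            qc=_build(QcThresholds, data.get("qc", {})),
        )


def _build(cls, data: dict):
    fields = {f.name: f for f in dataclasses.fields(cls)}
    kwargs = {}
    for k, v in data.items():
        if k not in fields:
            raise ValueError(f"unknown {cls.__name__} field {k!r}")
        if isinstance(v, list):
            v = tuple(v)
        kwargs[k] = v
    return cls(**kwargs)
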