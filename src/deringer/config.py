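"""Run configuration: one home for every tunable threshold.

``RunConfig`` gathers the RTV, HRA-loop, LRA-loop and simulation
parameters plus the run seed, and round-trips losslessly through YAML.
"""

from __future__ import annotations

from dataclasses import asdict, dataclass, field, fields

import yaml

from .hra import HRAParams
from .lra import LRAParams
from .rtv import RTVParams
from .simulate import RingSimulationSpec

__all__ = ["RunConfig"]


def _from_mapping(cls, mapping):
    names = {f.name for f in fields(cls)}
    unknown = set(mapping) - names
    if unknown:
        raise ValueError(f"unknown {cls.__name__} keys: {sorted(unknown)}")
    kwargs = dict(mapping)
    for key, value in kwargs.items():
        if isinstance(value, list):
            kwargs[key] = tuple(value)
    return cls(**kwargs)


@dataclass
class RunConfig:
    """Complete parameterisation of a correction / simulation run."""

    rtv: RTVParams = field(default_factory=RTVParams)
    hra: HRAParams = field(default_factory=HRAParams)
    lra: LRAParams = field(default_factory=LRAParams)
    simulation: RingSimulationSpec = field(default_factory=RingSimulationSpec)
    stages: tuple[str, ...] = ("hra", "lra")
    seed: int = 0
    log_level: str = "INFO"

    def __post_init__(self) -> None:
        for stage in self.stages:
            if stage not in ("hra", "lra"):
                raise ValueError(f"unknown stage {stage!r}")

    def to_dict(self) -> dict:
        d = asdict(self)
        d["stages"] = list(self.stages)
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "RunConfig":
        d = dict(d)
        return cls(
            rtv=_from_mapping(RTVParams, d.pop("rtv", {})),
            hra=_from_mapping(HRAParams, d.pop("hra", {})),
            lra=_from_mapping(LRAParams, d.pop("lra", {})),
            simulation=_from_mapping(RingSimulationSpec, d.pop("simulation", {})),
            stages=tuple(d.pop("stages", ("hra", "lra"))),
            **d,
        )

    def to_yaml(self, path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(self.to_dict(), fh, sort_keys=False)

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        with open(path) as fh:
            return cls.from_dict(yaml.safe_load(fh) or {})
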