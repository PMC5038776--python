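"""Run configuration: one serializable object covering every tunable.

A ``RunConfig`` bundles the SCM parameters, patch geometry, similarity
normalizers and metric window, and round-trips losslessly through YAML so a
run can be reproduced from its config file alone. ``cs1``/``cs2`` may be the
string ``"auto"``, resolving to ``3 * n_max`` and ``5 * pi``.
"""

from __future__ import annotations

from dataclasses import asdict, dataclass, field
from pathlib import Path
from typing import Union

import numpy as np
import yaml

from .features import PatchSpec, SimilarityConstants
from .fusion import FusionConfig
from .metrics import SlidingWindowSpec
from .scm import ScmParams

__all__ = ["RunConfig", "load_config", "save_config"]

AutoFloat = Union[float, str]


@dataclass(frozen=True)
class RunConfig:
    f: float = 0.9
    g: float = 0.3
    h: float = 20.0
    n_max: int = 20
    link_radius: int = 1
    threshold_uses_current_pulse: bool = False
    l_p: int = 1
    cs1: AutoFloat = "auto"
    cs2: AutoFloat = "auto"
    window_side: int = 8
    window_step: int = 1
    log_level: str = "INFO"

    def resolve_cs(self) -> SimilarityConstants:
        cs1 = 3.0 * self.n_max if self.cs1 == "auto" else float(self.cs1)
        cs2 = 5.0 * np.pi if self.cs2 == "auto" else float(self.cs2)
        return SimilarityConstants(cs1=cs1, cs2=cs2)

    def fusion_config(self) -> FusionConfig:
        return FusionConfig(
            scm=ScmParams(
                f=self.f,
                g=self.g,
                h=self.h,
                n_max=self.n_max,
                link_radius=self.link_radius,
                threshold_uses_current_pulse=self.threshold_uses_current_pulse,
            ),
            patch=PatchSpec(l_p=self.l_p),
            constants=self.resolve_cs(),
        )

    def window_spec(self) -> SlidingWindowSpec:
        return SlidingWindowSpec(side=self.window_side, step=self.window_step)

    def to_dict(self) -> dict:
        return asdict(self)


def load_config(path) -> RunConfig:
    with open(Path(path)) as fh:
        payload = yaml.safe_load(fh) or {}
    if not isinstance(payload, dict):
        raise ValueError(f"config file {path} must contain a mapping")
    unknown = set(payload) - set(RunConfig.__dataclass_fields__)
    if unknown:
        raise ValueError(f"unknown config keys in {path}: {sorted(unknown)}")
    return RunConfig(**payload)


def save_config(config: RunConfig, path) -> None:
    with open(Path(path), "w") as fh:
        yaml.safe_dump(config.to_dict(), fh, sort_keys=False)
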