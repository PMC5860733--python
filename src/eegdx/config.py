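"""Schema-validated run configuration (YAML-friendly, unknown keys rejected)."""

from __future__ import annotations

from pathlib import Path
from typing import Literal

import yaml
from pydantic import BaseModel, ConfigDict, Field

from .recording import GROUPS

__all__ = ["RunConfig", "CohortSettings", "EpEnSettings", "MorletSettings",
           "SVMSettings", "SelectionSettings"]


class _Strict(BaseModel):
    model_config = ConfigDict(extra="forbid")


class CohortSettings(_Strict):
    n_per_group: dict[str, int] = Field(
        default_factory=lambda: {"SCI": 22, "AD": 49, "MCI": 58, "OtherPath": 40}
    )
    fs: float = 256.0
    duration: float = 20.0
    effect_entropy: float = 1.0
    effect_theta_bursts: float = 0.16
    effect_beta_bursts: float = 0.05
    noise_sd: float = 10.0
    alpha_snr: float = 2.0


class EpEnSettings(_Strict):
    n_states: int = 3
    n_mix: int = 4
    var_floor: float = 1e-3
    rel_tol: float = 1e-4
    max_iter: int = 100
    estimator: Literal["mc", "literal"] = "mc"


class MorletSettings(_Strict):
    cycles: float = 7.0
    f_min: float = 1.0
    f_max: float = 30.0
    f_step: float = 0.5
    max_bumps: int = 50
    min_amplitude: float = 2.0
    agg: Literal["rate", "mean_amplitude", "total_amplitude"] = "rate"


class SVMSettings(_Strict):
    C: float = 1.0
    degree: int = 2
    coef0: float = 1.0
    platt_folds: int = 3


class SelectionSettings(_Strict):
    mode: Literal["nested", "global", "none"] = "nested"
    risk: float = 0.10
    n_probes: int = 100
    probe_kind: Literal["permute", "gauss"] = "permute"


class RunConfig(_Strict):
    """Full end-to-end pipeline configuration."""

    seed: int = 0
    group_scheme: Literal["2", "3", "4"] = "2"
    cohort: CohortSettings = Field(default_factory=CohortSettings)
    epen: EpEnSettings = Field(default_factory=EpEnSettings)
    morlet: MorletSettings = Field(default_factory=MorletSettings)
    svm: SVMSettings = Field(default_factory=SVMSettings)
    selection: SelectionSettings = Field(default_factory=SelectionSettings)
    #: optional restriction of the feature bank (names), e.g. for quick runs
    feature_subset: list[str] | None = None

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        return cls.model_validate(yaml.safe_load(Path(path).read_text()) or {})

    def to_yaml(self, path: str | Path) -> None:
        Path(path).write_text(yaml.safe_dump(self.model_dump(), sort_keys=False))

    def group_labels(self) -> list[str]:
        if self.group_scheme == "2":
            return ["SCI", "AD"]
        if self.group_scheme == "3":
            return ["SCI", "AD", "Other"]
        return list(GROUPS)
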