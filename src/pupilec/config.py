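"""Pipeline configuration with validated defaults.

Unknown keys are rejected so silently misspelled options cannot change an
analysis; the effective configuration is serialized next to every results
tree for provenance.
"""

from __future__ import annotations

from pathlib import Path

import yaml
from pydantic import BaseModel, ConfigDict

__all__ = ["Config"]


class _Strict(BaseModel):
    model_config = ConfigDict(extra="forbid")


class ParadigmConfig(_Strict):
    n_trials_per_run: int = 105
    n_runs: int = 5
    n_subjects: int = 19
    oddball_fraction: float = 0.2
    iti_range: tuple[float, float] = (2.0, 3.0)
    stim_duration: float = 0.2
    first_k_standard: int = 5
    forbid_consecutive_oddballs: bool = True


class PupilConfig(_Strict):
    blink_pad: float = 0.1
    lowpass_hz: float = 4.0
    epoch_window: tuple[float, float] = (-0.5, 2.0)


class DiscriminantConfig(_Strict):
    window_width_ms: float = 50.0
    window_start_ms: float = 0.0
    window_stop_ms: float = 1000.0
    window_step_ms: float = 25.0
    ridge: float = 1.0
    n_permutations: int = 100
    alpha: float = 0.01


class GLMConfig(_Strict):
    tr: float = 2.1
    tau: float = 0.375
    stv_duration: float = 0.1


class ECConfig(_Strict):
    fit_fs: float = 100.0
    coupling_prior_precision: float = 1.0
    noise_prior_shape: float = 0.01
    noise_prior_rate: float = 0.01
    obs_prior_shape: float = 0.01
    obs_prior_rate: float = 0.01
    max_iter: int = 200
    elbo_tol: float = 1.0e-6


class GroupConfig(_Strict):
    alpha: float = 0.05
    significant_only_strengths: bool = False


class Config(_Strict):
    seed: int = 0
    simulate: bool = True
    n_nodes: int = 4
    paradigm: ParadigmConfig = ParadigmConfig()
    pupil: PupilConfig = PupilConfig()
    discriminant: DiscriminantConfig = DiscriminantConfig()
    glm: GLMConfig = GLMConfig()
    ec: ECConfig = ECConfig()
    group: GroupConfig = GroupConfig()

    @classmethod
    def from_yaml(cls, path: str | Path) -> "Config":
        data = yaml.safe_load(Path(path).read_text()) or {}
        return cls(**data)

    def to_yaml(self, path: str | Path) -> None:
        Path(path).write_text(yaml.safe_dump(self.model_dump(), sort_keys=False))
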