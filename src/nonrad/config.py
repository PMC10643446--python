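"""Run-configuration schema (YAML), validated before anything runs.

Unknown keys are rejected with their location; defaults carry the
standard protocol settings (0.5 fs step, 250 fs runs, 300 K sampling,
decoherence parameter 0.1, Arrhenius width 100, 0.1 eV gap criterion).
Atom indices in coordinate definitions may be given 1-based by setting
``index_base: 1``.
"""
from __future__ import annotations

from typing import Literal, Optional, Union

import yaml
from pydantic import BaseModel, ConfigDict, Field, field_validator

from . import geometry, models, tsh


class _Strict(BaseModel):
    model_config = ConfigDict(extra="forbid")


class ModelSection(_Strict):
    name: Literal["carbonyl_lock", "tully", "harmonic"] = "carbonyl_lock"
    params: dict = Field(default_factory=dict)

    def build(self) -> models.DiabaticModel:
        if self.name == "tully":
            return models.build_tully_single_crossing(**self.params)
        if self.name == "harmonic":
            return models.build_uncoupled_harmonic(**self.params)
        return models.build_carbonyl_lock_model(models.CarbonylLockParams(**self.params))


class SamplingSection(_Strict):
    temperature: float = 300.0
    n_samples: int = 200
    burn_in_fs: float = 1000.0
    stride_fs: float = 100.0
    friction_ps: float = 20.0


class DecoherenceSection(_Strict):
    C: float = 0.1
    enabled: bool = True


class DynamicsSection(_Strict):
    dt_fs: float = 0.5
    n_substeps_electronic: int = 20
    t_max_fs: float = 250.0
    gap_stop_ev: float = 0.1
    forbid_recrossing: bool = True
    stop_on_decay_gap: bool = True
    decoherence: DecoherenceSection = Field(default_factory=DecoherenceSection)

    def integrator(self, seed: int) -> tsh.IntegratorConfig:
        return tsh.IntegratorConfig(
            dt_fs=self.dt_fs,
            n_substeps_electronic=self.n_substeps_electronic,
            t_max_fs=self.t_max_fs,
            gap_stop_ev=self.gap_stop_ev,
            forbid_recrossing=self.forbid_recrossing,
            stop_on_decay_gap=self.stop_on_decay_gap,
            seed=seed,
            decoherence=tsh.DecoherenceParams(
                C=self.decoherence.C, enabled=self.decoherence.enabled
            ),
        )


class CoordinateSection(_Strict):
    kind: Literal["distance", "distance_difference", "improper_dihedral"]
    atom_indices: list[int]
    label: str = ""
    index_base: Literal[0, 1] = 0

    def build(self) -> geometry.CoordinateDefinition:
        idx = tuple(i - self.index_base for i in self.atom_indices)
        return geometry.CoordinateDefinition(self.kind, idx, self.label)


class ConstraintSection(_Strict):
    coordinate: Union[int, CoordinateSection]
    k: float = 100.0
    target: Optional[float] = None

    def build(self) -> tsh.ConstraintSpec:
        coord = (
            self.coordinate
            if isinstance(self.coordinate, int)
            else self.coordinate.build()
        )
        return tsh.ConstraintSpec(coordinate=coord, k=self.k, target=self.target)


class AnalysisSection(_Strict):
    alpha: float = 100.0
    temperature: float = 300.0
    align: bool = True
    mass_weight: bool = False
    include_nondecaying: bool = False
    gap_threshold_ev: float = 0.1
    coordinates: list[CoordinateSection] = Field(default_factory=list)


class OutputSection(_Strict):
    directory: str = "results"
    write_xyz: bool = False


class RunConfig(_Strict):
    seed: int = 0
    model: ModelSection = Field(default_factory=ModelSection)
    sampling: SamplingSection = Field(default_factory=SamplingSection)
    dynamics: DynamicsSection = Field(default_factory=DynamicsSection)
    constraints: list[ConstraintSection] = Field(default_factory=list)
    analysis: AnalysisSection = Field(default_factory=AnalysisSection)
    output: OutputSection = Field(default_factory=OutputSection)

    @field_validator("seed")
    @classmethod
    def _seed_range(cls, v: int) -> int:
        if not 0 <= v < 2**31:
            raise ValueError("seed must be in [0, 2^31)")
        return v


def load_config(path: str) -> RunConfig:
    with open(path) as fh:
        raw = yaml.safe_load(fh) or {}
    return RunConfig.model_validate(raw)
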