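"""Pipeline configuration schema (pydantic, strict).

One JSON document configures every stage; unknown keys are rejected and the
whole document round-trips through ``model_dump_json``.  A single global
``seed`` drives every stochastic choice: simulation, splitting, SMOTE,
weight initialisation, shuffling and dropout all derive their generators
from it.
"""

from __future__ import annotations

from pydantic import BaseModel, ConfigDict, Field, model_validator

from .balance import DEFAULT_MULTIPLICITY
from .simulate import TABLE_COUNTS

__all__ = ["PipelineConfig", "demo_config"]


class _Strict(BaseModel):
    model_config = ConfigDict(extra="forbid", validate_assignment=True)


class SimulateSection(_Strict):
    n_per_class: dict[int, int] = Field(default_factory=lambda: dict(TABLE_COUNTS))
    fs_hz: float = 720.0
    record_seconds: float = 60.0
    noise_sd: float = 5.0
    baseline_amp: float = 50.0
    baseline_freq_hz: float = 0.3


class SplitSection(_Strict):
    train: float = 0.6
    val: float = 0.2
    test: float = 0.2
    stratified: bool = True

    @model_validator(mode="after")
    def _fractions_sum(self):
        if abs(self.train + self.val + self.test - 1.0) > 1e-9:
            raise ValueError(
                f"split fractions must sum to 1, got {self.train + self.val + self.test}"
            )
        return self


class SmoteSection(_Strict):
    enabled: bool = False
    k_neighbors: int = 5
    multiplicity: dict[int, int] = Field(default_factory=lambda: dict(DEFAULT_MULTIPLICITY))


class SvmSection(_Strict):
    C: float = 2.0
    gamma: float = 3.0
    grid_search: bool = False


class DcnnSection(_Strict):
    batch_size: int = 8
    max_epochs: int = 1000
    patience: int = 10


class FcnnSection(_Strict):
    batch_size: int = 32
    max_epochs: int = 1000
    patience: int = 10


class StackingSection(_Strict):
    n_folds: int = 5


class PipelineConfig(_Strict):
    simulate: SimulateSection = Field(default_factory=SimulateSection)
    split: SplitSection = Field(default_factory=SplitSection)
    smote: SmoteSection = Field(default_factory=SmoteSection)
    svm: SvmSection = Field(default_factory=SvmSection)
    dcnn: DcnnSection = Field(default_factory=DcnnSection)
    fcnn: FcnnSection = Field(default_factory=FcnnSection)
    stacking: StackingSection = Field(default_factory=StackingSection)
    seed: int = 0
    out_dir: str = "pulse_dssn_out"


def demo_config(seed: int = 0, n_per_class: int = 50) -> PipelineConfig:
    """A small configuration that completes in minutes on one CPU."""
    cfg = PipelineConfig(seed=seed)
    cfg.simulate.n_per_class = {c: n_per_class for c in range(1, 8)}
    cfg.simulate.record_seconds = 15.0
    cfg.dcnn.max_epochs = 40
    return cfg
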