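"""Run configuration: every tunable parameter of every stage, with defaults
equal to the study's stated values where stated.

The configuration serializes losslessly to/from YAML and fans a single
top-level seed out to named per-stage sub-seeds.
"""

from __future__ import annotations

from pathlib import Path
from typing import Literal

import numpy as np
import yaml
from pydantic import BaseModel, Field, model_validator

from .simulate import BOTH, HORMONE, NON_HORMONE, EffectSpec, SimulationTruth

SEED_NAMES = (
    "discovery_cohort", "discovery_ct", "replication_cohort", "split",
    "replication_mfi", "cfs", "ensemble", "report",
)


class EffectParam(BaseModel):
    mirna_id: str
    stratum: Literal["hormone", "non_hormone", "both"]
    log2_effect: float


def _default_effects() -> list[EffectParam]:
    return [
        EffectParam(mirna_id="syn-miR-101", stratum=HORMONE, log2_effect=1.0),
        EffectParam(mirna_id="syn-miR-102", stratum=HORMONE, log2_effect=-1.0),
        EffectParam(mirna_id="syn-miR-103", stratum=NON_HORMONE, log2_effect=1.0),
        EffectParam(mirna_id="syn-miR-104", stratum=NON_HORMONE, log2_effect=-1.0),
        EffectParam(mirna_id="syn-miR-105", stratum=BOTH, log2_effect=1.0),
    ]


class SimulationParams(BaseModel):
    """Synthetic study-shape parameters (cohort sizes mirror the study)."""

    n_cases_discovery: int = 10
    control_ratio_discovery: int = 1
    hormone_fraction_discovery: float = 0.5
    n_cases_replication: int = 54
    control_ratio_replication: int = 2
    hormone_fraction_replication: float = 0.78
    age_range: tuple[int, int] = (13, 25)
    pathology_confirmed_fraction: float = 0.6
    n_mirnas: int = 754
    noise_sd_ct: float = 0.2
    duplicate_sd: float = 0.2
    sample_shift_sd: float = 0.5
    missing_rate: float = 0.02
    noise_sd_log10mfi: float = 0.15
    negative_rate: float = 0.002
    n_literature_probes: int = 8
    n_positive_controls: int = 3
    n_negative_controls: int = 3
    blank_wells: int = 3
    qc_fraction: float = 0.05
    effects: list[EffectParam] = Field(default_factory=_default_effects)
    reference_mirnas: list[str] = Field(
        default_factory=lambda: [f"syn-ref-{i:02d}" for i in range(1, 6)]
    )

    def truth(self) -> SimulationTruth:
        return SimulationTruth(
            effects=tuple(
                EffectSpec(e.mirna_id, e.stratum, e.log2_effect) for e in self.effects
            ),
            reference_mirnas=tuple(self.reference_mirnas),
            noise_sd_ct=self.noise_sd_ct,
            noise_sd_log10mfi=self.noise_sd_log10mfi,
            missing_rate=self.missing_rate,
            duplicate_sd=self.duplicate_sd,
            sample_shift_sd=self.sample_shift_sd,
            negative_rate=self.negative_rate,
        )


class DiscoveryParams(BaseModel):
    max_duplicate_discordance: float = 1.0
    ct_max: float = 34.0
    max_missing_fraction: float = 0.5
    outlier_flagging: bool = True
    outlier_alpha: float = 0.05
    impute_strategy: Literal["cell_mean", "grand_mean"] = "cell_mean"
    k_references: int = 5
    normfinder_shrinkage: bool = False
    p_strict: float = 0.005
    p_both: float = 0.05
    welch: bool = False


class ReplicationParams(BaseModel):
    shift_value: float = 0.001
    subtract_background: bool = False
    train_fraction: float = 2.0 / 3.0
    split_strata: tuple[str, ...] = ("group", "hormone_use")
    p_gate: float = 0.15
    cfs_folds: int = 10
    min_fold_fraction: float = 0.5
    stall_limit: int = 5
    exhaustive_max: int = 15
    locally_predictive: bool = False


class MlpParams(BaseModel):
    n_networks: int = 15000
    top_k: int = 50
    max_iter: int = 150
    l2: float = 1e-4


class EvaluationParams(BaseModel):
    threshold: float = 0.5
    ci_level: float = 0.95
    ci_method: Literal["clopper-pearson", "wilson"] = "clopper-pearson"


class RunConfig(BaseModel):
    seed: int = 0
    sensitivity_pathology_confirmed_only: bool = False
    simulation: SimulationParams = Field(default_factory=SimulationParams)
    discovery: DiscoveryParams = Field(default_factory=DiscoveryParams)
    replication: ReplicationParams = Field(default_factory=ReplicationParams)
    mlp: MlpParams = Field(default_factory=MlpParams)
    evaluation: EvaluationParams = Field(default_factory=EvaluationParams)

    def sub_seeds(self) -> dict[str, int]:
        """Named per-stage seeds fanned out from the top-level seed."""
        state = np.random.SeedSequence(self.seed).generate_state(len(SEED_NAMES))
        return {name: int(s & 0x7FFFFFFF) for name, s in zip(SEED_NAMES, state)}

    @classmethod
    def test_profile(cls, seed: int = 0, **overrides) -> "RunConfig":
        """Reduced-sweep profile for quick runs: 200 networks instead of the
        full 15,000; everything else at study-shape defaults."""
        cfg = cls(seed=seed, **overrides)
        return cfg.model_copy(update={"mlp": MlpParams(n_networks=200)})

    def to_yaml(self) -> str:
        return yaml.safe_dump(self.model_dump(mode="json"), sort_keys=True)

    @classmethod
    def from_yaml(cls, text: str) -> "RunConfig":
        return cls.model_validate(yaml.safe_load(text))

    @classmethod
    def load(cls, path: str | Path) -> "RunConfig":
        return cls.from_yaml(Path(path).read_text())
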