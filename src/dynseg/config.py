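"""Configuration objects for the synthetic cohort and the full pipeline.

All randomness in the package flows from the integer ``seed`` carried here,
expanded with :class:`numpy.random.SeedSequence` so that every stage draws
from an independent, reproducible stream.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict
from pathlib import Path

import yaml

__all__ = ["CohortConfig", "WindowConfig", "StateConfig", "ModularityConfig",
           "BehaviorConfig", "PipelineConfig", "load_config"]


@dataclass
class CohortConfig:
    """Study conditions for the synthetic cohort generator.

    The defaults are the desk-scale study: 40 subjects, 60 nodes in 4
    networks, 700 scans, 8 stimuli repeated 98 times during learning, and a
    cross-subject correlation of -0.5 between the brain-state transition
    rate and the behavioral learning rate (habit strength uncoupled).
    """

    n_subjects: int = 40
    n_nodes: int = 60
    n_networks: int = 4
    scans_per_subject: int = 700
    trials_per_subject: int = 784        # phase-2 learning trials (stimuli x repetitions)
    n_repetitions: int = 98
    phase3_trials_per_condition: int = 80
    tr_seconds: float = 2.0

    # latent connectivity states (correlation values of the block covariances)
    within_r_integrated: float = 0.25
    between_r_integrated: float = 0.20
    within_r_segregated: float = 0.55
    between_r_segregated: float = -0.10
    noise_sd: float = 0.5
    n_segments: int = 100                # ~7-scan state dwell at the default scale

    # cross-subject coupling structure
    coupling_rho: float = -0.5           # corr(transition_rate, learning_rate)
    habit_rho: float = 0.0

    # subject-parameter population distributions
    transition_rate_mean: float = 4.0
    transition_rate_sd: float = 1.5
    transition_midpoint: float = 0.5
    learning_rate_mean: float = -0.38    # learning rate = -(power-law exponent b)
    learning_rate_sd: float = 0.16
    habit_mean: float = 0.13
    habit_sd: float = 0.28

    # drift-diffusion forward model
    drift_alpha: float = 0.38
    drift_vmax: float = 2.5
    ddm_a_mean: float = 1.6
    ddm_a_sd: float = 0.10
    ddm_ter_mean: float = 0.30
    ddm_ter_sd: float = 0.03
    ddm_z: float = 0.5

    seed: int = 0

    def validate(self) -> None:
        for name in ("within_r_integrated", "between_r_integrated",
                     "within_r_segregated", "between_r_segregated"):
            if abs(getattr(self, name)) >= 1:
                raise ValueError(f"{name} must have magnitude < 1")
        if not abs(self.coupling_rho) < 1:
            raise ValueError("|coupling_rho| must be < 1")
        if not abs(self.habit_rho) < 1:
            raise ValueError("|habit_rho| must be < 1")
        if self.within_r_segregated <= self.within_r_integrated:
            raise ValueError("segregated state must have stronger within-network correlation")
        if self.between_r_segregated >= self.between_r_integrated:
            raise ValueError("segregated state must have weaker between-network correlation")
        for name in ("n_subjects", "n_nodes", "n_networks", "scans_per_subject",
                     "trials_per_subject", "n_repetitions", "n_segments"):
            if getattr(self, name) < 0 or (name != "n_subjects" and getattr(self, name) == 0):
                raise ValueError(f"{name} must be positive")
        if self.noise_sd <= 0:
            raise ValueError("noise_sd must be positive")
        if self.n_networks > self.n_nodes:
            raise ValueError("more networks than nodes")


@dataclass
class WindowConfig:
    n_windows: int = 20
    mode: str = "half_overlap"           # or "non_overlapping"
    theta_override: float | None = None  # taper decay; default window_length / 3


@dataclass
class StateConfig:
    k: int = 2
    replicates: int = 10


@dataclass
class ModularityConfig:
    gamma: float = 1.0
    n_runs: int = 10
    consensus: bool = True
    tau: float = 0.5


@dataclass
class BehaviorConfig:
    bin_width: int = 7
    fit_method: str = "lar"              # "lar" or "ls"
    min_trials_per_bin: int = 20


@dataclass
class PipelineConfig:
    cohort: CohortConfig = field(default_factory=CohortConfig)
    windows: WindowConfig = field(default_factory=WindowConfig)
    states: StateConfig = field(default_factory=StateConfig)
    modularity: ModularityConfig = field(default_factory=ModularityConfig)
    behavior: BehaviorConfig = field(default_factory=BehaviorConfig)
    highpass_seconds: float = 128.0
    skip_behavior: bool = False
    skip_states: bool = False
    seed: int = 0

    def validate(self) -> None:
        self.cohort.validate()
        if self.windows.mode not in ("non_overlapping", "half_overlap"):
            raise ValueError("windows.mode must be non_overlapping or half_overlap")

    def to_dict(self) -> dict:
        return asdict(self)

    @classmethod
    def from_dict(cls, d: dict) -> "PipelineConfig":
        kwargs = dict(d)
        sub = {"cohort": CohortConfig, "windows": WindowConfig, "states": StateConfig,
               "modularity": ModularityConfig, "behavior": BehaviorConfig}
        for key, typ in sub.items():
            if key in kwargs and isinstance(kwargs[key], dict):
                kwargs[key] = typ(**kwargs[key])
        cfg = cls(**kwargs)
        # the pipeline seed is authoritative for every stage
        cfg.cohort.seed = cfg.seed
        return cfg


def load_config(path: str | Path) -> PipelineConfig:
    """Read a pipeline configuration from a YAML file."""
    with open(path) as fh:
        raw = yaml.safe_load(fh) or {}
    cfg = PipelineConfig.from_dict(raw)
    cfg.validate()
    return cfg
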