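"""Run-level configuration: one JSON object describing a full pipeline run.

A ``RunConfig`` bundles the scenario constants, the cohort design, the
synthetic-population hyperparameters, the MCMC settings and the master
seed, so a study plus its analysis is reproducible from a single file.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass, field
from pathlib import Path

from .bayes import MCMCConfig
from .engine import EPSILON_BY_LEVEL, LEVEL_ORDER
from .scenario import ScenarioConfig


@dataclass(frozen=True)
class PopulationConfig:
    """Hyperparameters of the synthetic participant population."""

    sigma_u: float = 1.0
    weights: tuple = (0.59, 0.29, 0.12)
    p_verbal_given_response: float = 0.8
    p_physical_given_response: float = 0.4

    def __post_init__(self) -> None:
        if self.sigma_u < 0:
            raise ValueError("sigma_u must be >= 0")


@dataclass(frozen=True)
class RunConfig:
    """Everything one pipeline run needs, serialisable as JSON.

    ``groups`` maps cohort label to epsilon and must follow the
    None -> Medium -> High design when emulating the original study.
    """

    scenario: ScenarioConfig = field(default_factory=ScenarioConfig)
    groups: tuple = tuple(EPSILON_BY_LEVEL.items())
    n_per_group: int = 15
    population: PopulationConfig = field(default_factory=PopulationConfig)
    mcmc: MCMCConfig = field(default_factory=MCMCConfig)
    master_seed: int = 0
    output_dir: str = "study_out"

    def __post_init__(self) -> None:
        labels = tuple(label for label, _ in self.groups)
        if labels != LEVEL_ORDER:
            raise ValueError(f"groups must be ordered {LEVEL_ORDER}, got {labels}")
        for label, eps in self.groups:
            if not (0.0 <= eps <= 1.0):
                raise ValueError(f"epsilon for {label} must be in [0, 1], got {eps}")
        if self.n_per_group < 1:
            raise ValueError("n_per_group must be >= 1")

    def to_json(self) -> str:
        obj = {
            "scenario": json.loads(self.scenario.to_json()),
            "groups": [[label, eps] for label, eps in self.groups],
            "n_per_group": self.n_per_group,
            "population": asdict(self.population),
            "mcmc": {
                "iterations": self.mcmc.iterations,
                "chains": self.mcmc.chains,
                "warmup": self.mcmc.warmup,
                "seed": self.mcmc.seed,
            },
            "master_seed": self.master_seed,
            "output_dir": self.output_dir,
        }
        return json.dumps(obj, indent=2)

    @classmethod
    def from_json(cls, text: str) -> "RunConfig":
        obj = json.loads(text)
        pop = obj.get("population", {})
        if "weights" in pop:
            pop["weights"] = tuple(pop["weights"])
        return cls(
            scenario=ScenarioConfig(**obj.get("scenario", {})),
            groups=tuple((label, eps) for label, eps in obj.get(
                "groups", [[k, v] for k, v in EPSILON_BY_LEVEL.items()]
            )),
            n_per_group=obj.get("n_per_group", 15),
            population=PopulationConfig(**pop),
            mcmc=MCMCConfig(**obj.get("mcmc", {})),
            master_seed=obj.get("master_seed", 0),
            output_dir=obj.get("output_dir", "study_out"),
        )

    @classmethod
    def from_file(cls, path) -> "RunConfig":
        return cls.from_json(Path(path).read_text())
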