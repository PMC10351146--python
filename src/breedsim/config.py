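"""Run configuration: schema, validation, scaling and file loading.

The defaults reproduce the full-scale breeding-program design: a
29-chromosome genome with 1800 evenly spaced loci per 100-cM chromosome,
a 2200-generation historical population (2000 -> 200 -> 1000), cohorts of
6000 males and 6000 females, 120 sires under pedigree selection, 40 sires
under optimum contribution selection with a kinship-rate target of 0.005,
an 8-generation data window for genomic evaluation, and 360,000 sampled
pairs for the empirical mean kinship.

A single ``scale`` factor in (0, 1] shrinks every count (cohort sizes,
loci, QTL, sires, historical population sizes and phase durations, sampled
pairs) to produce statistically comparable desk-scale runs.
"""

from __future__ import annotations

from pathlib import Path
from typing import Optional

import yaml
from pydantic import BaseModel, ConfigDict, Field, ValidationError, field_validator

__all__ = [
    "GenomeConfig",
    "ProgramConfig",
    "EvaluationConfig",
    "OCSConfig",
    "MetricsConfig",
    "StatsConfig",
    "RunConfig",
    "load_config",
    "ConfigError",
]


class ConfigError(ValueError):
    """Raised when a configuration file fails schema validation."""


class TrajectoryPhase(BaseModel):
    """One phase of the historical population-size trajectory.

    ``size`` is the population size at the end of the phase; sizes change
    linearly per generation from the previous phase's size.
    """

    model_config = ConfigDict(extra="forbid")

    size: int = Field(gt=1)
    generations: int = Field(gt=0)


class GenomeConfig(BaseModel):
    model_config = ConfigDict(extra="forbid")

    n_chromosomes: int = Field(default=29, gt=0)
    loci_per_chromosome: int = Field(default=1800, gt=0)
    chromosome_length: float = Field(default=1.0, gt=0, description="Morgan")
    mutation_rate: float = Field(default=2e-5, ge=0.0, lt=1.0)
    historical_trajectory: list[TrajectoryPhase] = Field(
        default_factory=lambda: [
            TrajectoryPhase(size=2000, generations=2000),
            TrajectoryPhase(size=200, generations=100),
            TrajectoryPhase(size=1000, generations=100),
        ]
    )
    n_qtl: int = Field(default=3000, gt=0)
    n_neutral: int = Field(default=3000, gt=0)
    base_males: int = Field(default=6000, gt=0)
    base_females: int = Field(default=6000, gt=0)

    @field_validator("historical_trajectory")
    @classmethod
    def _non_empty(cls, v):
        if not v:
            raise ValueError("historical_trajectory must have at least one phase")
        return v


class ProgramConfig(BaseModel):
    model_config = ConfigDict(extra="forbid")

    generations: int = Field(default=20, gt=0, description="selection events; cohorts 0..generations")
    pedigree_generations: int = Field(
        default=5, gt=0, description="cohorts bred before genomic selection starts"
    )
    n_sires_pblup: int = Field(default=120, gt=1)
    n_sires_ocs: int = Field(default=40, gt=1)
    calves_per_dam: int = Field(default=2, ge=2)


class EvaluationConfig(BaseModel):
    model_config = ConfigDict(extra="forbid")

    heritability: float = Field(default=0.4, gt=0.0, lt=1.0)
    window_generations: int = Field(default=8, gt=0)
    ssgblup_rounds: int = Field(default=3, ge=0, description="genomic rounds using ssGBLUP before switching to GBLUP")
    always_gblup: bool = False
    n_genotyped_males: int = Field(default=2000, gt=1)
    blend_weight: float = Field(default=0.95, gt=0.0, le=1.0)


class OCSConfig(BaseModel):
    model_config = ConfigDict(extra="forbid")

    delta_f: float = Field(default=0.005, ge=0.0, lt=1.0)
    max_enumeration: int = Field(default=100_000, gt=0)


class MetricsConfig(BaseModel):
    model_config = ConfigDict(extra="forbid")

    n_kinship_pairs: int = Field(default=360_000, gt=0)
    maf_threshold: float = Field(default=0.001, ge=0.0, lt=0.5)
    genic_variance_factor2: bool = False


class StatsConfig(BaseModel):
    model_config = ConfigDict(extra="forbid")

    alpha: float = Field(default=0.05, gt=0.0, lt=1.0)


class RunConfig(BaseModel):
    model_config = ConfigDict(extra="forbid")

    scale: float = Field(default=1.0, gt=0.0, le=1.0)
    master_seed: int = 1
    out_dir: str = "runs"
    genome: GenomeConfig = Field(default_factory=GenomeConfig)
    program: ProgramConfig = Field(default_factory=ProgramConfig)
    evaluation: EvaluationConfig = Field(default_factory=EvaluationConfig)
    ocs: OCSConfig = Field(default_factory=OCSConfig)
    metrics: MetricsConfig = Field(default_factory=MetricsConfig)
    stats: StatsConfig = Field(default_factory=StatsConfig)

    def scaled(self) -> "RunConfig":
        """Resolve ``scale`` into concrete counts and return a scale-1 config.

        Historical phase durations shrink with population sizes so that the
        per-phase drift (generations / 2N) is preserved.
        """
        s = self.scale
        if s == 1.0:
            return self

        def c(x: int, lo: int = 1) -> int:
            return max(lo, round(x * s))

        cfg = self.model_copy(deep=True)
        g = cfg.genome
        g.loci_per_chromosome = c(g.loci_per_chromosome)
        g.n_qtl = c(g.n_qtl)
        g.n_neutral = c(g.n_neutral)
        g.base_males = c(g.base_males, 2)
        g.base_females = c(g.base_females, 2)
        g.historical_trajectory = [
            TrajectoryPhase(size=max(4, round(p.size * s)), generations=c(p.generations))
            for p in g.historical_trajectory
        ]
        p = cfg.program
        p.n_sires_pblup = c(p.n_sires_pblup, 2)
        p.n_sires_ocs = c(p.n_sires_ocs, 2)
        e = cfg.evaluation
        e.n_genotyped_males = c(e.n_genotyped_males, 2)
        m = cfg.metrics
        m.n_kinship_pairs = max(100, round(m.n_kinship_pairs * s * s))
        cfg.scale = 1.0
        return cfg


def load_config(path: Optional[str | Path] = None) -> RunConfig:
    """Load and validate a YAML configuration file.

    An absent path or an empty file yields the full-scale defaults.
    Unknown keys and invalid values raise :class:`ConfigError` with the
    offending field path in the message.
    """
    data = {}
    if path is not None:
        text = Path(path).read_text()
        data = yaml.safe_load(text) or {}
        if not isinstance(data, dict):
            raise ConfigError(f"config root must be a mapping, got {type(data).__name__}")
    try:
        return RunConfig.model_validate(data)
    except ValidationError as exc:
        lines = []
        for err in exc.errors():
            loc = ".".join(str(x) for x in err["loc"])
            lines.append(f"{loc}: {err['msg']}")
        raise ConfigError("invalid configuration: " + "; ".join(lines)) from exc
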