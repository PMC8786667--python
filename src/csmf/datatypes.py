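"""Shared dataclasses: study records, envelopes, exogenous series, config."""

from __future__ import annotations

from dataclasses import dataclass, field
from enum import Enum
from pathlib import Path
from typing import Sequence

import numpy as np
import yaml

from .taxonomy import AgeGroup


class SourceType(str, Enum):
    VA_STUDY = "va_study"
    VR_COUNTRY_YEAR = "vr_country_year"


class ExogenousCause(str, Enum):
    MEASLES = "measles"
    HIV = "hiv"
    TETANUS = "tetanus"
    MALARIA_REPORTED = "malaria_reported"
    TB_PULMONARY = "tb_pulmonary"
    TB_EXTRAPULMONARY = "tb_extrapulmonary"


class CrisisType(str, Enum):
    NATURAL_DISASTER = "natural_disaster"
    CONFLICT_MALNUTRITION = "conflict_malnutrition"
    EPIDEMIC_CONGENITAL = "epidemic_congenital"
    PRO_RATA = "pro_rata"


@dataclass
class StudyDataset:
    """One study's (or VR country-year's) reported-cause death counts.

    ``reported_causes`` are the categories the study actually distinguishes;
    they need not match the taxonomy's true causes — the study's
    misclassification matrix maps true causes onto them.
    """

    study_id: str
    country: str
    midyear: int
    age_group: AgeGroup
    reported_causes: tuple[str, ...]
    deaths: np.ndarray  # int counts aligned to reported_causes
    covariates: np.ndarray  # aligned to a shared covariate-name list
    covariate_names: tuple[str, ...]
    nationally_representative: bool = False
    source_type: SourceType = SourceType.VA_STUDY

    def __post_init__(self) -> None:
        self.deaths = np.asarray(self.deaths, dtype=np.int64)
        self.covariates = np.asarray(self.covariates, dtype=float)
        if len(set(self.reported_causes)) != len(self.reported_causes):
            raise ValueError(f"{self.study_id}: reported causes not unique")
        if (self.deaths < 0).any():
            raise ValueError(f"{self.study_id}: negative death counts")
        if len(self.deaths) != len(self.reported_causes):
            raise ValueError(f"{self.study_id}: deaths/causes length mismatch")
        if not np.isfinite(self.covariates).all():
            raise ValueError(f"{self.study_id}: non-finite covariates")

    @property
    def total_deaths(self) -> int:
        return int(self.deaths.sum())

    @property
    def empirical_fractions(self) -> np.ndarray:
        n = self.total_deaths
        if n == 0:
            return np.full(len(self.deaths), np.nan)
        return self.deaths / n


@dataclass
class MortalityEnvelope:
    """All-cause expected deaths for one country-year-age group."""

    country: str
    year: int
    age_group: AgeGroup
    deaths: float
    livebirths: float
    draw_sd_log: float = 0.0

    def __post_init__(self) -> None:
        if self.deaths < 0:
            raise ValueError(f"{self.country} {self.year}: negative envelope deaths")
        if self.livebirths <= 0:
            raise ValueError(f"{self.country} {self.year}: livebirths must be > 0")

    @property
    def rate(self) -> float:
        """All-cause deaths per 1000 livebirths."""
        return self.deaths / self.livebirths * 1000.0


@dataclass
class ExogenousCauseSeries:
    """Single-cause death estimate supplied from outside the model
    (WHO measles/tetanus programmes, UNAIDS HIV, World Malaria Report, TB)."""

    country: str
    year: int
    age_group: AgeGroup
    cause: ExogenousCause
    deaths: float
    draw_sd_log: float = 0.0

    def __post_init__(self) -> None:
        if self.deaths < 0:
            raise ValueError(f"{self.country} {self.year} {self.cause}: negative deaths")


@dataclass
class CrisisEvent:
    """Short, large mortality shock attributed outside the regression model."""

    country: str
    year_start: int
    year_end: int
    age_group: AgeGroup
    crisis_deaths: float
    crisis_type: CrisisType

    def __post_init__(self) -> None:
        if self.year_end - self.year_start + 1 >= 5:
            raise ValueError("crisis span must be shorter than 5 years")
        if self.crisis_deaths <= 10:
            raise ValueError("crisis events require more than ten deaths")


@dataclass
class CountryCauseEstimate:
    """Final per-country-year-cause output row."""

    country: str
    year: int
    age_group: AgeGroup
    cause: str
    fraction: float
    deaths: float
    rate: float  # per 1000 livebirths
    lower: float = np.nan
    upper: float = np.nan


@dataclass
class MCMCSettings:
    n_chains: int = 4
    n_iter: int = 5000  # post-burn-in iterations per chain
    burn_in: int = 2500
    seed: int = 0
    init_retries: int = 5


@dataclass
class PipelineConfig:
    """All tunable knobs, serialisable to/from YAML."""

    lambda_grid: tuple[float, ...] = (0.5, 1.0, 2.0, 4.0, 8.0, 16.0)
    sigma_bound_high: float = 0.14
    sigma_bound_low: float = 0.01
    intercept_sd: float = 10.0
    per_contrast_sigma: bool = False
    mcmc: MCMCSettings = field(default_factory=MCMCSettings)
    cv_mcmc: MCMCSettings = field(
        default_factory=lambda: MCMCSettings(n_chains=2, n_iter=600, burn_in=400)
    )
    n_folds: int = 5
    cv_metric: str = "mae"  # or "mse"
    one_se_multiplier: float = 1.0
    strata_thresholds: dict = field(
        default_factory=lambda: {
            AgeGroup.NEONATAL: (10.0, 20.0),
            AgeGroup.CHILD_1TO59M: (25.0, 35.0),
        }
    )
    exogenous_cap_share: float = 0.9
    vaccine_ve_paf: dict = field(
        default_factory=lambda: {"hib": 0.15, "pcv": 0.12, "rotavirus": 0.20}
    )
    n_draws: int = 500
    seed: int = 0

    def __post_init__(self) -> None:
        if self.sigma_bound_high > 0.14:
            raise ValueError("sigma_bound_high may not exceed 0.14")
        if any(l <= 0 for l in self.lambda_grid):
            raise ValueError("lambda grid must be positive")
        for ag, (lo, hi) in self.strata_thresholds.items():
            if not lo < hi:
                raise ValueError(f"strata thresholds for {ag} must satisfy low < high")

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        raw = yaml.safe_load(Path(path).read_text()) or {}
        if "mcmc" in raw:
            raw["mcmc"] = MCMCSettings(**raw["mcmc"])
        if "cv_mcmc" in raw:
            raw["cv_mcmc"] = MCMCSettings(**raw["cv_mcmc"])
        if "strata_thresholds" in raw:
            raw["strata_thresholds"] = {
                AgeGroup(k): tuple(v) for k, v in raw["strata_thresholds"].items()
            }
        return cls(**raw)

    def to_yaml(self, path: str | Path) -> None:
        d = {
            "lambda_grid": list(self.lambda_grid),
            "sigma_bound_high": self.sigma_bound_high,
            "sigma_bound_low": self.sigma_bound_low,
            "intercept_sd": self.intercept_sd,
            "per_contrast_sigma": self.per_contrast_sigma,
            "mcmc": vars(self.mcmc),
            "cv_mcmc": vars(self.cv_mcmc),
            "n_folds": self.n_folds,
            "cv_metric": self.cv_metric,
            "one_se_multiplier": self.one_se_multiplier,
            "strata_thresholds": {
                k.value: list(v) for k, v in self.strata_thresholds.items()
            },
            "exogenous_cap_share": self.exogenous_cap_share,
            "vaccine_ve_paf": dict(self.vaccine_ve_paf),
            "n_draws": self.n_draws,
            "seed": self.seed,
        }
        Path(path).write_text(yaml.safe_dump(d, sort_keys=False))
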