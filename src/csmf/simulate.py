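"""Ground-truthed synthetic inputs with the statistical structure the
analysis assumes.

The generator emulates the moving parts of the real estimation problem at
desk scale: a standardised country-year covariate panel that is smooth in
time; multi-study multinomial death counts whose true-cause log odds
follow a sparse linear model in the covariates plus bounded study-level
random effects; study-specific cause-list aggregation (some studies merge
causes into coarser reported categories); declining all-cause envelope
series that cross the mortality-strata thresholds; and exogenous
single-cause series as shares of the envelope with lognormal noise.
Ground truth (coefficients, random effects, per-study true fractions) is
returned alongside so parameter recovery is checkable end-to-end.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .datatypes import (
    ExogenousCause,
    ExogenousCauseSeries,
    MortalityEnvelope,
    SourceType,
    StudyDataset,
)
from .io import load_region_lookup
from .misclassification import MisclassMatrix, build_matrix
from .model import _expand_eta, softmax_fractions
from .taxonomy import AgeGroup, CauseTaxonomy


@dataclass
class GroundTruth:
    """Generating parameters and latent quantities behind a synthetic bundle."""

    beta: np.ndarray  # (C-1, 1+K), base-cause contrast implicitly zero
    sigma: float
    study_effects: np.ndarray = field(default_factory=lambda: np.empty((0, 0)))
    true_fractions: np.ndarray = field(default_factory=lambda: np.empty((0, 0)))

    def __post_init__(self) -> None:
        if self.true_fractions.size:
            sums = self.true_fractions.sum(axis=-1)
            if not np.allclose(sums, 1.0):
                raise ValueError("true fraction vectors must sum to 1")


def _country_codes(n: int) -> list[str]:
    codes = sorted(load_region_lookup())
    if n > len(codes):
        raise ValueError(f"at most {len(codes)} countries supported")
    return codes[:n]


def generate_covariates(
    n_countries: int,
    n_years: int,
    n_covariates: int,
    seed: int,
    rho: float = 0.8,
    start_year: int = 2000,
) -> pd.DataFrame:
    """Standardised country-year covariate panel, AR(1)-smooth in time.

    Each covariate follows an independent stationary AR(1) per country
    with autocorrelation ``rho``; columns are standardised to mean 0,
    SD 1 over the whole panel.  Countries are real ISO3 codes drawn from
    the bundled region lookup so downstream IO validation passes.
    """
    if min(n_countries, n_years, n_covariates) <= 0:
        raise ValueError("all dimensions must be positive")
    rng = np.random.default_rng(seed)
    countries = _country_codes(n_countries)
    innov_sd = np.sqrt(1.0 - rho**2) if abs(rho) < 1 else 1.0
    X = np.empty((n_countries, n_years, n_covariates))
    X[:, 0, :] = rng.standard_normal((n_countries, n_covariates))
    for t in range(1, n_years):
        X[:, t, :] = rho * X[:, t - 1, :] + innov_sd * rng.standard_normal(
            (n_countries, n_covariates)
        )
    flat = X.reshape(-1, n_covariates)
    flat = (flat - flat.mean(axis=0)) / flat.std(axis=0)
    df = pd.DataFrame(flat, columns=[f"x{k+1}" for k in range(n_covariates)])
    df.insert(0, "year", np.tile(np.arange(start_year, start_year + n_years), n_countries))
    df.insert(0, "country", np.repeat(countries, n_years))
    return df


def sparse_truth(
    taxonomy: CauseTaxonomy,
    n_covariates: int,
    n_nonzero: int = 2,
    effect_size: float = 0.5,
    sigma: float = 0.14,
    intercept_scale: float = 0.5,
    seed: int = 0,
) -> GroundTruth:
    """A sparse generating coefficient matrix: ``n_nonzero`` covariates get
    alternating-sign effects of ``effect_size`` on every cause contrast;
    the rest are exactly zero.  Intercepts are mildly dispersed so cause
    fractions are unequal but none is rare."""
    rng = np.random.default_rng(seed)
    Cm1 = taxonomy.n_causes - 1
    beta = np.zeros((Cm1, 1 + n_covariates))
    beta[:, 0] = rng.normal(0.0, intercept_scale, Cm1)
    active = rng.choice(n_covariates, size=n_nonzero, replace=False)
    for j, k in enumerate(active):
        signs = np.where((np.arange(Cm1) + j) % 2 == 0, 1.0, -1.0)
        beta[:, 1 + k] = signs * effect_size
    return GroundTruth(beta=beta, sigma=sigma)


def full_reporting_pattern(taxonomy: CauseTaxonomy) -> dict[str, str]:
    return {c: c for c in taxonomy.causes}


def merged_reporting_pattern(
    taxonomy: CauseTaxonomy, merge_into_other: tuple[str, ...]
) -> dict[str, str]:
    """Pattern folding the named causes into the residual 'other' category."""
    return {
        c: ("other" if c in merge_into_other else c) for c in taxonomy.causes
    }


def generate_studies(
    truth: GroundTruth,
    covariates: pd.DataFrame,
    taxonomy: CauseTaxonomy,
    study_sizes: list[int],
    reporting_patterns: list[dict[str, str]] | None = None,
    seed: int = 0,
    age_group: AgeGroup | None = None,
    representative_every: int = 0,
) -> tuple[list[StudyDataset], list[MisclassMatrix], GroundTruth]:
    """Simulate studies from the multinomial-logit model.

    For study s at a sampled covariate row: eta = x'beta + u_s with
    u_s ~ Normal(0, sigma) per contrast, p = softmax(eta), and reported
    deaths ~ Multinomial(N_s, G_s p).  ``reporting_patterns`` cycles over
    studies (default: all full reporting).  Returns the studies, their
    aggregation matrices, and the ground truth augmented with the drawn
    random effects and per-study true fractions.
    """
    rng = np.random.default_rng(seed)
    age_group = age_group or taxonomy.age_group
    cov_cols = [c for c in covariates.columns if c.startswith("x")]
    K = len(cov_cols)
    if truth.beta.shape != (taxonomy.n_causes - 1, 1 + K):
        raise ValueError("truth.beta shape inconsistent with taxonomy/covariates")
    patterns = reporting_patterns or [full_reporting_pattern(taxonomy)]
    for pat in patterns:
        missing = [c for c in taxonomy.causes if c not in pat]
        if missing:
            raise ValueError(f"reporting pattern leaves causes unmapped: {missing}")

    S = len(study_sizes)
    rows = covariates.iloc[rng.integers(0, len(covariates), size=S)]
    u = rng.normal(0.0, truth.sigma, size=(S, taxonomy.n_causes - 1)) if truth.sigma > 0 else np.zeros((S, taxonomy.n_causes - 1))

    studies, matrices, fractions = [], [], []
    for s, (N, (_, row)) in enumerate(zip(study_sizes, rows.iterrows())):
        x = row[cov_cols].to_numpy(dtype=float)
        contrasts = truth.beta @ np.concatenate([[1.0], x]) + u[s]
        p = softmax_fractions(_expand_eta(contrasts, taxonomy.base_index))
        fractions.append(p)
        pat = patterns[s % len(patterns)]
        reported = tuple(dict.fromkeys(pat[c] for c in taxonomy.causes))
        m = build_matrix(taxonomy, reported, pat, study_id=f"S{s:03d}")
        q = m.G @ p
        deaths = rng.multinomial(N, q)
        studies.append(
            StudyDataset(
                study_id=f"S{s:03d}",
                country=str(row["country"]),
                midyear=int(row["year"]),
                age_group=age_group,
                reported_causes=reported,
                deaths=deaths,
                covariates=x,
                covariate_names=tuple(cov_cols),
                nationally_representative=(
                    representative_every > 0 and s % representative_every == 0
                ),
                source_type=SourceType.VA_STUDY,
            )
        )
        matrices.append(m)

    full_truth = GroundTruth(
        beta=truth.beta,
        sigma=truth.sigma,
        study_effects=u,
        true_fractions=np.array(fractions),
    )
    return studies, matrices, full_truth


def generate_envelope_series(
    n_countries: int,
    years: range | list[int],
    seed: int,
    age_group: AgeGroup = AgeGroup.CHILD_1TO59M,
    rate_start_range: tuple[float, float] = (15.0, 120.0),
    annual_decline: tuple[float, float] = (0.02, 0.08),
    draw_sd_log: float = 0.05,
) -> list[MortalityEnvelope]:
    """Smoothly declining all-cause mortality series.

    Starting rates are spread log-uniformly across ``rate_start_range``
    (spanning every mortality stratum) and decline log-linearly at a
    country-specific annual rate, so several countries cross strata
    thresholds over the period — exactly the situation model averaging
    exists for.  Livebirths are constant per country.
    """
    rng = np.random.default_rng(seed)
    years = list(years)
    countries = _country_codes(n_countries)
    lo, hi = rate_start_range
    start_rates = np.exp(rng.uniform(np.log(lo), np.log(hi), n_countries))
    declines = rng.uniform(*annual_decline, n_countries)
    livebirths = np.exp(rng.uniform(np.log(5e4), np.log(2e6), n_countries))
    out = []
    for i, c in enumerate(countries):
        for t, y in enumerate(years):
            rate = start_rates[i] * (1.0 - declines[i]) ** t
            lb = livebirths[i]
            out.append(
                MortalityEnvelope(
                    country=c, year=y, age_group=age_group,
                    deaths=rate * lb / 1000.0, livebirths=lb,
                    draw_sd_log=draw_sd_log,
                )
            )
    return out


def generate_exogenous_series(
    envelopes: list[MortalityEnvelope],
    shares: dict[ExogenousCause, float],
    seed: int,
    draw_sd_log: float = 0.1,
) -> list[ExogenousCauseSeries]:
    """Exogenous single-cause series as envelope shares with lognormal jitter.

    Shares must each lie in [0, 1) and sum to below 1 (the exogenous
    causes cannot exhaust the envelope)."""
    vals = list(shares.values())
    if any(not 0.0 <= v < 1.0 for v in vals):
        raise ValueError("shares must lie in [0, 1)")
    if sum(vals) >= 1.0:
        raise ValueError(f"exogenous shares sum to {sum(vals):.2f} >= 1")
    rng = np.random.default_rng(seed)
    out = []
    for env in envelopes:
        for cause, share in shares.items():
            mean = share * env.deaths
            jitter = np.exp(rng.normal(-0.5 * draw_sd_log**2, draw_sd_log)) if mean > 0 else 1.0
            out.append(
                ExogenousCauseSeries(
                    country=env.country, year=env.year, age_group=env.age_group,
                    cause=cause, deaths=mean * jitter, draw_sd_log=draw_sd_log,
                )
            )
    return out
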