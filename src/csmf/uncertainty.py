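"""Monte-Carlo uncertainty propagation, uncertainty ranges, regional
aggregation, rates, and annual-rate-of-reduction reporting.

Uncertainty ranges (URs) are 2.5th-97.5th centiles of Monte-Carlo draws.
Every source of variation — posterior cause-fraction draws, envelope
draws, exogenous single-cause draws — is propagated by running the full
post-processing chain per draw; regional and global quantities are summed
across countries *within* each draw before centiles are taken, so
cross-country correlation induced by shared parameters is handled
correctly.
"""

from __future__ import annotations

from typing import Callable, Mapping, Sequence

import numpy as np
import pandas as pd

from .datatypes import MortalityEnvelope
from .postprocess import run_postprocessing


def _resample(arr: np.ndarray, n_draws: int, rng: np.random.Generator) -> np.ndarray:
    """First axis resized to n_draws (truncate or resample with replacement)."""
    arr = np.asarray(arr, dtype=float)
    if arr.shape[0] == n_draws:
        return arr
    if arr.shape[0] > n_draws:
        return arr[:n_draws]
    idx = rng.integers(0, arr.shape[0], size=n_draws)
    return arr[idx]


def propagate_draws(
    fraction_draws: np.ndarray,
    envelope: MortalityEnvelope,
    causes: Sequence[str],
    n_draws: int,
    seed: int,
    exogenous: Mapping[str, tuple[float, float]] | None = None,
    postprocess_kwargs: dict | None = None,
) -> pd.DataFrame:
    """Per-cause death draws for one country-year.

    Parameters
    ----------
    fraction_draws : (M, C) posterior draws of modelled cause fractions.
    envelope : the all-cause envelope; its ``draw_sd_log`` drives lognormal
        envelope draws (zero SD means a degenerate point mass).
    exogenous : cause -> (deaths, draw_sd_log) for the squeezed causes.
    postprocess_kwargs : forwarded to :func:`run_postprocessing`
        (splits, TB, vaccine, crises).

    Returns a DataFrame with one row per draw and one column per output
    cause; row sums equal the corresponding envelope draw.
    """
    if n_draws <= 0:
        raise ValueError("n_draws must be positive")
    rng = np.random.default_rng(seed)
    fr = _resample(np.atleast_2d(fraction_draws), n_draws, rng)
    fr = fr / fr.sum(axis=1, keepdims=True)

    if envelope.draw_sd_log > 0:
        env_draws = envelope.deaths * np.exp(
            rng.normal(-0.5 * envelope.draw_sd_log**2, envelope.draw_sd_log, n_draws)
        )
    else:
        env_draws = np.full(n_draws, envelope.deaths)

    exo_draws: dict[str, np.ndarray] = {}
    for cause, (deaths, sd_log) in (exogenous or {}).items():
        if sd_log > 0 and deaths > 0:
            exo_draws[cause] = deaths * np.exp(rng.normal(-0.5 * sd_log**2, sd_log, n_draws))
        else:
            exo_draws[cause] = np.full(n_draws, deaths)

    kwargs = dict(postprocess_kwargs or {})
    rows = []
    for d in range(n_draws):
        env_d = MortalityEnvelope(
            envelope.country, envelope.year, envelope.age_group,
            env_draws[d], envelope.livebirths,
        )
        exo_d = {c: v[d] for c, v in exo_draws.items()}
        rows.append(run_postprocessing(env_d, fr[d], causes, exogenous_deaths=exo_d, **kwargs))
    return pd.DataFrame(rows).fillna(0.0)


def uncertainty_range(draws: np.ndarray) -> tuple[float, float]:
    """95% uncertainty range: empirical 2.5th and 97.5th centiles.

    Centiles use the linear-interpolation convention between order
    statistics (numpy's default), documented because URs are the headline
    outputs.
    """
    draws = np.asarray(draws, dtype=float)
    if draws.size < 40:
        raise ValueError("need at least 40 draws for a 95% uncertainty range")
    lo, hi = np.percentile(draws, [2.5, 97.5], method="linear")
    return float(lo), float(hi)


def summarise_draws(draws: pd.DataFrame) -> pd.DataFrame:
    """Point estimate (mean) and UR per cause from a draws table."""
    out = pd.DataFrame(
        {
            "deaths": draws.mean(axis=0),
            "lower": draws.quantile(0.025, interpolation="linear"),
            "upper": draws.quantile(0.975, interpolation="linear"),
        }
    )
    out.index.name = "cause"
    return out


def aggregate_region(
    country_draws: Mapping[str, pd.DataFrame], region_lookup: Mapping[str, str]
) -> dict[str, pd.DataFrame]:
    """Sum per-draw country death tables into regional draw tables.

    Summation happens draw-by-draw (before any centile computation).
    Every country must map to exactly one region.
    """
    unmapped = [c for c in country_draws if c not in region_lookup]
    if unmapped:
        raise KeyError(f"countries without region mapping: {unmapped}")
    regions: dict[str, pd.DataFrame] = {}
    for country, draws in country_draws.items():
        r = region_lookup[country]
        regions[r] = draws.copy() if r not in regions else regions[r].add(draws, fill_value=0.0)
    return regions


def cause_rate(deaths: float | np.ndarray, livebirths: float) -> float | np.ndarray:
    """Cause-specific mortality rate per 1000 livebirths."""
    if livebirths <= 0:
        raise ValueError("livebirths must be positive")
    return deaths / livebirths * 1000.0


def annual_rate_reduction(
    rate_t1: float, rate_t2: float, t1: int, t2: int
) -> float:
    """Average annual rate of reduction (ARR), percent per year.

    Log-linear decline convention: ARR = 100 * ln(rate_t1/rate_t2)/(t2-t1).
    Positive when mortality falls; negative when it rises.
    """
    if rate_t1 <= 0 or rate_t2 <= 0:
        raise ValueError(
            "ARR undefined for nonpositive rates; report the cause as undefined"
        )
    if t2 <= t1:
        raise ValueError("t2 must exceed t1")
    return 100.0 * np.log(rate_t1 / rate_t2) / (t2 - t1)


def sdg_projection(
    current_rates: Mapping[str, float],
    arr_percent: Mapping[str, float],
    current_year: int,
    target_year: int,
    target_all_cause_rate: float,
) -> pd.DataFrame:
    """Required vs projected cause-specific rates at the target year.

    The required rate assumes each cause keeps its current share of
    all-cause mortality when the target all-cause rate is reached; the
    projected rate extrapolates the cause's current ARR.  Causes whose
    projection exceeds the requirement are flagged as off-track.
    """
    if target_all_cause_rate <= 0:
        raise ValueError("target all-cause rate must be positive")
    total = sum(current_rates.values())
    years = target_year - current_year
    rows = []
    for cause, rate in current_rates.items():
        share = rate / total if total > 0 else 0.0
        required = share * target_all_cause_rate
        projected = rate * np.exp(-arr_percent.get(cause, 0.0) / 100.0 * years)
        rows.append(
            {
                "cause": cause,
                "current_rate": rate,
                "required_rate": required,
                "projected_rate": projected,
                "off_track": bool(projected > required),
            }
        )
    return pd.DataFrame(rows).set_index("cause")
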