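"""Turn modelled cause fractions into cause-specific death counts.

The modelled fractions describe only the causes the regression can see.
Several causes are instead estimated by outside programmes (measles and
tetanus by WHO immunisation programmes, HIV by UNAIDS, malaria outside
sub-Saharan Africa from the World Malaria Report, tuberculosis from WHO TB
estimates); these single-cause series are reconciled with the all-cause
envelope by "squeezing": the exogenous deaths are taken off the top and
the remainder of the envelope is distributed over the modelled causes in
proportion to their fractions.  Afterwards come the deterministic
adjustments: the combined neonatal sepsis/meningitis cause and the child
perinatal cause are split using external ratios, tuberculosis is carved
out of lower respiratory infections (pulmonary) and the residual
communicable share of "other" (extrapulmonary), vaccine-era mortality for
LRI/meningitis (Hib, PCV) and diarrhoea (rotavirus) is scaled down where
coverage data say the study-era burden overstates today's, and crisis
deaths are attributed by the nature of each crisis.

Every step conserves the envelope total and keeps all categories
nonnegative; the fixed order is squeeze -> splits -> TB -> vaccine ->
crisis.
"""

from __future__ import annotations

import logging
import warnings
from typing import Mapping, Sequence

import numpy as np

from .datatypes import CrisisEvent, CrisisType, MortalityEnvelope

logger = logging.getLogger(__name__)

_ATOL = 1e-6


def apply_envelope(fractions: np.ndarray, envelope: MortalityEnvelope) -> np.ndarray:
    """Cause deaths = fraction x all-cause envelope deaths."""
    fractions = np.asarray(fractions, dtype=float)
    if abs(fractions.sum() - 1.0) > _ATOL:
        raise ValueError(f"fractions sum to {fractions.sum():.8f}, not 1")
    return fractions * envelope.deaths


def squeeze_exogenous(
    envelope_deaths: float,
    modeled_fractions: np.ndarray,
    exogenous_deaths: Mapping[str, float],
    cap_share: float = 0.9,
) -> tuple[np.ndarray, dict[str, float]]:
    """Reconcile exogenous single-cause deaths with the envelope.

    The exogenous causes take their estimated deaths off the envelope
    (rescaled pro rata if together they would exceed ``cap_share`` of it);
    the remaining envelope is distributed over the modelled causes by
    their fractions.  Returns (modelled cause deaths, exogenous deaths as
    allocated); the two together sum to the envelope.
    """
    modeled_fractions = np.asarray(modeled_fractions, dtype=float)
    exo = {k: float(v) for k, v in exogenous_deaths.items()}
    if any(v < 0 for v in exo.values()):
        raise ValueError("negative exogenous deaths")
    total_exo = sum(exo.values())
    cap = cap_share * envelope_deaths
    if total_exo > cap and total_exo > 0:
        scale = cap / total_exo
        logger.warning(
            "exogenous deaths %.1f exceed %.0f%% of envelope %.1f; rescaled pro rata",
            total_exo, 100 * cap_share, envelope_deaths,
        )
        exo = {k: v * scale for k, v in exo.items()}
        total_exo = cap
    remaining = envelope_deaths - total_exo
    frac = modeled_fractions / modeled_fractions.sum() if modeled_fractions.sum() > 0 else modeled_fractions
    return remaining * frac, exo


def split_proportion(deaths: float, ratio: float) -> tuple[float, float]:
    """Split a death count into (1-ratio, ratio) parts; sum conserved."""
    if not 0.0 <= ratio <= 1.0:
        raise ValueError("split ratio must lie in [0, 1]")
    second = ratio * deaths
    return deaths - second, second


def split_neonatal_sepsis(
    sepsis_meningitis_deaths: float, meningitis_ratio: float
) -> tuple[float, float]:
    """Split the combined neonatal sepsis/meningitis cause: meningitis is an
    externally supplied proportion of the combined count (GBD-style ratio).

    Returns (sepsis deaths, meningitis deaths)."""
    return split_proportion(sepsis_meningitis_deaths, meningitis_ratio)


def split_perinatal(
    perinatal_deaths: float, preterm_share: float | None = None
) -> tuple[float, float]:
    """Split child perinatal deaths into (preterm, intrapartum) using an
    external preterm share; defaults to an equal split with a warning when
    no external table is supplied."""
    if preterm_share is None:
        warnings.warn("no external perinatal split supplied; using equal split")
        preterm_share = 0.5
    intrapartum, preterm = split_proportion(perinatal_deaths, preterm_share)
    return preterm, intrapartum


def allocate_tb(
    lri_deaths: float,
    other_communicable_deaths: float,
    tb_pulmonary: float,
    tb_extrapulmonary: float,
) -> tuple[float, float, float]:
    """Carve tuberculosis out as an explicit cause.

    Pulmonary TB is taken as a fraction of lower respiratory infection
    deaths; extrapulmonary TB as a fraction of the communicable share of
    "other" deaths, with any excess over that share reassigned out of LRI.
    No category is driven below zero — un-absorbable excess is truncated
    with a warning.  Returns (adjusted LRI, adjusted other-communicable,
    TB deaths); the three sum to the inputs' total plus the TB absorbed.
    """
    if min(lri_deaths, other_communicable_deaths, tb_pulmonary, tb_extrapulmonary) < 0:
        raise ValueError("inputs must be nonnegative")
    take_p = min(tb_pulmonary, lri_deaths)
    if take_p < tb_pulmonary:
        warnings.warn("pulmonary TB exceeds LRI deaths; truncated")
    lri = lri_deaths - take_p
    take_e = min(tb_extrapulmonary, other_communicable_deaths)
    other = other_communicable_deaths - take_e
    excess = tb_extrapulmonary - take_e
    take_x = min(excess, lri)
    lri -= take_x
    if excess > take_x:
        warnings.warn(
            f"extrapulmonary TB excess {excess - take_x:.1f} cannot be absorbed; truncated"
        )
    return lri, other, take_p + take_e + take_x


def vaccine_adjust(
    deaths: np.ndarray,
    causes: Sequence[str],
    target_cause: str,
    coverage: float,
    ve_paf: float,
    coverage_ref: float = 0.0,
) -> np.ndarray:
    """Scale a vaccine-preventable cause for post-study-era coverage.

    The adjustment factor is (1 - cov*VE*PAF) / (1 - cov_ref*VE*PAF):
    the ratio of disease burden under current coverage to burden under the
    coverage prevailing when the contributing studies were run (zero by
    default).  Deaths freed from the target cause are reallocated pro rata
    over the remaining causes so the envelope total is conserved.
    """
    if not 0.0 <= coverage <= 1.0 or not 0.0 <= coverage_ref <= 1.0:
        raise ValueError("coverage must lie in [0, 1]")
    deaths = np.asarray(deaths, dtype=float).copy()
    factor = (1.0 - coverage * ve_paf) / (1.0 - coverage_ref * ve_paf)
    if not 0.0 < factor <= 1.0:
        raise ValueError(f"adjustment factor {factor:.3f} outside (0, 1]")
    i = list(causes).index(target_cause)
    freed = deaths[i] * (1.0 - factor)
    deaths[i] -= freed
    others = np.arange(len(deaths)) != i
    pool = deaths[others].sum()
    if pool > 0:
        deaths[others] += freed * deaths[others] / pool
    else:
        deaths[i] += freed  # nothing to absorb the freed deaths
    return deaths


def allocate_crisis(
    envelope_deaths: float,
    modeled_fractions: np.ndarray,
    causes: Sequence[str],
    crisis_deaths: float,
    crisis_type: CrisisType,
) -> np.ndarray:
    """Attribute crisis deaths by the nature of the crisis, distributing the
    non-crisis remainder of the envelope by the modelled fractions.

    Natural disasters go to injury; conflict-related malnutrition to the
    residual "other" group; congenital epidemics (Zika-like) to congenital
    abnormalities; pro-rata crises follow the modelled fractions.
    """
    if crisis_deaths > envelope_deaths:
        raise ValueError("crisis deaths exceed the envelope")
    modeled_fractions = np.asarray(modeled_fractions, dtype=float)
    base = (envelope_deaths - crisis_deaths) * modeled_fractions
    target = {
        CrisisType.NATURAL_DISASTER: "injury",
        CrisisType.CONFLICT_MALNUTRITION: "other",
        CrisisType.EPIDEMIC_CONGENITAL: "congenital",
    }.get(crisis_type)
    if target is None:  # pro rata
        return base + crisis_deaths * modeled_fractions
    i = list(causes).index(target)
    base[i] += crisis_deaths
    return base


def run_postprocessing(
    envelope: MortalityEnvelope,
    modeled_fractions: np.ndarray,
    causes: Sequence[str],
    exogenous_deaths: Mapping[str, float] | None = None,
    meningitis_ratio: float | None = None,
    preterm_share: float | None = None,
    tb_pulmonary: float = 0.0,
    tb_extrapulmonary: float = 0.0,
    other_communicable_share: float = 0.5,
    vaccine_adjustments: Sequence[tuple[str, float, float, float]] = (),
    crises: Sequence[CrisisEvent] = (),
    cap_share: float = 0.9,
) -> dict[str, float]:
    """Full deterministic chain for one country-year-age group:
    squeeze -> splits -> TB -> vaccine -> crisis.

    ``vaccine_adjustments`` rows are (cause, coverage, VE*PAF, reference
    coverage).  Crisis deaths are reallocated over the final cause set:
    targeted crisis types move their deaths onto one cause, pro-rata
    crises leave the distribution unchanged.  Returns a cause -> deaths
    mapping whose values sum to the envelope.
    """
    causes = list(causes)
    fr = np.asarray(modeled_fractions, dtype=float)
    if abs(fr.sum() - 1.0) > _ATOL:
        raise ValueError("modelled fractions must sum to 1")

    modeled, exo = squeeze_exogenous(
        envelope.deaths, fr, exogenous_deaths or {}, cap_share
    )

    out: dict[str, float] = dict(zip(causes, modeled))
    out.update(exo)

    if "sepsis_meningitis" in out and meningitis_ratio is not None:
        sepsis, meningitis = split_neonatal_sepsis(
            out.pop("sepsis_meningitis"), meningitis_ratio
        )
        out["sepsis"] = sepsis
        out["meningitis"] = out.get("meningitis", 0.0) + meningitis
    if "perinatal" in out and preterm_share is not None:
        preterm, intrapartum = split_perinatal(out.pop("perinatal"), preterm_share)
        out["preterm"] = out.get("preterm", 0.0) + preterm
        out["intrapartum"] = out.get("intrapartum", 0.0) + intrapartum

    if tb_pulmonary > 0 or tb_extrapulmonary > 0:
        lri = out.get("lower_respiratory_infections", 0.0)
        other = out.get("other", 0.0)
        other_comm = other * other_communicable_share
        lri_adj, comm_adj, tb = allocate_tb(lri, other_comm, tb_pulmonary, tb_extrapulmonary)
        out["lower_respiratory_infections"] = lri_adj
        out["other"] = other - other_comm + comm_adj
        out["tuberculosis"] = out.get("tuberculosis", 0.0) + tb

    for cause, cov, ve_paf, cov_ref in vaccine_adjustments:
        names = list(out.keys())
        vals = vaccine_adjust(
            np.array([out[c] for c in names]), names, cause, cov, ve_paf, cov_ref
        )
        out = dict(zip(names, vals))

    for crisis in crises:
        if not crisis.year_start <= envelope.year <= crisis.year_end:
            continue
        names = list(out.keys())
        vals = np.array([out[c] for c in names])
        total = vals.sum()
        fr_now = vals / total if total > 0 else vals
        vals = allocate_crisis(
            total, fr_now, names, min(crisis.crisis_deaths, total), crisis.crisis_type
        )
        out = dict(zip(names, vals))

    return out
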