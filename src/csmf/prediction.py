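"""Country-year fraction prediction: mortality strata, model averaging,
and the empirical vital-registration path.

Which fitted model supplies a country-year's cause fractions depends on
its all-cause mortality rate: below the low threshold the low-mortality
model applies, at or above the high threshold the high-mortality model
applies, and in the moderate band between them the two models are averaged
with a weight that rises linearly in the rate — so predicted fractions are
continuous in the rate as countries transition between mortality eras.
Countries with high-quality vital registration bypass the models entirely:
their reported cause fractions are interpolated between reporting years
and carried forward/backward outside the reporting span.
"""

from __future__ import annotations

from dataclasses import dataclass
from enum import Enum

import numpy as np

from .datatypes import PipelineConfig
from .taxonomy import AgeGroup, CauseTaxonomy


class Stratum(str, Enum):
    LOW = "low"
    MODERATE = "moderate"
    HIGH = "high"


@dataclass(frozen=True)
class StratumAssignment:
    country: str
    year: int
    age_group: AgeGroup
    stratum: Stratum
    weight_high: float

    def __post_init__(self) -> None:
        w = self.weight_high
        if self.stratum == Stratum.LOW and w != 0.0:
            raise ValueError("low stratum requires weight_high = 0")
        if self.stratum == Stratum.HIGH and w != 1.0:
            raise ValueError("high stratum requires weight_high = 1")
        if self.stratum == Stratum.MODERATE and not 0.0 < w < 1.0:
            raise ValueError("moderate stratum requires 0 < weight_high < 1")


def classify_stratum(
    rate: float,
    age_group: AgeGroup,
    config: PipelineConfig | None = None,
    country: str = "",
    year: int = 0,
) -> StratumAssignment:
    """Assign a country-year to a mortality stratum from its all-cause rate.

    Thresholds (deaths per 1000 livebirths): neonates low < 10, high >= 20;
    children 1-59 months low < 25, high >= 35.  The averaging weight for
    the high-mortality model is (rate - L)/(H - L) clipped to [0, 1].
    """
    if rate < 0:
        raise ValueError("mortality rate must be nonnegative")
    config = config or PipelineConfig()
    low, high = config.strata_thresholds[age_group]
    w = float(np.clip((rate - low) / (high - low), 0.0, 1.0))
    if rate < low:
        stratum = Stratum.LOW
    elif rate >= high:
        stratum = Stratum.HIGH
    else:
        stratum = Stratum.MODERATE
        # boundary rate == low falls in MODERATE per the threshold definition
        # only when low < rate; rate == low belongs to the low model edge
    if stratum == Stratum.MODERATE and w == 0.0:
        stratum = Stratum.LOW
    return StratumAssignment(country, year, age_group, stratum, w)


def align_causes(
    fractions: np.ndarray,
    causes_from: tuple[str, ...],
    causes_to: tuple[str, ...],
    fill: float = 0.0,
) -> np.ndarray:
    """Embed fraction draws over one cause list into another, filling
    causes absent from the source with ``fill``.

    Used to harmonise the low-mortality neonatal model (fitted without
    diarrhoea, which is assumed zero in low-mortality settings) with the
    full neonatal cause list before model averaging.  No renormalisation
    is applied: a filled zero leaves the vector summing to 1.
    """
    fractions = np.atleast_2d(np.asarray(fractions, dtype=float))
    out = np.full(fractions.shape[:-1] + (len(causes_to),), fill)
    for i, cause in enumerate(causes_from):
        if cause not in causes_to:
            raise ValueError(f"cause {cause!r} absent from target cause list")
        out[..., causes_to.index(cause)] = fractions[..., i]
    return out


def average_models(
    frac_low: np.ndarray, frac_high: np.ndarray, weight_high: float
) -> np.ndarray:
    """Convex combination of low- and high-model fraction draws,
    renormalised to sum to 1 per draw."""
    if not 0.0 <= weight_high <= 1.0:
        raise ValueError("weight_high must lie in [0, 1]")
    frac_low = np.asarray(frac_low, dtype=float)
    frac_high = np.asarray(frac_high, dtype=float)
    if frac_low.shape != frac_high.shape:
        raise ValueError(
            f"cause-list mismatch: {frac_low.shape} vs {frac_high.shape}"
        )
    f = weight_high * frac_high + (1.0 - weight_high) * frac_low
    return f / f.sum(axis=-1, keepdims=True)


def vr_empirical_fractions(
    report_years: np.ndarray,
    report_fractions: np.ndarray,
    target_years: np.ndarray,
) -> np.ndarray:
    """Complete a vital-registration cause-fraction series over target years.

    Linear interpolation per cause between reporting years; constant
    carry-forward/backward beyond the reporting span (recent years past
    the last report reuse the last reported distribution).  Rows are
    renormalised to sum to 1 after interpolation.
    """
    report_years = np.asarray(report_years, dtype=float)
    if report_years.size == 0:
        raise ValueError("at least one reporting year required")
    report_fractions = np.atleast_2d(np.asarray(report_fractions, dtype=float))
    if report_fractions.shape[0] != report_years.size:
        raise ValueError("one fraction row per reporting year required")
    order = np.argsort(report_years)
    report_years = report_years[order]
    report_fractions = report_fractions[order]
    target_years = np.asarray(target_years, dtype=float)
    out = np.column_stack(
        [
            np.interp(target_years, report_years, report_fractions[:, c])
            for c in range(report_fractions.shape[1])
        ]
    )
    return out / out.sum(axis=1, keepdims=True)


def reference_cause(age_group: AgeGroup, stratum: Stratum) -> str:
    """The designated reference cause for each fitted model: preterm birth
    complications (low-mortality neonatal), intrapartum-related events
    (high-mortality neonatal), lower respiratory infections (children,
    both strata) — each the expected largest-burden cause in its stratum."""
    if age_group == AgeGroup.NEONATAL:
        return "preterm" if stratum == Stratum.LOW else "intrapartum"
    return "lower_respiratory_infections"


def check_reference_cause(taxonomy: CauseTaxonomy, stratum: Stratum) -> None:
    """Raise if a taxonomy's base cause is not the designated reference for
    the model being fitted."""
    expected = reference_cause(taxonomy.age_group, stratum)
    if taxonomy.base_cause != expected:
        raise ValueError(
            f"{taxonomy.age_group.value} {stratum.value}-mortality model must use "
            f"{expected!r} as reference cause, got {taxonomy.base_cause!r}"
        )
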