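"""Delimited-text readers and writers for every pipeline input and output.

All files are comma-separated UTF-8 with "." as the decimal separator.
Countries are identified by ISO3 codes validated against the bundled
UNICEF-region lookup, which is editable: pass a custom CSV to any reader
that validates countries (or to :func:`load_region_lookup`) to extend it.
"""

from __future__ import annotations

import logging
from importlib import resources
from pathlib import Path

import numpy as np
import pandas as pd

from .datatypes import (
    CountryCauseEstimate,
    CrisisEvent,
    CrisisType,
    ExogenousCause,
    ExogenousCauseSeries,
    MortalityEnvelope,
    SourceType,
    StudyDataset,
)
from .taxonomy import AgeGroup, CauseTaxonomy

logger = logging.getLogger(__name__)


def load_region_lookup(path: str | Path | None = None) -> dict[str, str]:
    """ISO3 -> UNICEF-region mapping from the bundled (or a custom) table."""
    if path is None:
        with resources.files("csmf.data").joinpath("unicef_regions.csv").open() as fh:
            df = pd.read_csv(fh)
    else:
        df = pd.read_csv(path)
    return dict(zip(df["iso3"], df["region"]))


def _check_country(code: str, lookup: dict[str, str], context: str) -> None:
    if code not in lookup:
        raise ValueError(
            f"{context}: unknown country code {code!r} "
            "(extend the region lookup table to add it)"
        )


def read_studies(
    path: str | Path,
    taxonomy: CauseTaxonomy,
    region_lookup: dict[str, str] | None = None,
) -> list[StudyDataset]:
    """Read study records from a long CSV (one row per study x reported cause).

    Required columns: study_id, country, midyear, age_group,
    nationally_representative, source_type, reported_cause, deaths; any
    column starting with ``x`` is treated as a covariate (constant within
    a study).
    """
    lookup = region_lookup or load_region_lookup()
    df = pd.read_csv(path)
    if df.empty:
        logger.warning("study file %s contains no rows", path)
        return []
    cov_cols = [c for c in df.columns if c.startswith("x")]
    neg = df.index[df["deaths"] < 0]
    if len(neg):
        raise ValueError(f"negative death count at row {neg[0] + 2}")  # 1-based + header
    dup = df.duplicated(subset=["study_id", "reported_cause"], keep=False)
    if dup.any():
        pair = df.loc[dup, ["study_id", "reported_cause"]].iloc[0]
        raise ValueError(
            f"duplicated (study_id, reported_cause) row: "
            f"({pair['study_id']!r}, {pair['reported_cause']!r})"
        )
    studies = []
    for sid, g in df.groupby("study_id", sort=False):
        first = g.iloc[0]
        _check_country(str(first["country"]), lookup, f"study {sid}")
        studies.append(
            StudyDataset(
                study_id=str(sid),
                country=str(first["country"]),
                midyear=int(first["midyear"]),
                age_group=AgeGroup(first["age_group"]),
                reported_causes=tuple(g["reported_cause"]),
                deaths=g["deaths"].to_numpy(dtype=np.int64),
                covariates=first[cov_cols].to_numpy(dtype=float),
                covariate_names=tuple(cov_cols),
                nationally_representative=bool(first["nationally_representative"]),
                source_type=SourceType(first["source_type"]),
            )
        )
    return studies


def write_studies(studies: list[StudyDataset], path: str | Path) -> None:
    rows = []
    for s in studies:
        for cause, d in zip(s.reported_causes, s.deaths):
            row = {
                "study_id": s.study_id,
                "country": s.country,
                "midyear": s.midyear,
                "age_group": s.age_group.value,
                "nationally_representative": s.nationally_representative,
                "source_type": s.source_type.value,
                "reported_cause": cause,
                "deaths": int(d),
            }
            row.update(dict(zip(s.covariate_names, s.covariates)))
            rows.append(row)
    pd.DataFrame(rows).to_csv(path, index=False)


def read_cause_mappings(path: str | Path) -> dict[str, dict[str, str]]:
    """Per-study true-cause -> reported-category mapping table."""
    df = pd.read_csv(path)
    out: dict[str, dict[str, str]] = {}
    for sid, g in df.groupby("study_id", sort=False):
        out[str(sid)] = dict(zip(g["true_cause"], g["reported_category"]))
    return out


def read_envelopes(
    path: str | Path, region_lookup: dict[str, str] | None = None
) -> list[MortalityEnvelope]:
    """Country-year all-cause envelopes; rate = deaths/livebirths x 1000."""
    lookup = region_lookup or load_region_lookup()
    df = pd.read_csv(path)
    out = []
    for i, row in df.iterrows():
        _check_country(str(row["country"]), lookup, f"envelope row {i + 2}")
        out.append(
            MortalityEnvelope(
                country=str(row["country"]),
                year=int(row["year"]),
                age_group=AgeGroup(row["age_group"]),
                deaths=float(row["deaths"]),
                livebirths=float(row["livebirths"]),
                draw_sd_log=float(row.get("draw_sd_log", 0.0)),
            )
        )
    return out


def write_envelopes(envelopes: list[MortalityEnvelope], path: str | Path) -> None:
    pd.DataFrame(
        [
            {
                "country": e.country, "year": e.year, "age_group": e.age_group.value,
                "deaths": e.deaths, "livebirths": e.livebirths,
                "draw_sd_log": e.draw_sd_log,
            }
            for e in envelopes
        ]
    ).to_csv(path, index=False)


def read_exogenous(path: str | Path) -> list[ExogenousCauseSeries]:
    df = pd.read_csv(path)
    return [
        ExogenousCauseSeries(
            country=str(r["country"]), year=int(r["year"]),
            age_group=AgeGroup(r["age_group"]), cause=ExogenousCause(r["cause"]),
            deaths=float(r["deaths"]), draw_sd_log=float(r.get("draw_sd_log", 0.0)),
        )
        for _, r in df.iterrows()
    ]


def write_exogenous(series: list[ExogenousCauseSeries], path: str | Path) -> None:
    pd.DataFrame(
        [
            {
                "country": s.country, "year": s.year, "age_group": s.age_group.value,
                "cause": s.cause.value, "deaths": s.deaths,
                "draw_sd_log": s.draw_sd_log,
            }
            for s in series
        ]
    ).to_csv(path, index=False)


def read_crises(path: str | Path) -> list[CrisisEvent]:
    df = pd.read_csv(path)
    return [
        CrisisEvent(
            country=str(r["country"]), year_start=int(r["year_start"]),
            year_end=int(r["year_end"]), age_group=AgeGroup(r["age_group"]),
            crisis_deaths=float(r["crisis_deaths"]),
            crisis_type=CrisisType(r["crisis_type"]),
        )
        for _, r in df.iterrows()
    ]


_ESTIMATE_COLS = [
    "country", "year", "age_group", "cause", "fraction", "deaths", "rate",
    "lower", "upper",
]


def write_estimates(estimates: list[CountryCauseEstimate], path: str | Path) -> None:
    """Long-format estimates table; floats are written at full precision so
    the table round-trips losslessly."""
    pd.DataFrame(
        [
            {
                "country": e.country, "year": e.year, "age_group": e.age_group.value,
                "cause": e.cause, "fraction": e.fraction, "deaths": e.deaths,
                "rate": e.rate, "lower": e.lower, "upper": e.upper,
            }
            for e in estimates
        ],
        columns=_ESTIMATE_COLS,
    ).to_csv(path, index=False, float_format=lambda v: format(v, ".17g"))


def read_estimates(path: str | Path) -> list[CountryCauseEstimate]:
    df = pd.read_csv(path, float_precision="round_trip")
    return [
        CountryCauseEstimate(
            country=str(r["country"]), year=int(r["year"]),
            age_group=AgeGroup(r["age_group"]), cause=str(r["cause"]),
            fraction=float(r["fraction"]), deaths=float(r["deaths"]),
            rate=float(r["rate"]), lower=float(r["lower"]), upper=float(r["upper"]),
        )
        for _, r in df.iterrows()
    ]
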