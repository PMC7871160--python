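"""Bundled example data: the published urban / non-urban smoking
prevalence percentages by gender, age group and survey year (2004-2019).

The survey publishes prevalences, not the underlying estimated household
counts, so the loader attaches a configurable constant denominator per
cell (default 10,000) and reconstructs integer smoker counts by rounding.
Observed prevalences round-trip to the printed one-decimal percentages.
"""

from __future__ import annotations

from importlib import resources

import pandas as pd

from .survey_data import PrevalenceTable, table_from_frame

__all__ = ["load_smoking_prevalence", "smoking_prevalence_frame"]

_CSV = "table1_smoking_prevalence.csv"

GENDERS = ("men", "women")
AREAS = ("urban", "non-urban")


def smoking_prevalence_frame() -> pd.DataFrame:
    """The full bundled table: gender, area, age_group, year, prevalence_pct."""
    with resources.files("prevapc.data").joinpath(_CSV).open() as fh:
        return pd.read_csv(fh)


def load_smoking_prevalence(
    gender: str, area: str, denominator: int = 10_000
) -> PrevalenceTable:
    """One stratum of the bundled prevalence data as a count table."""
    if gender not in GENDERS or area not in AREAS:
        raise ValueError(f"gender must be in {GENDERS} and area in {AREAS}")
    df = smoking_prevalence_frame()
    sub = df[(df.gender == gender) & (df.area == area)].copy()
    sub["denominator"] = int(denominator)
    return table_from_frame(
        sub[["age_group", "year", "prevalence_pct", "denominator"]],
        stratum_label=f"{gender}/{area}",
        value_col="prevalence_pct",
    )
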