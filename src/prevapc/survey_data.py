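"""Stratified prevalence count tables.

A :class:`PrevalenceTable` holds the smoker counts ``y_ij`` and denominators
``n_ij`` on a complete age-group x survey-year lattice for one stratum
(e.g. "men/urban").  Surveys often publish prevalences rather than counts,
so the reader also accepts percentage columns and reconstructs integer
counts by rounding against a user-supplied denominator.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = [
    "PrevalenceTable",
    "PrevalenceTableError",
    "LatticeError",
    "StratumConsistencyError",
    "read_prevalence_table",
    "write_prevalence_table",
    "derive_nonurban",
    "observed_prevalence",
]


class PrevalenceTableError(ValueError):
    """Base class for prevalence-table validation failures."""


class LatticeError(PrevalenceTableError):
    """The age x period lattice is incomplete or irregular."""


class StratumConsistencyError(PrevalenceTableError):
    """National and urban tables are mutually inconsistent (negative difference)."""


def _check_axis(values: tuple[int, ...], name: str) -> int:
    """Validate a strictly increasing, constant-step axis; return the step."""
    if len(values) == 0:
        raise LatticeError(f"{name}: empty axis")
    if len(values) == 1:
        return 0
    steps = np.diff(values)
    if np.any(steps <= 0):
        raise LatticeError(f"{name}: values must be strictly increasing, got {values}")
    if len(set(steps.tolist())) != 1:
        raise LatticeError(f"{name}: non-constant step, got {values}")
    return int(steps[0])


@dataclass(frozen=True)
class PrevalenceTable:
    """Binomial count table for one stratum on an age x period lattice.

    Parameters
    ----------
    stratum_label
        Free-form label, e.g. ``"men/urban"``.
    age_groups
        Start years of the age groups (e.g. 20 for "20-24"), strictly
        increasing with a constant step.
    periods
        Survey years, strictly increasing with a constant step.
    smokers
        ``(I, J)`` integer array of smoker counts ``y_ij``.
    denominators
        ``(I, J)`` integer array of denominators ``n_ij``, all positive.
    """

    stratum_label: str
    age_groups: tuple[int, ...]
    periods: tuple[int, ...]
    smokers: np.ndarray = field(repr=False)
    denominators: np.ndarray = field(repr=False)

    def __post_init__(self) -> None:
        object.__setattr__(self, "age_groups", tuple(int(a) for a in self.age_groups))
        object.__setattr__(self, "periods", tuple(int(p) for p in self.periods))
        y = np.asarray(self.smokers, dtype=np.int64)
        n = np.asarray(self.denominators, dtype=np.int64)
        object.__setattr__(self, "smokers", y)
        object.__setattr__(self, "denominators", n)
        _check_axis(self.age_groups, "age_groups")
        _check_axis(self.periods, "periods")
        shape = (len(self.age_groups), len(self.periods))
        if y.shape != shape or n.shape != shape:
            raise LatticeError(
                f"count arrays must have shape {shape}, got {y.shape} and {n.shape}"
            )
        if np.any(n <= 0):
            raise PrevalenceTableError("denominators must be positive")
        if np.any(y < 0) or np.any(y > n):
            raise PrevalenceTableError("smoker counts must satisfy 0 <= y_ij <= n_ij")

    # -- geometry -------------------------------------------------------
    @property
    def I(self) -> int:  # noqa: E743 - field-standard index-count name
        return len(self.age_groups)

    @property
    def J(self) -> int:
        return len(self.periods)

    @property
    def age_step(self) -> int:
        return _check_axis(self.age_groups, "age_groups")

    @property
    def period_step(self) -> int:
        return _check_axis(self.periods, "periods")

    def age_labels(self, width: int | None = None) -> list[str]:
        """Age-group labels ``"A-B"`` with A the start year."""
        w = width if width is not None else (self.age_step or 5)
        return [f"{a}-{a + w - 1}" for a in self.age_groups]

    def to_frame(self) -> pd.DataFrame:
        """Tidy long-format frame (age_group, year, smokers, denominator)."""
        rows = []
        labels = self.age_labels()
        for i, lab in enumerate(labels):
            for j, year in enumerate(self.periods):
                rows.append(
                    {
                        "age_group": lab,
                        "year": year,
                        "smokers": int(self.smokers[i, j]),
                        "denominator": int(self.denominators[i, j]),
                    }
                )
        return pd.DataFrame(rows)


def _round_half_away(x: np.ndarray) -> np.ndarray:
    """Round half away from zero (np.round rounds half to even)."""
    return np.sign(x) * np.floor(np.abs(x) + 0.5)


def _parse_age_group(value) -> int:
    """Accept '20-24' labels or bare integer starts."""
    s = str(value).strip()
    if "-" in s:
        return int(s.split("-")[0])
    return int(s)


def read_prevalence_table(path, stratum_label: str) -> PrevalenceTable:
    """Read a stratum table from CSV.

    Accepted column sets: ``(age_group, year, smokers, denominator)`` or
    ``(age_group, year, prevalence_pct, denominator)``.  With percentages,
    counts are reconstructed as ``round(prevalence_pct / 100 * denominator)``
    (half away from zero).

    Raises
    ------
    LatticeError
        If a cell of the age x year lattice is missing or duplicated.
    PrevalenceTableError
        If a prevalence lies outside [0, 100] or a count exceeds its
        denominator.
    """
    df = pd.read_csv(path)
    cols = set(df.columns)
    needed = {"age_group", "year", "denominator"}
    if not needed <= cols:
        raise PrevalenceTableError(f"missing required columns {needed - cols}")
    if "smokers" in cols:
        value_col = "smokers"
    elif "prevalence_pct" in cols:
        value_col = "prevalence_pct"
    else:
        raise PrevalenceTableError("need a 'smokers' or 'prevalence_pct' column")
    return table_from_frame(df, stratum_label, value_col=value_col)


def table_from_frame(
    df: pd.DataFrame, stratum_label: str, value_col: str = "smokers"
) -> PrevalenceTable:
    """Build a :class:`PrevalenceTable` from a tidy long-format frame."""
    df = df.copy()
    df["_age_start"] = df["age_group"].map(_parse_age_group)
    ages = sorted(df["_age_start"].unique())
    years = sorted(int(y) for y in df["year"].unique())
    if len(df) != len(ages) * len(years):
        raise LatticeError(
            f"expected {len(ages) * len(years)} rows for a complete "
            f"{len(ages)}x{len(years)} lattice, got {len(df)}"
        )
    piv_n = df.pivot(index="_age_start", columns="year", values="denominator")
    piv_v = df.pivot(index="_age_start", columns="year", values=value_col)
    piv_n = piv_n.reindex(index=ages, columns=years)
    piv_v = piv_v.reindex(index=ages, columns=years)
    if piv_n.isna().any().any() or piv_v.isna().any().any():
        raise LatticeError("incomplete lattice: missing (age_group, year) cells")
    n = piv_n.to_numpy(dtype=np.int64)
    if value_col == "prevalence_pct":
        pct = piv_v.to_numpy(dtype=float)
        if np.any(pct < 0) or np.any(pct > 100):
            raise PrevalenceTableError("prevalence_pct outside [0, 100]")
        y = _round_half_away(pct / 100.0 * n).astype(np.int64)
    else:
        y = piv_v.to_numpy(dtype=np.int64)
    return PrevalenceTable(
        stratum_label=stratum_label,
        age_groups=tuple(ages),
        periods=tuple(years),
        smokers=y,
        denominators=n,
    )


def write_prevalence_table(table: PrevalenceTable, path) -> None:
    """Write a table as tidy CSV (counts format); inverse of the reader."""
    table.to_frame().to_csv(path, index=False)


def derive_nonurban(
    national: PrevalenceTable,
    urban: PrevalenceTable,
    stratum_label: str | None = None,
) -> PrevalenceTable:
    """Non-urban stratum by cell-wise subtraction: national minus urban.

    Mirrors the construction of non-urban survey counts as the national
    totals minus the urban (designated-city) totals.

    Raises
    ------
    StratumConsistencyError
        If the grids differ, any difference is negative, or a resulting
        denominator is zero.
    """
    if national.age_groups != urban.age_groups or national.periods != urban.periods:
        raise StratumConsistencyError("national and urban tables are on different grids")
    y = national.smokers - urban.smokers
    n = national.denominators - urban.denominators
    if np.any(y < 0) or np.any(n < 0):
        raise StratumConsistencyError("urban counts exceed national counts in some cell")
    if np.any(n == 0):
        raise StratumConsistencyError("zero non-urban denominator in some cell")
    if np.any(y > n):
        raise StratumConsistencyError(
            "non-urban smokers exceed non-urban denominator in some cell"
        )
    label = stratum_label or f"{national.stratum_label}/non-urban"
    return PrevalenceTable(
        stratum_label=label,
        age_groups=national.age_groups,
        periods=national.periods,
        smokers=y,
        denominators=n,
    )


def observed_prevalence(table: PrevalenceTable) -> np.ndarray:
    """Observed cell prevalences ``p_hat_ij = y_ij / n_ij`` as an (I, J) array."""
    return table.smokers / table.denominators
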