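"""The age-period-cohort design lattice with unequal interval widths.

Age groups are 5-year-wide and surveys 3 years apart, while birth cohorts
are indexed on a 1-year grid, so consecutive cohorts overlap: cell (i, j)
maps to cohort index

    k(i, j) = age_step * (I - i) + period_step * (j - 1) + 1        (1-based)

with k = 1 the oldest cohort (oldest age group in the earliest period) and
k = K the youngest.  The total number of 1-year-shifted cohorts is

    K = age_step * (I - 1) + period_step * (J - 1) + 1.

Not every k is hit by a cell; the unobserved interior indices are retained
and later estimated by the random-walk smoothing prior.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .survey_data import PrevalenceTable

__all__ = ["APCGrid", "GridError", "build_grid", "cohort_label", "grid_summary"]


class GridError(ValueError):
    """Invalid design-lattice construction."""


@dataclass(frozen=True)
class APCGrid:
    """Design lattice: age/period axes plus the 1-year cohort grid.

    Indexing convention (1-based, used throughout): i = 1 is the youngest
    age group, j = 1 the earliest period, k = 1 the oldest cohort.
    """

    age_starts: tuple[int, ...]
    period_years: tuple[int, ...]
    age_step: int
    period_step: int
    cohort_step: int = 1

    # derived, filled in __post_init__
    cohort_index: np.ndarray = field(init=False, repr=False, compare=False)

    def __post_init__(self) -> None:
        object.__setattr__(self, "age_starts", tuple(int(a) for a in self.age_starts))
        object.__setattr__(self, "period_years", tuple(int(p) for p in self.period_years))
        I, J = self.I, self.J
        if I < 1 or J < 1:
            raise GridError("need at least one age group and one period")
        if self.age_step <= 0 or self.period_step <= 0 or self.cohort_step <= 0:
            raise GridError("steps must be positive")
        for name, axis, step in (
            ("age_starts", self.age_starts, self.age_step),
            ("period_years", self.period_years, self.period_step),
        ):
            diffs = set(np.diff(axis).tolist())
            if len(axis) > 1 and diffs != {step}:
                raise GridError(f"{name}: expected constant step {step}, got {sorted(diffs)}")
        i = np.arange(1, I + 1)[:, None]
        j = np.arange(1, J + 1)[None, :]
        k = self.age_step * (I - i) + self.period_step * (j - 1) + 1
        object.__setattr__(self, "cohort_index", k)
        self.cohort_index.setflags(write=False)

    @property
    def I(self) -> int:  # noqa: E743
        return len(self.age_starts)

    @property
    def J(self) -> int:
        return len(self.period_years)

    @property
    def K(self) -> int:
        return self.age_step * (self.I - 1) + self.period_step * (self.J - 1) + 1

    @property
    def oldest_cohort_start(self) -> int:
        """Birth year of the first member of cohort k = 1."""
        return self.period_years[0] - self.age_starts[-1] - (self.age_step - 1)

    @property
    def observed_cohorts(self) -> frozenset[int]:
        """Cohort indices hit by at least one (i, j) cell."""
        return frozenset(int(k) for k in np.unique(self.cohort_index))

    @property
    def unobserved_cohorts(self) -> frozenset[int]:
        return frozenset(range(1, self.K + 1)) - self.observed_cohorts

    def cohort_of_cell(self, i: int, j: int) -> int:
        """1-based cohort index of cell (i, j)."""
        if not (1 <= i <= self.I and 1 <= j <= self.J):
            raise GridError(f"cell ({i}, {j}) outside the {self.I}x{self.J} lattice")
        return int(self.cohort_index[i - 1, j - 1])

    def age_labels(self) -> list[str]:
        return [f"{a}-{a + self.age_step - 1}" for a in self.age_starts]

    def cohort_labels(self) -> list[str]:
        return [cohort_label(self, k) for k in range(1, self.K + 1)]


def build_grid(
    age_starts,
    period_years,
    age_step: int | None = None,
    period_step: int | None = None,
) -> APCGrid:
    """Construct the design lattice from the two observed axes.

    Steps are inferred from the axes when they have at least two levels;
    for degenerate single-level axes an explicit step is used (defaults:
    5-year age groups, 3-year survey interval).
    """
    age_starts = tuple(int(a) for a in age_starts)
    period_years = tuple(int(p) for p in period_years)

    def infer(axis, given, default, name):
        if len(axis) >= 2:
            diffs = set(np.diff(axis).tolist())
            if len(diffs) != 1 or min(diffs) <= 0:
                raise GridError(f"{name}: not strictly increasing with constant step")
            step = int(diffs.pop())
            if given is not None and given != step:
                raise GridError(f"{name}: supplied step {given} != observed step {step}")
            return step
        return int(given) if given is not None else default

    astep = infer(age_starts, age_step, 5, "age_starts")
    pstep = infer(period_years, period_step, 3, "period_years")
    return APCGrid(age_starts, period_years, astep, pstep)


def cohort_label(grid: APCGrid, k: int) -> str:
    """Birth-year range label of cohort k, e.g. ``"1925-1929"``.

    Each cohort spans ``age_step`` birth years starting at
    ``oldest_cohort_start + (k - 1) * cohort_step``.
    """
    if not (1 <= k <= grid.K):
        raise GridError(f"cohort index {k} outside 1..{grid.K}")
    start = grid.oldest_cohort_start + (k - 1) * grid.cohort_step
    return f"{start}-{start + grid.age_step - 1}"


def grid_summary(grid: APCGrid) -> pd.DataFrame:
    """One row per cell: indices, labels and cohort assignment, for audit."""
    rows = []
    labels = grid.age_labels()
    for i in range(1, grid.I + 1):
        for j in range(1, grid.J + 1):
            k = grid.cohort_of_cell(i, j)
            rows.append(
                {
                    "i": i,
                    "j": j,
                    "age_group": labels[i - 1],
                    "year": grid.period_years[j - 1],
                    "cohort_index": k,
                    "cohort_label": cohort_label(grid, k),
                }
            )
    return pd.DataFrame(rows)


def grid_from_table(table: PrevalenceTable) -> APCGrid:
    """Build the lattice matching a prevalence table's axes."""
    return build_grid(
        table.age_groups,
        table.periods,
        age_step=table.age_step or None,
        period_step=table.period_step or None,
    )
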