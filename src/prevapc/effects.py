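"""Posterior post-processing: effect-level prevalences, prevalence ratios,
direct age standardization, heterogeneity diagnostics.

Effect-level prevalence follows the back-transformation
``expit(delta + effect_t)`` applied draw-by-draw, so the reported point
estimate is the posterior mean of the transformed quantity and the bounds
are equal-tailed 2.5/97.5 percentiles.  The heterogeneity term z_ij is
deliberately excluded from these curves: they show the smooth additive
structure, while z absorbs cell-level residual variation.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.special import expit

from .apc_grid import cohort_label
from .inference import PosteriorSamples
from .survey_data import PrevalenceTable, observed_prevalence

__all__ = [
    "EffectSeries",
    "RatioSeries",
    "StandardPopulation",
    "HeterogeneitySummary",
    "UnsupportedAxisError",
    "effect_prevalence",
    "prevalence_ratio",
    "prevalence_ratio_draws",
    "age_standardize",
    "standardize_observed",
    "heterogeneity_summary",
]

AXES = ("age", "period", "cohort")


class UnsupportedAxisError(ValueError):
    """The requested effect axis is not part of the fitted model."""


@dataclass(frozen=True)
class EffectSeries:
    """Estimated prevalence with 95% credible bounds along one axis."""

    axis: str
    levels: tuple[str, ...]
    estimate: np.ndarray
    lower95: np.ndarray
    upper95: np.ndarray

    def __post_init__(self) -> None:
        est = np.asarray(self.estimate, dtype=float)
        lo = np.asarray(self.lower95, dtype=float)
        hi = np.asarray(self.upper95, dtype=float)
        if not (len(self.levels) == len(est) == len(lo) == len(hi)):
            raise ValueError("levels and value arrays must have equal length")
        if np.any(lo > est + 1e-12) or np.any(est > hi + 1e-12):
            raise ValueError("credible bounds must bracket the estimate")
        if np.any(lo < 0) or np.any(hi > 1):
            raise ValueError("prevalences must lie in [0, 1]")

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "axis": self.axis,
                "level": list(self.levels),
                "estimate": self.estimate,
                "lower95": self.lower95,
                "upper95": self.upper95,
            }
        )


@dataclass(frozen=True)
class RatioSeries:
    """Prevalence ratio (numerator stratum / denominator stratum) per level."""

    axis: str
    levels: tuple[str, ...]
    ratio: np.ndarray

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({"axis": self.axis, "level": list(self.levels), "ratio": self.ratio})


@dataclass(frozen=True)
class StandardPopulation:
    """Age-group weights of a standard population (normalized to sum 1)."""

    age_groups: tuple[int, ...]
    weights: np.ndarray

    def __post_init__(self) -> None:
        w = np.asarray(self.weights, dtype=float)
        if len(w) != len(self.age_groups):
            raise ValueError("one weight per age group required")
        if np.any(w < 0):
            raise ValueError("weights must be non-negative")
        total = w.sum()
        if total <= 0:
            raise ValueError("weights must not all be zero")
        object.__setattr__(self, "weights", w / total)
        object.__setattr__(self, "age_groups", tuple(int(a) for a in self.age_groups))

    @classmethod
    def from_csv(cls, path) -> "StandardPopulation":
        """CSV with columns (age_group, weight); labels 'A-B' or starts."""
        from .survey_data import _parse_age_group

        df = pd.read_csv(path)
        ages = [_parse_age_group(a) for a in df["age_group"]]
        return cls(age_groups=tuple(ages), weights=df["weight"].to_numpy(dtype=float))


@dataclass(frozen=True)
class HeterogeneitySummary:
    """Posterior-mean heterogeneity surface with marginal dispersion."""

    z_mean: pd.DataFrame          # I x J, age labels x years
    per_age: pd.DataFrame         # columns: mean, sd
    per_period: pd.DataFrame      # columns: mean, sd
    overall_sd: float


def _effect_draws(samples: PosteriorSamples, axis: str) -> tuple[np.ndarray, tuple[str, ...]]:
    grid = samples.grid
    if axis == "age":
        if grid.I < 2:
            raise UnsupportedAxisError("degenerate age axis")
        return samples.alpha, tuple(grid.age_labels())
    if axis == "period":
        if not samples.spec.include_period:
            raise UnsupportedAxisError("period effect excluded from this model")
        return samples.beta, tuple(str(y) for y in grid.period_years)
    if axis == "cohort":
        if not samples.spec.include_cohort:
            raise UnsupportedAxisError("cohort effect excluded from this model")
        return samples.gamma, tuple(cohort_label(grid, k) for k in range(1, grid.K + 1))
    raise UnsupportedAxisError(f"unknown axis {axis!r}; expected one of {AXES}")


def effect_prevalence(samples: PosteriorSamples, axis: str) -> EffectSeries:
    """Prevalence curve along one axis: expit(delta + effect_t) per draw.

    Estimate = posterior mean; bounds = equal-tailed 95% interval.  The
    cohort curve covers all K indices, including those never observed in
    a cell (interpolated by the RW1 prior).
    """
    eff, levels = _effect_draws(samples, axis)
    p = expit(samples.delta[:, None] + eff)
    lo, hi = np.percentile(p, [2.5, 97.5], axis=0)
    return EffectSeries(
        axis=axis, levels=levels, estimate=p.mean(axis=0), lower95=lo, upper95=hi
    )


def prevalence_ratio(nonurban: EffectSeries, urban: EffectSeries) -> RatioSeries:
    """Ratio of two strata's prevalence curves (point estimates).

    Strata are fitted independently, so the default ratio divides the two
    posterior-mean curves level by level.
    """
    if nonurban.axis != urban.axis:
        raise ValueError(f"axis mismatch: {nonurban.axis} vs {urban.axis}")
    if nonurban.levels != urban.levels:
        raise ValueError("level mismatch between the two series")
    if np.any(urban.estimate <= 0):
        raise ZeroDivisionError("zero denominator prevalence")
    return RatioSeries(
        axis=nonurban.axis,
        levels=nonurban.levels,
        ratio=nonurban.estimate / urban.estimate,
    )


def prevalence_ratio_draws(
    numerator: PosteriorSamples, denominator: PosteriorSamples, axis: str
) -> pd.DataFrame:
    """Per-draw ratio distribution (optional alternative to point ratios).

    Pairs draws index-by-index across the two independent fits; both fits
    must have the same number of draws.  Returns level, estimate (mean of
    per-draw ratios) and 95% bounds.
    """
    pn, levels = _effect_draws(numerator, axis)
    pdm, levels_d = _effect_draws(denominator, axis)
    if levels != levels_d:
        raise ValueError("level mismatch between the two fits")
    if numerator.n_draws != denominator.n_draws:
        raise ValueError("fits must have equal draw counts to pair draws")
    rn = expit(numerator.delta[:, None] + pn) / expit(denominator.delta[:, None] + pdm)
    lo, hi = np.percentile(rn, [2.5, 97.5], axis=0)
    return pd.DataFrame(
        {"axis": axis, "level": list(levels), "estimate": rn.mean(axis=0),
         "lower95": lo, "upper95": hi}
    )


def age_standardize(prevalence_by_age: np.ndarray, std: StandardPopulation) -> float:
    """Directly age-standardized prevalence: weighted mean of age-specific
    prevalences with the standard population's (normalized) weights."""
    p = np.asarray(prevalence_by_age, dtype=float)
    if p.shape != (len(std.age_groups),):
        raise ValueError(
            f"expected one prevalence per standard-population age group "
            f"({len(std.age_groups)}), got shape {p.shape}"
        )
    return float(np.dot(std.weights, p))


def standardize_observed(table: PrevalenceTable, std: StandardPopulation) -> pd.Series:
    """Age-standardized observed prevalence per survey year (one stratum)."""
    if std.age_groups != table.age_groups:
        raise ValueError("standard population covers different age groups than the table")
    phat = observed_prevalence(table)
    vals = [age_standardize(phat[:, j], std) for j in range(table.J)]
    return pd.Series(vals, index=list(table.periods), name=table.stratum_label)


def heterogeneity_summary(samples: PosteriorSamples) -> HeterogeneitySummary:
    """Posterior-mean z_ij surface plus per-age and per-period dispersion.

    Structured (non-iid-looking) patterns in these summaries indicate
    effects missing from the model: e.g. fitting an age-only model to
    data with a declining period effect leaves a monotone trend in the
    per-period means of z.
    """
    if not samples.spec.include_heterogeneity:
        raise ValueError("heterogeneity term excluded from this model")
    grid = samples.grid
    zm = samples.z.mean(axis=0)
    z_mean = pd.DataFrame(zm, index=grid.age_labels(), columns=list(grid.period_years))
    per_age = pd.DataFrame(
        {"mean": zm.mean(axis=1), "sd": zm.std(axis=1)}, index=grid.age_labels()
    )
    per_period = pd.DataFrame(
        {"mean": zm.mean(axis=0), "sd": zm.std(axis=0)}, index=list(grid.period_years)
    )
    return HeterogeneitySummary(
        z_mean=z_mean, per_age=per_age, per_period=per_period,
        overall_sd=float(zm.std()),
    )
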