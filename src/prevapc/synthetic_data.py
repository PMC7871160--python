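"""Survey-like synthetic prevalence tables with known ground truth.

The generator emulates the structure of the smoking-prevalence tables the
model consumes: 5-year age groups 20-24 ... 75-79, survey years 2004 ...
2019 every 3 years, binomial counts per cell.  Ground-truth effect curves
are deterministic parametric shapes chosen to mimic the field's typical
findings — prevalence declining in age and over periods, rise-then-fall
across birth cohorts — so recovery tests are reproducible and
interpretable.  RW1-draw truth is available behind a flag.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.special import expit, logit

from .apc_grid import APCGrid, build_grid
from .apc_model import APCParameters, cell_probability
from .survey_data import PrevalenceTable

__all__ = [
    "SyntheticTruth",
    "SCENARIOS",
    "make_survey_grid",
    "generate_truth",
    "generate_table",
    "generate_strata_pair",
]

#: scenario -> (age active, period active, cohort active)
SCENARIOS: dict[str, tuple[bool, bool, bool]] = {
    "null": (False, False, False),
    "age_only": (True, False, False),
    "age_period": (True, True, False),
    "age_cohort": (True, False, True),
    "full": (True, True, True),
}

# log-odds amplitudes of the unit-scale effect shapes; spans chosen to
# resemble a men-like stratum (prevalence ~0.5 young falling to ~0.2 old,
# moderate period decline, rise-then-fall cohort bump)
_AGE_SPAN = 1.4
_PERIOD_SPAN = 0.8
_COHORT_AMPLITUDE = 0.6


@dataclass(frozen=True)
class SyntheticTruth:
    """Generating parameters for one synthetic stratum."""

    params: APCParameters
    grid: APCGrid
    denominators: np.ndarray = field(repr=False)
    seed: int
    scenario: str = "full"

    def cell_prevalence(self) -> np.ndarray:
        """True cell prevalences p_ij = expit(eta_ij)."""
        return cell_probability(self.params, self.grid)


def make_survey_grid() -> APCGrid:
    """The 12 x 6 study lattice: ages 20-24..75-79, years 2004..2019, K = 71."""
    return build_grid(range(20, 80, 5), range(2004, 2020, 3))


def _centered(v: np.ndarray) -> np.ndarray:
    return v - v.mean() if len(v) else v


def _unit_positions(length: int) -> np.ndarray:
    return np.linspace(0.0, 1.0, length) if length > 1 else np.zeros(length)


def generate_truth(
    grid: APCGrid,
    scenario: str = "full",
    effect_scale: float = 1.0,
    heterogeneity_sd: float = 0.05,
    seed: int = 0,
    baseline_prevalence: float = 0.35,
    denominator: int = 10_000,
    effect_curves: str = "parametric",
) -> SyntheticTruth:
    """Draw a ground-truth parameter set on the given lattice.

    Parameters
    ----------
    scenario
        Which effects are active: one of ``null``, ``age_only``,
        ``age_period``, ``age_cohort``, ``full``.  Inactive effects are
        identically zero.
    effect_scale
        Multiplier on the log-odds amplitude of every active effect
        (0 flattens them all).
    heterogeneity_sd
        SD of the iid normal cell-level term z_ij on the log-odds scale.
    baseline_prevalence
        Overall level; the intercept is its logit.
    effect_curves
        ``"parametric"`` (default, deterministic shapes) or ``"rw1"``
        (centered random-walk draws with increment SD effect_scale * 0.1).
    """
    if scenario not in SCENARIOS:
        raise ValueError(f"unknown scenario {scenario!r}; expected one of {list(SCENARIOS)}")
    if effect_scale < 0:
        raise ValueError("effect_scale must be non-negative")
    use_age, use_period, use_cohort = SCENARIOS[scenario]
    I, J, K = grid.I, grid.J, grid.K
    rng = np.random.default_rng(np.random.SeedSequence([int(seed), 0]))

    def rw1(length: int) -> np.ndarray:
        incr = rng.normal(0.0, 0.1 * effect_scale, size=max(length - 1, 0))
        return _centered(np.concatenate([[0.0], np.cumsum(incr)]))

    if effect_curves == "rw1":
        alpha = rw1(I) if use_age else np.zeros(I)
        beta = rw1(J) if use_period else np.zeros(J)
        gamma = rw1(K) if use_cohort else np.zeros(K)
    elif effect_curves == "parametric":
        ta, tp, tc = _unit_positions(I), _unit_positions(J), _unit_positions(K)
        alpha = (
            _centered(-_AGE_SPAN * effect_scale * ta) if use_age else np.zeros(I)
        )
        beta = (
            _centered(-_PERIOD_SPAN * effect_scale * tp) if use_period else np.zeros(J)
        )
        # quadratic bump peaking about a third of the way through the
        # cohort axis: rise across early cohorts, fall across late ones
        gamma = (
            _centered(_COHORT_AMPLITUDE * effect_scale * (1.0 - ((tc - 0.35) / 0.55) ** 2))
            if use_cohort
            else np.zeros(K)
        )
    else:
        raise ValueError("effect_curves must be 'parametric' or 'rw1'")

    z = rng.normal(0.0, heterogeneity_sd, size=(I, J)) if heterogeneity_sd > 0 else np.zeros((I, J))

    def inc_sd(v: np.ndarray) -> float:
        return float(np.std(np.diff(v))) if len(v) > 1 else 0.0

    params = APCParameters(
        delta=float(logit(baseline_prevalence)),
        alpha=alpha, beta=beta, gamma=gamma, z=z,
        sigma_alpha=inc_sd(alpha), sigma_beta=inc_sd(beta),
        sigma_gamma=inc_sd(gamma), sigma_z=float(heterogeneity_sd),
    )
    denominators = np.full((I, J), int(denominator), dtype=np.int64)
    p = cell_probability(params, grid)
    assert np.all((p > 0) & (p < 1))
    return SyntheticTruth(
        params=params, grid=grid, denominators=denominators,
        seed=int(seed), scenario=scenario,
    )


def generate_table(truth: SyntheticTruth, stratum_label: str = "synthetic") -> PrevalenceTable:
    """Draw the binomial counts y_ij ~ Binomial(n_ij, p_ij) for one truth.

    Deterministic given the truth (its stored seed feeds a dedicated
    substream, so truth and counts are independently reproducible).
    """
    rng = np.random.default_rng(np.random.SeedSequence([truth.seed, 1]))
    p = truth.cell_prevalence()
    y = rng.binomial(truth.denominators, p)
    return PrevalenceTable(
        stratum_label=stratum_label,
        age_groups=truth.grid.age_starts,
        periods=truth.grid.period_years,
        smokers=y,
        denominators=truth.denominators,
    )


def generate_strata_pair(
    grid: APCGrid,
    period_gap: float = 0.3,
    seed: int = 0,
    **kwargs,
) -> dict[str, SyntheticTruth]:
    """Urban / non-urban truth pair whose period declines differ.

    The urban stratum gets the full period decline; the non-urban stratum's
    decline is shallower by ``period_gap`` (log-odds span), emulating a
    faster urban drop in prevalence.  Both strata share the age and cohort
    shapes.
    """
    urban = generate_truth(grid, scenario="full", seed=seed, **kwargs)
    nonurban = generate_truth(grid, scenario="full", seed=seed + 1, **kwargs)
    J = grid.J
    softer = _centered(period_gap * _unit_positions(J))
    beta_nu = nonurban.params.beta + softer
    params_nu = APCParameters(
        delta=nonurban.params.delta, alpha=nonurban.params.alpha,
        beta=beta_nu, gamma=nonurban.params.gamma, z=nonurban.params.z,
        sigma_alpha=nonurban.params.sigma_alpha,
        sigma_beta=float(np.std(np.diff(beta_nu))) if J > 1 else 0.0,
        sigma_gamma=nonurban.params.sigma_gamma, sigma_z=nonurban.params.sigma_z,
    )
    return {
        "urban": urban,
        "non-urban": SyntheticTruth(
            params=params_nu, grid=grid, denominators=nonurban.denominators,
            seed=nonurban.seed, scenario="full",
        ),
    }
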