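"""The Bayesian binomial age-period-cohort model family.

Smoker counts are modelled as ``y_ij ~ Binomial(n_ij, p_ij)`` with log-odds

    eta_ij = delta + alpha_i + beta_j + gamma_k(i,j) + z_ij,

where delta is the intercept, alpha/beta/gamma are age, period and cohort
effects and z_ij is a cell-level heterogeneity term absorbing
extra-binomial variation.  Each effect vector is constrained to sum to
zero so that the overall level lives in delta; first-order random-walk
(RW1) priors smooth each effect along its axis and interpolate cohort
indices never hit by a cell.  The four standard submodels keep the age
effect and toggle the period and cohort effects: age (a), age-period
(ap), age-cohort (ac) and the full model (apc).

The well-known APC aliasing (linear trends in alpha, beta, gamma trading
off against each other) is not resolved beyond sum-to-zero plus RW1
shrinkage; fitted probabilities and second differences of effects remain
identified.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np
import yaml
from scipy.special import expit, gammaln
from scipy.stats import halfnorm, norm

from .apc_grid import APCGrid
from .survey_data import PrevalenceTable

__all__ = [
    "APCModelSpec",
    "APCParameters",
    "MODEL_NAMES",
    "linear_predictor",
    "cell_probability",
    "log_likelihood",
    "log_prior",
    "center_effects",
]

#: short names of the four submodels -> (include_period, include_cohort)
MODEL_NAMES: dict[str, tuple[bool, bool]] = {
    "a": (False, False),
    "ap": (True, False),
    "ac": (False, True),
    "apc": (True, True),
}


@dataclass(frozen=True)
class APCModelSpec:
    """Which effects are included, plus prior hyperparameters.

    ``prior_scale_effects`` is the scale of the half-normal hyperprior on
    the RW1 increment SDs (sigma_alpha, sigma_beta, sigma_gamma);
    ``prior_scale_heterogeneity`` the same for sigma_z; both on the
    log-odds scale.  ``prior_scale_intercept`` is the SD of the
    Normal(0, .) prior on the intercept delta.
    """

    include_period: bool = True
    include_cohort: bool = True
    include_heterogeneity: bool = True
    prior_scale_effects: float = 1.0
    prior_scale_heterogeneity: float = 1.0
    prior_scale_intercept: float = 10.0

    def __post_init__(self) -> None:
        for name in ("prior_scale_effects", "prior_scale_heterogeneity", "prior_scale_intercept"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")

    @property
    def name(self) -> str:
        """Short submodel name: a, ap, ac or apc."""
        for name, flags in MODEL_NAMES.items():
            if flags == (self.include_period, self.include_cohort):
                return name
        raise AssertionError("unreachable")

    @classmethod
    def from_name(cls, name: str, **kwargs) -> "APCModelSpec":
        try:
            period, cohort = MODEL_NAMES[name.lower()]
        except KeyError:
            raise ValueError(f"unknown model name {name!r}; expected one of {list(MODEL_NAMES)}")
        return cls(include_period=period, include_cohort=cohort, **kwargs)

    def to_yaml(self, path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(self.__dict__ | {}, fh, sort_keys=False)

    @classmethod
    def from_yaml(cls, path) -> "APCModelSpec":
        with open(path) as fh:
            return cls(**yaml.safe_load(fh))


@dataclass(frozen=True)
class APCParameters:
    """One point in parameter space (or one posterior draw).

    Effects excluded from a model are identically zero vectors; sigmas of
    inactive effects may be zero.
    """

    delta: float
    alpha: np.ndarray
    beta: np.ndarray
    gamma: np.ndarray
    z: np.ndarray
    sigma_alpha: float = 0.0
    sigma_beta: float = 0.0
    sigma_gamma: float = 0.0
    sigma_z: float = 0.0

    def __post_init__(self) -> None:
        object.__setattr__(self, "alpha", np.asarray(self.alpha, dtype=float))
        object.__setattr__(self, "beta", np.asarray(self.beta, dtype=float))
        object.__setattr__(self, "gamma", np.asarray(self.gamma, dtype=float))
        object.__setattr__(self, "z", np.asarray(self.z, dtype=float))
        if self.z.ndim != 2:
            raise ValueError("z must be an (I, J) matrix")
        for s in (self.sigma_alpha, self.sigma_beta, self.sigma_gamma, self.sigma_z):
            if s < 0:
                raise ValueError("sigmas must be non-negative")


def linear_predictor(params: APCParameters, grid: APCGrid) -> np.ndarray:
    """Cell log-odds eta_ij = delta + alpha_i + beta_j + gamma_k(i,j) + z_ij."""
    I, J = grid.I, grid.J
    if params.alpha.shape != (I,) or params.beta.shape != (J,):
        raise ValueError(
            f"alpha/beta lengths {params.alpha.shape[0]}/{params.beta.shape[0]} "
            f"do not match grid ({I}, {J})"
        )
    if params.gamma.shape != (grid.K,):
        raise ValueError(f"gamma length {params.gamma.shape[0]} != K = {grid.K}")
    if params.z.shape != (I, J):
        raise ValueError(f"z shape {params.z.shape} != ({I}, {J})")
    k0 = grid.cohort_index - 1  # 0-based lookup
    return (
        params.delta
        + params.alpha[:, None]
        + params.beta[None, :]
        + params.gamma[k0]
        + params.z
    )


def cell_probability(params: APCParameters, grid: APCGrid) -> np.ndarray:
    """Cell prevalences p_ij = expit(eta_ij)."""
    return expit(linear_predictor(params, grid))


def log_likelihood(params: APCParameters, table: PrevalenceTable, grid: APCGrid) -> float:
    """Binomial log-likelihood, including the binomial coefficients.

    The coefficients are constant in the parameters but keep deviances —
    and hence DIC values — comparable across submodels.
    """
    if (table.I, table.J) != (grid.I, grid.J):
        raise ValueError("table and grid dimensions do not match")
    eta = linear_predictor(params, grid)
    y = table.smokers
    n = table.denominators
    # log C(n, y) + y*eta - n*log(1 + e^eta), numerically stable in eta
    log_coef = gammaln(n + 1) - gammaln(y + 1) - gammaln(n - y + 1)
    return float(np.sum(log_coef + y * eta - n * np.logaddexp(0.0, eta)))


def _rw1_logpdf(effect: np.ndarray, sigma: float) -> float:
    """Sum of Normal(0, sigma^2) log-densities of the first differences."""
    if len(effect) < 2:
        return 0.0
    if sigma <= 0:
        raise ValueError("non-positive sigma for an active effect")
    return float(np.sum(norm.logpdf(np.diff(effect), scale=sigma)))


def log_prior(params: APCParameters, spec: APCModelSpec) -> float:
    """Joint log prior density of one parameter point.

    RW1 increment terms for each active effect (the cohort walk runs over
    the full 1..K grid, interpolating unobserved indices), iid
    Normal(0, sigma_z^2) terms for the heterogeneity cells, half-normal
    hyperpriors on the active sigmas and a Normal(0, scale^2) prior on the
    intercept.  Inactive effects contribute nothing.
    """
    lp = float(norm.logpdf(params.delta, scale=spec.prior_scale_intercept))
    active = [(params.alpha, params.sigma_alpha)]
    if spec.include_period:
        active.append((params.beta, params.sigma_beta))
    if spec.include_cohort:
        active.append((params.gamma, params.sigma_gamma))
    for effect, sigma in active:
        if len(effect) >= 2:
            lp += _rw1_logpdf(effect, sigma)
            lp += float(halfnorm.logpdf(sigma, scale=spec.prior_scale_effects))
    if spec.include_heterogeneity:
        if params.sigma_z <= 0:
            raise ValueError("non-positive sigma_z with heterogeneity active")
        lp += float(np.sum(norm.logpdf(params.z, scale=params.sigma_z)))
        lp += float(halfnorm.logpdf(params.sigma_z, scale=spec.prior_scale_heterogeneity))
    return lp


def center_effects(params: APCParameters) -> APCParameters:
    """Re-impose the sum-to-zero gauge, pushing effect means into delta.

    The linear predictor is exactly invariant: each effect loses its mean
    and delta gains the sum of the removed means.  Idempotent.
    """
    means = {
        "alpha": params.alpha.mean() if len(params.alpha) else 0.0,
        "beta": params.beta.mean() if len(params.beta) else 0.0,
        "gamma": params.gamma.mean() if len(params.gamma) else 0.0,
    }
    return replace(
        params,
        delta=params.delta + means["alpha"] + means["beta"] + means["gamma"],
        alpha=params.alpha - means["alpha"],
        beta=params.beta - means["beta"],
        gamma=params.gamma - means["gamma"],
    )
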