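"""A small Hamiltonian Monte Carlo engine.

Static-trajectory HMC with dual-averaging step-size tuning (warmup only)
and a pluggable mass matrix:

* :class:`DiagonalMass` — diagonal metric, refreshed once mid-warmup from
  sample variances (the usual windowed scheme);
* :class:`DenseMass` — full covariance metric, typically the inverse
  Gauss-Newton Hessian at the posterior mode.  A dense metric is what
  makes the age-period-cohort posterior tractable: the linear-trend
  trade-off between the age, period and cohort effects creates a strongly
  correlated, nearly flat ridge that no diagonal preconditioner can
  absorb.

Everything is plain numpy; the log density and its gradient are supplied
as one callable so the engine stays model-agnostic.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable

import numpy as np
from scipy.linalg import cho_factor, cho_solve, cholesky, solve_triangular

__all__ = ["DiagonalMass", "DenseMass", "HMCChainResult", "sample_chain"]

LogpGrad = Callable[[np.ndarray], tuple[float, np.ndarray]]

# treat an energy jump this large as a divergent trajectory
_DIVERGENCE_ENERGY = 1000.0


class DiagonalMass:
    """Diagonal momentum covariance (= estimated posterior precision)."""

    adaptive = True

    def __init__(self, precision_diag: np.ndarray):
        self._set(np.asarray(precision_diag, dtype=float))

    def _set(self, m: np.ndarray) -> None:
        if np.any(~np.isfinite(m)) or np.any(m <= 0):
            raise ValueError("mass diagonal must be positive and finite")
        self.m = m
        self._sqrt_m = np.sqrt(m)
        self._inv_m = 1.0 / m

    def sample_momentum(self, rng: np.random.Generator) -> np.ndarray:
        return rng.standard_normal(self.m.size) * self._sqrt_m

    def velocity(self, p: np.ndarray) -> np.ndarray:
        return p * self._inv_m

    def kinetic(self, p: np.ndarray) -> float:
        return 0.5 * float(np.sum(p * p * self._inv_m))

    def refresh(self, window: np.ndarray) -> None:
        """Replace by shrunken inverse sample variances of warmup draws."""
        n = len(window)
        var = np.var(window, axis=0)
        shrink = n / (n + 5.0)
        var = shrink * var + (1.0 - shrink) * self._inv_m
        good = np.isfinite(var) & (var > 0)
        m = self.m.copy()
        m[good] = 1.0 / var[good]
        self._set(m)


class DenseMass:
    """Dense momentum covariance given as a precision matrix.

    With momentum p ~ N(0, H) and velocity H^{-1} p, HMC on a Gaussian
    posterior with precision H mixes in O(1) trajectories regardless of
    conditioning.
    """

    adaptive = False

    def __init__(self, precision: np.ndarray):
        H = 0.5 * (precision + precision.T)
        dim = H.shape[0]
        jitter = 1e-10 * np.trace(H) / dim
        for _ in range(8):
            try:
                self._chol_prec = cholesky(H + jitter * np.eye(dim), lower=True)
                break
            except np.linalg.LinAlgError:
                jitter *= 100.0
        else:  # pragma: no cover - pathological input
            raise np.linalg.LinAlgError("precision matrix is not positive definite")
        self._cov_factor = cho_factor(H + jitter * np.eye(dim), lower=True)

    def sample_momentum(self, rng: np.random.Generator) -> np.ndarray:
        xi = rng.standard_normal(self._chol_prec.shape[0])
        return self._chol_prec @ xi

    def velocity(self, p: np.ndarray) -> np.ndarray:
        return cho_solve(self._cov_factor, p)

    def kinetic(self, p: np.ndarray) -> float:
        return 0.5 * float(p @ self.velocity(p))

    def sample_point(self, rng: np.random.Generator, center: np.ndarray,
                     scale: float = 1.0) -> np.ndarray:
        """Draw from N(center, scale^2 * H^{-1}); used for chain inits."""
        xi = rng.standard_normal(center.size)
        return center + scale * solve_triangular(self._chol_prec.T, xi, lower=False)

    def refresh(self, window: np.ndarray) -> None:  # pragma: no cover
        pass


def slice_sample_1d(
    logf: Callable[[float], float],
    x0: float,
    rng: np.random.Generator,
    width: float = 0.25,
    max_steps: int = 50,
    lower: float = -np.inf,
    upper: float = np.inf,
) -> float:
    """One update of Neal's univariate slice sampler with stepping out."""
    logy = logf(x0) + np.log(rng.uniform())
    u = rng.uniform()
    lo = max(x0 - width * u, lower)
    hi = min(lo + width, upper)
    steps = int(rng.integers(0, max_steps + 1))
    j, k = steps, max_steps - steps
    while j > 0 and lo > lower and logf(lo) > logy:
        lo = max(lo - width, lower)
        j -= 1
    while k > 0 and hi < upper and logf(hi) > logy:
        hi = min(hi + width, upper)
        k -= 1
    for _ in range(100):
        x1 = rng.uniform(lo, hi)
        if logf(x1) > logy:
            return float(x1)
        if x1 < x0:
            lo = x1
        else:
            hi = x1
    return float(x0)  # pragma: no cover - shrinkage exhausted


@dataclass
class HMCChainResult:
    draws: np.ndarray  # (n_draws, dim)
    accept_rate: float
    step_size: float
    divergences: int
    mass: object = field(repr=False)


class _DualAveraging:
    """Nesterov dual averaging of log step size (Hoffman & Gelman scheme)."""

    def __init__(self, eps0: float, target: float = 0.8,
                 gamma: float = 0.05, t0: float = 10.0, kappa: float = 0.75):
        self.mu = np.log(10.0 * eps0)
        self.target = target
        self.gamma, self.t0, self.kappa = gamma, t0, kappa
        self.log_eps = np.log(eps0)
        self.log_eps_bar = np.log(eps0)
        self.h_bar = 0.0
        self.t = 0

    def update(self, accept_prob: float) -> float:
        self.t += 1
        frac = 1.0 / (self.t + self.t0)
        self.h_bar = (1 - frac) * self.h_bar + frac * (self.target - accept_prob)
        self.log_eps = self.mu - np.sqrt(self.t) / self.gamma * self.h_bar
        w = self.t ** (-self.kappa)
        self.log_eps_bar = w * self.log_eps + (1 - w) * self.log_eps_bar
        return float(np.exp(self.log_eps))


def _leapfrog(logp_grad: LogpGrad, x, p, grad, eps: float, n_steps: int, mass):
    """n_steps leapfrog steps; returns (x, p, logp, grad) or None on overflow."""
    p = p + 0.5 * eps * grad
    for step in range(n_steps):
        x = x + eps * mass.velocity(p)
        logp, grad = logp_grad(x)
        if not np.isfinite(logp):
            return None
        if step < n_steps - 1:
            p = p + eps * grad
    p = p + 0.5 * eps * grad
    return x, p, logp, grad


def _find_initial_step(logp_grad: LogpGrad, x, logp, grad, mass, rng) -> float:
    """Double/halve a trial step until one-step acceptance crosses 0.5."""
    eps = 0.1
    p = mass.sample_momentum(rng)
    h0 = -logp + mass.kinetic(p)

    def one_step_dh(eps):
        out = _leapfrog(logp_grad, x, p, grad, eps, 1, mass)
        if out is None:
            return -np.inf
        _, p1, logp1, _ = out
        return h0 - (-logp1 + mass.kinetic(p1))

    dh = one_step_dh(eps)
    direction = 1.0 if dh > np.log(0.5) else -1.0
    for _ in range(50):
        eps = eps * (2.0 ** direction)
        dh = one_step_dh(eps)
        if (direction == 1.0 and dh <= np.log(0.5)) or (
            direction == -1.0 and dh >= np.log(0.5)
        ):
            break
        if eps < 1e-10 or eps > 1e3:
            break
    return float(np.clip(eps, 1e-10, 1e3))


def sample_chain(
    logp_grad: LogpGrad,
    x0: np.ndarray,
    n_warmup: int,
    n_draws: int,
    rng: np.random.Generator,
    mass: DiagonalMass | DenseMass | None = None,
    target_accept: float = 0.8,
    traj_length: float = 1.5,
    max_steps: int = 64,
    aux_update: Callable[[np.ndarray, np.random.Generator], None] | None = None,
    metric_refresh: Callable[[np.ndarray], "DiagonalMass | DenseMass"] | None = None,
) -> HMCChainResult:
    """Run one HMC chain; returns kept draws only.

    ``traj_length`` is the nominal integration time; the number of
    leapfrog steps is round(traj_length / step), capped at ``max_steps``,
    with a +-10% step-size jitter to avoid periodic orbits.

    ``aux_update``, if given, is an extra transition kernel applied in
    place to the state before every HMC sweep (e.g. exact Gibbs updates
    of coordinates HMC mixes poorly, such as hierarchical scales).
    """
    x = np.array(x0, dtype=float)
    dim = x.size
    mass = DiagonalMass(np.ones(dim)) if mass is None else mass
    logp, grad = logp_grad(x)
    if not np.isfinite(logp):
        raise FloatingPointError("non-finite log density at the initial point")

    eps = _find_initial_step(logp_grad, x, logp, grad, mass, rng)
    da = _DualAveraging(eps, target=target_accept)

    window_start = max(1, int(0.30 * n_warmup))
    window_end = max(window_start + 1, int(0.85 * n_warmup))
    window: list[np.ndarray] = []

    draws = np.empty((n_draws, dim))
    n_accept = 0.0
    n_total = 0
    divergences = 0

    for it in range(n_warmup + n_draws):
        warming = it < n_warmup
        if not warming and it == n_warmup and n_warmup > 0:
            eps = float(np.exp(da.log_eps_bar))
        if aux_update is not None:
            aux_update(x, rng)
            logp, grad = logp_grad(x)
        eps_it = eps * rng.uniform(0.9, 1.1)
        n_steps = int(np.clip(round(traj_length / eps_it), 1, max_steps))
        p0 = mass.sample_momentum(rng)
        h0 = -logp + mass.kinetic(p0)
        out = _leapfrog(logp_grad, x, p0, grad, eps_it, n_steps, mass)
        if out is None:
            accept_prob = 0.0
            divergences += not warming
        else:
            x1, p1, logp1, grad1 = out
            dh = h0 - (-logp1 + mass.kinetic(p1))
            if not np.isfinite(dh) or -dh > _DIVERGENCE_ENERGY:
                accept_prob = 0.0
                divergences += not warming
            else:
                accept_prob = min(1.0, float(np.exp(min(dh, 0.0))))
                if rng.uniform() < accept_prob:
                    x, logp, grad = x1, logp1, grad1

        if warming:
            eps = da.update(accept_prob)
            if it == window_end - 1 and metric_refresh is not None:
                # re-evaluate the metric at the chain's current position
                # (curvature depends on where the scales have settled)
                mass = metric_refresh(x)
                logp, grad = logp_grad(x)
                da = _DualAveraging(eps, target=target_accept)
            elif mass.adaptive:
                if window_start <= it < window_end:
                    window.append(x.copy())
                if it == window_end - 1 and len(window) >= 10:
                    mass.refresh(np.asarray(window))
                    da = _DualAveraging(eps, target=target_accept)
        else:
            draws[it - n_warmup] = x
            n_accept += accept_prob
            n_total += 1

    return HMCChainResult(
        draws=draws,
        accept_rate=n_accept / max(n_total, 1),
        step_size=eps,
        divergences=divergences,
        mass=mass,
    )
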