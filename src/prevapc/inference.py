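"""Posterior sampling, convergence checking and DIC for the APC model.

The sampler works in an unconstrained parameterization chosen for
geometry rather than readability:

* each effect vector is expressed in an orthonormal basis of the
  sum-to-zero subspace (the RW1 increment penalty restricted to that
  subspace is a proper Gaussian, because its only flat direction — the
  constant vector — is excluded);
* every block (age, period, cohort, heterogeneity) is sampled centered
  or non-centered depending on whether the likelihood or the prior
  carries more precision per coordinate at the posterior mode — decided
  per fit from a deterministic pilot mode search; all standard
  deviations live on the log scale and are Gibbs-updated from
  closed-form conditionals (via interweaving for non-centered blocks);
* the exactly-aliased age-period-cohort linear trend gets its own exact
  Gibbs draw each sweep (the likelihood is perfectly flat along it).

Reported draws are mapped back to the natural parameters (alpha, beta,
gamma, z, sigmas) and re-centered, so every stored draw satisfies the
sum-to-zero constraints.  Convergence is assessed with rank-normalized
split R-hat (arviz).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import arviz as az
import numpy as np
import pandas as pd
from scipy.linalg import helmert
from scipy.special import expit, gammaln, logit

from ._hmc import DenseMass, DiagonalMass, sample_chain
from .apc_grid import APCGrid
from .apc_model import APCModelSpec, APCParameters, center_effects
from .survey_data import PrevalenceTable

__all__ = [
    "PosteriorSamples",
    "DICResult",
    "ConvergenceReport",
    "SingleChainError",
    "sample_posterior",
    "check_convergence",
    "compute_dic",
    "save_fit",
    "load_fit",
]


class SingleChainError(RuntimeError):
    """R-hat requires at least two chains."""


# --------------------------------------------------------------------------
# transformed-space model
# --------------------------------------------------------------------------

def _sum_zero_basis(length: int) -> tuple[np.ndarray, np.ndarray]:
    """Orthonormal basis B (length x length-1) of the sum-to-zero subspace
    and the RW1 precision M = (D B)' (D B) in basis coordinates."""
    if length < 2:
        return np.zeros((length, 0)), np.zeros((0, 0))
    B = helmert(length).T  # columns orthonormal, each summing to zero
    DB = np.diff(B, axis=0)
    return B, DB.T @ DB


@dataclass
class _Block:
    name: str
    start: int
    size: int

    @property
    def sl(self) -> slice:
        return slice(self.start, self.start + self.size)


@dataclass
class _EffectDesc:
    """One additive block of the linear predictor: basis, prior
    precision, hyperprior scale, and parameterization style.

    The smooth effects use the orthonormal sum-to-zero basis with the
    RW1 increment precision; the heterogeneity term uses the identity
    basis with an iid prior.  ``centered`` blocks are sampled on their
    natural scale (right when the likelihood dominates every
    coordinate); non-centered blocks are sampled as unit-scale raw
    coordinates times exp(t) (right when the prior dominates).  The
    style is chosen per block from the information balance at the
    posterior mode.
    """

    vname: str
    tname: str
    B: np.ndarray
    M: np.ndarray
    hyper_scale: float
    centered: bool


class _TransformedModel:
    """Packs/unpacks the unconstrained vector and evaluates logp + grad."""

    def __init__(
        self,
        table: PrevalenceTable,
        grid: APCGrid,
        spec: APCModelSpec,
        styles: dict[str, bool] | None = None,
    ):
        if (table.I, table.J) != (grid.I, grid.J):
            raise ValueError("table and grid dimensions do not match")
        self.table, self.grid, self.spec = table, grid, spec
        self.y = table.smokers.astype(float)
        self.n = table.denominators.astype(float)
        I, J, K = grid.I, grid.J, grid.K
        self.I, self.J, self.K = I, J, K
        self.k0 = (grid.cohort_index - 1).ravel()
        self.row_idx = np.repeat(np.arange(I), J)
        self.col_idx = np.tile(np.arange(J), I)

        styles = styles or {}
        s_eff = spec.prior_scale_effects
        self.effects: dict[str, _EffectDesc] = {}
        if I >= 2:
            B, M = _sum_zero_basis(I)
            self.effects["alpha"] = _EffectDesc(
                "v_alpha", "t_alpha", B, M, s_eff, styles.get("alpha", True))
        if spec.include_period and J >= 2:
            B, M = _sum_zero_basis(J)
            self.effects["beta"] = _EffectDesc(
                "v_beta", "t_beta", B, M, s_eff, styles.get("beta", True))
        if spec.include_cohort and K >= 2:
            B, M = _sum_zero_basis(K)
            self.effects["gamma"] = _EffectDesc(
                "v_gamma", "t_gamma", B, M, s_eff, styles.get("gamma", False))
        if spec.include_heterogeneity:
            ncells = I * J
            self.effects["z"] = _EffectDesc(
                "v_z", "t_z", np.eye(ncells), np.eye(ncells),
                spec.prior_scale_heterogeneity, styles.get("z", False))

        blocks = [("delta", 1)]
        for e in self.effects.values():
            blocks.append((e.vname, e.B.shape[1]))
        for e in self.effects.values():
            blocks.append((e.tname, 1))
        self.blocks: dict[str, _Block] = {}
        pos = 0
        for name, size in blocks:
            self.blocks[name] = _Block(name, pos, size)
            pos += size
        self.dim = pos
        self._init_trend_direction()

    def _init_trend_direction(self) -> None:
        """Precompute the exactly-aliased linear-trend direction.

        Because k(i, j) is a linear function of i and j, a linear trend
        in the cohort effect can be absorbed exactly by linear trends in
        the age and period effects plus the intercept, leaving every
        eta_ij unchanged.  The likelihood is therefore perfectly flat
        along this combined direction and its conditional posterior is
        available in closed form up to a 1-D density — sampled exactly
        in the Gibbs sweep.
        """
        self.trend = None
        if not {"alpha", "beta", "gamma"} <= set(self.effects):
            return
        I, J, K = self.I, self.J, self.K
        grid = self.grid
        i = np.arange(1, I + 1)
        j = np.arange(1, J + 1)
        k = np.arange(1, K + 1)
        gamma_add = k - k.mean()
        alpha_raw = grid.age_step * (I - i).astype(float)
        beta_raw = grid.period_step * (j - 1).astype(float)
        alpha_add = alpha_raw - alpha_raw.mean()
        beta_add = beta_raw - beta_raw.mean()
        delta_add = 1.0 - k.mean() + alpha_raw.mean() + beta_raw.mean()
        e_a, e_b, e_g = self.effects["alpha"], self.effects["beta"], self.effects["gamma"]
        # gamma gains the trend, alpha/beta/delta compensate with the
        # opposite sign so that eta stays exactly unchanged
        self.trend = {
            "delta_add": -float(delta_add),
            "alpha": -(e_a.B.T @ alpha_add),
            "beta": -(e_b.B.T @ beta_add),
            "gamma": e_g.B.T @ gamma_add,
        }

    # -- helpers --------------------------------------------------------
    def _margin(self, r: np.ndarray, name: str) -> np.ndarray:
        """Accumulate a cell array onto one block's coordinate axis."""
        if name == "alpha":
            return r.sum(axis=1)
        if name == "beta":
            return r.sum(axis=0)
        if name == "gamma":
            return np.bincount(self.k0, weights=r.ravel(), minlength=self.K)
        return r.ravel()

    def _expand(self, effect: np.ndarray, name: str) -> np.ndarray:
        """Broadcast one block's natural vector onto the (I, J) lattice."""
        if name == "alpha":
            return np.broadcast_to(effect[:, None], (self.I, self.J))
        if name == "beta":
            return np.broadcast_to(effect[None, :], (self.I, self.J))
        if name == "gamma":
            return effect[self.k0].reshape(self.I, self.J)
        return effect.reshape(self.I, self.J)

    def _cell_rows(self, name: str) -> np.ndarray:
        return {"alpha": self.row_idx, "beta": self.col_idx, "gamma": self.k0,
                "z": np.arange(self.I * self.J)}[name]

    def _effect_value(self, x: np.ndarray, name: str) -> np.ndarray:
        """Natural-scale vector of one block at x (zeros when inactive)."""
        if name not in self.effects:
            size = {"alpha": self.I, "beta": self.J, "gamma": self.K,
                    "z": self.I * self.J}[name]
            return np.zeros(size)
        e = self.effects[name]
        v = x[self.blocks[e.vname].sl]
        raw = e.B @ v
        return raw if e.centered else float(np.exp(x[self.blocks[e.tname].start])) * raw

    def natural(self, x: np.ndarray) -> APCParameters:
        """Map an unconstrained point to natural APC parameters."""
        b = self.blocks

        def sigma(name):
            e = self.effects.get(name)
            return float(np.exp(x[b[e.tname].start])) if e else 0.0

        return APCParameters(
            delta=float(x[0]),
            alpha=self._effect_value(x, "alpha"),
            beta=self._effect_value(x, "beta"),
            gamma=self._effect_value(x, "gamma"),
            z=self._effect_value(x, "z").reshape(self.I, self.J),
            sigma_alpha=sigma("alpha"), sigma_beta=sigma("beta"),
            sigma_gamma=sigma("gamma"), sigma_z=sigma("z"),
        )

    def _eta(self, x: np.ndarray) -> np.ndarray:
        eta = np.full((self.I, self.J), float(x[0]))
        for name in self.effects:
            eta = eta + self._expand(self._effect_value(x, name), name)
        return eta

    def logp_grad(self, x: np.ndarray) -> tuple[float, np.ndarray]:
        spec = self.spec
        b = self.blocks
        grad = np.zeros(self.dim)

        # reject absurd scale coordinates before exp() can overflow
        for e in self.effects.values():
            if abs(float(x[b[e.tname].start])) > 40.0:
                return -np.inf, grad

        eta = self._eta(x)
        mu = expit(eta)
        lp = float(np.sum(self.y * eta - self.n * np.logaddexp(0.0, eta)))
        r = self.y - self.n * mu  # d loglik / d eta

        delta = float(x[0])
        s_d = spec.prior_scale_intercept
        lp += -0.5 * delta * delta / (s_d * s_d)
        grad[0] = np.sum(r) - delta / (s_d * s_d)

        for name, e in self.effects.items():
            v = x[b[e.vname].sl]
            t = float(x[b[e.tname].start])
            sig2 = np.exp(2.0 * t)
            s2 = e.hyper_scale ** 2
            r_margin = self._margin(r, name)
            Mv = e.M @ v
            m = e.M.shape[0]
            if e.centered:
                # Gaussian prior with precision M / sigma^2 on the effect
                inv_s2 = np.exp(-2.0 * t)
                q = float(v @ Mv)
                lp += -0.5 * q * inv_s2 - m * t
                grad[b[e.vname].sl] = r_margin @ e.B - inv_s2 * Mv
                grad[b[e.tname].sl] = q * inv_s2 - m - sig2 / s2 + 1.0
            else:
                # unit-scale prior on v; effect = sigma * B v
                sig = np.exp(t)
                effect = sig * (e.B @ v)
                lp += -0.5 * float(v @ Mv)
                grad[b[e.vname].sl] = sig * (r_margin @ e.B) - Mv
                grad[b[e.tname].sl] = float(r_margin @ effect) - sig2 / s2 + 1.0
            # half-normal hyperprior on sigma = exp(t), with Jacobian
            lp += -0.5 * sig2 / s2 + t

        return lp, grad

    def jacobian(self, x: np.ndarray) -> np.ndarray:
        """(cells x dim) Jacobian of the cell log-odds eta wrt the
        unconstrained parameters."""
        b = self.blocks
        ncells = self.I * self.J
        J = np.zeros((ncells, self.dim))
        J[:, 0] = 1.0
        for name, e in self.effects.items():
            rows = self._cell_rows(name)
            if e.centered:
                J[:, b[e.vname].sl] = e.B[rows, :]
            else:
                sig = float(np.exp(x[b[e.tname].start]))
                J[:, b[e.vname].sl] = sig * e.B[rows, :]
                J[:, b[e.tname].start] = self._effect_value(x, name)[rows]
        return J

    def gauss_newton_hessian(self, x: np.ndarray) -> np.ndarray:
        """Dense Gauss-Newton curvature J' W J + prior precision.

        W is the binomial Fisher weight n * mu * (1 - mu) per cell.  For
        centered blocks the likelihood term is constant in the scale
        coordinates; for non-centered blocks it is small whenever sigma
        is small — in both regimes the metric frozen at the mode stays
        accurate across the posterior.
        """
        b = self.blocks
        mu = expit(self._eta(x))
        w = (self.n * mu * (1.0 - mu)).ravel()
        Jac = self.jacobian(x)
        H = (Jac * w[:, None]).T @ Jac
        H[0, 0] += self.spec.prior_scale_intercept ** -2
        for e in self.effects.values():
            v = x[b[e.vname].sl]
            t = float(x[b[e.tname].start])
            sl = b[e.vname].sl
            ti = b[e.tname].start
            sig2 = np.exp(2.0 * t)
            s2 = e.hyper_scale ** 2
            if e.centered:
                H[sl, sl] += np.exp(-2.0 * t) * e.M
                q = float(v @ (e.M @ v))
                H[ti, ti] += 2.0 * q * np.exp(-2.0 * t) + 2.0 * sig2 / s2 + 0.5
            else:
                H[sl, sl] += e.M
                H[ti, ti] += 2.0 * sig2 / s2 + 0.5
        return H

    def _empirical_start(self) -> np.ndarray:
        """Initial point from empirical cell logits (deterministic)."""
        x = np.zeros(self.dim)
        b = self.blocks
        ell = logit((self.y + 0.5) / (self.n + 1.0))
        x[0] = ell.mean()
        resid = ell - ell.mean()
        counts = np.bincount(self.k0, minlength=self.K)
        for name, e in self.effects.items():
            if name == "z":
                x[b[e.tname].sl] = np.log(0.1)
                continue
            margin = self._margin(resid, name)
            if name == "alpha":
                margin = margin / self.J
            elif name == "beta":
                margin = margin / self.I
            else:
                margin = np.where(counts > 0, margin / np.maximum(counts, 1), 0.0)
            effect = margin - margin.mean()
            sig0 = max(float(np.std(np.diff(effect))), 0.02)
            x[b[e.tname].sl] = np.log(sig0)
            if e.centered:
                x[b[e.vname].sl] = e.B.T @ effect
            else:
                x[b[e.vname].sl] = (e.B.T @ effect) / sig0
            resid = resid - self._expand(effect, name)
        return x

    def map_point(self, maxiter: int = 1000) -> np.ndarray:
        """Posterior mode in the unconstrained space (deterministic).

        The log-sigma coordinates are box-bounded away from the funnel
        tip so the optimizer cannot dive towards sigma -> 0.
        """
        from scipy.optimize import minimize

        x0 = self._empirical_start()
        bounds = [(None, None)] * self.dim
        for e in self.effects.values():
            bounds[self.blocks[e.tname].start] = (np.log(1e-3), np.log(10.0))

        def neg(x):
            lp, g = self.logp_grad(x)
            return -lp, -g

        res = minimize(neg, x0, jac=True, method="L-BFGS-B",
                       bounds=bounds, options={"maxiter": maxiter})
        return res.x

    def chosen_styles(self, x_map: np.ndarray) -> dict[str, bool]:
        """Centered vs non-centered per block, from the information
        balance at the mode: centered where the likelihood carries more
        precision per natural coordinate than the prior."""
        mu = expit(self._eta(x_map))
        w = self.n * mu * (1.0 - mu)
        styles = {}
        for name, e in self.effects.items():
            t = float(x_map[self.blocks[e.tname].start])
            like_info = float(np.median(self._margin(w, name)))
            prior_prec = float(np.median(np.diag(e.M))) * np.exp(-2.0 * t)
            styles[name] = like_info > prior_prec
        return styles

    def convert_point(self, x: np.ndarray, other: "_TransformedModel") -> np.ndarray:
        """Map a point of this model to an equivalent point of ``other``
        (same blocks, possibly different centering styles)."""
        out = np.zeros(other.dim)
        out[0] = x[0]
        for name, e in self.effects.items():
            eo = other.effects[name]
            t = float(x[self.blocks[e.tname].start])
            out[other.blocks[eo.tname].start] = t
            natural = self._effect_value(x, name)
            coords = eo.B.T @ natural
            if not eo.centered:
                coords = coords / np.exp(t)
            out[other.blocks[eo.vname].sl] = coords
        return out

    def gibbs_trend_update(self, x: np.ndarray, rng: np.random.Generator) -> None:
        """Collapsed Gibbs draw along the aliased linear-trend direction.

        Moving distance s along the direction adds a linear trend to the
        cohort effect and subtracts the compensating trends from the age
        and period effects and the intercept, leaving the likelihood
        untouched.  The density of s is evaluated with the centered
        blocks' scales integrated out analytically — the scale integral
        is a generalized-inverse-Gaussian normalizer, a Bessel-K closed
        form — which decouples the gauge move from the current scale
        values (otherwise a small sigma pins the trend and the two
        random-walk together).  s is drawn by slice sampling on this 1-D
        marginal; the scales are refreshed afterwards by
        :meth:`gibbs_sigma_update`.
        """
        if self.trend is None:
            return
        from scipy.special import kve

        from ._hmc import slice_sample_1d

        b = self.blocks
        d_add = self.trend["delta_add"]

        # Gaussian pieces: intercept prior and any non-centered block
        prec = self.spec.prior_scale_intercept ** -2
        quad_g = d_add * d_add * prec
        lin_g = d_add * float(x[0]) * prec
        marg = []  # centered blocks: Bessel-marginalized
        moves = []
        for name in ("alpha", "beta", "gamma"):
            e = self.effects[name]
            direction = self.trend[name]
            v = x[b[e.vname].sl]
            if not e.centered:
                direction = direction / float(np.exp(x[b[e.tname].start]))
            moves.append((e, direction))
            Md = e.M @ direction
            q2 = float(direction @ Md)
            q1 = float(v @ Md)
            q0 = float(v @ (e.M @ v))
            if e.centered:
                lam = -(e.M.shape[0] - 1) / 2.0
                marg.append((q0, q1, q2, lam, e.hyper_scale))
            else:
                quad_g += q2
                lin_g += q1

        def logdens(s: float) -> float:
            val = -0.5 * quad_g * s * s - lin_g * s
            for q0, q1, q2, lam, hs in marg:
                q = max(q0 + 2.0 * q1 * s + q2 * s * s, 1e-300)
                arg = np.sqrt(q) / hs
                # log K_lam(arg) via exponentially scaled Bessel
                val += 0.5 * lam * np.log(q) + np.log(kve(lam, arg)) - arg
            return float(val)

        width = 2.0 / np.sqrt(quad_g + sum(m[2] for m in marg) + 1e-12)
        s = slice_sample_1d(logdens, 0.0, rng, width=width, max_steps=200)
        x[0] += s * d_add
        for e, direction in moves:
            x[b[e.vname].sl] += s * direction

    def gibbs_sigma_update(self, x: np.ndarray, rng: np.random.Generator) -> None:
        """Exact in-place update of every scale from its conditional given
        the natural-scale vector it governs.

        In centered coordinates the conditional of t = log sigma is
        log f(t) = -q e^{-2t} / 2 - (m - 1) t - e^{2t} / (2 s^2)
        with q the squared prior norm of the natural vector and m its
        coordinate count; drawn by univariate slice sampling.  For
        non-centered blocks this is an interweaving (ASIS) move: the
        scale is drawn in the centered frame — where the likelihood does
        not constrain it — and the raw coordinates are rescaled so the
        natural vector is unchanged.  HMC alone mixes scale coordinates
        slowly in either frame; the conditional draws restore mixing.
        """
        from ._hmc import slice_sample_1d

        b = self.blocks
        for e in self.effects.values():
            v = x[b[e.vname].sl]
            q = float(v @ (e.M @ v))
            t_old = float(x[b[e.tname].start])
            if not e.centered:
                q *= np.exp(2.0 * t_old)
            m = e.M.shape[0]
            s2 = e.hyper_scale ** 2

            def logf(t, q=q, m=m, s2=s2):
                return -0.5 * q * np.exp(-2.0 * t) - (m - 1) * t - 0.5 * np.exp(2.0 * t) / s2

            t_new = slice_sample_1d(
                logf, t_old, rng, lower=np.log(1e-5), upper=np.log(1e3)
            )
            x[b[e.tname].start] = t_new
            if not e.centered:
                # interweaving: the natural-scale vector is held fixed,
                # so the raw coordinates absorb the change
                x[b[e.vname].sl] *= np.exp(t_old - t_new)

    def gibbs_update(self, x: np.ndarray, rng: np.random.Generator) -> None:
        """Full Gibbs sweep interleaved with HMC: collapsed trend move,
        then every scale from its conditional."""
        self.gibbs_trend_update(x, rng)
        self.gibbs_sigma_update(x, rng)

    def curvature(self, x: np.ndarray) -> np.ndarray:
        """Diagonal of the Gauss-Newton curvature (fallback metric)."""
        return np.diag(self.gauss_newton_hessian(x)).copy()

    def initial_point(self, rng: np.random.Generator) -> np.ndarray:
        x = self._empirical_start()
        return x + 0.1 * rng.standard_normal(self.dim)


# --------------------------------------------------------------------------
# posterior containers
# --------------------------------------------------------------------------

@dataclass
class PosteriorSamples:
    """Centered posterior draws of the APC parameters.

    Arrays are stacked over all chains: S = chains x kept iterations.
    Sigmas of inactive effects are identically zero.
    """

    spec: APCModelSpec
    grid: APCGrid
    seed: int
    n_chains: int
    chain_ids: np.ndarray  # (S,)
    delta: np.ndarray      # (S,)
    alpha: np.ndarray      # (S, I)
    beta: np.ndarray       # (S, J)
    gamma: np.ndarray      # (S, K)
    z: np.ndarray          # (S, I, J)
    sigma_alpha: np.ndarray
    sigma_beta: np.ndarray
    sigma_gamma: np.ndarray
    sigma_z: np.ndarray
    rhat: dict[str, float] = field(default_factory=dict)
    diagnostics: dict = field(default_factory=dict)

    @property
    def n_draws(self) -> int:
        return len(self.delta)

    def parameters(self, s: int) -> APCParameters:
        """Natural parameters of draw s."""
        return APCParameters(
            delta=float(self.delta[s]), alpha=self.alpha[s], beta=self.beta[s],
            gamma=self.gamma[s], z=self.z[s],
            sigma_alpha=float(self.sigma_alpha[s]), sigma_beta=float(self.sigma_beta[s]),
            sigma_gamma=float(self.sigma_gamma[s]), sigma_z=float(self.sigma_z[s]),
        )

    def linear_predictor_draws(self) -> np.ndarray:
        """(S, I, J) draws of the cell log-odds eta_ij."""
        k0 = self.grid.cohort_index - 1
        return (
            self.delta[:, None, None]
            + self.alpha[:, :, None]
            + self.beta[:, None, :]
            + self.gamma[:, k0]
            + self.z
        )

    def cell_probability_draws(self) -> np.ndarray:
        """(S, I, J) draws of the cell prevalences p_ij."""
        return expit(self.linear_predictor_draws())

    def to_dataframe(self) -> pd.DataFrame:
        """One row per draw, one column per scalar parameter (plus chain)."""
        cols: dict[str, np.ndarray] = {"chain": self.chain_ids, "delta": self.delta}
        for i in range(self.alpha.shape[1]):
            cols[f"alpha[{i + 1}]"] = self.alpha[:, i]
        for j in range(self.beta.shape[1]):
            cols[f"beta[{j + 1}]"] = self.beta[:, j]
        for k in range(self.gamma.shape[1]):
            cols[f"gamma[{k + 1}]"] = self.gamma[:, k]
        for i in range(self.z.shape[1]):
            for j in range(self.z.shape[2]):
                cols[f"z[{i + 1},{j + 1}]"] = self.z[:, i, j]
        for name in ("sigma_alpha", "sigma_beta", "sigma_gamma", "sigma_z"):
            cols[name] = getattr(self, name)
        return pd.DataFrame(cols)


@dataclass(frozen=True)
class DICResult:
    """Deviance information criterion: dic = dbar + pd, pd = dbar - dhat."""

    dic: float
    dbar: float
    dhat: float
    pd: float


@dataclass(frozen=True)
class ConvergenceReport:
    passed: bool
    threshold: float
    offenders: tuple[tuple[str, float], ...]
    max_rhat: float


# --------------------------------------------------------------------------
# public operations
# --------------------------------------------------------------------------

def sample_posterior(
    table: PrevalenceTable,
    grid: APCGrid,
    spec: APCModelSpec,
    chains: int = 4,
    iterations: int = 2000,
    seed: int = 0,
    warmup: int | None = None,
    target_accept: float = 0.8,
) -> PosteriorSamples:
    """Draw from the posterior of the APC model by HMC.

    ``iterations`` is the number of kept draws per chain; warmup defaults
    to the same number.  Deterministic given (seed, inputs).  Divergent
    trajectories after warmup are reported in ``diagnostics`` rather than
    silently dropped.

    The HMC metric is the dense Gauss-Newton Hessian of the Laplace
    approximation at the posterior mode, which preconditions away the
    correlated near-flat ridge created by the age-period-cohort
    linear-trend aliasing; chains start from overdispersed draws of the
    Laplace approximation.
    """
    if chains < 1:
        raise ValueError("need at least one chain")
    warmup = iterations if warmup is None else warmup
    pilot = _TransformedModel(table, grid, spec)
    x_pilot = pilot.map_point()
    # re-parameterize per block from the information balance at the mode
    model = _TransformedModel(table, grid, spec, styles=pilot.chosen_styles(x_pilot))
    x_map = pilot.convert_point(x_pilot, model)
    try:
        mass = DenseMass(model.gauss_newton_hessian(x_map))
    except np.linalg.LinAlgError:  # pragma: no cover - degenerate fallback
        mass = DiagonalMass(model.curvature(x_map))
    seeds = np.random.SeedSequence(seed).spawn(chains)
    per_chain = []
    diagnostics: dict = {"divergences": 0, "accept_rate": [], "step_size": []}
    for c in range(chains):
        rng = np.random.default_rng(seeds[c])
        if isinstance(mass, DenseMass):
            x0 = mass.sample_point(rng, x_map, scale=1.5)
        else:  # pragma: no cover
            x0 = model.initial_point(rng)
        res = sample_chain(
            model.logp_grad, x0, warmup, iterations, rng,
            mass=mass, target_accept=target_accept,
            aux_update=model.gibbs_update,
            metric_refresh=lambda xc: DenseMass(model.gauss_newton_hessian(xc)),
        )
        per_chain.append(res.draws)
        diagnostics["divergences"] += res.divergences
        diagnostics["accept_rate"].append(res.accept_rate)
        diagnostics["step_size"].append(res.step_size)

    X = np.asarray(per_chain)  # (chains, iterations, dim)
    samples = _unpack_draws(model, X, spec, grid, seed)
    samples.diagnostics.update(diagnostics)
    samples.rhat.update(_compute_rhat(samples))
    return samples


def _unpack_draws(model, X, spec, grid, seed) -> PosteriorSamples:
    chains, iters, _ = X.shape
    flat = X.reshape(chains * iters, -1)
    b = model.blocks
    I, J, K = model.I, model.J, model.K
    S = chains * iters
    sizes = {"alpha": I, "beta": J, "gamma": K, "z": I * J}

    effs: dict[str, np.ndarray] = {}
    sigs: dict[str, np.ndarray] = {}
    for name, size in sizes.items():
        e = model.effects.get(name)
        if e is None:
            effs[name] = np.zeros((S, size))
            sigs[name] = np.zeros(S)
        else:
            sig = np.exp(flat[:, b[e.tname].start])
            raw = flat[:, b[e.vname].sl] @ e.B.T
            effs[name] = raw if e.centered else sig[:, None] * raw
            sigs[name] = sig
    alpha, beta, gamma = effs["alpha"], effs["beta"], effs["gamma"]
    sa, sb, sg, sz = sigs["alpha"], sigs["beta"], sigs["gamma"], sigs["z"]
    z = effs["z"].reshape(S, I, J)
    delta = flat[:, 0]

    # hard sum-to-zero gauge on every reported draw (the basis already has
    # zero column sums; this removes the remaining float dust exactly)
    for eff in (alpha, beta, gamma):
        if eff.shape[1]:
            m = eff.mean(axis=1)
            delta = delta + m
            eff -= m[:, None]

    return PosteriorSamples(
        spec=spec, grid=grid, seed=seed, n_chains=chains,
        chain_ids=np.repeat(np.arange(chains), iters),
        delta=delta, alpha=alpha, beta=beta, gamma=gamma, z=z,
        sigma_alpha=sa, sigma_beta=sb, sigma_gamma=sg, sigma_z=sz,
    )


def _arviz_dataset(samples: PosteriorSamples):
    C = samples.n_chains
    T = samples.n_draws // C

    def chainwise(a):
        return a.reshape((C, T) + a.shape[1:])

    data = {"delta": chainwise(samples.delta)}
    if samples.spec.include_heterogeneity:
        data["sigma_z"] = chainwise(samples.sigma_z)
        data["z"] = chainwise(samples.z)
    if samples.alpha.shape[1] >= 2:
        data["alpha"] = chainwise(samples.alpha)
        data["sigma_alpha"] = chainwise(samples.sigma_alpha)
    if samples.spec.include_period and samples.beta.shape[1] >= 2:
        data["beta"] = chainwise(samples.beta)
        data["sigma_beta"] = chainwise(samples.sigma_beta)
    if samples.spec.include_cohort and samples.gamma.shape[1] >= 2:
        data["gamma"] = chainwise(samples.gamma)
        data["sigma_gamma"] = chainwise(samples.sigma_gamma)
    return az.from_dict(posterior=data)


def _compute_rhat(samples: PosteriorSamples) -> dict[str, float]:
    if samples.n_chains < 2:
        return {}
    rh = az.rhat(_arviz_dataset(samples))
    out: dict[str, float] = {}
    for name, da in rh.data_vars.items():
        vals = np.atleast_1d(np.asarray(da.values))
        if vals.ndim == 0 or vals.size == 1:
            out[name] = float(vals.reshape(-1)[0])
        elif vals.ndim == 1:
            for idx, v in enumerate(vals):
                out[f"{name}[{idx + 1}]"] = float(v)
        else:
            for idx, v in np.ndenumerate(vals):
                label = ",".join(str(t + 1) for t in idx)
                out[f"{name}[{label}]"] = float(v)
    return out


def check_convergence(samples: PosteriorSamples, threshold: float = 1.05) -> ConvergenceReport:
    """Flag scalars whose rank-normalized split R-hat exceeds the threshold."""
    if samples.n_chains < 2:
        raise SingleChainError("R-hat needs at least 2 chains")
    rhat = samples.rhat or _compute_rhat(samples)
    offenders = tuple(
        sorted(
            ((k, v) for k, v in rhat.items() if np.isfinite(v) and v > threshold),
            key=lambda kv: -kv[1],
        )
    )
    max_rhat = max((v for v in rhat.values() if np.isfinite(v)), default=float("nan"))
    return ConvergenceReport(
        passed=len(offenders) == 0, threshold=threshold,
        offenders=offenders, max_rhat=max_rhat,
    )


def _deviance(p: np.ndarray, y: np.ndarray, n: np.ndarray) -> np.ndarray:
    """-2 x binomial log-likelihood (with coefficients) for p of shape (..., I, J)."""
    log_coef = gammaln(n + 1) - gammaln(y + 1) - gammaln(n - y + 1)
    p = np.clip(p, 1e-300, 1 - 1e-16)
    ll = log_coef + y * np.log(p) + (n - y) * np.log1p(-p)
    return -2.0 * ll.sum(axis=(-2, -1))


def compute_dic(samples: PosteriorSamples, table: PrevalenceTable, grid: APCGrid) -> DICResult:
    """Deviance information criterion with the plug-in at the posterior
    mean of the cell probabilities p_ij (well-defined under the
    sum-to-zero gauge)."""
    if samples.n_draws == 0:
        raise ValueError("empty draw set")
    if (table.I, table.J) != (grid.I, grid.J):
        raise ValueError("table and grid dimensions do not match")
    y = table.smokers.astype(float)
    n = table.denominators.astype(float)
    P = samples.cell_probability_draws()
    dbar = float(np.mean(_deviance(P, y, n)))
    dhat = float(_deviance(P.mean(axis=0), y, n))
    pd_ = dbar - dhat
    return DICResult(dic=dbar + pd_, dbar=dbar, dhat=dhat, pd=pd_)


# --------------------------------------------------------------------------
# persistence (CSV + YAML, text only)
# --------------------------------------------------------------------------

def save_fit(samples: PosteriorSamples, table: PrevalenceTable, outdir) -> None:
    """Write draws, data, model spec and run metadata into a directory."""
    from pathlib import Path

    out = Path(outdir)
    out.mkdir(parents=True, exist_ok=True)
    samples.to_dataframe().to_csv(out / "draws.csv", index=False)
    table.to_frame().to_csv(out / "data.csv", index=False)
    samples.spec.to_yaml(out / "spec.yaml")
    report = check_convergence(samples) if samples.n_chains >= 2 else None
    with open(out / "run_metadata.txt", "w") as fh:
        fh.write(f"stratum: {table.stratum_label}\n")
        fh.write(f"seed: {samples.seed}\n")
        fh.write(f"chains: {samples.n_chains}\n")
        fh.write(f"draws_per_chain: {samples.n_draws // samples.n_chains}\n")
        fh.write(f"divergences: {samples.diagnostics.get('divergences', 'n/a')}\n")
        if report is not None:
            fh.write(f"max_rhat: {report.max_rhat:.4f}\n")
            fh.write(f"converged_at_1.05: {report.passed}\n")


def load_fit(fitdir) -> tuple[PosteriorSamples, PrevalenceTable]:
    """Reload a fit written by :func:`save_fit`."""
    from pathlib import Path

    from .apc_grid import grid_from_table
    from .survey_data import read_prevalence_table

    fit = Path(fitdir)
    table = read_prevalence_table(fit / "data.csv", stratum_label=fit.name)
    spec = APCModelSpec.from_yaml(fit / "spec.yaml")
    grid = grid_from_table(table)
    df = pd.read_csv(fit / "draws.csv")
    S = len(df)
    I, J, K = grid.I, grid.J, grid.K
    alpha = df[[f"alpha[{i + 1}]" for i in range(I)]].to_numpy()
    beta = df[[f"beta[{j + 1}]" for j in range(J)]].to_numpy()
    gamma = df[[f"gamma[{k + 1}]" for k in range(K)]].to_numpy()
    z = np.stack(
        [df[[f"z[{i + 1},{j + 1}]" for j in range(J)]].to_numpy() for i in range(I)],
        axis=1,
    )
    chain_ids = df["chain"].to_numpy()
    samples = PosteriorSamples(
        spec=spec, grid=grid, seed=-1, n_chains=int(chain_ids.max()) + 1,
        chain_ids=chain_ids, delta=df["delta"].to_numpy(),
        alpha=alpha, beta=beta, gamma=gamma, z=z,
        sigma_alpha=df["sigma_alpha"].to_numpy(),
        sigma_beta=df["sigma_beta"].to_numpy(),
        sigma_gamma=df["sigma_gamma"].to_numpy(),
        sigma_z=df["sigma_z"].to_numpy(),
    )
    samples.rhat.update(_compute_rhat(samples))
    return samples, table


def _center_all(samples: PosteriorSamples) -> None:
    """Apply :func:`center_effects` draw-wise, in place (idempotent)."""
    for s in range(samples.n_draws):
        p = center_effects(samples.parameters(s))
        samples.delta[s] = p.delta
        samples.alpha[s] = p.alpha
        samples.beta[s] = p.beta
        samples.gamma[s] = p.gamma
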