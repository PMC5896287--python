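"""Shared-component model for birth-cohort disease mapping (SMBC).

Observed deaths ``y_it`` in area ``i`` and birth-cohort ``t`` are
conditionally independent Poisson with mean ``theta_it * E_it``, and the log
relative risk decomposes as

    log theta_it = beta0 + beta1 * x_it + alpha_t + delta_it
    delta_it     = omega_t * psi_s_i + psi_p_it

where the shared component ``psi_s = gamma_s + phi_s`` is a BYM convolution
(iid heterogeneity plus an intrinsic-CAR clustering field) common to all
cohorts, scaled per cohort by ``omega_t`` with ``sum_t log omega_t = 0``, and
the cohort-specific components ``psi_p[:, t] = gamma_p[:, t] + phi_p[:, t]``
are BYM convolutions of their own.  Field precisions carry Gamma(0.5, 0.0005)
shape-rate hyperpriors; regression coefficients and cohort intercepts carry
wide centred normals.  Posteriors are explored by Metropolis-within-Gibbs:
elementwise random-walk Metropolis on the fields (vectorised over
conditionally independent sites via graph coloring), conjugate Gamma draws
for the precisions, and exact re-centring each iteration to pin down the
over-parameterised decomposition.
"""

from __future__ import annotations

import dataclasses
import warnings
from typing import Any

import numpy as np
import scipy.sparse as sp
import yaml

from . import _mh
from .car import (
    AdjacencyGraph,
    ValidationError,
    build_structure_matrix,
    car_rank,
    sum_zero_basis,
)
from .lexis import CohortData


# ---------------------------------------------------------------------------
# Configuration
# ---------------------------------------------------------------------------

_DEFAULT_STEPS = {
    "beta0": 0.05,
    "beta1": 0.05,
    "alpha": 0.05,
    "log_omega": 0.1,
    "gamma_s": 0.2,
    "phi_s": 0.2,
    "gamma_p": 0.3,
    "phi_p": 0.3,
    # interaction-model blocks share the same adapter
    "v": 0.2,
    "u": 0.2,
    "phi_t": 0.05,
    "psi": 0.3,
}


@dataclasses.dataclass
class MCMCConfig:
    """Sampler protocol and hyperparameters.

    Defaults mirror a production run (100,000 burn-in, 1,000 kept samples
    thinned by 100 from the following 100,000 iterations); tests and examples
    use much shorter runs.  ``prior_shape``/``prior_rate`` parameterise the
    shape-rate Gamma hyperprior on every field precision; ``sigma2_omega`` is
    the per-cohort variance of the constrained log shared-field scalings.
    """

    n_burnin: int = 100_000
    n_keep: int = 1_000
    thin: int = 100
    seed: int = 0
    step_sizes: dict[str, float] = dataclasses.field(default_factory=lambda: dict(_DEFAULT_STEPS))
    adapt_window: int = 50
    prior_shape: float = 0.5
    prior_rate: float = 0.0005
    sigma2_omega: float = 1.0
    beta_prior_var: float = 1.0e4
    alpha_prior_var: float = 1.0e4
    interaction_variant: str = "rw1-time"

    def __post_init__(self) -> None:
        if self.n_burnin < 0 or self.n_keep < 1 or self.thin < 1:
            raise ValidationError("need n_burnin >= 0, n_keep >= 1, thin >= 1")

    @classmethod
    def from_yaml(cls, path) -> "MCMCConfig":
        with open(path) as fh:
            raw: dict[str, Any] = yaml.safe_load(fh) or {}
        return cls(**raw)

    def to_yaml(self, path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(dataclasses.asdict(self), fh)


# ---------------------------------------------------------------------------
# State
# ---------------------------------------------------------------------------


@dataclasses.dataclass
class SMBCState:
    """One complete parameter state of the shared-component model."""

    beta0: float
    beta1: float
    alpha: np.ndarray  # (T,)
    log_omega: np.ndarray  # (T,), sums to zero
    gamma_s: np.ndarray  # (I,)
    phi_s: np.ndarray  # (I,)
    gamma_p: np.ndarray  # (I, T)
    phi_p: np.ndarray  # (I, T)
    lambda_gamma: float
    lambda_gamma_p: float
    lambda_phi: float
    lambda_phi_p: float

    @property
    def omega(self) -> np.ndarray:
        return np.exp(self.log_omega)

    @property
    def psi_s(self) -> np.ndarray:
        return self.gamma_s + self.phi_s

    @property
    def psi_p(self) -> np.ndarray:
        return self.gamma_p + self.phi_p

    @property
    def delta(self) -> np.ndarray:
        return self.omega[None, :] * self.psi_s[:, None] + self.psi_p

    def log_theta(self, x: np.ndarray | None) -> np.ndarray:
        eta = self.beta0 + self.alpha[None, :] + self.delta
        if x is not None:
            eta = eta + self.beta1 * x
        return eta

    def theta(self, x: np.ndarray | None) -> np.ndarray:
        return np.exp(self.log_theta(x))

    def copy(self) -> "SMBCState":
        return SMBCState(
            self.beta0,
            self.beta1,
            self.alpha.copy(),
            self.log_omega.copy(),
            self.gamma_s.copy(),
            self.phi_s.copy(),
            self.gamma_p.copy(),
            self.phi_p.copy(),
            self.lambda_gamma,
            self.lambda_gamma_p,
            self.lambda_phi,
            self.lambda_phi_p,
        )


def initial_state(data: CohortData, rng: np.random.Generator) -> SMBCState:
    I, T = data.shape
    smr = np.log(np.maximum(data.y, 0.5) / data.E)
    return SMBCState(
        beta0=float(smr.mean()),
        beta1=0.0,
        alpha=np.zeros(T),
        log_omega=np.zeros(T),
        gamma_s=np.zeros(I),
        phi_s=np.zeros(I),
        gamma_p=np.zeros((I, T)),
        phi_p=np.zeros((I, T)),
        lambda_gamma=10.0,
        lambda_gamma_p=10.0,
        lambda_phi=10.0,
        lambda_phi_p=10.0,
    )


# ---------------------------------------------------------------------------
# Log posterior
# ---------------------------------------------------------------------------


def smbc_log_posterior(
    state: SMBCState, data: CohortData, graph: AdjacencyGraph, config: MCMCConfig
) -> float:
    """Unnormalised log posterior (up to an additive constant in the data).

    Poisson log likelihood plus: wide normal priors on beta0, beta1 and
    alpha_t; the singular normal on log omega restricted to its sum-to-zero
    subspace; centred normals on the heterogeneity fields; intrinsic-CAR
    kernels on the clustering fields; Gamma hyperpriors on the precisions.
    Precision-dependent normalising terms (rank/2 * log lambda) are kept so
    the conjugate updates match this density.
    """
    I, T = data.shape
    eta = state.log_theta(data.x)
    if not np.all(np.isfinite(eta)):
        raise ValidationError("non-finite linear predictor")
    theta_E = np.exp(eta) * data.E
    loglik = float(np.sum(data.y * (eta + np.log(data.E)) - theta_E))

    lp = loglik
    lp += -0.5 * (state.beta0**2 + state.beta1**2) / config.beta_prior_var
    lp += -0.5 * float(state.alpha @ state.alpha) / config.alpha_prior_var

    if T >= 2:
        if abs(float(state.log_omega.sum())) > 1e-8:
            raise ValidationError("log omega must sum to zero")
        b = sum_zero_basis(T)
        z = b.T @ state.log_omega
        s2 = config.sigma2_omega * T / (T - 1)
        lp += -0.5 * float(z @ z) / s2

    k = build_structure_matrix(graph)
    rank_k = car_rank(graph)

    lp += 0.5 * I * np.log(state.lambda_gamma) - 0.5 * state.lambda_gamma * float(
        state.gamma_s @ state.gamma_s
    )
    lp += 0.5 * I * T * np.log(state.lambda_gamma_p) - 0.5 * state.lambda_gamma_p * float(
        np.sum(state.gamma_p**2)
    )
    lp += 0.5 * rank_k * np.log(state.lambda_phi) - 0.5 * state.lambda_phi * k.quad_form(
        state.phi_s
    )
    quad_p = sum(k.quad_form(state.phi_p[:, t]) for t in range(T))
    lp += 0.5 * rank_k * T * np.log(state.lambda_phi_p) - 0.5 * state.lambda_phi_p * quad_p

    for lam in (state.lambda_gamma, state.lambda_gamma_p, state.lambda_phi, state.lambda_phi_p):
        lp += _mh.gamma_logpdf(lam, config.prior_shape, config.prior_rate)
    if not np.isfinite(lp):
        raise ValidationError("non-finite log posterior")
    return float(lp)


# ---------------------------------------------------------------------------
# Sampler
# ---------------------------------------------------------------------------


@dataclasses.dataclass
class SMBCSamples:
    """Kept post-burn-in states, stacked along the first axis."""

    area_ids: tuple[str, ...]
    cohort_labels: tuple[str, ...]
    beta0: np.ndarray
    beta1: np.ndarray
    alpha: np.ndarray  # (n, T)
    log_omega: np.ndarray  # (n, T)
    gamma_s: np.ndarray  # (n, I)
    phi_s: np.ndarray  # (n, I)
    gamma_p: np.ndarray  # (n, I, T)
    phi_p: np.ndarray  # (n, I, T)
    lambdas: np.ndarray  # (n, 4): gamma, gamma_p, phi, phi_p
    theta: np.ndarray  # (n, I, T)

    @property
    def n_samples(self) -> int:
        return self.beta0.shape[0]

    @property
    def omega(self) -> np.ndarray:
        return np.exp(self.log_omega)

    @property
    def psi_s(self) -> np.ndarray:
        return self.gamma_s + self.phi_s

    @property
    def psi_p(self) -> np.ndarray:
        return self.gamma_p + self.phi_p

    def state(self, k: int) -> SMBCState:
        return SMBCState(
            float(self.beta0[k]),
            float(self.beta1[k]),
            self.alpha[k],
            self.log_omega[k],
            self.gamma_s[k],
            self.phi_s[k],
            self.gamma_p[k],
            self.phi_p[k],
            *map(float, self.lambdas[k]),
        )

    def to_long_frame(self):
        """Long-format (iteration, parameter, value) table of scalar traces."""
        import pandas as pd

        recs = []
        for k in range(self.n_samples):
            recs.append((k, "beta0", self.beta0[k]))
            recs.append((k, "beta1", self.beta1[k]))
            for t, coh in enumerate(self.cohort_labels):
                recs.append((k, f"alpha[{coh}]", self.alpha[k, t]))
                recs.append((k, f"omega[{coh}]", np.exp(self.log_omega[k, t])))
            for j, name in enumerate(("lambda_gamma", "lambda_gamma_p", "lambda_phi", "lambda_phi_p")):
                recs.append((k, name, self.lambdas[k, j]))
        return pd.DataFrame(recs, columns=["iteration", "parameter", "value"])

    def write_csv(self, path) -> None:
        self.to_long_frame().to_csv(path, index=False)


def _poisson_ll(y: np.ndarray, E: np.ndarray, eta: np.ndarray) -> np.ndarray:
    return y * eta - E * np.exp(eta)


def run_smbc_mcmc(
    data: CohortData, graph: AdjacencyGraph, config: MCMCConfig
) -> SMBCSamples:
    """Metropolis-within-Gibbs sampler for the shared-component model.

    Single-site random-walk Metropolis on every non-conjugate block,
    vectorised over conditionally independent sites (all areas at once for
    the iid heterogeneity fields; one graph-color class at a time for the
    CAR fields); conjugate Gamma draws for the four precisions; exact
    re-centring each iteration (clustering fields to zero per connected
    component, cohort means of the specific heterogeneity into alpha, the
    alpha mean into beta0) with the removed means pushed through the linear
    predictor so the fitted risks are untouched on connected maps.
    """
    I, T = data.shape
    if graph.n_areas != I:
        raise ValidationError("graph and data disagree on the number of areas")
    rng = np.random.default_rng(config.seed)
    x = data.x
    y, E = data.y, data.E

    k_struct = build_structure_matrix(graph)
    adjacency = sp.csr_matrix(-sp.triu(k_struct.matrix, 1) - sp.tril(k_struct.matrix, -1))
    n_i = graph.n_i.astype(float)
    not_island = n_i > 0
    rank_k = car_rank(graph)
    comps = graph.connected_components()
    single_comp = len(comps) == 1
    colors = graph.coloring()
    color_masks = [np.flatnonzero((colors == c) & not_island) for c in range(colors.max() + 1)]
    color_masks = [m for m in color_masks if m.size]

    b_omega = sum_zero_basis(T) if T >= 2 else np.zeros((T, 0))
    s2_sub = config.sigma2_omega * T / (T - 1) if T >= 2 else 1.0

    state = initial_state(data, rng)
    z = np.zeros(T - 1) if T >= 2 else np.zeros(0)

    steps = _mh.StepSizes(sizes=dict(config.step_sizes), window=config.adapt_window)

    def eta_of(st: SMBCState) -> np.ndarray:
        return st.log_theta(x)

    n_iter = config.n_burnin + config.n_keep * config.thin
    kept = 0
    out = SMBCSamples(
        area_ids=data.area_ids,
        cohort_labels=data.cohort_labels,
        beta0=np.empty(config.n_keep),
        beta1=np.empty(config.n_keep),
        alpha=np.empty((config.n_keep, T)),
        log_omega=np.empty((config.n_keep, T)),
        gamma_s=np.empty((config.n_keep, I)),
        phi_s=np.empty((config.n_keep, I)),
        gamma_p=np.empty((config.n_keep, I, T)),
        phi_p=np.empty((config.n_keep, I, T)),
        lambdas=np.empty((config.n_keep, 4)),
        theta=np.empty((config.n_keep, I, T)),
    )

    for it in range(n_iter):
        eta = eta_of(state)
        mu = E * np.exp(eta)

        # --- beta0 (scalar RW-MH) --------------------------------------
        d = steps.sizes["beta0"] * rng.standard_normal()
        dll = float(np.sum(y * d - mu * np.expm1(d)))
        dlp = dll - 0.5 * ((state.beta0 + d) ** 2 - state.beta0**2) / config.beta_prior_var
        acc = np.log(rng.random()) < dlp
        if acc:
            state.beta0 += d
            eta += d
            mu *= np.exp(d)
        steps.record("beta0", float(acc), 1.0)

        # --- beta1 ------------------------------------------------------
        if x is not None:
            d = steps.sizes["beta1"] * rng.standard_normal()
            de = d * x
            dll = float(np.sum(y * de - mu * np.expm1(de)))
            dlp = dll - 0.5 * ((state.beta1 + d) ** 2 - state.beta1**2) / config.beta_prior_var
            acc = np.log(rng.random()) < dlp
            if acc:
                state.beta1 += d
                eta += de
                mu *= np.exp(de)
            steps.record("beta1", float(acc), 1.0)

        # --- alpha (columns are conditionally independent) ---------------
        d = steps.sizes["alpha"] * rng.standard_normal(T)
        dll = np.sum(y * d[None, :] - mu * np.expm1(d)[None, :], axis=0)
        dlp = dll - 0.5 * ((state.alpha + d) ** 2 - state.alpha**2) / config.alpha_prior_var
        mask = _mh.mh_accept_mask(dlp, rng)
        if mask.any():
            state.alpha[mask] += d[mask]
            eta += np.where(mask, d, 0.0)[None, :]
            mu *= np.exp(np.where(mask, d, 0.0))[None, :]
        steps.record("alpha", float(mask.sum()), float(T))

        # --- log omega on the sum-to-zero subspace -----------------------
        if T >= 2:
            psi_s = state.psi_s
            omega = state.omega
            for kk in range(T - 1):
                d = steps.sizes["log_omega"] * rng.standard_normal()
                z_new = z.copy()
                z_new[kk] += d
                lw_new = b_omega @ z_new
                d_omega = np.exp(lw_new) - omega
                de = psi_s[:, None] * d_omega[None, :]
                dll = float(np.sum(y * de - mu * np.expm1(de)))
                dlp = dll - 0.5 * (z_new[kk] ** 2 - z[kk] ** 2) / s2_sub
                if np.log(rng.random()) < dlp:
                    z = z_new
                    state.log_omega = lw_new
                    omega = np.exp(lw_new)
                    eta += de
                    mu *= np.exp(de)
                    steps.record("log_omega", 1.0, 1.0)
                else:
                    steps.record("log_omega", 0.0, 1.0)

        # --- gamma_s (iid; all areas at once) ----------------------------
        omega = state.omega
        d = steps.sizes["gamma_s"] * rng.standard_normal(I)
        de = d[:, None] * omega[None, :]
        dll = np.sum(y * de - mu * np.expm1(de), axis=1)
        dlp = dll - 0.5 * state.lambda_gamma * ((state.gamma_s + d) ** 2 - state.gamma_s**2)
        mask = _mh.mh_accept_mask(dlp, rng)
        if mask.any():
            state.gamma_s[mask] += d[mask]
            de_acc = np.where(mask, d, 0.0)[:, None] * omega[None, :]
            eta += de_acc
            mu *= np.exp(de_acc)
        steps.record("gamma_s", float(mask.sum()), float(I))

        # --- phi_s (CAR; one color class at a time) ----------------------
        for cm in color_masks:
            nb_sum = np.asarray(adjacency[cm] @ state.phi_s).ravel()
            d = steps.sizes["phi_s"] * rng.standard_normal(cm.size)
            de = d[:, None] * omega[None, :]
            dll = np.sum(y[cm] * de - mu[cm] * np.expm1(de), axis=1)
            phi_old = state.phi_s[cm]
            dquad = n_i[cm] * ((phi_old + d) ** 2 - phi_old**2) - 2.0 * d * nb_sum
            dlp = dll - 0.5 * state.lambda_phi * dquad
            mask = _mh.mh_accept_mask(dlp, rng)
            if mask.any():
                idx = cm[mask]
                state.phi_s[idx] += d[mask]
                de_acc = d[mask][:, None] * omega[None, :]
                eta[idx] += de_acc
                mu[idx] *= np.exp(de_acc)
            steps.record("phi_s", float(mask.sum()), float(cm.size))

        # --- gamma_p (iid over cells) ------------------------------------
        d = steps.sizes["gamma_p"] * rng.standard_normal((I, T))
        dll = y * d - mu * np.expm1(d)
        dlp = dll - 0.5 * state.lambda_gamma_p * ((state.gamma_p + d) ** 2 - state.gamma_p**2)
        mask = _mh.mh_accept_mask(dlp, rng)
        if mask.any():
            d_acc = np.where(mask, d, 0.0)
            state.gamma_p += d_acc
            eta += d_acc
            mu *= np.exp(d_acc)
        steps.record("gamma_p", float(mask.sum()), float(I * T))

        # --- phi_p (CAR per cohort; colored) -----------------------------
        for t in range(T):
            for cm in color_masks:
                nb_sum = np.asarray(adjacency[cm] @ state.phi_p[:, t]).ravel()
                d = steps.sizes["phi_p"] * rng.standard_normal(cm.size)
                dll = y[cm, t] * d - mu[cm, t] * np.expm1(d)
                phi_old = state.phi_p[cm, t]
                dquad = n_i[cm] * ((phi_old + d) ** 2 - phi_old**2) - 2.0 * d * nb_sum
                dlp = dll - 0.5 * state.lambda_phi_p * dquad
                mask = _mh.mh_accept_mask(dlp, rng)
                if mask.any():
                    idx = cm[mask]
                    state.phi_p[idx, t] += d[mask]
                    eta[idx, t] += d[mask]
                    mu[idx, t] *= np.exp(d[mask])
                steps.record("phi_p", float(mask.sum()), float(cm.size))

        # --- conjugate precision draws -----------------------------------
        state.lambda_gamma = _mh.sample_precision(
            config.prior_shape, config.prior_rate, I, float(state.gamma_s @ state.gamma_s), rng
        )
        state.lambda_gamma_p = _mh.sample_precision(
            config.prior_shape, config.prior_rate, I * T, float(np.sum(state.gamma_p**2)), rng
        )
        state.lambda_phi = _mh.sample_precision(
            config.prior_shape, config.prior_rate, rank_k, k_struct.quad_form(state.phi_s), rng
        )
        quad_p = sum(k_struct.quad_form(state.phi_p[:, t]) for t in range(T))
        state.lambda_phi_p = _mh.sample_precision(
            config.prior_shape, config.prior_rate, rank_k * T, quad_p, rng
        )

        # --- identifiability re-centring ---------------------------------
        omega = state.omega
        for comp in comps:
            m = float(state.phi_s[comp].mean())
            state.phi_s[comp] -= m
            if single_comp:
                state.alpha += omega * m
            for t in range(T):
                mt = float(state.phi_p[comp, t].mean())
                state.phi_p[comp, t] -= mt
                if single_comp:
                    state.alpha[t] += mt
        m = float(state.gamma_s.mean())
        state.gamma_s -= m
        state.alpha += omega * m
        mt = state.gamma_p.mean(axis=0)
        state.gamma_p -= mt[None, :]
        state.alpha += mt
        m = float(state.alpha.mean())
        state.alpha -= m
        state.beta0 += m

        if it < config.n_burnin:
            if (it + 1) % config.adapt_window == 0:
                steps.adapt()
        elif it == config.n_burnin:
            steps.frozen = True

        if it >= config.n_burnin and (it - config.n_burnin + 1) % config.thin == 0:
            out.beta0[kept] = state.beta0
            out.beta1[kept] = state.beta1
            out.alpha[kept] = state.alpha
            out.log_omega[kept] = state.log_omega
            out.gamma_s[kept] = state.gamma_s
            out.phi_s[kept] = state.phi_s
            out.gamma_p[kept] = state.gamma_p
            out.phi_p[kept] = state.phi_p
            out.lambdas[kept] = (
                state.lambda_gamma,
                state.lambda_gamma_p,
                state.lambda_phi,
                state.lambda_phi_p,
            )
            out.theta[kept] = state.theta(x)
            if not np.all(np.isfinite(out.theta[kept])):
                raise RuntimeError(f"non-finite posterior state at iteration {it}: {state}")
            kept += 1

    rates = steps.acceptance_rates()
    bad = {b: r for b, r in rates.items() if not 0.05 <= r <= 0.95}
    if bad:
        warnings.warn(f"post-adaptation acceptance rates outside [0.05, 0.95]: {bad}")
    return out


# ---------------------------------------------------------------------------
# Posterior summaries
# ---------------------------------------------------------------------------


@dataclasses.dataclass
class SMBCSummary:
    """Posterior means and central 95% intervals of the reported quantities."""

    area_ids: tuple[str, ...]
    cohort_labels: tuple[str, ...]
    beta1_mean: float
    beta1_ci: tuple[float, float]
    theta_mean: np.ndarray
    theta_lo: np.ndarray
    theta_hi: np.ndarray
    exp_psi_s_mean: np.ndarray
    exp_psi_s_lo: np.ndarray
    exp_psi_s_hi: np.ndarray
    exp_psi_p_mean: np.ndarray
    omega_mean: np.ndarray
    omega_ci: np.ndarray  # (T, 2)
    omega_boxplot: np.ndarray  # (T, 5): min-whisker five-number summary

    def to_area_frame(self):
        import pandas as pd

        recs = []
        for i, aid in enumerate(self.area_ids):
            rec = {
                "area_id": aid,
                "exp_psi_s_mean": self.exp_psi_s_mean[i],
                "exp_psi_s_lo": self.exp_psi_s_lo[i],
                "exp_psi_s_hi": self.exp_psi_s_hi[i],
            }
            for t, coh in enumerate(self.cohort_labels):
                rec[f"theta_mean[{coh}]"] = self.theta_mean[i, t]
                rec[f"exp_psi_p_mean[{coh}]"] = self.exp_psi_p_mean[i, t]
            recs.append(rec)
        return pd.DataFrame(recs)

    def write_csv(self, path) -> None:
        self.to_area_frame().to_csv(path, index=False)


def _five_number(a: np.ndarray) -> np.ndarray:
    return np.quantile(a, [0.0, 0.25, 0.5, 0.75, 1.0])


def summarize_smbc(samples: SMBCSamples) -> SMBCSummary:
    """Posterior means, 95% intervals and omega box-plot summaries."""
    if samples.n_samples < 2:
        raise ValidationError("need at least 2 kept samples to summarise")
    q = lambda a, p: np.quantile(a, p, axis=0)
    exp_psi_s = np.exp(samples.psi_s)
    omega = samples.omega
    return SMBCSummary(
        area_ids=samples.area_ids,
        cohort_labels=samples.cohort_labels,
        beta1_mean=float(samples.beta1.mean()),
        beta1_ci=(float(np.quantile(samples.beta1, 0.025)), float(np.quantile(samples.beta1, 0.975))),
        theta_mean=samples.theta.mean(axis=0),
        theta_lo=q(samples.theta, 0.025),
        theta_hi=q(samples.theta, 0.975),
        exp_psi_s_mean=exp_psi_s.mean(axis=0),
        exp_psi_s_lo=q(exp_psi_s, 0.025),
        exp_psi_s_hi=q(exp_psi_s, 0.975),
        exp_psi_p_mean=np.exp(samples.psi_p).mean(axis=0),
        omega_mean=omega.mean(axis=0),
        omega_ci=np.column_stack([q(omega, 0.025), q(omega, 0.975)]),
        omega_boxplot=np.stack([_five_number(omega[:, t]) for t in range(omega.shape[1])]),
    )
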