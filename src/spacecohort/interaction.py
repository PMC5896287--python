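"""Space-cohort interaction model (comparison model).

Log relative risk:

    log theta_it = beta0 + beta1 * x_it + v_i + u_i + phi_t + psi_it

with iid heterogeneity ``v``, an intrinsic-CAR clustering field ``u``, an
iid cohort effect ``phi_t`` and a spatially structured interaction field
``psi`` whose precision structure is the Kronecker product of the spatial
structure matrix with a temporal factor (RW1 by default, identity as a
variant).  The posterior-mean maps of ``exp(psi_it)`` show how each
cohort's spatial pattern departs from the common one.  The sampler mirrors
the shared-component one: colored elementwise Metropolis for structured
fields, conjugate Gamma draws for the four precisions, and per-iteration
projection of ``psi`` off its structure matrix's null space (derived
numerically, so both temporal variants stay identifiable).
"""

from __future__ import annotations

import dataclasses
import warnings

import networkx as nx
import numpy as np
import scipy.sparse as sp

from . import _mh
from .car import (
    AdjacencyGraph,
    ValidationError,
    build_interaction_structure,
    build_structure_matrix,
    car_rank,
)
from .lexis import CohortData
from .smbc import MCMCConfig


@dataclasses.dataclass
class InteractionState:
    """One parameter state of the space-cohort interaction model."""

    beta0: float
    beta1: float
    v: np.ndarray  # (I,) unstructured spatial
    u: np.ndarray  # (I,) structured spatial
    phi_t: np.ndarray  # (T,) unstructured cohort
    psi: np.ndarray  # (I, T) interaction
    tau_v: float
    tau_u: float
    tau_phi: float
    tau_psi: float

    def log_theta(self, x: np.ndarray | None) -> np.ndarray:
        eta = self.beta0 + self.v[:, None] + self.u[:, None] + self.phi_t[None, :] + self.psi
        if x is not None:
            eta = eta + self.beta1 * x
        return eta

    def theta(self, x: np.ndarray | None) -> np.ndarray:
        return np.exp(self.log_theta(x))


def _psi_null_basis(k_psi_dense: np.ndarray) -> np.ndarray:
    """Orthonormal basis of the interaction structure matrix's null space."""
    evals, evecs = np.linalg.eigh(k_psi_dense)
    tol = 1e-9 * max(float(evals.max()), 1.0)
    return evecs[:, evals <= tol]


def interaction_log_posterior(
    state: InteractionState, data: CohortData, graph: AdjacencyGraph, config: MCMCConfig
) -> float:
    """Unnormalised log posterior of the interaction model."""
    I, T = data.shape
    eta = state.log_theta(data.x)
    if not np.all(np.isfinite(eta)):
        raise ValidationError("non-finite linear predictor")
    theta_E = np.exp(eta) * data.E
    lp = float(np.sum(data.y * (eta + np.log(data.E)) - theta_E))

    lp += -0.5 * (state.beta0**2 + state.beta1**2) / config.beta_prior_var

    k_u = build_structure_matrix(graph)
    k_psi = build_interaction_structure(k_u, T, config.interaction_variant)
    rank_u = car_rank(graph)
    rank_psi = rank_u * (T - 1 if config.interaction_variant == "rw1-time" else T)

    lp += 0.5 * I * np.log(state.tau_v) - 0.5 * state.tau_v * float(state.v @ state.v)
    lp += 0.5 * rank_u * np.log(state.tau_u) - 0.5 * state.tau_u * k_u.quad_form(state.u)
    lp += 0.5 * T * np.log(state.tau_phi) - 0.5 * state.tau_phi * float(state.phi_t @ state.phi_t)
    lp += 0.5 * rank_psi * np.log(state.tau_psi) - 0.5 * state.tau_psi * k_psi.quad_form(
        state.psi.ravel()
    )
    for tau in (state.tau_v, state.tau_u, state.tau_phi, state.tau_psi):
        lp += _mh.gamma_logpdf(tau, config.prior_shape, config.prior_rate)
    if not np.isfinite(lp):
        raise ValidationError("non-finite log posterior")
    return float(lp)


@dataclasses.dataclass
class InteractionSamples:
    """Kept post-burn-in states of the interaction model."""

    area_ids: tuple[str, ...]
    cohort_labels: tuple[str, ...]
    beta0: np.ndarray
    beta1: np.ndarray
    v: np.ndarray  # (n, I)
    u: np.ndarray  # (n, I)
    phi_t: np.ndarray  # (n, T)
    psi: np.ndarray  # (n, I, T)
    taus: np.ndarray  # (n, 4): v, u, phi, psi
    theta: np.ndarray  # (n, I, T)

    @property
    def n_samples(self) -> int:
        return self.beta0.shape[0]

    def to_long_frame(self):
        import pandas as pd

        recs = []
        for k in range(self.n_samples):
            recs.append((k, "beta0", self.beta0[k]))
            recs.append((k, "beta1", self.beta1[k]))
            for j, name in enumerate(("tau_v", "tau_u", "tau_phi", "tau_psi")):
                recs.append((k, name, self.taus[k, j]))
        return pd.DataFrame(recs, columns=["iteration", "parameter", "value"])

    def write_csv(self, path) -> None:
        self.to_long_frame().to_csv(path, index=False)


def run_interaction_mcmc(
    data: CohortData, graph: AdjacencyGraph, config: MCMCConfig
) -> InteractionSamples:
    """Metropolis-within-Gibbs for the space-cohort interaction model."""
    I, T = data.shape
    if graph.n_areas != I:
        raise ValidationError("graph and data disagree on the number of areas")
    rng = np.random.default_rng(config.seed)
    x, y, E = data.x, data.y, data.E

    k_u = build_structure_matrix(graph)
    adjacency = sp.csr_matrix(-sp.triu(k_u.matrix, 1) - sp.tril(k_u.matrix, -1))
    n_i = graph.n_i.astype(float)
    not_island = n_i > 0
    rank_u = car_rank(graph)
    comps = graph.connected_components()
    single_comp = len(comps) == 1
    colors = graph.coloring()
    color_masks = [np.flatnonzero((colors == c) & not_island) for c in range(colors.max() + 1)]
    color_masks = [m for m in color_masks if m.size]

    k_psi = build_interaction_structure(k_u, T, config.interaction_variant)
    k_psi_mat = k_psi.matrix
    k_psi_diag = np.asarray(k_psi_mat.diagonal())
    rank_psi = rank_u * (T - 1 if config.interaction_variant == "rw1-time" else T)
    null_basis = _psi_null_basis(k_psi.dense())

    # conflict graph of the interaction sites from the off-diagonal sparsity;
    # equal-color sites never interact through K_psi, so they update together
    conflict = nx.Graph()
    conflict.add_nodes_from(range(I * T))
    coo = k_psi_mat.tocoo()
    conflict.add_edges_from(
        (int(r), int(c)) for r, c, val in zip(coo.row, coo.col, coo.data) if r < c and val != 0
    )
    psi_colors = nx.greedy_color(conflict, strategy="largest_first")
    psi_color_arr = np.array([psi_colors[s] for s in range(I * T)])
    active = k_psi_diag > 0  # sites of isolated areas keep psi = 0
    psi_color_masks = [
        np.flatnonzero((psi_color_arr == c) & active) for c in range(psi_color_arr.max() + 1)
    ]
    psi_color_masks = [m for m in psi_color_masks if m.size]

    state = InteractionState(
        beta0=float(np.log(np.maximum(y, 0.5) / E).mean()),
        beta1=0.0,
        v=np.zeros(I),
        u=np.zeros(I),
        phi_t=np.zeros(T),
        psi=np.zeros((I, T)),
        tau_v=10.0,
        tau_u=10.0,
        tau_phi=10.0,
        tau_psi=10.0,
    )
    steps = _mh.StepSizes(sizes=dict(config.step_sizes), window=config.adapt_window)

    n_iter = config.n_burnin + config.n_keep * config.thin
    kept = 0
    out = InteractionSamples(
        area_ids=data.area_ids,
        cohort_labels=data.cohort_labels,
        beta0=np.empty(config.n_keep),
        beta1=np.empty(config.n_keep),
        v=np.empty((config.n_keep, I)),
        u=np.empty((config.n_keep, I)),
        phi_t=np.empty((config.n_keep, T)),
        psi=np.empty((config.n_keep, I, T)),
        taus=np.empty((config.n_keep, 4)),
        theta=np.empty((config.n_keep, I, T)),
    )

    for it in range(n_iter):
        eta = state.log_theta(x)
        mu = E * np.exp(eta)

        # beta0
        d = steps.sizes["beta0"] * rng.standard_normal()
        dlp = float(np.sum(y * d - mu * np.expm1(d)))
        dlp -= 0.5 * ((state.beta0 + d) ** 2 - state.beta0**2) / config.beta_prior_var
        if np.log(rng.random()) < dlp:
            state.beta0 += d
            eta += d
            mu *= np.exp(d)
            steps.record("beta0", 1.0, 1.0)
        else:
            steps.record("beta0", 0.0, 1.0)

        # beta1
        if x is not None:
            d = steps.sizes["beta1"] * rng.standard_normal()
            de = d * x
            dlp = float(np.sum(y * de - mu * np.expm1(de)))
            dlp -= 0.5 * ((state.beta1 + d) ** 2 - state.beta1**2) / config.beta_prior_var
            if np.log(rng.random()) < dlp:
                state.beta1 += d
                eta += de
                mu *= np.exp(de)
                steps.record("beta1", 1.0, 1.0)
            else:
                steps.record("beta1", 0.0, 1.0)

        # v (iid; rows independent)
        d = steps.sizes["v"] * rng.standard_normal(I)
        dll = np.sum(y * d[:, None] - mu * np.expm1(d)[:, None], axis=1)
        dlp = dll - 0.5 * state.tau_v * ((state.v + d) ** 2 - state.v**2)
        mask = _mh.mh_accept_mask(dlp, rng)
        if mask.any():
            d_acc = np.where(mask, d, 0.0)
            state.v += d_acc
            eta += d_acc[:, None]
            mu *= np.exp(d_acc)[:, None]
        steps.record("v", float(mask.sum()), float(I))

        # u (CAR; colored)
        for cm in color_masks:
            nb_sum = np.asarray(adjacency[cm] @ state.u).ravel()
            d = steps.sizes["u"] * rng.standard_normal(cm.size)
            dll = np.sum(y[cm] * d[:, None] - mu[cm] * np.expm1(d)[:, None], axis=1)
            u_old = state.u[cm]
            dquad = n_i[cm] * ((u_old + d) ** 2 - u_old**2) - 2.0 * d * nb_sum
            dlp = dll - 0.5 * state.tau_u * dquad
            mask = _mh.mh_accept_mask(dlp, rng)
            if mask.any():
                idx = cm[mask]
                state.u[idx] += d[mask]
                eta[idx] += d[mask][:, None]
                mu[idx] *= np.exp(d[mask])[:, None]
            steps.record("u", float(mask.sum()), float(cm.size))

        # phi_t (iid; columns independent)
        d = steps.sizes["phi_t"] * rng.standard_normal(T)
        dll = np.sum(y * d[None, :] - mu * np.expm1(d)[None, :], axis=0)
        dlp = dll - 0.5 * state.tau_phi * ((state.phi_t + d) ** 2 - state.phi_t**2)
        mask = _mh.mh_accept_mask(dlp, rng)
        if mask.any():
            d_acc = np.where(mask, d, 0.0)
            state.phi_t += d_acc
            eta += d_acc[None, :]
            mu *= np.exp(d_acc)[None, :]
        steps.record("phi_t", float(mask.sum()), float(T))

        # psi (interaction; colored on the K_psi conflict graph)
        vec = state.psi.ravel()
        for cm in psi_color_masks:
            r = np.asarray(k_psi_mat[cm] @ vec).ravel()
            d = steps.sizes["psi"] * rng.standard_normal(cm.size)
            ii, tt = cm // T, cm % T
            dll = y[ii, tt] * d - mu[ii, tt] * np.expm1(d)
            dquad = 2.0 * d * r + k_psi_diag[cm] * d**2
            dlp = dll - 0.5 * state.tau_psi * dquad
            mask = _mh.mh_accept_mask(dlp, rng)
            if mask.any():
                idx = cm[mask]
                vec[idx] += d[mask]
                eta[ii[mask], tt[mask]] += d[mask]
                mu[ii[mask], tt[mask]] *= np.exp(d[mask])
            steps.record("psi", float(mask.sum()), float(cm.size))
        state.psi = vec.reshape(I, T)

        # conjugate precisions
        state.tau_v = _mh.sample_precision(
            config.prior_shape, config.prior_rate, I, float(state.v @ state.v), rng
        )
        state.tau_u = _mh.sample_precision(
            config.prior_shape, config.prior_rate, rank_u, k_u.quad_form(state.u), rng
        )
        state.tau_phi = _mh.sample_precision(
            config.prior_shape, config.prior_rate, T, float(state.phi_t @ state.phi_t), rng
        )
        state.tau_psi = _mh.sample_precision(
            config.prior_shape, config.prior_rate, rank_psi, k_psi.quad_form(state.psi.ravel()), rng
        )

        # identifiability: project psi off the null space of K_psi, pushing
        # the removed additive structure into v, phi_t and beta0 so theta is
        # unchanged on connected maps
        vec = state.psi.ravel()
        removed = (null_basis @ (null_basis.T @ vec)).reshape(I, T)
        g = float(removed.mean())
        a = removed.mean(axis=1) - g
        b = removed.mean(axis=0) - g
        state.psi = state.psi - removed
        state.v += a
        state.phi_t += b
        state.beta0 += g

        for comp in comps:
            m = float(state.u[comp].mean())
            state.u[comp] -= m
            if single_comp:
                state.beta0 += m
        m = float(state.v.mean())
        state.v -= m
        state.beta0 += m
        m = float(state.phi_t.mean())
        state.phi_t -= m
        state.beta0 += m

        if it < config.n_burnin:
            if (it + 1) % config.adapt_window == 0:
                steps.adapt()
        elif it == config.n_burnin:
            steps.frozen = True

        if it >= config.n_burnin and (it - config.n_burnin + 1) % config.thin == 0:
            out.beta0[kept] = state.beta0
            out.beta1[kept] = state.beta1
            out.v[kept] = state.v
            out.u[kept] = state.u
            out.phi_t[kept] = state.phi_t
            out.psi[kept] = state.psi
            out.taus[kept] = (state.tau_v, state.tau_u, state.tau_phi, state.tau_psi)
            out.theta[kept] = state.theta(x)
            if not np.all(np.isfinite(out.theta[kept])):
                raise RuntimeError(f"non-finite posterior state at iteration {it}")
            kept += 1

    rates = steps.acceptance_rates()
    bad = {bk: rr for bk, rr in rates.items() if not 0.05 <= rr <= 0.95}
    if bad:
        warnings.warn(f"post-adaptation acceptance rates outside [0.05, 0.95]: {bad}")
    return out


@dataclasses.dataclass
class InteractionSummary:
    """Posterior means / intervals of the interaction-model quantities."""

    area_ids: tuple[str, ...]
    cohort_labels: tuple[str, ...]
    beta1_mean: float
    beta1_ci: tuple[float, float]
    theta_mean: np.ndarray
    exp_psi_mean: np.ndarray  # posterior mean of exp(psi_it), the cohort-difference maps
    exp_psi_lo: np.ndarray
    exp_psi_hi: np.ndarray

    def to_area_frame(self):
        import pandas as pd

        recs = []
        for i, aid in enumerate(self.area_ids):
            rec = {"area_id": aid}
            for t, coh in enumerate(self.cohort_labels):
                rec[f"theta_mean[{coh}]"] = self.theta_mean[i, t]
                rec[f"exp_psi_mean[{coh}]"] = self.exp_psi_mean[i, t]
            recs.append(rec)
        return pd.DataFrame(recs)

    def write_csv(self, path) -> None:
        self.to_area_frame().to_csv(path, index=False)


def summarize_interaction(samples: InteractionSamples) -> InteractionSummary:
    if samples.n_samples < 2:
        raise ValidationError("need at least 2 kept samples to summarise")
    exp_psi = np.exp(samples.psi)
    return InteractionSummary(
        area_ids=samples.area_ids,
        cohort_labels=samples.cohort_labels,
        beta1_mean=float(samples.beta1.mean()),
        beta1_ci=(
            float(np.quantile(samples.beta1, 0.025)),
            float(np.quantile(samples.beta1, 0.975)),
        ),
        theta_mean=samples.theta.mean(axis=0),
        exp_psi_mean=exp_psi.mean(axis=0),
        exp_psi_lo=np.quantile(exp_psi, 0.025, axis=0),
        exp_psi_hi=np.quantile(exp_psi, 0.975, axis=0),
    )
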