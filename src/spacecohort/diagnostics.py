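"""Convergence diagnostics and posterior reporting.

The Gelman-Rubin potential scale reduction factor compares between- and
within-chain variance over parallel chains started from different seeds;
partial autocorrelations of a single trace diagnose residual dependence
after thinning.  Convergence is conventionally flagged at R-hat below 1.1.
"""

from __future__ import annotations

import dataclasses
from typing import Sequence

import numpy as np
import pandas as pd

from .car import ValidationError

RHAT_THRESHOLD = 1.1


def gelman_rubin(chains: Sequence[np.ndarray]) -> float:
    """Potential scale reduction factor of m >= 2 equal-length chains.

    With within-chain variance W and between-chain variance B (n times the
    variance of the chain means), returns sqrt(((n-1)/n * W + B/n) / W).
    Identical constant chains return 1 by convention; constant chains that
    disagree have undefined scale and raise.
    """
    arr = np.asarray([np.asarray(c, dtype=float) for c in chains])
    if arr.ndim != 2 or arr.shape[0] < 2:
        raise ValidationError("need >= 2 equal-length chains")
    m, n = arr.shape
    if n < 2:
        raise ValidationError("chains must have length >= 2")
    means = arr.mean(axis=1)
    w = float(arr.var(axis=1, ddof=1).mean())
    b = float(n * means.var(ddof=1))
    if w == 0.0:
        if b == 0.0:
            return 1.0
        raise ValidationError("zero within-chain variance with nonzero between-chain variance")
    return float(np.sqrt(((n - 1) / n * w + b / n) / w))


def partial_autocorrelation(chain: np.ndarray, max_lag: int) -> np.ndarray:
    """PACF at lags 1..max_lag via the Levinson-Durbin recursion."""
    chain = np.asarray(chain, dtype=float)
    if chain.ndim != 1 or chain.size <= max_lag:
        raise ValidationError("chain length must exceed max_lag")
    if max_lag < 1:
        raise ValidationError("max_lag must be >= 1")
    if np.ptp(chain) == 0:
        raise ValidationError("PACF undefined for a constant chain")
    from statsmodels.tsa.stattools import levinson_durbin

    _, _, pacf, _, _ = levinson_durbin(chain, nlags=max_lag, isacov=False)
    return np.asarray(pacf[1:], dtype=float)


@dataclasses.dataclass
class PosteriorSummary:
    """Per-parameter posterior summaries with convergence statistics."""

    table: pd.DataFrame  # parameter, mean, q2.5, q50, q97.5, rhat

    def converged(self, threshold: float = RHAT_THRESHOLD) -> bool:
        rhat = self.table["rhat"].dropna()
        return bool((rhat < threshold).all()) if len(rhat) else False

    def write_csv(self, path) -> None:
        self.table.to_csv(path, index=False)


def summarize_chains(
    chains_by_param: dict[str, Sequence[np.ndarray]],
) -> PosteriorSummary:
    """Pool parallel chains per parameter into means, quantiles and R-hat.

    ``chains_by_param`` maps a parameter name to >= 1 chains; R-hat is
    reported only where >= 2 chains are available.
    """
    recs = []
    for name, chains in chains_by_param.items():
        pooled = np.concatenate([np.asarray(c, dtype=float) for c in chains])
        rhat = gelman_rubin(chains) if len(chains) >= 2 else np.nan
        recs.append(
            {
                "parameter": name,
                "mean": pooled.mean(),
                "q2.5": np.quantile(pooled, 0.025),
                "q50": np.quantile(pooled, 0.5),
                "q97.5": np.quantile(pooled, 0.975),
                "rhat": rhat,
            }
        )
    return PosteriorSummary(table=pd.DataFrame(recs))


def monitored_subset(
    sample_frames: Sequence[pd.DataFrame],
    n_theta: int = 10,
    subset_seed: int = 1234,
) -> PosteriorSummary:
    """Convergence summary over the conventional monitored subset.

    Monitors the regression coefficients, cohort intercepts, shared-field
    scalings and precision hyperparameters from long-format sample tables
    (columns iteration, parameter, value), one table per chain; if
    area-level relative-risk traces are present, a fixed-seed random subset
    of ``n_theta`` of them is added.
    """
    if not sample_frames:
        raise ValidationError("no chains supplied")
    params = set(sample_frames[0]["parameter"].unique())
    for df in sample_frames[1:]:
        params &= set(df["parameter"].unique())
    core = [
        p
        for p in sorted(params)
        if p.startswith(("beta", "alpha", "omega", "lambda", "tau"))
    ]
    theta_params = sorted(p for p in params if p.startswith("theta"))
    if theta_params:
        rng = np.random.default_rng(subset_seed)
        pick = rng.choice(len(theta_params), size=min(n_theta, len(theta_params)), replace=False)
        core += [theta_params[k] for k in sorted(pick)]
    chains_by_param = {
        p: [df.loc[df["parameter"] == p, "value"].to_numpy() for df in sample_frames]
        for p in core
    }
    return summarize_chains(chains_by_param)
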