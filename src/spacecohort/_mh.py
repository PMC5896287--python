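"""Shared Metropolis-within-Gibbs plumbing for the two mortality samplers."""

from __future__ import annotations

import dataclasses

import numpy as np


@dataclasses.dataclass
class StepSizes:
    """Per-block random-walk step sizes with burn-in adaptation.

    During burn-in each block's log step size is nudged so that its empirical
    acceptance rate approaches the single-site optimum (~0.44); after burn-in
    the sizes are frozen.
    """

    sizes: dict[str, float]
    target: float = 0.44
    window: int = 50
    kappa: float = 0.6
    _acc: dict[str, float] = dataclasses.field(default_factory=dict)
    _prop: dict[str, float] = dataclasses.field(default_factory=dict)
    frozen: bool = False

    def record(self, block: str, accepted: float, proposed: float) -> None:
        self._acc[block] = self._acc.get(block, 0.0) + accepted
        self._prop[block] = self._prop.get(block, 0.0) + proposed

    def adapt(self) -> None:
        if self.frozen:
            return
        for block, prop in self._prop.items():
            if prop > 0:
                rate = self._acc[block] / prop
                self.sizes[block] *= float(np.exp(self.kappa * (rate - self.target)))
        self._acc.clear()
        self._prop.clear()

    def acceptance_rates(self) -> dict[str, float]:
        return {b: self._acc[b] / p for b, p in self._prop.items() if p > 0}


def sample_precision(
    prior_shape: float, prior_rate: float, rank: int, quad_form: float, rng: np.random.Generator
) -> float:
    """Conjugate Gamma draw for a field precision.

    Posterior shape = prior shape + rank/2, posterior rate = prior rate +
    quadratic-form/2, where rank is the rank of the field's structure matrix
    and the quadratic form is ``field' K field``.
    """
    shape = prior_shape + 0.5 * rank
    rate = prior_rate + 0.5 * quad_form
    return float(rng.gamma(shape, 1.0 / rate))


def mh_accept_mask(log_ratio: np.ndarray, rng: np.random.Generator) -> np.ndarray:
    """Elementwise Metropolis accept decisions for a vector of log ratios."""
    log_ratio = np.asarray(log_ratio, dtype=float)
    return np.log(rng.random(log_ratio.shape)) < log_ratio


def gamma_logpdf(x: float, shape: float, rate: float) -> float:
    """Log density of a shape-rate Gamma, up to no dropped terms."""
    from scipy.special import gammaln

    if x <= 0:
        return -np.inf
    return shape * np.log(rate) - gammaln(shape) + (shape - 1.0) * np.log(x) - rate * x
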