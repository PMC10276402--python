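"""Adaptive MALA-within-Gibbs sampling of bursting parameters.

One chain per gene: empirical initialization, per-coordinate Langevin
proposals with adaptive scaling toward the 0.574 optimal acceptance rate,
gradient estimated from accepted moves, and automatic fallback from the
cell-specific conversion model (model 2) to the cell-pooled one (model 3)
when the approximate new-transcript pmf goes unstable too often inside a
rolling window.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Callable, Dict, List, Optional, Sequence, Tuple

import numpy as np

from .distributions import BurstParams, ConversionRates
from .likelihoods import GeneObservations, ModelEvaluator

__all__ = [
    "PriorConfig",
    "AdaptiveState",
    "ChainConfig",
    "PosteriorChain",
    "InitializationError",
    "empirical_init",
    "mala_propose",
    "mh_accept",
    "update_gradient",
    "update_adaptive",
    "gibbs_sweep",
    "run_chain",
    "select_genes",
]

PARAM_NAMES = ("mu", "a", "gamma", "b", "kappa", "delta")
COORDS = ("mu", "a", "gamma")

ACC_TARGET = 0.574
ETA_DECAY = 0.999


class InitializationError(RuntimeError):
    """Chain initialization failed to find positive posterior density."""


@dataclass(frozen=True)
class PriorConfig:
    """Flat, independent priors on (mu, a, gamma)."""

    mu_max: float = 100000.0
    a_max: float = 100000.0
    gamma_min: float = 1.0
    gamma_max: float = 100000.0

    def contains(self, theta: np.ndarray) -> bool:
        mu, a, gamma = theta
        return (
            0.0 < mu < self.mu_max
            and 0.0 < a < self.a_max
            and self.gamma_min <= gamma <= self.gamma_max
        )


@dataclass
class AdaptiveState:
    """Per-coordinate proposal scales and gradient estimates."""

    S: np.ndarray
    eta: float = 0.1
    grad: np.ndarray = field(default_factory=lambda: np.zeros(3))
    acc_target: float = ACC_TARGET

    @classmethod
    def from_init(cls, theta1: np.ndarray) -> "AdaptiveState":
        return cls(S=np.asarray(theta1, dtype=float) / 100.0, eta=0.1, grad=np.zeros(3))


@dataclass
class ChainConfig:
    """Chain length, posterior-window and model-switch settings.

    Leave the optional fields unset to have them resolved from the empirical
    expression level: high-expression genes (mu_hat >= 1000) use a shorter
    chain with a proportionally shorter window.
    """

    n_steps: Optional[int] = None
    window: Optional[int] = None
    thinning: int = 2
    switch_window: Optional[int] = None
    quantile: float = 0.9999
    likelihood: str = "L1+L2"
    max_init_draws: int = 1000
    max_m: int = 20000
    max_m_kernel: int = 5000
    high_mu: float = 1000.0

    def resolve(self, mu_hat: float) -> Tuple[int, int, int]:
        """(n_steps, posterior window, rolling switch window) for this gene."""
        high = mu_hat >= self.high_mu
        n_steps = self.n_steps if self.n_steps is not None else (1500 if high else 5000)
        window = self.window if self.window is not None else (1000 if high else 2500)
        w = self.switch_window if self.switch_window is not None else (100 if high else 500)
        window = min(window, n_steps)
        return n_steps, window, w


@dataclass
class PosteriorChain:
    """A finished chain with its posterior summaries."""

    gene_id: str
    likelihood: str
    model: int
    switch_step: Optional[int]
    samples: np.ndarray  # (n_steps, 3) raw chain of (mu, a, gamma)
    accepts: np.ndarray  # (n_steps, 3) boolean sub-step acceptances
    unstable_steps: np.ndarray  # (n_steps,) instability-rejection indicator
    thinned: np.ndarray  # (n_post, 6) thinned post-window samples, all params
    summaries: Dict[str, Dict[str, float]]
    acceptance_rates: Dict[str, float]
    init_params: BurstParams

    @property
    def max_cv(self) -> float:
        return max(s["cv"] for s in self.summaries.values())


# ---------------------------------------------------------------------------
# initialization
# ---------------------------------------------------------------------------


def empirical_gamma_hat(lam: float, rates: ConversionRates) -> float:
    """Lifetime guess from the gene's overall conversion rate."""
    if rates.lambda_n > 0:
        inner = 1.0 - (lam - rates.lambda_s) / rates.lambda_n
    else:
        inner = 0.9
    inner = min(0.9, max(0.1, inner))
    return -rates.t / math.log(inner)


def empirical_init(
    gene: GeneObservations,
    rates: ConversionRates,
    rng: np.random.Generator,
    priors: Optional[PriorConfig] = None,
    log_target: Optional[Callable[[np.ndarray], Tuple[float, bool]]] = None,
    max_draws: int = 1000,
) -> BurstParams:
    """Semi-random start: empirical mu, lifetime from the conversion rate,
    log-uniform burst rate; redrawn until the target density is positive."""
    if priors is None:
        priors = PriorConfig()
    if len(gene) == 0:
        raise InitializationError(f"{gene.gene_id}: no cells")
    mu_hat = float(np.mean(gene.ls / gene.alphas))
    if not mu_hat > 0:
        raise InitializationError(f"{gene.gene_id}: empirical expression level is zero")
    gamma_hat = empirical_gamma_hat(gene.observed_conversion_rate(), rates)
    for _ in range(max_draws):
        a = math.exp(rng.uniform(math.log(1.0), math.log(10.0)))
        gamma = rng.normal(gamma_hat, gamma_hat / 5.0)
        theta = np.array([mu_hat, a, gamma])
        if not priors.contains(theta):
            continue
        if log_target is not None:
            lp, _ = log_target(theta)
            if not np.isfinite(lp):
                continue
        return BurstParams(mu=mu_hat, a=a, gamma=gamma)
    raise InitializationError(
        f"{gene.gene_id}: no positive-density start found in {max_draws} draws"
    )


# ---------------------------------------------------------------------------
# MALA-within-Gibbs primitives
# ---------------------------------------------------------------------------


def mala_propose(theta_k: float, S_k: float, grad_k: float, rng: np.random.Generator) -> float:
    """Langevin proposal: Normal(theta_k + S_k * grad_k, scale=sqrt(2 S_k))."""
    if not S_k > 0:
        raise ValueError("S_k must be > 0")
    return float(rng.normal(theta_k + S_k * grad_k, math.sqrt(2.0 * S_k)))


def mh_accept(
    log_target_current: float,
    log_target_proposed: float,
    rng: np.random.Generator,
) -> Tuple[bool, float]:
    """Metropolis decision; impossible proposals get A = 0 for adaptation."""
    if not np.isfinite(log_target_proposed):
        return False, 0.0
    if not np.isfinite(log_target_current):
        return True, 1.0
    A = min(1.0, math.exp(min(log_target_proposed - log_target_current, 0.0)))
    return bool(rng.random() < A or A >= 1.0), A


def update_gradient(
    theta_old: float,
    theta_new: float,
    log_target_old: float,
    log_target_new: float,
    accepted: bool,
) -> float:
    """Secant gradient estimate on acceptance, zero on rejection."""
    if not accepted:
        return 0.0
    dtheta = theta_new - theta_old
    if dtheta == 0.0:
        return 0.0
    return (log_target_new - log_target_old) / dtheta


def update_adaptive(S_k: float, eta: float, A: float) -> Tuple[float, float]:
    """Multiplicative scale update toward the 0.574 target, with eta decay."""
    S_new = math.exp(math.log(S_k) + eta * (A - ACC_TARGET))
    return S_new, ETA_DECAY * eta


def gibbs_sweep(
    theta: np.ndarray,
    log_target: Callable[[np.ndarray], Tuple[float, bool]],
    current_lp: float,
    state: AdaptiveState,
    rng: np.random.Generator,
) -> Tuple[np.ndarray, float, np.ndarray, int]:
    """One full sweep over (mu, a, gamma), each sub-step conditioning on the
    freshest values of the other coordinates.

    Returns (theta, log target, per-coordinate acceptance flags, number of
    sub-step rejections caused by pmf instability). ``state`` is updated in
    place.
    """
    theta = theta.copy()
    accepted_flags = np.zeros(3, dtype=bool)
    instab = 0
    for k in range(3):
        prop = mala_propose(theta[k], state.S[k], state.grad[k], rng)
        theta_prop = theta.copy()
        theta_prop[k] = prop
        lp_prop, unstable = log_target(theta_prop)
        accepted, A = mh_accept(current_lp, lp_prop, rng)
        if accepted:
            state.grad[k] = update_gradient(theta[k], prop, current_lp, lp_prop, True)
            theta = theta_prop
            current_lp = lp_prop
            accepted_flags[k] = True
        else:
            state.grad[k] = 0.0
            if unstable:
                instab += 1
        state.S[k], state.eta = update_adaptive(state.S[k], state.eta, A)
    return theta, current_lp, accepted_flags, instab


# ---------------------------------------------------------------------------
# full chain
# ---------------------------------------------------------------------------


def _make_target(
    evaluator: ModelEvaluator,
    priors: PriorConfig,
    likelihood: str,
) -> Callable[[np.ndarray], Tuple[float, bool]]:
    def log_target(theta: np.ndarray) -> Tuple[float, bool]:
        if not priors.contains(theta):
            return -np.inf, False
        try:
            params = BurstParams(mu=theta[0], a=theta[1], gamma=theta[2])
            value, unstable = evaluator.loglik(params, likelihood)
        except (OverflowError, ValueError, FloatingPointError):
            return -np.inf, False
        if unstable:
            return -np.inf, True
        if not np.isfinite(value):
            return -np.inf, False
        return value, False

    return log_target


def _derived_matrix(samples: np.ndarray) -> np.ndarray:
    """(mu, a, gamma) samples -> columns (mu, a, gamma, b, kappa, delta)."""
    mu, a, gamma = samples[:, 0], samples[:, 1], samples[:, 2]
    delta = 1.0 / gamma
    return np.column_stack([mu, a, gamma, mu / a, a * delta, delta])


def _summaries(thinned: np.ndarray) -> Dict[str, Dict[str, float]]:
    out: Dict[str, Dict[str, float]] = {}
    for j, name in enumerate(PARAM_NAMES):
        col = thinned[:, j]
        mean = float(col.mean())
        sd = float(col.std(ddof=1)) if col.size > 1 else 0.0
        out[name] = {"mean": mean, "sd": sd, "cv": sd / mean if mean != 0 else math.inf}
    return out


def run_chain(
    gene: GeneObservations,
    rates: ConversionRates,
    rng: np.random.Generator,
    config: Optional[ChainConfig] = None,
    priors: Optional[PriorConfig] = None,
) -> PosteriorChain:
    """Sample the posterior for one gene, switching to model 3 if needed."""
    config = config or ChainConfig()
    priors = priors or PriorConfig()
    evaluator = ModelEvaluator(
        gene,
        rates,
        quantile=config.quantile,
        max_m=config.max_m,
        max_m_kernel=config.max_m_kernel,
    )
    mu_hat = float(np.mean(gene.ls / gene.alphas)) if len(gene) else 0.0
    n_steps, window, w = config.resolve(mu_hat)
    switch_threshold = w / 20.0

    likelihood = config.likelihood
    model = {"L1": 1, "L2": 2, "L1+L2": 2, "L3": 3, "L1+L3": 3}[likelihood]
    switch_step: Optional[int] = None

    while True:
        log_target = _make_target(evaluator, priors, likelihood)
        init = empirical_init(
            gene, rates, rng, priors=priors, log_target=log_target,
            max_draws=config.max_init_draws,
        )
        theta = init.as_array()
        state = AdaptiveState.from_init(theta)
        current_lp, _ = log_target(theta)
        samples = np.empty((n_steps, 3))
        accepts = np.zeros((n_steps, 3), dtype=bool)
        unstable_steps = np.zeros(n_steps, dtype=bool)
        restart = False
        monitor = likelihood == "L1+L2"
        for j in range(n_steps):
            theta, current_lp, acc, instab = gibbs_sweep(
                theta, log_target, current_lp, state, rng
            )
            samples[j] = theta
            accepts[j] = acc
            unstable_steps[j] = instab > 0
            if monitor:
                lo = max(w // 2, j - w + 1)  # step indices are 0-based here
                if unstable_steps[lo : j + 1].sum() >= switch_threshold:
                    switch_step = j + 1
                    likelihood = "L1+L3"
                    model = 3
                    restart = True
                    break
        if not restart:
            break

    post = samples[n_steps - window :][:: config.thinning]
    thinned = _derived_matrix(post)
    half = n_steps // 2
    acc_rates = {
        name: float(accepts[half:, k].mean()) for k, name in enumerate(COORDS)
    }
    return PosteriorChain(
        gene_id=gene.gene_id,
        likelihood=likelihood,
        model=model,
        switch_step=switch_step,
        samples=samples,
        accepts=accepts,
        unstable_steps=unstable_steps,
        thinned=thinned,
        summaries=_summaries(thinned),
        acceptance_rates=acc_rates,
        init_params=init,
    )


def select_genes(
    results: Sequence[PosteriorChain], cv_max: float = 0.45
) -> List[PosteriorChain]:
    """Keep genes whose every parameter CV is at most cv_max."""
    return [r for r in results if r.max_cv <= cv_max]
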