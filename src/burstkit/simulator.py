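"""Exact stochastic simulation of two-state bursty transcription with a
labelling pulse, plus the in-silico sequencing generator.

Two transcript pools are tracked: RNA0 (made before the pulse) and RNA1 (made
during it). A burn-in run synthesises into pool 0 only; the pulse run switches
synthesis to pool 1 while both pools keep decaying. Sequencing draws capture,
reads-per-UMI, per-read genomic-T content and per-read conversions.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import List, Optional, Tuple, Union

import numpy as np
from numba import njit

from .distributions import BurstParams, UracilDistribution
from .likelihoods import CellObservation, GeneObservations

__all__ = [
    "RateConstants",
    "SystemState",
    "SeqNoiseConfig",
    "gillespie_run",
    "simulate_cell",
    "sequence_cell",
    "simulate_gene_dataset",
    "params_to_rates",
    "stationary_mean",
    "sample_ztpois",
]


@dataclass(frozen=True)
class RateConstants:
    """Reaction rate constants (per minute) for the two-pool two-state scheme."""

    beta0: float
    beta1: float
    delta0: float
    delta1: float
    kon: float
    koff: float

    def __post_init__(self):
        for name in ("beta0", "beta1", "delta0", "delta1", "kon", "koff"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")


@dataclass
class SystemState:
    """(RNA0, RNA1, Gon, Goff) with exactly one gene-state indicator set."""

    rna0: int = 0
    rna1: int = 0
    gon: int = 0
    goff: int = 1

    def __post_init__(self):
        if self.gon + self.goff != 1:
            raise ValueError("exactly one of gon/goff must be 1")
        if self.rna0 < 0 or self.rna1 < 0:
            raise ValueError("counts must be >= 0")


@dataclass(frozen=True)
class SeqNoiseConfig:
    """Sequencing-noise and protocol settings for the in-silico generator."""

    alpha_beta: Tuple[float, float] = (1.0, 9.0)
    alpha_fixed: Optional[float] = None  # overrides the Beta draw when set
    nu: float = 5.0
    u_hat: float = 60.0
    lambda_s: float = 0.01
    lambda_n: float = 0.075
    t0: float = 200000.0
    t1: float = 1000.0
    n_cells: int = 10000


@njit(cache=False)
def _ssa_core(rna0, rna1, gon, t_end, beta0, beta1, delta0, delta1, kon, koff, seed):
    np.random.seed(seed)
    t = 0.0
    while True:
        a1 = beta0 * gon
        a2 = beta1 * gon
        a3 = delta0 * rna0
        a4 = delta1 * rna1
        a5 = kon * (1 - gon)
        a6 = koff * gon
        a0 = a1 + a2 + a3 + a4 + a5 + a6
        if a0 <= 0.0:
            break
        t += np.random.exponential(1.0 / a0)
        if t > t_end:
            break
        r = np.random.random() * a0
        if r < a1:
            rna0 += 1
        elif r < a1 + a2:
            rna1 += 1
        elif r < a1 + a2 + a3:
            rna0 -= 1
        elif r < a1 + a2 + a3 + a4:
            rna1 -= 1
        elif r < a1 + a2 + a3 + a4 + a5:
            gon = 1
        else:
            gon = 0
    return rna0, rna1, gon


def _spawn_seed(rng: np.random.Generator) -> int:
    return int(rng.integers(0, 2**31 - 1))


def gillespie_run(
    state0: SystemState,
    rates: RateConstants,
    t_end: float,
    rng: np.random.Generator,
) -> SystemState:
    """Exact SSA endpoint after t_end minutes of simulated time."""
    if t_end < 0:
        raise ValueError("t_end must be >= 0")
    rna0, rna1, gon = _ssa_core(
        state0.rna0,
        state0.rna1,
        state0.gon,
        float(t_end),
        rates.beta0,
        rates.beta1,
        rates.delta0,
        rates.delta1,
        rates.kon,
        rates.koff,
        _spawn_seed(rng),
    )
    return SystemState(rna0=rna0, rna1=rna1, gon=gon, goff=1 - gon)


def simulate_cell(
    rates_pre: RateConstants,
    rates_pulse: RateConstants,
    t0: float,
    t1: float,
    rng: np.random.Generator,
) -> Tuple[int, int]:
    """Burn-in then pulse; returns (RNA0, RNA1) at the sequencing point."""
    if rates_pre.beta1 != 0:
        raise ValueError("burn-in run must not synthesise into pool 1")
    if rates_pulse.beta0 != 0:
        raise ValueError("pulse run must not synthesise into pool 0")
    state = gillespie_run(SystemState(0, 0, 0, 1), rates_pre, t0, rng)
    state = gillespie_run(state, rates_pulse, t1, rng)
    return state.rna0, state.rna1


def sample_ztpois(nu: float, size: int, rng: np.random.Generator) -> np.ndarray:
    """Zero-truncated Poisson draws via rejection of zeros."""
    out = rng.poisson(nu, size=size)
    while True:
        zero = out == 0
        n_zero = int(zero.sum())
        if n_zero == 0:
            return out
        out[zero] = rng.poisson(nu, size=n_zero)


def sequence_cell(
    rna0: int,
    rna1: int,
    noise: SeqNoiseConfig,
    rng: np.random.Generator,
    cell_id: str = "cell",
    alpha: Optional[float] = None,
) -> CellObservation:
    """In-silico sequencing of one cell's two transcript pools.

    ``alpha`` overrides the capture-efficiency draw so several genes can share
    one cell panel.
    """
    if rna0 < 0 or rna1 < 0:
        raise ValueError("pool counts must be >= 0")
    if alpha is not None:
        alpha = float(alpha)
    elif noise.alpha_fixed is not None:
        alpha = float(noise.alpha_fixed)
    else:
        alpha = float(rng.beta(*noise.alpha_beta))
        alpha = min(max(alpha, 1e-12), 1.0)
    l0 = int(rng.binomial(rna0, alpha))
    l1 = int(rng.binomial(rna1, alpha))
    reads_u: List[np.ndarray] = []
    reads_i: List[np.ndarray] = []
    for l_k, rate in ((l0, noise.lambda_s), (l1, noise.lambda_s + noise.lambda_n)):
        if l_k == 0:
            continue
        r_per_umi = sample_ztpois(noise.nu, l_k, rng)
        n_reads = int(r_per_umi.sum())
        u = rng.poisson(noise.u_hat, size=n_reads)
        i = rng.binomial(u, rate)
        reads_u.append(u)
        reads_i.append(i)
    if reads_u:
        u_all = np.concatenate(reads_u)
        i_all = np.concatenate(reads_i)
        reads = np.column_stack([u_all, i_all])
        vals, counts = np.unique(i_all, return_counts=True)
        y = {int(v): int(c) for v, c in zip(vals, counts)}
    else:
        reads = np.zeros((0, 2), dtype=int)
        y = {}
    return CellObservation(cell_id=cell_id, l=l0 + l1, alpha=alpha, y=y, reads=reads)


def params_to_rates(
    params: BurstParams, koff: float = 1.0
) -> Tuple[RateConstants, RateConstants]:
    """Map (mu, a, gamma) to SSA rate constants with fixed koff.

    beta = b * koff and kon = kappa, the instantaneous-burst limit mapping.
    Returns (burn-in rates, pulse rates).
    """
    beta = params.b * koff
    delta = params.delta
    pre = RateConstants(beta0=beta, beta1=0.0, delta0=delta, delta1=delta,
                        kon=params.kappa, koff=koff)
    pulse = RateConstants(beta0=0.0, beta1=beta, delta0=delta, delta1=delta,
                          kon=params.kappa, koff=koff)
    return pre, pulse


def stationary_mean(rates: RateConstants) -> float:
    """Closed-form stationary mean total RNA of the two-state model."""
    denom = rates.delta0 * (rates.kon + rates.koff)
    if denom == 0:
        raise ValueError("stationary mean undefined for zero rates")
    return rates.beta0 * rates.kon / denom


def simulate_gene_dataset(
    burst: Union[BurstParams, Tuple[RateConstants, RateConstants]],
    noise: SeqNoiseConfig,
    rng: np.random.Generator,
    gene_id: str = "gene",
    koff: float = 1.0,
    alphas: Optional[np.ndarray] = None,
) -> Tuple[GeneObservations, np.ndarray]:
    """Simulate a full gene dataset: N cells of SSA + sequencing.

    Returns the observations plus the (RNA0, RNA1) truth matrix. The gene's
    uracil distribution is the truncated Poisson(u_hat) pmf the reads were
    drawn from.
    """
    if isinstance(burst, BurstParams):
        rates_pre, rates_pulse = params_to_rates(burst, koff=koff)
    else:
        rates_pre, rates_pulse = burst
    if rates_pre.delta0 > 0 and noise.t0 * rates_pre.delta0 < 10:
        warnings.warn(
            f"burn-in t0={noise.t0} is under 10 transcript lifetimes; "
            "the pre-pulse pool may not be stationary",
            stacklevel=2,
        )
    if alphas is not None and len(alphas) != noise.n_cells:
        raise ValueError("alphas must have one entry per cell")
    cells = []
    pools = np.zeros((noise.n_cells, 2), dtype=int)
    for c in range(noise.n_cells):
        rna0, rna1 = simulate_cell(rates_pre, rates_pulse, noise.t0, noise.t1, rng)
        pools[c] = (rna0, rna1)
        cells.append(
            sequence_cell(
                rna0, rna1, noise, rng, cell_id=f"c{c}",
                alpha=None if alphas is None else float(alphas[c]),
            )
        )
    udist = UracilDistribution.from_poisson(noise.u_hat)
    gene = GeneObservations(gene_id=gene_id, cells=cells, lambda_s=noise.lambda_s, udist=udist)
    return gene, pools
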