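"""Per-gene likelihood functions over UMI counts and T>C conversion histograms.

Five likelihoods are exposed: the UMI-only term (L1), the cell-specific
conversion term (L2), their product (model 2), the cell-pooled conversion term
(L3) and its product with L1 (model 3). The multinomial coefficient is omitted
throughout -- it is constant in the parameters and cancels in every Metropolis
ratio.

``ModelEvaluator`` is the single computational path: the public ``loglik_*``
functions delegate to a fresh evaluator, while the sampler keeps one alive per
gene so per-cell constants and conversion mixtures are built once.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Dict, List, Optional, Sequence

import numpy as np
from scipy.special import gammaln

from .distributions import (
    PROB_FLOOR,
    BurstParams,
    ConversionRates,
    FSPBound,
    InstabilityFlag,
    UracilDistribution,
    fsp_bound,
    log_nb_pmf_vector,
    new_fraction_weights,
    poisson_mixture,
    safe_log,
)

__all__ = [
    "CellObservation",
    "GeneObservations",
    "ConversionKernel",
    "InstabilityError",
    "ModelEvaluator",
    "build_kernel",
    "loglik_L1",
    "loglik_L2",
    "loglik_model2",
    "loglik_L3",
    "loglik_model3",
    "gene_inclusion_filter",
]

LIKELIHOODS = ("L1", "L2", "L1+L2", "L3", "L1+L3")


class InstabilityError(RuntimeError):
    """Raised when a likelihood hits the unstable region of the new-count pmf."""

    def __init__(self, flag: InstabilityFlag):
        super().__init__(f"unstable new-transcript pmf (first negative at n={flag.first_negative_n})")
        self.flag = flag


@dataclass
class CellObservation:
    """One cell's observations for one gene.

    y maps a per-read conversion count i to the number of reads showing it.
    reads optionally keeps the per-read (u, i) pairs the histogram came from.
    """

    cell_id: str
    l: int
    alpha: float
    y: Dict[int, int] = field(default_factory=dict)
    reads: Optional[np.ndarray] = None  # shape (n_reads, 2) columns (u, i)

    def __post_init__(self):
        if self.l < 0:
            raise ValueError("l must be >= 0")
        if not 0 < self.alpha <= 1:
            raise ValueError("alpha must lie in (0, 1]")
        if any(v < 0 for v in self.y.values()):
            raise ValueError("conversion histogram has negative counts")

    @property
    def n_reads(self) -> int:
        return int(sum(self.y.values()))


class GeneObservations:
    """All cells' observations for one gene plus gene-level conversion context."""

    def __init__(
        self,
        gene_id: str,
        cells: Sequence[CellObservation],
        lambda_s: float,
        udist: UracilDistribution,
    ):
        self.gene_id = gene_id
        self.cells: List[CellObservation] = list(cells)
        self.lambda_s = float(lambda_s)
        self.udist = udist
        self._dense = None

    def __len__(self) -> int:
        return len(self.cells)

    # -- dense views -------------------------------------------------------
    def _build_dense(self):
        ls = np.array([c.l for c in self.cells], dtype=float)
        alphas = np.array([c.alpha for c in self.cells], dtype=float)
        imax = 0
        for c in self.cells:
            if c.y:
                imax = max(imax, max(c.y))
        Y = np.zeros((len(self.cells), imax + 1))
        for r, c in enumerate(self.cells):
            for i, cnt in c.y.items():
                Y[r, i] = cnt
        self._dense = (ls, alphas, Y)

    @property
    def ls(self) -> np.ndarray:
        if self._dense is None:
            self._build_dense()
        return self._dense[0]

    @property
    def alphas(self) -> np.ndarray:
        if self._dense is None:
            self._build_dense()
        return self._dense[1]

    @property
    def Y(self) -> np.ndarray:
        """Dense per-cell conversion histogram, shape (n_cells, i_max + 1)."""
        if self._dense is None:
            self._build_dense()
        return self._dense[2]

    @property
    def i_support(self) -> np.ndarray:
        return np.arange(self.Y.shape[1])

    @property
    def pooled_y(self) -> np.ndarray:
        """Cell-summed conversion histogram."""
        return self.Y.sum(axis=0)

    @property
    def total_reads(self) -> int:
        return int(self.pooled_y.sum())

    def observed_conversion_rate(self) -> float:
        """Converted Ts / genomic Ts across all reads of the gene.

        Uses per-read (u, i) pairs when available, otherwise approximates the
        denominator with the mean of the uracil distribution.
        """
        if all(c.reads is not None for c in self.cells):
            tot_u = sum(int(c.reads[:, 0].sum()) for c in self.cells)
            tot_i = sum(int(c.reads[:, 1].sum()) for c in self.cells)
        else:
            tot_i = float(self.i_support @ self.pooled_y)
            tot_u = self.udist.mean * self.total_reads
        if tot_u <= 0:
            return 0.0
        return float(tot_i) / float(tot_u)


def gene_inclusion_filter(gene_4su: GeneObservations, gene_ctrl: Optional[GeneObservations] = None) -> bool:
    """Keep genes with at least one read and one observed conversion.

    When a control (no-label) counterpart is supplied the same predicate must
    hold there too.
    """

    def _ok(g: GeneObservations) -> bool:
        py = g.pooled_y
        return g.total_reads >= 1 and float(py[1:].sum()) > 0

    return _ok(gene_4su) and (gene_ctrl is None or _ok(gene_ctrl))


# ---------------------------------------------------------------------------
# conversion kernel
# ---------------------------------------------------------------------------


@dataclass
class ConversionKernel:
    """P(i | m) factorized through the expected labelled fraction per m.

    P(i|m) = w[m] * A[i] + (1 - w[m]) * B[i] where A/B are the labelled and
    background Poisson mixtures over the uracil distribution; the matrix is
    materialized on demand.
    """

    params: BurstParams
    bound: FSPBound
    w: np.ndarray
    A: np.ndarray
    B: np.ndarray
    flag: InstabilityFlag

    @property
    def matrix(self) -> np.ndarray:
        return np.outer(self.w, self.A) + np.outer(1.0 - self.w, self.B)


def build_kernel(
    params: BurstParams,
    rates: ConversionRates,
    udist: UracilDistribution,
    i_support: np.ndarray,
    quantile: float = 0.9999,
    bound: Optional[FSPBound] = None,
) -> ConversionKernel:
    if bound is None:
        bound = fsp_bound(params, quantile)
    tau = params.tau(rates.t)
    A = poisson_mixture(i_support, rates.lambda_n + rates.lambda_s, udist)
    B = poisson_mixture(i_support, rates.lambda_s, udist)
    w, _, flag = new_fraction_weights(params, tau, bound.M)
    return ConversionKernel(params=params, bound=bound, w=w, A=A, B=B, flag=flag)


# ---------------------------------------------------------------------------
# evaluator
# ---------------------------------------------------------------------------


class ModelEvaluator:
    """Fast repeated likelihood evaluation for one gene.

    Caches everything that does not depend on the parameter vector: per-cell
    capture constants and the labelled/background conversion mixtures.
    """

    def __init__(
        self,
        gene: GeneObservations,
        rates: ConversionRates,
        quantile: float = 0.9999,
        max_m: int = 20000,
        max_m_kernel: int = 5000,
    ):
        self.gene = gene
        self.rates = rates
        self.quantile = quantile
        self.max_m = max_m
        self.max_m_kernel = max_m_kernel
        ls, alphas = gene.ls, gene.alphas
        self._ls = ls
        self._alphas = alphas
        self._cell_const = -gammaln(ls + 1.0)
        self._Y = gene.Y
        self._isup = gene.i_support
        self.A = poisson_mixture(self._isup, rates.lambda_n + rates.lambda_s, gene.udist)
        self.B = poisson_mixture(self._isup, rates.lambda_s, gene.udist)
        self._logm = np.array([-np.inf])

    def _logm_vec(self, M: int) -> np.ndarray:
        if self._logm.size < M + 1:
            grown = np.empty(M + 1)
            grown[0] = -np.inf
            grown[1:] = np.log(np.arange(1, M + 1, dtype=float))
            self._logm = grown
        return self._logm[: M + 1]

    def _cell_rows(self, params: BurstParams, M: int) -> np.ndarray:
        """log P(l_c | m, alpha_c) + log P(m) for m = 0..M, one row per cell."""
        m = np.arange(M + 1, dtype=float)
        lognb = log_nb_pmf_vector(m, params)
        logm = self._logm_vec(M)
        ls = self._ls[:, None]
        with np.errstate(invalid="ignore"):
            lcap = np.where(ls > 0, ls * (logm[None, :] + np.log(self._alphas)[:, None]), 0.0)
        lcap -= np.outer(self._alphas, m)
        lcap += self._cell_const[:, None]
        return lcap + lognb[None, :]

    def _l1_and_weights(self, params: BurstParams, M: int):
        rows = self._cell_rows(params, M)
        rowmax = rows.max(axis=1)
        finite = np.isfinite(rowmax)
        shifted = np.exp(rows - np.where(finite, rowmax, 0.0)[:, None])
        sumexp = shifted.sum(axis=1)
        log_marg = np.where(finite, safe_log(sumexp) + rowmax, np.log(PROB_FLOOR))
        log_marg = np.maximum(log_marg, np.log(PROB_FLOOR))
        l1 = float(log_marg.sum())
        with np.errstate(invalid="ignore"):
            weights = shifted / np.where(sumexp > 0, sumexp, 1.0)[:, None]
        return l1, weights

    # -- public pieces -----------------------------------------------------
    def loglik(self, params: BurstParams, likelihood: str = "L1+L2"):
        """Return (log-likelihood, unstable) for the requested components."""
        if likelihood not in LIKELIHOODS:
            raise ValueError(f"unknown likelihood {likelihood!r}; expected one of {LIKELIHOODS}")
        bound = fsp_bound(params, self.quantile)
        if bound.M > self.max_m:
            raise OverflowError(f"FSP bound M={bound.M} exceeds max_m={self.max_m}")
        total = 0.0
        weights = None
        if likelihood in ("L1", "L1+L2", "L1+L3", "L2"):
            l1, weights = self._l1_and_weights(params, bound.M)
            if likelihood != "L2":
                total += l1
        if likelihood in ("L2", "L1+L2"):
            if bound.M > self.max_m_kernel:
                raise OverflowError(
                    f"FSP bound M={bound.M} exceeds max_m_kernel={self.max_m_kernel}"
                )
            kernel = build_kernel(
                params, self.rates, self.gene.udist, self._isup,
                quantile=self.quantile, bound=bound,
            )
            if kernel.flag.unstable:
                return -np.inf, True
            W = weights @ kernel.w
            pmat = W[:, None] * self.A[None, :] + (1.0 - W)[:, None] * self.B[None, :]
            total += float((self._Y * safe_log(pmat)).sum())
        if likelihood in ("L3", "L1+L3"):
            tau = params.tau(self.rates.t)
            e = math.exp(-min(tau, 700.0))
            pi = (1.0 - e) * self.A + e * self.B
            total += float(self.gene.pooled_y @ safe_log(pi))
        return total, False


# ---------------------------------------------------------------------------
# public likelihood functions
# ---------------------------------------------------------------------------


def _evaluator(gene, rates, quantile, evaluator):
    if evaluator is not None:
        return evaluator
    if rates is None:
        # L1 never touches the conversion machinery; any valid rates object works
        rates = ConversionRates(lambda_s=0.0, lambda_n=0.0, t=1.0)
    return ModelEvaluator(gene, rates, quantile=quantile)


def loglik_L1(
    gene: GeneObservations,
    params: BurstParams,
    quantile: float = 0.9999,
    evaluator: Optional[ModelEvaluator] = None,
) -> float:
    """UMI-count log-likelihood; depends on (mu, a) only, flat in gamma."""
    ev = _evaluator(gene, None, quantile, evaluator)
    value, _ = ev.loglik(params, "L1")
    return value


def loglik_L2(
    gene: GeneObservations,
    params: BurstParams,
    rates: ConversionRates,
    quantile: float = 0.9999,
    evaluator: Optional[ModelEvaluator] = None,
) -> float:
    """Cell-specific conversion log-likelihood (multinomial coefficient omitted)."""
    ev = _evaluator(gene, rates, quantile, evaluator)
    value, unstable = ev.loglik(params, "L2")
    if unstable:
        raise InstabilityError(InstabilityFlag(True, None))
    return value


def loglik_model2(
    gene: GeneObservations,
    params: BurstParams,
    rates: ConversionRates,
    quantile: float = 0.9999,
    evaluator: Optional[ModelEvaluator] = None,
) -> float:
    """Full model-2 log-likelihood: L1 + L2."""
    ev = _evaluator(gene, rates, quantile, evaluator)
    value, unstable = ev.loglik(params, "L1+L2")
    if unstable:
        raise InstabilityError(InstabilityFlag(True, None))
    return value


def loglik_L3(
    gene: GeneObservations,
    params: BurstParams,
    rates: ConversionRates,
    quantile: float = 0.9999,
    evaluator: Optional[ModelEvaluator] = None,
) -> float:
    """Cell-pooled conversion log-likelihood; depends on theta only through tau."""
    ev = _evaluator(gene, rates, quantile, evaluator)
    value, _ = ev.loglik(params, "L3")
    return value


def loglik_model3(
    gene: GeneObservations,
    params: BurstParams,
    rates: ConversionRates,
    quantile: float = 0.9999,
    evaluator: Optional[ModelEvaluator] = None,
) -> float:
    """Full model-3 log-likelihood: L1 + L3."""
    ev = _evaluator(gene, rates, quantile, evaluator)
    value, _ = ev.loglik(params, "L1+L3")
    return value
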