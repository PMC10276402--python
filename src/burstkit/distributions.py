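"""Probability kernels for bursty transcription with metabolic labelling.

Latent-count distributions (steady state, surviving, newly made transcripts),
the capture/UMI observation model, and the per-read T>C conversion mixtures.
All heavy lifting is done on numpy arrays; scalar entry points mirror the
vector routines. Every pmf has a log-space companion.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Optional

import numpy as np
from numba import njit as _njit
from scipy import stats
from scipy.special import gammaln, logsumexp

__all__ = [
    "BurstParams",
    "FSPBound",
    "UracilDistribution",
    "ConversionRates",
    "InstabilityFlag",
    "PROB_FLOOR",
    "safe_log",
    "nb_steady_state",
    "log_nb_steady_state",
    "nb_pmf_vector",
    "log_nb_pmf_vector",
    "fsp_bound",
    "capture_pmf",
    "log_capture_pmf",
    "umi_marginal",
    "log_umi_marginal",
    "surviving_conditional",
    "surviving_marginal",
    "surviving_pmf_vector",
    "new_transcript_pmf",
    "new_transcript_pmf_vector",
    "posterior_m_given_l",
    "new_given_total",
    "new_fraction_weights",
    "conversions_given_m",
    "conversions_given_umi",
    "pooled_conversion_pmf",
    "poisson_mixture",
]

#: Probabilities are clipped here before logging so that MCMC can traverse
#: low-likelihood regions without -inf arithmetic.
PROB_FLOOR = 1e-300

#: Largest tau for which exp(tau) is representable; beyond it the labelled
#: fraction is treated as exactly 1.
_TAU_MAX = 700.0


def safe_log(p):
    """log with the global probability floor applied."""
    return np.log(np.clip(p, PROB_FLOOR, None))


# ---------------------------------------------------------------------------
# domain types
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class BurstParams:
    """Bursting parameter vector (mu, a, gamma) with derived quantities.

    mu
        Mean transcripts per cell (mu = a * b).
    a
        Burst rate: bursts per transcript lifetime.
    gamma
        Transcript lifetime in minutes (>= 1).
    """

    mu: float
    a: float
    gamma: float

    def __post_init__(self):
        if not (self.mu > 0 and np.isfinite(self.mu)):
            raise ValueError(f"mu must be positive and finite, got {self.mu}")
        if not (self.a > 0 and np.isfinite(self.a)):
            raise ValueError(f"a must be positive and finite, got {self.a}")
        if not (self.gamma >= 1 and np.isfinite(self.gamma)):
            raise ValueError(f"gamma must be >= 1 and finite, got {self.gamma}")

    @property
    def b(self) -> float:
        """Mean transcripts per burst."""
        return self.mu / self.a

    @property
    def delta(self) -> float:
        """Decay rate per minute."""
        return 1.0 / self.gamma

    @property
    def kappa(self) -> float:
        """Burst frequency per minute."""
        return self.a * self.delta

    def tau(self, t: float) -> float:
        """Pulse duration t (minutes) in units of transcript lifetimes."""
        return t * self.delta

    @classmethod
    def from_burst(cls, b: float, kappa: float, delta: float) -> "BurstParams":
        """Construct from (b, kappa, delta)."""
        a = kappa / delta
        return cls(mu=b * a, a=a, gamma=1.0 / delta)

    def as_array(self) -> np.ndarray:
        return np.array([self.mu, self.a, self.gamma], dtype=float)


@dataclass(frozen=True)
class FSPBound:
    """Finite-state-projection truncation of the latent transcript count."""

    M: int
    quantile: float = 0.9999

    @property
    def error(self) -> float:
        return 1.0 - self.quantile


@dataclass(frozen=True)
class ConversionRates:
    """T>C conversion rates and the labelling pulse duration.

    lambda_s: gene-specific background conversion probability per genomic T.
    lambda_n: additional conversion probability per T on labelled transcripts.
    t: pulse duration in minutes.
    """

    lambda_s: float
    lambda_n: float
    t: float

    def __post_init__(self):
        if not (0 <= self.lambda_s < 1):
            raise ValueError(f"lambda_s must be in [0, 1), got {self.lambda_s}")
        if not (0 <= self.lambda_n < 1):
            raise ValueError(f"lambda_n must be in [0, 1), got {self.lambda_n}")
        if not self.t > 0:
            raise ValueError(f"t must be positive, got {self.t}")


@dataclass(frozen=True)
class InstabilityFlag:
    """Records whether an approximate pmf evaluation produced an invalid value."""

    unstable: bool = False
    first_negative_n: Optional[int] = None

    def __bool__(self) -> bool:  # pragma: no cover - convenience
        return self.unstable


STABLE = InstabilityFlag(False, None)


class UracilDistribution:
    """Pmf over the number of genomic T bases covered by a read."""

    def __init__(self, u: np.ndarray, p: np.ndarray):
        u = np.asarray(u, dtype=int)
        p = np.asarray(p, dtype=float)
        if u.ndim != 1 or p.shape != u.shape:
            raise ValueError("u and p must be 1-d arrays of equal length")
        if np.any(p < 0):
            raise ValueError("uracil pmf has negative entries")
        total = p.sum()
        if not total > 0:
            raise ValueError("uracil pmf sums to zero")
        self.u = u
        self.p = p / total

    @classmethod
    def from_poisson(cls, u_hat: float, tail: float = 1e-8) -> "UracilDistribution":
        """Poisson(u_hat) truncated at the 1 - tail quantile and renormalized."""
        u_max = int(stats.poisson.ppf(1.0 - tail, u_hat))
        u = np.arange(u_max + 1)
        return cls(u, stats.poisson.pmf(u, u_hat))

    @classmethod
    def from_counts(cls, u_values: np.ndarray) -> "UracilDistribution":
        """Empirical pmf from observed per-read genomic-T counts."""
        u_values = np.asarray(u_values, dtype=int)
        if u_values.size == 0:
            raise ValueError("no reads to build a uracil distribution from")
        counts = np.bincount(u_values)
        u = np.nonzero(counts)[0]
        return cls(u, counts[u].astype(float))

    @property
    def mean(self) -> float:
        return float(np.dot(self.u, self.p))

    def __eq__(self, other):
        return (
            isinstance(other, UracilDistribution)
            and np.array_equal(self.u, other.u)
            and np.allclose(self.p, other.p)
        )


# ---------------------------------------------------------------------------
# steady-state transcript count (negative binomial)
# ---------------------------------------------------------------------------


def log_nb_pmf_vector(m: np.ndarray, params: BurstParams) -> np.ndarray:
    a, b = params.a, params.b
    m = np.asarray(m, dtype=float)
    return (
        gammaln(m + a)
        - gammaln(m + 1.0)
        - gammaln(a)
        + m * (np.log(b) - np.log1p(b))
        - a * np.log1p(b)
    )


def nb_pmf_vector(m: np.ndarray, params: BurstParams) -> np.ndarray:
    return np.exp(log_nb_pmf_vector(m, params))


def nb_steady_state(m: int, params: BurstParams) -> float:
    """Steady-state pmf of the transcript count under instantaneous geometric bursts."""
    if m < 0:
        raise ValueError("m must be >= 0")
    return float(nb_pmf_vector(np.array([m]), params)[0])


def log_nb_steady_state(m: int, params: BurstParams) -> float:
    if m < 0:
        raise ValueError("m must be >= 0")
    return float(log_nb_pmf_vector(np.array([m]), params)[0])


def fsp_bound(params: BurstParams, quantile: float = 0.9999) -> FSPBound:
    """Smallest M whose steady-state CDF reaches ``quantile``."""
    if not 0 < quantile < 1:
        raise ValueError("quantile must lie in (0, 1)")
    M = int(stats.nbinom.ppf(quantile, params.a, 1.0 / (1.0 + params.b)))
    return FSPBound(M=M, quantile=quantile)


# ---------------------------------------------------------------------------
# capture / UMI observation model
# ---------------------------------------------------------------------------


def log_capture_pmf(l: int, m, alpha: float):
    """Poisson approximation of binomial capture: log P(l | m, alpha)."""
    if l < 0:
        raise ValueError("l must be >= 0")
    if not 0 < alpha <= 1:
        raise ValueError("alpha must lie in (0, 1]")
    m = np.asarray(m, dtype=float)
    mean = m * alpha
    with np.errstate(divide="ignore", invalid="ignore"):
        out = np.where(
            mean > 0,
            l * np.log(np.where(mean > 0, mean, 1.0)) - mean - gammaln(l + 1.0),
            0.0 if l == 0 else -np.inf,
        )
    return out


def capture_pmf(l: int, m: int, alpha: float) -> float:
    """P(l | m, alpha); deliberately positive even when m < l."""
    return float(np.exp(log_capture_pmf(l, np.array([m]), alpha))[0])


def log_umi_marginal(
    l: int, alpha: float, params: BurstParams, bound: Optional[FSPBound] = None
) -> float:
    if bound is None:
        bound = fsp_bound(params)
    m = np.arange(bound.M + 1)
    return float(logsumexp(log_capture_pmf(l, m, alpha) + log_nb_pmf_vector(m, params)))


def umi_marginal(
    l: int, alpha: float, params: BurstParams, bound: Optional[FSPBound] = None
) -> float:
    """P(l | alpha) marginalized over the FSP-truncated steady state."""
    return float(np.exp(log_umi_marginal(l, alpha, params, bound)))


def posterior_m_given_l(
    l: int, alpha: float, params: BurstParams, bound: Optional[FSPBound] = None
) -> np.ndarray:
    """Posterior over the latent transcript count m in [0, M] given (l, alpha)."""
    if bound is None:
        bound = fsp_bound(params)
    m = np.arange(bound.M + 1)
    logw = log_capture_pmf(l, m, alpha) + log_nb_pmf_vector(m, params)
    top = logw.max()
    if not np.isfinite(top):
        raise ValueError(
            f"observation l={l} has zero marginal probability under the FSP bound M={bound.M}"
        )
    w = np.exp(logw - top)
    return w / w.sum()


# ---------------------------------------------------------------------------
# surviving (pre-pulse) transcripts
# ---------------------------------------------------------------------------


def surviving_conditional(s: int, m: int, tau: float) -> float:
    """Binomial survival: P(s | m) with per-transcript survival exp(-tau)."""
    if s < 0 or m < 0:
        raise ValueError("counts must be >= 0")
    if tau < 0:
        raise ValueError("tau must be >= 0")
    if s > m:
        return 0.0
    return float(stats.binom.pmf(s, m, math.exp(-min(tau, _TAU_MAX))))


def surviving_pmf_vector(s: np.ndarray, params: BurstParams, tau: float) -> np.ndarray:
    b_thin = params.b * math.exp(-min(tau, _TAU_MAX))
    if b_thin <= 0:
        out = np.zeros(np.asarray(s).shape, dtype=float)
        out[np.asarray(s) == 0] = 1.0
        return out
    return stats.nbinom.pmf(s, params.a, 1.0 / (1.0 + b_thin))


def surviving_marginal(s: int, params: BurstParams, tau: float) -> float:
    """Marginal pmf of surviving transcripts: NB with thinned odds b*exp(-tau)."""
    if s < 0:
        raise ValueError("s must be >= 0")
    return float(surviving_pmf_vector(np.array([s]), params, tau)[0])


# ---------------------------------------------------------------------------
# newly synthesised transcripts (approximate non-equilibrium solution)
# ---------------------------------------------------------------------------

#: Above this many negative entries the evaluation is declared unstable without
#: attempting high-precision re-evaluation (genuine oscillation, not roundoff).
_MAX_MPMATH_RESCUE = 20


@_njit(cache=False)
def _hyp2f1_terminating(n_max: int, a: float, z: float) -> np.ndarray:
    """2F1(-n, -a, 1-a-n; z) for n = 0..n_max via the terminating series.

    The series for each n has n+1 terms; within the terminating range the
    denominator Pochhammer factor (k - a - n) is strictly negative for a > 0,
    so the recursion over term ratios never divides by zero. Overflow yields a
    NaN entry which the caller turns into an instability flag.
    """
    out = np.empty(n_max + 1)
    out[0] = 1.0
    for n in range(1, n_max + 1):
        term = 1.0
        acc = 1.0
        for k in range(1, n + 1):
            term *= ((k - 1.0 - n) * (k - 1.0 - a)) / ((k - a - n) * k) * z
            acc += term
            if term == 0.0:
                break
        if not np.isfinite(acc):
            acc = np.nan
        out[n] = acc
    return out


def _hyp2f1_mpmath(n: int, a: float, z: float) -> float:
    import mpmath

    with mpmath.workdps(60):
        return float(mpmath.hyp2f1(-n, -a, 1 - a - n, z))


def new_transcript_pmf_vector(
    params: BurstParams, tau: float, n_max: int
) -> tuple[np.ndarray, InstabilityFlag]:
    """P(n) for n = 0..n_max plus an instability flag.

    The approximate solution oscillates into negative values when a and/or b are
    large and/or tau is small. Slightly negative entries caused by float64
    cancellation are re-evaluated at high precision before flagging; genuine
    instability (many/strong negatives or overflow) sets the flag.
    """
    if tau <= 0:
        raise ValueError("tau must be > 0")
    a, b = params.a, params.b
    n = np.arange(n_max + 1, dtype=float)
    exp_neg = math.exp(-min(tau, _TAU_MAX))
    z = 0.0 if tau >= _TAU_MAX else (1.0 + b) / (math.exp(tau) + b)
    log_pref = (
        gammaln(a + n)
        - gammaln(n + 1.0)
        - gammaln(a)
        + n * (np.log(b) - np.log1p(b))
        + a * (np.log1p(b * exp_neg) - np.log1p(b))
    )
    F = _hyp2f1_terminating(n_max, a, z)

    bad = ~np.isfinite(F)
    if np.any(bad):
        first = int(np.nonzero(bad)[0][0])
        return np.full(n_max + 1, np.nan), InstabilityFlag(True, first)

    neg = np.nonzero(F < 0)[0]
    if neg.size > _MAX_MPMATH_RESCUE:
        out = _combine_pref(log_pref, F)
        return out, InstabilityFlag(True, int(neg[0]))
    for idx in neg:  # roundoff rescue: re-evaluate suspect entries exactly
        F[idx] = _hyp2f1_mpmath(int(idx), a, z)
    still_neg = np.nonzero(F < 0)[0]
    out = _combine_pref(log_pref, F)
    if still_neg.size:
        return out, InstabilityFlag(True, int(still_neg[0]))
    return out, STABLE


def _combine_pref(log_pref: np.ndarray, F: np.ndarray) -> np.ndarray:
    """exp(log_pref) * F evaluated in log magnitude to dodge underflow."""
    with np.errstate(divide="ignore", over="ignore"):
        mag = np.where(F != 0, np.exp(log_pref + np.log(np.abs(np.where(F != 0, F, 1.0)))), 0.0)
    return np.sign(F) * mag


def new_transcript_pmf(
    n: int, params: BurstParams, tau: float
) -> tuple[float, InstabilityFlag]:
    """Approximate pmf of the newly synthesised transcript count at time tau."""
    if n < 0:
        raise ValueError("n must be >= 0")
    vec, flag = new_transcript_pmf_vector(params, tau, n)
    return float(vec[n]), flag


def new_given_total(
    m: int, params: BurstParams, tau: float
) -> tuple[np.ndarray, InstabilityFlag]:
    """P(n | m) over n in [0, m], normalized by the (n, s) convolution."""
    if m < 0:
        raise ValueError("m must be >= 0")
    if m == 0:
        return np.ones(1), STABLE
    pn, flag = new_transcript_pmf_vector(params, tau, m)
    if flag.unstable:
        return np.full(m + 1, np.nan), flag
    ps = surviving_pmf_vector(np.arange(m + 1), params, tau)
    joint = pn * ps[::-1]
    total = joint.sum()
    if not total > 0:
        return np.full(m + 1, np.nan), InstabilityFlag(True, 0)
    return joint / total, STABLE


def new_fraction_weights(
    params: BurstParams, tau: float, M: int
) -> tuple[np.ndarray, np.ndarray, InstabilityFlag]:
    """E[n/m | m] for all m in [0, M], plus the convolution normalizer.

    Returns ``(w, Z, flag)`` where ``w[m] = sum_n (n/m) P(n|m)`` (``w[0] = 0``,
    the background-only convention for empty cells) and ``Z[m]`` is the
    convolution ``sum_n P(n) P(s=m-n)`` which approximates the steady state.
    """
    pn, flag = new_transcript_pmf_vector(params, tau, M)
    if flag.unstable:
        nanv = np.full(M + 1, np.nan)
        return nanv, nanv, flag
    ps = surviving_pmf_vector(np.arange(M + 1), params, tau)
    Z = np.convolve(pn, ps)[: M + 1]
    num = np.convolve(np.arange(M + 1) * pn, ps)[: M + 1]
    w = np.zeros(M + 1)
    mgrid = np.arange(1, M + 1, dtype=float)
    with np.errstate(invalid="ignore", divide="ignore"):
        w[1:] = num[1:] / (mgrid * Z[1:])
    if not np.all(np.isfinite(w)):
        return w, Z, InstabilityFlag(True, int(np.nonzero(~np.isfinite(w))[0][0]))
    np.clip(w, 0.0, 1.0, out=w)
    return w, Z, STABLE


# ---------------------------------------------------------------------------
# T>C conversion mixtures
# ---------------------------------------------------------------------------


def poisson_mixture(i, rate: float, udist: UracilDistribution) -> np.ndarray:
    """sum_u P(u) Pois(i | u * rate) evaluated at the given i values."""
    i = np.atleast_1d(np.asarray(i, dtype=int))
    means = udist.u[:, None] * rate
    with np.errstate(divide="ignore"):
        pm = stats.poisson.pmf(i[None, :], np.where(means > 0, means, 0.0))
    return udist.p @ pm


def conversions_given_m(
    i: int,
    m: int,
    params: BurstParams,
    rates: ConversionRates,
    udist: UracilDistribution,
) -> tuple[float, InstabilityFlag]:
    """P(i | m): per-read conversion count mixed over the labelled fraction.

    For m = 0 the cell has no labelled transcripts and the background-only
    mixture is returned.
    """
    tau = params.tau(rates.t)
    lab = float(poisson_mixture(i, rates.lambda_n + rates.lambda_s, udist)[0])
    bg = float(poisson_mixture(i, rates.lambda_s, udist)[0])
    if m == 0:
        return bg, STABLE
    pnm, flag = new_given_total(m, params, tau)
    if flag.unstable:
        return float("nan"), flag
    w = float(np.dot(np.arange(m + 1) / m, pnm))
    return w * lab + (1.0 - w) * bg, STABLE


def conversions_given_umi(
    i: int,
    l: int,
    alpha: float,
    params: BurstParams,
    rates: ConversionRates,
    udist: UracilDistribution,
    bound: Optional[FSPBound] = None,
) -> tuple[float, InstabilityFlag]:
    """P(i | l, alpha): conversion pmf mixed over the posterior of m given l."""
    if bound is None:
        bound = fsp_bound(params)
    tau = params.tau(rates.t)
    post = posterior_m_given_l(l, alpha, params, bound)
    w_m, _, flag = new_fraction_weights(params, tau, bound.M)
    if flag.unstable:
        return float("nan"), flag
    W = float(np.dot(post, w_m))
    lab = float(poisson_mixture(i, rates.lambda_n + rates.lambda_s, udist)[0])
    bg = float(poisson_mixture(i, rates.lambda_s, udist)[0])
    return W * lab + (1.0 - W) * bg, STABLE


def pooled_conversion_pmf(
    i: int,
    params: BurstParams,
    rates: ConversionRates,
    udist: UracilDistribution,
) -> float:
    """Cell-pooled conversion pmf; depends on theta only through tau."""
    tau = params.tau(rates.t)
    if tau <= 0:
        raise ValueError("tau must be > 0")
    e = math.exp(-min(tau, _TAU_MAX))
    lab = float(poisson_mixture(i, rates.lambda_n + rates.lambda_s, udist)[0])
    bg = float(poisson_mixture(i, rates.lambda_s, udist)[0])
    return (1.0 - e) * lab + e * bg
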