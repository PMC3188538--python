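"""Luria–Delbrück fluctuation analysis.

Parallel cultures grown from a small inoculum accumulate resistance
mutations at random times during exponential growth.  Early mutations
found large "jackpot" clones, so the distribution of mutant counts
across cultures is heavy-tailed.  This module implements the Lea–Coulson
formulation of that distribution, maximum-likelihood estimation of the
expected number of mutation events per culture (``m``), likelihood-ratio
confidence intervals, and conversion to a per-cell-division mutation
rate ``mu_T = m / Nt`` where ``Nt`` is the total number of cell
divisions (taken equal to the final colony-forming-unit count, since
growth from ~1 cell implies divisions ≈ final cells).

Probability model
-----------------
The Lea–Coulson probability generating function is

    G(s) = exp( m * (1 - s)/s * ln(1 - s) )

equivalently a compound Poisson: Poisson(m) mutation events, each
founding a clone whose final size K has P(K = k) = 1/(k(k+1)).  The pmf
is evaluated by the Ma–Sandri–Sarkar-style recursion obtained by
differentiating the pgf,

    p_0 = exp(-m),    p_n = (m/n) * sum_{j<n} p_j / (n - j + 1),

which is exact and normalises to 1 (the exponent series of G has
coefficients m/(k(k+1)), so G' = H'G gives the weights 1/(k+1)).

Partial plating (a fraction ``z`` of each culture plated, modelling
1:10–1:200 dilutions) thins each mutant clone binomially.  The thinned
pgf is G(1 - z + z*s); for z <= 1/2 its exponent is expanded as a power
series and exponentiated term by term (exact, no tail truncation), and
for 1/2 < z < 1 the thinning convolution against the full-culture pmf
is evaluated directly over a horizon where the binomial kernel has
decayed to negligibility.  The two routes compute the same distribution.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field, replace
from typing import Optional, Sequence

import numpy as np
from scipy import optimize
from scipy.stats import binom, chi2

__all__ = [
    "CultureSet",
    "RateEstimate",
    "ConvergenceError",
    "ld_pmf",
    "log_likelihood",
    "mle_m",
    "lr_interval",
    "estimate_rate",
    "pool_experiments",
]

logger = logging.getLogger(__name__)


class ConvergenceError(RuntimeError):
    """Raised when the MLE or a confidence bound cannot be located."""


@dataclass(frozen=True)
class CultureSet:
    """One fluctuation experiment.

    Parameters
    ----------
    counts
        Mutant colonies observed in each parallel culture.
    n_total
        Nt, total cell divisions during growth, inferred from
        colony-forming units (divisions ≈ final cells).
    plating_fraction
        Fraction of each culture actually plated, in (0, 1].
    label
        Free-text experiment identifier.
    flagged
        Set by :func:`pool_experiments` when Nt values were too
        discordant to pool and the sets should be estimated
        independently.
    """

    counts: tuple
    n_total: float
    plating_fraction: float = 1.0
    label: str = ""
    flagged: bool = False

    def __post_init__(self):
        counts = tuple(int(c) for c in self.counts)
        if len(counts) == 0:
            raise ValueError("counts must be non-empty")
        if any(c < 0 for c in counts):
            raise ValueError("mutant counts must be non-negative")
        if not (self.n_total > 0):
            raise ValueError("n_total (Nt) must be positive")
        if not (0.0 < self.plating_fraction <= 1.0):
            raise ValueError("plating_fraction must be in (0, 1]")
        object.__setattr__(self, "counts", counts)


@dataclass(frozen=True)
class RateEstimate:
    """Maximum-likelihood mutation estimate for one experiment.

    ``m_hat`` is the expected number of mutation events per culture;
    ``rate`` is the phenotypic mutation rate mu_T = m_hat / Nt in
    mutants per cell division.  ``ci_m``/``ci_rate`` are the two-sided
    likelihood-ratio interval at ``level`` (None until computed).
    """

    m_hat: float
    n_total: float
    rate: float
    ci_m: Optional[tuple] = None
    ci_rate: Optional[tuple] = None
    level: float = 0.95
    label: str = ""

    @classmethod
    def from_m(cls, m_hat, n_total, ci_m=None, level=0.95, label=""):
        ci_rate = None
        if ci_m is not None:
            ci_m = (float(ci_m[0]), float(ci_m[1]))
            ci_rate = (ci_m[0] / n_total, ci_m[1] / n_total)
        return cls(
            m_hat=float(m_hat),
            n_total=float(n_total),
            rate=float(m_hat) / float(n_total),
            ci_m=ci_m,
            ci_rate=ci_rate,
            level=level,
            label=label,
        )


# ---------------------------------------------------------------------------
# pmf machinery
# ---------------------------------------------------------------------------

def _mss_pmf(m: float, n_max: int) -> np.ndarray:
    """Lea–Coulson full-culture (z = 1) pmf by the pgf-derivative recursion.

    p_n = (m/n) * sum_{k=1..n} p_{n-k} / (k+1); exact and normalising
    (verified against FFT inversion of the pgf and mechanistic
    Monte-Carlo in the test suite).
    """
    p = np.zeros(n_max + 1)
    p[0] = math.exp(-m)
    if n_max == 0 or m == 0.0:
        if m == 0.0:
            p[0] = 1.0
        return p
    w = 1.0 / (np.arange(1, n_max + 1, dtype=float) + 1.0)
    for n in range(1, n_max + 1):
        p[n] = (m / n) * np.dot(w[:n], p[n - 1::-1])
    return p


def _exp_series(h: np.ndarray) -> np.ndarray:
    """Coefficients of exp(h(s)) from the coefficients of h(s)."""
    K = len(h) - 1
    p = np.zeros(K + 1)
    p[0] = math.exp(h[0])
    kh = np.arange(K + 1) * h
    for n in range(1, K + 1):
        p[n] = np.dot(kh[1:n + 1], p[n - 1::-1]) / n
    return p


def _thinned_pmf_series(m: float, n_max: int, z: float) -> np.ndarray:
    """Exact thinned pmf via the pgf G(1 - z + z s); stable for z <= 1/2.

    Exponent h(s) = m * z(1-s)/(1-z+zs) * (ln z + ln(1-s)); the rational
    factor is expanded geometrically (ratio z/(1-z), convergent for
    z < 1/2 on |s| <= 1) and multiplied by the log series.
    """
    c = 1.0 - z
    K = n_max
    P = np.zeros(K + 1)
    P[0] = math.log(z)
    if K >= 1:
        P[1:] = -1.0 / np.arange(1, K + 1)
    q = (1.0 / c) * (-z / c) ** np.arange(K + 1)
    B = z * (q - np.concatenate(([0.0], q[:-1])))
    h = m * np.convolve(B, P)[: K + 1]
    return _exp_series(h)


def _thinned_pmf_conv(m: float, n_max: int, z: float) -> np.ndarray:
    """Binomial thinning of the z = 1 pmf by explicit convolution.

    The horizon N is chosen so the Binomial(n, z) kernel at k <= n_max
    has decayed to negligibility for n > N; used for z > 1/2 where the
    series route is unstable, and as an independent cross-check.
    """
    N = int(math.ceil((n_max + 40.0) / z + 10.0 * math.sqrt((n_max + 1.0) * (1.0 - z)) / z)) + 50
    N = max(N, n_max)
    base = _mss_pmf(m, N)
    ns = np.arange(N + 1)
    out = np.zeros(n_max + 1)
    chunk = 512
    for start in range(0, n_max + 1, chunk):
        ks = np.arange(start, min(start + chunk, n_max + 1))
        kernel = binom.pmf(ks[:, None], ns[None, :], z)
        out[ks] = kernel @ base
    return out


def ld_pmf(m: float, n_max: int, plating_fraction: float = 1.0) -> np.ndarray:
    """Probability of observing 0..n_max mutant colonies in one culture.

    Parameters
    ----------
    m
        Expected mutation events per culture (Lea–Coulson parameter).
    n_max
        Largest colony count to evaluate; the returned vector has
        length ``n_max + 1``.
    plating_fraction
        Fraction of the culture plated; counts are binomially thinned.

    With ``plating_fraction == 1``, entry 0 is exactly ``exp(-m)``.
    Entries are non-negative and partial sums are <= 1 (the tail mass
    beyond ``n_max`` is not included).
    """
    if not (m >= 0) or not math.isfinite(m):
        raise ValueError(f"m must be a finite non-negative real, got {m!r}")
    n_max = int(n_max)
    if n_max < 0:
        raise ValueError("n_max must be >= 0")
    z = float(plating_fraction)
    if not (0.0 < z <= 1.0):
        raise ValueError("plating_fraction must be in (0, 1]")
    if m == 0.0:
        p = np.zeros(n_max + 1)
        p[0] = 1.0
        return p
    if z == 1.0:
        return _mss_pmf(m, n_max)
    if z <= 0.5:
        return _thinned_pmf_series(m, n_max, z)
    return _thinned_pmf_conv(m, n_max, z)


# ---------------------------------------------------------------------------
# likelihood and estimation
# ---------------------------------------------------------------------------

def log_likelihood(cultures: CultureSet, m: float) -> float:
    """Log-likelihood of ``m`` for the observed per-culture counts.

    The pmf is evaluated up to the largest observed count (never
    truncated below it).  Returns ``-inf`` for ``m == 0`` with any
    non-zero count (an impossible outcome).
    """
    if not (m >= 0):
        raise ValueError("m must be non-negative")
    counts = np.asarray(cultures.counts, dtype=int)
    if m == 0.0:
        return 0.0 if counts.max() == 0 else -math.inf
    p = ld_pmf(m, int(counts.max()), cultures.plating_fraction)
    with np.errstate(divide="ignore"):
        terms = np.log(np.clip(p[counts], 1e-320, None))
    return float(terms.sum())


def mle_m(cultures: CultureSet, level: float = 0.95) -> RateEstimate:
    """Maximum-likelihood estimate of ``m`` (and the rate m/Nt).

    All-zero counts give the boundary maximum ``m_hat = 0`` exactly.
    Raises :class:`ConvergenceError` if the optimizer fails or the
    maximum sits on the search cap after repeated expansion.
    """
    counts = np.asarray(cultures.counts, dtype=int)
    z = cultures.plating_fraction
    if counts.max() == 0:
        return RateEstimate.from_m(0.0, cultures.n_total, level=level, label=cultures.label)

    zero_frac = float((counts == 0).mean())
    if zero_frac > 0.0:
        m0 = -math.log(zero_frac)
    else:
        m0 = max(float(counts.mean()), 1.0)
    hi = max(50.0, 20.0 * counts.mean() / z, 4.0 * m0)
    lo = 1e-6

    def neg_ll(t):
        return -log_likelihood(cultures, math.exp(t))

    for _ in range(6):
        res = optimize.minimize_scalar(
            neg_ll,
            bounds=(math.log(lo), math.log(hi)),
            method="bounded",
            options={"xatol": 1e-10, "maxiter": 500},
        )
        if not res.success:
            raise ConvergenceError(
                f"MLE failed for {cultures.label!r}: {res.message} "
                f"(bounds [{lo:g}, {hi:g}], start {m0:g})"
            )
        m_hat = math.exp(res.x)
        if m_hat < 0.99 * hi:
            break
        hi *= 16.0
        logger.debug("MLE at upper bound; expanding cap to %g", hi)
    else:
        raise ConvergenceError(
            f"MLE did not converge below search cap {hi:g} for {cultures.label!r}"
        )
    logger.debug("MLE for %r: m_hat=%g (start %g, %d fn evals)",
                 cultures.label, m_hat, m0, res.nfev)
    return RateEstimate.from_m(m_hat, cultures.n_total, level=level, label=cultures.label)


def lr_interval(cultures: CultureSet, level: float = 0.95,
                m_hat: Optional[float] = None) -> tuple:
    """Likelihood-ratio confidence interval for ``m``.

    Each bound solves 2*[l(m_hat) - l(m)] = chi2_1(level) (3.841 at
    0.95) by bracketed root finding.  The lower bound is reported as 0
    when even m -> 0 stays inside the acceptance region (boundary
    case, e.g. all-zero counts).
    """
    if not (0.0 < level < 1.0):
        raise ValueError("level must be in (0, 1)")
    if m_hat is None:
        m_hat = mle_m(cultures, level=level).m_hat
    ll_hat = log_likelihood(cultures, m_hat)
    halfcrit = chi2.ppf(level, df=1) / 2.0

    def g(m):
        # positive outside the confidence region
        return (ll_hat - log_likelihood(cultures, m)) - halfcrit

    # lower bound
    tiny = 1e-10
    if m_hat <= tiny or g(tiny) < 0.0:
        lo = 0.0
    else:
        lo = optimize.brentq(g, tiny, m_hat, xtol=1e-12, rtol=1e-10)

    # upper bound: expand a bracket geometrically
    a = max(m_hat, tiny)
    b = max(2.0 * m_hat, 0.05)
    cap = max(1e7, 1e4 * max(m_hat, 1.0))
    while g(b) < 0.0:
        a = b
        b *= 2.0
        if b > cap:
            raise ConvergenceError(
                f"upper confidence bound exceeds search cap {cap:g}")
    hi = optimize.brentq(g, a, b, xtol=1e-12, rtol=1e-10)
    return (lo, hi)


def estimate_rate(cultures: CultureSet, level: float = 0.95) -> RateEstimate:
    """Convenience wrapper: MLE plus likelihood-ratio interval."""
    est = mle_m(cultures, level=level)
    ci = lr_interval(cultures, level=level, m_hat=est.m_hat)
    return RateEstimate.from_m(est.m_hat, cultures.n_total, ci_m=ci,
                               level=level, label=cultures.label)


# ---------------------------------------------------------------------------
# pooling
# ---------------------------------------------------------------------------

def pool_experiments(sets: Sequence[CultureSet], max_ratio: float = 2.0):
    """Merge replicate experiments whose Nt values agree within 2-fold.

    Sets are ordered by Nt and grouped greedily: a set joins the
    current group while its Nt is < ``max_ratio`` times the smallest Nt
    in the group and its plating fraction matches.  (On a sorted
    sequence this greedy rule yields the minimal number of mutually
    compatible groups.)  A merged set concatenates the member counts
    and carries the mean member Nt, so a single pooled rate
    m_pooled / mean(Nt) is reported.  When more than one group remains,
    every returned set is flagged for independent estimation.
    """
    sets = list(sets)
    if not sets:
        raise ValueError("need at least one CultureSet")
    order = sorted(sets, key=lambda s: (s.plating_fraction, s.n_total))
    groups = [[order[0]]]
    for s in order[1:]:
        g = groups[-1]
        if (s.plating_fraction == g[0].plating_fraction
                and s.n_total / g[0].n_total < max_ratio):
            g.append(s)
        else:
            groups.append([s])
    out = []
    flag = len(groups) > 1
    for g in groups:
        if len(g) == 1:
            merged = g[0]
        else:
            merged = CultureSet(
                counts=sum((list(s.counts) for s in g), []),
                n_total=float(np.mean([s.n_total for s in g])),
                plating_fraction=g[0].plating_fraction,
                label="+".join(s.label for s in g if s.label) or g[0].label,
            )
        out.append(replace(merged, flagged=flag))
    return out
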