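"""Independent oracles used by the test suite.

Each oracle evaluates the same quantity as the implementation by a
different route (FFT inversion of the generating function, dense grid
search, exhaustive enumeration, direct Monte-Carlo of the mechanistic
process), so agreement is evidence of correctness rather than
repetition.
"""

from __future__ import annotations

import numpy as np

from errorthreshold.fluctuation import CultureSet, log_likelihood


def lc_pmf_fft(m: float, n_max: int, radius: float = 0.999,
               n_points: int = 1 << 14) -> np.ndarray:
    """Lea–Coulson pmf by numeric inversion of the pgf
    G(s) = exp(m (1-s)/s ln(1-s)) on a circle of the given radius."""
    theta = 2j * np.pi * np.arange(n_points) / n_points
    s = radius * np.exp(theta)
    G = np.exp(m * (1 - s) / s * np.log(1 - s))
    p = np.real(np.fft.fft(G)) / n_points / radius ** np.arange(n_points)
    return p[: n_max + 1]


def mc_mutant_counts(m: float, reps: int, rng: np.random.Generator,
                     plating_fraction: float = 1.0) -> np.ndarray:
    """Mechanistic simulation of the mutation–growth process: Poisson(m)
    clones per culture, clone size floor(1/U) (uniform time of origin on
    the exponential growth curve), binomial plating."""
    n_events = rng.poisson(m, reps)
    totals = np.zeros(reps, dtype=np.int64)
    for i in np.nonzero(n_events)[0]:
        u = rng.random(n_events[i])
        totals[i] = int(np.floor(1.0 / u).sum())
    if plating_fraction < 1.0:
        totals = rng.binomial(totals, plating_fraction)
    return totals


def grid_mle(cultures: CultureSet, lo: float = 1e-4, hi: float = 50.0,
             coarse: int = 3000, fine: int = 2000) -> float:
    """Dense grid search of the likelihood with one local refinement;
    relative resolution ~ a few 1e-6."""
    grid = np.geomspace(lo, hi, coarse)
    lls = np.array([log_likelihood(cultures, m) for m in grid])
    i = int(np.argmax(lls))
    a = grid[max(i - 1, 0)]
    b = grid[min(i + 1, coarse - 1)]
    fine_grid = np.linspace(a, b, fine)
    fls = np.array([log_likelihood(cultures, m) for m in fine_grid])
    return float(fine_grid[int(np.argmax(fls))])


def grid_lr_interval(cultures: CultureSet, m_hat: float, halfcrit: float,
                     n_points: int = 4000):
    """Likelihood-ratio interval endpoints located by scanning the
    profile log-likelihood and interpolating the crossings."""
    ll_hat = log_likelihood(cultures, m_hat)

    def crossing(ms):
        vals = np.array([2.0 * (ll_hat - log_likelihood(cultures, m)) for m in ms])
        target = 2.0 * halfcrit
        sign = vals - target
        idx = np.nonzero(np.diff(np.sign(sign)))[0]
        roots = []
        for i in idx:
            x0, x1 = ms[i], ms[i + 1]
            y0, y1 = sign[i], sign[i + 1]
            roots.append(x0 - y0 * (x1 - x0) / (y1 - y0))
        return roots

    lo_scan = np.geomspace(max(m_hat * 1e-3, 1e-8), m_hat, n_points)
    hi_scan = np.geomspace(m_hat, m_hat * 50, n_points)
    lo_roots = crossing(lo_scan)
    hi_roots = crossing(hi_scan)
    lo = lo_roots[-1] if lo_roots else 0.0
    hi = hi_roots[0]
    return lo, hi


def brute_min_groups(n_totals, max_ratio: float = 2.0):
    """Minimal number of mutually-compatible (max/min < ratio) groups of
    a sorted Nt sequence, by dynamic programming over contiguous runs."""
    nts = sorted(n_totals)
    n = len(nts)
    best = [0] + [n + 1] * n
    for i in range(1, n + 1):
        for j in range(i):
            if nts[i - 1] / nts[j] < max_ratio:
                best[i] = min(best[i], best[j] + 1)
    return best[n]


def all_single_indel_placements(long_seq: str, short_seq: str):
    """Every 1-based start position p such that deleting
    len(long)-len(short) bases of long at p yields short."""
    d = len(long_seq) - len(short_seq)
    assert d > 0
    out = []
    for p in range(1, len(short_seq) + 2):
        if long_seq[: p - 1] + long_seq[p - 1 + d:] == short_seq:
            out.append(p)
    return out
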