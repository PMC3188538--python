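"""Branching-process model of replication error-induced extinction.

A haploid genome of G genes, a fraction f of them essential, acquires
inactivating mutations at a per-gene, per-division rate mu.  Each cell
division produces two daughters, each independently carrying a
Poisson(f*G*mu) number of essential-gene hits; a daughter with one or
more hits arrests — it persists as a cell in the colony but never
divides again.  Colony formation is therefore a Galton–Watson process
whose offspring distribution is Binomial(2, s) with per-daughter
survival s = exp(-f*G*mu): colonies grow while the dividing lineage
survives, and fail when the mean offspring number 2s drops to 1, i.e.
at the critical per-gene rate mu* = ln 2 / (f G).

With the budding-yeast defaults (G = 6000, f = 1/6) a rate of 1e-3
inactivating mutations per gene per division corresponds to ~6 gene
inactivations per genome per division, one of them essential on
average, and mu* = ln 2 / 1000 ≈ 6.9e-4 — the same order as the
observed ~1e-3 viability threshold.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Optional, Tuple, Union

import numpy as np

__all__ = [
    "GenomeModel",
    "ColonyOutcome",
    "expected_inactivations",
    "simulate_colony",
    "survival_probability",
    "gw_survival_analytic",
    "critical_rate",
]


@dataclass(frozen=True)
class GenomeModel:
    """Genome-scale parameters of the extinction model.

    ``per_gene_rate`` is mu, inactivating mutations per gene per cell
    division.  ``visibility_threshold`` is the total cell count (live
    plus arrested) constituting a visible colony.  ``max_divisions``
    is the simulation horizon in generations; a visible 1e5-cell
    colony needs only ~17 doublings, so the default of 150 is a
    generous stand-in for the finite growth period of a plate assay.
    """

    n_genes: int = 6000
    essential_fraction: float = 1.0 / 6.0
    per_gene_rate: float = 0.0
    visibility_threshold: int = 100_000
    max_divisions: int = 150

    def __post_init__(self):
        if self.n_genes <= 0 or self.visibility_threshold <= 0 or self.max_divisions <= 0:
            raise ValueError("n_genes, visibility_threshold, max_divisions must be positive")
        if not (0.0 < self.essential_fraction <= 1.0):
            raise ValueError("essential_fraction must be in (0, 1]")
        if self.per_gene_rate < 0:
            raise ValueError("per_gene_rate must be non-negative")
        if self.essential_fraction * self.n_genes < 1:
            raise ValueError("model needs at least one essential gene (f*G >= 1)")

    @property
    def lethal_hit_rate(self) -> float:
        """Poisson rate of essential-gene hits per daughter, f*G*mu."""
        return self.essential_fraction * self.n_genes * self.per_gene_rate


@dataclass(frozen=True)
class ColonyOutcome:
    reached_visibility: bool
    final_cells: int
    divisions_elapsed: int
    lethal_hits_total: int


def expected_inactivations(model: GenomeModel) -> Tuple[float, float]:
    """(all-gene, essential-gene) expected inactivations per cell per division.

    G*mu genes in total, f*G*mu of them essential.
    """
    total = model.n_genes * model.per_gene_rate
    return total, model.essential_fraction * total


def _ztp_table(lam: float, tail: float = 1e-12):
    """Support and probabilities of the zero-truncated Poisson(lam)."""
    if lam <= 0:
        return np.array([1]), np.array([1.0])
    probs = []
    k, term = 1, lam * math.exp(-lam)
    norm = 1.0 - math.exp(-lam)
    while term / norm > tail or k <= lam + 1:
        probs.append(term)
        k += 1
        term *= lam / k
        if k > 500:
            break
    p = np.array(probs) / norm
    p = p / p.sum()
    return np.arange(1, len(probs) + 1), p


def simulate_colony(model: GenomeModel,
                    seed: Union[int, np.random.Generator, None] = None) -> ColonyOutcome:
    """Grow one colony from a single founder cell.

    Each generation every dividing cell yields two daughters; each
    daughter survives (stays able to divide) with probability
    s = exp(-f*G*mu), else it arrests with >= 1 essential hit (the hit
    count drawn from the zero-truncated Poisson).  All cells, arrested
    included, count toward colony visibility; growth stops when no
    dividing lineage remains, when the visibility threshold is
    reached, or at the generation horizon.  Trajectories are
    bit-reproducible for a given integer seed.
    """
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    lam = model.lethal_hit_rate
    s = math.exp(-lam)
    support, probs = _ztp_table(lam)
    dividing, arrested, hits, gens = 1, 0, 0, 0
    while (dividing > 0 and dividing + arrested < model.visibility_threshold
           and gens < model.max_divisions):
        daughters = 2 * dividing
        survivors = int(rng.binomial(daughters, s)) if lam > 0 else daughters
        newly_arrested = daughters - survivors
        if newly_arrested:
            hits += int(rng.choice(support, size=newly_arrested, p=probs).sum())
        dividing = survivors
        arrested += newly_arrested
        gens += 1
    total = dividing + arrested
    return ColonyOutcome(
        reached_visibility=total >= model.visibility_threshold,
        final_cells=total,
        divisions_elapsed=gens,
        lethal_hits_total=hits,
    )


def survival_probability(model: GenomeModel, reps: int,
                         seed: Union[int, np.random.Generator, None] = None) -> float:
    """Monte-Carlo probability that a founder cell yields a visible colony."""
    if reps < 1:
        raise ValueError("reps must be >= 1")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    hits = sum(simulate_colony(model, rng).reached_visibility for _ in range(reps))
    return hits / reps


def gw_survival_analytic(model: GenomeModel) -> float:
    """Closed-form Galton–Watson survival probability.

    With per-daughter survival s = exp(-f*G*mu), the extinction
    probability q is the smallest root in [0, 1] of
    q = (1 - s + s q)^2; the survival probability is 1 - q.
    """
    s = math.exp(-model.lethal_hit_rate)
    if s <= 0.5:
        return 0.0  # mean offspring 2s <= 1: extinction almost sure
    a = 1.0 - s
    # s^2 q^2 + (2 a s - 1) q + a^2 = 0
    A, Bc, Cc = s * s, 2.0 * a * s - 1.0, a * a
    disc = Bc * Bc - 4.0 * A * Cc
    if disc <= 0.0:
        return 0.0  # critical or subcritical: extinction almost sure
    q = (-Bc - math.sqrt(disc)) / (2.0 * A)
    q = min(max(q, 0.0), 1.0)
    return 1.0 - q


def critical_rate(model: GenomeModel, reps: int = 400,
                  seed: Optional[int] = None,
                  survival_cutoff: float = 0.01,
                  bracket: Tuple[float, float] = (1e-5, 1e-2),
                  iterations: int = 18) -> float:
    """Per-gene rate at which colony-forming probability crosses the cutoff.

    Bisection on mu using :func:`simulate_colony` with common random
    numbers per evaluation.  The estimate tracks the analytic
    criterion mu* = ln 2 / (f G) up to Monte-Carlo and finite-horizon
    error.  Returns ``inf`` when survival still exceeds the cutoff at
    the upper bracket (no lethal targets, e.g. f -> 0 is approached);
    raises if survival is already below the cutoff at the lower
    bracket.
    """
    if reps < 100:
        raise ValueError("reps must be >= 100 for a stable crossing estimate")
    lo, hi = bracket
    if not (0 <= lo < hi):
        raise ValueError("bracket must satisfy 0 <= lo < hi")
    ss = np.random.SeedSequence(seed)
    eval_seed = ss.spawn(1)[0]

    def surv(mu):
        m = GenomeModel(
            n_genes=model.n_genes,
            essential_fraction=model.essential_fraction,
            per_gene_rate=mu,
            visibility_threshold=model.visibility_threshold,
            max_divisions=model.max_divisions,
        )
        return survival_probability(m, reps, np.random.default_rng(eval_seed))

    if surv(lo) <= survival_cutoff:
        raise ValueError(
            f"survival at lower bracket mu={lo:g} already below cutoff "
            f"{survival_cutoff:g}; bounds do not bracket the crossing")
    if surv(hi) > survival_cutoff:
        return math.inf  # crossing above the search cap
    for _ in range(iterations):
        mid = math.sqrt(lo * hi) if lo > 0 else hi / 2.0
        if surv(mid) > survival_cutoff:
            lo = mid
        else:
            hi = mid
    return math.sqrt(lo * hi)
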