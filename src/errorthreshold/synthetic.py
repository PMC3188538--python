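"""Synthetic inputs with the statistical structure the analysis assumes.

Two generators stand in for the wet-lab data:

* :func:`simulate_cultures` emulates a fluctuation assay.  Mutations
  arise during deterministic exponential growth from ``n0`` to
  ``n_final`` cells at rate mu per division, so the number of events
  per culture is Poisson(m) with m = mu*(n_final - n0).  A mutation
  arising when the population has n cells founds a clone of final size
  n_final/n; with a uniformly distributed cell of origin this gives
  the clone-size law P(K >= k) = 1/k, i.e. exactly the Lea–Coulson
  compound-Poisson that the estimator assumes (a discrete-generation
  power-of-two clone model would not match the pmf).  Plating a
  fraction z thins the counts binomially.

* :func:`simulate_spectrum` emits mutant copies of a reporter CDS,
  each carrying one sampled event (chain-terminating, missense, indel
  or complex) at a site compatible with the requested effect, plus a
  truth table that the diff/classify/tally pipeline must recover
  exactly.

A synthetic 1773-bp open reading frame (ATG start, no internal in-frame
stops) is bundled as ``data/synthetic_orf.fasta`` and stands in for the
CAN1 coding sequence; nothing requires the real CAN1 sequence.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from importlib import resources
from typing import Optional, Sequence, Tuple, Union

import numpy as np
import pandas as pd

from .fluctuation import CultureSet
from .spectra import (
    CHAIN_TERMINATING,
    COMPLEX,
    DELETION,
    INSERTION,
    MISSENSE,
    SUBSTITUTION,
    _BASES,
    classify_substitution,
)

__all__ = [
    "FluctuationDesign",
    "simulate_cultures",
    "sample_mutant_counts",
    "simulate_spectrum",
    "load_reference_orf",
    "can1_design",
    "ura3_design",
    "ci_coverage_study",
]

JACKPOT_GUARD = 1e3  # refuse mu * n_final beyond this: every culture saturates


@dataclass(frozen=True)
class FluctuationDesign:
    """Study design of one synthetic fluctuation experiment.

    ``n0`` founder cells grow to ``n_final`` (which also serves as Nt,
    divisions ≈ final cells); ``mutation_rate`` is the per-division
    rate mu, so the Lea–Coulson parameter is m = mu*(n_final - n0).
    """

    n_cultures: int
    mutation_rate: float
    n0: int = 1
    n_final: float = 1e7
    plating_fraction: float = 1.0
    seed: Optional[int] = None
    label: str = "synthetic"

    def __post_init__(self):
        if self.n_cultures < 1:
            raise ValueError("need at least one culture")
        if not (self.n_final > self.n0 >= 1):
            raise ValueError("require n_final > n0 >= 1")
        if self.mutation_rate < 0:
            raise ValueError("mutation_rate must be non-negative")
        if not (0.0 < self.plating_fraction <= 1.0):
            raise ValueError("plating_fraction must be in (0, 1]")

    @property
    def m(self) -> float:
        """Expected mutation events per culture."""
        return self.mutation_rate * (self.n_final - self.n0)


def can1_design(mutation_rate: float, seed: Optional[int] = None,
                plating_fraction: float = 1.0) -> FluctuationDesign:
    """Canavanine-resistance-style design: 7–11 excised colonies per
    genotype (9 used here), grown from single cells, dilutions down to
    1:200 supported through ``plating_fraction``."""
    return FluctuationDesign(n_cultures=9, mutation_rate=mutation_rate,
                             n0=1, n_final=1e7,
                             plating_fraction=plating_fraction,
                             seed=seed, label="CAN1-style")


def ura3_design(mutation_rate: float, seed: Optional[int] = None) -> FluctuationDesign:
    """FOA-resistance-style microculture design: 12 parallel 100-cell
    cultures of which 9 are plated."""
    return FluctuationDesign(n_cultures=9, mutation_rate=mutation_rate,
                             n0=100, n_final=1e7, seed=seed,
                             label="URA3-style")


def sample_mutant_counts(m: float, n_cultures: int, rng: np.random.Generator,
                         plating_fraction: float = 1.0,
                         clone_cap: float = 1e7) -> np.ndarray:
    """Mutant counts for ``n_cultures`` cultures at Lea–Coulson parameter m.

    Compound Poisson: Poisson(m) clones per culture, clone sizes
    floor(1/U) capped at ``clone_cap`` (a clone cannot outgrow the
    culture), binomially thinned at the plating fraction.
    """
    counts = np.zeros(n_cultures, dtype=np.int64)
    n_events = rng.poisson(m, size=n_cultures)
    for i, k in enumerate(n_events):
        if k == 0:
            continue
        u = rng.random(k)
        sizes = np.minimum(np.floor(1.0 / u), clone_cap)
        counts[i] = int(sizes.sum())
    if plating_fraction < 1.0:
        counts = rng.binomial(counts, plating_fraction)
    return counts


def simulate_cultures(design: FluctuationDesign,
                      rng: Union[np.random.Generator, None] = None) -> CultureSet:
    """Simulate one fluctuation experiment under ``design``.

    Refuses designs where mu*n_final exceeds the jackpot guard (every
    culture would saturate with mutants and the count distribution
    becomes uninformative).
    """
    if design.mutation_rate * design.n_final > JACKPOT_GUARD:
        raise ValueError(
            f"mu*n_final = {design.mutation_rate * design.n_final:g} exceeds "
            f"the jackpot guard {JACKPOT_GUARD:g}")
    if rng is None:
        rng = np.random.default_rng(design.seed)
    counts = sample_mutant_counts(
        design.m, design.n_cultures, rng,
        plating_fraction=design.plating_fraction,
        clone_cap=design.n_final / max(design.n0, 1),
    )
    return CultureSet(
        counts=tuple(int(c) for c in counts),
        n_total=design.n_final,
        plating_fraction=design.plating_fraction,
        label=design.label,
    )


def ci_coverage_study(m_true: float, n_cultures: int, n_datasets: int,
                      seed: Optional[int] = None, level: float = 0.95,
                      n_final: float = 1e4) -> dict:
    """Parameter-recovery study: MLE and CI coverage over synthetic data.

    Simulates ``n_datasets`` fluctuation experiments at the true
    Lea–Coulson parameter ``m_true``, estimates each by maximum
    likelihood with a likelihood-ratio interval, and reports the
    empirical coverage of the true value plus all point estimates.
    ``n_final`` bounds individual jackpot clones (the culture size).
    """
    from .fluctuation import lr_interval, mle_m

    rng = np.random.default_rng(seed)
    covered = 0
    m_hats = np.empty(n_datasets)
    for i in range(n_datasets):
        counts = sample_mutant_counts(m_true, n_cultures, rng, clone_cap=n_final)
        cs = CultureSet(counts=tuple(int(c) for c in counts), n_total=n_final)
        est = mle_m(cs, level=level)
        lo, hi = lr_interval(cs, level=level, m_hat=est.m_hat)
        covered += lo <= m_true <= hi
        m_hats[i] = est.m_hat
    return {"coverage": covered / n_datasets, "m_hats": m_hats,
            "level": level, "m_true": m_true}


# ---------------------------------------------------------------------------
# spectrum generator
# ---------------------------------------------------------------------------

def load_reference_orf() -> str:
    """The bundled synthetic 1773-bp reporter open reading frame."""
    text = resources.files("errorthreshold").joinpath(
        "data/synthetic_orf.fasta").read_text()
    return "".join(line.strip() for line in text.splitlines()
                   if not line.startswith(">"))

_ALT = {b: [x for x in "ACGT" if x != b] for b in "ACGT"}


def _effect_sites(cds: str, wanted: str):
    """All (position, alt) substitutions with the requested effect."""
    sites = []
    for pos in range(1, len(cds) + 1):
        for alt in _ALT[cds[pos - 1]]:
            if classify_substitution(cds, pos, alt) == wanted:
                sites.append((pos, alt))
    return sites


def simulate_spectrum(n_clones: int, proportions: Sequence[float], cds: str,
                      seed: Optional[int] = None) -> Tuple[list, pd.DataFrame]:
    """Mutant sequences with one sampled event each, plus a truth table.

    ``proportions`` gives the (chain_terminating, missense, indel,
    complex) simplex.  Sites are uniform over the positions compatible
    with the requested effect.  Returns ``(mutants, truth)`` where
    ``mutants`` is a list of (clone_id, sequence) pairs and ``truth``
    a DataFrame with columns clone_id, kind, effect, position.
    Running :func:`errorthreshold.spectra.diff_sequences` and
    :func:`errorthreshold.spectra.tally_spectrum` over the mutants
    reproduces the truth tallies exactly.
    """
    props = np.asarray(proportions, dtype=float)
    if props.shape != (4,) or (props < 0).any() or not math.isclose(props.sum(), 1.0,
                                                                    abs_tol=1e-9):
        raise ValueError("proportions must be a length-4 simplex "
                         "(chain_terminating, missense, indel, complex)")
    if n_clones < 0:
        raise ValueError("n_clones must be non-negative")
    cds = str(cds).upper()
    if set(cds) - _BASES or len(cds) % 3:
        raise ValueError("cds must be coding-length over A/C/G/T")
    rng = np.random.default_rng(seed)

    mutants, rows = [], []
    if n_clones == 0:
        return mutants, pd.DataFrame(columns=["clone_id", "kind", "effect", "position"])

    kinds = rng.choice(4, size=n_clones, p=props)
    site_cache = {}
    for idx, code in enumerate(kinds):
        clone = f"clone{idx + 1:04d}"
        if code in (0, 1):
            wanted = CHAIN_TERMINATING if code == 0 else MISSENSE
            if wanted not in site_cache:
                sites = _effect_sites(cds, wanted)
                if not sites:
                    raise ValueError(
                        f"no site in the CDS can produce a {wanted} substitution")
                site_cache[wanted] = sites
            pos, alt = site_cache[wanted][rng.integers(len(site_cache[wanted]))]
            seq = cds[:pos - 1] + alt + cds[pos:]
            rows.append((clone, SUBSTITUTION, wanted, pos))
        elif code == 2:
            # single-base insertion or deletion, recorded at its
            # left-aligned placement so the diff recovers it verbatim
            if rng.random() < 0.5:
                pos = int(rng.integers(1, len(cds) + 1))
                seq = cds[:pos - 1] + cds[pos:]
                while pos > 1 and cds[pos - 2] == cds[pos - 1]:
                    pos -= 1
                rows.append((clone, DELETION, "", pos))
            else:
                pos = int(rng.integers(1, len(cds) + 1))
                base = "ACGT"[rng.integers(4)]
                seq = cds[:pos - 1] + base + cds[pos - 1:]
                while pos > 1 and cds[pos - 2] == base:
                    pos -= 1
                rows.append((clone, INSERTION, "", pos))
        else:
            # complex event: a 2-bp deletion plus a nearby substitution,
            # resampled in the rare case end-anchoring can explain it
            # as one clean indel
            from .spectra import diff_sequences
            for _ in range(50):
                pos = int(rng.integers(1, len(cds) - 8))
                sub_pos = pos + 4
                alt = _ALT[cds[sub_pos - 1]][rng.integers(3)]
                seq = (cds[:pos - 1] + cds[pos + 1:sub_pos - 1]
                       + alt + cds[sub_pos:])
                recs = diff_sequences(cds, seq)
                if len(recs) == 1 and recs[0].kind == COMPLEX:
                    pos = recs[0].position
                    break
            else:  # pragma: no cover - 50 failures would mean a broken CDS
                raise RuntimeError("could not place a complex event")
            rows.append((clone, COMPLEX, "", pos))
        mutants.append((clone, seq))

    truth = pd.DataFrame(rows, columns=["clone_id", "kind", "effect", "position"])
    return mutants, truth
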