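"""Per-base-pair rate conversion and repair-pathway arithmetic.

A phenotypic mutation rate mu_T (mutants per cell division at a
reporter locus) undercounts the true per-base-pair rate because most
base substitutions do not inactivate the reporter.  Drake's correction
anchors detectability on chain-terminating (nonsense) substitutions,
which are assumed fully detectable: among random substitutions, 3 of 64
codon outcomes are stops, so the excess of observed stops over 3/64
measures the fraction of substitutions that go unseen.

    C   = (64/3) * B_CT / B                 substitution-only correction
    C'' = [ (64/3) * B_CT + I ] / M         substitutions + indels
    tau = T / C''                           effective target size (bp)
    mu_b = mu_T * C'' / T = mu_T / tau      per-base-pair rate

where B_CT / B count chain-terminating / all detectable substitutions,
I counts indels (incl. complex events) and M = B + I events from the
sequenced mutants, and T is the reporter length in bp.  These formulas
are validated against the printed reference outputs in the test suite.

Repair-pathway efficiencies compare isogenic strains differing in one
pathway: a fold rate increase F upon losing the pathway means it
corrected a fraction 1 - 1/F of errors, i.e. efficiency = 100*(1-1/F) %.
Pathways acting in series multiply their fold effects.
"""

from __future__ import annotations

import json
import math
import warnings
from dataclasses import dataclass
from importlib import resources
from typing import Optional, Sequence

import pandas as pd

from .spectra import SpectrumCounts

__all__ = [
    "TargetLocus",
    "CorrectionFactors",
    "RepairEfficiency",
    "GrowthBands",
    "UndefinedCorrectionError",
    "correction_factors",
    "per_bp_rate",
    "allele_target_size",
    "fold_effect",
    "repair_efficiency",
    "combined_fidelity",
    "predict_double_mutant_rate",
    "classify_growth",
    "robustness_table",
    "load_locus_presets",
    "load_reference_rates",
]

CODONS = 64
STOP_CODONS = 3


class UndefinedCorrectionError(ValueError):
    """No chain-terminating substitutions: the Drake anchor is undefined."""


@dataclass(frozen=True)
class TargetLocus:
    """A mutation-reporter locus of length ``T`` base pairs.

    ``intrinsic_adjust`` is a cross-locus rate multiplier applied when
    comparing loci of different intrinsic mutability (e.g. 1.8 to put
    URA3 rates on the CAN1 scale); default 1.
    """

    name: str
    T: int
    intrinsic_adjust: float = 1.0

    def __post_init__(self):
        if self.T <= 0:
            raise ValueError("target length T must be positive")
        if self.intrinsic_adjust <= 0:
            raise ValueError("intrinsic_adjust must be positive")


@dataclass(frozen=True)
class CorrectionFactors:
    """Drake correction factors and the effective target size.

    ``C`` corrects substitutions only, ``C2`` (C'') substitutions plus
    indels; ``tau = T / C2`` is the bp count at which every mutation
    would be detected.
    """

    C: float
    C2: float
    tau: float

    @classmethod
    def from_target_size(cls, tau: float) -> "CorrectionFactors":
        """Factors for a locus characterised only by its target size
        (e.g. the mouse ouabain-resistance codons), where mu_b = mu_T / tau."""
        if tau <= 0:
            raise ValueError("tau must be positive")
        return cls(C=math.nan, C2=math.nan, tau=float(tau))


@dataclass(frozen=True)
class RepairEfficiency:
    """Fold rate increase on pathway loss and % of errors corrected."""

    fold: float
    efficiency_pct: float


@dataclass(frozen=True)
class GrowthBands:
    """Colony-growth grade boundaries (phenotypic rate, per division).

    Wild-type growth (+++) up to ``full``; slowed growth (++) up to
    ``severe``; severe deficit (+) up to ``lethal``; no visible
    colonies (-) beyond.
    """

    full: float = 5e-5
    severe: float = 1e-3
    lethal: float = 2e-3


def correction_factors(counts: SpectrumCounts, locus: TargetLocus) -> CorrectionFactors:
    """Drake correction factors for a spectrum observed at ``locus``.

    Requires at least one chain-terminating substitution (the
    detectability anchor) and a non-empty spectrum.
    """
    if counts.M <= 0:
        raise UndefinedCorrectionError("empty spectrum: M must be positive")
    if counts.B_CT <= 0:
        raise UndefinedCorrectionError(
            "no chain-terminating substitutions; correction undefined")
    ratio = CODONS / STOP_CODONS
    C = ratio * counts.B_CT / counts.B
    C2 = (ratio * counts.B_CT + counts.I) / counts.M
    return CorrectionFactors(C=C, C2=C2, tau=locus.T / C2)


def per_bp_rate(mu_T: float, factors: CorrectionFactors,
                locus: Optional[TargetLocus] = None) -> float:
    """Per-base-pair rate mu_b = mu_T / tau (= mu_T * C'' / T).

    When ``locus`` is given, its ``intrinsic_adjust`` multiplier is
    applied (cross-locus comparison); otherwise the unadjusted rate is
    returned.
    """
    if mu_T < 0:
        raise ValueError("mu_T must be non-negative")
    rate = mu_T / factors.tau
    if locus is not None:
        rate *= locus.intrinsic_adjust
    return rate


def allele_target_size(bp_per_allele: float, n_alleles: int) -> float:
    """Effective target size of a dominant-resistance, multi-allele locus."""
    if bp_per_allele <= 0 or n_alleles <= 0:
        raise ValueError("bp_per_allele and n_alleles must be positive")
    return bp_per_allele * n_alleles


def fold_effect(rate_deficient: float, rate_proficient: float) -> float:
    """Rate ratio deficient/proficient for isogenic strains."""
    if rate_proficient <= 0:
        raise ValueError("proficient rate must be positive")
    if rate_deficient < 0:
        raise ValueError("deficient rate must be non-negative")
    return rate_deficient / rate_proficient


def repair_efficiency(fold: float) -> RepairEfficiency:
    """Percentage of errors corrected by a pathway with rate-fold ``F``.

    efficiency = 100 * (1 - 1/F).  A fold below 1 (an antimutator
    input) yields a negative efficiency and a warning rather than an
    error, so exploratory comparisons still report a number.
    """
    if fold <= 0:
        raise ValueError("fold must be positive")
    if fold < 1:
        warnings.warn(
            f"fold {fold:g} < 1 (antimutator input); reporting negative efficiency",
            stacklevel=2,
        )
    return RepairEfficiency(fold=fold, efficiency_pct=100.0 * (1.0 - 1.0 / fold))


def combined_fidelity(fold_mmr: float, fold_exo: float) -> float:
    """Combined fold contribution of two pathways acting in series."""
    if fold_mmr < 1 or fold_exo < 1:
        raise ValueError("series combination expects folds >= 1")
    return fold_mmr * fold_exo


def predict_double_mutant_rate(rate_single: float, avg_fold: float) -> float:
    """Predicted rate of an unmeasurable double mutant.

    The single-pathway-deficient rate times the average fold effect of
    losing the second pathway (e.g. MMR-proficient mutator rate x 157).
    """
    if rate_single <= 0 or avg_fold <= 0:
        raise ValueError("rate and fold must be positive")
    return rate_single * avg_fold


def classify_growth(rate: float, bands: GrowthBands = GrowthBands()) -> str:
    """Semi-quantitative colony-growth grade for a phenotypic rate.

    '+++' (wild-type) for rate <= bands.full, '++' below bands.severe,
    '+' below bands.lethal, '-' (no visible colonies) otherwise.
    """
    if rate < 0:
        raise ValueError("rate must be non-negative")
    if rate <= bands.full:
        return "+++"
    if rate < bands.severe:
        return "++"
    if rate < bands.lethal:
        return "+"
    return "-"


def load_locus_presets() -> dict:
    """Bundled locus/conversion presets (haploid CAN1, diploid URA3,
    mouse ouabain)."""
    text = resources.files("errorthreshold").joinpath("data/loci.json").read_text()
    return json.loads(text)


def load_reference_rates() -> pd.DataFrame:
    """Published Pol delta proofreading/MMR strain rates bundled as inputs.

    Rates are x 1e-7 mutants per cell division, rounded as printed;
    the ``msh6d_effect`` and ``pol3_01_effect`` columns are the
    published per-strain fold ratios, and ``proofreading_ok`` marks
    strains whose suppressor allele leaves proofreading intact (rate
    within 2-fold of the proofreading-proficient MMR-null control).
    These serve as inputs for fold/efficiency arithmetic; the
    underlying colony counts are not published, so the rates themselves
    are not recomputable.
    """
    path = resources.files("errorthreshold").joinpath("data/pol3_eex_rates.tsv")
    with resources.as_file(path) as p:
        return pd.read_csv(p, sep="\t", comment="#", na_values=["NA"])


def _entry_factors(entry: dict) -> tuple:
    mode = entry.get("mode", "drake")
    adjust = float(entry.get("adjust", 1.0))
    if mode == "drake":
        try:
            T = float(entry["T"])
            C2 = float(entry["C2"])
        except KeyError as exc:
            raise KeyError(f"missing conversion constant {exc} for drake mode")
        factors = CorrectionFactors(C=float(entry.get("C", math.nan)),
                                    C2=C2, tau=T / C2)
    elif mode == "target_size":
        try:
            factors = CorrectionFactors.from_target_size(float(entry["tau"]))
        except KeyError as exc:
            raise KeyError(f"missing conversion constant {exc} for target_size mode")
    else:
        raise ValueError(f"unknown conversion mode {mode!r}")
    return factors, adjust


def robustness_table(entries: Sequence[dict],
                     bands: GrowthBands = GrowthBands()) -> pd.DataFrame:
    """Cross-organism per-base-pair rate table.

    Each entry is a dict with keys ``organism``, ``mu_T`` and either a
    ``preset`` name (see :func:`load_locus_presets`) or explicit
    conversion constants (``mode``/``T``/``C2`` or ``tau``, optional
    ``adjust``).  Returns organism, phenotypic rate, unadjusted and
    adjusted per-bp rates, and the growth grade of the phenotypic rate.
    """
    presets = load_locus_presets()
    rows = []
    for entry in entries:
        spec = dict(presets[entry["preset"]]) if "preset" in entry else dict(entry)
        factors, adjust = _entry_factors(spec)
        mu_T = float(entry["mu_T"])
        mu_b = per_bp_rate(mu_T, factors)
        rows.append({
            "organism": entry.get("organism", entry.get("preset", "")),
            "mu_T": mu_T,
            "tau_bp": factors.tau,
            "mu_b": mu_b,
            "mu_b_adjusted": mu_b * adjust,
            "grade": classify_growth(mu_T, bands),
        })
    return pd.DataFrame(
        rows, columns=["organism", "mu_T", "tau_bp", "mu_b", "mu_b_adjusted", "grade"])
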