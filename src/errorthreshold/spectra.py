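"""Mutation-spectrum classification for a reporter coding sequence.

Resistance reporters such as CAN1 detect mutations that inactivate the
encoded protein: every chain-terminating (nonsense) substitution is
detectable, only a fraction of missense changes are, and silent changes
are invisible.  The tallies produced here (chain-terminating vs
missense substitutions, indels and complex events) feed the effective
target-size correction in :mod:`errorthreshold.fidelity`.

Coordinates are 1-based on the coding strand of the reporter CDS.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Dict, List, Mapping, Optional, Sequence

from Bio.Data.CodonTable import unambiguous_dna_by_id

__all__ = [
    "MutationRecord",
    "SpectrumCounts",
    "classify_substitution",
    "diff_sequences",
    "tally_spectrum",
    "apply_mutation",
]

_TABLE = unambiguous_dna_by_id[1]  # standard nuclear genetic code
_STOPS = set(_TABLE.stop_codons)
_BASES = set("ACGT")

SUBSTITUTION = "substitution"
INSERTION = "insertion"
DELETION = "deletion"
COMPLEX = "complex"

CHAIN_TERMINATING = "chain_terminating"
MISSENSE = "missense"
SILENT = "silent"


@dataclass(frozen=True)
class MutationRecord:
    """One scored mutation event in the reporter CDS.

    ``position`` is the 1-based coordinate of the event (for an indel,
    the first affected base of the left-aligned placement).  ``ref``
    and ``alt`` hold the replaced/introduced bases ("" for the empty
    side of an indel).  ``effect`` is set for substitutions only.
    """

    position: int
    ref: str
    alt: str
    kind: str
    effect: Optional[str] = None

    def __post_init__(self):
        if self.kind not in (SUBSTITUTION, INSERTION, DELETION, COMPLEX):
            raise ValueError(f"unknown mutation kind {self.kind!r}")
        if self.position < 1:
            raise ValueError("position is 1-based and must be >= 1")
        if self.kind == SUBSTITUTION:
            if self.ref == self.alt:
                raise ValueError("substitution requires ref != alt")
            if self.ref not in _BASES or self.alt not in _BASES:
                raise ValueError("substitution bases must be A/C/G/T")


@dataclass(frozen=True)
class SpectrumCounts:
    """Event tallies over a collection of sequenced mutants.

    ``B_CT`` chain-terminating and ``B_mis`` missense substitutions sum
    to the detectable substitutions ``B``; ``I`` pools insertions,
    deletions and complex events; ``M = B + I`` counts mutation events
    (a clone carrying two scored mutations contributes both).  Silent
    substitutions, undetectable in a resistance reporter, are tracked
    separately and excluded from ``B`` and ``M``.
    """

    B_CT: int
    B_mis: int
    I: int
    silent: int = 0

    def __post_init__(self):
        if min(self.B_CT, self.B_mis, self.I, self.silent) < 0:
            raise ValueError("spectrum counts must be non-negative")

    @property
    def B(self) -> int:
        return self.B_CT + self.B_mis

    @property
    def M(self) -> int:
        return self.B + self.I


def _validate_cds(cds: str) -> str:
    cds = str(cds).upper()
    bad = set(cds) - _BASES
    if bad:
        raise ValueError(f"CDS contains non-ACGT characters: {sorted(bad)}")
    if len(cds) % 3 != 0:
        raise ValueError("CDS length must be divisible by 3")
    return cds


def classify_substitution(cds: str, position: int, alt_base: str) -> str:
    """Effect of replacing the base at ``position`` (1-based) with ``alt_base``.

    Returns ``"chain_terminating"`` when the mutated codon is TAA, TAG
    or TGA, ``"silent"`` when the encoded amino acid is unchanged under
    the standard nuclear genetic code, and ``"missense"`` otherwise.
    """
    cds = _validate_cds(cds)
    alt_base = str(alt_base).upper()
    if alt_base not in _BASES:
        raise ValueError(f"invalid alternate base {alt_base!r}")
    if not (1 <= position <= len(cds)):
        raise ValueError(f"position {position} outside CDS of length {len(cds)}")
    if cds[position - 1] == alt_base:
        raise ValueError("alternate base equals the reference base")
    ci = (position - 1) // 3
    codon = cds[3 * ci: 3 * ci + 3]
    off = (position - 1) % 3
    mutated = codon[:off] + alt_base + codon[off + 1:]
    if mutated in _STOPS:
        return CHAIN_TERMINATING
    if codon in _STOPS:
        # reference stop codon changed to a sense codon: read-through
        return MISSENSE
    if _TABLE.forward_table[mutated] == _TABLE.forward_table[codon]:
        return SILENT
    return MISSENSE


def _check_seq(seq: str, name: str) -> str:
    seq = str(seq).upper()
    for i, b in enumerate(seq):
        if b not in _BASES:
            raise ValueError(
                f"{name} contains ambiguity/invalid code {b!r} at position {i + 1}")
    return seq


def diff_sequences(ref_cds: str, mutant_cds: str) -> List[MutationRecord]:
    """Mutation records explaining ``mutant_cds`` relative to ``ref_cds``.

    Equal-length inputs are scanned position by position; each mismatch
    becomes a substitution record (classified when the reference is a
    whole number of codons).  Inputs of unequal length are explained by
    a single left-aligned insertion or deletion when an end-anchored
    alignment (longest common prefix + suffix) accounts for every other
    base; otherwise the event is reported as one ``complex`` record
    covering the discordant interval.  Identical inputs give ``[]``.
    """
    ref = _check_seq(ref_cds, "reference")
    mut = _check_seq(mutant_cds, "mutant")

    if len(ref) == len(mut):
        records = []
        coding = len(ref) % 3 == 0
        for i, (a, b) in enumerate(zip(ref, mut)):
            if a != b:
                effect = classify_substitution(ref, i + 1, b) if coding else None
                records.append(MutationRecord(i + 1, a, b, SUBSTITUTION, effect))
        return records

    long_, short = (ref, mut) if len(ref) > len(mut) else (mut, ref)
    d = len(long_) - len(short)
    lcp = 0
    while lcp < len(short) and long_[lcp] == short[lcp]:
        lcp += 1
    lcs = 0
    while (lcs < len(short)
           and long_[len(long_) - 1 - lcs] == short[len(short) - 1 - lcs]):
        lcs += 1
    if lcp + lcs >= len(short):
        # clean single indel; left-align the gap
        pos = max(1, len(long_) - d - lcs + 1)
        seg = long_[pos - 1: pos - 1 + d]
        if len(ref) > len(mut):
            return [MutationRecord(pos, seg, "", DELETION)]
        return [MutationRecord(pos, "", seg, INSERTION)]
    # not a single indel: one complex record over the discordant core
    r_core = ref[lcp: len(ref) - lcs]
    m_core = mut[lcp: len(mut) - lcs]
    return [MutationRecord(lcp + 1, r_core, m_core, COMPLEX)]


def apply_mutation(cds: str, record: MutationRecord) -> str:
    """Reference sequence with ``record`` applied (round-trip helper)."""
    i = record.position - 1
    if record.kind == SUBSTITUTION:
        if cds[i] != record.ref:
            raise ValueError("record.ref does not match the sequence")
        return cds[:i] + record.alt + cds[i + 1:]
    if record.kind == DELETION:
        if cds[i: i + len(record.ref)] != record.ref:
            raise ValueError("record.ref does not match the sequence")
        return cds[:i] + cds[i + len(record.ref):]
    if record.kind == INSERTION:
        return cds[:i] + record.alt + cds[i:]
    # complex: replace the discordant core
    if cds[i: i + len(record.ref)] != record.ref:
        raise ValueError("record.ref does not match the sequence")
    return cds[:i] + record.alt + cds[i + len(record.ref):]


def tally_spectrum(clones: Mapping[str, Sequence[MutationRecord]]) -> SpectrumCounts:
    """Tally spectrum counts over records grouped by mutant clone.

    Every scored event counts once, so ``M`` is the event total (a
    clone with two mutations contributes two events).  Substitutions
    classified silent are excluded from ``B`` with a warning — they are
    undetectable in a resistance reporter and should not occur among
    selected mutants.
    """
    b_ct = b_mis = indel = silent = 0
    for clone, records in clones.items():
        if len(records) == 0:
            raise ValueError(f"clone {clone!r} contributes no records")
        for rec in records:
            if rec.kind == SUBSTITUTION:
                if rec.effect == CHAIN_TERMINATING:
                    b_ct += 1
                elif rec.effect == MISSENSE:
                    b_mis += 1
                elif rec.effect == SILENT:
                    silent += 1
                else:
                    raise ValueError(
                        f"substitution in clone {clone!r} lacks an effect; "
                        "classify against the reporter CDS first")
            else:
                indel += 1
    if silent:
        warnings.warn(
            f"{silent} silent substitution(s) excluded from the detectable "
            "spectrum; silent changes are invisible in a resistance reporter",
            stacklevel=2,
        )
    return SpectrumCounts(B_CT=b_ct, B_mis=b_mis, I=indel, silent=silent)
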