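"""File formats, configuration and report formatting.

TSV dialect: tab-separated, UTF-8, mandatory header row, ``#`` comment
lines permitted, '.' decimal point.  Every writer emits a comment
header echoing the package version and the configuration that produced
the file, and every writer's output is readable by the matching reader.
Rates in report tables are printed as value x 1e-7 with two significant
figures and the 95% CI bounds alongside.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field
from decimal import ROUND_HALF_UP, Decimal
from pathlib import Path
from typing import Dict, List, Mapping, Optional, Sequence

import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from . import __version__
from .fluctuation import CultureSet, RateEstimate
from .spectra import MutationRecord, SUBSTITUTION

__all__ = [
    "PipelineConfig",
    "round_sig",
    "read_counts_tsv",
    "write_counts_tsv",
    "write_rates_tsv",
    "read_spectrum_tsv",
    "write_spectrum_tsv",
    "read_fasta",
    "write_fasta",
    "InputError",
]

RATE_SCALE = 1e-7  # report tables print rates as multiples of 1e-7


class InputError(ValueError):
    """Malformed input file; message carries the offending line number."""


@dataclass(frozen=True)
class PipelineConfig:
    """Run configuration echoed into every output header."""

    level: float = 0.95
    seed: int = 0
    rate_scale: float = RATE_SCALE
    rate_sig_figs: int = 2
    version: str = __version__

    @classmethod
    def from_file(cls, path) -> "PipelineConfig":
        data = json.loads(Path(path).read_text())
        known = {k: data[k] for k in ("level", "seed", "rate_scale", "rate_sig_figs")
                 if k in data}
        return cls(**known)

    def header_lines(self) -> List[str]:
        return [
            f"# errorthreshold v{self.version}",
            f"# config: level={self.level} seed={self.seed} "
            f"rate_scale={self.rate_scale:g} sig_figs={self.rate_sig_figs}",
        ]


def round_sig(x: float, n: int) -> float:
    """Round to ``n`` significant figures, half away from zero.

    Mirrors the convention of printed report tables (3.25 -> 3.3 at two
    figures), unlike banker's rounding.
    """
    if x == 0 or not math.isfinite(x):
        return float(x)
    d = Decimal(repr(abs(float(x))))
    # pre-round at 12 significant digits so binary representation noise
    # (e.g. 3.2499999999999996 for the decimal 3.25) cannot flip the digit
    e = d.adjusted()
    d = d.scaleb(-(e - 11)).quantize(Decimal(1), rounding=ROUND_HALF_UP).scaleb(e - 11)
    e = d.adjusted()
    q = d.scaleb(-(e - n + 1)).quantize(Decimal(1), rounding=ROUND_HALF_UP)
    return float(q.scaleb(e - n + 1)) * (1 if x > 0 else -1)


# ---------------------------------------------------------------------------
# fluctuation counts and rate reports
# ---------------------------------------------------------------------------

def read_counts_tsv(path) -> List[CultureSet]:
    """Read per-culture mutant counts, one row per culture.

    Columns: experiment_id, count, n_total, plating_fraction.  Rows
    sharing an experiment_id form one :class:`CultureSet` and must
    agree on n_total and plating_fraction.
    """
    try:
        df = pd.read_csv(path, sep="\t", comment="#", dtype=str)
    except Exception as exc:  # pragma: no cover - pandas error text varies
        raise InputError(f"{path}: cannot parse TSV ({exc})")
    required = ["experiment_id", "count", "n_total", "plating_fraction"]
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise InputError(f"{path}: missing required column(s) {missing}")
    sets = []
    for exp_id, grp in df.groupby("experiment_id", sort=False):
        try:
            counts = [int(v) for v in grp["count"]]
            n_totals = {float(v) for v in grp["n_total"]}
            fractions = {float(v) for v in grp["plating_fraction"]}
        except ValueError as exc:
            rows = ", ".join(str(i + 2) for i in grp.index[:5])
            raise InputError(f"{path}: non-numeric value in rows {rows} ({exc})")
        if len(n_totals) != 1 or len(fractions) != 1:
            raise InputError(
                f"{path}: experiment {exp_id!r} mixes n_total or plating_fraction values")
        sets.append(CultureSet(counts=counts, n_total=n_totals.pop(),
                               plating_fraction=fractions.pop(), label=str(exp_id)))
    if not sets:
        raise InputError(f"{path}: no culture rows found")
    return sets


def write_counts_tsv(sets: Sequence[CultureSet], path,
                     config: Optional[PipelineConfig] = None) -> None:
    config = config or PipelineConfig()
    with open(path, "w", encoding="utf-8") as fh:
        fh.write("\n".join(config.header_lines()) + "\n")
        fh.write("experiment_id\tcount\tn_total\tplating_fraction\n")
        for cs in sets:
            for c in cs.counts:
                fh.write(f"{cs.label}\t{c}\t{cs.n_total:g}\t{cs.plating_fraction:g}\n")


def write_rates_tsv(estimates: Sequence[RateEstimate], path,
                    config: Optional[PipelineConfig] = None) -> None:
    """Rate report in the style of a mutation-rate table.

    ``rate_e7`` columns are the phenotypic rate and its 95% CI bounds
    in units of 1e-7 per cell division, rounded to the configured
    number of significant figures; ``m_hat`` and its CI are unscaled.
    """
    config = config or PipelineConfig()
    sf = config.rate_sig_figs
    with open(path, "w", encoding="utf-8") as fh:
        fh.write("\n".join(config.header_lines()) + "\n")
        fh.write("experiment_id\tm_hat\tm_lo\tm_hi\trate_e7\trate_lo_e7\trate_hi_e7\n")
        for est in estimates:
            ci_m = est.ci_m or (float("nan"), float("nan"))
            ci_r = est.ci_rate or (float("nan"), float("nan"))
            fh.write(
                f"{est.label}\t{est.m_hat:.6g}\t{ci_m[0]:.6g}\t{ci_m[1]:.6g}\t"
                f"{round_sig(est.rate / config.rate_scale, sf):g}\t"
                f"{round_sig(ci_r[0] / config.rate_scale, sf):g}\t"
                f"{round_sig(ci_r[1] / config.rate_scale, sf):g}\n")


def read_rates_tsv(path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", comment="#")


# ---------------------------------------------------------------------------
# spectra
# ---------------------------------------------------------------------------

_SPECTRUM_COLS = ["clone_id", "position", "ref", "alt", "kind", "effect"]


def write_spectrum_tsv(clones: Mapping[str, Sequence[MutationRecord]], path,
                       config: Optional[PipelineConfig] = None) -> None:
    config = config or PipelineConfig()
    with open(path, "w", encoding="utf-8") as fh:
        fh.write("\n".join(config.header_lines()) + "\n")
        fh.write("\t".join(_SPECTRUM_COLS) + "\n")
        for clone, records in clones.items():
            for r in records:
                fh.write(f"{clone}\t{r.position}\t{r.ref or '-'}\t{r.alt or '-'}\t"
                         f"{r.kind}\t{r.effect or '-'}\n")


def read_spectrum_tsv(path) -> Dict[str, List[MutationRecord]]:
    df = pd.read_csv(path, sep="\t", comment="#", dtype=str)
    missing = [c for c in _SPECTRUM_COLS if c not in df.columns]
    if missing:
        raise InputError(f"{path}: missing required column(s) {missing}")
    clones: Dict[str, List[MutationRecord]] = {}
    for i, row in df.iterrows():
        try:
            rec = MutationRecord(
                position=int(row["position"]),
                ref="" if row["ref"] in ("-", "", None) else str(row["ref"]),
                alt="" if row["alt"] in ("-", "", None) else str(row["alt"]),
                kind=str(row["kind"]),
                effect=None if row["effect"] in ("-", "", None) else str(row["effect"]),
            )
        except (ValueError, TypeError) as exc:
            raise InputError(f"{path}: bad record at data row {i + 2}: {exc}")
        clones.setdefault(str(row["clone_id"]), []).append(rec)
    return clones


# ---------------------------------------------------------------------------
# sequences
# ---------------------------------------------------------------------------

def read_fasta(path) -> List[tuple]:
    """(id, sequence) pairs from a FASTA file."""
    return [(rec.id, str(rec.seq).upper()) for rec in SeqIO.parse(str(path), "fasta")]


def write_fasta(entries: Sequence[tuple], path) -> None:
    """Write (id, sequence) pairs, 60-column wrapped."""
    records = [SeqRecord(Seq(seq), id=name, description="") for name, seq in entries]
    SeqIO.write(records, str(path), "fasta")
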