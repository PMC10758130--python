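"""Base composition and strand-asymmetry (skew) statistics.

AT skew = (A - T) / (A + T) and GC skew = (G - C) / (G + C), computed on
whichever strand the sequence is given in: positive AT skew means adenine is
overrepresented on that strand.  Whole-genome statistics use the deposited
(plus) strand; per-gene statistics use the coding orientation, which is why a
minus-strand gene such as ND6 can show a strongly positive AT skew while the
genome as a whole shows a moderate one.
"""

from __future__ import annotations

import statistics
from dataclasses import dataclass
from decimal import ROUND_HALF_UP, Decimal

import pandas as pd

from .genome_io import MitoGenomeRecord, extract_gene

__all__ = [
    "CompositionStats",
    "base_composition",
    "region_composition",
    "composition_table",
    "round_half_up",
]


def round_half_up(x: float, ndigits: int = 2) -> float:
    """Decimal half-up rounding (0.145 -> 0.15), as printed report tables use."""
    q = Decimal(1).scaleb(-ndigits)
    return float(Decimal(repr(x)).quantize(q, rounding=ROUND_HALF_UP))


@dataclass(frozen=True)
class CompositionStats:
    """Counts and derived composition statistics for one sequence.

    ``N`` bases are counted separately and excluded from percentages and
    skews.  Skews are ``None`` whenever their denominator is zero.
    """

    n_A: int
    n_C: int
    n_G: int
    n_T: int
    n_N: int = 0

    @property
    def total(self) -> int:
        return self.n_A + self.n_C + self.n_G + self.n_T

    @property
    def pct_AT(self) -> float | None:
        if self.total == 0:
            return None
        return 100.0 * (self.n_A + self.n_T) / self.total

    @property
    def pct_A(self) -> float | None:
        return None if self.total == 0 else 100.0 * self.n_A / self.total

    @property
    def pct_C(self) -> float | None:
        return None if self.total == 0 else 100.0 * self.n_C / self.total

    @property
    def pct_G(self) -> float | None:
        return None if self.total == 0 else 100.0 * self.n_G / self.total

    @property
    def pct_T(self) -> float | None:
        return None if self.total == 0 else 100.0 * self.n_T / self.total

    @property
    def at_skew(self) -> float | None:
        denom = self.n_A + self.n_T
        return None if denom == 0 else (self.n_A - self.n_T) / denom

    @property
    def gc_skew(self) -> float | None:
        denom = self.n_G + self.n_C
        return None if denom == 0 else (self.n_G - self.n_C) / denom


def base_composition(seq: str) -> CompositionStats:
    """Exact base counts and skews for a sequence over {A,C,G,T,N}."""
    seq = seq.upper()
    stats = CompositionStats(
        n_A=seq.count("A"),
        n_C=seq.count("C"),
        n_G=seq.count("G"),
        n_T=seq.count("T"),
        n_N=seq.count("N"),
    )
    if stats.total + stats.n_N != len(seq):
        bad = set(seq) - set("ACGTN")
        raise ValueError(f"sequence contains unsupported characters {sorted(bad)}")
    return stats


_REGION_FTYPES = {"PCGs": "PCG", "tRNAs": "tRNA", "rRNAs": "rRNA", "CR": "CR"}


def region_composition(record: MitoGenomeRecord) -> pd.DataFrame:
    """Composition per region class: whole genome, PCGs, tRNAs, rRNAs, CR.

    Region sequences are concatenations of strand-corrected gene extractions;
    the whole-genome row is computed on the plus strand as deposited.  Region
    classes absent from the feature table are omitted (with a note in the
    ``note`` column of the returned frame's attrs).
    """
    rows = []
    notes: list[str] = []

    def _row(region: str, seq: str) -> dict:
        s = base_composition(seq)
        return {
            "region": region, "length_bp": len(seq),
            "pct_AT": s.pct_AT, "at_skew": s.at_skew, "gc_skew": s.gc_skew,
            "pct_A": s.pct_A, "pct_C": s.pct_C, "pct_G": s.pct_G, "pct_T": s.pct_T,
        }

    rows.append(_row("whole", record.sequence))
    for region, ftype in _REGION_FTYPES.items():
        names = [f.name for f in record.features if f.ftype == ftype]
        if not names:
            notes.append(f"no {ftype} features; region {region} omitted")
            continue
        seq = "".join(extract_gene(record, n) for n in names)
        rows.append(_row(region, seq))
    df = pd.DataFrame(rows)
    df.attrs["notes"] = notes
    return df


def composition_table(
    records: list[MitoGenomeRecord], ndigits: int = 2
) -> pd.DataFrame:
    """Per-genome composition table plus a summary row.

    One row per record (organism, accession, length, AT%, AT skew, GC skew,
    per-base percentages) rounded half-up to ``ndigits``; the final ``mean``
    and ``sd`` rows summarize the unrounded per-genome values and are rounded
    last.  Raw unrounded values are kept in ``df.attrs['raw']``.
    """
    if not records:
        raise ValueError("need at least one record")
    raw_rows = []
    for rec in records:
        s = base_composition(rec.sequence)
        raw_rows.append(
            {
                "organism": rec.organism, "accession": rec.accession,
                "length_bp": rec.length_bp, "pct_AT": s.pct_AT,
                "at_skew": s.at_skew, "gc_skew": s.gc_skew,
                "pct_A": s.pct_A, "pct_C": s.pct_C,
                "pct_G": s.pct_G, "pct_T": s.pct_T,
            }
        )
    raw = pd.DataFrame(raw_rows)
    value_cols = ["pct_AT", "at_skew", "gc_skew", "pct_A", "pct_C", "pct_G", "pct_T"]

    def _sd(vals: list[float]) -> float:
        return statistics.stdev(vals) if len(vals) > 1 else 0.0

    mean_row = {"organism": "mean", "accession": "", "length_bp": ""}
    sd_row = {"organism": "sd", "accession": "", "length_bp": ""}
    for col in value_cols:
        vals = raw[col].tolist()
        mean_row[col] = round_half_up(statistics.fmean(vals), ndigits)
        sd_row[col] = round_half_up(_sd(vals), ndigits)

    table = raw.copy()
    for col in value_cols:
        table[col] = [round_half_up(v, ndigits) for v in table[col]]
    table = pd.concat(
        [table, pd.DataFrame([mean_row, sd_row])], ignore_index=True
    )
    table.attrs["raw"] = raw
    return table
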