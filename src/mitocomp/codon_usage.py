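"""Start/stop-codon usage and relative synonymous codon usage (RSCU).

All codon work uses the vertebrate mitochondrial genetic code (NCBI
translation table 2), under which TAA, TAG, AGA and AGG are stops and 60
codons encode amino acids.  RSCU for a codon is its observed count divided by
the mean count of its synonymous family: values above 1 mark codons used more
often than expected under uniform usage within the family.

Mitochondrial CDSs frequently end in an incomplete stop (``T-`` or ``TA-``)
completed by polyadenylation of the transcript; these are tallied verbatim,
as are non-canonical annotated terminal codons, so annotation artifacts are
preserved and flagged rather than re-translated away.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass, field

import pandas as pd
from Bio.Data.CodonTable import unambiguous_dna_by_id

from .genome_io import PCG_NAMES, MitoGenomeRecord, extract_gene

__all__ = [
    "VERTEBRATE_MITO_TABLE",
    "SENSE_CODONS",
    "STOP_CODONS",
    "START_CODON_TYPES",
    "CodonCountTable",
    "StartStopReport",
    "codon_iter",
    "count_codons",
    "start_stop_usage",
    "rscu",
    "rscu_table",
]

#: NCBI translation table 2 (vertebrate mitochondrial).
VERTEBRATE_MITO_TABLE = unambiguous_dna_by_id[2]
STOP_CODONS: frozenset[str] = frozenset(VERTEBRATE_MITO_TABLE.stop_codons)
SENSE_CODONS: tuple[str, ...] = tuple(sorted(VERTEBRATE_MITO_TABLE.forward_table))
#: Conventional vertebrate mitochondrial initiation codons.
START_CODON_TYPES = ("ATG", "GTG", "ATA", "ATC", "ATT")

#: codon -> amino acid (sense codons only).
CODON_TO_AA: dict[str, str] = dict(VERTEBRATE_MITO_TABLE.forward_table)

#: amino acid -> tuple of synonymous codons.
SYNONYMOUS_FAMILIES: dict[str, tuple[str, ...]] = {}
for _codon, _aa in sorted(CODON_TO_AA.items()):
    SYNONYMOUS_FAMILIES.setdefault(_aa, ())
    SYNONYMOUS_FAMILIES[_aa] += (_codon,)


def codon_iter(cds: str, codon_start: int = 1) -> tuple[list[str], str]:
    """Split a coding-orientation CDS into codons plus a trailing remainder.

    ``codon_start`` is the GenBank frame offset (1-based); the 1-2 nt left
    over after the last full codon are returned as the remainder and are the
    candidate incomplete stop codon.
    """
    if codon_start not in {1, 2, 3}:
        raise ValueError("codon_start must be 1, 2 or 3")
    seq = cds.upper()[codon_start - 1 :]
    if len(seq) < 3:
        raise ValueError("CDS shorter than one codon after frame offset")
    n_full = len(seq) // 3
    codons = [seq[3 * i : 3 * i + 3] for i in range(n_full)]
    return codons, seq[3 * n_full :]


@dataclass
class CodonCountTable:
    """Codon counts over the sense codons of the vertebrate mito code.

    Stop codons encountered while counting are tracked separately so the
    sense-codon total equals the number of in-frame non-stop codons seen.
    """

    counts: dict[str, int] = field(
        default_factory=lambda: {c: 0 for c in SENSE_CODONS}
    )
    stop_counts: dict[str, int] = field(default_factory=dict)
    genetic_code: str = "vertebrate mitochondrial (translation table 2)"

    @property
    def total(self) -> int:
        return sum(self.counts.values())

    def add_cds(self, cds: str, codon_start: int = 1) -> None:
        codons, _rem = codon_iter(cds, codon_start)
        for c in codons:
            if c in STOP_CODONS:
                self.stop_counts[c] = self.stop_counts.get(c, 0) + 1
            elif c in self.counts:
                self.counts[c] += 1
            # codons containing N are not countable; ignore


def count_codons(
    records: list[MitoGenomeRecord], genes: tuple[str, ...] = PCG_NAMES
) -> dict[str, CodonCountTable]:
    """Per-species codon counts pooled over the given PCGs (default all 13)."""
    out: dict[str, CodonCountTable] = {}
    for rec in records:
        table = CodonCountTable()
        for gene in genes:
            table.add_cds(extract_gene(rec, gene))
        out[rec.accession] = table
    return out


@dataclass
class StartStopReport:
    """Per-gene start/stop codons and their aggregate usage frequencies."""

    starts: pd.DataFrame  # columns: accession, gene, start_codon
    stops: pd.DataFrame  # columns: accession, gene, stop_codon, complete
    start_frequencies: pd.DataFrame  # codon, count, pct
    stop_frequencies: pd.DataFrame  # codon, count, pct
    warnings: list[str] = field(default_factory=list)


def _terminal_stop(cds: str) -> tuple[str, bool]:
    """Annotated terminal (stop) codon of a CDS, verbatim.

    Returns ``(codon, complete)``; an incomplete stop is reported in the
    ``T-`` / ``TA-`` notation.  The terminal codon is recorded even when it
    is not a stop under table 2 (e.g. an annotated AAA terminator), so such
    artifacts surface in the report instead of being re-translated.
    """
    codons, rem = codon_iter(cds)
    if rem:
        return rem + "-" * (3 - len(rem)), False
    return codons[-1], True


def start_stop_usage(
    records: list[MitoGenomeRecord], genes: tuple[str, ...] = PCG_NAMES
) -> StartStopReport:
    """Tally start and stop codons across all PCGs of all records."""
    start_rows, stop_rows, warnings = [], [], []
    for rec in records:
        for gene in genes:
            cds = extract_gene(rec, gene)
            codons, _ = codon_iter(cds)
            start = codons[0]
            if start not in START_CODON_TYPES:
                warnings.append(
                    f"{rec.accession} {gene}: start codon {start} outside the "
                    f"conventional set {START_CODON_TYPES}"
                )
            stop, complete = _terminal_stop(cds)
            start_rows.append(
                {"accession": rec.accession, "gene": gene, "start_codon": start}
            )
            stop_rows.append(
                {"accession": rec.accession, "gene": gene, "stop_codon": stop,
                 "complete": complete}
            )

    def _freq(rows: list[dict], key: str) -> pd.DataFrame:
        counts = Counter(r[key] for r in rows)
        total = sum(counts.values())
        return pd.DataFrame(
            [
                {"codon": c, "count": n, "pct": 100.0 * n / total}
                for c, n in sorted(counts.items(), key=lambda kv: (-kv[1], kv[0]))
            ]
        )

    return StartStopReport(
        starts=pd.DataFrame(start_rows),
        stops=pd.DataFrame(stop_rows),
        start_frequencies=_freq(start_rows, "start_codon"),
        stop_frequencies=_freq(stop_rows, "stop_codon"),
        warnings=warnings,
    )


def rscu(counts: CodonCountTable) -> dict[str, float | None]:
    """Relative synonymous codon usage for every sense codon.

    For an amino acid with ``k`` synonymous codons and family total ``X``,
    ``RSCU(c) = count(c) * k / X``; families never observed (``X == 0``)
    yield ``None`` for all their codons.
    """
    out: dict[str, float | None] = {}
    for _aa, family in SYNONYMOUS_FAMILIES.items():
        x = sum(counts.counts[c] for c in family)
        k = len(family)
        for c in family:
            out[c] = None if x == 0 else counts.counts[c] * k / x
    return out


def rscu_table(tables: dict[str, CodonCountTable]) -> pd.DataFrame:
    """Long-form RSCU table: one row per (species, amino acid, codon)."""
    rows = []
    for label, table in tables.items():
        values = rscu(table)
        for aa, family in sorted(SYNONYMOUS_FAMILIES.items()):
            for codon in family:
                rows.append(
                    {"species": label, "amino_acid": aa, "codon": codon,
                     "count": table.counts[codon], "rscu": values[codon]}
                )
    return pd.DataFrame(rows)
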