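"""Per-gene alignment statistics and Nei-Gojobori selection analysis.

Implements, for in-frame codon alignments of mitochondrial protein-coding
genes:

* alignment cleaning (terminal stops and gapped codon columns removed),
* site classification (variable / parsimony-informative / singleton),
* pooled transition:transversion count ratios,
* uncorrected p-distances and their mean over all pairs (Aupd),
* the Nei-Gojobori (1986) method for synonymous (Ks/dS) and nonsynonymous
  (Ka/dN) substitution rates with Jukes-Cantor correction.

Nei-Gojobori counts, for each codon, the fraction of the nine possible
single-nucleotide changes that are synonymous (synonymous sites) versus
nonsynonymous; changes producing a stop codon are excluded from both
numerators, so a stop-adjacent codon carries slightly fewer than three
countable sites.  Observed differences between a codon pair are partitioned
into synonymous and nonsynonymous changes by averaging over all minimal
mutational pathways with equal weight, excluding pathways that pass through
a stop codon.  Proportions pS = Sd/S and pN = Nd/N are then corrected for
multiple hits with the Jukes-Cantor formula d = -3/4 ln(1 - 4/3 p).
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass, field
from functools import lru_cache

import pandas as pd

from .codon_usage import CODON_TO_AA, STOP_CODONS, codon_iter
from .composition import base_composition
from .genome_io import MitoGenomeRecord, extract_gene

__all__ = [
    "CodonAlignment",
    "SiteClassification",
    "NGPairResult",
    "GeneDivergenceStats",
    "build_alignment",
    "clean_alignment",
    "classify_sites",
    "ts_tv_ratio",
    "p_distance",
    "aupd",
    "ng_site_counts",
    "ng_codon_diffs",
    "ng_pairwise",
    "gene_kaks",
    "gene_divergence_table",
]

_TRANSITIONS = {frozenset("AG"), frozenset("CT")}
_BASES = "ACGT"


# ---------------------------------------------------------------------------
# Alignment container and cleaning
# ---------------------------------------------------------------------------

@dataclass
class CodonAlignment:
    """Equal-length, in-frame nucleotide alignment of one gene across taxa."""

    gene: str
    taxa: list[str]
    rows: list[str]

    def __post_init__(self) -> None:
        if len(self.taxa) != len(self.rows):
            raise ValueError("taxa and rows must have equal length")
        lengths = {len(r) for r in self.rows}
        if len(lengths) > 1:
            raise ValueError(
                f"{self.gene}: rows have unequal lengths {sorted(lengths)}"
            )
        self.rows = [r.upper() for r in self.rows]

    @property
    def length(self) -> int:
        return len(self.rows[0]) if self.rows else 0

    def codon_columns(self) -> list[list[str]]:
        """List of codon columns; each entry is the per-taxon codon list."""
        return [
            [row[i : i + 3] for row in self.rows] for i in range(0, self.length, 3)
        ]


def build_alignment(
    records: list[MitoGenomeRecord], gene: str
) -> CodonAlignment:
    """Stack per-record coding-orientation extractions of one gene.

    Mitochondrial PCGs are essentially indel-free across close relatives, so
    homologous extractions of equal length already constitute a codon
    alignment.  Unequal lengths indicate a true indel; align externally and
    load the FASTA instead.
    """
    rows = [extract_gene(r, gene) for r in records]
    if len({len(x) for x in rows}) > 1:
        raise ValueError(
            f"{gene}: extracted lengths differ between records; supply an "
            "externally aligned FASTA for this gene"
        )
    return CodonAlignment(gene, [r.accession for r in records], rows)


def clean_alignment(aln: CodonAlignment) -> CodonAlignment:
    """Remove terminal stop codons, incomplete tails and gapped codon columns.

    The trailing partial codon (1-2 nt, incomplete stop) is dropped first,
    then trailing codon columns containing a stop in any taxon, then every
    codon column containing a gap in any taxon.  Any stop codon remaining
    after cleaning indicates a frame problem and raises with the offending
    taxon and codon index.
    """
    trim = aln.length - (aln.length % 3)
    cols = [
        [row[i : i + 3] for row in aln.rows] for i in range(0, trim, 3)
    ]
    while cols and any(c in STOP_CODONS for c in cols[-1]):
        cols.pop()
    kept = [col for col in cols if not any("-" in c for c in col)]
    for j, col in enumerate(kept):
        for taxon, codon in zip(aln.taxa, col):
            if codon in STOP_CODONS:
                raise ValueError(
                    f"{aln.gene}: internal stop codon {codon} in {taxon} at "
                    f"codon {j + 1} after cleaning (check reading frame)"
                )
    rows = ["".join(col[i] for col in kept) for i in range(len(aln.taxa))]
    return CodonAlignment(aln.gene, list(aln.taxa), rows)


# ---------------------------------------------------------------------------
# Site classification
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class SiteClassification:
    n_sites: int
    n_variable: int
    n_parsimony_informative: int
    n_singleton: int

    @property
    def pct_Vs(self) -> float:
        return 100.0 * self.n_variable / self.n_sites if self.n_sites else 0.0

    @property
    def pct_Pis(self) -> float:
        return (
            100.0 * self.n_parsimony_informative / self.n_sites
            if self.n_sites
            else 0.0
        )

    @property
    def pct_S(self) -> float:
        return 100.0 * self.n_singleton / self.n_sites if self.n_sites else 0.0


def classify_sites(aln: CodonAlignment) -> SiteClassification:
    """Count variable, parsimony-informative and singleton sites.

    A site is variable with >= 2 distinct nucleotide states, parsimony
    informative when >= 2 states each occur in >= 2 taxa, and a singleton
    when variable but not informative.  Gaps and Ns do not count as states.
    """
    if len(aln.rows) < 2:
        raise ValueError("site classification needs at least 2 sequences")
    n_var = n_inf = 0
    for i in range(aln.length):
        states: dict[str, int] = {}
        for row in aln.rows:
            b = row[i]
            if b in _BASES:
                states[b] = states.get(b, 0) + 1
        if len(states) >= 2:
            n_var += 1
            if sum(1 for c in states.values() if c >= 2) >= 2:
                n_inf += 1
    return SiteClassification(aln.length, n_var, n_inf, n_var - n_inf)


def ts_tv_ratio(aln: CodonAlignment) -> float | None:
    """Pooled transition/transversion count ratio over all sequence pairs.

    Counts every differing, ungapped site in every unordered pair; returns
    ``None`` when no transversions are observed.
    """
    ts = tv = 0
    for a, b in itertools.combinations(aln.rows, 2):
        for x, y in zip(a, b):
            if x == y or x not in _BASES or y not in _BASES:
                continue
            if frozenset((x, y)) in _TRANSITIONS:
                ts += 1
            else:
                tv += 1
    return None if tv == 0 else ts / tv


def p_distance(a: str, b: str) -> float | None:
    """Uncorrected proportion of differing sites between two aligned rows."""
    if len(a) != len(b):
        raise ValueError("aligned rows must have equal length")
    diffs = compared = 0
    for x, y in zip(a.upper(), b.upper()):
        if x in _BASES and y in _BASES:
            compared += 1
            diffs += x != y
    return None if compared == 0 else diffs / compared


def aupd(aln: CodonAlignment) -> float | None:
    """Average uncorrected pairwise distance over all C(n,2) pairs."""
    dists = [
        d
        for a, b in itertools.combinations(aln.rows, 2)
        if (d := p_distance(a, b)) is not None
    ]
    return None if not dists else sum(dists) / len(dists)


# ---------------------------------------------------------------------------
# Nei-Gojobori (1986) Ka/Ks
# ---------------------------------------------------------------------------

@lru_cache(maxsize=None)
def ng_site_counts(codon: str) -> tuple[float, float]:
    """Synonymous and nonsynonymous site counts of one codon.

    Each codon position contributes 1/3 of a site per possible nucleotide
    change: changes preserving the amino acid count toward synonymous sites,
    changes altering it toward nonsynonymous sites, and changes creating a
    stop codon toward neither.  Hence ``syn + nonsyn <= 3`` with equality iff
    no single-nucleotide neighbor is a stop.
    """
    codon = codon.upper()
    if codon in STOP_CODONS:
        raise ValueError(f"stop codon {codon} has no site counts")
    if codon not in CODON_TO_AA:
        raise ValueError(f"not a valid codon: {codon!r}")
    aa = CODON_TO_AA[codon]
    syn = nonsyn = 0
    for pos in range(3):
        for b in _BASES:
            if b == codon[pos]:
                continue
            mutant = codon[:pos] + b + codon[pos + 1 :]
            if mutant in STOP_CODONS:
                continue
            if CODON_TO_AA[mutant] == aa:
                syn += 1
            else:
                nonsyn += 1
    return syn / 3.0, nonsyn / 3.0


@lru_cache(maxsize=None)
def ng_codon_diffs(c1: str, c2: str) -> tuple[float, float, bool]:
    """Synonymous/nonsynonymous differences between two sense codons.

    Averages over all minimal mutational pathways (orderings of the differing
    positions) with equal weight, excluding pathways whose intermediate
    codons are stops.  Returns ``(sd, nd, via_stop_only)``: when every
    pathway passes through a stop, pathways are averaged including the stop
    intermediates (classifying each step by the encoded amino acids of its
    endpoints, stop steps as nonsynonymous) and the flag is set.
    """
    c1, c2 = c1.upper(), c2.upper()
    for c in (c1, c2):
        if c not in CODON_TO_AA:
            raise ValueError(f"not a sense codon: {c!r}")
    positions = [i for i in range(3) if c1[i] != c2[i]]
    if not positions:
        return 0.0, 0.0, False

    def walk(order: tuple[int, ...], allow_stops: bool) -> tuple[float, float] | None:
        cur = c1
        sd = nd = 0
        for pos in order:
            nxt = cur[:pos] + c2[pos] + cur[pos + 1 :]
            if nxt in STOP_CODONS and not allow_stops:
                return None
            a1, a2 = CODON_TO_AA.get(cur), CODON_TO_AA.get(nxt)
            if a1 is not None and a1 == a2:
                sd += 1
            else:
                nd += 1
            cur = nxt
        return sd, nd

    orders = list(itertools.permutations(positions))
    viable = [r for o in orders if (r := walk(o, allow_stops=False)) is not None]
    via_stop_only = not viable
    if via_stop_only:
        viable = [walk(o, allow_stops=True) for o in orders]
    sd = sum(r[0] for r in viable) / len(viable)
    nd = sum(r[1] for r in viable) / len(viable)
    return sd, nd, via_stop_only


@dataclass(frozen=True)
class NGPairResult:
    """Nei-Gojobori statistics for one sequence pair."""

    S: float
    N: float
    Sd: float
    Nd: float
    pS: float
    pN: float
    Ks: float | None  # dS, Jukes-Cantor corrected
    Ka: float | None  # dN, Jukes-Cantor corrected
    ka_ks: float | None
    notes: tuple[str, ...] = ()


def _jukes_cantor(p: float) -> float | None:
    if p >= 0.75:
        return None
    return -0.75 * math.log(1.0 - 4.0 * p / 3.0)


def ng_pairwise(a: str, b: str) -> NGPairResult:
    """Nei-Gojobori Ka/Ks between two equal-length, gap-free, in-frame CDSs.

    Site totals S and N are averaged over the two sequences; observed
    differences are summed over codon pairs via :func:`ng_codon_diffs`.
    ``Ks``/``Ka`` are ``None`` when the Jukes-Cantor correction is undefined
    (p >= 3/4); ``ka_ks`` is ``None`` when ``Ks`` is 0 or undefined.
    """
    codons_a, rem_a = codon_iter(a)
    codons_b, rem_b = codon_iter(b)
    if len(a) != len(b):
        raise ValueError("sequences must have equal length")
    notes: list[str] = []
    s_a = n_a = s_b = n_b = 0.0
    sd = nd = 0.0
    for ca, cb in zip(codons_a, codons_b):
        sa, na = ng_site_counts(ca)
        sb, nb = ng_site_counts(cb)
        s_a += sa
        n_a += na
        s_b += sb
        n_b += nb
        dsd, dnd, flagged = ng_codon_diffs(ca, cb)
        if flagged:
            notes.append(f"{ca}->{cb}: all minimal pathways pass through a stop")
        sd += dsd
        nd += dnd
    S = (s_a + s_b) / 2.0
    N = (n_a + n_b) / 2.0
    pS = sd / S if S > 0 else 0.0
    pN = nd / N if N > 0 else 0.0
    Ks = _jukes_cantor(pS)
    Ka = _jukes_cantor(pN)
    if Ks is None:
        notes.append("pS >= 3/4: Jukes-Cantor correction undefined for Ks")
    if Ka is None:
        notes.append("pN >= 3/4: Jukes-Cantor correction undefined for Ka")
    ka_ks = None
    if Ka is not None and Ks is not None and Ks > 0:
        ka_ks = Ka / Ks
    return NGPairResult(S, N, sd, nd, pS, pN, Ks, Ka, ka_ks, tuple(notes))


def gene_kaks(
    aln: CodonAlignment, mean_of_ratios: bool = False
) -> tuple[float | None, float | None, float | None]:
    """Gene-level (Ka, Ks, Ka/Ks) aggregated over all sequence pairs.

    Default aggregates as the ratio of mean dN to mean dS over all pairs with
    defined distances, which stays finite when individual pairs have dS == 0;
    ``mean_of_ratios=True`` instead averages the per-pair ratios that exist.
    """
    kas, kss, ratios = [], [], []
    for x, y in itertools.combinations(aln.rows, 2):
        res = ng_pairwise(x, y)
        if res.Ka is not None:
            kas.append(res.Ka)
        if res.Ks is not None:
            kss.append(res.Ks)
        if res.ka_ks is not None:
            ratios.append(res.ka_ks)
    ka = sum(kas) / len(kas) if kas else None
    ks = sum(kss) / len(kss) if kss else None
    if mean_of_ratios:
        kaks = sum(ratios) / len(ratios) if ratios else None
    else:
        kaks = ka / ks if ka is not None and ks not in (None, 0) else None
    return ka, ks, kaks


# ---------------------------------------------------------------------------
# Per-gene summary table
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class GeneDivergenceStats:
    """One summary-table row for a gene."""

    gene: str
    length_bp: int
    pct_AT: float
    at_skew: float | None
    gc_skew: float | None
    sites: SiteClassification
    ts_tv: float | None
    Ks: float | None
    Ka: float | None
    ka_ks: float | None
    aupd: float | None
    notes: tuple[str, ...] = ()


def _mean_composition(rows: list[str]) -> tuple[float, float | None, float | None]:
    stats = [base_composition(r.replace("-", "")) for r in rows]
    pct = [s.pct_AT for s in stats if s.pct_AT is not None]
    ats = [s.at_skew for s in stats if s.at_skew is not None]
    gcs = [s.gc_skew for s in stats if s.gc_skew is not None]
    return (
        sum(pct) / len(pct) if pct else 0.0,
        sum(ats) / len(ats) if ats else None,
        sum(gcs) / len(gcs) if gcs else None,
    )


def gene_divergence(
    aln: CodonAlignment,
    already_clean: bool = False,
    composition_on: str = "cleaned",
) -> GeneDivergenceStats:
    """All divergence statistics for one gene alignment (cleaning included).

    Per-gene composition is the mean over taxa computed on the cleaned
    coding-strand rows; ``composition_on='raw'`` computes it on the rows as
    supplied (gaps stripped) instead.
    """
    cleaned = aln if already_clean else clean_alignment(aln)
    comp_rows = aln.rows if composition_on == "raw" else cleaned.rows
    pct_at, at_sk, gc_sk = _mean_composition(comp_rows)
    sites = classify_sites(cleaned)
    ka, ks, kaks = gene_kaks(cleaned)
    return GeneDivergenceStats(
        gene=cleaned.gene,
        length_bp=cleaned.length,
        pct_AT=pct_at,
        at_skew=at_sk,
        gc_skew=gc_sk,
        sites=sites,
        ts_tv=ts_tv_ratio(cleaned),
        Ks=ks,
        Ka=ka,
        ka_ks=kaks,
        aupd=aupd(cleaned),
    )


def gene_divergence_table(
    alignments: dict[str, CodonAlignment],
    already_clean: bool = False,
    composition_on: str = "cleaned",
) -> pd.DataFrame:
    """Per-gene divergence summary (one row per gene) plus min/max attrs.

    Columns: cleaned length, mean per-taxon composition on the coding strand,
    %Vs / %Pis / %S site percentages, pooled ts/tv, gene-level Ks, Ka, Ka/Ks
    and the mean uncorrected pairwise distance (Aupd).
    """
    rows = []
    for gene, aln in alignments.items():
        st = gene_divergence(
            aln, already_clean=already_clean, composition_on=composition_on
        )
        rows.append(
            {
                "gene": gene, "length_bp": st.length_bp, "pct_AT": st.pct_AT,
                "at_skew": st.at_skew, "gc_skew": st.gc_skew,
                "pct_Vs": st.sites.pct_Vs, "pct_Pis": st.sites.pct_Pis,
                "pct_S": st.sites.pct_S, "ts_tv": st.ts_tv,
                "Ks": st.Ks, "Ka": st.Ka, "ka_ks": st.ka_ks, "aupd": st.aupd,
            }
        )
    df = pd.DataFrame(rows)
    if not df.empty and df["ka_ks"].notna().any():
        df.attrs["max_ka_ks_gene"] = df.loc[df["ka_ks"].idxmax(), "gene"]
        df.attrs["min_ka_ks_gene"] = df.loc[df["ka_ks"].idxmin(), "gene"]
    return df
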