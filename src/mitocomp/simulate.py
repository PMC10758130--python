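"""Mitogenome simulator: known architecture, known tree, known parameters.

Generates an ancestral annotated mitogenome with the architecture typical of
avian mitochondria — 37 genes (13 PCGs, 22 tRNAs, 2 rRNAs) plus one control
region, with ND6 and eight tRNAs on the minus strand — and evolves it along
a user-supplied tree under a codon model for PCGs (transition:transversion
rate ratio ``kappa``, per-gene nonsynonymous/synonymous rate ratio ``omega``,
stop codons forbidden) and a two-parameter nucleotide model for RNA genes,
spacers and the control region.

Branch lengths are in expected substitutions per nucleotide site; per gene,
substitution rates are normalized by the ancestral mean rate per site, so a
branch of length *b* produces about *b* substitutions/site in the neutral
nucleotide model and proportionally fewer in constrained codon models.
Substitutions are realized with exponential waiting times (Gillespie), which
is exact under the model and fast at the ~17 kb scale.

Everything is deterministic given the configuration seed; there is no global
random state.
"""

from __future__ import annotations

import dataclasses
import json
import pathlib
from dataclasses import dataclass, field

import dendropy
import numpy as np

from .codon_usage import CODON_TO_AA, STOP_CODONS
from .genome_io import (
    GeneFeature,
    MitoGenomeRecord,
    reverse_complement,
    write_genbank,
)

__all__ = [
    "GENOME_ARCHITECTURE",
    "DEFAULT_OMEGA",
    "SimulationConfig",
    "FixtureBundle",
    "make_ancestor",
    "evolve",
    "fixture_set",
    "simulate_cds_alignment",
    "simulate_neutral_alignment",
]

_BASES = "ACGT"
_TS_PARTNER = {"A": "G", "G": "A", "C": "T", "T": "C"}

#: CDS length in bp per protein-coding gene (start codon through terminal
#: stop; genes listed in ``DEFAULT_INCOMPLETE_STOPS`` instead end in a 1-nt
#: incomplete stop, hence length % 3 == 1).
PCG_CDS_LENGTHS: dict[str, int] = {
    "ND1": 978, "ND2": 1039, "COI": 1551, "COII": 684, "ATP8": 168,
    "ATP6": 684, "COIII": 784, "ND3": 351, "ND4L": 297, "ND4": 1375,
    "ND5": 1815, "Cyt b": 1113, "ND6": 516,
}

DEFAULT_INCOMPLETE_STOPS = ("ND2", "COIII", "ND4")

#: (name, ftype, strand) in genome order; ND6 plus eight tRNAs on the minus
#: strand, control region last (avian arrangement).
GENOME_ARCHITECTURE: tuple[tuple[str, str, str], ...] = (
    ("tRNA-Phe", "tRNA", "+"), ("12S", "rRNA", "+"), ("tRNA-Val", "tRNA", "+"),
    ("16S", "rRNA", "+"), ("tRNA-Leu(UUR)", "tRNA", "+"), ("ND1", "PCG", "+"),
    ("tRNA-Ile", "tRNA", "+"), ("tRNA-Gln", "tRNA", "-"),
    ("tRNA-Met", "tRNA", "+"), ("ND2", "PCG", "+"), ("tRNA-Trp", "tRNA", "+"),
    ("tRNA-Ala", "tRNA", "-"), ("tRNA-Asn", "tRNA", "-"),
    ("tRNA-Cys", "tRNA", "-"), ("tRNA-Tyr", "tRNA", "-"), ("COI", "PCG", "+"),
    ("tRNA-Ser(UCN)", "tRNA", "-"), ("tRNA-Asp", "tRNA", "+"),
    ("COII", "PCG", "+"), ("tRNA-Lys", "tRNA", "+"), ("ATP8", "PCG", "+"),
    ("ATP6", "PCG", "+"), ("COIII", "PCG", "+"), ("tRNA-Gly", "tRNA", "+"),
    ("ND3", "PCG", "+"), ("tRNA-Arg", "tRNA", "+"), ("ND4L", "PCG", "+"),
    ("ND4", "PCG", "+"), ("tRNA-His", "tRNA", "+"),
    ("tRNA-Ser(AGY)", "tRNA", "+"), ("tRNA-Leu(CUN)", "tRNA", "+"),
    ("ND5", "PCG", "+"), ("Cyt b", "PCG", "+"), ("tRNA-Thr", "tRNA", "+"),
    ("tRNA-Pro", "tRNA", "-"), ("ND6", "PCG", "-"), ("tRNA-Glu", "tRNA", "-"),
    ("CR", "CR", "+"),
)

#: Default per-gene dN/dS, heterogeneous in the pattern seen in shorebird
#: mitogenomes: COI and COIII most constrained, ATP8 least.
DEFAULT_OMEGA: dict[str, float] = {
    "ND1": 0.03, "ND2": 0.09, "COI": 0.02, "COII": 0.04, "ATP8": 0.16,
    "ATP6": 0.06, "COIII": 0.02, "ND3": 0.08, "ND4L": 0.05, "ND4": 0.09,
    "ND5": 0.10, "Cyt b": 0.05, "ND6": 0.12,
}

#: 12-tip tree of published shape used for the bundled fixture data set.
FIXTURE_TREE = (
    "((((sim_sp01:0.02,sim_sp02:0.02):0.015,(sim_sp03:0.025,sim_sp04:0.02)"
    ":0.01):0.02,((sim_sp05:0.03,sim_sp06:0.025):0.015,(sim_sp07:0.02,"
    "sim_sp08:0.03):0.02):0.015):0.02,((sim_sp09:0.03,sim_sp10:0.025):0.02,"
    "(sim_sp11:0.035,sim_sp12:0.03):0.015):0.02);"
)


@dataclass
class SimulationConfig:
    """All parameters of one simulation run.

    ``pct_at``, ``at_skew`` and ``gc_skew`` set the target whole-genome
    composition on the deposited (plus) strand; ``omega`` maps each PCG to
    its dN/dS; ``kappa`` is the transition:transversion rate ratio shared by
    all genes; ``spacers`` maps a gene name to the intergenic gap inserted
    after it.  Defaults emulate an AT-rich shorebird mitogenome with positive
    AT skew, negative GC skew and strong purifying selection.
    """

    tree: str = FIXTURE_TREE
    omega: dict[str, float] = field(default_factory=lambda: dict(DEFAULT_OMEGA))
    kappa: float = 8.0
    pct_at: float = 55.0
    at_skew: float = 0.14
    gc_skew: float = -0.38
    cr_length: int = 1325
    trna_length: int = 70
    rrna_lengths: dict[str, int] = field(
        default_factory=lambda: {"12S": 975, "16S": 1590}
    )
    spacers: dict[str, int] = field(
        default_factory=lambda: {"tRNA-Tyr": 23, "tRNA-Asn": 5}
    )
    incomplete_stop_genes: tuple[str, ...] = DEFAULT_INCOMPLETE_STOPS
    start_codons: dict[str, str] = field(
        default_factory=lambda: {"COI": "GTG", "ND3": "ATC", "ND5": "GTG"}
    )
    seed: int = 0

    def __post_init__(self) -> None:
        if self.kappa <= 0:
            raise ValueError("kappa must be > 0")
        for gene, w in self.omega.items():
            if w < 0:
                raise ValueError(f"omega must be >= 0 (gene {gene})")
        f = self.base_frequencies()
        if any(v <= 0 for v in f.values()):
            raise ValueError("composition targets imply a non-positive base frequency")

    def base_frequencies(self) -> dict[str, float]:
        """Plus-strand base frequencies implied by AT% and the two skews."""
        at = self.pct_at / 100.0
        gc = 1.0 - at
        a = at * (1.0 + self.at_skew) / 2.0
        g = gc * (1.0 + self.gc_skew) / 2.0
        return {"A": a, "T": at - a, "G": g, "C": gc - g}


# ---------------------------------------------------------------------------
# Ancestor construction
# ---------------------------------------------------------------------------

_SENSE = tuple(sorted(CODON_TO_AA))


def _codon_distribution(freqs: dict[str, float]) -> tuple[np.ndarray, tuple[str, ...]]:
    w = np.array(
        [freqs[c[0]] * freqs[c[1]] * freqs[c[2]] for c in _SENSE], dtype=float
    )
    return w / w.sum(), _SENSE


def _mirror(freqs: dict[str, float]) -> dict[str, float]:
    """Frequencies whose reverse complement realizes ``freqs``."""
    return {"A": freqs["T"], "T": freqs["A"], "G": freqs["C"], "C": freqs["G"]}


def _draw_bases(rng: np.random.Generator, freqs: dict[str, float], n: int) -> str:
    p = np.array([freqs[b] for b in _BASES])
    return "".join(np.array(list(_BASES))[rng.choice(4, size=n, p=p / p.sum())])


def _conditional_codon_composition(freqs: dict[str, float]) -> dict[str, float]:
    """Per-base composition of codons drawn from ``freqs`` given no stop."""
    probs, codons = _codon_distribution(freqs)
    counts = {b: 0.0 for b in _BASES}
    for p, c in zip(probs, codons):
        for b in c:
            counts[b] += p
    total = sum(counts.values())
    return {b: v / total for b, v in counts.items()}


def _calibrated_frequencies(config: SimulationConfig) -> dict[str, float]:
    """Sampling frequencies whose realized whole-genome composition hits target.

    Excluding stop codons while drawing PCG bodies biases the realized
    composition away from the raw target frequencies (PCGs are ~2/3 of the
    genome), so the plus-strand sampling distribution is adjusted by a short
    multiplicative fixed-point iteration.  Non-PCG blocks contribute the
    sampling frequencies unchanged (a minus-strand block drawn from mirrored
    frequencies reverse-complements back onto them).
    """
    target = config.base_frequencies()
    w_pcg_plus = sum(
        v for g, v in PCG_CDS_LENGTHS.items() if g != "ND6"
    )
    w_pcg_minus = PCG_CDS_LENGTHS["ND6"]
    total_len = (
        sum(PCG_CDS_LENGTHS.values())
        + 22 * config.trna_length
        + sum(config.rrna_lengths.values())
        + config.cr_length
        + sum(config.spacers.values())
    )
    w_other = total_len - w_pcg_plus - w_pcg_minus
    pi = dict(target)
    for _ in range(200):
        g_plus = _conditional_codon_composition(pi)
        g_minus = _mirror(_conditional_codon_composition(_mirror(pi)))
        realized = {
            b: (
                w_other * pi[b]
                + w_pcg_plus * g_plus[b]
                + w_pcg_minus * g_minus[b]
            )
            / total_len
            for b in _BASES
        }
        pi = {b: pi[b] * target[b] / realized[b] for b in _BASES}
        s = sum(pi.values())
        pi = {b: v / s for b, v in pi.items()}
    return pi


def _draw_cds(
    rng: np.random.Generator,
    gene: str,
    freqs: dict[str, float],
    config: SimulationConfig,
) -> str:
    length = PCG_CDS_LENGTHS[gene]
    start = config.start_codons.get(gene, "ATG")
    incomplete = gene in config.incomplete_stop_genes
    tail = "T" if incomplete else "TAA"
    n_body = (length - len(start) - len(tail)) // 3
    probs, codons = _codon_distribution(freqs)
    idx = rng.choice(len(codons), size=n_body, p=probs)
    return start + "".join(codons[i] for i in idx) + tail


def make_ancestor(config: SimulationConfig) -> MitoGenomeRecord:
    """Build a random ancestral mitogenome honoring the configuration.

    PCGs begin with their configured start codon, contain no internal stop
    codon, and end with TAA or (for the designated genes) a 1-nt incomplete
    stop.  Deterministic for a fixed seed.
    """
    rng = np.random.default_rng(config.seed)
    freqs = _calibrated_frequencies(config)
    blocks: list[str] = []
    features: list[GeneFeature] = []
    pos = 0
    for name, ftype, strand in GENOME_ARCHITECTURE:
        f = freqs if strand == "+" else _mirror(freqs)
        if ftype == "PCG":
            coding = _draw_cds(rng, name, f, config)
        elif ftype == "tRNA":
            coding = _draw_bases(rng, f, config.trna_length)
        elif ftype == "rRNA":
            coding = _draw_bases(rng, f, config.rrna_lengths[name])
        else:  # CR
            coding = _draw_bases(rng, f, config.cr_length)
        plus = coding if strand == "+" else reverse_complement(coding)
        blocks.append(plus)
        features.append(
            GeneFeature(
                name=name, ftype=ftype, start=pos + 1, end=pos + len(plus),
                strand=strand, codon_start=1 if ftype == "PCG" else None,
            )
        )
        pos += len(plus)
        gap = config.spacers.get(name, 0)
        if gap:
            blocks.append(_draw_bases(rng, freqs, gap))
            pos += gap
    sequence = "".join(blocks)
    if not 15000 <= len(sequence) <= 18000:
        raise ValueError(
            f"configured lengths give an implausible genome of {len(sequence)} bp"
        )
    return MitoGenomeRecord(
        accession="SIMANC1",
        organism="synthetic ancestor",
        sequence=sequence,
        is_circular=True,
        features=features,
    )


# ---------------------------------------------------------------------------
# Evolution along a tree
# ---------------------------------------------------------------------------

_CODON_IDX = {c: i for i, c in enumerate(_SENSE)}

# neighbor tables: for each sense codon, the single-nucleotide mutations that
# do not create a stop:
# (target codon index, target base index, is_transition, is_synonymous)
_NEIGHBORS: list[list[tuple[int, int, bool, bool]]] = []
for _c in _SENSE:
    _nbrs = []
    for _p in range(3):
        for _b in _BASES:
            if _b == _c[_p]:
                continue
            _m = _c[:_p] + _b + _c[_p + 1 :]
            if _m in STOP_CODONS:
                continue
            _nbrs.append(
                (_CODON_IDX[_m], _BASES.index(_b), _TS_PARTNER[_c[_p]] == _b,
                 CODON_TO_AA[_m] == CODON_TO_AA[_c])
            )
    _NEIGHBORS.append(_nbrs)

_rate_cache: dict[tuple, tuple[np.ndarray, list[np.ndarray]]] = {}


def _freq_key(freqs: dict[str, float]) -> tuple[float, ...]:
    return tuple(round(freqs[b], 12) for b in _BASES)


def _codon_rates(omega: float, kappa: float, freqs: dict[str, float]):
    """Per-codon total rates and per-neighbor rate vectors.

    HKY-style parameterization: the rate of a change is proportional to the
    equilibrium frequency of the target base, times ``kappa`` for
    transitions, times ``omega`` for amino-acid-changing substitutions, so
    the configured composition is (approximately) stationary under
    evolution instead of eroding toward uniformity.
    """
    key = (omega, kappa, _freq_key(freqs))
    if key not in _rate_cache:
        pi = [freqs[b] for b in _BASES]
        per_neighbor: list[np.ndarray] = []
        totals = np.zeros(len(_SENSE))
        for i, nbrs in enumerate(_NEIGHBORS):
            rates = np.array(
                [
                    pi[tb] * (kappa if is_ts else 1.0) * (1.0 if is_syn else omega)
                    for (_t, tb, is_ts, is_syn) in nbrs
                ]
            )
            per_neighbor.append(rates)
            totals[i] = rates.sum()
        _rate_cache[key] = (totals, per_neighbor)
    return _rate_cache[key]


def _evolve_codons(
    codons: np.ndarray,
    branch_length: float,
    omega: float,
    kappa: float,
    freqs: dict[str, float],
    nu: float,
    rng: np.random.Generator,
) -> np.ndarray:
    """Gillespie simulation of the codon model along one branch (in place copy)."""
    totals, per_neighbor = _codon_rates(omega, kappa, freqs)
    seq = codons.copy()
    rates = totals[seq]
    q = rates.sum()
    t = 0.0
    while q > 0:
        t += rng.exponential(nu / q)
        if t >= branch_length:
            break
        cum = np.cumsum(rates)
        i = int(np.searchsorted(cum, rng.random() * cum[-1], side="right"))
        nbr_rates = per_neighbor[seq[i]]
        j = int(
            np.searchsorted(
                np.cumsum(nbr_rates), rng.random() * nbr_rates.sum(), side="right"
            )
        )
        seq[i] = _NEIGHBORS[seq[i]][j][0]
        rates[i] = totals[seq[i]]
        q = rates.sum()
    return seq


def _nucleotide_rates(kappa: float, freqs: dict[str, float]):
    """4x4 HKY rate matrix (zero diagonal) and per-state total rates."""
    key = ("nt", kappa, _freq_key(freqs))
    if key not in _rate_cache:
        pi = np.array([freqs[b] for b in _BASES])
        ts_target = np.array([2, 3, 0, 1])  # A<->G, C<->T on alphabet ACGT
        rates = np.zeros((4, 4))
        for i in range(4):
            for j in range(4):
                if i == j:
                    continue
                rates[i, j] = pi[j] * (kappa if ts_target[i] == j else 1.0)
        _rate_cache[key] = (rates.sum(axis=1), [rates[i] for i in range(4)])
    return _rate_cache[key]


def _evolve_nucleotides(
    seq: np.ndarray,
    branch_length: float,
    kappa: float,
    freqs: dict[str, float],
    rng: np.random.Generator,
) -> np.ndarray:
    """HKY-style nucleotide Gillespie, normalized to the stationary flux.

    Rates are scaled so one unit of branch length yields about one expected
    substitution per site at equilibrium; the configured composition is the
    stationary distribution, so skew and AT-richness persist along the tree.
    """
    totals, per_state = _nucleotide_rates(kappa, freqs)
    out = seq.copy()
    n = len(out)
    if n == 0 or branch_length <= 0:
        return out
    pi = np.array([freqs[b] for b in _BASES])
    nu = float((pi * totals).sum())  # stationary per-site substitution flux
    rates = totals[out]
    q = rates.sum()
    t = 0.0
    while q > 0:
        t += rng.exponential(nu / q)
        if t >= branch_length:
            break
        cum = np.cumsum(rates)
        i = int(np.searchsorted(cum, rng.random() * cum[-1], side="right"))
        row = per_state[out[i]]
        j = int(
            np.searchsorted(np.cumsum(row), rng.random() * row.sum(), side="right")
        )
        out[i] = j  # the zero-width diagonal entry can never be drawn
        rates[i] = totals[j]
        q = rates.sum()
    return out


@dataclass
class _Block:
    name: str | None  # None for intergenic spacers
    ftype: str | None
    strand: str
    head: str  # fixed prefix of a PCG (start codon)
    codons: np.ndarray | None  # PCG body as sense-codon indices
    tail: str  # fixed suffix of a PCG (stop codon / incomplete stop)
    bases: np.ndarray | None  # non-PCG payload as base indices

    def coding_sequence(self) -> str:
        if self.codons is not None:
            return self.head + "".join(_SENSE[i] for i in self.codons) + self.tail
        return "".join(_BASES[i] for i in self.bases)


def _decompose(record: MitoGenomeRecord) -> list[_Block]:
    """Split a record into evolvable blocks in genome order."""
    feats = sorted(record.features, key=lambda f: f.start)
    blocks: list[_Block] = []
    pos = 0
    for f in feats:
        if f.start - 1 > pos:
            gap = record.sequence[pos : f.start - 1]
            blocks.append(
                _Block(None, None, "+", "", None, "",
                       np.array([_BASES.index(b) for b in gap]))
            )
        raw = record.sequence[f.start - 1 : f.end]
        coding = raw if f.strand == "+" else reverse_complement(raw)
        if f.ftype == "PCG":
            head = coding[:3]
            n_rem = (len(coding) - 3) % 3
            tail_len = 3 if n_rem == 0 else n_rem
            tail = coding[len(coding) - tail_len :]
            body = coding[3 : len(coding) - tail_len]
            codons = np.array(
                [_CODON_IDX[body[i : i + 3]] for i in range(0, len(body), 3)],
                dtype=np.int64,
            )
            blocks.append(_Block(f.name, f.ftype, f.strand, head, codons, tail, None))
        else:
            blocks.append(
                _Block(f.name, f.ftype, f.strand, "", None, "",
                       np.array([_BASES.index(b) for b in coding]))
            )
        pos = f.end
    if pos < record.length_bp:
        gap = record.sequence[pos:]
        blocks.append(
            _Block(None, None, "+", "", None, "",
                   np.array([_BASES.index(b) for b in gap]))
        )
    return blocks


def _reassemble(
    blocks: list[_Block], template: MitoGenomeRecord, label: str
) -> MitoGenomeRecord:
    parts = []
    for b in blocks:
        coding = b.coding_sequence()
        parts.append(coding if b.strand == "+" else reverse_complement(coding))
    return MitoGenomeRecord(
        accession=label,
        organism=label,
        sequence="".join(parts),
        is_circular=template.is_circular,
        features=list(template.features),
    )


def evolve(
    ancestor: MitoGenomeRecord, config: SimulationConfig
) -> dict[str, MitoGenomeRecord]:
    """Evolve the ancestor along ``config.tree``; returns tip label -> record.

    Gene content, order, strands and lengths are invariant (the model has no
    indels or rearrangements); PCG start codons and terminal stops are held
    fixed, body codons evolve under the per-gene omega; everything else
    evolves neutrally.  Reproducible for a fixed seed.
    """
    tree = dendropy.Tree.get(
        data=config.tree, schema="newick", preserve_underscores=True
    )
    tips = tree.leaf_nodes()
    if len(tips) < 2:
        raise ValueError("tree must have at least 2 tips")
    for edge in tree.preorder_edge_iter():
        if edge.length is not None and edge.length < 0:
            raise ValueError("negative branch lengths are not allowed")
    rng = np.random.default_rng(np.random.SeedSequence([config.seed, 7919]))
    root_blocks = _decompose(ancestor)
    omega = dict(DEFAULT_OMEGA)
    omega.update(config.omega)
    pi_plus = config.base_frequencies()
    pi_minus = _mirror(pi_plus)

    def block_freqs(b: "_Block") -> dict[str, float]:
        return pi_plus if b.strand == "+" else pi_minus

    # per-PCG rate normalization from the ancestral sequence
    nu: dict[int, float] = {}
    for bi, b in enumerate(root_blocks):
        if b.codons is not None and len(b.codons):
            totals, _ = _codon_rates(
                omega.get(b.name, 0.1), config.kappa, block_freqs(b)
            )
            nu[bi] = totals[b.codons].sum() / (3.0 * len(b.codons))

    out: dict[str, MitoGenomeRecord] = {}

    def _descend(node, blocks: list[_Block]) -> None:
        for child in node.child_nodes():
            bl = child.edge.length or 0.0
            child_blocks: list[_Block] = []
            for bi, b in enumerate(blocks):
                if b.codons is not None:
                    if len(b.codons) and bl > 0:
                        codons = _evolve_codons(
                            b.codons, bl, omega.get(b.name, 0.1),
                            config.kappa, block_freqs(b), nu[bi], rng,
                        )
                    else:
                        codons = b.codons.copy()
                    child_blocks.append(dataclasses.replace(b, codons=codons))
                else:
                    bases = _evolve_nucleotides(
                        b.bases, bl, config.kappa, block_freqs(b), rng
                    )
                    child_blocks.append(dataclasses.replace(b, bases=bases))
            if child.is_leaf():
                label = child.taxon.label
                out[label] = _reassemble(child_blocks, ancestor, label)
            else:
                _descend(child, child_blocks)

    _descend(tree.seed_node, root_blocks)
    return out


# ---------------------------------------------------------------------------
# Single-locus simulators (parameter-recovery and tree-inference harnesses)
# ---------------------------------------------------------------------------

def _tip_sequences(tree_text: str, root, branch_fn, rng) -> dict[str, np.ndarray]:
    tree = dendropy.Tree.get(
        data=tree_text, schema="newick", preserve_underscores=True
    )
    out: dict[str, np.ndarray] = {}

    def _descend(node, seq):
        for child in node.child_nodes():
            child_seq = branch_fn(seq, child.edge.length or 0.0, rng)
            if child.is_leaf():
                out[child.taxon.label] = child_seq
            else:
                _descend(child, child_seq)

    _descend(tree.seed_node, root)
    return out


def simulate_cds_alignment(
    tree: str,
    n_codons: int,
    omega: float,
    kappa: float = 8.0,
    freqs: dict[str, float] | None = None,
    seed: int = 0,
    gene: str = "sim",
) -> "CodonAlignment":
    """Evolve one protein-coding locus along a tree; returns the alignment.

    The ancestral sequence is ``n_codons`` sense codons drawn from the base
    frequencies (stop codons excluded); evolution follows the same codon
    model as :func:`evolve`.  Because the model has no indels the tip
    sequences are an alignment by construction.
    """
    from .divergence import CodonAlignment

    rng = np.random.default_rng(seed)
    if freqs is None:
        freqs = SimulationConfig().base_frequencies()
    probs, _codons = _codon_distribution(freqs)
    root = rng.choice(len(_SENSE), size=n_codons, p=probs)
    totals, _ = _codon_rates(omega, kappa, freqs)
    nu = totals[root].sum() / (3.0 * n_codons)

    def branch(seq, bl, rng):
        if bl <= 0:
            return seq.copy()
        return _evolve_codons(seq, bl, omega, kappa, freqs, nu, rng)

    tips = _tip_sequences(tree, root, branch, rng)
    labels = sorted(tips)
    rows = ["".join(_SENSE[i] for i in tips[t]) for t in labels]
    return CodonAlignment(gene, labels, rows)


def simulate_neutral_alignment(
    tree: str,
    length: int,
    kappa: float = 8.0,
    freqs: dict[str, float] | None = None,
    seed: int = 0,
) -> tuple[list[str], list[str]]:
    """Neutral nucleotide locus along a tree: (labels, aligned rows)."""
    rng = np.random.default_rng(seed)
    if freqs is None:
        freqs = SimulationConfig().base_frequencies()
    p = np.array([freqs[b] for b in _BASES])
    root = rng.choice(4, size=length, p=p / p.sum())

    def branch(seq, bl, rng):
        return _evolve_nucleotides(seq, bl, kappa, freqs, rng)

    tips = _tip_sequences(tree, root, branch, rng)
    labels = sorted(tips)
    rows = ["".join(_BASES[i] for i in tips[t]) for t in labels]
    return labels, rows


# ---------------------------------------------------------------------------
# Bundled fixture data set
# ---------------------------------------------------------------------------

@dataclass
class FixtureBundle:
    """A small simulated comparative data set with its ground truth."""

    ancestor: MitoGenomeRecord
    records: dict[str, MitoGenomeRecord]
    config: SimulationConfig
    truth: dict


def fixture_set(seed: int = 0, out_dir: str | pathlib.Path | None = None) -> FixtureBundle:
    """Deterministically regenerate the 12-genome fixture bundle.

    Twelve tips on a fixed published-shape tree, evolved from one ancestor
    under the default heterogeneous-omega configuration.  Every ground-truth
    quantity (composition targets, spacer profile, per-gene omega, the true
    tree) is carried in ``truth`` and, when ``out_dir`` is given, written to
    ``truth.json`` next to one GenBank flat file per genome.
    """
    config = SimulationConfig(seed=seed)
    ancestor = make_ancestor(config)
    records = evolve(ancestor, config)
    truth = {
        "tree": config.tree,
        "omega": dict(sorted(config.omega.items())),
        "kappa": config.kappa,
        "pct_at": config.pct_at,
        "at_skew": config.at_skew,
        "gc_skew": config.gc_skew,
        "spacers": dict(config.spacers),
        "gene_order": [(n, s) for n, _t, s in GENOME_ARCHITECTURE],
        "seed": seed,
    }
    bundle = FixtureBundle(ancestor, records, config, truth)
    if out_dir is not None:
        out = pathlib.Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        for label, rec in sorted(records.items()):
            (out / f"{label}.gb").write_text(write_genbank(rec))
        (out / "truth.json").write_text(json.dumps(truth, indent=2))
    return bundle
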