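"""Supermatrix assembly, phylogenetics file exports and distance-tree tests.

Builds concatenated multi-gene matrices with partition tables, writes the
standard inference inputs (relaxed PHYLIP, NEXUS with a SETS/charset block,
RAxML-style partition files), computes neighbor-joining trees from distance
matrices with a deterministic tie-break, and answers topology questions
(monophyly under outgroup rooting, Robinson-Foulds bipartition distance).

Bayesian/ML inference engines are deliberately out of scope: their input
files are exported, and topology claims are exercised in-repo with NJ on
p- or Jukes-Cantor distances plus explicit hypothesis trees.

Trees are represented as :class:`dendropy.Tree`; any function accepting a
tree also accepts a Newick string.
"""

from __future__ import annotations

import itertools
import math
import re
from dataclasses import dataclass

import dendropy
import numpy as np
import pandas as pd
from dendropy.calculate import treecompare

from .divergence import CodonAlignment, p_distance
from .genome_io import PCG_NAMES, RRNA_NAMES

__all__ = [
    "ConcatenatedMatrix",
    "DEFAULT_GENE_ORDER",
    "concatenate",
    "export",
    "export_phylip",
    "export_nexus",
    "export_raxml_partitions",
    "import_nexus",
    "sanitize_labels",
    "p_distance_matrix",
    "jc_distance_matrix",
    "nj_tree",
    "as_tree",
    "is_monophyletic",
    "robinson_foulds",
]

#: Fixed concatenation order: the 13 PCGs in canonical genome order, then the
#: two rRNAs, then anything else alphabetically.
DEFAULT_GENE_ORDER: tuple[str, ...] = PCG_NAMES + RRNA_NAMES


@dataclass
class ConcatenatedMatrix:
    """Multi-gene supermatrix with 1-based inclusive partition boundaries."""

    taxa: list[str]
    rows: list[str]
    partitions: list[tuple[str, int, int]]

    def __post_init__(self) -> None:
        if len(self.taxa) != len(self.rows):
            raise ValueError("taxa and rows must have equal length")
        if len(set(self.taxa)) != len(self.taxa):
            raise ValueError("duplicate taxon labels")
        lengths = {len(r) for r in self.rows}
        if len(lengths) > 1:
            raise ValueError("rows have unequal lengths")
        expected = 1
        for name, start, end in self.partitions:
            if start != expected or end < start:
                raise ValueError(
                    f"partition {name} ({start}-{end}) breaks the tiling at "
                    f"{expected}"
                )
            expected = end + 1
        if self.partitions and self.rows and expected != len(self.rows[0]) + 1:
            raise ValueError("partitions do not tile the full matrix length")

    @property
    def length(self) -> int:
        return len(self.rows[0]) if self.rows else 0


def concatenate(
    gene_alignments: dict[str, CodonAlignment],
    taxa: list[str] | None = None,
    order: tuple[str, ...] = DEFAULT_GENE_ORDER,
) -> ConcatenatedMatrix:
    """Concatenate gene alignments into a supermatrix with partitions.

    Genes are concatenated in the fixed ``order`` (genes absent from it are
    appended alphabetically), so the result is independent of the input
    mapping's iteration order.  A taxon missing from a gene gets a ``?``
    block for that partition; a taxon present in no gene is an error.
    """
    names = [g for g in order if g in gene_alignments]
    names += sorted(g for g in gene_alignments if g not in order)
    if taxa is None:
        seen: list[str] = []
        for g in names:
            for t in gene_alignments[g].taxa:
                if t not in seen:
                    seen.append(t)
        taxa = seen
    for t in taxa:
        if not any(t in gene_alignments[g].taxa for g in names):
            raise ValueError(f"taxon {t!r} present in no gene alignment")
    rows = {t: [] for t in taxa}
    partitions: list[tuple[str, int, int]] = []
    pos = 1
    for g in names:
        aln = gene_alignments[g]
        idx = {t: i for i, t in enumerate(aln.taxa)}
        for t in taxa:
            rows[t].append(aln.rows[idx[t]] if t in idx else "?" * aln.length)
        partitions.append((g, pos, pos + aln.length - 1))
        pos += aln.length
    return ConcatenatedMatrix(
        taxa=list(taxa), rows=["".join(rows[t]) for t in taxa],
        partitions=partitions,
    )


# ---------------------------------------------------------------------------
# Exports
# ---------------------------------------------------------------------------

def sanitize_labels(labels: list[str]) -> tuple[list[str], dict[str, str]]:
    """Replace whitespace and format-hostile characters; return the mapping."""
    clean: list[str] = []
    mapping: dict[str, str] = {}
    for lab in labels:
        c = re.sub(r"[\s;:,()\[\]']+", "_", lab.strip())
        base, k = c, 2
        while c in clean:
            c = f"{base}_{k}"
            k += 1
        clean.append(c)
        mapping[lab] = c
    return clean, mapping


def export_phylip(matrix: ConcatenatedMatrix) -> str:
    """Relaxed PHYLIP: header line then one ``label<TAB>sequence`` per taxon."""
    clean, _ = sanitize_labels(matrix.taxa)
    lines = [f" {len(matrix.taxa)} {matrix.length}"]
    lines += [f"{lab}\t{row}" for lab, row in zip(clean, matrix.rows)]
    return "\n".join(lines) + "\n"


def export_nexus(matrix: ConcatenatedMatrix) -> str:
    """NEXUS with a DATA block and a SETS block of per-gene charsets."""
    clean, _ = sanitize_labels(matrix.taxa)
    width = max(len(c) for c in clean) + 2
    lines = [
        "#NEXUS",
        "BEGIN DATA;",
        f"    DIMENSIONS NTAX={len(matrix.taxa)} NCHAR={matrix.length};",
        "    FORMAT DATATYPE=DNA MISSING=? GAP=-;",
        "    MATRIX",
    ]
    lines += [f"    {lab.ljust(width)}{row}" for lab, row in zip(clean, matrix.rows)]
    lines += ["    ;", "END;"]
    if matrix.partitions:
        lines.append("BEGIN SETS;")
        for name, start, end in matrix.partitions:
            cname = re.sub(r"\W", "_", name)
            lines.append(f"    CHARSET {cname} = {start}-{end};")
        lines.append("END;")
    return "\n".join(lines) + "\n"


def export_raxml_partitions(matrix: ConcatenatedMatrix) -> str:
    """RAxML-style partition file: one ``DNA, name = start-end`` line per gene."""
    lines = [
        f"DNA, {re.sub(r'[^A-Za-z0-9_]', '_', name)} = {start}-{end}"
        for name, start, end in matrix.partitions
    ]
    return "\n".join(lines) + "\n"


_EXPORTERS = {
    "phylip": export_phylip,
    "nexus": export_nexus,
    "raxml": export_raxml_partitions,
}


def export(matrix: ConcatenatedMatrix, format: str) -> str:
    """Dispatch to one of the exporters: 'phylip', 'nexus' or 'raxml'."""
    try:
        return _EXPORTERS[format](matrix)
    except KeyError:
        raise ValueError(
            f"unknown format {format!r}; choose from {sorted(_EXPORTERS)}"
        ) from None


def import_nexus(text: str) -> ConcatenatedMatrix:
    """Parse a NEXUS DATA (+ SETS) file back into a :class:`ConcatenatedMatrix`.

    Labels are re-sanitized on import (NEXUS readers map underscores to
    spaces), so export -> import is the identity on sanitized matrices.
    """
    dcm = dendropy.DnaCharacterMatrix.get(data=text, schema="nexus")
    taxa = [t.label for t in dcm.taxon_namespace]
    clean, _ = sanitize_labels(taxa)
    rows = [str(dcm[t]).upper() for t in dcm.taxon_namespace]
    partitions: list[tuple[str, int, int]] = []
    for name, subset in dcm.character_subsets.items():
        idx = sorted(subset.character_indices)
        partitions.append((name, idx[0] + 1, idx[-1] + 1))
    partitions.sort(key=lambda p: p[1])
    return ConcatenatedMatrix(taxa=clean, rows=rows, partitions=partitions)


# ---------------------------------------------------------------------------
# Distance matrices
# ---------------------------------------------------------------------------

def p_distance_matrix(taxa: list[str], rows: list[str]) -> pd.DataFrame:
    """Symmetric matrix of uncorrected p-distances (pairwise deletion)."""
    n = len(taxa)
    d = np.zeros((n, n))
    for i, j in itertools.combinations(range(n), 2):
        pij = p_distance(rows[i], rows[j])
        d[i, j] = d[j, i] = math.nan if pij is None else pij
    return pd.DataFrame(d, index=taxa, columns=taxa)


def jc_distance_matrix(taxa: list[str], rows: list[str]) -> pd.DataFrame:
    """Jukes-Cantor corrected distances; NaN where p >= 3/4."""
    pm = p_distance_matrix(taxa, rows)
    with np.errstate(invalid="ignore"):
        corrected = -0.75 * np.log(1.0 - 4.0 * pm.values / 3.0)
    np.fill_diagonal(corrected, 0.0)
    return pd.DataFrame(corrected, index=taxa, columns=taxa)


# ---------------------------------------------------------------------------
# Neighbor joining
# ---------------------------------------------------------------------------

def nj_tree(distances: pd.DataFrame) -> dendropy.Tree:
    """Saitou-Nei neighbor joining with a deterministic tie-break.

    ``distances`` must be symmetric with a zero diagonal and no negative
    entries, labels on the index.  At each step the pair minimizing the Q
    criterion is joined; exact ties are broken by the lexicographically
    smallest pair of cluster representatives (the minimal leaf label in each
    cluster).  The result is an unrooted tree whose seed node has degree 3.
    """
    labels = [str(x) for x in distances.index]
    d = distances.values.astype(float)
    n = len(labels)
    if n < 3:
        raise ValueError("neighbor joining needs at least 3 taxa")
    if distances.shape[0] != distances.shape[1]:
        raise ValueError("distance matrix must be square")
    if not np.allclose(d, d.T, atol=1e-12):
        raise ValueError("distance matrix must be symmetric")
    if np.any(np.diag(d) != 0):
        raise ValueError("distance matrix diagonal must be zero")
    if np.any(d < 0):
        raise ValueError("negative input distances are not allowed")

    tns = dendropy.TaxonNamespace(labels)
    tree = dendropy.Tree(taxon_namespace=tns)
    tree.is_rooted = False

    nodes: list[dendropy.Node] = []
    for lab in labels:
        node = dendropy.Node(taxon=tns.get_taxon(lab))
        nodes.append(node)
    reps = list(labels)  # cluster representatives for tie-breaking
    dm = {(i, j): d[i, j] for i in range(n) for j in range(n)}
    active = list(range(n))
    next_id = n

    def dist(i: int, j: int) -> float:
        return 0.0 if i == j else dm[(min(i, j), max(i, j))]

    rep = {i: reps[i] for i in range(n)}
    node_of = {i: nodes[i] for i in range(n)}

    while len(active) > 3:
        m = len(active)
        r = {i: sum(dist(i, k) for k in active if k != i) for i in active}
        best = None
        for a_pos in range(m):
            for b_pos in range(a_pos + 1, m):
                i, j = active[a_pos], active[b_pos]
                q = (m - 2) * dist(i, j) - r[i] - r[j]
                key = tuple(sorted((rep[i], rep[j])))
                if best is None or q < best[0] - 1e-12 or (
                    abs(q - best[0]) <= 1e-12 and key < best[1]
                ):
                    best = (q, key, i, j)
        _, _, i, j = best
        dij = dist(i, j)
        vi = dij / 2.0 + (r[i] - r[j]) / (2.0 * (m - 2))
        vj = dij - vi
        u = dendropy.Node()
        ni, nj = node_of[i], node_of[j]
        u.add_child(ni)
        u.add_child(nj)
        ni.edge.length = vi
        nj.edge.length = vj
        uid = next_id
        next_id += 1
        for k in active:
            if k in (i, j):
                continue
            duk = (dist(i, k) + dist(j, k) - dij) / 2.0
            dm[(min(uid, k), max(uid, k))] = duk
        active = [k for k in active if k not in (i, j)] + [uid]
        node_of[uid] = u
        rep[uid] = min(rep[i], rep[j])

    a, b, c = sorted(active, key=lambda k: rep[k])
    dab, dac, dbc = dist(a, b), dist(a, c), dist(b, c)
    va = (dab + dac - dbc) / 2.0
    vb = (dab + dbc - dac) / 2.0
    vc = (dac + dbc - dab) / 2.0
    seed = tree.seed_node
    for k, v in ((a, va), (b, vb), (c, vc)):
        seed.add_child(node_of[k])
        node_of[k].edge.length = v
    tree.update_bipartitions(suppress_unifurcations=True)
    return tree


# ---------------------------------------------------------------------------
# Topology tests
# ---------------------------------------------------------------------------

def as_tree(
    tree: dendropy.Tree | str,
    taxon_namespace: dendropy.TaxonNamespace | None = None,
) -> dendropy.Tree:
    """Coerce a Newick string or dendropy tree into a dendropy tree."""
    if isinstance(tree, dendropy.Tree):
        if taxon_namespace is None:
            return tree
        tree = tree.as_string(schema="newick")
    kwargs = (
        {"taxon_namespace": taxon_namespace} if taxon_namespace is not None else {}
    )
    return dendropy.Tree.get(
        data=tree, schema="newick", preserve_underscores=True, **kwargs
    )


def is_monophyletic(
    tree: dendropy.Tree | str, taxa_set: set[str], outgroup: str
) -> bool:
    """Whether ``taxa_set`` forms a complete clade when rooted at ``outgroup``."""
    t = as_tree(
        as_tree(tree).as_string(schema="newick")  # work on a private copy
    )
    labels = {leaf.taxon.label for leaf in t.leaf_node_iter()}
    missing = (set(taxa_set) | {outgroup}) - labels
    if missing:
        raise ValueError(f"taxa not present in tree: {sorted(missing)}")
    og = next(
        leaf for leaf in t.leaf_node_iter() if leaf.taxon.label == outgroup
    )
    t.to_outgroup_position(og, update_bipartitions=True)
    t.is_rooted = True
    mrca = t.mrca(taxon_labels=sorted(taxa_set))
    clade = {leaf.taxon.label for leaf in mrca.leaf_iter()}
    return clade == set(taxa_set)


def robinson_foulds(
    t1: dendropy.Tree | str, t2: dendropy.Tree | str
) -> int:
    """Unrooted Robinson-Foulds distance: count of non-shared bipartitions."""
    tns = dendropy.TaxonNamespace()
    a = as_tree(as_tree(t1).as_string(schema="newick"), taxon_namespace=tns)
    b = as_tree(as_tree(t2).as_string(schema="newick"), taxon_namespace=tns)
    if {x.taxon.label for x in a.leaf_node_iter()} != {
        x.taxon.label for x in b.leaf_node_iter()
    }:
        raise ValueError("trees must share an identical taxon set")
    a.is_rooted = False
    b.is_rooted = False
    a.update_bipartitions()
    b.update_bipartitions()
    return int(treecompare.symmetric_difference(a, b))
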