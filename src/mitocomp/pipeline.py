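"""One-command reproduction of the full comparative-mitogenomics surface.

:func:`run_all` takes a directory of annotated GenBank records and emits the
complete report bundle: genome composition table, per-gene divergence table,
RSCU and start/stop-codon usage tables, gene order and intergenic-spacer
audits, concatenated supermatrices with partition files for the two standard
gene sets (a: Cyt b + 12S + ND2; b: 13 PCGs + both rRNAs), a neighbor-joining
tree on Jukes-Cantor distances, optional monophyly verdicts, a structured run
log and a checksum manifest.  Given identical inputs and configuration the
bundle is byte-identical across runs.

Records that fail to parse or validate are quarantined and logged; the run
continues as long as at least two usable records remain.  No network access
happens here: inputs are local files (see ``mitocomp fetch`` for the
separate, explicit download helper).
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import pathlib
from dataclasses import dataclass, field

import pandas as pd

from . import codon_usage, composition, divergence, genome_io, phylo

__all__ = ["RunConfig", "run_all", "DATASET_A_GENES", "DATASET_B_GENES"]

DATASET_A_GENES: tuple[str, ...] = ("Cyt b", "12S", "ND2")
DATASET_B_GENES: tuple[str, ...] = genome_io.PCG_NAMES + genome_io.RRNA_NAMES


@dataclass
class RunConfig:
    """Configuration of one pipeline run (JSON-loadable)."""

    input_paths: list[str]
    out_dir: str
    dataset_a: tuple[str, ...] = DATASET_A_GENES
    dataset_b: tuple[str, ...] = DATASET_B_GENES
    ndigits: int = 2
    #: (clade name, taxa accessions, outgroup accession) monophyly queries
    clade_tests: list[tuple[str, list[str], str]] = field(default_factory=list)
    seed: int = 0

    def __post_init__(self) -> None:
        known = set(genome_io.PCG_NAMES) | set(genome_io.RRNA_NAMES) | {"CR"}
        for gene in tuple(self.dataset_a) + tuple(self.dataset_b):
            if gene not in known and not gene.startswith("tRNA-"):
                raise ValueError(f"unknown gene {gene!r} in dataset definition")

    @classmethod
    def from_json(cls, path: str | pathlib.Path) -> "RunConfig":
        data = json.loads(pathlib.Path(path).read_text())
        if "clade_tests" in data:
            data["clade_tests"] = [tuple(x) for x in data["clade_tests"]]
        return cls(**data)


def _load_records(paths, log):
    records, quarantined = [], []
    for p in paths:
        p = pathlib.Path(p)
        try:
            recs = genome_io.parse_genbank(p.read_text())
        except Exception as exc:  # quarantine, do not abort the run
            quarantined.append((str(p), str(exc)))
            log(f"stage=parse status=quarantined file={p} error={exc!r}")
            continue
        for rec in recs:
            records.append(rec)
            log(
                f"stage=parse status=ok file={p} accession={rec.accession} "
                f"n_features={len(rec.features)} n_warnings={len(rec.warnings)}"
            )
    return records, quarantined


def _gene_alignment(records, gene, log) -> divergence.CodonAlignment:
    """Stack per-record extractions; trim trailing overhangs to a shared frame.

    Mitochondrial genes are near indel-free, so length differences between
    records are terminal (alternative stop annotations); rows are truncated
    to the shortest extraction, which the cleaning step then tidies to whole
    codons.  Internal indels require an externally aligned FASTA instead.
    """
    rows = [genome_io.extract_gene(r, gene) for r in records]
    n = min(len(r) for r in rows)
    if any(len(r) != n for r in rows):
        log(
            f"stage=align gene={gene} note=trimmed_to_{n}bp "
            f"(unequal terminal lengths)"
        )
    return divergence.CodonAlignment(
        gene, [r.accession for r in records], [r[:n] for r in rows]
    )


def run_all(config: RunConfig) -> dict:
    """Run the whole analysis; returns the manifest (also written to disk)."""
    out = pathlib.Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    log_lines: list[str] = []

    def log(line: str) -> None:
        log_lines.append(line)

    records, quarantined = _load_records(config.input_paths, log)
    if len(records) < 2:
        raise ValueError(
            f"comparative analysis needs >= 2 parseable records, got {len(records)} "
            f"({len(quarantined)} quarantined)"
        )

    written: dict[str, pathlib.Path] = {}

    def save(name: str, text: str) -> None:
        path = out / name
        path.write_text(text)
        written[name] = path

    def save_tsv(name: str, df: pd.DataFrame) -> None:
        save(name, df.to_csv(sep="\t", index=False))

    # composition (Table-1 surface)
    comp = composition.composition_table(records, ndigits=config.ndigits)
    save_tsv("composition.tsv", comp.drop(columns=[], errors="ignore"))
    log(f"stage=composition n_records={len(records)} out=composition.tsv")

    # genome audits
    save_tsv("gene_order.tsv", genome_io.gene_order_table(records))
    save_tsv("spacers.tsv", genome_io.spacer_table(records))
    log("stage=audit out=gene_order.tsv,spacers.tsv")

    # codon usage
    usage = codon_usage.start_stop_usage(records)
    save_tsv("start_codons.tsv", usage.start_frequencies)
    save_tsv("stop_codons.tsv", usage.stop_frequencies)
    counts = codon_usage.count_codons(records)
    save_tsv("rscu.tsv", codon_usage.rscu_table(counts))
    log(f"stage=codon n_warnings={len(usage.warnings)} out=rscu.tsv")

    # divergence (Table-2 surface)
    alignments = {
        g: _gene_alignment(records, g, log) for g in genome_io.PCG_NAMES
    }
    div = divergence.gene_divergence_table(alignments)
    save_tsv("divergence.tsv", div)
    log(f"stage=divergence n_genes={len(alignments)} out=divergence.tsv")

    # supermatrices + exports
    cleaned = {g: divergence.clean_alignment(a) for g, a in alignments.items()}
    for label, genes in (("dataset_a", config.dataset_a),
                         ("dataset_b", config.dataset_b)):
        parts = {}
        for g in genes:
            if g in cleaned:
                parts[g] = cleaned[g]
            else:  # rRNAs and any non-PCG: raw stacked extraction
                parts[g] = _gene_alignment(records, g, log)
        matrix = phylo.concatenate(parts)
        save(f"{label}.phy", phylo.export_phylip(matrix))
        save(f"{label}.nex", phylo.export_nexus(matrix))
        save(f"{label}.partitions.txt", phylo.export_raxml_partitions(matrix))
        log(
            f"stage=concat dataset={label} n_taxa={len(matrix.taxa)} "
            f"length={matrix.length} n_partitions={len(matrix.partitions)}"
        )
        if label == "dataset_b":
            dist = phylo.jc_distance_matrix(matrix.taxa, matrix.rows)
            save("dataset_b.jc_distances.tsv", dist.to_csv(sep="\t"))
            tree = phylo.nj_tree(dist)
            save(
                "nj_tree.nwk",
                tree.as_string(schema="newick", suppress_rooting=True),
            )
            log(f"stage=nj n_taxa={len(matrix.taxa)} out=nj_tree.nwk")

    # monophyly verdicts
    if config.clade_tests:
        verdict_rows = []
        tree_text = written["nj_tree.nwk"].read_text()
        for name, taxa, outgroup in config.clade_tests:
            ok = phylo.is_monophyletic(tree_text, set(taxa), outgroup)
            verdict_rows.append(
                {"clade": name, "n_taxa": len(taxa), "outgroup": outgroup,
                 "monophyletic": ok}
            )
        save_tsv("monophyly.tsv", pd.DataFrame(verdict_rows))
        log(f"stage=monophyly n_tests={len(config.clade_tests)} out=monophyly.tsv")

    save("run.log", "\n".join(log_lines) + "\n")
    manifest = {
        "config": {
            **dataclasses.asdict(config),
            "dataset_a": list(config.dataset_a),
            "dataset_b": list(config.dataset_b),
        },
        "n_records": len(records),
        "quarantined": quarantined,
        "outputs": {
            name: hashlib.sha256(path.read_bytes()).hexdigest()
            for name, path in sorted(written.items())
        },
    }
    (out / "manifest.json").write_text(json.dumps(manifest, indent=2))
    return manifest
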