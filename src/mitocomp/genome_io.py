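"""Reading, validating and writing annotated mitogenome records.

The in-memory model is a :class:`MitoGenomeRecord`: one circular (or linear)
nucleotide sequence plus an ordered feature table of named genes.  Coordinates
are 1-based inclusive throughout, following the GenBank convention; a feature
whose ``start > end`` wraps across the origin of a circular molecule.

GenBank flat-file parsing and writing are delegated to Biopython; this module
adds the domain model, canonical gene naming, strand-corrected extraction and
the gene-order / intergenic-spacer audits used by the downstream statistics.
"""

from __future__ import annotations

import io
import re
from dataclasses import dataclass, field

import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqFeature import CompoundLocation, SeqFeature, SimpleLocation
from Bio.SeqRecord import SeqRecord

__all__ = [
    "GeneFeature",
    "MitoGenomeRecord",
    "SpacerRecord",
    "CANONICAL_GENE_NAMES",
    "PCG_NAMES",
    "RRNA_NAMES",
    "canonical_gene_name",
    "reverse_complement",
    "parse_genbank",
    "write_genbank",
    "extract_gene",
    "intergenic_spacers",
    "gene_order",
    "gene_order_table",
    "spacer_table",
]

# ---------------------------------------------------------------------------
# Domain types
# ---------------------------------------------------------------------------

#: The 13 mitochondrial protein-coding genes, in a fixed canonical order.
PCG_NAMES = (
    "ND1", "ND2", "COI", "COII", "ATP8", "ATP6", "COIII",
    "ND3", "ND4L", "ND4", "ND5", "ND6", "Cyt b",
)

RRNA_NAMES = ("12S", "16S")

_COMPLEMENT = str.maketrans("ACGTNacgtn", "TGCANtgcan")


def reverse_complement(seq: str) -> str:
    """Reverse complement of a nucleotide string over {A,C,G,T,N}."""
    return seq.translate(_COMPLEMENT)[::-1]


@dataclass(frozen=True)
class GeneFeature:
    """One annotated gene (or the control region) on a mitogenome.

    ``start``/``end`` are 1-based inclusive; ``start > end`` encodes a feature
    wrapping the origin of a circular molecule.  ``codon_start`` is the
    GenBank reading-frame offset (1, 2 or 3) and is only meaningful for PCGs.
    """

    name: str
    ftype: str  # one of {"PCG", "tRNA", "rRNA", "CR"}
    start: int
    end: int
    strand: str  # "+" or "-"
    codon_start: int | None = None

    def __post_init__(self) -> None:
        if self.ftype not in {"PCG", "tRNA", "rRNA", "CR"}:
            raise ValueError(f"unknown feature type {self.ftype!r} for {self.name}")
        if self.strand not in {"+", "-"}:
            raise ValueError(f"strand must be '+' or '-', got {self.strand!r}")
        if self.ftype == "PCG" and self.codon_start not in {1, 2, 3}:
            raise ValueError(f"PCG {self.name} needs codon_start in {{1,2,3}}")
        if min(self.start, self.end) < 1:
            raise ValueError(f"coordinates must be >= 1 for {self.name}")

    @property
    def wraps(self) -> bool:
        return self.start > self.end

    def length(self, genome_length: int | None = None) -> int:
        if not self.wraps:
            return self.end - self.start + 1
        if genome_length is None:
            raise ValueError(f"{self.name} wraps the origin; genome length required")
        return (genome_length - self.start + 1) + self.end


@dataclass(frozen=True)
class SpacerRecord:
    """Intergenic gap between two adjacent features.

    ``length_bp`` is positive for a gap, zero for abutting genes and negative
    where the two annotations overlap.
    """

    left_gene: str
    right_gene: str
    length_bp: int


@dataclass
class MitoGenomeRecord:
    """One annotated mitogenome: sequence, feature table and metadata."""

    accession: str
    organism: str
    sequence: str
    is_circular: bool = True
    features: list[GeneFeature] = field(default_factory=list)
    warnings: list[str] = field(default_factory=list)

    @property
    def length_bp(self) -> int:
        return len(self.sequence)

    def __post_init__(self) -> None:
        self.sequence = self.sequence.upper()
        bad = set(self.sequence) - set("ACGTN")
        if bad:
            raise ValueError(
                f"{self.accession}: sequence contains unsupported ambiguity codes "
                f"{sorted(bad)}; only A/C/G/T/N are accepted"
            )
        self.validate()

    def validate(self) -> None:
        n = self.length_bp
        seen: set[str] = set()
        for f in self.features:
            if max(f.start, f.end) > n:
                raise ValueError(
                    f"{self.accession}: feature {f.name} coordinates "
                    f"{f.start}..{f.end} exceed genome length {n}"
                )
            if f.wraps and not self.is_circular:
                raise ValueError(
                    f"{self.accession}: feature {f.name} wraps the origin of a "
                    "linear record"
                )
            if f.ftype in {"PCG", "rRNA", "CR"}:
                if f.name in seen:
                    raise ValueError(
                        f"{self.accession}: duplicate {f.ftype} feature {f.name}"
                    )
                seen.add(f.name)

    def feature_by_name(self, name: str) -> GeneFeature:
        for f in self.features:
            if f.name == name:
                return f
        available = ", ".join(f.name for f in self.features)
        raise KeyError(f"no feature named {name!r}; available: {available}")


# ---------------------------------------------------------------------------
# Canonical gene names
# ---------------------------------------------------------------------------

#: Synonym table mapping the gene symbols found in GenBank annotations to the
#: canonical symbols used throughout this package.  User-extensible: pass an
#: augmented mapping to :func:`parse_genbank`.
CANONICAL_GENE_NAMES: dict[str, str] = {
    # NADH dehydrogenase
    "ND1": "ND1", "NAD1": "ND1", "NADH1": "ND1",
    "ND2": "ND2", "NAD2": "ND2", "NADH2": "ND2",
    "ND3": "ND3", "NAD3": "ND3", "NADH3": "ND3",
    "ND4": "ND4", "NAD4": "ND4", "NADH4": "ND4",
    "ND4L": "ND4L", "NAD4L": "ND4L", "NADH4L": "ND4L",
    "ND5": "ND5", "NAD5": "ND5", "NADH5": "ND5",
    "ND6": "ND6", "NAD6": "ND6", "NADH6": "ND6",
    # cytochrome c oxidase
    "COI": "COI", "COX1": "COI", "CO1": "COI", "COXI": "COI",
    "COII": "COII", "COX2": "COII", "CO2": "COII", "COXII": "COII",
    "COIII": "COIII", "COX3": "COIII", "CO3": "COIII", "COXIII": "COIII",
    # ATP synthase
    "ATP6": "ATP6", "ATPASE6": "ATP6", "ATPASE 6": "ATP6",
    "ATP8": "ATP8", "ATPASE8": "ATP8", "ATPASE 8": "ATP8",
    # cytochrome b
    "CYT B": "Cyt b", "CYTB": "Cyt b", "COB": "Cyt b", "CYB": "Cyt b",
    # ribosomal RNAs
    "12S": "12S", "12S RRNA": "12S", "12S RIBOSOMAL RNA": "12S",
    "S-RRNA": "12S", "RRNS": "12S", "SMALL SUBUNIT RIBOSOMAL RNA": "12S",
    "16S": "16S", "16S RRNA": "16S", "16S RIBOSOMAL RNA": "16S",
    "L-RRNA": "16S", "RRNL": "16S", "LARGE SUBUNIT RIBOSOMAL RNA": "16S",
    # control region
    "CR": "CR", "D-LOOP": "CR", "CONTROL REGION": "CR",
}

_TRNA_RE = re.compile(r"^TRNA[-_ ]?([A-Z]{3})\s*(\(([A-Z]{3})\))?$")

_AA3 = {
    "ALA": "Ala", "ARG": "Arg", "ASN": "Asn", "ASP": "Asp", "CYS": "Cys",
    "GLN": "Gln", "GLU": "Glu", "GLY": "Gly", "HIS": "His", "ILE": "Ile",
    "LEU": "Leu", "LYS": "Lys", "MET": "Met", "PHE": "Phe", "PRO": "Pro",
    "SER": "Ser", "THR": "Thr", "TRP": "Trp", "TYR": "Tyr", "VAL": "Val",
}


def canonical_gene_name(raw: str, synonyms: dict[str, str] | None = None) -> str:
    """Map an annotation gene symbol or product to its canonical name.

    tRNA names keep an optional isoacceptor tag, e.g. ``tRNA-Leu(UUR)``, which
    distinguishes the duplicated Leu and Ser genes.  Raises ``KeyError`` for
    symbols with no known synonym.
    """
    table = CANONICAL_GENE_NAMES if synonyms is None else synonyms
    key = raw.strip().upper()
    if key in table:
        return table[key]
    m = _TRNA_RE.match(key)
    if m:
        aa = _AA3.get(m.group(1))
        if aa is not None:
            tag = f"({m.group(3)})" if m.group(3) else ""
            return f"tRNA-{aa}{tag}"
    raise KeyError(f"unrecognized gene symbol {raw!r}")


# ---------------------------------------------------------------------------
# GenBank parsing / writing
# ---------------------------------------------------------------------------

_FTYPE_BY_KEY = {"CDS": "PCG", "tRNA": "tRNA", "rRNA": "rRNA", "D-loop": "CR"}


def _feature_name(bio_feature) -> str | None:
    for qual in ("gene", "product", "note"):
        vals = bio_feature.qualifiers.get(qual)
        if vals:
            return vals[0]
    if bio_feature.type == "D-loop":
        return "CR"
    return None


def _location_to_coords(location, genome_length: int) -> tuple[int, int, str]:
    strand = "-" if location.strand == -1 else "+"
    parts = getattr(location, "parts", [location])
    if len(parts) == 1:
        return int(location.start) + 1, int(location.end), strand
    # Origin-spanning join on a circular molecule: join(a..N, 1..b).
    parts = sorted(parts, key=lambda p: int(p.start))
    first, last = parts[-1], parts[0]
    if int(first.end) != genome_length or int(last.start) != 0:
        raise ValueError(f"unsupported compound location {location}")
    return int(first.start) + 1, int(last.end), strand


def parse_genbank(
    text: str, synonyms: dict[str, str] | None = None
) -> list[MitoGenomeRecord]:
    """Parse GenBank flat-file content into :class:`MitoGenomeRecord` objects.

    CDS, tRNA, rRNA and D-loop features are mapped to :class:`GeneFeature`
    with canonical names; any feature of those classes that cannot be mapped
    is reported on ``record.warnings`` rather than silently dropped.  Other
    feature keys (``source``, ``gene`` companions, ...) are ignored.
    """
    records: list[MitoGenomeRecord] = []
    for rec in SeqIO.parse(io.StringIO(text), "genbank"):
        seq = str(rec.seq).upper()
        is_circular = rec.annotations.get("topology", "linear") == "circular"
        features: list[GeneFeature] = []
        warnings: list[str] = []
        for bf in rec.features:
            ftype = _FTYPE_BY_KEY.get(bf.type)
            if ftype is None:
                continue
            raw = _feature_name(bf)
            if raw is None:
                warnings.append(f"{bf.type} at {bf.location}: no gene/product name")
                continue
            try:
                name = "CR" if ftype == "CR" else canonical_gene_name(raw, synonyms)
            except KeyError:
                warnings.append(f"{bf.type} {raw!r} at {bf.location}: unknown symbol")
                continue
            try:
                start, end, strand = _location_to_coords(bf.location, len(seq))
            except ValueError as exc:
                raise ValueError(f"feature {raw!r}: {exc}") from exc
            codon_start = None
            if ftype == "PCG":
                codon_start = int(bf.qualifiers.get("codon_start", ["1"])[0])
            features.append(
                GeneFeature(name, ftype, start, end, strand, codon_start)
            )
        records.append(
            MitoGenomeRecord(
                accession=rec.id if rec.id != "<unknown id>" else rec.name,
                organism=rec.annotations.get("organism", rec.description or ""),
                sequence=seq,
                is_circular=is_circular,
                features=features,
                warnings=warnings,
            )
        )
    if not records:
        raise ValueError("no LOCUS..// GenBank records found in input")
    return records


_KEY_BY_FTYPE = {"PCG": "CDS", "tRNA": "tRNA", "rRNA": "rRNA", "CR": "D-loop"}


def write_genbank(records: list[MitoGenomeRecord] | MitoGenomeRecord) -> str:
    """Serialize records back to GenBank flat-file text (via Biopython)."""
    if isinstance(records, MitoGenomeRecord):
        records = [records]
    out: list[SeqRecord] = []
    for rec in records:
        sr = SeqRecord(
            Seq(rec.sequence),
            id=rec.accession,
            name=rec.accession.split(".")[0][:16],
            description=f"{rec.organism} mitochondrion, complete genome",
        )
        sr.annotations["molecule_type"] = "DNA"
        sr.annotations["topology"] = "circular" if rec.is_circular else "linear"
        sr.annotations["organism"] = rec.organism
        sr.annotations["source"] = f"mitochondrion {rec.organism}"
        for f in rec.features:
            strand = -1 if f.strand == "-" else 1
            if f.wraps:
                loc = CompoundLocation(
                    [
                        SimpleLocation(f.start - 1, rec.length_bp, strand),
                        SimpleLocation(0, f.end, strand),
                    ]
                )
            else:
                loc = SimpleLocation(f.start - 1, f.end, strand)
            quals: dict[str, list[str]] = {"gene": [f.name]}
            if f.ftype == "PCG":
                quals["codon_start"] = [str(f.codon_start)]
            if f.ftype == "CR":
                quals = {"note": ["control region"]}
            sr.features.append(SeqFeature(loc, type=_KEY_BY_FTYPE[f.ftype], qualifiers=quals))
        out.append(sr)
    buf = io.StringIO()
    SeqIO.write(out, buf, "genbank")
    return buf.getvalue()


# ---------------------------------------------------------------------------
# Extraction and audits
# ---------------------------------------------------------------------------

def _raw_slice(record: MitoGenomeRecord, feature: GeneFeature) -> str:
    if not feature.wraps:
        return record.sequence[feature.start - 1 : feature.end]
    return record.sequence[feature.start - 1 :] + record.sequence[: feature.end]


def extract_gene(record: MitoGenomeRecord, name: str) -> str:
    """Gene sequence in coding orientation.

    Minus-strand features are reverse-complemented; PCGs additionally have
    the ``codon_start`` frame offset applied so the result begins at codon 1.
    """
    feature = record.feature_by_name(name)
    seq = _raw_slice(record, feature)
    if feature.strand == "-":
        seq = reverse_complement(seq)
    if feature.ftype == "PCG" and feature.codon_start and feature.codon_start > 1:
        seq = seq[feature.codon_start - 1 :]
    return seq


def gene_order(record: MitoGenomeRecord) -> list[tuple[str, str]]:
    """(name, strand) pairs ordered by start coordinate from the origin."""
    return [(f.name, f.strand) for f in sorted(record.features, key=lambda f: f.start)]


def intergenic_spacers(record: MitoGenomeRecord) -> list[SpacerRecord]:
    """Gap (or overlap, negative) between each adjacent feature pair.

    For circular records the closing pair (last feature back to the first
    across the origin) is included, so feature lengths plus spacer lengths
    tile the whole genome.
    """
    feats = sorted(record.features, key=lambda f: f.start)
    if len(feats) < 2:
        raise ValueError("need at least 2 features to compute spacers")
    n = record.length_bp
    spacers: list[SpacerRecord] = []
    for left, right in zip(feats, feats[1:]):
        spacers.append(SpacerRecord(left.name, right.name, right.start - left.end - 1))
    if record.is_circular:
        last, first = feats[-1], feats[0]
        gap = first.start - last.end - 1 + (0 if last.wraps else n)
        spacers.append(SpacerRecord(last.name, first.name, gap))
    return spacers


def gene_order_table(records: list[MitoGenomeRecord]) -> pd.DataFrame:
    """Long-form table of gene order across records (one row per feature)."""
    rows = []
    for rec in records:
        for pos, (name, strand) in enumerate(gene_order(rec), start=1):
            rows.append(
                {"accession": rec.accession, "position": pos, "gene": name,
                 "strand": strand}
            )
    return pd.DataFrame(rows)


def spacer_table(records: list[MitoGenomeRecord]) -> pd.DataFrame:
    rows = []
    for rec in records:
        for sp in intergenic_spacers(rec):
            rows.append(
                {"accession": rec.accession, "left_gene": sp.left_gene,
                 "right_gene": sp.right_gene, "length_bp": sp.length_bp}
            )
    return pd.DataFrame(rows)
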