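import pytest
from hypothesis import settings

from mitocomp import simulate

settings.register_profile("repro", derandomize=True, deadline=None)
settings.load_profile("repro")
from mitocomp.genome_io import GeneFeature, MitoGenomeRecord


@pytest.fixture(scope="session")
def bundle():
    """The bundled simulated data set: 12 genomes on a known tree."""
    return simulate.fixture_set(seed=11)


@pytest.fixture(scope="session")
def ancestor(bundle):
    return bundle.ancestor


def make_two_gene_record(accession="TEST0001", circular=True):
    """Minimal synthetic record: one PCG and one tRNA on 60 bp."""
    # PCG 1..21 (+): ATG AAA CCC GGG TTT ACA TAA
    pcg = "ATGAAACCCGGGTTTACATAA"
    trna = "ACGTACGTACGTACGTACGT"
    filler = "ACGTACGTACGTACGTACG"
    seq = pcg + trna + filler
    features = [
        GeneFeature("ND1", "PCG", 1, 21, "+", 1),
        GeneFeature("tRNA-Phe", "tRNA", 22, 41, "+"),
    ]
    return MitoGenomeRecord(
        accession=accession,
        organism="synthetic test organism",
        sequence=seq,
        is_circular=circular,
        features=features,
    )
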