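import pytest

from exsmallrna.references import ReferenceBundle, ReferenceRecord
from exsmallrna.simulate import build_synthetic_references, build_synthetic_species


@pytest.fixture(scope="session")
def refs():
    """Default synthetic reference set (deterministic, seed 1)."""
    return build_synthetic_references(seed=1)


@pytest.fixture(scope="session")
def species_trio():
    species, parents, ranks = build_synthetic_species(n_species=3, replicon_length=1000, seed=11)
    return species, parents, ranks


@pytest.fixture()
def tiny_bundle():
    """Hand-built bundle with one record per stage and a planted overlap."""
    trna = "GCATTGGTGGTTCAGTGGTAGAATTCTCGCCTGCCACGCGGGAGGCCCGGGTTCGATTCCCGGCCAATGCACCA"
    records = [
        ReferenceRecord("rRNA-A", "rRNA", "ACGT" * 30),
        ReferenceRecord("miR-A", "miRNA", "TGAGGTAGTAGGTTGTATAGTT"),
        ReferenceRecord("tRNA-GlyGCC-1", "tRNA", trna, family="GlyGCC"),
        ReferenceRecord("piR-A", "piRNA", trna[:30]),  # shares the tRNA 5' end
        ReferenceRecord("RNY4", "YRNA", "GGCTGGTCCGAAGGTAGTGAGTTATCTCAATTGATTGTTCACAGTCAGTTACAGATCGAACTCCT", parent="RNY4"),
        ReferenceRecord("ncRNA-A", "other_ncRNA", "CCTTAGCAGGAGACATCCGATACTGGACCTAGACCAATACCCGGTAAGGTTTCCTA"),
        ReferenceRecord("pc-A", "protein_coding", "ATGGCCAAGGACCTGAAGTTCAACCTGATCACCGAGATGCTGGAGCTGAAGGAGGCC"),
    ]
    genome = {"chr1": "TTTTTTTTTT".join(r.sequence for r in records) + "TTTTTTTTTT"}
    return ReferenceBundle(records, genome=genome)
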