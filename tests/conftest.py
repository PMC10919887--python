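import pytest

from zwturnover.locus import GeneModel
from zwturnover.synth import LocusSpec, generate_gene_model


@pytest.fixture(scope="session")
def gene_model() -> GeneModel:
    """Default synthetic 1,678-bp two-exon segment."""
    return generate_gene_model(LocusSpec(seed=7))


@pytest.fixture(scope="session")
def tiny_model() -> GeneModel:
    """Hand-built 26-bp model with known codons.

    exon1 = ATG GGA TGG TAC (positions 0-11), intron = GTAAAAAG
    (positions 12-19), exon2 = GCA TAA (positions 20-25).
    """
    model = GeneModel(
        reference_sequence="ATGGGATGGTAC" + "GTAAAAAG" + "GCATAA",
        exon_intervals=((0, 12), (20, 26)),
        initial_sd_site=12,
        initial_sd_alt_base="A",
    )
    assert model.validate() == []
    return model
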