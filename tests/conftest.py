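import numpy as np
import pytest

from mutscan import AMINO_ACIDS, CodingSequence, VariantCountTable

# Ten codons translating to MTEYKLVVVG, the Ras N-terminal motif.
TOY_DNA = "ATGACCGAATACAAACTGGTTGTTGTTGGC"


@pytest.fixture
def toy_reference() -> CodingSequence:
    return CodingSequence("toy", TOY_DNA, first_residue_number=1)


@pytest.fixture
def random_fitness(toy_reference):
    """Seeded continuous fitness map over positions 2-7 of the toy gene."""
    rng = np.random.default_rng(3)
    positions = range(2, 8)
    return {
        (p, a): float(rng.normal(0, 0.5))
        for p in positions
        for a in AMINO_ACIDS
        if a != toy_reference.aa_at(p)
    }


def make_tables(
    variant_counts_sel: dict,
    variant_counts_unsel: dict,
    wt_sel: dict,
    wt_unsel: dict,
) -> tuple[VariantCountTable, VariantCountTable]:
    sel = VariantCountTable("sel", counts=variant_counts_sel, wt_alleles=wt_sel)
    unsel = VariantCountTable("unsel", counts=variant_counts_unsel, wt_alleles=wt_unsel)
    return sel, unsel
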