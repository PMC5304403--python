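import pytest

from mirage import MatureReference, SeedDefinition

#: mature miR-29a (miRBase), the worked-example miRNA throughout the suite
MIR29A = "UAGCACCAUCUGAAAUCGGUUA"


@pytest.fixture
def mir29_seed() -> SeedDefinition:
    return SeedDefinition(MIR29A)


@pytest.fixture
def small_reference() -> MatureReference:
    return MatureReference(
        [
            ("miR-29a", "TAGCACCATCTGAAATCGGTTA"),
            ("miR-29b", "TAGCACCATTTGAAATCAGTGTT"),
            ("let-7a", "TGAGGTAGTAGGTTGTATAGTT"),
            ("miR-124", "TAAGGCACGCGGTGAATGCC"),
        ]
    )
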