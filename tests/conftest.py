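import pytest

from adrminer import synthdata, termdict


@pytest.fixture(scope="session")
def clean_universe():
    """Noise-free synthetic universe: planted 3-drug class sharing 43 ADRs."""
    config = synthdata.SynthConfig(seed=42, distractor_rate=0.0)
    return synthdata.generate_universe(config)


@pytest.fixture(scope="session")
def clean_dictionary(clean_universe):
    return termdict.compile_dictionary(clean_universe.entries)


@pytest.fixture()
def ast_entry():
    return termdict.TermEntry(
        "10003481",
        "Aspartate aminotransferase increased",
        abbreviations=frozenset([("aspartate aminotransferase", "AST")]),
    )
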