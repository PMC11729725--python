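import pytest

from vgstats import parse_gfa_text, toy_graphs


@pytest.fixture(scope="session")
def fixtures() -> dict[str, str]:
    return toy_graphs()


@pytest.fixture(scope="session")
def toy1(fixtures):
    return parse_gfa_text(fixtures["TOY1"])
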