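import io

import pytest
from hypothesis import HealthCheck, settings

settings.register_profile(
    "det",
    derandomize=True,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("det")

from ptmphind import ParsedProteome, ProteinRecord


@pytest.fixture
def tiny_proteome() -> ParsedProteome:
    return ParsedProteome(
        [
            ProteinRecord("P1", "MKPEPSIDEK"),
            ProteinRecord("P2", "AAAA"),
            ProteinRecord("P3", "MKTAYSTYKRSPQR"),
        ]
    )


@pytest.fixture
def text_io():
    return io.StringIO
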