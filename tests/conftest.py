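import numpy as np
import pytest

from estclean.elements import collect_element_hits
from estclean.patterns import (assemble_termini, build_pattern, disambiguate,
                               score_all)
from estclean.protocol import default_protocol


@pytest.fixture(scope="session")
def protocol():
    return default_protocol()


@pytest.fixture()
def rng():
    return np.random.default_rng(42)


def analyze(read, protocol):
    """Element scan -> assembled+scored+disambiguated termini -> pattern."""
    scan = collect_element_hits(read, protocol)
    termini = assemble_termini(read, scan.motif_hits, protocol)
    score_all(read, termini, protocol, scan.vector_hits, scan.segments)
    termini = disambiguate(termini)
    pattern = build_pattern(read, termini, scan.vector_hits, scan.segments)
    return scan, termini, pattern


@pytest.fixture(scope="session")
def analyze_read():
    return analyze
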