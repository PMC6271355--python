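import pytest

from qsarpipe import builtin_fixture


@pytest.fixture(scope="session")
def training():
    """The 21-compound artemisinin training table (4 descriptors, IC50, logRA)."""
    return builtin_fixture("training")


@pytest.fixture(scope="session")
def test_set():
    """The 8-compound test table of untested artemisinin derivatives."""
    return builtin_fixture("test")
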