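import pytest

from phasescramble import build_family, kernel_response_matrix


@pytest.fixture(scope="session")
def family():
    return build_family()


@pytest.fixture(scope="session")
def kernel_matrix(family):
    return kernel_response_matrix(family)
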