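import pytest

from caulocycle.models import build_g2a, build_g2b, build_g2_combined
from caulocycle.synthetic import builtin_fixtures


@pytest.fixture(scope="session")
def g2a():
    return build_g2a()


@pytest.fixture(scope="session")
def g2b():
    return build_g2b()


@pytest.fixture(scope="session")
def g2():
    return build_g2_combined()


@pytest.fixture(scope="session")
def fixtures():
    return builtin_fixtures()
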