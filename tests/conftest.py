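import pytest

from pdvkit import classify_cohort, load_paper_fixture
from pdvkit.engine import DEFAULT_OPTIONS


@pytest.fixture(scope="session")
def fixture_bundle():
    return load_paper_fixture()


@pytest.fixture(scope="session")
def fixture_classifications(fixture_bundle):
    return classify_cohort(fixture_bundle, DEFAULT_OPTIONS)
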