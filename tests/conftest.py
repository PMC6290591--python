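import pytest

from simaudit.fixtures import (
    FixtureSpec,
    generate_release,
    paper_examples_fixture,
)


@pytest.fixture(scope="session")
def paper_release(tmp_path_factory):
    """RF2 triple holding the documented worked-example concept pairs."""
    out = tmp_path_factory.mktemp("paper_release")
    return paper_examples_fixture(out)


@pytest.fixture(scope="session")
def synthetic_release(tmp_path_factory):
    """One default-sized synthetic release plus its ground-truth manifest."""
    out = tmp_path_factory.mktemp("synthetic_release")
    paths, manifest = generate_release(FixtureSpec(seed=7), out)
    return paths, manifest
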