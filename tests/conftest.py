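import pytest

from morphoclad.fixtures import build_paper_fixtures


@pytest.fixture(scope="session")
def paper():
    """The hominoid working topology + printed-character fixture matrix."""
    return build_paper_fixtures()


@pytest.fixture(scope="session")
def tree(paper):
    return paper.tree


@pytest.fixture(scope="session")
def matrix(paper):
    return paper.matrix
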