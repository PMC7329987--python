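import pytest

import thawpheno as tp


@pytest.fixture(scope="session")
def paper_like():
    """One paper_like synthetic landscape with its ground truth."""
    return tp.generate_landscape(tp.scenario("paper_like"), seed=1)


@pytest.fixture(scope="session")
def bundle(paper_like):
    return paper_like[0]


@pytest.fixture(scope="session")
def filtered(bundle):
    return tp.filter_flooded(bundle)


@pytest.fixture(scope="session")
def tables(bundle):
    """Full pipeline output on the paper_like landscape."""
    return tp.run_analysis(bundle)
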