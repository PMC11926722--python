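import datetime as dt

import numpy as np
import pytest

import sentirisk as sr


@pytest.fixture(scope="session")
def path3_graph():
    """Path graph 0-1-2."""
    return sr.make_region_graph(1, 3, seed=0)


@pytest.fixture(scope="session")
def lattice4x4():
    return sr.make_region_graph(4, 4, seed=7)


@pytest.fixture(scope="session")
def small_bundle():
    """2x2 regions, 40 weeks, modest counts: fast end-to-end fixture."""
    return sr.default_bundle(seed=11, n_rows=2, n_cols=2, n_weeks=40,
                             mean_ttw=500)


@pytest.fixture(scope="session")
def tiny_lexicon():
    return sr.Lexicon(
        negative_terms=frozenset({"angst", "flut", "schlimm"}),
        positive_terms=frozenset({"gut", "freude"}),
        stopwords=frozenset({"der", "die", "und"}),
    )


@pytest.fixture()
def week_origin():
    return dt.date(2019, 1, 1)
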