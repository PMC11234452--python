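import contextlib
import io

import pytest

from gelgen import FixtureConfig, make_corpus, make_labeled_set


@pytest.fixture(scope="session")
def small_corpus():
    """200 deterministic synthetic molecules."""
    return make_corpus(FixtureConfig(seed=11, n_molecules=200))


@pytest.fixture(scope="session")
def labeled_set():
    """Minority-positive labeled set with the planted carbamate rule."""
    return make_labeled_set(FixtureConfig(seed=23, n_molecules=1000, positive_fraction=0.137))


@pytest.fixture()
def quiet_stderr():
    """Silence training progress lines inside a test."""
    buf = io.StringIO()
    with contextlib.redirect_stderr(buf):
        yield buf
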