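import warnings

import numpy as np
import pytest

import multirep_ner as m

# near-hard-margin grid cells on non-separable views legitimately hit the
# solver iteration cap; the warnings are expected
warnings.filterwarnings("ignore", message=".*max_iter.*")
warnings.filterwarnings("ignore", category=UserWarning, module="sklearn")


@pytest.fixture(scope="session")
def suffix_fixture():
    """A suffix-rule corpus: only affix-derived features separate classes."""
    return m.generate_fixture(m.FixtureConfig(seed=11, n_documents=40))


@pytest.fixture(scope="session")
def suffix_candidates(suffix_fixture):
    fx = suffix_fixture
    matcher = m.build_matcher(fx.lexicon)
    cands = [c for d in fx.documents for c in m.find_candidates(d, matcher)]
    labeling = m.label_candidates(cands, fx.gold)
    return cands, labeling


@pytest.fixture(scope="session")
def suffix_bank(suffix_fixture, suffix_candidates):
    cands, _ = suffix_candidates
    return m.build_representation_bank(
        cands, suffix_fixture.representation_config()
    )


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)
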