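import numpy as np
import pytest

from paracoder import SimSpec, build_fixture_lexicon, simulate_trials
from paracoder.lexical_knowledge import packaged_kb, packaged_onomatopoeia
from paracoder.semantics import InMemoryLexicon


@pytest.fixture(scope="session")
def kb():
    return packaged_kb()


@pytest.fixture(scope="session")
def onomatopoeia():
    return packaged_onomatopoeia()


def _unit(angle_cos: float) -> np.ndarray:
    """2-d unit vector with the given cosine against (1, 0)."""
    return np.array([angle_cos, np.sqrt(1.0 - angle_cos**2)])


@pytest.fixture(scope="session")
def naming_lexicon():
    """Tiny hand-built lexicon for the cat-item worked examples.

    Cosines against 'cat' are planted directly in the first component;
    'cak' and 'choko' are deliberately absent (nonwords), and a compound
    and a capitonym entry exercise the variant paths.
    """
    return InMemoryLexicon({
        "cat": np.array([1.0, 0.0]),
        "dog": _unit(0.7609),
        "mat": _unit(0.2468),
        "rat": _unit(0.5328),
        "bread": _unit(0.1587),
        "kitten": _unit(0.70),
        "church": np.array([1.0, 0.0]),
        "father": _unit(0.248),
        "Father": _unit(0.435),
        "cheese_cake": _unit(0.05),
        "television": _unit(0.01),
        "animal": _unit(0.60),
        "doberman": _unit(0.55),
        "flower": _unit(0.02),
        "purr": _unit(0.3),
    })


IPA = {
    "cat": "kæt", "dog": "dɔɡ", "mat": "mæt", "rat": "ræt", "bread": "brɛd",
    "cak": "kæk", "choko": "tʃoʊkoʊ", "kitten": "kɪ́tən", "purr": "pɝ",
    "animal": "ænəməl", "doberman": "doʊbɚmən", "tv": "tivi",
    "television": "tɛləvɪʒən", "flower": "flaʊɚ",
}


@pytest.fixture(scope="session")
def ipa_lexicon():
    return dict(IPA)


@pytest.fixture(scope="session")
def small_sim():
    """A small noiseless simulated dataset with its resources."""
    spec = SimSpec(n_subjects=6, n_items=40, trials_per_item=2, seed=20260217)
    trials, res = simulate_trials(spec)
    return spec, trials, res
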