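import numpy as np
import pytest

from entroscan.grammar import Grammar
from entroscan.io import default_grammar_path
from entroscan.grammar import load_grammar


@pytest.fixture(scope="session")
def g6():
    """Bundled Knudsen-Hein-shaped (G6) grammar, structurally unambiguous."""
    return load_grammar(default_grammar_path("g6"))


@pytest.fixture(scope="session")
def rnd():
    """Bundled symmetric structurally ambiguous grammar."""
    return load_grammar(default_grammar_path("rnd"))


@pytest.fixture(scope="session")
def one_letter():
    """S -> SS | a over a one-letter alphabet: derivation counts are Catalan."""
    return Grammar.from_rule_probs([("S", "S S", 0.3), ("S", "a", 0.7)])


@pytest.fixture(scope="session")
def toy_eps():
    """Small grammar exercising epsilon and unit rules."""
    return Grammar.from_rule_probs(
        [
            ("S", "g E c", 0.2),
            ("S", "a S u", 0.1),
            ("S", "L S", 0.3),
            ("S", "L", 0.4),
            ("L", "a", 0.25),
            ("L", "c", 0.25),
            ("L", "g", 0.25),
            ("L", "u", 0.25),
            ("E", "eps", 0.6),
            ("E", "L", 0.4),
        ]
    )


@pytest.fixture()
def rng():
    return np.random.default_rng(20240917)
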