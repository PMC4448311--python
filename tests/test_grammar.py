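"""SCFG representation and dynamic programs vs the enumeration oracle."""

import math

import numpy as np
import pytest

from entroscan.grammar import (
    Grammar,
    GrammarError,
    SecondaryStructure,
    ZeroProbabilityError,
    cyk_predict,
    derivation_entropy,
    estimate_parameters,
    inside_logZ,
    load_grammar,
    pair_probabilities,
    sample_from_grammar,
)
from entroscan.oracle import enumerate_derivations
from entroscan.synth import random_sequence


# ---------------------------------------------------------------------------
# loading and invariants


def test_load_single_rule_grammar(tmp_path):
    p = tmp_path / "g.cfg"
    p.write_text("S -> a : 1.0\n")
    g = load_grammar(p)
    assert len(g.rules) == 1
    assert inside_logZ(g, "A") == 0.0


def test_load_rejects_bad_probability_sum(tmp_path):
    p = tmp_path / "g.cfg"
    p.write_text("S -> a : 0.5\nS -> c : 0.3\n")
    with pytest.raises(GrammarError, match="sum"):
        load_grammar(p)


def test_load_renormalizes_tiny_violation_with_warning(tmp_path):
    p = tmp_path / "g.cfg"
    p.write_text("S -> a : 0.5\nS -> c : 0.5000001\n")
    with pytest.warns(UserWarning, match="renormalized"):
        g = load_grammar(p)
    assert abs(sum(r.prob for r in g.rules) - 1.0) < 1e-12


def test_load_rejects_unknown_symbol(tmp_path):
    p = tmp_path / "g.cfg"
    p.write_text("S -> X : 1.0\n")
    with pytest.raises(GrammarError, match="unknown"):
        load_grammar(p)


def test_bundled_g6_shape(g6):
    # six production families: S->LS|L, L->xFy|x, F->xFy|LS
    kinds = {(r.lhs, r.kind) for r in g6.rules}
    assert kinds == {
        ("S", "binary"), ("S", "unit"),
        ("L", "pair"), ("L", "emit"),
        ("F", "pair"), ("F", "binary"),
    }
    for v in g6.nonterminals:
        assert sum(r.prob for r in g6.rules if r.lhs == v) == pytest.approx(1.0, abs=1e-9)
    assert g6.source_hash  # provenance hash recorded


def test_pair_emissions_respect_allowed_pairs():
    with pytest.raises(GrammarError, match="allowed"):
        Grammar.from_rule_probs(
            [("S", "g S g", 0.5), ("S", "a", 0.5)]  # G-G not a legal pair
        )


def test_cyclic_unit_rules_rejected():
    with pytest.raises(GrammarError, match="cycl"):
        Grammar.from_rule_probs(
            [("S", "T", 0.5), ("S", "a", 0.5), ("T", "S", 0.5), ("T", "a", 0.5)]
        ).compiled  # noqa: B018 - compilation triggers the check


# ---------------------------------------------------------------------------
# inside probability


def test_inside_two_parse_example(one_letter):
    # "aaa" has 2 parse trees, each 0.3^2 * 0.7^3
    assert inside_logZ(one_letter, "AAA") == pytest.approx(
        math.log(2 * 0.3**2 * 0.7**3), abs=1e-12
    )


def test_inside_zero_probability_distinct_signal():
    g = Grammar.from_rule_probs([("S", "a", 1.0)])
    with pytest.raises(ZeroProbabilityError):
        inside_logZ(g, "G")


def test_inside_empty_sequence_requires_epsilon_start(toy_eps):
    g = Grammar.from_rule_probs([("S", "eps", 0.4), ("S", "a", 0.6)])
    assert inside_logZ(g, "") == pytest.approx(math.log(0.4))
    with pytest.raises(ValueError, match="empty"):
        inside_logZ(toy_eps, "")


def test_inside_logZ_nonpositive_for_proper_grammars(g6, rnd, rng):
    for g in (g6, rnd):
        for _ in range(5):
            seq = random_sequence(int(rng.integers(5, 40)), 0.5, rng)
            assert inside_logZ(g, seq) <= 0.0


# ---------------------------------------------------------------------------
# entropy


def test_entropy_zero_for_unique_derivation():
    g = Grammar.from_rule_probs([("S", "a", 1.0)])
    assert derivation_entropy(g, "A") == 0.0


@pytest.mark.parametrize("seq,k", [("AAA", 2), ("AAAA", 5)])
def test_entropy_equiprobable_parses_is_log_count(one_letter, seq, k):
    # all parses of a^n are equiprobable under S->SS|a, so H = ln(#parses)
    assert derivation_entropy(one_letter, seq) == pytest.approx(math.log(k), abs=1e-12)


def test_entropy_base_conversion(one_letter):
    h2 = derivation_entropy(one_letter, "AAA", base=2)
    assert h2 == pytest.approx(1.0, abs=1e-12)  # 2 equiprobable parses = 1 bit


def test_entropy_bounds(toy_eps, rng):
    # 0 <= H <= ln(number of derivations)
    for _ in range(10):
        seq = random_sequence(int(rng.integers(2, 9)), 0.5, rng)
        e = enumerate_derivations(toy_eps, seq)
        h = derivation_entropy(toy_eps, seq)
        assert 0.0 <= h <= math.log(len(e.derivations)) + 1e-12


def test_scaling_stability_length_300(g6):
    # log-space DP at float64 agrees with an extended-precision re-computation
    seq = random_sequence(300, 0.5, seed=3)
    h64 = derivation_entropy(g6, seq)
    hext = derivation_entropy(g6, seq, dtype=np.longdouble)
    z64 = inside_logZ(g6, seq)
    zext = inside_logZ(g6, seq, dtype=np.longdouble)
    assert math.isfinite(h64) and math.isfinite(z64)
    assert h64 == pytest.approx(float(hext), abs=1e-6)
    assert z64 == pytest.approx(float(zext), abs=1e-6)


# ---------------------------------------------------------------------------
# pair probabilities and CYK


def test_pair_probabilities_no_legal_pair(g6):
    P = pair_probabilities(g6, "AAAA")
    assert np.all(P == 0.0)


def test_pair_probability_row_sums_at_most_one(g6, rnd, rng):
    for g in (g6, rnd):
        seq = random_sequence(30, 0.6, rng)
        P = pair_probabilities(g, seq)
        paired = P.sum(axis=0) + P.sum(axis=1)
        assert np.all(paired <= 1 + 1e-9)


def test_cyk_prefers_higher_probability_derivation():
    g = Grammar.from_rule_probs(
        [("S", "g E c", 0.6), ("S", "L S", 0.2), ("S", "L", 0.2),
         ("L", "g", 0.5), ("L", "c", 0.5), ("E", "eps", 1.0)]
    )
    assert cyk_predict(g, "GC").dotbracket == "()"


def test_cyk_tie_is_deterministic(one_letter):
    # paired and unpaired derivations of "GC" have equal probability, and the
    # two parses of "AAA" are exactly equiprobable; the prediction must be
    # stable across runs and across fresh grammar objects, and always attain
    # the enumerated maximum probability
    triples = [("S", "g E c", 0.03125), ("S", "L S", 0.5), ("S", "L", 0.25),
               ("S", "a S u", 0.21875),
               ("L", "g", 0.5), ("L", "c", 0.5), ("E", "eps", 1.0)]
    e = enumerate_derivations(Grammar.from_rule_probs(triples), "GC")
    probs = sorted(d.probability for d in e.derivations)
    assert probs[-1] == pytest.approx(probs[-2])  # genuine tie
    results = {
        cyk_predict(Grammar.from_rule_probs(triples), "GC").dotbracket for _ in range(5)
    }
    assert len(results) == 1
    _, lp = cyk_predict(Grammar.from_rule_probs(triples), "GC", return_logp=True)
    assert math.exp(lp) == pytest.approx(e.max_probability())
    # leftmost-split tie on the one-letter grammar
    assert len({cyk_predict(one_letter, "AAA").dotbracket for _ in range(5)}) == 1


def test_unique_derivation_structure(g6):
    # a sequence forced into a single structure predicts that structure
    g = Grammar.from_rule_probs(
        [("S", "g F c", 1.0), ("F", "a", 1.0)]
    )
    assert cyk_predict(g, "GAC").dotbracket == "(.)"


# ---------------------------------------------------------------------------
# oracle equivalence battery (smaller sibling of the acceptance run)


def test_oracle_equivalence_battery(g6, rnd, toy_eps, rng):
    worst = 0.0
    for g in (g6, rnd, toy_eps):
        for _ in range(12):
            seq = random_sequence(int(rng.integers(1, 11)), 0.5, rng)
            e = enumerate_derivations(g, seq)
            worst = max(worst, abs(e.log_inside() - inside_logZ(g, seq)))
            worst = max(worst, abs(e.entropy() - derivation_entropy(g, seq)))
            worst = max(
                worst, float(np.abs(e.pair_probabilities() - pair_probabilities(g, seq)).max())
            )
            ss, lp = cyk_predict(g, seq, return_logp=True)
            worst = max(worst, abs(math.exp(lp) - e.max_probability()))
            if len(e.argmax_structures()) == 1:
                assert ss in e.argmax_structures()
    assert worst < 1e-9


# ---------------------------------------------------------------------------
# training


def test_estimate_parameters_hand_count(g6):
    # unique derivation of GAAAC with (...): one G-C pair emission, three
    # unpaired A emissions; probabilities are the normalized counts
    trained = estimate_parameters([("GAAAC", SecondaryStructure("(...)"))], g6)
    by_text = {(r.lhs, r.rhs_text()): r.prob for r in trained.rules}
    assert by_text[("L", "g F c")] == pytest.approx(0.25)
    assert by_text[("L", "a")] == pytest.approx(0.75)
    assert by_text[("F", "L S")] == pytest.approx(1.0)
    assert by_text[("S", "L S")] == pytest.approx(1 / 3)


def test_estimate_parameters_empty_training(g6):
    with pytest.raises(ValueError, match="empty"):
        estimate_parameters([], g6)


def test_estimate_parameters_underivable_structure(g6):
    # G-G cannot pair, so the structure is not derivable under the shape
    with pytest.raises(ValueError, match="not derivable"):
        estimate_parameters([("GG", SecondaryStructure("()"))], g6)


def test_parameter_recovery_from_sampled_structures(g6):
    rng = np.random.default_rng(5)
    train = [sample_from_grammar(g6, rng, max_len=80) for _ in range(1000)]
    est = estimate_parameters(train, g6)
    for r_est, r_true in zip(est.rules, g6.rules):
        assert abs(r_est.prob - r_true.prob) <= 0.05


# ---------------------------------------------------------------------------
# secondary structure type


def test_dotbracket_validation():
    with pytest.raises(ValueError):
        SecondaryStructure("(()")
    with pytest.raises(ValueError):
        SecondaryStructure("())")
    with pytest.raises(ValueError):
        SecondaryStructure.from_pairs(4, [(1, 3), (2, 4)])  # crossing
    with pytest.raises(ValueError):
        SecondaryStructure.from_pairs(4, [(1, 3), (3, 4)])  # shared position
    s = SecondaryStructure("((..))")
    assert s.pairs == frozenset({(1, 6), (2, 5)})
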