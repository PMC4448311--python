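"""Composition, MFE engines, base-pairing entropy, feature assembly."""

import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from entroscan.features import (
    FeatureConfig,
    SimplePairEnergyEngine,
    SIMPLE_PAIR_ENERGIES,
    base_pair_entropy,
    composition,
    feature_vector,
    get_engine,
    minimum_free_energy,
    reverse_complement,
)
from entroscan.grammar import WATSON_CRICK_GU
from entroscan.oracle import min_energy_by_enumeration
from entroscan.synth import random_sequence

rna_strings = st.text(alphabet="ACGU", min_size=1, max_size=30)


@pytest.mark.parametrize(
    "seq,gc,gu,gcu,u",
    [
        ("GGCC", 1.0, 0.5, 1.0, 0.0),
        ("GAUC", 0.5, 0.5, 0.75, 0.25),
        ("AAAA", 0.0, 0.0, 0.0, 0.0),
    ],
)
def test_composition_examples(seq, gc, gu, gcu, u):
    assert composition(seq) == pytest.approx((gc, gu, gcu, u))


def test_composition_empty_sequence():
    with pytest.raises(ValueError):
        composition("")


@pytest.mark.parametrize("seq,rc", [("GAUC", "GAUC"), ("AAGG", "CCUU")])
def test_reverse_complement_examples(seq, rc):
    assert reverse_complement(seq) == rc


@settings(deadline=None, derandomize=True)
@given(rna_strings)
def test_reverse_complement_involution_and_symmetries(seq):
    rc = reverse_complement(seq)
    assert reverse_complement(rc) == seq
    gc, _, _, u = composition(seq)
    gc_rc, _, _, u_rc = composition(rc)
    assert gc_rc == pytest.approx(gc)  # GC preserved under antisense
    assert u_rc == pytest.approx(seq.count("A") / len(seq))  # U(rc) = A-fraction
    assert len(rc) == len(seq)


def test_reverse_complement_invalid_character():
    with pytest.raises(ValueError):
        reverse_complement("AXG")


# ---------------------------------------------------------------------------
# base-pairing entropy


def test_base_pair_entropy_zero_matrix():
    assert base_pair_entropy(np.zeros((5, 5)), 5) == 0.0


def test_base_pair_entropy_half_probability_pair():
    P = np.zeros((2, 2))
    P[0, 1] = 0.5
    # -(1/2) * 0.5 ln 0.5
    assert base_pair_entropy(P, 2) == pytest.approx(0.173287, abs=1e-6)


def test_base_pair_entropy_certain_pair_contributes_zero():
    P = np.zeros((4, 4))
    P[0, 3] = 1.0
    assert base_pair_entropy(P, 4) == 0.0


def test_base_pair_entropy_requires_positive_length():
    with pytest.raises(ValueError):
        base_pair_entropy(np.zeros((2, 2)), 0)


def test_base_pair_entropy_order_invariant(rng):
    # symmetric under permutation-conjugation of the matrix entries' order
    P = np.triu(rng.random((6, 6)) * 0.3, k=1)
    v = base_pair_entropy(P, 6)
    assert v >= 0
    assert base_pair_entropy(P * 1.0, 6) == pytest.approx(v)


# ---------------------------------------------------------------------------
# MFE engines


def test_simple_engine_open_chain():
    eng = SimplePairEnergyEngine()
    assert minimum_free_energy("AAAA", eng) == 0.0


@pytest.mark.parametrize("seed", range(4))
def test_simple_engine_matches_enumeration(seed):
    eng = SimplePairEnergyEngine(min_hairpin=3)
    seq = random_sequence(11, 0.6, seed=seed)
    brute = min_energy_by_enumeration(
        seq, SIMPLE_PAIR_ENERGIES, WATSON_CRICK_GU, min_hairpin=3
    )
    assert eng.mfe(seq) == pytest.approx(brute, abs=1e-9)


def test_simple_engine_ggg_aaa_ccc():
    eng = SimplePairEnergyEngine(min_hairpin=3)
    seq = "GGGAAACCC"
    brute = min_energy_by_enumeration(
        seq, SIMPLE_PAIR_ENERGIES, WATSON_CRICK_GU, min_hairpin=3
    )
    e, struct = eng.fold(seq)
    assert e == pytest.approx(brute)
    assert e == pytest.approx(-9.0)  # three GC pairs
    assert struct.dotbracket == "(((...)))"


def test_vienna_engine_mfe_nonpositive():
    eng = get_engine("vienna")
    for seed in range(3):
        assert eng.mfe(random_sequence(60, 0.55, seed=seed)) <= 0.0


def test_unknown_engine_rejected():
    with pytest.raises(ValueError):
        get_engine("nupack")


# ---------------------------------------------------------------------------
# feature vector


def test_feature_vector_assembly_and_determinism(g6, rnd):
    seq = random_sequence(60, 0.5, seed=9)
    cfg = FeatureConfig(
        bjk_grammar=g6, rnd_grammar=rnd, engine=SimplePairEnergyEngine(),
        compute_sil=True, sil_samples=40, seed=11,
    )
    fv1 = feature_vector(seq, cfg, seq_id="x")
    fv2 = feature_vector(seq, cfg, seq_id="x")
    assert fv1.L == 60
    assert fv1.as_dict() == fv2.as_dict()
    assert fv1.RND >= 0 and fv1.BJK >= 0 and fv1.BJKbp >= 0
    assert -1 <= fv1.Sil <= 1


def test_feature_vector_antisense_symmetry(g6):
    seq = random_sequence(40, 0.5, seed=2)
    cfg = FeatureConfig(bjk_grammar=g6)
    sense = feature_vector(seq, cfg)
    anti = feature_vector(reverse_complement(seq), cfg)
    assert anti.L == sense.L
    assert anti.GC == pytest.approx(sense.GC)
    assert anti.U == pytest.approx(seq.count("A") / len(seq))


def test_feature_vector_length_normalization(rnd):
    seq = random_sequence(50, 0.5, seed=4)
    total = feature_vector(seq, FeatureConfig(rnd_grammar=rnd))
    per_nt = feature_vector(seq, FeatureConfig(rnd_grammar=rnd, normalize_by_length=True))
    assert per_nt.RND == pytest.approx(total.RND / 50)
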