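"""Window extraction conventions, ranking, and empirical p-values."""

import numpy as np
import pytest

from entroscan.classify import LogisticModel
from entroscan.features import FeatureConfig, get_engine
from entroscan.scan import (
    GenomeAnnotation,
    Interval,
    ScanFilters,
    empirical_pvalue,
    extract_windows,
    intergenic_regions,
    scan_and_rank,
    tile_region,
    true_positive_windows,
)
from entroscan.synth import mirrored_toy_genome, toy_genome


@pytest.fixture(scope="module")
def tg():
    return toy_genome(seed=1)


@pytest.fixture(scope="module")
def hand_model():
    # stability + GC composition separate planted switch-like windows
    return LogisticModel(
        classes=("background", "riboswitch"),
        reference_class="background",
        feature_names=("MFE", "GC"),
        coefficients=np.array([[0.0, 0.0, 0.0], [-3.0, -0.05, 2.0]]),
    )


@pytest.fixture(scope="module")
def scan_config():
    return FeatureConfig(engine=get_engine("vienna"))


# ---------------------------------------------------------------------------
# tiling conventions


def test_tiling_window_count_formula(rng):
    for _ in range(50):
        R = int(rng.integers(1, 900))
        W = int(rng.integers(10, 300))
        S = W - int(rng.integers(0, W))
        region = Interval("x", 101, 100 + R, "+")
        n = len(tile_region(region, W, W - S))
        expected = 1 + (R - W) // S if R >= W else 0
        assert n == expected


def test_region_of_150_is_skipped():
    genome = {"x": "A" * 1000}
    ann = GenomeAnnotation(
        [Interval("x", 1, 100, "+", "g1"), Interval("x", 251, 1000, "+", "g2")]
    )  # intergenic region 101..250 has length exactly 150
    assert extract_windows(genome, ann, 100, 0) == []


def test_region_just_over_cutoff_yields_downstream_anchored_window():
    genome = {"x": "A" * 1000}
    ann = GenomeAnnotation(
        [Interval("x", 1, 100, "+", "g1"), Interval("x", 301, 1000, "+", "g2")]
    )  # region 101..300, length 200
    ws = extract_windows(genome, ann, 157, 0, strands="+")
    assert len(ws) == 1
    assert (ws[0].start, ws[0].end) == (144, 300)  # ends at the start codon


def test_two_windows_for_length_314():
    genome = {"x": "C" * 1400}
    ann = GenomeAnnotation(
        [Interval("x", 1, 86, "+", "g1"), Interval("x", 401, 1400, "+", "g2")]
    )  # region 87..400, length 314
    ws = extract_windows(genome, ann, 157, 0, strands="+")
    assert [(w.start, w.end) for w in ws] == [(244, 400), (87, 243)]
    assert ws[0].end == 400  # downstream window flush against the gene start


def test_reverse_strand_window_sequence_is_reverse_complemented():
    genome = {"x": "G" * 160 + "A" * 200 + "C" * 160}
    ann = GenomeAnnotation(
        [Interval("x", 1, 160, "+", "g1"), Interval("x", 361, 520, "+", "g2")]
    )
    ws = extract_windows(genome, ann, 157, 0)
    fwd = [w for w in ws if w.strand == "+"]
    rev = [w for w in ws if w.strand == "-"]
    assert fwd and rev
    assert all(set(w.sequence) == {"A"} for w in fwd)
    assert all(set(w.sequence) == {"U"} for w in rev)


def test_invalid_window_parameters():
    region = Interval("x", 1, 500, "+")
    with pytest.raises(ValueError):
        tile_region(region, 0, 0)
    with pytest.raises(ValueError):
        tile_region(region, 100, 100)


def test_annotation_must_match_genome(tg):
    bad = GenomeAnnotation([Interval("nope", 1, 10, "+")])
    with pytest.raises(ValueError, match="unknown sequence"):
        intergenic_regions(tg.sequences, bad)


# ---------------------------------------------------------------------------
# empirical p-values


@pytest.mark.parametrize(
    "rank,total,printed",
    [(347, 28340, "0.0122"), (535, 28340, "0.0189")],
)
def test_empirical_pvalue_prints_published_values(rank, total, printed):
    assert f"{empirical_pvalue(rank, total):.4f}" == printed


def test_empirical_pvalue_extremes():
    assert empirical_pvalue(1, 10) == pytest.approx(0.1)
    assert empirical_pvalue(10, 10) == 1.0
    with pytest.raises(ValueError):
        empirical_pvalue(0, 10)
    with pytest.raises(ValueError):
        empirical_pvalue(11, 10)


# ---------------------------------------------------------------------------
# full scan on the toy genome


def test_planted_windows_rank_first(tg, hand_model, scan_config):
    ws = extract_windows(tg.sequences, tg.annotation, 157, 0, strands="+")
    hits = scan_and_rank(ws, hand_model, scan_config, p_value_features=("GC", "U"))
    planted = {(k.start, k.end) for k in tg.known_elements}
    top = {(h.window.start, h.window.end) for h in hits[: len(planted)]}
    assert top == planted
    # ranks are 1..N and p-values monotone in rank with best = 1/N
    assert [h.rank for h in hits] == list(range(1, len(ws) + 1))
    ps = [min(h.empirical_p.values()) for h in hits]
    assert min(ps) == pytest.approx(1 / len(ws))


def test_known_elements_match_their_windows(tg):
    ws = extract_windows(tg.sequences, tg.annotation, 157, 0, strands="+")
    tp = true_positive_windows(ws, tg.known_elements)
    for k in tg.known_elements:
        w = tp[k.name]
        assert w is not None and (w.start, w.end) == (k.start, k.end)


def test_mirrored_scan_reproduces_hits_with_flipped_strand(tg, hand_model, scan_config):
    mirror = mirrored_toy_genome(tg)
    ws_f = extract_windows(tg.sequences, tg.annotation, 157, 0)
    ws_m = extract_windows(mirror.sequences, mirror.annotation, 157, 0)
    L = len(tg.sequences["toy1"])

    def key(w):
        return (w.seq_id, w.start, w.end, w.strand, w.sequence)

    flipped = {
        (w.seq_id, L - w.end + 1, L - w.start + 1, "-" if w.strand == "+" else "+", w.sequence)
        for w in ws_m
    }
    assert {key(w) for w in ws_f} == flipped


def test_probability_ties_break_by_coordinate(tg, hand_model):
    # all-equal features (constant windows) force probability ties
    genome = {"x": "A" * 160 + "GCGC" * 100 + "A" * 160}
    ann = GenomeAnnotation(
        [Interval("x", 1, 160, "+", "g1"), Interval("x", 561, 720, "+", "g2")]
    )
    ws = extract_windows(genome, ann, 100, 50, strands="+")
    model = LogisticModel(
        ("background", "riboswitch"), "background", ("GC",),
        np.array([[0.0, 0.0], [0.0, 1.0]]),
    )
    hits = scan_and_rank(ws, model, FeatureConfig(), p_value_features=("GC",))
    starts = [h.window.start for h in hits]
    probs = [h.probability for h in hits]
    tied = [s for s, p in zip(starts, probs) if p == probs[0]]
    assert tied == sorted(tied)
    # tied feature values share the best (smallest) rank
    tied_ps = {h.empirical_p["GC"] for h in hits if h.probability == probs[0]}
    assert len(tied_ps) == 1


def test_composition_filter_excludes_out_of_range(tg, hand_model, scan_config):
    ws = extract_windows(tg.sequences, tg.annotation, 157, 0, strands="+")
    filters = ScanFilters(u_range=(0.2484, 0.40127))
    hits = scan_and_rank(ws, hand_model, scan_config, filters=filters)
    assert all(0.2484 <= h.features["U"] <= 0.40127 for h in hits)
    full = scan_and_rank(ws, hand_model, scan_config)
    assert len(hits) < len(full)  # GC-rich planted windows are uracil-poor


def test_operon_distances(tg, hand_model, scan_config):
    ws = extract_windows(tg.sequences, tg.annotation, 157, 0, strands="+")
    hits = scan_and_rank(ws, hand_model, scan_config, annotation=tg.annotation)
    for h in hits:
        assert h.dist_upstream is None or h.dist_upstream < 0
        assert h.dist_downstream is None or h.dist_downstream > 0


def test_empty_window_set_rejected(hand_model, scan_config):
    with pytest.raises(ValueError):
        scan_and_rank([], hand_model, scan_config)
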