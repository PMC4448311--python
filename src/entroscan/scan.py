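"""Sliding-window scanning of intergenic regions.

Windows are tiled through each intergenic region *anchored at the
downstream end*: the most downstream window ends exactly at the start
codon of the downstream gene/operon (where a riboswitch would sit),
further windows step upstream by ``window_len − overlap``.  Regions of
150 nt or shorter are skipped, partial windows are dropped, and
reverse-strand windows carry the reverse-complemented sequence.
Coordinates are reported 1-based inclusive on the forward axis (GenBank
convention); internal arithmetic is half-open and converted at I/O.

Each window is scored with a fitted classifier; the riboswitch-class
probability ranks the windows, and per-feature empirical p-values
(rank within the scan divided by the number of windows) quantify how
extreme a window's statistic is relative to the genomic background.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .classify import LogisticModel, predict_proba
from .features import FeatureConfig, feature_vector, reverse_complement

#: regions must be strictly longer than this many nucleotides to be scanned
MIN_REGION_LENGTH = 150


@dataclass
class Interval:
    """1-based inclusive genomic interval."""

    seq_id: str
    start: int
    end: int
    strand: str
    name: str = ""

    def __post_init__(self):
        if self.start > self.end:
            raise ValueError(f"interval start > end: {self}")
        if self.strand not in "+-":
            raise ValueError(f"strand must be + or -: {self.strand!r}")

    @property
    def length(self) -> int:
        return self.end - self.start + 1


@dataclass
class GenomeAnnotation:
    """Gene/operon intervals per sequence."""

    intervals: list[Interval]

    @classmethod
    def read_tsv(cls, path: str | Path) -> "GenomeAnnotation":
        df = pd.read_csv(path, sep="\t", comment="#")
        required = {"seq_id", "start", "end", "strand"}
        if not required <= set(df.columns):
            raise ValueError(f"annotation needs columns {sorted(required)}")
        ivs = [
            Interval(
                str(r.seq_id), int(r.start), int(r.end), str(r.strand),
                str(getattr(r, "name", "")) if "name" in df.columns else "",
            )
            for r in df.itertuples()
        ]
        return cls(ivs)

    def write_tsv(self, path: str | Path) -> None:
        pd.DataFrame(
            [
                {"seq_id": i.seq_id, "start": i.start, "end": i.end,
                 "strand": i.strand, "name": i.name}
                for i in self.intervals
            ]
        ).to_csv(path, sep="\t", index=False)

    def validate_against(self, genome: Mapping[str, str]) -> None:
        for iv in self.intervals:
            if iv.seq_id not in genome:
                raise ValueError(f"annotation references unknown sequence {iv.seq_id!r}")
            if iv.end > len(genome[iv.seq_id]):
                raise ValueError(f"interval beyond sequence end: {iv}")


@dataclass
class Window:
    """One scanned segment (coordinates 1-based inclusive, forward axis)."""

    seq_id: str
    start: int
    end: int
    strand: str
    sequence: str
    region_id: str = ""

    @property
    def center(self) -> float:
        return (self.start + self.end) / 2


@dataclass
class WindowHit:
    """A scored window."""

    window: Window
    features: dict
    probability: float
    rank: int = 0
    empirical_p: dict = field(default_factory=dict)
    dist_upstream: float | None = None
    dist_downstream: float | None = None
    upstream_name: str = ""
    downstream_name: str = ""


def intergenic_regions(
    genome: Mapping[str, str], annotation: GenomeAnnotation
) -> list[Interval]:
    """Maximal intervals not covered by any annotated gene/operon."""
    annotation.validate_against(genome)
    regions = []
    for seq_id, seq in genome.items():
        ivs = sorted(
            (iv for iv in annotation.intervals if iv.seq_id == seq_id),
            key=lambda iv: iv.start,
        )
        pos = 1
        counter = 0
        merged: list[tuple[int, int]] = []
        for iv in ivs:
            if merged and iv.start <= merged[-1][1] + 1:
                merged[-1] = (merged[-1][0], max(merged[-1][1], iv.end))
            else:
                merged.append((iv.start, iv.end))
        for s, e in merged:
            if s > pos:
                counter += 1
                regions.append(
                    Interval(seq_id, pos, s - 1, "+", name=f"{seq_id}_ig{counter}")
                )
            pos = max(pos, e + 1)
        if pos <= len(seq):
            counter += 1
            regions.append(
                Interval(seq_id, pos, len(seq), "+", name=f"{seq_id}_ig{counter}")
            )
    return regions


def tile_region(
    region: Interval, window_len: int, overlap: int
) -> list[tuple[int, int]]:
    """Window coordinates for one region, downstream-anchored for + strand.

    The last window ends at the region's 3' end (forward axis end); windows
    step upstream by ``window_len − overlap``; partial windows are dropped.
    For a region of length R: ``1 + floor((R − W)/S)`` windows when R ≥ W.
    """
    if window_len < 1:
        raise ValueError("window_len must be >= 1")
    if not (0 <= overlap < window_len):
        raise ValueError("overlap must satisfy 0 <= overlap < window_len")
    step = window_len - overlap
    out = []
    end = region.end
    while end - window_len + 1 >= region.start:
        out.append((end - window_len + 1, end))
        end -= step
    return out


def extract_windows(
    genome: Mapping[str, str],
    annotation: GenomeAnnotation,
    window_len: int,
    overlap: int = 0,
    strands: str = "+-",
    min_region_length: int = MIN_REGION_LENGTH,
) -> list[Window]:
    """All scan windows over the intergenic regions of ``genome``.

    Only regions strictly longer than ``min_region_length`` are tiled.
    On the forward strand windows anchor at the region's right edge (the
    downstream gene's start codon); on the reverse strand the downstream
    gene lies to the left, so windows anchor at the region's left edge and
    the emitted sequence is reverse-complemented.
    """
    windows: list[Window] = []
    for region in intergenic_regions(genome, annotation):
        if region.length <= min_region_length:
            continue
        seq = genome[region.seq_id]
        if "+" in strands:
            for s, e in tile_region(region, window_len, overlap):
                windows.append(
                    Window(region.seq_id, s, e, "+", seq[s - 1 : e], region.name)
                )
        if "-" in strands:
            # mirror: anchor at the region's left edge, step right
            step = window_len - overlap
            start = region.start
            while start + window_len - 1 <= region.end:
                s, e = start, start + window_len - 1
                windows.append(
                    Window(
                        region.seq_id, s, e, "-",
                        reverse_complement(seq[s - 1 : e]), region.name,
                    )
                )
                start += step
    return windows


def empirical_pvalue(rank: int, total: int) -> float:
    """rank/total; the scan's empirical significance of a ranked window."""
    if not (1 <= rank <= total):
        raise ValueError(f"rank {rank} out of range 1..{total}")
    return rank / total


def _ranks_min_ties(values: np.ndarray, descending: bool) -> np.ndarray:
    """Competition ranks (1 = most extreme); ties share the best rank."""
    v = -values if descending else values
    order = np.argsort(v, kind="stable")
    ranks = np.empty(len(v), dtype=int)
    r = 1
    for k, idx in enumerate(order):
        if k > 0 and v[idx] != v[order[k - 1]]:
            r = k + 1
        ranks[idx] = r
    return ranks


@dataclass
class ScanFilters:
    """Post-ranking hit filters.

    ``u_range``/``gc_range`` restrict composition to the span observed in
    known riboswitches; ``max_feature_p`` demands per-feature empirical
    significance; ``min_probability`` cuts on the classifier score.
    """

    u_range: tuple[float, float] | None = None
    gc_range: tuple[float, float] | None = None
    max_feature_p: Mapping[str, float] = field(default_factory=dict)
    min_probability: float | None = None

    def keeps(self, hit: WindowHit) -> bool:
        f = hit.features
        if self.u_range and not (self.u_range[0] <= f["U"] <= self.u_range[1]):
            return False
        if self.gc_range and not (self.gc_range[0] <= f["GC"] <= self.gc_range[1]):
            return False
        for feat, cutoff in self.max_feature_p.items():
            if hit.empirical_p.get(feat, 1.0) >= cutoff:
                return False
        if self.min_probability is not None and hit.probability < self.min_probability:
            return False
        return True


#: which direction counts as "extreme" for per-feature empirical p-values
P_VALUE_DIRECTIONS = {"RND": "high", "BJK": "high", "BJKbp": "high", "Sil": "high",
                      "GC": "low", "U": "low", "MFE": "low"}


def scan_and_rank(
    windows: Sequence[Window],
    model: LogisticModel,
    feature_config: FeatureConfig,
    riboswitch_class: str = "riboswitch",
    filters: ScanFilters | None = None,
    annotation: GenomeAnnotation | None = None,
    p_value_features: Sequence[str] = (),
) -> list[WindowHit]:
    """Score every window, rank by riboswitch probability, attach p-values.

    Ranking is by probability descending with ties broken by genomic
    coordinate; per-feature empirical p-values are computed within the
    scan (rank of the feature value in its extreme direction over the
    number of windows, ties sharing the best rank).  ``filters`` are
    applied after ranking, so ranks and p-values refer to the full scan.
    """
    if not windows:
        raise ValueError("empty window set")
    rows = []
    for w in windows:
        fv = feature_vector(w.sequence, feature_config, seq_id=f"{w.seq_id}:{w.start}-{w.end}{w.strand}")
        rows.append(fv.as_dict())
    table = pd.DataFrame(rows)
    probs = predict_proba(model, table)
    if riboswitch_class not in probs.columns:
        raise ValueError(f"model has no class {riboswitch_class!r}")
    p_ribo = probs[riboswitch_class].to_numpy()

    hits = [
        WindowHit(window=w, features=rows[i], probability=float(p_ribo[i]))
        for i, w in enumerate(windows)
    ]
    total = len(hits)
    for feat in p_value_features:
        vals = table[feat].to_numpy(dtype=float)
        descending = P_VALUE_DIRECTIONS.get(feat, "high") == "high"
        ranks = _ranks_min_ties(vals, descending)
        for h, r in zip(hits, ranks):
            h.empirical_p[feat] = empirical_pvalue(int(r), total)

    hits.sort(key=lambda h: (-h.probability, h.window.seq_id, h.window.start, h.window.strand))
    for i, h in enumerate(hits, start=1):
        h.rank = i
    if annotation is not None:
        for h in hits:
            _attach_operon_distances(h, annotation)
    if filters is not None:
        hits = [h for h in hits if filters.keeps(h)]
    return hits


def _attach_operon_distances(hit: WindowHit, annotation: GenomeAnnotation) -> None:
    """Signed distances from the window center to the flanking annotations.

    Negative = to the upstream operon's stop-codon side (behind the
    window), positive = to the downstream operon's start codon.
    """
    c = hit.window.center
    left = [iv for iv in annotation.intervals if iv.seq_id == hit.window.seq_id and iv.end < hit.window.start]
    right = [iv for iv in annotation.intervals if iv.seq_id == hit.window.seq_id and iv.start > hit.window.end]
    if left:
        up = max(left, key=lambda iv: iv.end)
        hit.dist_upstream = -(c - up.end)
        hit.upstream_name = up.name
    if right:
        down = min(right, key=lambda iv: iv.start)
        hit.dist_downstream = down.start - c
        hit.downstream_name = down.name


def true_positive_windows(
    windows: Sequence[Window], known: Sequence[Interval]
) -> dict[str, Window | None]:
    """For each known element, the window with maximum overlap (or None)."""
    out: dict[str, Window | None] = {}
    for k in known:
        best = None
        best_ov = 0
        for w in windows:
            if w.seq_id != k.seq_id:
                continue
            ov = min(w.end, k.end) - max(w.start, k.start) + 1
            if ov > best_ov:
                best_ov = ov
                best = w
        out[k.name or f"{k.seq_id}:{k.start}-{k.end}"] = best
    return out


def hits_to_table(hits: Sequence[WindowHit]) -> pd.DataFrame:
    """Report table: location, features, probability, p-values, distances."""
    rows = []
    for h in hits:
        row = {
            "seq_id": h.window.seq_id,
            "start": h.window.start,
            "end": h.window.end,
            "strand": h.window.strand,
            "rank": h.rank,
            "probability": h.probability,
            "dist_upstream": h.dist_upstream,
            "dist_downstream": h.dist_downstream,
            "upstream": h.upstream_name,
            "downstream": h.downstream_name,
        }
        row.update({k: v for k, v in h.features.items() if k != "id"})
        row.update({f"p_{k}": v for k, v in h.empirical_p.items()})
        rows.append(row)
    return pd.DataFrame(rows)
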