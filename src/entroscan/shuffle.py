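"""Dinucleotide-preserving shuffles and the MFE-similarity filter.

Negative-control sequences are generated by the Altschul–Erickson
Eulerian-path scheme: the sequence is viewed as a walk on the
nucleotide multigraph whose edges are its dinucleotides; a uniformly
random Eulerian path with the same start and end vertex yields a shuffle
with exactly the same dinucleotide multiset (hence the same
mononucleotide counts, length, and first/last base).  Uniformity over
Eulerian paths follows from drawing the "last-exit" edges as a uniformly
random arborescence into the terminal vertex (BEST theorem) and
permuting the remaining edges uniformly.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass, field

import numpy as np

from .grammar import normalize_sequence


def dinucleotide_counts(seq: str) -> Counter:
    return Counter(seq[i : i + 2] for i in range(len(seq) - 1))


def dinucleotide_shuffle(seq: str, seed: int | np.random.Generator = 0) -> str:
    """One uniform-random dinucleotide-preserving shuffle of ``seq``.

    Preserves the dinucleotide multiset and the first and last
    nucleotide; deterministic under ``seed``.
    """
    seq = normalize_sequence(seq)
    if len(seq) < 2:
        raise ValueError("sequence must have length >= 2")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)

    first, last = seq[0], seq[-1]
    edges: dict[str, list[str]] = {}
    for i in range(len(seq) - 1):
        edges.setdefault(seq[i], []).append(seq[i + 1])
    vertices = sorted(edges.keys() | {last})

    def reaches_last(last_exit: dict[str, str]) -> bool:
        # the chosen last-exit edges must form an arborescence into `last`
        for v in vertices:
            if v == last:
                continue
            seen = set()
            u = v
            while u != last:
                if u in seen or u not in last_exit:
                    return False
                seen.add(u)
                u = last_exit[u]
        return True

    while True:  # rejection-sample the last-exit arborescence
        last_exit = {}
        for v in vertices:
            if v == last or v not in edges:
                continue
            last_exit[v] = edges[v][int(rng.integers(len(edges[v])))]
        if reaches_last(last_exit):
            break

    # permute the remaining edges uniformly, append the last-exit edge
    ordering: dict[str, list[str]] = {}
    for v, out in edges.items():
        rest = list(out)
        if v != last:
            rest.remove(last_exit[v])
        perm = [rest[i] for i in rng.permutation(len(rest))]
        if v != last:
            perm.append(last_exit[v])
        else:
            # edges out of the terminal vertex are fully permuted
            perm = [out[i] for i in rng.permutation(len(out))]
        ordering[v] = perm

    walk = [first]
    position = {v: 0 for v in vertices}
    u = first
    for _ in range(len(seq) - 1):
        nxt = ordering[u][position[u]]
        position[u] += 1
        walk.append(nxt)
        u = nxt
    out = "".join(walk)
    assert dinucleotide_counts(out) == dinucleotide_counts(seq)
    return out


@dataclass
class ShuffleSet:
    """Shuffles of one source sequence plus the MFE-filter verdicts."""

    source_id: str
    source_seq: str
    shuffles: list[str]
    seed: int
    mfes: list[float] = field(default_factory=list)
    kept_mask: list[bool] = field(default_factory=list)

    @property
    def kept(self) -> list[str]:
        if not self.kept_mask:
            return list(self.shuffles)
        return [s for s, k in zip(self.shuffles, self.kept_mask) if k]


def make_shuffles(source_id: str, seq: str, n: int, seed: int = 0) -> ShuffleSet:
    rng = np.random.default_rng(seed)
    return ShuffleSet(
        source_id=source_id,
        source_seq=normalize_sequence(seq),
        shuffles=[dinucleotide_shuffle(seq, rng) for _ in range(n)],
        seed=seed,
    )


# ---------------------------------------------------------------------------
# MFE-similarity filter


@dataclass
class MfeFilterRule:
    """Threshold rule f(mean, std) deciding which shuffles to keep.

    ``mode='discard_above_mean_plus_std'`` (default) discards shuffles
    whose MFE exceeds reference mean + k·std — i.e. weakly folding
    shuffles are removed so the control set's stability matches the
    riboswitches.  ``mode='discard_above_mean_minus_std'`` is the literal
    mirror-image reading; both are provided because the filter direction
    is genuinely ambiguous for negative energies.
    """

    mode: str = "discard_above_mean_plus_std"
    k: float = 1.0

    def threshold(self, mean: float, std: float) -> float:
        if self.mode == "discard_above_mean_plus_std":
            return mean + self.k * std
        if self.mode == "discard_above_mean_minus_std":
            return mean - self.k * std
        raise ValueError(f"unknown filter mode {self.mode!r}")

    def keeps(self, mfe: float, mean: float, std: float) -> bool:
        return mfe <= self.threshold(mean, std)


def filter_by_mfe(
    shuffle_set: ShuffleSet,
    reference_mfes: list[float],
    rule: MfeFilterRule | None = None,
    engine=None,
) -> ShuffleSet:
    """Apply the MFE-similarity filter in place and return the set.

    ``reference_mfes`` are the MFEs of the real sequences whose stability
    distribution the kept shuffles should match; the threshold is
    ``rule.threshold(mean, std)`` of that reference.  Shuffle MFEs are
    taken from ``shuffle_set.mfes`` or computed with ``engine``.
    """
    if not reference_mfes:
        raise ValueError("empty reference MFE set")
    rule = rule or MfeFilterRule()
    if not shuffle_set.mfes:
        if engine is None:
            raise ValueError("no shuffle MFEs stored and no engine supplied")
        shuffle_set.mfes = [engine.mfe(s) for s in shuffle_set.shuffles]
    mean = float(np.mean(reference_mfes))
    std = float(np.std(reference_mfes, ddof=1)) if len(reference_mfes) > 1 else 0.0
    shuffle_set.kept_mask = [rule.keeps(m, mean, std) for m in shuffle_set.mfes]
    return shuffle_set


def summarize_sets(feature_rows: "list[dict]") -> "object":
    """Mean/std summary of L, MFE, GC for a set of sequences (table-style)."""
    import pandas as pd

    df = pd.DataFrame(feature_rows)
    out = {}
    for col in ("L", "MFE", "GC"):
        if col in df:
            out[col] = float(df[col].mean())
            out[f"std({col})"] = float(df[col].std(ddof=1))
    return pd.Series(out)
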