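"""Brute-force enumeration oracles.

Exhaustive recursion over all derivations (and all non-crossing
structures) for short sequences.  Deliberately independent of the
dynamic programs in :mod:`entroscan.grammar`: these are the reference
implementations the charts are tested against, kept naive on purpose.
"""

from __future__ import annotations

import math
from collections import Counter
from dataclasses import dataclass

import numpy as np

from .grammar import Grammar, Rule, SecondaryStructure, normalize_sequence


@dataclass
class Derivation:
    probability: float
    pairs: frozenset[tuple[int, int]]  # 1-based
    rule_uses: Counter

    def structure(self, n: int) -> SecondaryStructure:
        return SecondaryStructure.from_pairs(n, self.pairs)


@dataclass
class DerivationEnumeration:
    """All derivations of one sequence with exact probabilities."""

    sequence: str
    derivations: list[Derivation]

    @property
    def total(self) -> float:
        return sum(d.probability for d in self.derivations)

    def log_inside(self) -> float:
        return math.log(self.total)

    def entropy(self) -> float:
        z = self.total
        return -sum(
            (d.probability / z) * math.log(d.probability / z) for d in self.derivations
        )

    def pair_probabilities(self) -> np.ndarray:
        n = len(self.sequence)
        z = self.total
        P = np.zeros((n, n))
        for d in self.derivations:
            for i, j in d.pairs:
                P[i - 1, j - 1] += d.probability / z
        return P

    def max_probability(self) -> float:
        return max(d.probability for d in self.derivations)

    def argmax_structures(self) -> set[SecondaryStructure]:
        """All structures attaining the maximum derivation probability."""
        m = self.max_probability()
        n = len(self.sequence)
        return {
            d.structure(n) for d in self.derivations if math.isclose(d.probability, m, rel_tol=1e-12)
        }

    def structure_distribution(self) -> dict[SecondaryStructure, float]:
        z = self.total
        n = len(self.sequence)
        dist: dict[SecondaryStructure, float] = {}
        for d in self.derivations:
            s = d.structure(n)
            dist[s] = dist.get(s, 0.0) + d.probability / z
        return dist


def enumerate_derivations(g: Grammar, seq: str, cap: int = 10) -> DerivationEnumeration:
    """Enumerate every derivation of ``seq`` with its exact probability.

    Plain recursion over spans; memoized; refuses sequences longer than
    ``cap`` (the whole point is to stay exhaustive and obviously correct).
    """
    seq = normalize_sequence(seq)
    if len(seq) > cap:
        raise ValueError(f"sequence longer than enumeration cap ({cap})")
    n = len(seq)
    rules_of: dict[str, list[Rule]] = {}
    for r in g.rules:
        rules_of.setdefault(r.lhs, []).append(r)
    memo: dict[tuple[str, int, int], list[Derivation]] = {}
    in_progress: set[tuple[str, int, int]] = set()

    # nullable closure: which nonterminals can derive the empty string
    nullable: set[str] = set()
    changed = True
    while changed:
        changed = False
        for r in g.rules:
            if r.lhs in nullable or r.prob <= 0:
                continue
            ok = (
                r.kind == "empty"
                or (r.kind == "unit" and r.child in nullable)
                or (r.kind == "binary" and all(c in nullable for c in r.children))
            )
            if ok:
                nullable.add(r.lhs)
                changed = True

    def derive(v: str, i: int, j: int) -> list[Derivation]:
        key = (v, i, j)
        if key in memo:
            return memo[key]
        if key in in_progress:
            raise RecursionError("cyclic unit/epsilon derivations")
        in_progress.add(key)
        out: list[Derivation] = []
        for r in rules_of.get(v, []):
            if r.prob <= 0:
                continue
            if r.kind == "empty":
                if i == j:
                    out.append(Derivation(r.prob, frozenset(), Counter([r])))
            elif r.kind == "emit":
                if j - i == 1 and seq[i] == r.terminal:
                    out.append(Derivation(r.prob, frozenset(), Counter([r])))
            elif r.kind == "unit":
                for d in derive(r.child, i, j):
                    out.append(
                        Derivation(r.prob * d.probability, d.pairs, d.rule_uses + Counter([r]))
                    )
            elif r.kind == "pair":
                if (
                    j - i >= 2
                    and seq[i] == r.left
                    and seq[j - 1] == r.right
                    and (j - i - 2) >= g.min_hairpin
                ):
                    for d in derive(r.child, i + 1, j - 1):
                        out.append(
                            Derivation(
                                r.prob * d.probability,
                                d.pairs | {(i + 1, j)},
                                d.rule_uses + Counter([r]),
                            )
                        )
            else:  # binary
                w, z = r.children
                for m in range(0, j - i + 1):
                    if m == 0 and w not in nullable:
                        continue
                    if m == j - i and j > i and z not in nullable:
                        continue
                    for dl in derive(w, i, i + m):
                        for dr in derive(z, i + m, j):
                            out.append(
                                Derivation(
                                    r.prob * dl.probability * dr.probability,
                                    dl.pairs | dr.pairs,
                                    dl.rule_uses + dr.rule_uses + Counter([r]),
                                )
                            )
        in_progress.discard(key)
        memo[key] = out
        return out

    return DerivationEnumeration(seq, derive(g.start, 0, n))


def enumerate_structures(
    seq: str,
    allowed_pairs: frozenset[tuple[str, str]],
    min_hairpin: int = 0,
) -> list[SecondaryStructure]:
    """All non-crossing structures on ``seq`` under the pairing rules."""
    seq = normalize_sequence(seq)
    n = len(seq)
    memo: dict[tuple[int, int], list[frozenset]] = {}

    def structs(i: int, j: int) -> list[frozenset]:
        if j - i <= 0:
            return [frozenset()]
        key = (i, j)
        if key in memo:
            return memo[key]
        out = [frozenset(s) for s in structs(i + 1, j)]  # i unpaired
        for k in range(i + 1 + min_hairpin, j):
            if (seq[i], seq[k]) in allowed_pairs:
                for inner in structs(i + 1, k):
                    for rest in structs(k + 1, j):
                        out.append(inner | rest | {(i + 1, k + 1)})
        memo[key] = out
        return out

    return [SecondaryStructure.from_pairs(n, s) for s in structs(0, n)]


def min_energy_by_enumeration(
    seq: str,
    pair_energies: dict[frozenset, float],
    allowed_pairs: frozenset[tuple[str, str]],
    min_hairpin: int = 0,
) -> float:
    """Minimum additive pair energy over all enumerated structures."""
    best = 0.0
    for s in enumerate_structures(seq, allowed_pairs, min_hairpin):
        e = sum(
            pair_energies[frozenset((seq[i - 1], seq[j - 1]))] for i, j in s.pairs
        )
        best = min(best, e)
    return best
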