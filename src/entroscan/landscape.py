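"""Energy-landscape bimodality: the Sil feature.

A sequence's folding landscape is sampled (500 structures by default),
pairwise base-pair distances are computed, the points are partitioned
into two clusters by medoid-based partitioning on the distance matrix,
and the mean silhouette width is reported.  A landscape that splits
cleanly into two structural basins — the signature of a conformational
switch — gives Sil near 1; a unimodal landscape gives values near 0 or
below.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .grammar import Grammar, SecondaryStructure, sample_structures_scfg


def bp_distance(s1: SecondaryStructure, s2: SecondaryStructure) -> int:
    """Base-pair distance: size of the symmetric difference of pair sets.

    A metric on structures of the same underlying length.
    """
    if len(s1) != len(s2):
        raise ValueError("structures have different lengths")
    return len(s1.pairs ^ s2.pairs)


@dataclass
class LandscapeSample:
    """A sampled set of structures on one sequence."""

    sequence: str
    structures: list[SecondaryStructure]
    seed: int

    def distance_matrix(self) -> np.ndarray:
        k = len(self.structures)
        D = np.zeros((k, k), dtype=float)
        for a in range(k):
            for b in range(a + 1, k):
                D[a, b] = D[b, a] = bp_distance(self.structures[a], self.structures[b])
        return D


def sample_structures(
    seq: str,
    k: int,
    sampler: str = "scfg",
    grammar: Grammar | None = None,
    engine=None,
    seed: int = 0,
) -> LandscapeSample:
    """Draw ``k`` structures from the configured sampling engine.

    ``scfg`` draws exact conditional samples from a grammar's folding
    distribution; ``vienna`` draws Boltzmann samples from the
    thermodynamic ensemble (requires an engine exposing ``sample``).
    """
    if k <= 0:
        raise ValueError("sample count must be positive")
    rng = np.random.default_rng(seed)
    if sampler == "scfg":
        if grammar is None:
            raise ValueError("scfg sampler requires a grammar")
        structures = sample_structures_scfg(grammar, seq, k, rng)
    elif sampler == "vienna":
        if engine is None or not hasattr(engine, "sample"):
            raise ValueError("vienna sampler requires an engine with .sample")
        structures = engine.sample(seq, k, rng)
    else:
        raise ValueError(f"unknown sampler {sampler!r}")
    return LandscapeSample(sequence=seq, structures=structures, seed=seed)


def _two_medoid_partition(D: np.ndarray) -> np.ndarray:
    """Deterministic 2-medoid partition of a distance matrix.

    Multi-start: every point is tried as the first medoid, the second is
    completed greedily (the point minimizing total assignment cost), the
    lowest-cost pair wins; ties go to the lexicographically smallest
    medoid indices.  Returns a 0/1 label per point.
    """
    n = D.shape[0]
    best: tuple[float, int, int] | None = None
    for m1 in range(n):
        costs = np.minimum(D[m1][None, :], D)  # row m2 -> assignment costs
        totals = costs.sum(axis=1)
        totals[m1] = np.inf
        m2 = int(np.argmin(totals))
        cand = (float(totals[m2]), *sorted((m1, m2)))
        if best is None or cand < best:
            best = cand
    _, m1, m2 = best
    # assign to nearest medoid; ties to the first medoid
    return (D[m2] < D[m1]).astype(int)


def two_cluster_silhouette(dist: np.ndarray) -> float:
    """Mean silhouette width of the deterministic two-medoid partition.

    ``s(i) = (b - a) / max(a, b)`` with the convention s(i)=0 when
    a=b=0 (all-identical degenerate case); result in [−1, 1].
    """
    D = np.asarray(dist, dtype=float)
    if D.ndim != 2 or D.shape[0] != D.shape[1]:
        raise ValueError("distance matrix must be square")
    if not np.allclose(D, D.T):
        raise ValueError("distance matrix must be symmetric")
    n = D.shape[0]
    if n < 4:
        raise ValueError("need at least 4 points for a two-cluster silhouette")
    labels = _two_medoid_partition(D)
    return float(mean_silhouette(D, labels))


def mean_silhouette(D: np.ndarray, labels: np.ndarray) -> float:
    """Mean silhouette width for a given 2-way labeling of a distance matrix."""
    labels = np.asarray(labels)
    n = D.shape[0]
    s = np.zeros(n)
    for i in range(n):
        own = labels == labels[i]
        other = ~own
        n_own = own.sum() - 1
        if other.sum() == 0 or n_own == 0:
            s[i] = 0.0  # singleton-cluster convention, as in Rousseeuw
            continue
        a = D[i, own].sum() / n_own
        b = D[i, other].mean()
        denom = max(a, b)
        s[i] = 0.0 if denom == 0 else (b - a) / denom
    return float(s.mean())


def landscape_silhouette(
    seq: str,
    k: int = 500,
    sampler: str = "scfg",
    grammar: Grammar | None = None,
    engine=None,
    seed: int = 0,
) -> float:
    """The Sil feature: sample, distance matrix, 2-medoid partition, mean
    silhouette."""
    sample = sample_structures(seq, k, sampler=sampler, grammar=grammar, engine=engine, seed=seed)
    return two_cluster_silhouette(sample.distance_matrix())
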