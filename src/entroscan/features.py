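"""Per-sequence features: composition, MFE, structural entropies, Sil.

The feature set mirrors the statistics used to characterize riboswitch
folding spaces: sequence length L, minimum free energy MFE (kcal/mol),
composite base compositions GC / GU / GCU / U, the structural entropies
of two SCFG folding models (RND: symmetric structurally ambiguous; BJK:
the Knudsen–Hein/G6-shaped unambiguous model), the base-pairing entropy
of the BJK posterior pair matrix (BJKbp), and the two-cluster landscape
silhouette (Sil).
"""

from __future__ import annotations

import functools
import math
from dataclasses import dataclass, field
from typing import Mapping

import numpy as np

from .grammar import (
    WATSON_CRICK_GU,
    Grammar,
    SecondaryStructure,
    derivation_entropy,
    normalize_sequence,
    pair_probabilities,
)

_COMPLEMENT = str.maketrans("ACGU", "UGCA")

FEATURE_COLUMNS = ("L", "MFE", "GC", "GU", "GCU", "U", "RND", "BJK", "BJKbp", "Sil")


def composition(seq: str) -> tuple[float, float, float, float]:
    """Composite base fractions (GC, GU, GCU, U).

    GU and GCU are mononucleotide composites — (#G+#U)/L and (#G+#C+#U)/L —
    not dinucleotide frequencies; see docs/methods.md for why this reading
    of the composite features was adopted.
    """
    seq = normalize_sequence(seq)
    if not seq:
        raise ValueError("empty sequence")
    n = len(seq)
    g = seq.count("G")
    c = seq.count("C")
    u = seq.count("U")
    return ((g + c) / n, (g + u) / n, (g + c + u) / n, u / n)


def reverse_complement(seq: str) -> str:
    """Reversed Watson-Crick complement (the antisense sequence)."""
    return normalize_sequence(seq).translate(_COMPLEMENT)[::-1]


def base_pair_entropy(pair_prob: np.ndarray, n: int) -> float:
    """Base-pairing entropy −(1/n)·Σ_{i<j} P_ij ln P_ij (natural log, ≥ 0).

    ``pair_prob`` is the posterior pairing matrix (upper triangle used);
    0·ln 0 is taken as 0.
    """
    if n <= 0:
        raise ValueError("sequence length must be positive")
    iu = np.triu_indices(pair_prob.shape[0], k=1)
    p = np.asarray(pair_prob)[iu]
    if ((p < -1e-12) | (p > 1 + 1e-12)).any():
        raise ValueError("pair probabilities outside [0,1]")
    p = np.clip(p, 0.0, 1.0)
    nz = p[p > 0]
    return float(-(nz * np.log(nz)).sum() / n)


# ---------------------------------------------------------------------------
# Folding engines


#: additive stacking-free pair energies (kcal/mol) for the simple model
SIMPLE_PAIR_ENERGIES = {
    frozenset(("G", "C")): -3.0,
    frozenset(("A", "U")): -2.0,
    frozenset(("G", "U")): -1.0,
}


class SimplePairEnergyEngine:
    """Additive base-pair-scoring folding model (test/reference engine).

    Energy of a structure = sum of pair energies (GC −3, AU −2, GU −1
    kcal/mol); the minimum over all non-crossing structures is found by a
    Nussinov-style dynamic program.  This is a deliberately simple model
    whose optimum is checkable by exhaustive enumeration; results carry
    ``engine_name = "simple"`` so downstream tables can flag them.
    """

    engine_name = "simple"

    def __init__(self, min_hairpin: int = 3, allowed_pairs=WATSON_CRICK_GU):
        self.min_hairpin = min_hairpin
        self.allowed_pairs = frozenset(allowed_pairs)

    def _energy(self, a: str, b: str) -> float:
        if (a, b) not in self.allowed_pairs:
            return math.inf
        return SIMPLE_PAIR_ENERGIES[frozenset((a, b))]

    @functools.lru_cache(maxsize=4096)
    def fold(self, seq: str) -> tuple[float, SecondaryStructure]:
        seq = normalize_sequence(seq)
        n = len(seq)
        E = np.zeros((n + 1, n + 1))
        back: dict[tuple[int, int], tuple[int, int] | None] = {}
        for L in range(2, n + 1):
            for i in range(0, n - L + 1):
                j = i + L
                best = E[i + 1, j]  # i unpaired
                arg = None
                for k in range(i + 1 + self.min_hairpin, j):
                    e = self._energy(seq[i], seq[k])
                    if e == math.inf:
                        continue
                    cand = e + E[i + 1, k] + E[k + 1, j]
                    if cand < best - 1e-12:
                        best = cand
                        arg = (i, k)
                E[i, j] = best
                back[(i, j)] = arg
        pairs = []
        stack = [(0, n)]
        while stack:
            i, j = stack.pop()
            if j - i < 2:
                continue
            arg = back.get((i, j))
            if arg is None:
                stack.append((i + 1, j))
            else:
                _, k = arg
                pairs.append((i + 1, k + 1))
                stack.append((i + 1, k))
                stack.append((k + 1, j))
        return float(E[0, n]), SecondaryStructure.from_pairs(n, pairs)

    def mfe(self, seq: str) -> float:
        return self.fold(seq)[0]


class ViennaRNAEngine:
    """Thermodynamic nearest-neighbor folding via the ViennaRNA bindings.

    Default parameters; the standard engine for real analyses.  Import is
    deferred so the package works where the bindings are absent.
    """

    engine_name = "vienna"

    def __init__(self):
        import RNA  # deferred; raises ImportError when unavailable

        self._RNA = RNA

    def fold(self, seq: str) -> tuple[float, SecondaryStructure]:
        seq = normalize_sequence(seq)
        db, e = self._RNA.fold(seq)
        return float(e), SecondaryStructure(db)

    def mfe(self, seq: str) -> float:
        return self.fold(seq)[0]

    def sample(self, seq: str, k: int, rng: np.random.Generator) -> list[SecondaryStructure]:
        """Boltzmann-distributed structures via stochastic backtracking."""
        RNA = self._RNA
        # Vienna keeps a global RNG; derive its seed from ours for reproducibility
        RNA.init_rand(int(rng.integers(1, 2**31 - 1)))
        fc = RNA.fold_compound(normalize_sequence(seq))
        _, mfe = fc.mfe()
        fc.exp_params_rescale(mfe)
        fc.pf()
        return [SecondaryStructure(db) for db in fc.pbacktrack(k)]


def get_engine(name: str = "vienna"):
    """Engine factory: ``vienna`` (thermodynamic) or ``simple`` (additive)."""
    if name == "vienna":
        return ViennaRNAEngine()
    if name == "simple":
        return SimplePairEnergyEngine()
    raise ValueError(f"unknown folding engine {name!r}")


def minimum_free_energy(seq: str, engine) -> float:
    """MFE in kcal/mol under ``engine``; 0.0 for a sequence with no structure."""
    return engine.mfe(seq)


# ---------------------------------------------------------------------------
# Feature vector assembly


@dataclass
class FeatureConfig:
    """What to compute and with which models.

    ``compute_sil`` is off by default because landscape sampling is by far
    the most expensive feature; ``sil_samples`` follows the fixed sample
    size of 500 structures.
    """

    bjk_grammar: Grammar | None = None
    rnd_grammar: Grammar | None = None
    engine: object | None = None
    compute_sil: bool = False
    sil_samples: int = 500
    sil_sampler: str = "scfg"  # or "vienna"
    seed: int = 0
    normalize_by_length: bool = False


@dataclass
class FeatureVector:
    """One row of the per-sequence feature table."""

    seq_id: str
    L: int
    GC: float
    GU: float
    GCU: float
    U: float
    MFE: float | None = None
    RND: float | None = None
    BJK: float | None = None
    BJKbp: float | None = None
    Sil: float | None = None
    extra: Mapping[str, float] = field(default_factory=dict)

    def as_dict(self) -> dict:
        d = {
            "id": self.seq_id,
            "L": self.L,
            "MFE": self.MFE,
            "GC": self.GC,
            "GU": self.GU,
            "GCU": self.GCU,
            "U": self.U,
            "RND": self.RND,
            "BJK": self.BJK,
            "BJKbp": self.BJKbp,
            "Sil": self.Sil,
        }
        d.update(self.extra)
        return d


def feature_vector(seq: str, config: FeatureConfig, seq_id: str = "") -> FeatureVector:
    """Assemble the feature vector for one sequence.

    Deterministic given ``config.seed`` (the only stochastic component is
    landscape sampling for Sil).  Entropy features are per-sequence totals;
    set ``normalize_by_length`` for the /L variants.
    """
    seq = normalize_sequence(seq)
    gc, gu, gcu, u = composition(seq)
    n = len(seq)
    fv = FeatureVector(seq_id=seq_id, L=n, GC=gc, GU=gu, GCU=gcu, U=u)
    scale = (1.0 / n) if config.normalize_by_length else 1.0
    if config.engine is not None:
        fv.MFE = minimum_free_energy(seq, config.engine) * scale
    if config.rnd_grammar is not None:
        fv.RND = derivation_entropy(config.rnd_grammar, seq) * scale
    if config.bjk_grammar is not None:
        fv.BJK = derivation_entropy(config.bjk_grammar, seq) * scale
        fv.BJKbp = base_pair_entropy(pair_probabilities(config.bjk_grammar, seq), n) * scale
    if config.compute_sil:
        from .landscape import landscape_silhouette

        fv.Sil = landscape_silhouette(
            seq,
            k=config.sil_samples,
            sampler=config.sil_sampler,
            grammar=config.bjk_grammar,
            engine=config.engine,
            seed=config.seed,
        )
    return fv
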