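"""Synthetic data generation.

Everything the test-suite and examples need without genome downloads:
seeded random sequences with a target GC composition, a hairpin training
set for grammar estimation, and a small two-strand toy genome with
annotated "genes", intergenic regions straddling the 150-nt scan cutoff,
and planted riboswitch-like windows (GC-rich, strongly stem-forming)
that a simple classifier separates cleanly from background.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .features import reverse_complement
from .grammar import SecondaryStructure
from .scan import GenomeAnnotation, Interval

_PAIR_FOR = {"G": "C", "C": "G", "A": "U", "U": "A"}


def random_sequence(length: int, gc_target: float = 0.5, seed: int | np.random.Generator = 0) -> str:
    """I.i.d. sequence with P(G)=P(C)=gc/2 and P(A)=P(U)=(1−gc)/2."""
    if not (0.0 <= gc_target <= 1.0):
        raise ValueError("gc_target must be in [0,1]")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    p = np.array([(1 - gc_target) / 2, gc_target / 2, gc_target / 2, (1 - gc_target) / 2])
    return "".join(np.array(list("ACGU"))[rng.choice(4, size=length, p=p)])


def random_hairpin(
    stem: int, loop: int, rng: np.random.Generator, gc_target: float = 0.6
) -> tuple[str, SecondaryStructure]:
    """A perfect hairpin (stem fully paired, loop unpaired) with structure."""
    five = random_sequence(stem, gc_target, rng)
    loop_seq = random_sequence(loop, gc_target, rng)
    three = "".join(_PAIR_FOR[c] for c in reversed(five))
    seq = five + loop_seq + three
    n = len(seq)
    pairs = [(i + 1, n - i) for i in range(stem)]
    return seq, SecondaryStructure.from_pairs(n, pairs)


def hairpin_training_set(
    n: int = 40, seed: int = 7, min_stem: int = 3, max_stem: int = 8,
    min_loop: int = 3, max_loop: int = 8, flank: int = 4,
) -> list[tuple[str, SecondaryStructure]]:
    """Hairpins with unpaired flanks: the default grammar-training fixture.

    Gives the trained grammar realistic mass on both paired and unpaired
    emissions and on the stem/continuation rule families.
    """
    rng = np.random.default_rng(seed)
    out = []
    for _ in range(n):
        stem = int(rng.integers(min_stem, max_stem + 1))
        loop = int(rng.integers(min_loop, max_loop + 1))
        hp, hp_struct = random_hairpin(stem, loop, rng)
        left = random_sequence(int(rng.integers(1, flank + 1)), 0.4, rng)
        right = random_sequence(int(rng.integers(1, flank + 1)), 0.4, rng)
        seq = left + hp + right
        pairs = [(i + len(left), j + len(left)) for i, j in hp_struct.pairs]
        out.append((seq, SecondaryStructure.from_pairs(len(seq), pairs)))
    return out


def planted_switch_window(length: int, rng: np.random.Generator) -> str:
    """A riboswitch-like window: two long GC-rich stems over a background.

    The strong stems give a very low MFE and high GC, so a classifier
    weighting stability and composition ranks these windows above random
    background of moderate GC.
    """
    stem = max(8, length // 8)
    loop = 5
    h1, _ = random_hairpin(stem, loop, rng, gc_target=0.9)
    h2, _ = random_hairpin(stem, loop, rng, gc_target=0.9)
    filler = length - len(h1) - len(h2) - 4
    mid = random_sequence(max(filler, 0), 0.5, rng)
    seq = h1 + "AA" + h2 + "AA" + mid
    return seq[:length]


@dataclass
class ToyGenome:
    """A generated genome with its annotation, planted elements, manifest."""

    sequences: dict[str, str]
    annotation: GenomeAnnotation
    known_elements: list[Interval]
    seed: int
    manifest: dict = field(default_factory=dict)


#: intergenic-region lengths straddling the 150-nt cutoff
_REGION_PLAN = (150, 170, 200, 314, 471, 800, 120, 650)
_GENE_LEN = 900


def toy_genome(seed: int = 0, window_len: int = 157) -> ToyGenome:
    """Two-strand synthetic genome for scan tests (~10 kb).

    Genes of 900 nt alternate with intergenic regions whose lengths
    straddle the 150-nt cutoff; three regions carry a planted
    riboswitch-like window placed exactly where the downstream-anchored
    tiling puts its most downstream window (ending at the next gene's
    start codon).  Deterministic under ``seed``.
    """
    rng = np.random.default_rng(seed)
    parts: list[str] = []
    intervals: list[Interval] = []
    known: list[Interval] = []
    pos = 1  # 1-based next free position
    seq_id = "toy1"
    planted_regions = {3, 4, 7}  # 0-based indices into _REGION_PLAN (length > window)

    for gi, region_len in enumerate(_REGION_PLAN):
        gene = random_sequence(_GENE_LEN, 0.5, rng)
        parts.append(gene)
        intervals.append(
            Interval(seq_id, pos, pos + _GENE_LEN - 1, "+", name=f"gene{gi + 1:02d}")
        )
        pos += _GENE_LEN
        region = random_sequence(region_len, 0.4, rng)
        if gi in planted_regions and region_len > max(150, window_len - 1):
            planted = planted_switch_window(window_len, rng)
            region = region[: region_len - window_len] + planted
            known.append(
                Interval(
                    seq_id,
                    pos + region_len - window_len,
                    pos + region_len - 1,
                    "+",
                    name=f"planted{len(known) + 1}",
                )
            )
        parts.append(region)
        pos += region_len
    gene = random_sequence(_GENE_LEN, 0.5, rng)
    parts.append(gene)
    intervals.append(
        Interval(seq_id, pos, pos + _GENE_LEN - 1, "+", name=f"gene{len(_REGION_PLAN) + 1:02d}")
    )
    genome = {seq_id: "".join(parts)}
    manifest = {
        "seed": seed,
        "length": len(genome[seq_id]),
        "n_genes": len(intervals),
        "region_lengths": list(_REGION_PLAN),
        "planted": [(k.name, k.start, k.end) for k in known],
    }
    return ToyGenome(genome, GenomeAnnotation(intervals), known, seed, manifest)


def mirrored_toy_genome(g: ToyGenome) -> ToyGenome:
    """The reverse complement of a toy genome with mirrored annotation.

    Used to check strand correctness: a forward scan of the mirror must
    reproduce the original scan's hit set with flipped strands.
    """
    out_seqs = {k: reverse_complement(v) for k, v in g.sequences.items()}
    n = {k: len(v) for k, v in g.sequences.items()}

    def flip(iv: Interval) -> Interval:
        L = n[iv.seq_id]
        return Interval(
            iv.seq_id, L - iv.end + 1, L - iv.start + 1,
            "-" if iv.strand == "+" else "+", iv.name,
        )

    return ToyGenome(
        out_seqs,
        GenomeAnnotation([flip(iv) for iv in g.annotation.intervals]),
        [flip(k) for k in g.known_elements],
        g.seed,
        dict(g.manifest, mirrored=True),
    )
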