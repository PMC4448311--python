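"""Dinucleotide-shuffle negative controls with the MFE-similarity filter.

Shuffles a small set of structured sequences, folds everything, and keeps
only shuffles whose stability is comparable to the real set's MFE
distribution (threshold = reference mean + 1 std).
"""

import numpy as np

from entroscan import MfeFilterRule, filter_by_mfe, get_engine
from entroscan.shuffle import dinucleotide_counts, make_shuffles
from entroscan.synth import random_hairpin, random_sequence

rng = np.random.default_rng(4)
engine = get_engine("vienna")

# "real" set: moderately structured sequences (a hairpin plus flanks)
sources = []
for i in range(5):
    hp, _ = random_hairpin(int(rng.integers(6, 10)), 5, rng, gc_target=0.6)
    sources.append(random_sequence(10, 0.45, rng) + hp + random_sequence(10, 0.45, rng))
reference_mfes = [engine.mfe(s) for s in sources]
mean, std = np.mean(reference_mfes), np.std(reference_mfes, ddof=1)
print(f"reference MFEs: {np.round(reference_mfes, 1).tolist()}  "
      f"(mean {mean:.1f}, std {std:.1f}, keep <= {mean + std:.1f})")

kept = total = 0
for i, src in enumerate(sources):
    ss = make_shuffles(f"src{i}", src, n=10, seed=i)
    assert all(dinucleotide_counts(s) == dinucleotide_counts(src) for s in ss.shuffles)
    filter_by_mfe(ss, reference_mfes, rule=MfeFilterRule(), engine=engine)
    kept += sum(ss.kept_mask)
    total += len(ss.shuffles)
print(f"kept {kept}/{total} shuffles after the MFE-similarity filter")
print(
    "\nEvery shuffle preserves the exact dinucleotide multiset and end bases,\n"
    "so composition-driven signals survive while real structure is destroyed.\n"
    "Shuffles that fold much less stably than the real set (MFE above the\n"
    "reference mean + 1 std) are discarded so that classifiers cannot\n"
    "separate the sets on stability alone."
)
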