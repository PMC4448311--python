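"""Training a logistic classifier to tell sequences from their antisense.

Sense and antisense share length and GC exactly, so separation must come
from asymmetric features (uracil composition, folding-space entropy).
Synthetic "sense" sequences get A-rich unstructured tails — mimicking
the A/U asymmetry of real mRNA regulatory regions — and the fit picks
the U feature up.
"""

import numpy as np
import pandas as pd

from entroscan import (
    FeatureConfig,
    default_grammar_path,
    feature_vector,
    fit_logistic,
    load_grammar,
    predict_proba,
    reverse_complement,
    roc_auc,
)
from entroscan.synth import random_hairpin

rng = np.random.default_rng(0)
cfg = FeatureConfig(rnd_grammar=load_grammar(default_grammar_path("rnd")))
bases = np.array(list("ACGU"))
tail_probs = [0.40, 0.20, 0.20, 0.20]  # A-rich, U-poor tails on the sense strand

rows, labels = [], []
for i in range(30):
    hp, _ = random_hairpin(int(rng.integers(8, 14)), 6, rng, gc_target=0.7)
    tail = "".join(bases[rng.choice(4, size=40, p=tail_probs)])
    sense = hp + tail
    for seq, label in ((sense, "sense"), (reverse_complement(sense), "antisense")):
        rows.append(feature_vector(seq, cfg).as_dict())
        labels.append(label)

table = pd.DataFrame(rows)[["L", "GC", "U", "RND"]]
model = fit_logistic(table, labels, reference_class="antisense")
print("classes:", model.classes, "(reference coefficients fixed at 0)")
print("sense coefficients (intercept, L, GC, U, RND):",
      np.round(model.coefficients[1], 3).tolist())

scores = predict_proba(model, table)["sense"]
_, auc = roc_auc(scores, [1 if l == "sense" else 0 for l in labels])
print(f"in-sample grid-ROC AUC: {auc:.3f}")
print(
    "\nThe L and GC coefficients contribute nothing (the classes are exactly\n"
    "matched on them); the strongly negative U coefficient carries the\n"
    "separation, because the antisense of an A-rich sense strand is U-rich."
)
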