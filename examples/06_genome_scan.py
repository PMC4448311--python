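"""Genome-wide sliding-window scan of intergenic regions.

Generates the synthetic toy genome with three planted riboswitch-like
windows, scans with a 157-nt non-overlapping window, and ranks windows
by classifier probability.
"""

import numpy as np

from entroscan import FeatureConfig, LogisticModel, extract_windows, get_engine, scan_and_rank
from entroscan.scan import hits_to_table
from entroscan.synth import toy_genome

tg = toy_genome(seed=1)
print(f"toy genome: {tg.manifest['length']} nt, {tg.manifest['n_genes']} genes, "
      f"planted elements at {[p[1:] for p in tg.manifest['planted']]}")

windows = extract_windows(tg.sequences, tg.annotation, window_len=157, overlap=0, strands="+")
print(f"{len(windows)} forward windows from intergenic regions > 150 nt")

# stability + composition classifier (riboswitch-like = low MFE, high GC)
model = LogisticModel(
    classes=("background", "riboswitch"), reference_class="background",
    feature_names=("MFE", "GC"),
    coefficients=np.array([[0.0, 0.0, 0.0], [-3.0, -0.05, 2.0]]),
)
hits = scan_and_rank(
    windows, model, FeatureConfig(engine=get_engine("vienna")),
    annotation=tg.annotation, p_value_features=("GC", "U"),
)
cols = ["rank", "start", "end", "probability", "MFE", "GC", "p_U", "dist_downstream"]
print(hits_to_table(hits)[cols].head(6).round(4).to_string(index=False))
print(
    "\nThe three planted windows occupy the top ranks: their strong GC-rich\n"
    "stems give far lower MFE than background. p_U is the within-scan\n"
    "empirical p-value of the uracil composition (low U counts as extreme,\n"
    "as in known riboswitches); dist_downstream is the distance from the\n"
    "window center to the next gene's start codon."
)
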