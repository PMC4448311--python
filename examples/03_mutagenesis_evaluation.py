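"""Scoring features by their response to structure-disrupting mutations.

Uses the bundled table of 18 published riboswitch mutants: a feature is
informative when structural mutants (which break one of the two
functional conformations) show a *decrease* relative to wild type.
"""

from entroscan import bundled_mutant_records, evaluate_all

records = bundled_mutant_records()
print(f"{len(records)} mutant records "
      f"({sum(r.disrupts_one_structure for r in records)} structural)")

table = evaluate_all(records, ["BJKbp", "BJK", "RND", "Sil"])
print(table.round(3).to_string(index=False))
print(
    "\nSensitivity: % of structural mutants whose feature dropped below the\n"
    "per-record threshold (0, or -0.74 for the length-changed ROSE-P2 mutant).\n"
    "Specificity: % of non-structural mutants that did not drop. The\n"
    "base-pairing entropy (BJKbp) separates the two classes best."
)
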