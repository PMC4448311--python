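# Symmetric structurally ambiguous folding model ("RND-like").
# One nonterminal; uniform probabilities within each rule family:
# branching 0.25, pair emission 0.25 spread uniformly over the six
# admissible pairings, unpaired emission 0.50 spread over the four bases.
# Subcritical (mean offspring 0.75), so unconditional derivations are finite.
@pairs AU CG GU
S -> S S : 0.25
S -> a S u : 0.041666666666666664
S -> u S a : 0.041666666666666664
S -> c S g : 0.041666666666666664
S -> g S c : 0.041666666666666664
S -> g S u : 0.041666666666666664
S -> u S g : 0.041666666666666664
S -> a : 0.125
S -> c : 0.125
S -> g : 0.125
S -> u : 0.125
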