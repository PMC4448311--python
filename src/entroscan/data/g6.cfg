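# Knudsen-Hein-shaped (G6) folding model: S -> LS | L ; L -> xFy | x ; F -> xFy | LS.
# Structurally unambiguous: one derivation per secondary structure, so the
# derivation entropy of this grammar equals the structure entropy.
# Probabilities: counting MLE (pseudocount 0.5) on the bundled synthetic
# hairpin training set (data/hairpin_training.dbn).
@pairs AU CG GU
S -> L S : 0.8191011235955056
S -> L : 0.18089887640449437
L -> a F u : 0.019427402862985686
L -> u F a : 0.015337423312883436
L -> c F g : 0.02965235173824131
L -> g F c : 0.02147239263803681
L -> g F u : 0.0010224948875255625
L -> u F g : 0.0010224948875255625
L -> a : 0.22188139059304704
L -> c : 0.23824130879345604
L -> g : 0.25869120654396727
L -> u : 0.19325153374233128
F -> a F u : 0.1540130151843818
F -> u F a : 0.17136659436008678
F -> c F g : 0.24078091106290672
F -> g F c : 0.25379609544468545
F -> g F u : 0.0021691973969631237
F -> u F g : 0.0021691973969631237
F -> L S : 0.175704989154013
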