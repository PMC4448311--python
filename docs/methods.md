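# Methods

This note documents the models, numerical choices, and conventions
behind entroscan, and what the synthetic test data does and does not
establish.

## Folding models

Both bundled models are lightweight SCFGs over {A, C, G, U} that permit
only Watson–Crick and G–U pairs and exclude pseudoknots.

**BJK** (`data/g6.cfg`) has the Knudsen–Hein/G6 shape
`S → LS | L;  L → xFy | x;  F → xFy | LS`. The shape is structurally
unambiguous: each secondary structure corresponds to exactly one
derivation, so the derivation entropy *is* the structure entropy. The
bundled probabilities are a counting MLE (pseudocount 0.5) on the
bundled synthetic hairpin set `data/hairpin_training.dbn`; the original
benchmark-trained parameters of this grammar family are not
redistributable here, so any result depends on the grammar file used —
which is why every loaded grammar carries a SHA-256 content hash that
the CLI logs. Users with their own trained parameter files can drop
them in unchanged.

**RND** (`data/rnd.cfg`) is a deliberately symmetric, structurally
ambiguous one-nonterminal model: branching 0.25, pair emission 0.25
spread uniformly over the six admissible pairs, unpaired emission 0.50
spread uniformly over the four bases. Mean offspring is 0.75
(subcritical), so its unconditional derivations are finite. Because the
model is ambiguous, several derivations can map to one structure; the
entropy reported is over *derivations*, the tractable operational
definition. Marginalizing to structures is intractable in general, and
for a symmetric "null" folding model the derivation-space spread is the
quantity of interest anyway.

## Exact entropy without enumeration

For each chart cell the inside pass carries two numbers: the log inside
mass `ln Z_v(i,j)` and the conditional expectation
`A_v(i,j) = E[ln P(π)]` over derivations of the span. A rule
combination contributes mass `p·Z₁·Z₂` and expectation
`ln p + A₁ + A₂`, and cells combine expectations by mass-weighted
averaging — a convex combination, so `A` stays O(n) in magnitude while
all masses live in log space. The entropy is `H = ln Z − A_start(1,n)`,
in nats (natural log throughout, including the base-pairing entropy; a
`base=` argument converts). This runs in O(n³·|rules|) and is stable far
beyond 300 nt; the suite cross-checks float64 against an 80-bit
extended-precision recomputation at n = 300 (1e-6 agreement) and against
exhaustive enumeration for n ≤ 10 (1e-9, in practice ~1e-13).

Epsilon rules are supported through an "effective unit closure": a
binary rule with an ε-deriving child acts on non-empty spans as a unit
rule scaled by the child's ε mass. The effective-unit graph must be
acyclic (checked at compilation). Grammar training rejects ε-deriving
shapes; the bundled shapes have none.

Other conventions: T→U and case folding on input, any other character
is an error (no IUPAC codes — the grammars emit only the four bases);
minimum hairpin loop length defaults to 0 (grammar-faithful) and is
configurable; CYK ties prefer the first rule in file order and the
leftmost split (stable across runs); a non-derivable sequence raises a
dedicated zero-probability error distinct from numerical failure.

## Training

`estimate_parameters` is counting maximum likelihood: rule probabilities
are relative frequencies of rule uses over the structure-faithful
derivations of the training pairs. Uses are extracted by a
structure-constrained max-probability traceback, exact when the shape is
structure-unambiguous (its precondition). Nonterminals never observed
keep their shape probabilities; a smoothing pseudocount (default 0) is
available. Recovery is verified by re-estimating from 1000 structures
sampled from a known grammar (every probability within ±0.05).

## Features

Per-sequence features: length L; MFE (kcal/mol); composite base
fractions GC, GU, GCU, U; RND and BJK structural entropies (nats,
per-sequence totals, with /L variants available); BJKbp
`= −(1/n) Σ_{i<j} P_ij ln P_ij` with 0·ln 0 = 0; Sil (below). GU and
GCU are mononucleotide composites ((G+U)/L, (G+C+U)/L) — the composite
reading is the one consistent with their use alongside GC and U as
composition features; a dinucleotide-frequency reading is not used.
Externally computed columns (e.g. centroid free energy or
Boltzmann-shape probability ratios) are merged by sequence id, never
computed internally.

MFE engines are pluggable. The default is ViennaRNA (default
parameters, via the Python bindings). A built-in additive
pair-energy model (GC −3, AU −2, GU −1 kcal/mol, Nussinov-style DP,
minimum hairpin loop 3) exists as a simple, enumeration-checkable
engine: its optimum is verified against exhaustive structure
enumeration for n ≤ 12, and results computed with it are flagged
`engine_name="simple"`. It is a crude stacking-free model, not a
substitute for thermodynamic folding in analyses.

## Landscape silhouette (Sil)

Sample 500 structures (fixed default), compute all pairwise base-pair
distances (symmetric-difference metric), partition into two clusters,
report the mean silhouette width `s(i) = (b−a)/max(a,b)` (0 for
singletons and for the all-identical degenerate case; always in
[−1, 1]). The clustering is a deterministic two-medoid search: every
point is tried as the first medoid, the second is completed greedily,
lowest total assignment cost wins, ties to the smallest indices. The
clustering step is pluggable since the upstream literature does not pin
one algorithm. Samplers: exact SCFG conditional sampling (stochastic
traceback; validated distributionally against enumeration) or
ViennaRNA Boltzmann sampling. Pseudoknots are excluded throughout.

## Classifiers

Unregularized maximum-likelihood multinomial logistic regression
(statsmodels Newton; tolerance 1e-8; a capped quasi-Newton fallback with
a warning when the Hessian is singular, i.e. separable data). The
reference class's coefficients are identically zero — the convention
used when reporting riboswitch/UTR coefficients against the antisense
class. Prediction is a softmax over linear scores; the
maximum-likelihood class is the argmax.

The ROC is built on a fixed threshold grid of resolution 0.01 over
[0, 1]; a case is positive iff its score strictly exceeds the threshold;
area by trapezoid including (0,0) and (1,1). The conventional
unique-score sweep is available (`grid=False`). MCC comes from the
standard 2×2 formula with 0 returned when a marginal is empty.

## Mutagenesis protocol

For each mutant, Δ% = 100·(mutant − wild)/|wild| per feature. The
absolute-value denominator is an extension so that "decrease ⇒ negative
Δ" also holds for negative wild-type values (possible for Sil); the
curated records have no negative wild types, so it changes nothing
there. Prediction: "structural" iff Δ strictly below the per-record
threshold; zero or positive Δ predicts non-structural. The threshold is
0 except for mutants whose length differs from wild type, where a small
negative allowance (−0.74 for the bundled single-nucleotide-deletion
record) absorbs the roughly linear length dependence of entropy.
Sensitivity/specificity are over structural/non-structural records
respectively; MCC as above. The bundled 18-record table reproduces all
twelve published summary cells.

## Dinucleotide shuffles and the MFE filter

Shuffles use the Altschul–Erickson Eulerian-path scheme: last-exit
edges drawn as a uniformly random arborescence into the terminal vertex
(rejection sampling), remaining edges permuted uniformly — uniform over
Eulerian paths by the BEST theorem. Invariants (length, mono- and
dinucleotide counts, first/last base) are asserted on every draw, and
uniformity is tested against the enumerated shuffle universe of a small
sequence.

The MFE-similarity filter discards shuffles whose MFE exceeds the
reference set's mean + 1·std — i.e. removes shuffles that fold much
less stably than the real sequences. The filter direction for negative
energies is genuinely ambiguous in prose descriptions of this control;
the bundled default is the reading consistent with published kept-set
statistics (retention ~70–75%, kept-set mean MFE close to the real
set's), and the mirror-image rule is provided as an alternative
`MfeFilterRule` mode, logged explicitly.

## Genome scanning

Intergenic regions are the complement of the annotated gene/operon
intervals. Only regions strictly longer than 150 nt are scanned.
Windows tile each region anchored at the downstream end — the most
downstream window ends exactly at the next gene's start codon, where a
riboswitch would sit — stepping upstream by window − overlap; partial
windows are dropped, giving `1 + floor((R−W)/S)` windows per region.
Reverse-strand windows anchor at the region's other edge and carry
reverse-complemented sequence. Coordinates are 1-based inclusive on the
forward axis (GenBank convention); internal arithmetic is half-open and
converted at the boundaries. Typical window/overlap combinations
(100/50, 150/75, 200/100, 157/0) are configuration, not code.

Windows are ranked by classifier probability (descending; ties by
genomic coordinate). Per-feature empirical p-values are computed within
the scan as rank/N with ties sharing the best rank; the extreme
direction is per-feature (high for the entropies, low for GC and U,
matching the composition ranges observed in known riboswitches).
Filters — composition ranges, per-feature p cutoffs, minimum
probability — apply after ranking so ranks and p-values always refer to
the full scan. Distances to flanking operons are measured from the
window center (negative = upstream stop codon, positive = downstream
start codon). Known elements are matched to windows by maximum overlap
for true-positive bookkeeping, and annotated regions can be excluded.

## Synthetic data: what it shows and what it does not

The generators make every capability testable offline and seeded:
random i.i.d. sequences with a target GC; perfect hairpins with flanks
for grammar training; and a ~11 kb toy genome whose intergenic-region
lengths straddle the 150-nt cutoff (including one region of exactly
150 nt) with three planted GC-rich, strongly stem-forming windows placed
exactly where downstream-anchored tiling puts a window. The planted
windows separate from a GC≈0.4 background by construction, so the scan
test establishes the *conventions* (tiling, anchoring, strand handling,
ranking, p-values) and the pipeline's plumbing — not detection power on
real genomes, where signal-to-background is far smaller, composition is
inhomogeneous, and annotations are imperfect. Likewise the i.i.d.
backgrounds lack the repeat structure and skews of real intergenic
sequence. Scans of real genomes require only a FASTA, an annotation
TSV, and a trained model file.

## Problem sizes in the test suite

Oracle-equivalence batteries use sequences of length ≤ 10 (exhaustive
enumeration stays exact and fast); scaling checks run one 300-nt
sequence; parameter recovery uses 1000 sampled structures; logistic
recovery 5000 points (coefficients of magnitude ~1, where a ±10%
recovery claim has comfortable statistical margin at that n); shuffle
batteries 10,000 draws of a 50-nt sequence; the toy genome scans 16
forward windows of 157 nt. These sizes were chosen so each check is
statistically meaningful while the whole suite stays quick on a laptop.

## Known limitations

- No pseudoknots anywhere (grammar, distances, landscape).
- Derivation entropy for ambiguous grammars is not structure entropy.
- The bundled BJK parameters come from synthetic hairpins; results on
  real sequences should use a benchmark-trained grammar file.
- The simple pair-energy engine ignores stacking, loop penalties, and
  dangles.
- Cross-organism homology search, ORF prediction near hits, and motif
  searches are out of scope; hits are ranked and filtered, not
  annotated.
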