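# Methods

## Problem and model

`rnaflex` treats per-nucleotide flexibility prediction as regression: for
nucleotide *i* with topological feature vector **x**ᵢ ∈ ℝᵖ, predict the
normalized B-factor *y*ᵢ of its ribose C1' atom. The feature map and the
evaluation protocol carry the scientific content; the regressors themselves
are standard.

### Local element-specific persistence features

Around each C1' atom, heavy atoms (C, N, O, P; hydrogens discarded) within
cutoff *E* form a local region; one point cloud per element is built, each
including the central C1' (deduplicated for carbon). Each cloud is filtered
by the Vietoris–Rips complex with edge value the Euclidean distance,
truncated at *F* = *E* · (F/E), and persistence is computed over ℤ/2 for
dimensions 0..D (default {0, 1}; 2 available). Bars alive at *F* carry
death +∞. The simplicial complex is built up to dimension D+1 so deaths in
dimension D are correct.

Binning: the interval [0, F] carries grid points *kF/N*, *k* = 1..N with
*N* = round(F/f) ≥ 1. Component *k* counts bars with b ≤ kF/N ≤ d, both
comparisons inclusive, infinite deaths always satisfying the right one.
When F/f is not an integer the grid stays at kF/N (the count formula is
kept exact) and the effective bin width F/N is required to stay within 25%
of the nominal *f*; configurations outside that band are rejected rather
than silently re-gridded. Blocks are concatenated element-major (fixed
order C, N, O, P), dimension-minor (ascending), so a feature vector always
has length |elements| · |dims| · N and an element's ablation can only
touch its own slice — both properties are asserted in tests.

### Targets

Per chain, raw C1' B-factors pass through (1) outlier removal by the
modified z-score M = 0.6745 (x − median)/MAD with cutoff 3.5 (no removal
when MAD = 0), then (2) z-normalization with the *population* standard
deviation, so zero mean and unit variance hold exactly on the retained set.
The cutoff is configurable because the underlying "median-based" rule
admits variants; the Iglewicz–Hoaglin form is the canonical choice.
Removed nucleotides contribute no feature row. Chains with fewer than
three sample atoms, or zero B-factor variance, are skipped with a warning.

## Persistence backends

The production engine computes dimension 0 by union-find over edges sorted
by (length, vertex order) and higher dimensions by sparse column reduction
of the boundary matrix, one dimension at a time, with columns stored as
Python-integer bitsets (pivot = highest set bit = latest-entering facet).
Ties are broken by (filtration value, dimension, lexicographic vertex
tuple); bar multisets are tie-order invariant, which the tests assert.

An independent oracle (`brute_force_persistence`) enumerates every simplex
up to dimension D+1, sorts the full boundary matrix globally, and runs the
textbook reduction. It is limited to 12 points and exists purely to verify
the production engine; the suite checks multiset equality of
(birth, death, dim) within 1e-9 on seeded random clouds, including
dimension 2 on small clouds.

Zero-persistence bars (birth = death) are dropped for dimensions ≥ 1 — a
loop filled the instant it forms (e.g. an equilateral triangle) carries no
information — but kept for dimension 0, so the dimension-0 barcode always
has one bar per point. Degenerate inputs: a single-point cloud yields one
infinite dimension-0 bar and empty higher barcodes (its binned dimension-0
block is all ones); duplicate points yield zero-length dimension-0 bars.

## Synthetic data generator

The generator emulates single-stranded RNA-like chains at A-form-like
geometry: C1' atoms on a helix of radius 9.4 Å, twist 32.7°/nucleotide and
nominal rise 2.81 Å, with the other 20 heavy atoms of a ribonucleotide
(8 C, 4 N, 7 O, 1 P) at fixed template offsets in the local helix frame,
plus Gaussian jitter (sd 0.3 Å). The rise is modulated sinusoidally along
the chain (fractional amplitude 0.3, period 18 nucleotides, chain-specific
phase): compressed segments pack densely and stiffen, stretched segments
loosen, giving the graded flexibility profile real chains show. Without
this, interior packing is uniform and the only B-factor structure is at
the termini — which the median outlier rule then removes, leaving
essentially no learnable signal; an unmodulated helix is available by
setting the amplitude to zero.

Ground-truth B-factors follow a local-packing law independent of
persistent homology, so the pipeline is validated against an external
signal rather than against itself: B = 90 − 1.0 · n₆ + ε, where n₆ is the
number of heavy atoms within 6 Å, ε ~ N(0, σ²) with σ = 3 Å² by default
(roughly 40% of the structural signal's spread — a realistic noise level),
floored at 0.01 Å². Default study conditions: 8 chains of 30–60
nucleotides. Everything is a pure function of the configuration, including
the seed; per-chain streams are derived as `default_rng([seed, chain,
stream])` so chains are independent and files regenerate byte-identically
from the manifest.

What the generator does *not* emulate: base pairing and tertiary contacts,
sequence-dependent chemistry, crystal packing, refinement artefacts, and
the long-range contact structure of large RNAs. Passing tests therefore
show that the pipeline recovers a local-density flexibility signal through
the topological featurization under honest chain-grouped evaluation — not
that any particular PCC will be attained on real deposited structures.

## Learning protocol

Chains are the grouping unit everywhere. The 75/25 split rounds the train
size (at least one chain on each side); five cross-validation folds differ
in size by at most one chain. A hyperparameter combination is scored by
pooling the out-of-fold predictions of all training chains into a single
Pearson correlation ("pooled" rather than fold-averaged: one score over
all folds, which also keeps small folds from dominating). Final evaluation
reports the pooled test PCC plus per-chain PCCs; the two differ in general
(pooling is sensitive to between-chain offsets), which a constructed test
demonstrates.

Model families and notable choices:

- ridge / lasso: squared loss with α‖β‖₂² / α‖β‖₁ (scikit-learn).
- random forest: split candidates per node mtry = ⌈√p⌉ (Breiman's
  convention); trees and minimum leaf size are the tuned parameters.
- XGBoost: trees and maximum depth tuned, other parameters at library
  defaults.
- SVR: RBF kernel exp(−γ‖x−x′‖²); ε defaults to 0.1 (configurable).
- neural network: sigmoid hidden layers, leaky-ReLU output (slope 0.01),
  inverted dropout at 20%, Adam at its standard 1e-3 rate, mean-squared
  error, inputs standardized internally; implemented directly in numpy and
  fully deterministic per seed.

Presets `esph-single` (ridge α 500, lasso α 0.01, RF 500 trees / leaf 5,
XGBoost 50 trees / depth 3, SVR γ 0.01 C 0.1, net 4 × 68 for 15 epochs)
and `esph-cnop` (lasso α 1, RF 2000 trees, SVR γ 0.001, net 3 × 900 for
10 epochs; rest identical) cover the single-element and four-element
feature sets.

## Numerical and design notes

- Distances are Euclidean in Å; features are exact integer counts, so the
  feature matrix is bit-identical under rigid motions (asserted).
- Region membership and binning comparisons are inclusive (≤), matching
  the count formula literally.
- The grid search scores failed combinations as missing (NaN) and returns
  the argmax of its own score table.
- Chain leakage (a chain on both sides of any split) is a hard error, and
  out-of-fold predictions are verified to come from models blind to the
  predicted chain.
- Problem sizes in the test and acceptance runs (8 chains × 30–60
  nucleotides for recovery; 6 chains × 20–32 for sensitivity scans; random
  clouds of 4–8 points for the oracle suite) were chosen as the smallest
  sets on which the statistical claims are stable across seeds.

## Known limitations

- PDB only (first model, first altloc, HETATM off by default); no mmCIF.
- The brute-force oracle is exponential and capped at 12 points.
- Dimension-2 homology is available but quickly becomes the dominant cost
  for clouds beyond a few hundred points.
- The leaky-ReLU output squashes negative pre-activations by 100×, which
  slows learning on strongly negative normalized B-factors; it is kept as
  the specified architecture.
- Sensitivity trends on synthetic data plateau near the generator's
  interaction radius (≈6 Å), far below the 35 Å plateau reported for real
  RNA sets whose large chains dominate — the synthetic signal is purely
  local by construction.
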