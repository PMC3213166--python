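# Methods

## Scope and conventions

All sequences handled internally are 19-nt sense-strand siRNAs over
{A, C, G, U}; `T` is accepted on input as a synonym for `U`. Positions are
1-based, 5'→3' on the sense strand. Efficacy is percent inhibition of the
target mRNA and stays on the [0, 100] scale throughout — no label
normalization is applied before training, since Pearson r, the selection
and evaluation statistic, is invariant to affine rescaling of either
variable. The antisense (guide) strand is always derived as the reverse
complement of the sense input, so one canonical record suffices for both
sequence and thermodynamic views.

## Encodings

Numeric, binary and hybrid encodings are positional maps; the binary
quartet order is (G, C, U, A), i.e. A = `0001`, U = `0010`, C = `0100`,
G = `1000`, serialized position-major. Hybrid appends, per position, the
Pearson correlation between the indicator of the observed nucleotide at
that position and the training efficacies. Indicator cells with zero
variance (a nucleotide always or never present at a position, or constant
labels) receive weight 0 with a warning rather than NaN, keeping the
encoder a total function.

The rule encoding maps each position through 12 named rule sets to
{+1, 0, −1}. Conflicting verdicts *within* one set at one
(position, nucleotide) are rejected at load time; conflicts *across* sets
are expected and preserved — they are the signal. The shipped 12-set
table is a best-effort curated transcription of the published design-rule
literature and is data, not code; tests exercise the machinery with toy
tables so correctness does not hinge on the curation.

## Feature screening and selection

Candidate features are the 76 position-nucleotide indicators, every
subword of length 2–5 **observed** in the training sequences (absent
subwords have zero variance and an undefined correlation, so the full
4ⁿ universe is not enumerated), and 21 thermodynamic values. N-gram
counting is overlapping (`AA` occurs 3 times in `AAAA`): overlap
counting is the stricter, information-preserving reading of
frequency-based subword features, and it is what the worked example
(`AG` twice in `AGGAG`) is consistent with.

Significance is the exact two-sided t-test of a Pearson correlation
(p < 0.001); the |r| thresholds of the F85/F65/F47 methods are strict
(`|r| > t`, matching the ">" notation of their definition). Thermodynamic
features are retained unconditionally. Element order in a frozen feature
set is deterministic: kind (single, n-gram, thermo), then key
lexicographic. Screening is vectorized (column-wise centered dot
products); it reproduces `scipy.stats.pearsonr` per column to 1e-12,
which is asserted in the tests.

## Thermodynamics

The nearest-neighbor table is the Xia et al. (1998) RNA Watson–Crick set
(ΔG°₃₇, ΔH°, ΔS°), symmetry-expanded to all 16 dinucleotide steps and
shipped as editable TSV. Stack k (k = 1..18) is the parameter of the
antisense dinucleotide at positions (k, k+1), read 5'→3' on the guide
strand; `whole_dG` is strictly the sum of the 18 stacks — duplex
initiation, terminal-AU and symmetry corrections are deliberately
excluded, because the quantity used throughout (including the
−34.6 kcal/mol stratification threshold) is internal stacking stability,
not a full duplex formation energy. Orientation is covered by the
reverse-complement involution property test, and the whole-duplex sums by
a translation-invariance test (adding c to every step parameter adds 18c).

## Layer 1

Each characteristic method is an ε-SVR with RBF kernel.
Hyperparameters are selected by inner 5-fold grid search scored by
Pearson r. The default grid is deliberately small — C ∈ {1, 10, 100},
γ = "scale", ε = 0.1 — because the encodings are standardized-scale
one-hots, counts and energies for which C is the binding knob; an
arbitrary grid (e.g. full dyadic ranges of C, γ, ε) can be passed via
`param_grid` when an exhaustive search is wanted. The reported `cv_r_` is
the correlation between pooled 10-fold out-of-fold predictions and the
observed efficacies, with the *encoder refit inside every fold* (the
hybrid weights and feature selection are themselves trained statistics,
so leaving them fitted on the full data would leak). Folds are a seeded
shuffle split into near-equal parts; a fold with constant labels is
merged into its neighbor with a warning.

## Admission and stacking

Methods with cv r ≥ 0.6 (inclusive) are admitted and partitioned into
sequence-type and feature-type; layer 2 always fuses exactly one of
each. The fusion is trained on a stacking frame of out-of-fold layer-1
predictions, built with the hyperparameters each method selected on the
full data (re-running the grid per fold would multiply cost for no
measurable change in the frame). Reusing the fold seed lets the frame be
served from the layer-1 cache when the data are identical.

Whether to stack on in-fold or out-of-fold predictions was a genuinely
open design point; out-of-fold is the default because in-fold layer-1
predictions provably inflate the layer-2 training correlation — exactly
the overfitting failure mode that large unselected feature sets show —
and the frame builder demonstrates the gap on noisy data in tests.

## Fusion mechanisms

*SVR fusion* mirrors layer 1 on the 2-column frame.

*Neural-net fusion* is a 2-6-1 network with sigmoid hidden **and**
output units, trained by full-batch gradient descent with momentum
(lr 0.5, momentum 0.9, ≤ 5000 epochs, early stop after 200 epochs
without improvement). Inputs are standardized; targets are min-max
mapped to [0.1, 0.9] rather than [0, 1] to keep the output sigmoid off
its saturated tails, then inverted on prediction and clipped to the
percent range. It is written directly in numpy because the architecture
contract (sigmoid output, bounded rescaling) is part of the model, not
an off-the-shelf regressor configuration.

*GA fusion* evolves `R_pred = W₁R₁ + W₂R₂`, W ∈ [0, 1]², minimizing MSE.
Chromosomes are 2 × 16 bits decoded linearly to [0, 1] (granularity
1/65535, far below any meaningful weight resolution); selection is
fitness-proportional roulette on 1/(1+MSE) with elitism of 1; one-point
crossover at rate 0.7 and per-bit mutation at 0.001; defaults are
population 100 and 2000 generations. The weights are *not* constrained
to sum to 1. Since the MSE is a quadratic in (W₁, W₂), each
individual's fitness is evaluated from six precomputed second moments,
making cost independent of n. Elitism makes the best-fitness trajectory
non-increasing, and tests require the evolved MSE to land within 5% of
the box-constrained least-squares optimum computed by an independent
solver.

## Pair choice

With several admitted methods, the pair is chosen by fusion performance
on a seeded 80/20 split of the stacking frame (the study that motivated
this design selected on an external validation compilation; an internal
split mirrors that logic without requiring external data). An explicit
pair can always be forced.

## Evaluation

Classification metrics call "high-efficacy" at ≥ 70% inhibition
(boundary inclusive) on *both* observed and predicted values — a single
shared cut, exposed as two parameters for sensitivity analysis. MCC with
a zero denominator factor is reported as 0 with a warning; Sn/Sp are
reported absent (None) when their class is empty, which is a different
statement than 0. The ΔG stratification puts the boundary value
−34.6 kcal/mol in the "≥" (high-confidence) stratum; a stratum with
n < 3 reports its r as absent. Percentages print with 2 decimals.

## Synthetic data

The generator emulates the shape of published siRNA screens (thousands
of 19-mers with measured percent knockdown): sequences uniform over
{A,C,G,U}¹⁹ and `efficacy = clip(50 + effect·z(signal) + N(0, noise_sd),
0, 100)` with a planted signal — GC count, −whole ΔG (so efficacy
correlates negatively with ΔG, the direction seen in real screens), or a
weighted sum of position-specific nucleotide indicators echoing known
design rules. Defaults are n = 500, noise sd 10, effect size 20
(signal-to-noise r ≈ 0.9 before clipping), which a screen of validated
siRNAs roughly exhibits for its strongest composite predictors.

What the generator does **not** emulate: position-dependent epistasis,
target-site accessibility and mRNA secondary structure, measurement
batch effects, and the long-tailed efficacy distributions of real
screens. Passing tests therefore demonstrate that the machinery recovers
plantable linear-ish signal through every pathway — not that any
particular correlation will be reached on laboratory data.

## Problem sizes used by tests and the acceptance script

The acceptance script trains on 1000 records and evaluates on 300
held-out records (noise sd 10, effect 20); unit tests use 50–300 records.
These sizes give stable correlations (±0.02 across seeds at n = 1000)
while keeping a full run in minutes on one core.

## Known limitations

- The shipped rule table is a curated approximation of the published
  rule sets; users with an authoritative transcription should supply it
  as data.
- Feature identities (which 162/85/65/47 elements survive) depend
  entirely on the training set; the package freezes and serializes them
  per model rather than claiming a canonical list.
- The GA explores a 2-D quadratic bowl, so it is an interpretability
  device (exposing component weights), not a better optimizer than
  closed-form least squares; it is validated against the latter.
- Model bundles embed fitted scikit-learn objects via joblib and are not
  portable across major library versions.
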