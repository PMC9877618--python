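# Methods

## The SIELU activation and its numerics

The tanh-form GELU, `0.5·x·[1 + tanh(√(2/π)(x + 0.044715x³))]`, is an
approximation of the exact GELU `x·Φ(x)`. SIELU is the same expression
after the identity `tanh(y) = 2σ(2y) − 1`:

    SIELU(x) = x·σ(2√(2/π)(x + 0.044715x³))

We implement the canonical simplified form (an intermediate derivation step
that leaves a "−1" inside the sigmoid argument is algebraically spurious
and is not implemented). Because the identity is exact, the package treats
SIELU ≡ GELU as a falsifiable contract: `error_scan` checks the pointwise
difference (observed ≤ 2e−15 on [−10, 10], step 1e−3) and the test suite
trains seeded SIELU and GELU networks and requires identical trajectories
(observed max per-epoch loss difference ≈ 1e−17 over 500 epochs). The
analytic gradient `σ(u) + x·σ(u)(1−σ(u))·u′`, `u = 2√(2/π)(x + cx³)`, is
verified against central finite differences.

### Historical normal approximations

The module carries the approximations the GELU lineage descends from, all
for the upper tail with `t = η = √(ln(1/p²)) = √(−2 ln p)`:

- Hastings 4-constant quantile: `X*(q) = η − (a₀+a₁η)/(1+b₁η+b₂η²)` with
  a₀=2.30753, a₁=0.27061, b₁=0.99229, b₂=0.04481.
- Hastings 6-constant / rational inverse (identical constants
  C₀=2.515517, C₁=0.802853, C₂=0.010328, d₁=1.432788, d₂=0.189269,
  d₃=0.001308): `z = t − (C₀+C₁t+C₂t²)/(1+d₁t+d₂t²+d₃t³)`, classical
  error bound |e(p)| < 4.5×10⁻⁴.
- Composite-exponential CDF form:
  `Φ(z) − 0.5 ≈ 0.5·√(1 − (1/30)[7e^{−z²/2} + 16e^{−z²(2−√2)} +
  (7+πz²/4)e^{−z²}])`, for z ≥ 0 (callers use symmetry below 0). This is
  the end-corrected Simpson rule applied to the polar-coordinate integral
  for erf²: the weights 7, 16, 7 over 30 and the πz²/4 boundary term drop
  out of that quadrature exactly.

No scan domain is canonical for the quoted error bounds; we fix z ∈ [0, 10]
(step 1e−4) for the CDF form and p ∈ [10⁻⁶, 0.5] for the quantile, and
`error_scan` reports the arg-max so the choice is auditable. On these grids
the quantile bound verifies (max 4.443×10⁻⁴ at p ≈ 0.358). The CDF form's
measured maximum is 3.0365×10⁻⁵ at z ≈ 0.402 — about 1.2% above the
traditionally quoted 3×10⁻⁵; away from that neighborhood (z ≥ 0.5) the
maximum is 2.96×10⁻⁵. We report the measured value rather than adjusting
the formula or the grid; the quoted bound appears to be a rounding of the
true supremum. `sielunet benchmark-activations` exits nonzero when a quoted
bound fails on the fixed grid, which is the honest outcome here.

Elementary activations (sigmoid, tanh, ReLU, LeakyReLU σ=0.01, softmax)
use overflow-safe branch/shift forms; ReLU and LeakyReLU assign x = 0 to
the x ≥ 0 branch.

## The 46-feature encoding

Order: 20 composition fractions (A R N D C Q E G H I L K M F P T S W Y V),
coiled-coil score, nitrosylation A/B/C/total, nitrotyrosine A/B/C/total,
SUMOylation I/II/III/total, length, n_negative, n_positive, molecular
weight, theoretical pI, C/H/N/O/S atom counts, instability index, aliphatic
index, GRAVY.

Conventions, all recorded in `FeatureSchema` (whose hash travels with every
feature table and trained model):

- **Sanitization.** `strict` errors on non-standard letters; `drop`
  removes them; `impute` maps B→N, Z→Q, U→C, J→L, O→K and drops X. The
  pipeline default is `impute`; direct library calls default to `strict`.
- **Charged residues.** negative = D+E, positive = K+R. Histidine is mostly
  uncharged at physiological pH and is excluded from the positive count
  (configurable).
- **Molecular weight.** Average (not monoisotopic) masses via biopython;
  one water (18.0153 Da) per chain, so MW(AB) = MW(A) + MW(B) − 18.0153.
- **Atom counts.** Free-residue molecular formulas summed, minus (L−1)
  waters.
- **Theoretical pI.** Bisection on (0, 14) of the Henderson–Hasselbalch
  net charge under the EMBOSS pKa set (N-term 8.6, C-term 3.6, K 10.8,
  R 12.5, H 6.5, D 3.9, E 4.1, C 8.5, Y 10.1) to |charge| < 10⁻⁴. The
  charge is strictly decreasing in pH and brackets zero, so the root is
  unique. Biopython's Bjellqvist-set pI serves as a loose cross-check in
  tests; pKa sets legitimately differ by up to ~1 pH unit on short
  peptides.
- **Instability index.** `(10/L)·Σ DIWV(sᵢ, sᵢ₊₁)` with the published
  Guruprasad dipeptide table (via `Bio.SeqUtils.ProtParamData`); length
  ≥ 2 required.
- **Aliphatic index.** `X_Ala + 2.9·X_Val + 3.9·(X_Ile + X_Leu)` in mole
  percent. **GRAVY.** Mean Kyte–Doolittle hydropathy.
- **PTM motif counters (declared stand-ins).** No authoritative motif
  library is mandated for these columns, so deterministic, configurable
  patterns are used: SUMO I = ψ-K-x-E, SUMO II = ψ-K-x-D, SUMO III =
  inverted [ED]-x-K-ψ with ψ ∈ {A,I,L,M,V,F}, counted with overlap;
  nitrosylation (around C) and nitrotyrosine (around Y) classes A/B/C count
  center residues whose ±3 flank contains ≥1 acidic / basic / hydrophobic
  residue; each "total" is the sum of its three subcounts. Substituting an
  authoritative pattern set changes the schema hash.
- **Coiled-coil score (stand-in for an external predictor).** Number of
  length-28 windows in which, for the best of the 7 heptad phases, at
  least 75% of the a/d positions are hydrophobic (AILMFVW).

Permutation behavior is part of the contract: composition, charge/atom
counts, MW, pI, AI and GRAVY are invariant under residue permutation;
instability, PTM counts and the coiled-coil score are order-sensitive.

## Dataset preparation

- **Redundancy removal.** Greedy longest-first clustering: a record joins
  the first representative with identity ≥ 0.80, else founds a cluster.
  Identity = exact matches in a global alignment (unit match, zero
  mismatch, gap open −1 / extend −0.5, via biopython's PairwiseAligner)
  divided by the shorter length. This mirrors CD-HIT's documented
  semantics at desk scale; by construction no surviving pair reaches the
  threshold. Positives and negatives are deduplicated separately by
  default (joint dedup is available by concatenating record lists).
- **Scaling.** `zscore` (StandardScaler) is the pipeline default; `minmax`
  is selectable. The two are alternatives, never composed — applying both
  would make the min–max step a no-op statistically and muddy provenance.
  Scalers fit on training rows only; constant training columns are flagged
  and mapped to 0; state serializes to JSON with a training-set
  fingerprint.
- **Splitting.** Stratified 80:20 with per-class test count
  `round(n_class · test_fraction)`; a nested 80:20 split of the training
  rows yields train-core/validation. Stratified 5-fold partitioning wraps
  sklearn's shuffled StratifiedKFold. All splits are seed-deterministic.

## Models

Architecture (46 features in, 1 sigmoid unit out):

| piece | value | note |
|---|---|---|
| input layer | 150 units, He-normal init (σ² = 2/fan-in) | activation selectable: sielu, gelu, relu, tanh, sigmoid |
| hidden layer | 50 units + dropout 0.02 | dropout after the hidden activation, matching the stated ordering |
| optimizer | Adam α=1e−3, β₁=0.9, β₂=0.999, ε=1e−8 | batch size 32 |
| loss | MSE on the sigmoid output (default) | BCE available; MSE is kept as the published default even though BCE is the textbook choice for binary outputs |
| schedule | exactly 500 epochs, no early stopping | per-epoch (train acc, val acc, loss) history |

Two input modes interpret "a recurrent model over tabular features":
`recurrent` (default) feeds each sample as a length-1 sequence into a
one-step LSTM-style layer — input gate i = σ(Wᵢx), candidate g = act(W_g x),
output gate o = σ(W_o x), cell c = i⊙g, h = o⊙tanh(c); with a zero initial
state the forget gate multiplies nothing and is omitted — while `dense` is
the plain feed-forward reference (14,651 parameters:
46·150+150 + 150·50+50 + 50·1+1). The hidden-50 layer uses the same
selectable activation as the input layer (the source architecture names an
activation only for the input and output layers; sharing it is the least
surprising completion and keeps the SIELU/GELU trajectory-identity
property meaningful end to end).

The network is numpy with hand-written backprop, so fixed seed +
single-threaded BLAS gives bit-identical runs; serialization is a JSON
container (config, schema hash, weights, history) whose round-trip
reproduces predictions exactly (Python float repr round-trips). A
non-finite loss or pre-activation aborts training with a diagnostic naming
the epoch.

Baselines: SVC with polynomial kernel and kernel coefficient γ = 0.01, and
a random forest with min_weight_fraction_leaf = 0.1, both evaluated with
stratified 5-fold cross-validation.

## Evaluation

Accuracy, precision, recall (= sensitivity), F1 and specificity are
percentages; MCC is dimensionless in [−1, 1]. Degenerate cases are defined:
MCC = 0 when its denominator vanishes; precision = 0 (with a warning) when
nothing is predicted positive. Formatted output rounds percentages to two
decimals. ROC curves/areas come from sklearn (trapezoid rule; equal to the
all-pairs concordance probability, which the tests verify by an O(n²)
oracle); the PR-curve area is the average-precision summary, since
trapezoid integration of a raw PR step curve is biased at duplicated recall
values. The per-epoch history is emitted as an epoch/train_acc/val_acc/loss
table with an optional matplotlib plot.

## Synthetic data

`generate_sequences` draws i.i.d. sequences over the 20-letter alphabet:
class 0 from a background (uniform 1/20 by default, for analytic
transparency; a natural-abundance preset is included), class 1 from the
background shifted by an absolute composition delta (+0.05 on K and E by
default, compensated proportionally on the other residues) and enriched
with planted motifs (default one SUMO-I instance "LKSE" at Poisson rate
2/sequence). Lengths are uniform on 120–300, 200 sequences per class —
the scale of a curated stress-protein study set. These defaults are the
study conditions for the pipeline checks and are not tuned per run.

`generate_feature_table` skips sequences and draws unit-variance Gaussian
46-column matrices with class 1 shifted by `d` standard deviations on the
first k columns, so the Bayes-optimal accuracy is `Φ(d√k/2)` in closed
form; the tests require every model to come within 5 points of it
(d = 1, k = 5, n = 2000).

What passing these checks does **not** show: real stress/non-stress protein
sets differ by diffuse, correlated biological signal, not by clean planted
shifts; performance on the synthetic conditions says the pipeline is
correct and sensitive, not that any particular real-data accuracy will be
reached. Redundancy structure, homology families, length biases and
class imbalance of real UniProt queries are all absent.

## Problem sizes and runtimes

Chosen as the package's own working scale: error scans use 1e5–5e5 grid
points; the trajectory comparison trains two 500-epoch networks on
320 × 46 tables; the pipeline checks use 200 sequences/class (≈ 80 test
sequences), 500 epochs for the signal run and 150 for the shuffled-label
null; the dedup contract is verified by exhaustive pairwise alignment on a
120-record pool with 40 planted near-duplicates. The full acceptance
recomputation takes ~1.5 minutes on one CPU.

## Known limitations

- The PTM and coiled-coil counters are motivated stand-ins, not validated
  predictors; treat those 13 columns as deterministic sequence statistics.
- Greedy identity clustering is quadratic; fine for thousands of
  sequences, wrong tool for millions.
- The one-step recurrent mode is a degenerate LSTM by construction; it
  exists to honor the named architecture, and the dense mode is the
  cleaner reference.
- MSE-on-sigmoid has weaker gradients than BCE near saturated outputs;
  it is kept as the default deliberately.
- pI, MW and instability values depend on the declared tables (EMBOSS
  pKa, average masses, Guruprasad DIWV); swapping tables changes the
  schema hash but not the code path.
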