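# Methods

## Problem setting

Candidate carbonylation sites are K, R, T or P residues. Each annotated
site is represented as a fixed-length peptide window (default L = 21,
site at the centre; windows overhanging a protein terminus are padded
with `X`, which never enters any feature count). The positive class
(carbonylated) is rare: imbalance ratios IR = M/m of 5–700 are typical,
and the constructed benchmarks here use M = 1000 negatives against
m ∈ {200, 100, 10, 3} positives (IR 5, 10, 100, 333).

## DR features

A window is encoded by distance-based residue (DR) counts:

- `D_0`: the 20 single-residue counts, residues ordered alphabetically
  (A, C, D, …, Y);
- `D_k`, k = 1..d_max: the 400 ordered-pair counts of residues at
  positions (p, p + k) — distance *exactly* k, so the blocks are
  disjoint and, for an `X`-free window, `ΣD_0 = L` and `ΣD_k = L − k`.

Vector length is `20 + 400·d_max`. `d_max` defaults to 3 (1220
features); the appropriate value is data-dependent and configurable —
larger `d_max` adds sparser, noisier pair blocks. Features are
min-max scaled per column, fitted on the training partition only;
constant columns map to 0 and out-of-range test values are not clipped.

## Two-way rebalancing

**Optimal scale.** Oversampling beyond the data supports noise;
undersampling discards information. Balancing the two ratios —
minimising `s/m + M/s` over integer `s ∈ [m, M]` — gives
`s = √(mM)`, implemented as nearest-integer rounding (half away from
zero) clamped to `[m, M]`. The rounded value can differ from the true
integer minimiser by at most 1 when both straddle `√(mM)`; for the
IR = 333 benchmark, `s = round(√3000) = 55`.

**Attention-based undersampling.** Attention here is the row-softmax of
the cosine-similarity matrix; every row is a distribution (entries in
[0, 1], summing to 1). A sample's diagonal entry measures how much of
its attention stays on itself: low values mark samples that resemble
many others (representative), high values mark outliers. Stage 1 keeps
the `⌈(s+M)/2⌉` negatives with the smallest self-attention among the
negatives alone. Stage 2 pools those with all positives, recomputes
attention, and keeps the `s` negatives with the largest self-attention —
the ones least similar to the pool and hence least positive-like.
Both stages are deterministic; ties break toward the lower original
index. Cosine requires non-zero rows; a zero row is an error rather
than an imputed similarity. "Softmax over cosines" is our reading of
"normalize": it is the only standard normalisation that guarantees the
stated [0, 1] range and row-stochasticity when cosines can be negative.

**GAN-based oversampling.** The generator (noise → features, sigmoid
output) and discriminator (features → real/fake logit) are two small
MLPs with LeakyReLU(0.2) hidden layers, trained alternately with the
standard adversarial objective; the generator uses the non-saturating
variant (maximise `log D(G(t))`) rather than literally minimising
`log(1 − D(G(t)))`, the usual stability substitute on small data.
Implementation is plain numpy with hand-written backprop and Adam
(β₁ = 0.5), fully seeded and bit-reproducible.

Defaults: noise_dim 32, hidden (128, 128), batch `min(32, m)`,
learning rate 2e-4, 200 epochs **with a floor of 2000 optimizer
updates** (`min_updates`). The floor matters: for m ≤ 32 an epoch is a
single minibatch, and 200 Adam steps at 2e-4 measurably leave generated
samples off the data manifold (closer to the negative class than to the
positives); at ≳2000 updates generated samples sit on the positive
manifold with realistic spread. The generator's output-layer bias is
initialised to `logit(column means)` so generation starts at the data's
marginal profile instead of the 0.5 cube centre — on sparse count
features the latter is many standard deviations from the data.

Two practical caveats, both visible in the benchmarks below: a GAN
fitted on very few positives (single digits) approaches a resampler of
those points, and its synthetic cloud cannot restore information the
sample does not contain.

## Classifier and evaluation

The SVM dual with Gaussian kernel `K(x,z) = exp(−‖x−z‖²/2σ²)` is solved
by libsvm (scikit-learn `SVC`); the multipliers satisfy `Σαᵢyᵢ = 0`,
`0 ≤ αᵢ ≤ C` (asserted in tests), and the bias is recomputed as
`b* = yⱼ − Σᵢ αᵢyᵢK(xᵢ,xⱼ)` averaged over free support vectors
(0 < α < C), falling back to the solver's intercept when none are free.
Defaults: C = 1 and the scale heuristic `σ = √(d·mean column variance/2)`.

Sensitivity is `TP/P`, specificity `TN/N` (scores ≥ 0 predict
positive), and AUC is the fraction of correctly ordered
(positive, negative) score pairs with ties counted ½ — identical to the
normalised Mann–Whitney U statistic, so `AUC(s) + AUC(−s) = 1` and the
value is invariant under strictly increasing score transforms.

Cross-validation is stratified; scaling, attention selection and GAN
training see only each fold's training split. The per-fold
rebalance+train cycle can be repeated `n_repeats` times with derived
seeds, keeping the model with the best training-split AUC (the
repeated-model-selection protocol; the tests and the benchmark runs use
`n_repeats = 1` to stay inside a desk-scale CPU budget — the protocol's
historical value is 200). Extreme imbalance caps usable folds: m = 3
positives cannot populate 10 folds, so the IR benchmarks instead train
on the imbalanced set and score on a balanced, independently drawn
synthetic test set (500 + 500), identical across strategy arms.

## Synthetic data

`make_feature_dataset` draws negatives from a mixture of (default 3)
Gaussian clusters — so attention undersampling has structure to
exploit — and positives from a single Gaussian offset by
`class_separation` within-class standard deviations, then squashes
everything into (0, 1) with a logistic transform (clipping would pile
atoms on the boundary and distort cosines). Cluster centres and the
offset direction are functions of the seed: a train/test pair must be a
split of one draw, not two differently-seeded draws.

`make_peptide_dataset` emits windows with the requested centre residue;
positives carry signature residues at five fixed offsets
(−5:D, −3:E, −1:P, +2:G, +4:S) with probability
`1/20 + motif_bias` (exact categorical draw, so `motif_bias = 0` makes
the classes statistically identical); all other positions are uniform
over the 20 residues. This emulates a compositional motif only — no
claim of real carbonylation biology — so a green downstream test
establishes signal recovery, not biological validity.

## What the benchmarks show (and don't)

On the peptide benchmark (motif_bias 0.5, seed 0, balanced external
test), the two-way strategy reproduces the intended qualitative
behaviour at moderate-to-extreme imbalance for the ranking metric: its
AUC is the best of all arms at IR = 100 (0.856 vs 0.848 none, 0.787
random undersampling) and IR = 333 (0.815 vs 0.786 / 0.765), and its
sensitivity at IR 5–10 (0.44 / 0.30) far exceeds no-resampling and
SMOTE (≤ 0.23) at equal AUC.

Two behaviours do not match the idealised expectations:

- At IR = 333 (m = 3) *every* strategy that trains on a geometrically
  meaningful positive set scores all far-field test points negative at
  threshold 0 (sensitivity 0): with 3 real positives the fitted
  positive region cannot cover independently drawn positives in
  1220-dimensional DR space. Plain random undersampling's non-zero
  sensitivity at m = 3 is a 3-vs-3 calibration artifact (specificity
  0.64, AUC below every other arm), not generalisation.
- The AUC-vs-scale curve has an interior maximum but a shallow one,
  right-shifted from `√(mM)` (at IR = 100: 0.862 at s = 250 vs 0.856 at
  s = 100); the `s/m + M/s` trade-off predicts the right region, not
  the exact argmax, on this fixture.

## Numerical choices

- Rounding of `√(mM)`: nearest integer, half away from zero.
- Stage-1 cutoff `(s+M)/2`: ceiling when odd.
- Attention ties: lower original index wins (determinism).
- AUC ties: ½ per tied pair.
- Scores exactly 0 predict positive.
- Free support vectors: `1e-8 < α < C(1 − 1e-8)`; margins are exact only
  to the solver tolerance (~1e-3).
- All randomness flows through `numpy.random.default_rng` seeds; derived
  sub-seeds stay below 2³¹.

## Limitations

- The GAN is an unconditional MLP pair; no Wasserstein/gradient-penalty
  variants, no rejection filtering of generated samples.
- Oversampling operates in DR feature space; generated vectors are not
  decoded back to peptide sequences.
- No probability calibration; Sen/Spe are reported at the fixed
  threshold 0.
- Real carbonylation corpora are external downloads and are not
  bundled; all shipped data are synthetic.
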