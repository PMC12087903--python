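# Methods

This note documents the models implemented in `stgdan`, the assumptions
and numerical choices behind them, what the synthetic-data generator
does and does not emulate, and the design decisions taken where the
construction was genuinely open.

## Data model

A trial is a sequence of per-second differential-entropy (DE) samples
`X = (X₁ … X_L) ∈ ℝ^{L×N×F_de}` with one emotion label per trial and a
subject/session identity per recording.  The model input is the sliding
window `X_i = (X_{i−d}, …, X_{i+d}) ∈ ℝ^{T×N×F_de}` with
`T = 2d + 1`; a trial of length `L` yields exactly `L − 2d` windows
(0-based centres `d … L−d−1`), each inheriting the trial label.  Labels
are trial-level by convention of the public DE releases; windows of the
same trial are therefore not independent samples, which is why
evaluation also reports a trial-level majority vote.

DE extraction from raw signals (optional; the model consumes
pre-computed DE) band-passes with a zero-phase 4th-order Butterworth
filter, takes the variance per non-overlapping 1-s epoch, and applies
the Gaussian closed form `DE = ½ ln(2πeσ²)` in nats.  A variance floor
of 1e−12 guards silent epochs (the DE of a constant is −∞) and emits a
warning.  Features pass through unsmoothed; any external smoothing
(e.g. LDS) is the caller's choice.

## Attention

Temporal scores are the bilinear form
`Q = V_e · σ((X′U₁)U₂ · (U₃X″) + b_e)` with `X′ ∈ ℝ^{T×F×N}`,
`X″ ∈ ℝ^{N×F×T}`; spatial scores mirror it with `W₁ ∈ ℝ^T`,
`W₂ ∈ ℝ^{F×T}`, `W₃ ∈ ℝ^F`, `V_s, b_s ∈ ℝ^{N×N}`.  Shape trace
(temporal): `X′U₁ : T×F`, `(·)U₂ : T×N`, `U₃X″ : N×T`, product `T×T`.
The contraction order follows this dimension bookkeeping; the bilinear
form is specified by shapes, not index-level formulas, so the trace
above is the normative definition here.  The bias sits inside the sigmoid; note that
consequently a row-shift of `b` is *not* a softmax-invariant operation
(softmax shift-invariance holds for the post-mixing logits and is
tested there).  Both score matrices are row-softmaxed with
max-subtraction (output-identical, numerically stable).

`Q′` mixes time slices, `X̂_t = Σ_s X_s Q′[s,t]` — the product contracts
source time `s` into target time `t`, left-to-right as written.  `P′`
is computed once per window and shared across its `T` segments (no
`t`-specific construction exists for it).  Initialisation: `V` matrices
start at the identity and the `U/W/b` tensors at fan-in-scaled uniform
noise, so attention starts near-uniform — a neutral prior.

Ablations replace each mechanism by the neutral element of its usage
site: `Q′ = I` (no temporal mixing) and `P′ = 𝟙` (all-ones mask, no
edge re-weighting).

## Adaptive graph

`A_mn = softmax_n(−ReLU(wᵀ|x_m − x_n|))`, computed per window from the
time-averaged `N×F_de` features of that (attended) window.  The
element-wise absolute difference makes the ReLU argument a true
dissimilarity; with a signed difference the expression would be
antisymmetric in `(m,n)` and the non-negativity rationale would fail.
Rows sum to one by construction; the diagonal is each row's maximum
whenever `w ≥ 0` (zero self-distance), which is also how `w` is
initialised (uniform on `[0, 0.1]`).

The regulariser is `L_gcn = τ Σ_{mn} ‖x_m − x_n‖² A_mn + ‖A‖_F²`:
`τ` weighs only the smoothness term, not the Frobenius term.  It is averaged over the
batch, computed on the raw (asymmetric) `A`, and only labelled source
batches contribute.  `w` is the only learnable quantity in the
adjacency; "dynamic updating of the graph" is realised solely through
back-propagation into `w`.  A distance-based initial graph
(`A ∝ exp(−d²/θ²)` from electrode positions) is provided as an optional
warm-start utility, and a fixed KNN graph (union-symmetrised,
row-normalised, ties broken by lowest index, no self-loops) implements
the non-adaptive ablation, with `L_gcn ≡ 0` since there is nothing to
regularise.

## Spectral convolution

The Laplacian uses the symmetrised surrogate `A_sym = (A + Aᵀ)/2`: the
graph is declared undirected and `L = D − A` needs a symmetric `A` for
a real, well-defined spectral filter, while row-softmax output is
asymmetric.  (`L_gcn` keeps the raw `A`.)  `λ_max` is computed per
window by dense symmetric eigensolve and treated as a constant in the
backward pass (stop-gradient) — standard practice in Chebyshev-GCN
implementations; gradients flow through `L` itself.  An edgeless graph
(`λ_max < 1e−9`) falls back to `λ_max = 2` with a warning, giving
`L̃ = −I` for the zero matrix.

The filter is `Σ_k (ξ_k(L̃) ⊙ P′) X̂_t θ_k` applied **per time step**
(the time index of the aggregate is read as "for each t": the
output must keep a time axis for the temporal convolution to act on).
The Hadamard mask preserves the polynomial's locality semantics — a
matrix product with `P′` would not — and `θ_k ∈ ℝ^{F_de×F_out}` carries
the width change, the only learnable slot available for it.  The
temporal convolution `ReLU(Φ ∗ ReLU(·))` acts along time only, with the
nonlinearity on both sides (a double ReLU), kernel length 3 by default (smallest
context-mixing kernel; configurable, odd) and zero padding so `T′ = T`.
Time is then collapsed by mean pooling (the least-committal reduction)
and flattened node-major to `N·F_out` — 310 at the reference
62-channel, `F_out = 5` operating point, matching the 310-64-64-64
extractor.

## Domain-adversarial training

Discriminator loss (exact form, summed over samples):
`L_disc = −Σ_S log d(·) − Σ_T log(1 − d(·))` on the source-probability
component, clamped at 1e−7.  The training loop uses the per-domain
*mean* form so the effective adversarial weight does not scale with
batch size.  The discriminator head is binary by construction; the
"2/3" in the conventional head-width shorthand 64-64-64-2/3 is read as the *classifier* head's
class count (3 for a 3-class corpus), a separate `64 → C` layer.

The min–max objective `min_θf max_θd L_cls + L_gcn − λ L_disc` is
realised with a gradient-reversal layer: one forward/backward pass in
which the discriminator receives the true gradient of `L_disc` and
everything upstream receives it scaled by `−λ`.  Target windows enter
only the discriminator branch; their labels are never read.

Two λ schedules ship.  `paper_decreasing`, the default, is the
decreasing form `λ(p) = 2/(1 − e^{−p}) − 1` with `p` = epoch / max
epochs — monotone decreasing from a pole at `p = 0` (epochs count from
1) towards 1.  `dann_increasing` is the standard ramp
`λ(p) = 2/(1 + e^{−γp}) − 1`, γ = 10.  **Known limitation:** on short
budgets the decreasing schedule is destructive — at epoch 1 of a
30-epoch run it yields λ ≈ 60, and the reversed gradient then swamps
the extractor before it has learned anything; in our LOSO experiments
this made the discriminator strictly harmful.  The reference
experiments therefore use `dann_increasing`; the decreasing variant
remains the default for fidelity and behaves reasonably only when
`max_epochs` is large enough that early epochs are a vanishing fraction
of training.

Optimisation is RMSprop (α = 0.99, ε = 1e−8) at lr 1e−3, batch 96,
source batches shuffled per epoch and paired with cyclically resampled
target batches.  Training aborts with a diagnostic on non-finite loss.
Everything — initialisation, shuffling, the generator — is seeded, and
two runs with the same config produce byte-identical reports.

## Protocols and evaluation

Within-subject: per subject, the first `m` trials are the labelled
source and the rest the unlabelled target/evaluation domain
(`m` defaults to 9 of 15 or 16 of 24, otherwise 60% rounded).
Cross-subject: leave-one-subject-out, each subject once the unlabelled
target.  Fold seeds derive deterministically from the config seed.
Accuracy is window-level argmax (ties to the lowest class index, the
argmax convention); a trial-level majority vote is reported alongside,
since reported accuracies in this literature rarely state their
granularity.  Reports
carry per-fold accuracy, mean ± SD, and pooled confusion counts.

## Synthetic data

`features[t] = gain_s ⊙ (μ_c + z_t) + offset_s + ε_t`: class means
`μ_c` with entries `N(0, class_sep²)`; `z` an AR(1) process
(coefficient `ar_coef`, unit stationary variance) whose innovations are
correlated `block_corr` within channel blocks and independent across;
`gain_s ~ N(1, shift²)` and `offset_s ~ N(0, shift²)` per
channel/band; `ε` iid `N(0, noise_sd²)`.  `class_sep` is thus in units
of the unit-SD structured noise.  DE features are simulated directly
rather than via raw-EEG synthesis: the model consumes DE, and this
isolates the method under test.

The generator emulates trial-level labels, class-dependent channel
patterns, within-trial temporal smoothness, block-structured channel
correlation and affine subject shift.  It does **not** emulate
volume-conduction topology, non-stationarity within trials, label
noise, artefacts, or non-linear subject differences (a hook for custom
shifts exists).  Passing tests therefore demonstrate the machinery is
correct and the adaptation behaves as designed under affine shift —
not clinical-grade performance on real EEG.

### Preset operating points

`tiny_within` (1 subject, 15 trials, L = 30, N = 8, F = 5, C = 3,
`class_sep = 3`): clearly separable, used for capacity and
determinism checks.  `tiny_cross` / `shifted_cross` (4 subjects,
6 trials, L = 18, `subject_shift` 0 / 0.5): here `class_sep = 0.6` of
the total noise SD.  The separation is deliberately modest: at large
separations the class boundary generalises across any affine shift,
LOSO sits at ceiling, and the adaptation experiment degenerates — the
no-discriminator baseline must have headroom for the comparison to
mean anything.  With this operating point the baseline sits near 85%
and adversarial alignment recovers several points (paired over seeds),
while under zero shift the two arms are statistically
indistinguishable.

### Reference experiment sizes

The reference studies (`stgdan.experiments`) use d = 1, 30–40 epochs
and 8 channels, sizes chosen so the full suite of repeated runs
completes in minutes on one CPU while leaving every qualitative effect
intact.  The graph-recovery study uses `τ = 1`: with unit-scale
features the Frobenius term dominates `L_gcn` at the classification
default `τ = 1e−2`, and the smoothness term — which carries the
block-structure signal — needs comparable weight for the learned graph
to be interpretable.  Recovery is measured as the Spearman correlation
between off-diagonal learned edge weights (averaged over windows) and
the generator's binary block affinity.

## Numerical choices

float64 throughout; softmax and logistic with max-subtraction /
absolute-argument forms; probability clamps at 1e−7; variance floor
1e−12 in DE extraction; λ_max floor 1e−9 with fallback 2; KNN ties by
stable sort.  The autodiff engine is eager, single-threaded numpy with
einsum-based vector-Jacobian products; every primitive and the composed
pipeline are validated against central finite differences at 1e−6
tolerance.

## Known limitations

* CPU-only and eager: fine for N ≤ a few hundred channels and the
  dataset sizes here; no GPU path, no approximate eigensolvers.
* The decreasing λ schedule is unusable on short training budgets (see
  above).
* Per-window dense eigensolve of an N×N Laplacian bounds scalability
  in N.
* The MAT reader targets the public "ExtractedFeatures" layout only and
  is a convenience, not a dependency of any result.
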