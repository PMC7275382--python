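# Methods

## Data model

The package operates on a binary interaction matrix `Y` (`N_r` RBP rows ×
`N_c` circRNA columns) assembled from a two-column edge list. IDs are
whitespace-stripped but case-sensitive (circBase-style circRNA IDs are
lowercase; case-folding could silently merge distinct IDs). Row/column
order is the sorted unique ID lists, so the matrix is a pure function of
the edge set. An optional whitelist file reproduces the curation step of
keeping only pairs whose circRNA appears in a reference ID list; whitelist
entries absent from the data are ignored. The matrix is stored dense: at
the intended scale (~63,000 cells, ~13% density) sparsity buys nothing.
Cells split into the positive set `P` (`y=1`) and the unlabeled set `U`
(`y=0`); `U` is never treated as verified negatives.

## Scoring kernels

**MFNN (profile towers + cosine).** Two ReLU feed-forward towers map the
raw profile row `y_i*` (input width `N_c`) and column `y_*j` (input width
`N_r`) to latent factors of dimension `d`; the pair score is their cosine.
"`n`-layer" counts weight layers after the input profile; the default is a
single layer to `d = 64`, the configuration that performed best in the
depth/width sweep this design follows (deeper towers are configurable and
supported by the same training loop). The cosine is clamped into
`[eps, 1−eps]` with `eps = 1e-6` before the loss. The clamp is applied
symmetrically — the motivating rule collapses only negative cosines to a
tiny positive number, but `log(1−f)` is equally undefined at `f = 1`, so
totality of the cross-entropy requires both ends. Raw cosines are retained
on the score objects for reporting. The cosine denominator adds `1e-12` to
each norm because ReLU can zero an entire latent vector.

**GMF / MLP / NeuMF (embedding kernels).** The neural-collaborative-
filtering family with per-ID embedding tables (equivalent to one-hot
inputs): GMF projects the element-wise product of the two embeddings
through a linear output; MLP feeds the concatenated embeddings through
ReLU hidden layers; NeuMF concatenates the GMF product vector with the
MLP's last hidden layer into a joint linear output. All three end in a
sigmoid. NeuMF is trained jointly from scratch — its two halves are not
pre-trained, since no pre-training protocol was specified for this
setting. For these kernels `layer_sizes[0]` is the embedding dimension and
the remaining entries are MLP hidden widths.

## Training

All kernels minimize clamped binary cross-entropy by mini-batch Adam
(β₁ = 0.9, β₂ = 0.999, ε = 1e-8 — conventional defaults; only the learning
rate was specified by the source setting). `bce_loss` exposes the summed
loss; the optimizer steps on the batch mean so the learning rate is
independent of batch size. Defaults are batch 256 and lr 1e-4. The
original loop condition ("while not converged and epoch > e") is
operationalized as an epoch cap (default 100) plus early stopping with
patience 10 on a stratified 90/10 train/validation split; the best-
validation parameters are restored. All forward/backward passes are
explicit numpy; gradients of every kernel are validated against central
finite differences (1e-4 relative) in the test suite. Initialization draws
*every* parameter, biases included, i.i.d. `Normal(0, 0.01²)` from the
model seed, so two models with the same seed are bit-identical, and the
whole fit is deterministic given its seed.

At toy scale (≤ a few hundred training pairs) the study-scale defaults
give only a handful of optimizer steps per epoch, so the small-problem
runs in the tests and the acceptance script use batch 64, lr 1e-3 and a
higher epoch cap (200, patience 30). This is pure problem-size scaling of
the optimizer schedule; the objective and architecture are unchanged.

### Held-out masking

During cross-validation the held-out positives are zeroed in the matrix
the profile towers read (`mask_heldout`, default on); otherwise the label
being predicted is literally a component of the model input. Whether the
original protocol masked is unstated, so the literal behaviour remains
available via `--no-mask-heldout`.

## Positive-unlabeled bagging

Round `t` draws `U_t ⊂ U` uniformly without replacement (`|U_t| = K`,
default `K = |P|`), trains a fresh kernel on `P` (label 1) vs `U_t`
(label 0), and scores only `U \ U_t`; accumulators `MFNN(u)` and counters
`t(u)` yield `F_u = MFNN(u)/t(u)`. A cell is never scored by the round
that trained on it (asserted per round). The round count is the minimal
`T` with `T(1 − K/|U|) ≥ n` (default `n = 5`), computed in exact integer
arithmetic (`T(|U|−K) ≥ n|U|`) so divisibility edge cases cannot
misround; a user-forced `T` is honoured as-is by the bagging loop, and
deterministic top-up rounds re-run the procedure on any still-unscored
cells so `t(u) ≥ 1` always holds on return. Per-round seeds are spawned
from the master seed (numpy `SeedSequence`), making rounds independently
reproducible. The averaged scores are the clamped probabilities — the
scale the objective was trained on — not raw cosines. Pairs with
`F_u > 0.7` (configurable) form the ranked high-confidence report.

## Evaluation

Sn, Sp, Pr, Acc and MCC are computed from the confusion tally at strict
`score > threshold` (default 0.5; a score exactly at the threshold is a
negative call). Any metric with a zero denominator is reported as NaN and
rendered `NA` in reports — silent zeros would corrupt cross-fold averages.
AUC is the Mann–Whitney rank statistic with ties counted ½ (exactly the
concordant-pair fraction); AUCPR is non-interpolated step-wise
precision-recall integration (equivalent to average precision). Both
export curve points for external plotting.

Cross-validation follows the P-U setting: each repeat redraws `|P|`
negatives from `U`, forms the balanced set, and splits it into `k` folds
*stratified by label* — the source protocol does not state stratification,
but unstratified folds can lose a class entirely at small `n`, which would
make several metrics undefined. Negatives are redrawn per repeat (not per
fold), the reading taken of the ambiguous "in each time". Aggregates are
unweighted NaN-aware means over all repeat × fold values. Fold/repeat
seeds derive from the master seed.

## Synthetic worlds

The generator plants a rank-`d` ground truth: factors `~ Normal(0,1)`,
cell probability `logistic(signal_scale · ⟨u_i, v_j⟩ + noise + bias)`,
with the bias calibrated by bisection so the expected density matches the
target within 0.01. The observed matrix is a Bernoulli draw, and
`hide_fraction` of the true interactions is relabeled 0 and recorded as
`hidden_positives`, giving ground truth for recovery experiments. The link
is deliberately logistic-of-inner-product rather than cosine, so the
kernel is tested on ranking structure it did not literally generate (a
cosine link is available as an option).

Two presets define the standard study conditions:

- `separable_preset`: 60 × 40, `d = 4`, density 0.20, 10% hidden
  positives, `signal_scale = 8`, `noise_sd = 0.05`. The scale saturates
  most probabilities, making the world strongly separable (true-probability
  ranking AUC ≈ 0.99); density 0.20 keeps ~480 positives so the toy world
  still carries enough training signal. These values were fixed once as
  the package's definition of "strongly separable at toy scale".
- `crim_preset`: 673 × 94 at density 8473/63262 ≈ 0.134, `d = 8`, same
  signal/noise — the real matrix's shape and density with strongly
  separable planted structure.

What the synthetic worlds do **not** emulate: real interaction matrices
have heavy-tailed row/column degree distributions, block structure from
protein families and cell-lineage batch effects, and their hidden
positives are not missing uniformly at random. Passing recovery tests
therefore demonstrates that the implementation learns planted low-rank
structure under the stated noise — not that it attains any particular
accuracy on laboratory data.

## Problem sizes in tests and the acceptance script

Unit tests run on matrices up to ~60 × 40; the acceptance checks use the
two presets: full 10× CV-5 at 673 × 94 study shape (50 kernel fits, a few
minutes on one CPU), a four-kernel 2× CV-5 comparison and the full P-U
bagging loop on the separable preset, and a 20-run coverage study of the
bagging contract on a 30 × 20 world. These sizes were chosen so the entire
suite reruns comfortably on a laptop-class single core while still
exercising the study-scale code path once.

## Known limitations

- Cold start: an RBP or circRNA with an empty profile gets a zero latent
  vector and an uninformative (clamped) score; matrix-factorization methods
  cannot rank entities with no known interactions.
- Sparse profiles: scores for rows/columns with very few positives are
  noisy, mirroring the recommendation-system behaviour of the method.
- The clamp zeroes gradients outside `(eps, 1−eps)`: negative pairs whose
  cosine is already negative receive no further push, which is the intended
  behaviour of the scoring rule but means the raw cosine scale below 0 is
  unconstrained.
- High-confidence counts on synthetic worlds depend on the calibration of
  the bagged probabilities, which is not guaranteed beyond the trained
  objective's scale; the 0.7 threshold is a reporting convention, not a
  calibrated posterior.
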