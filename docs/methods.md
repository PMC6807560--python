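# Methods

## Scope and model

relvox implements a transparent volumetric classification pipeline: a 3D
convolutional network produces a scalar diagnosis score for a single-channel
intensity volume, and epsilon-rule layer-wise relevance propagation (LRP)
decomposes that score into a signed per-voxel heatmap.  Downstream metrics
quantify what the heatmaps attend to (lesion-relevance fractions, atlas
region profiles, lesion-burden correlations), and two counterfactual
experiment designs probe what the classifier uses: retraining on
lesion-filled volumes, and transfer from a pre-training task whose
discriminative feature is global morphology rather than focal lesions.

### Network

The default architecture is four `conv3d(64 filters, 3x3x3, stride 1, zero
"same" padding)` blocks, each followed by an ELU; four `2x2x2` max-pooling
layers (stride 2); dropout after each pool; then flatten, a dense layer with
a single output, and a sigmoid.  Spatial extent is controlled entirely by
pooling.  The published description of the pooling placement admits two
readings ("four max-pooling layers applied after the first, second and
fourth" activation); both are implemented:

* `1-2-4-final` (default): pools after conv1, conv2 and conv4, plus a final
  pool before flattening;
* `every`: one pool after each conv.

Neither is asserted to be "the" original architecture.  Conv stride, padding
and pool geometry are not specified in the source description; stride-1
same-padded convs and 2x2x2/stride-2 pools are the conventional completion.
Class convention: label 1 (patient) is the positive class; sigmoid score
above 0.5 predicts it.

The engine is implemented directly on numpy (im2col convolutions with
analytic backward passes, Adam, inverted dropout).  This is a deliberate
design: relevance propagation needs per-layer weights, forward activations
and max-pool argmax state, and the explicit engine exposes exactly that
state rather than reconstructing it from a framework graph.  Gradient
correctness is pinned by central finite-difference tests, and training is
bit-reproducible from a seed in single-threaded mode.

### Training

Binary cross-entropy plus an L2 penalty `lambda * sum(W^2)` (lambda = 0.01)
on the third and fourth conv layers, minimized with Adam (default beta
parameters).  Two regimes are used: pre-training (lr 1e-3, patience 10) and
fine-tuning (lr 5e-4 with inverse-time decay `lr/(1+0.002*step)`, patience
15, augmentation on).  "0.0005 with a 0.002 decay" is interpreted as
inverse-time decay per optimizer step; the schedule is a pure function and
overridable.  Early stopping watches validation cross-entropy and restores
the best-validation checkpoint.  Augmentation mirrors the sagittal axis with
probability 0.5 and translates by integer offsets drawn uniformly from
{-2..2}^2 in the axial plane, zero padded; co-augmented masks receive the
identical transform.  Fine-tuning re-initializes nothing: all layers remain
trainable.

### Relevance propagation

For a linear layer with inputs `x`, weights `w` and pre-activations
`z_j = sum_k x_k w_jk`, the epsilon rule distributes upstream relevance as

    R_i = sum_j  x_i w_ji / (z_j + eps * sign(z_j)) * R_j ,

with `eps = 0.001` by default and `sign(0) := +1`.  Convolutions are treated
as the equivalent sparse linear map over receptive fields (implemented on
the same im2col patches as the forward pass).  Max-pooling routes relevance
winner-take-all to the argmax input (first maximal index in scan order on
ties); ELU, eval-mode dropout and flatten pass relevance through unchanged.
Relevance is always computed in eval mode.

Decomposition starts from the pre-sigmoid logit by default: the sigmoid is
monotone, and only a signed logit can express "total relevance is negative
for controls".  Starting from the sigmoid output is available
(`start_from="sigmoid"`).  Bias handling: `discard` (default) ignores biases
entirely, exactly as the rule is written above — at eps=0 this conserves the
relevance total at every layer, so for a bias-free network the heatmap total
equals the logit (asserted to 1e-6 relative in tests).  `absorb` adds the
bias into `z_j`, letting the bias soak up the share `b_j/z_j`, which is then
dropped.  `gradient_times_input` computes `(d logit / d x) * x`; on
activation-free bias-free stacks it coincides with LRP at eps=0, which is a
test oracle, not a redundancy.

### Heatmap metrics

The lesion-relevance fraction is `sum(lm * hm+) / sum(hm+)` with `lm` the
binary lesion mask and `hm+` the positive part of the heatmap: the share of
the network's positive evidence that falls on known lesions.  It is 0 for an
empty mask and undefined (error) when the map carries no positive relevance.
"Lesion sum" is the count of lesion-mask voxels; when voxel spacing is
known, a volume in ml can be used instead.  Region profiles average
relevance over all voxels of each (optionally left/right-merged) atlas
region per subject, then across subjects per group; the top-k ranking (k=30
by default) orders regions by the summed absolute group means, ties broken
lexicographically.  The lesion-sum/relevance-sum association uses Pearson r
with a two-sided permutation test on |r|: one margin is permuted, and the
p-value uses the add-one estimator `(1 + #{|r*| >= |r|}) / (1 + n_perm)`,
so it is never zero; when `n! <= n_perm` all permutations are enumerated and
the p-value is exact.  Which margin is permuted is immaterial for Pearson r.

### Lesion filling

Each lesion voxel is replaced by the mean intensity of reference voxels
(white-matter mask minus lesion mask) within the smallest sphere grown from
radius 3 voxels (in 1-voxel increments) that contains at least 10
references.  Filled voxels never serve as references, so the result is
independent of fill order; voxels outside the lesion mask are bit-identical
to the input.  Optional noise matching adds Gaussian noise with the local
reference standard deviation to each filled value; it defaults off, which
leaves filled areas smoother than their surroundings — a residual cue a
classifier can partially exploit, consistent with lesion-filled retraining
degrading rather than abolishing performance.

## Synthetic phantoms

The phantom generator emulates the statistical structure of a FLAIR lesion
study on a small grid (default 32^3): an ellipsoidal brain with an outer
"gray" band (mean 0.45) and "white" core (0.70), two low-intensity
ventricle lobes (0.15), and additive Gaussian voxel noise (sd 0.05).
Patients (label 1) receive Poisson(6) hyperintense ellipsoidal lesions with
additive gain 0.35 and a Gaussian-tapered skirt (scale 0.6 voxels) outside
the binary mask; controls receive Poisson(0.5) — controls with small
nonzero lesion loads keep the task non-degenerate, as in real cohorts.
Lesion centers fall in a periventricular shell (1-4 voxels from the
ventricle surface) with probability 0.7, else anywhere in white matter.
Structure radii are jittered per subject (5% relative).  The gain/noise
choice gives lesions a contrast-to-noise ratio of 7, reflecting how
conspicuous FLAIR lesions are clinically; per-subject min-max scaling then
leaves local lesion contrast as the dominant reliable signal.  A tissue
atlas (gray/white/ventricle, split left/right to exercise region merging)
and the exact lesion mask accompany every volume.

The pre-training task replaces lesions with global morphology: class 1
ventricles are dilated by a factor of 1.5, no subject has lesions.  This
emulates pre-training on a different disease whose signature (atrophy /
ventricular enlargement) does not overlap the target task's focal lesions.

What the phantoms do not model: MRI physics (bias fields, partial volume,
multi-sequence contrast), anatomy beyond three tissue classes, spatially
correlated noise, registration error.  Passing the phantom experiments
therefore shows the pipeline's statistical machinery works end-to-end on
data with the assumed structure, not that the specific accuracy numbers
transfer to clinical images.

## Desk-scale experiment design

All experiments run on one CPU in minutes; sizes were chosen as the
package's reference conditions:

* **End-to-end** (`phantom_endtoend`): 32^3 grid, 100 subjects per class,
  8-filter network, 40 epochs (patience 10), augmentation on.  Following
  the repeated-trials protocol, three trials run on the same split with
  derived seeds; holdout metrics are reported both as across-trial means
  and for the best-validation-selected trial, and that selected network is
  used for heatmap analysis (the same selection convention real studies use
  when one model must be taken downstream).  Because
  the reduced-width network's scores are well-ranked but not calibrated at
  0.5, each trial's decision threshold is selected on its validation scores
  (maximum balanced accuracy, ties toward 0.5) and applied unchanged to the
  holdout; `evaluate()` itself defaults to the fixed 0.5 threshold.  Reports
  the mean lesion-relevance fraction over patients against the cohort
  lesion-voxel fraction, and lesion-sum/relevance-sum correlations for
  training and holdout subjects separately.
* **Lesion filling** (`fill_experiment`): paired-seed comparison at 16^3
  (50 subjects per class, split protocol, fixed 12-epoch budget); each seed
  trains one network on the originals and one on the filled volumes,
  identical otherwise.
* **Transfer** (`transfer_experiment`): the network is pre-trained to
  convergence on the atrophy task, then for each paired seed the lesion
  task is trained under the fine-tuning regime from either the pre-trained
  weights or random initialization, on a deliberately scarce training set
  (10 training + 3 validation subjects per class); balanced accuracies are
  compared on the large held-out remainder so paired differences are
  measured tie-free.  Empirically, on this phantom pair the transfer
  effect is high-variance across cohorts and seeds and often negative
  (win rates of 3/10 to 3/5 observed, with paired mean differences of
  either sign): the pre-training feature (enlarged dark ventricles) is
  disjoint from the target feature (bright focal lesions), so the
  specialized representation and the confidently wrong output head must
  first be unlearned before the lesion signal can be fit — the classic
  negative-transfer regime for dissimilar tasks.  Reliable positive
  transfer of the kind reported for real MRI relies on generic low-level
  features learned from large heterogeneous pre-training data, which a
  three-tissue phantom with a single disjoint pre-training feature does
  not supply.  The experiment ships as a first-class design precisely
  because the direction of the effect is an empirical question.

Experiment trainings run in float32 (the engine supports float64 and
float32); relevance-propagation correctness is validated in float64.

Width scaling: the desk-scale networks use 8 filters instead of 64.  At
that width the published dropout rate (p=0.3 after every pool) starves the
network — a 0.3 drop rate on an 8-channel representation removes a large
fraction of its capacity at four separate depths, and training never leaves
the chance plateau — so the scaled experiments run dropout-free while
keeping the L2 regularizer.  The full-width default of `build_network`
retains p=0.3.

## Numerical choices and degenerate inputs

* float64 throughout the engine and LRP; conservation asserted at 1e-6
  relative, oracle equality at ~1e-10.
* `sign(0) := +1` in the epsilon stabilizer; a zero denominator at eps=0
  raises rather than returning inf.
* Max-pool ties: first maximal index in scan order, identically in the
  gradient and the relevance routing.
* Min-max scaling of a constant volume raises (undefined); resampling uses
  trilinear interpolation for intensities and nearest-neighbour for masks
  and atlases, which therefore stay integer.
* Stratified splitting requires at least 3 subjects per class; subjects
  with multiple scans are assigned at the subject level so no identity
  spans sets.
* Per-trial seeds derive from a master seed as `master*1000 + trial`
  (mod 2^31), logged per trial for auditability.

## Known limitations

* The numpy engine is single-threaded BLAS-bound; the full 96x114x96,
  64-filter configuration is expressible but not practical to train here.
* Only the epsilon rule and gradient*input are implemented (no alpha-beta or
  composite LRP variants, DeepLIFT, or integrated gradients).
* The lesion filler is a deterministic growing-sphere local mean, not a
  reimplementation of any published in-painting method.
* Phantom realism limits are listed above; in particular, absolute
  accuracies on phantoms are not comparable to clinical results.
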