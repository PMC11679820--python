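# Methods

## Problem and pipeline

`posefall` classifies short pose-keypoint clips into seven posture classes,
with fall detection as the safety-critical case. A clip is an ordered list
of frames, each carrying the 33 MediaPipe-Pose landmarks as image-normalized
`(x, y, z, visibility)` tuples; `y` grows downward, so a falling body
increases `y`. The pipeline is:

1. **Frame standardization.** The standard sequence length is the minimum
   clip length in the dataset. Longer clips are reduced by drawing a
   uniformly random subset of frames *without replacement* and re-emitting
   it in original order. Uniform subset sampling is the least-informative
   choice consistent with "random selection that preserves action order";
   it keeps expected temporal coverage even across the clip. Upsampling is
   refused — a clip shorter than the target is a data error, not something
   to fabricate frames for.
2. **Kalman smoothing.** Tracked points are filtered per coordinate axis
   with a constant-velocity linear-Gaussian model: state (position,
   velocity), `A = [[1,1],[0,1]]`, `H = [1,0]`. The textbook update has a
   control term `B uₖ`; tracked body points are passively observed, so it
   is fixed to zero. Defaults: process noise `Q = q·[[¼,½],[½,1]]` with
   `q = 1e-4`, observation noise `R = 2.5e-5` (the square of the synthetic
   generator's default coordinate noise sd 0.005), initial state seeded
   from the first observation with unit initial covariance. The filter is
   causal (no backward smoothing pass): each output is the estimate after
   assimilating that frame's observation, which is what a real-time
   monitor would have.
3. **Central point and speeds.** The torso central point is the midpoint of
   the two cross-body midpoints (left shoulder–right hip, right
   shoulder–left hip), i.e. exactly the mean of the four landmarks — an
   identity the tests assert at 1e-12. Speeds are Euclidean distances
   between consecutive *smoothed* positions (central point from smoothed
   shoulders/hips; knees and optionally the nose smoothed directly), with
   the first frame's speed defined as 0. Speeds use all three axes by
   default; a 2-D option exists because estimated depth is much noisier
   than the image-plane coordinates.
4. **Channel assembly.** The default feature matrix keeps the *raw* 33×3
   coordinate channels (mirroring keypoint tables in which unsmoothed
   coordinates coexist with derived speed columns) and appends three speed
   channels: central point, left knee, right knee. Flags add per-landmark
   visibility channels, a nose-speed channel, or smoothing of all
   positional channels. The nose-speed channel defaults to off so the
   default layout matches the three-speed table schema; the flag exists
   because the prose description of the tracked points also names the
   nose/head.
5. **Min-max normalization.** Per-channel min and max are fitted on the
   training split only and applied to validation/test — the defensible
   reading when a source describes normalizing "the data" without
   specifying leakage control. Constant channels map to 0; out-of-range
   values on held-out data are deliberately not clipped (they carry signal
   and the models tolerate them).

## Synthetic generator

The generator provides the *class-conditional* structure the classifier
must separate, not realistic human motion. Each class has a template:
torso-center height and body inclination transition between start and end
values along a sigmoid ramp; all 33 landmarks are then placed by a fixed
articulated offset table rotated by the inclination (stick figure). The
template's `peak_speed_scale` is made operational by deriving the sigmoid
sharpness from it, so the peak per-frame center displacement equals
`peak_speed_scale × 0.08` image units regardless of the drawn duration.

Defaults (chosen once as plausible for indoor monitoring footage at ~30
fps, where a body spans roughly a third of the frame):

| class     | duration (frames) | motion                                   | peak_speed_scale |
|-----------|-------------------|------------------------------------------|------------------|
| falling   | 18–28             | upright → supine, sharp                  | 1.0              |
| lie       | 45–65             | upright → supine, gentle                 | 0.15             |
| lie_down  | 40–60             | seated → supine, gentle                  | 0.15             |
| sit_down  | 35–55             | upright → seated                         | 0.12             |
| sleeping  | 50–70             | static supine                            | 0.0              |
| standing  | 40–60             | static upright, small lateral sway       | 0.0              |
| stand_up  | 45–65             | supine → upright                         | 0.18             |

100 clips per class by default (balanced, seven classes); coordinate noise
sd 0.005 — chosen so a static posture's raw speed is nonzero but an order
of magnitude below a fall's peak, giving the Kalman filter measurable work;
occlusion rate 0.02 (an occluded landmark gets visibility in [0.05, 0.45]
and 5× noise). Falls are deliberately the shortest clips so the
minimum-length standardization path is always exercised. Determinism: one
root seed sequence spawns a child stream per clip in fixed order, so a
config reproduces a byte-identical serialized dataset.

What the generator does **not** emulate: anthropometric variation beyond a
global scale, limb articulation during transitions (arms/legs ride rigidly
on the torso frame), camera perspective, multi-person scenes, and
pose-estimator failure modes other than occlusion noise. Passing tests
therefore show that the pipeline recovers class structure from
speed-plus-posture signatures under observation noise — not that it
reaches any particular accuracy on real recordings.

## Models and training

The classifiers run on a small reverse-mode autodiff engine written on
numpy (float64, single-threaded, fully seeded); no deep-learning framework
is required. The transformer uses a linear projection of the input
channels to `model_dim = 64` plus fixed sinusoidal positional encoding,
`num_blocks = 2` pre-norm encoder blocks (`num_heads = 4`, `key_dim = 32`,
1-D convolutional feed-forward with `4×model_dim` filters, kernel 1),
global average pooling over time, one 128-unit ReLU MLP layer with dropout
and L2 (`1e-4`) on dense kernels, and a softmax output. Depths and widths
are reconstructions — reasonable small-scale defaults, since only the layer
types of the reference stack are pinned down. Recurrent baselines are
stacked LSTM/GRU layers classifying from the final hidden state.

Training: categorical cross-entropy, optimizer per config (Adam, SGD, or
AdamW with decoupled weight decay `1e-4`), cosine-decayed learning rate
(base at epoch 0, decaying to 0 at `max_epochs`), batch shuffling and
dropout masks drawn from the run seed, early stopping on validation loss
with patience 10 (best weights restored), 100 epochs maximum. The
transformer presets use base learning rate `1e-3`: the `0.01` used for the
recurrent presets destabilizes attention training at this scale. Splits
are stratified 70/15/15 with largest-remainder rounding, so balanced data
splits into balanced partitions.

Nine named presets (`transformer1–3`, `lstm1–3`, `gru1–3`) reproduce a
benchmark grid of optimizer / dropout / batch-size combinations
(e.g. `transformer3` = AdamW, dropout 0.4, batch 64; `gru2` = SGD, which
reliably trails the adaptive optimizers).

## Evaluation

Confusion matrix with rows = true class, columns = predicted class.
Per-class precision/recall/F1 from the matrix tallies with the
zero-division convention P = R = F1 = 0 on empty denominators (reported via
a `zero_division_classes` flag). Macro (unweighted) averages are the
headline aggregate because the data are class-balanced; support-weighted F1
is reported alongside since the two coincide only under balance. ROC/AUC
binarizes to falling-vs-rest and sweeps thresholds over distinct scores
(ties grouped); AUC is trapezoidal and equals the normalized Mann–Whitney U
statistic, which the tests verify by exhaustive pair counting. The standard
metric computations are delegated to scikit-learn behind this module's
surface and cross-checked against independent brute-force oracles.

## Problem sizes used in the checked runs

The end-to-end acceptance check trains `transformer3` at 20 clips per class
(140 clips, 18-frame sequences, 102 channels) for seeds 0–2 and requires
macro-F1 ≥ 0.90 on each held-out test split — a scale chosen so the full
check runs in well under a minute per seed on one CPU while leaving the
class structure intact. The class-separability property (a falling clip's
peak central-point speed exceeds every non-falling clip's) is verified
directly over 100 generator seeds.

## Known limitations

- The Kalman filter is causal-only; a Rauch–Tung–Striebel smoother would
  denoise better offline but would not reflect streaming use.
- Sequence standardization discards frames from long clips rather than
  summarizing them; very long recordings lose resolution.
- The autodiff engine favors clarity over speed; it is adequate for the
  dataset sizes here (hundreds of clips, tens of frames) but not for
  large-scale training.
- Synthetic realism limits are listed above; absolute scores on synthetic
  data say nothing quantitative about real-camera performance.
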