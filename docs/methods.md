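# Methods

## Problem and model

Abundance estimation from survey video is cast as multi-object tracking:
detections from an external per-frame detector are linked into tracks, and
the estimate is the number of distinct track identities that ever reach
*confirmed* status. The tracker is a tracking-by-detection design with a
linear-Gaussian motion model and an appearance re-identification channel.

**Motion.** Each track's state is the 8-vector
(μ, ν, γ, h, μ̇, ν̇, γ̇, ḣ): box center, aspect ratio w/h, height, and their
per-frame velocities. Dynamics are constant-velocity with unit frame time;
observations are the first four components, taken directly from a detection
box. Process and measurement standard deviations scale with box height
(position-like terms weight 1/20, velocity-like 1/160), so uncertainty is
proportional to apparent object size; the unitless aspect ratio instead uses
small fixed stds (1e-2 process, 1e-1 measurement, 1e-5 velocity). Track
initiation doubles the positional stds and uses 10× the velocity stds, since
a single observation carries no velocity information.

**Association.** Confirmed tracks are matched by a cascade over
time-since-update: tracks updated most recently compete first, so a target
that has been occluded briefly cannot steal a detection from a target seen
last frame. Within each cascade level the match is a Hungarian assignment
(via `scipy.optimize.linear_sum_assignment`) on the gated cost
C = λ·d⁽¹⁾ + (1−λ)·d⁽²⁾, with

- d⁽¹⁾ the squared Mahalanobis distance in measurement space, gated
  inclusively at the χ² 0.95 quantile for 4 dof (9.4877);
- d⁽²⁾ the minimum cosine distance from the detection embedding to the
  track's bounded gallery (capacity 100, vectors re-normalized at
  insertion), gated inclusively at 0.3.

Inadmissible pairs carry a sentinel cost (1e5) and are stripped from the
solution, so a gated pair can never be matched. λ defaults to 0: under
significant camera motion the Mahalanobis distance is an unreliable ranking
signal (though still a sound gate), so the cost is appearance-driven. When a
detection has no embedding or a track's gallery is empty, that pair falls
back to the motion distance as its cost. Unconfirmed tracks and confirmed
tracks missed exactly one frame then enter an IoU-based Hungarian match
(cost 1 − IoU, inadmissible above 0.8).

**Lifecycle and counting.** New tracks are *tentative*; five consecutive
hits (`n_init = 5`) promote them to *confirmed*; a tentative track is
deleted on its first miss, a confirmed one after `max_age = 100` frames
without an update — the one persistence horizon the appearance model also
uses (its gallery spans the same 100-frame window). IDs are strictly
increasing and never reused. The video-level count is the number of IDs
ever confirmed; tentative flickers — in particular detector false positives
living fewer than `n_init` frames — contribute nothing. Long-gap fragments
that re-confirm under a new ID are accepted as distinct identities; no
re-linking is attempted.

## Attention operators

The three detector-side blocks are implemented as standalone, seeded,
deterministic NumPy operators; wiring them into a detector graph is out of
scope.

- **Global-context fusion.** Per sample, with X the C×HW matrix of channel
  vectors: F_local = X Xᵀ (the Gram matrix over channels), F_global the
  global average pool, output F_local · F_global reshaped to N×C×1×1. The
  printed form of the local product is dimensionally ambiguous; the Gram
  over channels is the only composition consistent with a C×1×1 fused
  output, and gives the scalar contract v → v³ (the map is cubically
  homogeneous). The block returns the fusion; composition with the trunk
  feature (add vs multiply) is left to the caller.
- **Omni-dimensional dynamic convolution.** n candidate kernels are
  collapsed into one effective kernel via four attention factors — spatial
  (k×k), input channel, output channel (sigmoid heads) and kernel index
  (softmax head) — generated from the globally pooled input through a
  linear squeeze (ratio 1/16, floor 1) + ReLU bottleneck. With all factors
  forced to 1 and one kernel, the operator reduces exactly to a static
  convolution, which is the unit contract tested against a loop-based
  reference convolution.
- **Coordinate attention.** Directional average pools along W and H give
  C×H and C×W descriptors; these are concatenated, reduced by a shared 1×1
  convolution (reduction ratio r = 32, clamped to the channel count in the
  functional wrapper), ReLU-activated, split, expanded back to C per
  direction and squashed by sigmoids; the input is multiplied by both maps.
  Outputs are therefore strictly inside (0, |x|) elementwise.

## ReID architecture

The appearance network is a residual stack for 3×128×64 crops: two 3×3
stride-1 convolutions at 32 channels, a 3×3 stride-2 max pool, residual
stages at 32/64/128/256 channels with stride-2 transitions, a 256→512
stride-1 expansion, adaptive global average pooling and batch
normalization to a 512-dim feature (L2-normalized on output). Stages that
change resolution or channel count use a 1×1 projection shortcut — the only
arrangement under which the printed per-layer shapes compose — identity
shortcuts elsewhere. Weights are seeded-random: the tracker consumes any
provider satisfying the "input → unit vector, deterministic under fixed
seed" contract, and training is explicitly out of scope. The 512-dim
provider and legacy 128-dim embeddings interoperate; the association stage
only requires unit norm.

## Evaluation suite

Precision and recall are percentages of TP/(TP+FP) and TP/(TP+FN); both
raise rather than report 0 on an empty denominator. AP uses all-point
interpolation (area under the precision envelope over recall); mAP is the
unweighted mean over classes; the default TP criterion for detections is
IoU ≥ 0.5. Tracking evaluation matches ground truth to hypotheses per frame
by minimum-cost bipartite matching on 1 − IoU (threshold 0.5), carries each
ground-truth object's last matched hypothesis ID across frames to count ID
switches, and reports the count-based MOTA
1 − (ΣFN + ΣFP + ΣIDS)/ΣGT_t — the only dimensionally consistent reading
when miss/false-detection *rates* are also defined; those rates are exposed
separately, with the false-detection rate falling back to FP/(FP+TP) when
no explicit negatives exist. Counting accuracy is 100·(1 − L1/true),
rounded half-up to one decimal to match conventional reporting.

## Synthetic scenes

The simulator emulates a constant-speed, low-altitude pass over a field of
stationary targets: identities are placed uniformly in a world strip sized
so the 640×640 viewport sweeps it exactly once at 6 px/frame over 200
frames; boxes have height ~N(40, 5²) px and aspect ~N(0.6, 0.08²) (ears are
taller than wide); each object gets a small random world drift
(σ = 0.05 px/frame) standing in for plant sway. Objects are placed so every
identity is fully visible for at least 10 frames — a target that never
plausibly enters view is not a countable object. Corruption defaults: 5%
independent miss probability per visible object per frame, occlusion
episodes starting at rate 0.01/identity/frame lasting 3 frames, box-center
jitter σ = 2 px (size jitter σ/2), and false positives as a per-frame
Poisson count with mean 5% of the visible objects, each living one frame
with a fresh random identity's embedding so it can never accumulate gallery
support. Embeddings come from a per-identity anchor on the unit sphere
(anchors near-orthogonal in 128 dims, so between-identity cosine distance
≈ 1) perturbed by noise of expected norm κ = 0.1, putting within-identity
cosine distance at O(κ²/2) ≈ 0.005 — far inside the 0.3 gate. Randomness is
split into independent sub-streams (placement, occlusion, jitter, miss,
false positives, confidence), so toggling one corruption leaves the others
bit-identical.

What the simulator does **not** emulate: pixel appearance (illumination,
blur — represented only abstractly through miss/jitter rates), variable
camera speed, perspective or scale change, correlated detector failures,
and appearance drift within an identity. Passing tests therefore establish
the correctness of the association/counting machinery under the modeled
noise, not detector robustness on real imagery.

## Numerical and design choices

- Kalman updates use a Cholesky solve of the innovation covariance;
  non-positive-definite S raises rather than silently regularizing.
  Covariances are re-symmetrized after each step.
- Confidence filtering is inclusive (≥ threshold); NMS drops at IoU
  strictly above its overlap threshold; NMS confidence ties break toward
  the lower detection index. Confidence filtering precedes NMS.
- Assignment ties resolve toward the lexicographically smallest
  (track, detection) pair via the solver's row-major scan; cascade depth
  equals `max_age`, so every live track gets exactly one chance per frame.
- Counting accuracy for the five-video protocol: one published row's
  accuracy is inconsistent with its own published counts; the formula
  consistent with the other four rows (and with the published mean L1 of
  4.2) is implemented, and that row's accuracy is simply not asserted.
- Problem sizes in the test suite and acceptance script (10 scenes of
  50–300 identities, 200 frames each) were chosen as the smallest regime in
  which all corruption modes are active simultaneously and count statistics
  are stable across seeds.

## Known limitations

- λ > 0 mixes a χ²-scale distance with a [0,2]-scale cosine distance; the
  default λ = 0 avoids the scale mismatch, and non-zero values should be
  small.
- The simulator's linear motion matches the tracker's model; it cannot
  reveal model-mismatch failures (e.g. abrupt camera acceleration, which is
  a known failure mode of this class of tracker).
- Identity fragments separated by gaps longer than `max_age` inflate the
  count by design; the counting protocol accepts this as the method's
  behavior.
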