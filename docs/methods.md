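# Methods

`metagait` implements a three-stage meta-transfer-learning pipeline for
estimating lower-limb joint angles (left/right hip, knee, ankle; degrees) from
three synchronized wearable/ambient modalities — an RGB image stream, 6-channel
surface EMG, and a pelvis-mounted visual-inertial odometry (VIO) pose stream —
together with a synthetic multimodal gait simulator that supplies ground truth
for every stage. This note documents the models, the numerical choices, and
what the synthetic experiments do and do not show.

## The synthetic gait simulator

Each subject is a draw of a `SubjectProfile`: per-joint baseline offsets,
truncated-Fourier harmonic amplitudes and phases (3 harmonics per joint —
enough for the biphasic knee/ankle pattern), a cadence multiplier, per-muscle
EMG gains, and noise levels. Joint angles follow

    theta_j(t) = offset_j + sum_{h=1..3} a_jh cos(2*pi*h*f0*t + phi_jh),

with stride frequency `f0 = (0.55 + 0.09 * speed_kmh) * cadence_scale` Hz —
about 0.9–1.1 Hz over the protocol speeds of 3.5 / 4.5 / 6 km/h. The right leg
lags the left by half a cycle (harmonic h is phase-shifted by h*pi). The
stance fraction of each cycle is `0.72 − 0.026 * speed`, clipped to
[0.55, 0.65], so it sits in the physiological band and decreases with speed;
the stance/swing mask is defined from the left (reference) foot with heel
strike at phase 0.

Streams per trial, hard-synchronized on one clock:

* **angles** — 100 Hz, exact (never noised); this is the regression target.
* **sEMG** — 1111.111 Hz, 6 channels (L/R rectus femoris, biceps femoris,
  gastrocnemius). Each channel is a phase-locked Gaussian activation envelope
  (RF near terminal swing/loading at cycle fraction 0.98, BF late swing at
  0.85, GA late stance at 0.45; width 0.06 cycles; baseline 0.1) multiplied by
  zero-mean unit-RMS Gaussian noise band-limited to 20–450 Hz — the standard
  surrogate for interference-pattern EMG — plus additive sensor noise.
* **VIO** — 200 Hz, 7 channels: pelvis position advancing along a 2 m-radius
  circular path at the belt speed (direction cw/ccw per trial), with
  step-frequency (2·f0) vertical oscillation, and a heading-aligned unit
  quaternion (yaw follows the path tangent). Rotation noise perturbs the yaw
  before the quaternion is formed, so unit norm is exact by construction.
* **image** — 30 Hz, 64×64 RGB: a sagittal stick figure (trunk, thigh, shank,
  foot segments for both legs, drawn into separate color channels) driven by
  the same angle trajectories, fixed camera, plus pixel noise.

A trial is 60 s; the protocol is 4 trials at each of the three speeds per
subject (12 trials), alternating direction. Ten-second clips are the few-shot
unit: a 60-s trial yields 6 non-overlapping clips, a subject 72, the default
10-subject cohort 720. Trailing remainders are dropped. Sample counts are
`round(rate × duration)` exactly (66667 EMG samples per trial at 1111.111 Hz).

**Inter-subject variability** (offset half-width 12°, amplitude scale 0.7–1.3,
cadence 0.85–1.15, phase jitter 0.4 rad) is set wide enough that subject
identity dominates trial-to-trial variation. This is a design requirement, not
a tuning knob: few-shot *intra-subject* adaptation is only a measurable effect
when held-out subjects differ systematically from the training pool, and
anatomical zero-point offsets of this order are realistic across individuals.

**What the simulator does not emulate:** soft-tissue artifact, electrode lift
or crosstalk, camera distortion and occlusion, VIO drift, fatigue, or
non-periodic movement. Passing results show the pipeline's mechanisms work
(alignment, fusion, modulation, episodic adaptation); they are not evidence
about accuracy on real gait data.

## The pose-estimation network

* **Image encoder** — CBAM-ResNet12: four residual stages, each three 3×3
  conv/batch-norm layers with an identity/projection skip, a convolutional
  block attention module (channel attention with a shared two-layer bottleneck
  over average- and max-pooled descriptors, then spatial attention from the
  channel-wise mean/max maps), and 2×2 max pooling. Frames are uniformly
  subsampled per clip and frame features mean-pooled (the clip-level feature
  r_i). Library defaults keep the cited CBAM settings (reduction 8, spatial
  kernel 7) and widths (16, 32, 64, 128).
* **Sequence encoders** — pre-norm transformers over patched tokens with fixed
  sinusoidal positions; the clip feature is the token mean. sEMG is rectified,
  decimated ~10× (to ≈111 Hz) and patched into 50-sample tokens; VIO into
  20-sample tokens. The pre-norm arrangement matters: the residual stream
  preserves input scale, so modality amplitude mismatches survive encoding and
  the alignment stage has real work to do.
* **Knowledge sharing** — per-modality affine transforms f_m into a shared
  D-dimensional space, trained with the pairwise alignment loss
  `L_KS = Σ_{k≠t} m_k·m_t·‖r̃_k − r̃_t‖₂` (per-clip distances averaged over the
  batch). The per-modality normalizers m_m are parameterized as exp of a free
  scalar so they stay positive; the pair weight is the product of the two
  scalars. The transform default is purely affine — identity-initializable and
  sufficient at this scale.
* **Fusion** — the aligned features are stacked into a length-3 sequence with
  D channels; three convolutional branches of 1, 2 and 3 blocks (conv/BN/leaky
  ReLU) process it, and their globally average-pooled outputs concatenate into
  the fused feature k. Without knowledge sharing (the nKS ablation) the raw
  encoder features are concatenated directly into k.
* **Decoder** — linear/BN/ReLU/dropout, then a linear head emitting the six
  angles at `n_out` uniformly spaced time points per clip (default 25). The
  head works in standardized units; per-joint offset/scale buffers fixed from
  the pretraining targets map back to degrees. This trajectory head is the
  package's resolution of a genuinely open design point: a single clip-level
  fused feature must still support per-phase (stance/swing) losses, which
  requires within-clip time resolution.

The pose loss is `L_PE = mean over samples of (1/6)Σ_j (y_j − ŷ_j)²`, so the
pooled RMSE in degrees is exactly `sqrt(L_PE)`.

## Training procedure

**Pretraining** is two-stage. Stage A trains everything on
`L_KS + λ·L_PE` (λ = 0.1): the pose term prevents the alignment objective's
trivial optimum (all transforms collapsing to a constant) and keeps encoder
features pose-relevant. Stage B freezes encoders and transforms and trains
fusion + decoder on `L_PE` alone — the knowledge-transfer module is trained
separately from the final regression stack. Adam (lr 1e-3), gradient norm
clipped at 5, seeded batch shuffling; the best-validation checkpoint is kept.
The epoch-0 validation RMSE is logged before anything (including the output
standardization) is fit from training data, so learnability is measured
against a genuinely untrained model.

**Meta-transfer** adapts a frozen pretrained model through scale/shift
modulation: each conv/linear weight W in the encoders, transforms and fusion
network gets a per-output-channel multiplier γw and each bias an additive γb,
so the modulated layer computes `(W ⊙ γw)x + (b + γb)`; γw=1, γb=0 reproduces
the base model bit-for-bit. The decoder head is fully fine-tuned in the inner
loop (configurable) because the subject-specific output statistics live there.
Meta-training is episodic with first-order outer gradients: per episode, clone
the shared initialization, run the inner loop on the support set, evaluate the
episodic loss `L_T = (1/(N·K)) Σ L_MSE` on the query set with the adapted
parameters, and apply the query gradient (taken at the adapted parameters) to
the initialization with Adam (lr 1e-3). N = 1 throughout the shipped
experiments; the episode machinery supports N > 1.

Four inner-loop choices deserve explanation:

* **Adam inner updates (lr 5e-2 at K=5, 10 steps).** Plain SGD on a
  degrees²-scale MSE either diverges or — under global-norm clipping — starves
  the decoder-bias direction that carries the subject offset, because that
  direction is a tiny fraction of the global gradient norm. Adam's
  per-parameter step bound makes the inner loop insensitive to the loss scale.
* **Mixed-shot episodes.** K is sampled per episode from the shot counts used
  at evaluation (e.g. {1, 5}), so the initialization is trained for the same
  adaptation regimes it will face.
* **Evidence-proportional adaptation budget.** The inner learning rate scales
  as `(K/5)^1.5`. With Adam, total parameter movement is roughly
  steps × lr regardless of loss scaling, so conservatism for small support
  sets must come through the step size. A single 10-s clip carries one walking
  speed; an unconstrained 1-shot fine-tune absorbs that speed-specific signal
  and can end up worse than no adaptation on mixed-speed queries. Shrinking
  the budget with K lets 1-shot harvest the robust subject-level signal only.
* **Proximal shrinkage.** The inner loss adds `(2/K)·Σ‖θ − θ₀‖²` toward the
  initialization — the standard regularized fine-tuning safeguard, mild at
  K=5 and stronger for smaller support sets.

Adaptation runs the network in evaluation mode (batch-norm uses pretrained
running statistics): with K as small as 1, batch statistics are degenerate,
while gradients through frozen statistics remain well-defined.

**Tasks.** A task is a subject, a walking speed (slow/moderate/fast), or a
gait phase (stance/swing). Phase tasks restrict the per-sample loss with the
clip's stance mask; speed tasks restrict the clip pool.

## Evaluation protocol

Leave-subjects-out: held-out subjects never appear in pretraining or
meta-training (validated at run time). Per held-out task and repeat, one
episode with K = max(shots) support clips and Q query clips is drawn; the
s-shot model adapts on the first s support clips and shot 0 is the unadapted
pretrained model, all evaluated on the same queries. The headline metric is
pooled RMSE over all joints and decoded samples; per-joint, per-phase and
per-speed RMSEs are reported alongside, and pooled RMSE² always equals the
count-weighted mean of the per-phase RMSE²s. Relative error reduction is
(before − after)/before. A `pretrain_fraction` flag (0.5/0.75/1.0) subsamples
only the pretraining clips, emulating small/middle/large-scale pretrained
models.

## Desk-scale problem sizes

The numerical core is a reverse-mode autodiff engine over numpy written for
this package, so the shipped experiment configuration is sized for a single
CPU: encoder frames F=2 per clip, 3× spatial decimation (22×22 inputs), widths
(8, 16, 32, 64) with CBAM reduction 4 and spatial kernel 3, transformers with
d_model 32 / 1 layer / 2 heads, shared dimension 32, branch widths
(16, 16, 16); cohorts of 8 subjects × 1 trial per speed for adaptation
experiments (6 training, 2 held-out; 3 seeds), 10 pretraining epochs, 10
meta-episodes. The generator itself always runs at the full acquisition rates
and the full 12-trial protocol is used wherever trial counts matter
(bookkeeping, learnability). Every stage is deterministic given its seed on
one device; cross-device bit-identity is not promised.

## Known limitations

* Absolute RMSEs on synthetic cohorts (≈10–14° at desk scale) are not
  comparable to values obtainable with full-scale architectures on real data;
  only relative effects (adaptation gain, shot ordering, KS vs nKS, the
  pretraining-scale "amplifier" interaction) are meaningful here.
* The alignment loss argument is read as per-clip features averaged over the
  batch; batch-aggregate readings are possible but untested.
* First-order outer gradients only; second-order meta-gradients are out of
  scope.
* The image branch sees 2 frames per clip at desk scale — sufficient for the
  mechanism tests, but it underuses the image stream by construction.
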