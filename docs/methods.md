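# Methods

## Problem and model

`gaitgcn` scores parkinsonian gait from whole-body 3-D motion-capture
marker trajectories recorded during timed-up-and-go (TUG) style trials.
Three session-level clinical targets are predicted simultaneously from
every 4 s analysis window:

* **FOG score** — the 0–4 freezing-of-gait item (MDS-UPDRS-III 3.11),
  a five-way classification;
* **medication state** — practically defined OFF (>12 h withdrawal)
  versus ON (supra-threshold levodopa), a binary classification;
* **motor severity** — the MDS-UPDRS-III motor total minus the FOG
  item (0–120), a regression.

The model is a multi-task spatial-temporal graph network with three
stages.

**Adaptive trimming (AT).** A four-layer temporal CNN (kernel 3×1, 64
maps, temporal halving max-pool per layer) reads the window with the
N markers × 3 channels flattened into N·3 input channels. Two
fully-connected heads (128 units, ReLU) predict a center
`c = sigmoid(F_center)` and width `w = exp(F_width)` of the core motion
segment, mapped to continuous endpoints `s = T·sigmoid(c − w/2)`,
`e = T·sigmoid(c + w/2)`, which satisfy `0 < s < e < T` for every
parameter value. The segment `[s, e]` is resampled to a fixed length
(default 240 samples) by linear interpolation, a 1-D analogue of the
spatial-transformer sampler, so gradients flow through `s` and `e`
into the trimming network. Because the exponential width head is
unbounded above, its logit is smoothly saturated into (−4, 2.5)
(tanh-shaped, identity near 0, never zero-gradient); `w` up to ~12
already spans essentially the full window through the sigmoids. The
width bias initializes to `w = 1`.

**Adaptive graph convolution (AGCN).** Four layers of

    f_out = Σ_k  W_k f_in (A_k + B_k + C_k),     k = 1..Kv (Kv = 3)

over the skeleton graph, with spatial-configuration partitioning:
subset 0 holds self-loops (plus equal-distance neighbours), subset 1
centripetal neighbours (nearer the hip-center root), subset 2
centrifugal neighbours. `A_k = Λ^{−1/2} Ā_k Λ^{−1/2}` with
`Λ_ii = Σ_j Ā_ij + α`, `α = 0.001` guarding empty rows. `B_k` is a
freely learned N×N attention map (zero-initialized, not constrained to
left/right symmetry). `C_k` is an embedded-Gaussian affinity:
per-node features are time-averaged, projected by learned 1×1
embeddings θ_k, φ_k (dimension 16), and compared by softmax-normalized
inner products, so each row of `C_k` sums to 1. The spatial step is
followed by a per-node temporal convolution (Kt = 5, same padding),
ReLU and temporal halving max-pool. After four layers, temporal
average pooling and a node mean produce one 64-vector per window.
Time-averaging inside the affinity is our choice; the equation itself
is silent on the temporal treatment.

Configuration toggles realize the baseline family: `graph: none`
removes node mixing entirely (TCN), `graph: fixed` keeps only `A_k`
(GCN), `graph: adaptive` is the full AGCN, and `at: true/false` adds or
removes the trimmer.

**Multi-task heads.** Two-layer MLPs (256, 128 units, ReLU) feed a
2-way and a 5-way softmax classifier (cross-entropy losses) and a
Gaussian-mixture regression head: `α = softmax(f_α)`, `μ = f_μ`,
`σ = exp(f_σ)` (m = 3 components by default), trained by the mixture
negative log-likelihood with log-sum-exp stabilization. Regression
targets are z-scored with training-split statistics only. The point
prediction for RMSE is the mixture mean `Σ α_i μ_i` mapped back to the
0–120 scale (dominant-component mean available). The joint loss is an
equally weighted sum; zeroing weights gives single-task training. A
plain MSE head serves as the non-mixture ablation.

## Numerical choices

The networks run on an in-package reverse-mode autodiff engine over
float32 numpy (`gaitgcn/nn.py`): batched-GEMM graph mixing and 1×1
convolutions, K-shifted-matmul temporal convolutions, compare-and-mask
halving max-pool, and the differentiable crop sampler. Choices that
matter:

* **Head output layers initialize at 1/100 scale** so softmax heads
  open uniform and the mixture opens at α uniform, μ = 0, σ = 1
  whatever the backbone feature magnitude. Without this the σ head can
  start saturated and the mixture fits only the target marginal.
* **1×1-conv initialization absorbs the mixing gain.** The Kv summed
  kernels and the ~2× magnitude of (A + B + C) (C is row-stochastic, A
  near-stochastic) would otherwise compound ~6× per layer; the He fan-in
  is scaled accordingly so activations stay O(1) without normalization
  layers.
* **Bounded heads saturate smoothly.** The width logit and log-σ use a
  tanh-shaped bound (identity near zero) rather than a hard clip; a
  hard clip freezes any parameter that starts outside the window.
* **Gradient clipping** at global norm 10 guards the first optimization
  steps; Adam runs at the fixed learning rate 1e-3, batch 16.
* **Restart on a failed initialization.** On some cohort/seed draws an
  early loss spike kills enough ReLU paths that training settles onto
  the chance plateau (uniform predictions) and never leaves it. A run
  whose training loss is still above 88% of the uniform-prediction
  floor after six epochs is abandoned and re-initialized from a fresh
  seed (up to two restarts) — the usual restart policy of mixture-model
  fitting, driven purely by the training loss.
* **Degenerate channels** (SD < 1e-8 after hip-centering, e.g. the root
  itself) are zeroed rather than divided by ~0.
* Crop indices stay continuous (no rounding); interpolation clamps the
  grid to [0, T−1] and the analytic endpoint gradients vanish only in
  the clamped region.
* Ties in attention rankings break by marker index (stable sort).

## Evaluation protocol

Cross-validation uses repeated grouped random resampling: each fold
draws whole trials into train/validation/test at 50/20/30% of windows
(a disjoint-test 10-fold partition cannot produce a 30% test share;
resampling is the reading consistent with both statements of the
protocol). Grouping at the trial level keeps overlapping windows —
windows are cut every 1 s from 4 s spans — on one side of every split.
Training stops when validation loss has not improved for `patience`
epochs (default 10, max 100; the protocol fixes only the criterion, not
the patience) and the best-validation weights are kept.

Metrics: per-class F1 with macro mean over the five FOG classes
(classes absent from both truth and prediction count as F1 = 0,
a conservative choice), binary F1 for medication state, RMSE on the
0–120 scale. F1-type metrics carry 95% Wilson score intervals with
n = test-window count — F1 is not a binomial proportion, so these
intervals are descriptive, matching the reporting convention of the
evaluation protocol rather than a coverage guarantee; RMSE carries a
normal-approximation interval on the squared errors. We report
per-fold metrics; pooled views are available from the per-window
predictions.

The demographic bias analysis regresses per-subject F1 (mean F1 over
the subject's windows, restricted to classes the subject presents) on
study group, dichotomized age (≥ 69 years) and sex, with Wald tests per
coefficient. A constant outcome would make the Wald statistic 0/0
float noise, so that degenerate case reports p = 1.

Attention is summarized by averaging `(A_k + B_k + C_k(x_i))` over
windows and kernels. The default readout averages the per-layer
aggregates over all layers: in practice individual layers emphasize
different mixes of raw-kinematic and task-shaped affinity and no single
layer is reliably representative, while the layer mean is stable; any
single layer is selectable by flag. Diagonal entries rank markers
("joints"), symmetrized off-diagonal entries rank marker pairs
("limbs"). Explanation plots take the most confidently
scored windows per (state, score) stratum, ranked by the entropy of the
FOG prediction, with the predicted core segment highlighted on the
left-heel height trace.

## Synthetic cohorts

No public motion-capture cohort with levodopa-cycle FOG labels exists,
so `synthetic_gait` generates one. It emulates, per FOG score, the
motifs clinicians describe: score 0 — periodic heel lifts at the step
frequency (1.8 Hz OFF); 1 — reduced amplitude (×0.5), shorter lift
duty, slightly slower; 2 — festination, step rate growing ~15%/s while
amplitude decays; 3/4 — alternating walk/freeze episodes covering 50% /
80% of the trial, the frozen heel resting at the floor with 3–8 Hz
"freeze-band" trembling (≤ 6 mm). Walking bouts are short (~1.2 s) so
every 4 s window of a freezing trial contains freezing. ON state
raises amplitude (×1.3) and cadence (×1.15) and reduces freeze fraction
(×0.6). Whole-body structure: the right side is phase-shifted by half
a cycle, ankle/knee/hip carry attenuated smoothed copies, the pelvis
advances in proportion to stepping activity (pausing during freezes),
arms swing anti-phase, and the head/chest oscillate gently. The left
side expresses the phenotype 5% more strongly, mirroring the left-turn
test protocol and giving the attention analysis a recoverable
asymmetry.

Motor severity shapes the kinematics through three clinically grounded
channels: arm swing shrinks (up to 80% at the scale maximum), a 4–6 Hz
hand tremor grows (0.5 mm per point), and cadence slows (bradykinesia,
up to 35% at the scale maximum). These are what make the regression
task learnable: per-channel z-normalization erases absolute amplitude,
so severity must be carried by frequencies and within-channel spectral
ratios. For the same reason the left/right asymmetry is visible to a
model only as a signal-to-noise asymmetry: each channel is rescaled to
unit SD, so the left side's larger amplitude matters exactly insofar as
it rises further above the (fixed) marker noise — with noise-free data
the asymmetry vanishes entirely. Severity labels are drawn from truncated normals with the
published group × state means/SDs plus +2.5 points per FOG score level,
clipped to [0, 120]; session counts per (state × score) follow the
published cohort table exactly (a 12+12-session version with all scores
present is the default demonstration cohort). Marker noise is additive
Gaussian, default SD 4 mm.

What the simulator does **not** model: biomechanically valid joint
kinematics, turning geometry and en-bloc turns, marker dropout/gaps,
dual-task conditions, within-session label drift, or inter-subject
style variability beyond the seeded waveform jitter. Passing the
end-to-end checks therefore demonstrates that the architecture,
training loop and evaluation machinery work and that the model can
extract multi-channel spatio-temporal structure — not that clinical
accuracy would be reproduced on real patients.

## Scaled-down problem sizes

The package's end-to-end checks run on the demonstration cohort: 12
subjects per state (session table OFF (3,3,2,2,2), ON (4,3,2,2,1)),
3 trials per session, 10 s trials at 120 Hz, 21 markers — 504 windows.
The full model trains on one grouped fold for up to 40 epochs (early
stopping, patience 12) at its stated dimensions (4+4 layers, 64 feature
maps, T = 480, T_c = 240).

The model-family comparison re-trains nine models (TCN/GCN/AGCN × 3
seeds), which at full scale would dwarf the rest of the test budget, so
it runs on a 40 Hz variant of the cohort (gait content lives below
~15 Hz, so 160-sample 4 s windows preserve every motif) with a
uniformly scaled-down family — 3 layers and 32 feature maps, identical
across all compared models — for 15 epochs per run. The ordering
comparison uses the noise-free cohort; the attention-asymmetry check
uses the same cohort with 2 mm marker noise (see above: without noise
there is no asymmetry left to find) and a tighter gradient clip (norm
2) that damps seed-to-seed oscillation at this truncated budget.

## Known limitations

* The autodiff engine is single-threaded numpy; it is adequate for the
  scaled-down cohorts but not for 60-marker, multi-hour datasets.
* `w = exp(·)` is kept literally from the trimming formulation even
  though the accompanying text states 0 < w < 1; the sigmoid mapping of
  the endpoints bounds the crop regardless, and the smooth saturation
  of the width logit keeps training stable.
* The "×1/2" temporal pooling reading (halving per layer) is an
  interpretation of an ambiguous typographic artifact in the source
  description of max pooling.
* Wilson intervals on F1 treat it as a proportion of test windows
  (reporting convention, not a coverage statement).
* One crop serves all three heads; per-task trimming is out of scope.
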