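# gaitgcn

Explainable multi-task scoring of **freezing of gait (FOG)** from
whole-body 3-D motion-capture kinematics, for movement-disorders and
digital-biomarker researchers.

Freezing of gait — episodic arrests of stepping despite the intention
to walk — is one of the most disabling features of Parkinson's disease,
yet it is rated with a single 0–4 ordinal item by specially trained
examiners. `gaitgcn` implements a deep spatial-temporal graph model
that scores FOG objectively from marker trajectories recorded during
timed-up-and-go tests, and explains *where* (which markers and limbs)
and *when* (which sub-interval of each window) it looked.

From every 4 s analysis window (N markers × 3 channels × 480 samples at
120 Hz, hip-centered and z-normalized) the model simultaneously:

* scores **FOG severity** 0–4 (five-way classifier, mean F1),
* classifies **levodopa medication state** OFF/ON (binary F1),
* regresses the **MDS-UPDRS-III motor total** minus the FOG item
  (0–120, RMSE), via a Gaussian-mixture head
  `p(y|x) = Σᵢ αᵢ(x) N(μᵢ(x), σᵢ²(x))`.

The architecture chains **Adaptive Trimming** — a learned,
differentiable crop `s = T·σ(c − w/2)`, `e = T·σ(c + w/2)` of the core
motion segment, resampled spatial-transformer-style — into a four-layer
**adaptive graph convolution**

    f_out = Σₖ Wₖ f_in (Aₖ + Bₖ + Cₖ),   k = 1..3,

where `Aₖ` is the normalized skeleton adjacency, `Bₖ` a learned
dataset-level attention map and `Cₖ` an input-conditioned
embedded-Gaussian affinity, followed by temporal convolutions and
temporal average pooling. Aggregating `(Aₖ + Bₖ + Cₖ)` over windows
yields interpretable per-marker and per-limb attention weights.

Because the clinical motion-capture cohort is not publicly available,
the package ships a **synthetic parkinsonian gait simulator** that
generates labeled TUG-like cohorts with clinically styled motifs
(normal stepping, reduced step length, festination, freeze-band
trembling during freezing episodes, medication-state modulation,
severity-dependent arm swing/tremor/cadence), so every stage of the
pipeline is testable end to end. All networks run on a small
self-contained numpy autodiff engine — no GPU or deep-learning
framework required.

## Worked example

```python
import numpy as np
import gaitgcn as gg

# 1. simulate a labeled cohort (12 subjects per state, 21 markers)
cfg = gg.demo_config(seed=11)
trials, sidecar = gg.simulate_cohort(cfg)

# 2. preprocess: hip-center + z-normalize, cut 4 s windows at 1 s stride
windows = []
for tr in trials:
    windows += gg.segment_windows(gg.hip_center_normalize(tr, cfg.skeleton.root_index))
X, med, fog, updrs = gg.stack_windows(windows)
print(len(trials), "trials ->", len(windows), "windows")

# 3. train the full model on one grouped fold and evaluate held-out trials
fold = gg.make_folds(windows, n_folds=1, seed=5)[0]
model, report, history = gg.run_fold(
    gg.ModelConfig(), cfg.skeleton, X, med, fog, updrs, fold,
    gg.TrainConfig(max_epochs=40, patience=12, seed=0),
)
print(f"med F1 {report.med_f1:.3f}  fog mean F1 {report.fog_mean_f1:.3f}  "
      f"RMSE {report.updrs_rmse:.2f}")

# 4. which markers did the model attend to?
summary = gg.aggregate_attention(model, X[np.asarray(fold.train)][:128])
print([name for _, name, _ in gg.top_k(summary, k=5)[0]])
```

prints (exact numbers can shift with the BLAS build; a ~15 min run on
one CPU):

```
72 trials -> 504 windows
med F1 1.000  fog mean F1 0.993  RMSE 4.92
['PELVIS', 'LHIP', 'RHEEL', 'LHAN', 'RHAN']
```

Read: on held-out trials of the synthetic cohort the model separates
OFF from ON windows perfectly, recovers the five FOG severity levels
almost perfectly (mean F1 0.99), and predicts the 0–120 motor score to
within ~5 points. Its attention spreads over the pelvis/hip region,
a heel and the hands — the whole-body pattern expected here, since the
simulated phenotype couples stepping, freezing, arm swing and hand
tremor.

The same pipeline is scriptable from the shell:

```bash
gaitgcn simulate --out cohort/ --seed 3
gaitgcn train    --cohort cohort/ --folds 1 --seed 1 --out run/
gaitgcn evaluate --cohort cohort/ --seeds 0,1,2 --out ablation/
gaitgcn explain  --weights run/weights_fold0.npz --cohort cohort/ --out explain/
```

## Layout

| module | contents |
| --- | --- |
| `gaitgcn.data_model` | skeleton graph, trial/window types, CSV+JSON IO, hip-centering, windowing, grouped folds |
| `gaitgcn.synthetic_gait` | phenotype waveform and whole-body cohort simulator |
| `gaitgcn.adaptive_trimming` | crop prediction and differentiable resampling |
| `gaitgcn.backbone` | adjacency partitioning/normalization, affinity, AGCN layers |
| `gaitgcn.heads` | classifiers, Gaussian-mixture regression, joint loss |
| `gaitgcn.model` | model assembly and the TCN/GCN/AGCN/AT toggles |
| `gaitgcn.train_eval` | training loop, metrics, Wilson CIs, ablations, bias analysis |
| `gaitgcn.interpret` | attention aggregation, top-k ranking, confident core segments |
| `gaitgcn.nn` | numpy reverse-mode autodiff engine |
| `gaitgcn.cli` | `simulate / train / evaluate / explain` commands |

See `docs/methods.md` for the model equations, design decisions and
the simulator's scope and limitations.
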