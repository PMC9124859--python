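# hemidiff

Decoding four-class motor imagery (MI) from EEG by combining cortical
source imaging with a dual-branch CNN that classifies the *difference*
between left- and right-hemisphere activity.

Imagined movement suppresses mu (10–12 Hz) and beta (18–25 Hz) rhythms over
the motor cortex contralateral to the imagined effector (event-related
desynchronisation).  `hemidiff` exploits this lateralisation explicitly:

1. **Source imaging** — scalp EEG (64-channel 10-10 montage, 160 Hz, 4 s
   trials band-passed 8–30 Hz) is mapped onto a cortical source space with
   a weighted minimum-norm inverse
   `K = R_w Lᵀ (L R_w Lᵀ + λC)⁻¹`, where `L` is an analytic three-shell
   spherical leadfield (or an imported BEM leadfield), `C` the noise
   covariance estimated from rest data, and `R_w` depth weighting.
2. **Scouts** — nine symmetric pairs of 20-vertex motor-cortex ROIs
   (FC5–FC6 … CP1–CP2) act as virtual electrodes; their series are stacked
   into a 1280 × 9 input per trial (left series over right series).
3. **Dual-branch CNN** — two four-stage conv/pool branches (640×9 →
   flatten 800 each) whose feature vectors are subtracted before a
   128-unit FC layer and 4-way softmax, trained with Adam, batch
   normalisation and spatial dropout.

A synthetic MI-EEG generator with ground-truth cortical activity (21
trials per class, 84 per subject, configurable ERD depth and sensor SNR)
makes the whole pipeline testable without downloads; EDF recordings can be
ingested for the same pipeline.

## Worked example

```python
from hemidiff import PipelineConfig, SimConfig, run_subject_level

cfg = PipelineConfig(sim=SimConfig(erd_depth=0.8, sensor_snr_db=10.0), seed=1)
report = run_subject_level(cfg)[0]
print(f"accuracy={report.accuracy:.3f} kappa={report.kappa:.3f} "
      f"auc={report.auc:.3f}")
print(report.confusion_frame())
```

On one CPU core this simulates one subject (84 trials), runs the full
source-imaging chain and trains the network for 600 iterations (a few
minutes), printing

```
accuracy=1.000 kappa=1.000 auc=1.000
    T1  T2  T3  T4
T1   2   0   0   0
T2   0   2   0   0
T3   0   0   2   0
T4   0   0   0   2
```

i.e. the 8 held-out trials (2 per class, stratified 90/10 split) are all
classified correctly: at ERD depth 0.8 and 10 dB SNR the lateralised
band-power signatures survive the inverse mapping and the
hemispheric-difference features separate the four classes.  With
`erd_depth=0` the classes are generated from the identical baseline
process and accuracy drops to chance (0.25).

The same can be run from the shell:

```bash
hemidiff simulate --subjects 1 --seed 1 --out data/
hemidiff run-subject --erd-depth 0.8 --seed 1 --out results/
hemidiff run-group --subjects 2 --seed 1 --ablation
hemidiff shapes          # layer-by-layer output sizes of the network
```

Estimators compose with scikit-learn: `BandpassFilter`, `WMNEInverse`
(fit on baseline segments, transform epochs), `ScoutAssembler` and
`DualCNNClassifier` (fit/predict/predict_proba) follow the usual
fit/transform contract.

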