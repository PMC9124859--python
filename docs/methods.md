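# Methods

## The decoding problem

Motor imagery (MI) — imagining left-fist, right-fist, both-fists or
both-feet movement — modulates sensorimotor rhythms: oscillatory power in
the mu (≈8–13 Hz) and beta (≈14–30 Hz) bands drops over the motor cortex
contralateral to the imagined effector (event-related desynchronisation,
ERD).  Scalp EEG blurs these cortical patterns through volume conduction.
The pipeline implemented here therefore (i) maps scalp EEG back onto a
cortical source space with a linear inverse, (ii) summarises the source
activity as nine symmetric pairs of motor-cortex "scout" time series, and
(iii) classifies the four imagery tasks with a dual-branch CNN that
explicitly computes the difference between left- and right-hemisphere
feature vectors before the softmax.

## Forward model

The forward problem is `y = L x + ε`, with `L` the sensors × sources gain
(leadfield) matrix.  `L` is computed analytically for three concentric
spherical shells (brain, skull, scalp; default radii 0.08/0.085/0.092 m,
conductivities 0.33/0.0042/0.33 S/m — the standard 1:1/80:1 skull ratio).
The dipole potential is expanded in Legendre polynomials; for each order
`n` the per-shell radial solutions `A r^n + B r^-(n+1)` are matched on
potential and radial current density at both interfaces, with zero current
through the scalp surface, giving a 5×5 linear system per order whose
surface coefficient multiplies the source term.  In the homogeneous limit
(equal conductivities) the factor reduces to `(2n+1)/n` and the series sums
to the classical closed-form single-sphere dipole potential; the test suite
checks this limit to 1e-6 relative accuracy against an independently coded
closed form.

Numerical choices: radii are normalised by the scalp radius before solving
so the per-order systems stay well conditioned up to a few hundred orders;
the series is truncated at `n_terms` (default 60; the pipeline itself uses
200 because its sources sit at 0.078 m, i.e. `b/R ≈ 0.85`, where 60 terms
leave a ≈1e-4 tail — a warning reports the achieved tolerance whenever the
last term exceeds 1e-10 of the accumulated gain).  Columns are
average-referenced.  Dipole orientations are radial, the spherical-model
counterpart of "perpendicular to the cortex".  Externally computed
leadfields (e.g. from a BEM solver) can be imported from delimited text
matrices instead.

The 64-channel 10-10 montage is taken from the standard template positions,
projected onto the scalp sphere and symmetrised so that left/right partner
electrodes are exact mirror images — the hemispheric-difference design
assumes this symmetry.  The source grid uses latitude rings with an even
number of longitudes per ring, making it exactly mirror-symmetric as well;
2000 vertices on a 120° cap give ≈5 mm spacing, small enough that the 18
disjoint 20-vertex scouts stay compact under the named electrodes.

## Inverse model (WMNE)

Sources are estimated by weighted minimum-norm estimation:

    x̂ = argmin (y − Lx)ᵀC⁻¹(y − Lx) + λ‖Wx‖²,
    K  = R_w Lᵀ (L R_w Lᵀ + λC)⁻¹,   R_w = diag(w)⁻²,

with `C` the sensor noise covariance and `w_i = ‖L[:,i]‖^γ` depth weights
(γ default 0.5; γ = 0 recovers plain MNE).  `C` is the sample covariance of
demeaned inter-trial rest segments, band-passed like the task data, with
diagonal loading `C ← (1−α)C + α·mean(diag C)·I` (α default 0.1, raised to
0.5 with a warning when fewer baseline samples than sensors are available).
λ defaults to `trace(L R_w Lᵀ) / (trace(C) · SNR²)` with an assumed
amplitude SNR of 3 — the standard minimum-norm regularisation heuristic.
The kernel is validated against direct regularised normal-equation
solutions (`(LᵀC⁻¹L + λW²)⁻¹LᵀC⁻¹y`) to 1e-8 on random problems.

## Scouts and input assembly

Each of the 18 electrodes FC5/3/1, C5/3/1, CP5/3/1 (left) and FC6/4/2,
C6/4/2, CP6/4/2 (right) is projected radially onto the source sphere; its
scout is the 20 nearest vertices.  Scouts are kept disjoint by claiming
vertices greedily in the fixed pair order (left before right within a
pair).  A scout's series is the sign-aligned mean of its vertex series:
each vertex series is flipped to correlate non-negatively with the patch's
first principal temporal component, computed once per scout over all trials
so the polarity is consistent across the dataset.  The overall polarity is
canonicalised — a majority of vertices keep their sign; on an exact tie the
first vertex is forced positive — so that a patch holding ten copies of `s`
and ten of `−s` yields `s`, not `−s` or `0`.  PCA aggregation would be the
natural alternative; the sign-aligned mean was chosen because it is linear
in the data given fixed signs, which keeps the extraction stage
interpretable.

The nine (left, right) series pairs are stacked into a 1280 × 9 matrix per
trial: column *j* holds the 640-sample left series of pair *j* followed by
its right series.  Splitting the rows in half therefore recovers the two
640 × 9 branch inputs exactly.

## Dual-branch CNN

Each branch applies four valid (unpadded, stride-1) convolutions, each
followed by max pooling with floor division:
640×9 → (11×9, 25 maps) → 630×1×25 → pool 3×1 → 210×1×25 → (11×1, 50) →
200×1×50 → pool 3×1 → 66×1×50 → (11×1, 100) → 56×1×100 → pool 3×1 →
18×1×100 → (11×1, 200) → 8×1×200 → pool 2×1 → 4×1×200 → flatten → 800.
The first kernel spans all nine pair columns, collapsing the channel axis.
The two 800-vectors are subtracted elementwise — the hemispheric-difference
feature — then passed through a 128-unit ReLU layer and a 4-way softmax.

Branches are independent by default (they see statistically different
inputs once ERD lateralises); a shared mode binds both branches to one
parameter set, making the difference features exactly antisymmetric under
branch swap in evaluation mode — a property the tests pin down.  Batch
normalisation sits after each convolution (before ReLU) and spatial dropout
(dropping whole feature maps) after each pooling stage.

The network is implemented directly on numpy: im2col convolutions,
explicit backward passes (verified against float64 numerical gradients per
layer), and Adam.  Training minimises categorical cross-entropy over
mini-batches; "iterations" counts mini-batch updates.  The learning curves
record the training mini-batch loss/accuracy (before the update) and the
full test set in evaluation mode, per iteration.  The softmax head is
initialised near zero so an untrained model starts at the chance-level loss
ln 4.

Training defaults: Adam at 1e-3, batch 32, 600 iterations, spatial-dropout
rate 0.3.  The rate deserves a note: with 84-trial subject datasets
(76 training trials), rate 0.5 drove persistent oscillation of held-out
predictions late in training (mini-batch training accuracy near 1.0 while
test accuracy fluctuated around 0.6); rate 0.3 regularises without the
instability.  Similarly, halving the learning rate while doubling the
iteration count destabilised late training; the defaults above are stable
across seeds.  All of these are config-exposed.

Inputs are standardised per pair column with training-set statistics inside
the classifier; the statistics are stored on the fitted estimator.

## Synthetic data generator

Real recordings are optional (EDF ingest is provided); the package is
exercised end to end on simulated data whose structure mirrors the public
64-channel, 160 Hz, 4 s-trial MI corpus: 21 trials per class, 84 per
subject.

Each scout's baseline source activity is a sum of three random-phase
sinusoids in the mu band (10–12 Hz, σ = 1.0) plus three in the beta band
(18–25 Hz, σ = 0.7), each under a slow (0.1–0.5 Hz) amplitude envelope,
plus 1/f pink background (σ = 0.4).  ERD multiplies the oscillation of
"active" scouts by `1 − erd_depth`: left fist suppresses the
right-hemisphere set, right fist the left set, both fists both sets, and
both feet both sets but in the beta band only — the ROI set is fixed by the
scout definition, so the feet class is given a spectral rather than spatial
signature; this is a simulation convention, not a physiological claim.
With `erd_depth = 0.8` the active/inactive mu-power ratio is
(1−0.8)² = 0.04 up to the small pink-noise floor inside the band, which the
tests verify by Welch band power.

Scout series are copied onto each of the scout's 20 vertices, projected
through the leadfield, and white Gaussian sensor noise is added at a
configured SNR (default 10 dB), defined as mean clean-signal power over
noise power across channels; a zero signal produces pure noise at an
absolute floor variance.  Default `erd_depth = 0.8` and 10 dB SNR are the
generator's study conditions: a strong, clean effect that makes end-to-end
class recovery a sharp correctness check rather than a benchmark.  What
passing does **not** show: robustness to artifacts (EOG/EMG/line noise),
correlated sensor noise, inter-subject anatomical variability, weak or
non-stationary ERD — none of which the generator models.

The generator writes EDF+ (one file per subject, trials separated by 2 s
annotated rest blocks used for the noise covariance) through a minimal
16-bit writer, and reading goes through mne, so the EDF path is round-trip
tested to the format's quantisation.

## Splits, metrics, ablation

Subject-level: stratified 90/10 split per class with rounding to nearest
(21 → 19/2 per class, 76/8 overall).  Group-level: each subject's trials
are cut into 10 near-equal parts (84 is not divisible by 10, so sizes
differ by at most one — "equal parts" is impossible literally); one part
per subject is pooled into the test set.  Metrics: confusion matrix,
accuracy, Cohen's kappa, macro precision/recall/F1 (a class never predicted
contributes precision 0), and macro one-vs-rest ROC-AUC from the softmax
scores.  The ablation grid trains the four dropout × batch-norm variants on
an identical split and seed.

## Determinism and problem sizes

Every stochastic stage derives from one pipeline seed (simulation, splits,
initialisation, batching, dropout), so a run is a pure function of
(config, seed) up to floating-point associativity.  The shipped experiment
sizes — one subject (84 trials) for subject-level runs, two subjects for
group-level, 600 training iterations, 2000 source vertices — were chosen so
a full pipeline completes in a few minutes on one CPU core while keeping
every stage at its intended dimensionality (64 channels, 18×20 scout
vertices, the full Table-sized network).

## Known limitations

- The spherical head model is a deliberate simplification; subject-specific
  BEM/FEM geometry is out of scope (import of external leadfields is the
  escape hatch).
- The published form of the inverse estimator in this literature is often
  written with unnamed weighting symbols; this package implements the
  standard WMNE estimator stated above and documents the mapping rather
  than guessing other conventions.
- No artifact rejection is implemented, matching the preprocessing it
  models.
- Real-data (EDF) decoding is supported as an ingest path but is not part
  of the automated test surface.
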