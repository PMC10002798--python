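# Methods

`slacspect` implements transmission-less attenuation compensation (AC) for
myocardial perfusion SPECT (MPS) and its task-based evaluation, end to end
on synthetic digital phantoms.  The method under study — here called SLAC —
estimates the patient's attenuation map from the emission data alone: the
Compton scatter window (114–126 keV) is reconstructed without AC, a
segmentation model carves the result into six tissue classes, and
predefined per-class attenuation coefficients turn the segmentation into a
piecewise-constant μ map used for ordinary attenuation-compensated OSEM of
the photopeak window (126–154 keV).  SLAC is compared against CT-based AC
(CTAC, the reference) and no AC (NAC) on the clinical task of detecting
myocardial perfusion defects.

## Digital phantom cohort

Each phantom is a 64×64×64 volume at 0.68 cm voxels pairing a Tc-99m
activity map, a 140 keV attenuation map, a six-class segmentation
(background, lungs, skin/subcutaneous adipose, muscles/organs, bones,
patient table) and the left-ventricular (LV) geometry.  Anatomy is
procedural: elliptical-cylinder body with a 1.4 cm adipose rind, two
ellipsoidal lungs, spine and sternum, a liver, a half-ellipsoidal LV shell
(outer short-axis radius 3.1 cm, wall ≈ 1.1 cm), and a flat table behind
the patient.  Nominal class attenuation coefficients (cm⁻¹ at 140 keV):
background 0, lungs 0.04, adipose 0.14, soft tissue 0.154, bone 0.25,
table 0.20, jittered ±5 % per phantom so that class-mean estimation is a
real estimation problem.

Population variability is deliberately two-tiered:

* **Habitus** — the body's lateral and anterior–posterior semi-axes vary
  independently by ±15 %, organs shift by up to ±1.2 cm.  Independent
  anterior–posterior depth variation is what spreads the attenuation path
  to the inferior LV wall across patients, the mechanism that degrades NAC
  reading clinically.
* **Heart** — LV size varies by only ±7 % and position by ±0.6 cm.  Hearts
  vary less than habitus in practice, and the short-axis reorientation and
  centroid-anchored ROI extraction absorb most of what remains; keeping the
  LV tight keeps the defect signature coherent across the cohort, as it is
  in clinical observer studies.

Uptake ratios (soft tissue = 1): myocardium 5–7, liver 1.8–2.5, lungs
0.2–0.4, adipose and bone 0.4, nothing outside the body.  Perfusion defects
follow a 27-entry grid — extent {30°, 60°, 90°} about the LV circumference,
severity {10 %, 25 %, 50 %} activity reduction, wall {anterior, inferior,
lateral} — applied over the full apex-to-base extent with sharp sector
boundaries (the simplest reading of a parametric sector defect; feathering
is not modeled).  Severity 0 is accepted as a degenerate identity spec for
testing only.

What the generator does **not** model: XCAT-grade organ detail, diaphragm
shape, breast tissue, respiratory/cardiac motion, extra-cardiac focal
uptake.  Passing tests therefore demonstrate internal consistency of the
method chain under habitus-driven attenuation variability, not performance
on clinical data.

## Forward model

Parallel-beam, rotation-based projector: per view the volume is rotated
in-plane by a precomputed sparse bilinear-interpolation operator, attenuated
by `exp(-∫μ dl)` (suffix sums along the ray with a half-voxel self term),
blurred per depth plane with a Gaussian collimator-detector response
σ(d) = 0.17 cm + 0.018·d, and summed with a bin-size scale so a slab of
thickness L attenuates a point source by exactly `exp(-μL)`.  The back
projector is the exact adjoint by construction (transposed sparse
operators, self-adjoint symmetric blur, diagonal attenuation), which OSEM
requires; the adjoint identity is tested to 1e-5 and holds to machine
precision.  The default orbit is the clinical anterior RAO→LPO 180° arc
(60 views at full scale; the desk-scale experiment uses 30).

The scatter window is modeled phenomenologically: the first-order scatter
source is the unscattered photon fluence (activity convolved with an
inverse-square kernel, lightly smoothed) modulated voxelwise by μ/μ_water,
projected with a broad-beam effective attenuation `0.3·μ` — photons
accepted in the scatter window have scattered at least once and see far
less net attenuation than primaries — and normalized so scatter counts are
30 % of primary counts.  A Gaussian-kernel effective-source variant without
the attenuation reduction was implemented first and discarded: its
scatter-window reconstruction correlated with the true μ map at r ≈ 0.2,
failing the method's premise, while the fluence model reaches r ≈ 0.5–0.6
on noiseless default phantoms.  Full Monte-Carlo transport, septal
penetration and energy resolution are out of scope.

Poisson noise scales the photopeak expectation to a total count budget
(default 4×10⁶ per study, a low-dose clinical order of magnitude) and draws
both windows with a seeded generator; all arms of the comparison
reconstruct the same noise realization.

## Reconstruction and post-processing

OSEM with bit-reversed subset ordering over the matched projector pair;
voxels with zero subset sensitivity are excluded rather than divided by.
Defaults: 6 subsets × 10 iterations for the photopeak (MLEM likelihood
monotonicity and matched-model recovery are verified in the suite), 6 × 2
for the initial estimates of both windows, which are each normalized to
unit mean over their support.  Iteration count matters scientifically, not
just numerically: early-stopped OSEM is implicitly regularized toward
uniform images and partially *hides* the NAC attenuation artifact; at 60
updates the artifact is fully expressed, which is what the three-arm
comparison is about.

Post-processing follows the standard MPS chain: 3-D radially symmetric
Butterworth filter (order 5, cutoff 0.44 cm⁻¹), rigid reorientation of the
LV long axis onto the slice normal (trilinear, heart center fixed), and a
32×32 ROI from the short-axis slice through the defect centroid, centroid
at pixel (16, 16).  The centroid comes from phantom ground truth — it is
known by construction, as in any insertion study.  Each ROI is normalized
to its own peak (the normal myocardial wall), matching the relative scale
on which perfusion images are read.

## Attenuation machinery

HU↔μ conversion is the standard bilinear model with breakpoint at 0 HU:
soft branch from (−1000 HU, 0) to (0 HU, μ_water = 0.1537 cm⁻¹ at
140 keV), bone slope calibrated so 1000 HU → 0.25 cm⁻¹.  The pseudo-CT is
the exact inverse-bilinear image of the phantom's μ map plus Gaussian HU
noise (default sd 20 HU).

Training attenuation maps are segmented by a Potts-model MRF: k-means
intensity initialization, then ICM with checkerboard updates minimizing
`(I−μ_c)²/(2σ²) + β·#{disagreeing 6-neighbors}` (σ pooled within-cluster,
so β = 0.5 is dimensionless; 10 sweeps max, energy non-increasing by
construction with early stop).  Table vs bone — nearly isointense — is
resolved by a spatial prior: the table lies posterior of the body, across
an air gap.  Per-class mean coefficients pooled over all training voxels
form the tissue model ("predefined attenuation coefficients"); applying
them to a segmentation yields the final piecewise-constant μ map.

## Segmentation backends

**McEUN** — a U-Net variant with one multi-channel-input encoder (scatter
and photopeak initial estimates) and six attention-gated decoders, one per
tissue class, each emitting a single score map; softmax across the six
heads gives per-voxel probabilities.  Glorot-normal kernels, all biases
0.03, dropout at the bottleneck, weighted cross-entropy (inverse-frequency
class weights normalized to mean 1 by default), Adam, five-fold
cross-validation (fresh network per fold; per-fold validation losses
logged) before the returned network trains on the full set.  The network
runs in 2-D transaxial-slice mode on a hand-rolled numpy reverse-mode
autodiff core (convolution, pooling, upsampling, attention gating,
dropout, fused weighted softmax cross-entropy), gradient-checked against
finite differences.  3-D convolution at 64³ was considered and rejected:
at roughly 50 GFLOP per training step it is not tractable on a single CPU,
and the slice mode reaches held-out Dice ≈ 0.9 for lungs and body in
minutes.  Default capacity: depth 3, 8 base filters — deliberately small;
the architecture, not the capacity, is the point.

**Classical fallback** — a deterministic threshold/morphology pipeline
(body support, posterior-half-space table split, low-intensity lungs,
high-intensity core bone, geometric adipose rind) that reaches ≈ 0.9 voxel
accuracy on noiseless default phantoms.  It lets the full SLAC chain run
with zero training and is the default backend for the desk-scale
experiment.  A `ground-truth` backend (true labels) isolates the effect of
class-mean quantization alone.

## Observer study

The observer is a channelized Hotelling observer with four rotationally
symmetric octave frequency bands, edges (1/64, 1/32, 1/16, 1/8, 1/4)
cycles/pixel realized as DFT annulus indicators, inverse-transformed and
unit-normalized.  Scoring is leave-one-out at the image level — the
standard protocol for this task — with a ridge of 1e-6·tr(S)/4 on the
pooled channel covariance.  Caveat, stated plainly: with defect-present
and defect-absent groups of 12 patients each and nine records per patient,
image-level LOO leaves sibling records of the held-out patient in the
template, which inflates all arms' AUCs by a shared small-sample component;
a `groups=` argument implements leave-one-patient-out for users who prefer
the stricter independence unit (it carries the opposite, pessimistic
small-sample bias).  At clinical scale (140 patients) both converge.

Empirical ROC/AUC is the Mann–Whitney statistic with ties counted half
(delegated to scikit-learn, verified against an O(n²) pairwise count);
95 % CIs by class-stratified percentile bootstrap.  The binormal ROC fit
discretizes the continuous ratings at truth-state runs of the ordered data
(capped at 20 categories), then maximizes the multinomial likelihood over
(a, b, thresholds) with L-BFGS-B; AUC = Φ(a/√(1+b²)); non-convergence is
flagged and the empirical AUC substituted.  Fidelity metrics are RMSE and
mean SSIM (standard constants, unit dynamic range) between per-record
short-axis volumes, each normalized to its own maximum, with the CTAC arm
as reference.

## Desk-scale experiment

Defaults: 10 training patients (tissue model), 12 defect-present and 12
defect-absent test patients, inferior-wall defects only (9 specs), 30-view
anterior arc, 4×10⁶ counts, fallback segmentation, seed 1234.  That is
12×9 = 108 present and 12×9 = 108 absent records (absent records collapse
to one reconstruction per patient), 3 arms, ≈ 10 minutes on one CPU.  The
clinical-scale arithmetic (71/69 patients → 1917/1863 samples, 639/621 in
the observer study) is reproduced by the same design code and verified in
the suite.

Known limitations: desk-scale AUC differences between arms are of the same
order as their bootstrap CIs, so the reported arm ordering is a fixed-seed
observation, not a powered comparison; the scatter model is effective, not
transport-based; the fallback segmenter's thresholds are tuned to this
phantom family; the binormal fit does not implement the proper (convex)
binormal variant.
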