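# Methods

This note documents the models, numerical choices and limitations of
`keratoscreen`, in the spirit of a statistical-software methods appendix.

## Coordinate and map conventions

All maps live on a polar grid: `n_rings` radial samples at radii
r_k = (k+1) R / n_rings (default 31 rings, R = 4 mm) crossed with
`n_meridians` angles (default 256), plus one apex sample at r = 0.  The
default grid was chosen to resolve focal cones (ring spacing 0.13 mm) while
keeping per-eye index computation in the tens of milliseconds; zone means
converge at O(1/n_rings) and the suite checks refinement stability.
Coordinates are right-handed, y superior-positive, angles counterclockwise
from +x; elevation is a height field in mm, positive toward the instrument,
apex at zero.  Thickness maps are in um.

Laterality: index computation canonicalizes every eye into the OD frame by
mirroring OS scans about the vertical axis (an exact meridian permutation
on this grid).  This makes nasal/temporal geometry comparable across eyes
and renders every index — including the Zernike-based EI, which is not
mirror-symmetric on its own — exactly laterality-equivariant.  The
symmetry-index hemisphere axes (81/261 deg OD, 99/279 deg OS) become
literal mirror images under this convention.

## Curvature

"Curvature in diopters" is implemented as root-Gaussian keratometric
power: principal curvatures k1, k2 (1/mm) come from the first and second
fundamental forms of the height field, and the map value is
D = 337.5 sign(K) sqrt(|K|) with K = k1 k2.  A sphere of radius R gives
337.5/R D everywhere; the sign-preserving root keeps saddle-shaped regions
of irregular corneas informative.  The keratometric index n = 1.3375 is
used for both surfaces so anterior and posterior indexes share one scale.

Derivatives are estimated by Gaussian-weighted biquadratic least-squares
fits over physical-distance neighborhoods (radius 2.2 ring spacings,
kernel w = exp(-(d/h)^2)).  On a polar grid, fixed index-space stencils
degenerate near the apex (neighbors become angularly clustered and nearly
collinear); distance-based neighborhoods stay well conditioned at the apex
and the rim.  The fits are precomputed per grid as sparse linear operators,
so a curvature map is five sparse mat-vecs.  Accuracy on analytic spheres
is better than 0.03 D away from the outermost ~3 rings; rim rows are
one-sided and a factor ~20 worse, which the zone-based indexes tolerate
(area-weighted means) and the max-based indexes inherit equally across
classes.

## Axial radii and K_Avg

The axial (sagittal) radius at a node is the distance along the surface
normal to the optical axis, R_a = r sqrt(1+z_r^2)/|z_r|; for a conicoid it
equals sqrt(R0^2 - Q r^2), which the tests use as an oracle.  Piston and
tilt are removed over the measurement zone first — tilt carries no
curvature information but breaks the axial-radius definition near the
vertex (a tilted surface has a near-stationary point off-axis).  Per-
meridian means over the central 3 mm are then fitted with
R(theta) = a0 + b cos 2theta + c sin 2theta; flat/steep radii are
a0 +/- amp and the flat axis is the phase.  A surface that is flat within
the zone (all |z_r| ~ 0 or R_a unbounded) raises a numerical error rather
than returning meaningless radii.  K_Avg = 337.5 (1/R_f + 1/R_s)/2.

## Zernike decomposition and the ectatic index

Elevation is decomposed on the orthonormal Zernike basis over the 4 mm
(default) disc, ANSI (n, m) ordering, radial order <= 8 — enough for the
shapes clinical ectasia indexes respond to; the fit is a cached weighted
pseudo-inverse, so it is a projection (verified by idempotence tests) and
coefficients are in um.

The ectatic index is EI = b + sum_nm (alpha_nm1 c_nm + alpha_nm2 c_nm^2),
a linear-plus-quadratic functional of the coefficients.  The weights are
not published anywhere; they are learned by L2-regularized logistic
discrimination of Normal vs Kcn on the (c, c^2) feature vector, with
feature standardization folded back so the stored alphas act on raw
coefficients, and the intercept kept (a constant shift that leaves every
ROC property unchanged).  The inverse-regularization budget C (default 50)
is applied per sample (C/n), which makes training invariant to duplicating
the training set.  Training is deterministic given data order.

## Reference surfaces and deviation maps

The reference family is an aspho-toric conicoid: sagitta with meridional
apical curvature c(theta) = c_flat + (c_steep - c_flat) sin^2(theta-axis)
and fixed asphericity (Q = -0.2 anterior, -0.3 posterior — physiologic
population means; Q is never fitted).  The fit minimizes area-weighted
residuals over the 8 mm zone in the smooth parametrization
c(theta) = u0 + u1 cos 2theta + u2 sin 2theta (no axis wrap-around, no
flat/steep ordering discontinuity), via Levenberg-Marquardt iterations
started from the closed-form best-fit sphere; tolerances 1e-12, at most
~800 residual evaluations.  The fit is deterministic and idempotent, and
self-fits recover generating parameters to 1e-3 mm / 0.5 deg.  Deviation
maps are node-wise elevation minus reference sagitta in um; DZ_Max is the
signed maximum (a cone protrudes toward the instrument, so its deviation
is positive; the signed convention was chosen over max-absolute because
the posterior float of normal toric eyes is symmetric around zero).

Extremum locations (DZ_Max, K_Max, thickness minima) break ties toward the
smallest radius, then the smallest angle index, so index vectors are fully
deterministic.

## Thickness-progression profiles

The percentage thickness increase profile is centered on the thinnest
point: CT(d) is the area-weighted mean thickness over the annulus band
(d-0.05, d+0.05] mm for d = 0.1 ... 3.0 mm (0.1 mm steps resolve focal
cones at the default grid; bands are clipped to the map support), and
PTI(d) = 100 (CT(d) - CT_min)/CT_min.  %TI is the maximum excess of the
subject profile over the normative 95th-percentile profile (pointwise p95
across a designated normal cohort); positive values mean abnormally fast
thickness recovery away from the thinnest point.  The same machinery runs
on the epithelial map for %EpiTI.  Profiles whose center sits within
0.5 mm of the rim are flagged as truncated.

## The classifier

A multilayer perceptron with bipolar sigmoid activations
f(x) = 2/(1+exp(-sigma x)) - 1 (= tanh(sigma x / 2)) at every neuron, 19
inputs, 5 outputs in the fixed class order (Abn, Kcn, MyPO, Normal, SKcn).
Inputs are normalized to [-1, 1] by per-feature cutoffs taken at the
1st/99th percentiles of the training data (values outside are clipped, so
>= 98% of training values pass through unclipped).  Targets are 1/0
one-hot codes and the loss is MSE; bipolar outputs can approach but never
reach the targets, which is immaterial since classification is argmax
(ties to the first class in order).  Training is full-batch gradient
descent with momentum; weights start uniform in [-0.5, 0.5] scaled by
1/sqrt(fan_in) from a seed; early stopping after 200 epochs without
improvement, 10,000 epoch cap.  Analytic gradients are verified against
numerical differentiation to 1e-6 relative.  A NaN loss aborts with a
divergence error; note that with bounded activations and bounded inputs
the MSE stays finite for any finite learning rate, so runaway
learning-rate configs plateau at high loss rather than NaN — the
hyperparameter search handles both (divergent configs are skipped; bad
ones lose on test macro-F1, with the variance of the last decile of the
training log as a stability tie-break).  The default search grid spans
learning rate {0.01, 0.05, 0.1}, momentum {0.0, 0.9}, sigma {1, 2}, hidden
layers {[10], [15], [10, 10]}; the reference pipeline uses a single
default config (lr 0.05, momentum 0.9, sigma 1, one hidden layer of 15),
which is well inside the regime where results are insensitive to the
choice.  Inverse-frequency class weighting is available but off by
default.

## Evaluation

Stratified splitting draws round(0.7 n) training members per class
(round half-up, so 10 -> 7/3 and 2663 -> 1864/799), seeded.  AUC is the
Mann-Whitney estimator P(score_pos > score_neg) + 0.5 P(tie) via midranks,
reported oriented (>= 0.5) with a direction flag; it is tested for exact
agreement with a brute-force pairwise oracle.  Discrimination grades use
cut points 0.5 / 0.7 / 0.8 / 0.95 with boundary values in the upper band
and exactly 0.5 graded "no discrimination".  Confusion-matrix metrics are
one-vs-rest: accuracy (TP+TN)/N, precision TP/(TP+FP), recall TP/(TP+FN),
F1 the harmonic mean; zero denominators yield 0 with a degenerate flag.
Percentiles use linear interpolation between order statistics (numpy
default).  A one-sample Kolmogorov-Smirnov utility against a fitted
normal is provided for descriptive use; nothing gates on it.  Normality
flags per index: inside (p5, p95) normal, in [p1, p5] or [p95, p99]
borderline, outside [p1, p99] abnormal.

## The simulator

Each synthetic eye starts from an aspho-toric base (anterior radius ~
N(7.8, 0.22) mm truncated to [7.2, 8.6], posterior ~ N(6.4, 0.20), Q -0.2
/ -0.3, toricity |N| ~ 0.9 D at a uniform axis, central thickness
N(545, 25) um, epithelium N(53, 3) um) with a quadratic peripheral
thickness gradient (+6 um/mm^2, ~545 -> 640 um center-to-rim).

Phenotypes:

* **Kcn** — a Gaussian protrusion (height N(25, 8) um truncated
  [12, 50], width sigma N(1.2, 0.2) mm) at an inferior para-central
  location (radius N(1.2, 0.35) mm, angle N(270, 20) deg), applied to
  both surfaces with the posterior amplified x1.3 (posterior-first
  ectasia); a co-located corneal thinning crater of 2.2 um per um of cone
  height; focal epithelial thinning (N(8, 2) um) over the cone with a
  compensatory annular thickening ring (N(4, 1.5) um at 1.8 cone-sigmas);
  and a hemisphere-wide inferior steepening term.  The last component
  reflects a fact of cone geometry: a localized bump *flattens* its own
  mid-peripheral skirt (the curvature of a Gaussian changes sign one sigma
  out), while real keratoconic corneas steepen the whole inferior
  hemisphere — the vertical-coma signature.  It is modeled as
  -(0.5 h) (3 rho^3 - 2 rho) cos(theta - theta_cone) um of elevation,
  which puts the classic 3-mm-ring I-S difference of a median cone near
  2 D (clinically typical) while leaving the apex untouched.  Steeper base
  radii and thinner corneas than normal complete the phenotype.
* **SKcn** — the same mechanism with cone height and epithelial thinning
  at half the keratoconic means (12.5 um / 4 um): an attenuated cone, not
  a distinct one — this is the definition of the suspect class here.
* **MyPO** — Munnerlyn-style paraboloid ablation, depth N(55, 25) um
  truncated [15, 120] over a 6 mm zone, removed from the anterior surface
  and the thickness map (central flattening, central thinning).
* **Abn** — band-limited random Zernike irregularity (orders 2-8, RMS
  N(8, 3) um) on the anterior surface, half that on the epithelium, with
  the epithelium floored at a physiologic 20 um.

Measurement noise: elevation error of real reconstructed surfaces is
spatially smooth, so it is modeled as a band-limited random surface
(Zernike orders 2-10) at 0.5 um RMS; pachymetry error is node-independent
Gaussian at twice that.  White noise on elevation would be amplified ~10x
into curvature by second derivatives at this grid spacing, which no device
exhibits after its own surface reconstruction.  Stroma is corneal minus
epithelial thickness by construction, so the additivity invariant holds
exactly.

A rule-based labeler provides a ground-truth cross-check on the
quantitative subset of the clinical criteria: I-S > 1.4 D on the 3 mm
ring (five inferior minus five superior points at 30 deg spacing), central
K > 47.2 D (mean anterior curvature over the central 3 mm — the criterion
source does not define "central K", and this reading is flagged as a
choice), focal corneal thinning (minimum below the normal 5th percentile,
off-center or co-located with the curvature maximum), and focal epithelial
thinning over the cone apex; two or more firing criteria label the eye
Kcn.  Qualitative pattern criteria (bow-tie morphology, skewed radial
axes) are not implemented.  On default cohorts the labeler agrees with
generator labels on >= 90% of Normal + Kcn eyes.

What the simulator does **not** emulate: real epithelial remodeling
dynamics, microstructural scar morphology, Placido mire artifacts, OCT
speckle or segmentation failures, inter-device calibration offsets, or the
correlation structure of real populations (age, refraction, ethnicity).
Passing tests on synthetic cohorts therefore demonstrates that the chain
implements its definitions correctly and discriminates the modeled
phenotypes, not that real-world screening accuracy matches any published
figure; the published-metric replays in the acceptance suite are exact
arithmetic checks, and the synthetic-study results are property targets at
the stated effect sizes.

## The pipeline

`run_screening_study` executes: cohort simulation -> stratified 70/30
split -> EI-weight training and normative-profile estimation on training
normals (and training Kcn for EI) only -> index computation for all eyes
-> normative percentiles and normalization cutoffs from the training
partition only -> MLP training (or hyperparameter search) -> frozen-model
evaluation on the test partition (confusion matrix, per-class metrics,
per-index AUC/grades for Normal-vs-Kcn and Normal-vs-SKcn).  Nothing
learned ever sees test-partition bytes; the suite verifies this by
tampering with the test partition and checking that every training-derived
checksum is unchanged.

The manifest records the config hash, package version, per-stage artifact
checksums and wall-clock timings.  Its comparable fingerprint covers the
content-bearing fields only (timings excluded, since wall-clock can never
reproduce); two runs from one seed produce identical fingerprints and
checksum sets.

The reference study size used by the acceptance script and the end-to-end
tests is 500 eyes per class with the single default training config — the
scale at which class overlap (SKcn straddling Normal and Kcn) becomes
visible while a full run stays in the minutes range on one CPU.  The
published-cohort class mix (2663/1616/210/1519/669) is available as
`DEFAULT_CLASS_MIX` for proportional sampling.

## Known limitations

* Curvature near the outermost rings uses one-sided stencils (~1 D error
  on a sphere at the rim); indexes that sample the rim average over it.
* The SI hemisphere discs (radius 1.5 mm, centers 3 mm from the vertex)
  graze the 8 mm support boundary and are clipped to it; the geometry
  constants are module-level and configurable.
* The aspho-toric reference fit assumes the vertex is the conicoid apex
  (no decentration or tilt parameters); strongly tilted surfaces fold
  their tilt into the residual.
* EI weights and normative profiles are cohort artifacts: models trained
  on one simulator configuration do not transfer to another (or to real
  data) without refitting.
* The MLP is a deliberately minimal, faithful implementation (full-batch,
  momentum, MSE); it is not a competitive modern classifier and is not
  meant to be.
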