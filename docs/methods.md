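# Methods

This note records the models, numerical choices and limitations behind
`acidmri`, in the order data flow through the package.

## Synthetic phantoms and forward models

**Tumor geometry and pH truth.** A phantom is an ellipsoid of voxels inside
a regular grid (default 48×48×8 voxels of 0.234×0.234×1.5 mm, radii
12×12×3 voxels ≈ 1800 voxels), standing in for an orthotopic mammary tumor
covered by an 8-slice acquisition. Per-voxel pH_e is drawn from a truncated
normal (rejection sampling, truncation to the calibration range
[6.0, 7.4]). The within-tumor voxel SD defaults to 0.10 pH units; this is a
free parameter of the generator — published work reports between-tumor
SDs, not voxelwise spreads — and is only indirectly constrained by the
acidity score it produces. An optional rim/core offset (core mean minus rim
mean; default −0.05 for the metastatic-like group, matching the reported
core 6.69 vs rim 6.74 pattern) is applied mean-preservingly after a
slice-wise erosion split, so the whole-tumor mean is untouched. Per-voxel
B0 shifts are normal with SD 0.15 ppm, i.e. shifts essentially confined to
±0.3 ppm.

**Z-spectrum model.** Spectra are a sum of Lorentzian lines — direct water
saturation (amplitude 0.85, HWHM 1.0 ppm), a broad semisolid/MT floor
(0.05, 30 ppm), and two agent amide pools at 4.2 and 5.5 ppm (HWHM
0.7 ppm) — rather than a Bloch-McConnell integration. The analysis consumes
only ST amplitudes, and the Lorentzian closure lets the two agent
amplitudes be solved (a 2×2 linear system accounting for the cross-talk of
each pool at the other's offset) so that the noiseless post-minus-pre ΔST
ratio equals the calibration inverse 10^((pH−p0)/p1) *exactly*. Recovery
tests are therefore meaningful: any pipeline error is pipeline error, not
forward-model mismatch. Exchange-rate physics, B1 inhomogeneity and motion
are out of scope.

The amplitude scale (noiseless ΔST at 5.5 ppm) defaults to 0.10, the order
of magnitude produced by a high iodine dose (4 g I/kg); it sets the
contrast-to-noise of the simulated study. Noise on Z-spectra is Gaussian
(high-SNR magnitude limit), default σ = 0.5% of the unsaturated signal;
noise on DCE magnitude signals is Rician.

**Offset grid.** The default saturation grid has 46 offsets over ±10 ppm,
nonuniform: 0.25-ppm spacing around water (B0 estimation) and across
3.5–6.5 ppm (the agent lines), coarse in the wings. Uniform 0.44-ppm
spacing would make spline interpolation at the agent offsets the accuracy
bottleneck; protocols for ratiometric agents allocate offsets the same way.

**Calibration.** The ratiometric coefficients are config inputs; defaults
p0 = 6.9, p1 = 1.5 pH units per decade were chosen so that the whole valid
range [6.0, 7.4] maps to ST ratios realizable with nonnegative agent-pool
amplitudes given the 4.2/5.5 ppm cross-talk at the chosen line width. The
in vivo calibration curve for iopamidol is instrument- and
protocol-specific and must be supplied by the user for real data.

**DCE forward model.** Tissue concentration follows the extended Tofts
model driven by a biexponential population arterial input function
(defaults a1 = 5.8 mM, m1 = 0.01 /s, a2 = 0.7 mM, m2 = 0.0002 /s, bolus at
the first post-baseline frame); no individual AIF measurement is modeled.
Concentration maps to signal through the spoiled-gradient-echo steady state
S = M0 sin α (1−E1)/(1−E1 cos α) with 1/T1(t) = 1/T10 + r1 C(t); defaults
TR 58 ms, flip 30°, 60 frames at 13 s (13-minute scan), 6 pre-contrast
frames, T10 = 1800 ms, r1 = 3.3 /mM/s (gadoteridol-class). K^trans is in
1/s throughout, consistent with group means of 0.0012 and 0.0052 against a
seconds time axis; the unit is explicit in the config because conventions
vary.

**Cohorts.** `simulate_cohort` draws per-tumor summary metrics as
independent normals from group-level (mean, SD) pairs. The defaults encode
the published two-group summaries — pH_e 6.72±0.06 vs 6.81±0.07, acidity
score 2.11±0.10 vs 1.96±0.12, K^trans 0.0012±0.0004 vs 0.0052±0.0026 /s,
v_p 0.04±0.02 vs 0.03±0.02, TGR 0.67±0.17 vs 0.49±0.15 — with 14 tumors
per group (7 mice, bilateral fat pads). Tumor volumes are normal
(220±90 mm³, floored at 20) purely to exercise the size-class machinery;
no published volume distribution exists. Bilateral tumors are treated as
independent, mirroring the study-design assumption; a mixed-effects
treatment of mouse-level clustering is a known limitation.

## CEST pipeline

Per voxel: normalize by the unsaturated reference (nonpositive reference →
voxel invalid), fit a natural cubic smoothing spline, locate the water
minimum within a ±1.5 ppm search window (window excludes the agent lines),
report the minimum location as the B0 shift, and resample the spline on the
offset grid displaced by the shift. A minimum at the window boundary means
no identifiable water line; the voxel is flagged unreliable. ST at the two
agent offsets is read from the shifted spline, differenced post-minus-pre,
and converted to pH by the log-linear calibration.

**Spline details.** The smoothing spline is the classical Reinsch form —
minimize Σ(y−f)² + λ∫f″² over natural cubic splines with knots at the
offsets — implemented via the Green–Silverman roughness matrix. Its
eigendecomposition is computed once per offset grid and cached, so
per-voxel fits, including the per-voxel choice of λ, cost O(n²) (~0.3 ms a
voxel). λ is chosen per voxel by *robust* generalized cross-validation
(Lukas' RGCV with γ = 0.3): plain GCV collapses to near-interpolation on a
sizable minority of noisy spectra, inflating the ST noise, while the
robustness factor γ + (1−γ)tr(S²)/n suppresses those undersmoothed minima
and leaves the noiseless case (near-zero λ) untouched. A scalar λ can be
passed to override GCV entirely.

**Validity policy.** Voxels with ΔST below the detectability floor
(default 0.5% ST) at either offset, a nonpositive denominator, an
unreliable B0 fit, or a degenerate reference are flagged invalid and carry
NaN. pH values outside [6.0, 7.4] are clamped to the boundary and flagged
"clamped" but remain valid, so downstream binning sees a defined value. The
QC report counts all four conditions and the mean B0 shift.

Under the default noise conditions the full chain recovers the mask-mean
pH within a few thousandths of a unit and individual voxels with a mean
absolute error just under 0.05 pH units; the acceptance tests assert the
±0.05 mask-mean band.

## DCE pipeline

Baseline T1 comes from the variable-flip-angle linearization
S/sin α = E1·(S/tan α) + M0(1−E1) by least squares; a slope outside (0, 1)
is nonphysical and flags the voxel (a nonlinear refinement mode exists and
agrees to 0.1% on clean data). Concentration conversion inverts the
spoiled-GRE equation frame by frame with M0 inferred from the baseline
mean, clamping frames whose signal implies a nonphysical T1.

The extended-Tofts fit minimizes squared residuals with bounded
least-squares (bounds K^trans ∈ [0, 0.5] /s, v_e ∈ [1e−4, 1],
v_p ∈ [0, 0.5]) from three starts spanning low/mid/high K^trans
(10⁻⁴, 2·10⁻³, 2·10⁻²), keeping the best cost. The convolution uses
trapezoid quadrature on the frame grid with a cached weight matrix. One
subtlety: at 13-s sampling a fast-exchange solution (k_ep·Δt ≫ 1) aliases
the plasma term and can tie the true minimum to machine precision; among
numerically indistinguishable costs the fit prefers the smallest-K^trans
(parsimonious) solution, which restores identifiability of pure-plasma
voxels. Flat curves are reported as K^trans = 0, v_p = 0 with v_e at its
lower bound and flagged rather than excluded, keeping map geometry stable.
Fits are voxelwise independent (no spatial regularization), matching how
parametric maps are usually shown.

## Heterogeneity metrics

The acidity score assigns each valid voxel to one of three bins —
neutral/mild [7.0, 7.4], moderate [6.7, 7.0), highly acidic [6.0, 6.7) —
and averages the labels 1/2/3 weighted by voxel fractions. Two
interpretations were fixed where the verbal definition is ambiguous: shared
bin edges (6.7, 7.0) belong to the less-acidic bin, and the aggregation is
the fraction-weighted mean, the only aggregation consistent with continuous
scores like 2.11. Clamped voxels participate; invalid voxels do not.

Rim/core splits erode each axial slice by a Euclidean disk (default radius
2 voxels ≈ 0.47 mm in-plane), 2-D because slices are 6× thicker than the
in-plane voxel; the rim is the complement within the mask. The erosion
agrees exactly with a distance-transform definition (distance to background
> depth) away from the array border, which is how it is tested. An empty
core (depth beyond the inradius) is a flagged condition, not an error.

TGR is the volume difference divided by elapsed days, unit-agnostic. The
immunohistochemistry score is the product of two ordinal 0–3 grades
(intensity × area, range 0–9); only the arithmetic is implemented, not any
image quantification.

## Cohort statistics

AUC is the Mann–Whitney pair-counting statistic computed from average ranks
(ties count ½), so 10⁵-per-group simulations stay in O(n log n).
Confidence intervals are stratified percentile bootstrap (default 2000
resamples, seeded, vectorized by row-wise ranking); the paper-style
sensitivity/specificity operating point maximizes Youden's J with the
smallest oriented threshold breaking ties. Orientation is explicit: lower
pH_e flags the metastatic class, higher acidity score does. Accuracy is
reported at the Youden point as (TP+TN)/N. The closed-form binormal AUC
Φ(|μ1−μ2|/√(σ1²+σ2²)) serves as the simulation oracle. Group comparisons
default to the pooled two-tailed Student t-test (Welch available);
correlations report Pearson r, the two-sided p, and the signed squared
correlation sign(r)·r², matching the convention in which inverse trends are
printed as negative r². The tumor-size split (small/medium) threshold is
configurable — both 200 and 220 mm³ appear in the source material — with
200 mm³ as the default.

## Determinism and problem sizes

Every stochastic component takes a seed; `run_study` derives per-tumor
seeds from a master generator, records a config hash and per-stage QC in a
manifest, and reruns bit-identically. The bundled demo study uses 24×24×6
phantoms (~200 tumor voxels) for its 2×14-tumor cohort so a full
simulate→maps→metrics→ROC pass takes about two minutes on one CPU; the
acceptance tests use the full-size default phantom (~1800 voxels, a few
seconds per phantom) for recovery checks and 10⁵-per-group draws for the
AUC targets.

## What passing tests do and do not show

The generator reproduces the group-level statistical structure the analysis
assumes — not raw-data realism. Real Z-spectra have non-Lorentzian MT and
amide-proton-transfer backgrounds, B1 variation, motion and partial-volume
effects; real DCE has bolus-arrival jitter, individual AIF variation, and
water-exchange effects; real cohorts have mouse-level clustering. Recovery
and ROC results on synthetic data therefore validate the *implementation*
(inversion, correction, fitting, statistics) under the stated noise models,
and calibrate expectations, but do not certify in vivo accuracy, which
depends on acquisition quality and a measured calibration curve.
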