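# Methods

This note documents the models, the numerical choices, and the places
where the design was genuinely open, in enough detail to reproduce or
re-derive every behavior the tests assert.

## Synthetic subjects (the phantom generator)

Each synthetic subject emulates the inputs of a free-breathing CT
elasticity study: an end-exhalation HU volume, five lobe labels, a
ground-truth Young's modulus (YM) map, a bellows-like breathing signal,
and a set of displacement vector fields (DVFs) standing in for scans
deformably registered to a reference geometry.

**Anatomy.** Two half-ellipsoid "lungs" on a 48³ grid at 2 mm isotropic
spacing (both configurable; the desk-scale default keeps the inverse
solve in minutes, where clinical grids are 1 mm). Oblique planes split
the left lung into 2 and the right into 3 lobes; at 64³ every lobe holds
at least 20³ voxels. Fissure realism is irrelevant to the statistics
being tested and is not attempted.

**Elasticity.** Per lobe, values are drawn from a two-component
log-normal mixture: a healthy component (median ≈ 5–6 kPa, log-sd
0.38–0.55 — log-normal keeps values positive and gives the long right
tail that makes the non-uniformity index ≈ 1) and a soft "diseased"
component whose mass lies almost entirely inside the 1–3 kPa biomarker
band (median 1.9 kPa, log-sd 0.22). The mixture weight is calibrated
analytically from the two components' band probabilities so that the
expected in-band fraction equals the lobe's diseased-fraction target;
empirical fractions land within ±3 percentage points for lobes of ≥ 20³
voxels. Severity presets: `none` (≈ 6–9% diseased per lobe), `mild`
(10–16%), `moderate_severe` (one lobe at 45% with higher dispersion —
the upper-lobe-predominant pattern), `homogeneous` (identical lobes; the
null case). Lower lobes are slightly stiffer, mirroring their larger
inspiratory deformation.

**HU.** Parenchyma is normal around −860 HU clipped strictly below
−705 HU, so phantom parenchyma is parenchymal by construction; vessels
are thin random tube tracks and tumors spheres, both above the −700 HU
threshold and assigned stiff truth values (they are excluded by masking
before any statistic).

**Breathing signal.** Raised-cosine cycles at 100 Hz with per-cycle
period (5%) and depth (8%) variability and an optional linear drift.
Amplitude units are arbitrary — the bellows voltage is uncalibrated and
only relative amplitudes enter the motion model. Flow is the
second-order central-difference derivative of the amplitude.

**Scan sets.** Each scan samples one (v, f) state; its DVF is
`α(v−v_ref) + β(f−f_ref)` plus i.i.d. Gaussian noise per component
(default 0.5 mm, the scale suggested by typical registration target
errors of ~1.3 mm). The reference entry's DVF is identically zero, as a
registration to the reference would produce. Three scans is the
identifiability floor (three unknown vector coefficients per voxel).

## Motion model

Per-voxel OLS of displacement on the design (1, v, f); no spatial
regularization and no scan weighting (the simplest faithful reading;
nothing in the study suggests either). The fit refuses rank-deficient
designs. Phase DVFs are the model at the 5th/85th percentile amplitudes
(linear-interpolation percentiles, declared because no convention is
universal) with zero flow, expressed relative to the reference geometry;
the exhale-to-inhale field is exactly `α·(v_85 − v_5)` by linearity.
With Gaussian scan noise of sd σ the per-voxel residual RMS converges to
`σ·√((N−3)/N)`; because the reference scan is noise-free by construction
the expectation is ~2% lower, well inside the 5% band the tests use.
Volume warping is pull-back trilinear resampling with a declared fill
value.

## Biomechanical model

One node per parenchymal voxel; elastic springs on the 6 face links and
shear springs on the 12 edge-diagonal links — the minimal lattice that
resists both stretch and angular distortion. Link force is `k·ΔL/L`
along the current link direction (geometrically nonlinear), with
`k = (YM_a + YM_b)/2` on face links (the model assigns YM per voxel, a
link needs one value) and the fixed shear modulus S = 4 kPa on
diagonals. A dashpot term `μ·(v_b − v_a)` completes the force model.
The shear force is implemented as a spring law that vanishes at rest:
the alternative form `S·(L − ΔL)/L` would exert a constant force in the
rest configuration, violating the force-free-rest invariant the tests
assert, so the vanishing-at-rest spring form is the deliberate choice.

**Forward solve.** Dynamic relaxation: explicit pseudo-time stepping
with unit step, fictitious nodal masses `m = 2·Σ k/L` over incident
links (Gershgorin bound ⇒ unconditionally stable), and kinetic damping —
velocities are zeroed whenever kinetic energy peaks, with a half-step
backtrack to the peak position. Kinetic damping is parameter-free;
per-link dashpots alone leave long-wavelength modes underdamped because
the damping matrix shares the stiffness matrix's structure. The hot loop
is a numba kernel; the public `compute_forces` is plain numpy.
Convergence: maximum interior force below `tol` (default 1e-4 of the
initial force scale); non-convergence raises with the last residual.
Oracles: two-spring chains match the series-spring closed form to 1e-6,
rest and rigid translation are force-free to 1e-10, and internal forces
sum to zero.

**Inverse estimator.** Outer loop: forward-solve under boundary
displacements taken from the target DVF, compare node-local mean
absolute link strains of model vs target, update
`YM ← YM·(model/target)^γ` with γ = 0.5 under-relaxation, clamp each
step to [0.25, 4]× and the result to [0.1, 100] kPa (brackets the 1–3
kPa biomarker band with headroom). Stop when the mean interior
displacement error falls below `outer_tol` (default 0.1 mm), when the
relative improvement drops below 0.5% (discrepancy-style stall stop —
for noisy targets the error bottoms out at the noise floor and further
iterations only chase noise), or with an error after five consecutive
increases. Nodes with negligible target strain or displacement
(< 1e-6 mm) are excluded from the ratio and inherit the median factor of
their link neighbors (breadth-first, so deep excluded regions fill from
the interior).

Three regularizations address the voxel-scale ill-posedness of the
inverse problem (a single node's modulus has almost no displacement
signature):

* the model and target strain fields are smoothed (mask-aware Gaussian,
  default 1 voxel) before the ratio, so updates respond to regional
  mismatch only;
* log-YM is smoothed after each update with a sigma that decays
  geometrically (1 voxel × 0.7^k): strong early smoothing removes
  initialization speckle, later iterations sharpen real contrast;
* optionally, an input-DVF Gaussian pre-filter (`smooth_sigma_voxels`,
  ~2 voxels recommended for 0.5 mm registration-scale noise — raw link
  strains amplify displacement noise by 1/spacing) and a near-boundary
  update margin (`update_margin_voxels`), since strains within a filter
  length of the prescribed boundary are dominated by boundary noise and
  filter edge effects.

On the 24³ two-block benchmark (1 vs 5 kPa, target generated by the
forward model with the ends loaded and lateral faces free), the
estimator recovers the modulus field with ~9% median relative error from
a uniform start, and a heterogeneous start against a uniform truth
homogenizes to under 10% of its initial coefficient of variation. With
0.5 mm i.i.d. noise added to the target DVF the best achievable median
error is ~40–45%: the per-link strain signal-to-noise ratio is ~0.13
(0.5 mm on 2 mm links carrying 3–5% strains), and with every surface
node displacement-prescribed on a domain only 24 voxels across, the
interior strain field is largely kinematically pinned, leaving the
modulus only weakly identified — the corresponding recovery test states
the tighter bound it aims for and currently fails it, deliberately.

**HU initialization.** Affine, −1000 HU → 0.1 kPa and −700 HU → 5 kPa,
clamped to [0.1, 100] kPa; monotone so denser tissue starts stiffer.

## Masking and lobar statistics

Parenchyma is lung voxels with HU strictly below −700 (the boundary
value is excluded; whether the boundary belongs to parenchyma has no
standard convention, so strict-less-than is declared here). Lobar
distributions report n, mean, sample (n−1) SD, and the 95th percentile
by linear interpolation. Empty lobes are flagged and excluded downstream
with a logged warning.

## Heterogeneity statistics

The band [1, 3] kPa is inclusive at both ends. EHI uses the maximal
percent-diseased value (tie-invariant) against the mean of the rest; it
is 0 iff the maximum equals that mean, bounded by 1, and defined as 0 in
the degenerate all-lobes-fully-diseased case. CV and NU are invariant
under positive rescaling of the elasticity values; EHI is not unless the
band is rescaled with them. Group comparisons: two-sided F-test with the
larger variance in the numerator chooses pooled vs Welch t-test at
α = 0.05; Mann–Whitney U is available; identical groups short-circuit to
p = 1 (the t statistic is 0/0 there). Raw p-values are reported, no
multiplicity correction by default, matching the analysis convention;
Holm adjustment is exposed behind a flag. Tumor contrast pools voxels
across tumor-bearing lobes, compares against the mean of the other
lobes' means, normalizes by the mean of all five lobar means, and flags
whether a tumor lobe is strictly stiffest (ties → false). Subjects of
unknown severity enter only the pooled all-COPD vs no-COPD contrast.

## Pipeline

Stages (simulate → fit-motion → mask → estimate-elasticity →
heterogeneity → cohort-report) run from a YAML config that round-trips
losslessly; every random operation traces to an explicit seed. Volumes
are uncompressed NIfTI (spacing in the header; DVFs 3-component, world
mm, pull-back convention), so deterministic stages are bit-identical
across reruns, which the manifest's per-file sha256 checksums make
checkable. By default the heterogeneity stage analyzes the phantom's
ground-truth elasticity; `analyze_estimated: true` switches it to the
inverse-estimated map. CV histograms use 10-percentage-point bins, a
free choice.

## What the phantom does and does not show

The generator reproduces the statistical structure the analysis assumes
— disjoint lobes, positive skewed lobar elasticity with controllable
inter-/intralobar heterogeneity, a quasi-periodic amplitude/flow signal,
and motion-model-consistent DVFs with Gaussian registration noise. It
does not simulate CT physics (no motion blur or reconstruction
artifacts), real fissure geometry, per-slice amplitude assignment of
helical acquisition, cardiac motion, or spatially correlated
registration error. Passing tests therefore demonstrate correctness of
the estimators and statistics under the stated assumptions, not
performance on clinical data. The phantom's motion truth and elasticity
truth are specified independently; physical consistency between DVF and
modulus is exercised where it matters, in the inverse-crime recovery
benchmarks whose targets come from the forward model itself.
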