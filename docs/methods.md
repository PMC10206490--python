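# Methods

## The model system

A constrictive cuff on a mouse carotid artery creates, in one vessel, the
two canonical shear environments of atherosclerosis research: a low-shear
zone immediately upstream and a low/oscillatory-shear recirculation zone
immediately downstream. `atheroflow` reproduces the computational side of a
flow-restoration study in this preparation: imaging-derived vessel geometry
and inlet velocity drive a pulsatile flow simulation whose wall-shear
readouts (pWSS, TAWSS, OSI) are compared across timepoints, alongside
histological plaque quantification and cohort statistics.

## Geometry

The vessel is represented as a straightened axisymmetric body: circular
cross-sections of radius r(z) on a straight centreline. This mirrors the
reconstruction convention of slice-based imaging (per-slice best-fit lumen
diameters placed on a straightened centreline, neglecting the small arterial
curvature). Two radius conventions are supported: half the mean of the min
and max Feret diameters when mask-derived diameters are available, and the
equivalent-circle radius √(A/π) when only areas are. Radii between slice
stations are interpolated with a monotone cubic (PCHIP) so the stenosis
shoulders cannot overshoot.

Flow extensions of 1.5× (inlet) and 7× (outlet) the local diameter are
prepended/appended at constant radius; they stabilize the boundary
conditions and are excluded from all metrics. Analysis regions are the 2-mm
segments abutting the cuff ends; without a cuff (baseline/decuffed vessels)
two 2-mm segments abutting the domain midpoint are used — a convention for
"the central portion" that is stated here because no unique definition
exists. Regions are clipped, with a warning and a flag, when the vessel is
too short.

The grid maps radial fraction η = r/R(z) ∈ [0, 1] onto each axial station.
Axial spacing follows three zones: ≤0.013 mm inside and within 2 mm of the
cuff, ≤0.025 mm at 2–3 mm, ≤0.05 mm elsewhere; the radial axis is uniform in
η with enough intervals that wall-adjacent spacing is ≤0.013 mm at the
largest radius (20 intervals at the defaults, giving ≥7 across the default
stenotic throat).

## Flow solver

Blood is treated as incompressible and Newtonian (μ = 3.5 mPa·s,
ρ = 1050 kg/m³); at the default conditions the Reynolds number is ~15 in the
straight vessel and ~100 through the throat, and the Womersley number is
α ≈ 0.99, so the flow is laminar and moderately unsteady.

Because the reconstructed geometry is axisymmetric by construction, the
solver works in the Stokes streamfunction / azimuthal vorticity variables
(ψ, ω) on the body-fitted (z, η) grid rather than as a 3-D primitive-
variable solve. This choice has three consequences worth stating:

* mass conservation is exact — the flow rate through every cross-section is
  2π ψ_wall by definition (the independent cross-check integrates the axial
  velocity and agrees within 1% at interior stations; the inlet station
  itself shows ~Δr/R because the prescribed plug profile is discontinuous
  at the wall corner);
* pressure is not a state variable, so flow fields carry (u, v, ψ, ω)
  snapshots and no pressure;
* the wall-shear vector is purely axial, so OSI "multidirectionality" is
  exactly sign reversal of τ — consistent with the observation that the
  non-recirculating upstream segment reports OSI = 0.00.

Boundary conditions: plug inflow v(t) at the inlet (ψ ∝ r², ω = 0),
fully-developed outflow (∂/∂z = 0, the zero-reference-pressure outlet),
no-slip wall (ψ fixed on the flux streamline plus a second-order
wall-vorticity closure of Thom type, with the wall-normal distance corrected
for wall slope), and regularity on the axis (ψ = ω = 0).

Time stepping combines semi-Lagrangian advection of ω/r — the quantity
materially conserved in inviscid axisymmetric flow — with θ-implicit
(θ = 0.55) viscous diffusion. The advected field is interpolated at RK2
departure points with cubic splines; linear interpolation is measurably too
diffusive for the TAWSS grid-convergence comparison. Both the implicit
diffusion and the streamfunction equation, including the wall closure, form
one sparse linear system in (ω, ψ) that is factorized once (SuperLU) and
solved once per step; the semi-Lagrangian step makes the scheme stable
without an advective CFL limit (the step count is still raised automatically
if the estimated Courant number exceeds 25). The system is assembled in
units of the largest radius and the peak inlet speed: in SI metres the wall
closure coefficient is ~10¹³ while the vorticity rows are O(1), and that
spread turns direct-solve roundoff into visible per-step noise on the wall
shear.

Simulations start from rest and run three cardiac cycles at 1000 steps per
cycle; the third cycle is reported. The cycle-to-cycle change in
region-mean TAWSS is recorded and must be <2%; with the default conditions
the start-up transient decays within a fraction of one cycle (viscous
timescale R²/ν ≈ 0.02 s versus a 0.12 s period), so the measured change is
at machine precision. Grid convergence is assessed by solving with all zone
spacings doubled: the region-mean TAWSS changes by ≤2% between the
0.026 mm and 0.013 mm fine-zone levels for the default stenotic case.

Validation against closed forms (enforced in the test suite):

* steady developed wall shear within 2% of Poiseuille, τ = 4 μ V̄ / R;
* wall shear under an oscillatory inlet within 5% L2 of the analytic
  Womersley (Bessel-series) solution for α ∈ {0.5, 1, 2}, measured
  mid-vessel over a full cycle (observed ≈0.7%);
* flow separation with wall-shear sign reversal downstream of the 14%-area
  stenosis, and attached flow upstream.

The rigid-wall assumption matches the modelling convention for this
preparation; fluid–structure interaction, non-Newtonian rheology and
turbulence are out of scope at these Reynolds numbers.

## WSS metrics

For each wall station, τ(t) over the reported cycle gives

* pWSS: |τ| at the phase of peak inlet velocity (earliest phase on ties),
  averaged over the region's stations;
* TAWSS: (1/T)∫|τ|dt (periodic trapezoid), averaged over stations;
* OSI: ½(1 − |∫τ dt|/∫|τ| dt), defined as 0 where shear vanishes.

Region OSI averages stations with OSI ≥ 0.01 — OSI localizes to parts of
the recirculation zone, and including the attached remainder would dilute
it — falling back to the whole-segment mean (flagged) when no station
qualifies. The threshold is applied to unrounded values; reported OSI is
rounded to two decimals. Station weighting is uniform; with near-uniform
fine-zone spacing this matches arc-length weighting to grid tolerance.

## Histomorphometry

Sections are quantified from manually segmented lumen / internal elastic
lamina (IEL) / external elastic lamina (EEL) contours. The intima (plaque)
is the pixel set inside the IEL and outside the lumen; pixels count as
inside a contour when their 0-based centre lies inside the polygon
(even-odd rule). Plaque burden is 100 × (IEL − lumen area)/EEL area using
shoelace polygon areas. Binary stains report the percentage of stain-
positive intimal pixels. The greyscale macrophage stain (0–105 scale)
reports 100 × Σ(intimal values)/(count × 30); the normalization constant 30
converts mean intensity to an area-fraction estimate, values above 100% are
possible and flagged rather than clipped. Collagen under polarized light is
thresholded twice (red/yellow and green/blue birefringence) and the masks
are combined as a union, counting overlap once. Threshold values are
deterministic inputs (observer-chosen in practice), not an algorithm.
Per-mouse values are unweighted means over viable sections (typically 3–4);
zero viable sections yields a missing value, never zero.

## Imaging metrics and statistics

Feret diameters are computed by rotating calipers over the mask's convex
hull at 1° resolution, adding each pixel's support (|cosθ|+|sinθ|) so the
measured extent is that of the pixel union (the convention of standard
image-analysis tools); the lumen diameter is the mean of the min and max
Feret. Maximum stenosis is the minimum per-slice area ratio to baseline,
slices matched by index from the carotid bifurcation (no registration).
Peak systolic velocity is the mean of per-cycle maxima over three cardiac
cycles, with cycle boundaries given, derived from a known period, or
detected from systolic peaks. Longitudinal values are expressed as
percent-of-baseline.

Group comparisons follow a normality-gated tree: Shapiro-Wilk (α = 0.05,
each group) routes to Welch ANOVA + t tests (equal/unequal variance decided
by a two-sided F test) or to Kruskal-Wallis + Mann-Whitney U with Levene's
test recorded; paired designs use repeated-measures ANOVA/paired t or
Friedman/Wilcoxon. Holm-Bonferroni (implemented in-package, cross-checked
against statsmodels) is applied within explicitly declared families —
family membership is a required input because there is no universal rule
for it. One-tailed contrasts test "first group greater". Empirical type-I
error of the full tree is ≤0.06 over 1000 seeded null cohorts.

## Synthetic data

The generators emulate the study's inputs with known ground truth:

* **Vessels** — 14 slices at 0.5 mm (a 6.5 mm stack), baseline radius
  0.25 mm; a raised-cosine radius dip centred on a slice station at 3.0 mm,
  1.5 mm long, reaching √(area fraction) × baseline radius (default area
  fraction 0.14, a severe cuff stenosis).
* **Waveforms** — a raised-cosine systolic pulse (peak 0.25 m/s) on a
  diastolic baseline solved so the discrete mean is exactly 0.10 m/s over a
  0.12 s cycle (500 bpm), with an optional early-diastolic reverse lobe
  reaching exactly −reversal_depth × peak. Peak, mean and minimum are
  attained exactly at sample points.
* **Histology** — concentric or eccentric lumen/IEL/EEL circles sized to a
  target intima fraction, with exactly ⌊fraction × N⌋ positive pixels
  (binary) or values rescaled to an exact normalized sum (greyscale),
  constructed with the same rasterizer the quantifier uses so recovery is
  exact (binary) or 10⁻⁹-relative (greyscale).
* **Cohorts** — tidy per-mouse tables with Gaussian group effects.

All generators are pure functions of their parameters and a seed. The
default physiology (radius, period, velocities) is typical for a mouse
common carotid and places simulated baseline peak-systolic WSS near
4 μ V_peak/R = 14 Pa, the physiological range for this vessel; absolute
values are not taken from any cohort (the study conditions are reported
percent-of-baseline), so they are package defaults, overridable everywhere.

What the synthetic data does **not** emulate: imaging physics (MRI partial
volume, Doppler angle error, speckle), segmentation error, vessel curvature
and non-circular lumens, wall compliance, and biological variability in
waveform shape. Passing tests therefore demonstrate correctness of the
computational chain on idealized inputs, not robustness to real-data
artefacts.

## Numerical choices and problem sizes

Default runs use the full zoned grid (≈12k nodes for the stenotic vessel,
≈4.5k for the uniform one) at 1000 steps/cycle for 3 cycles; a complete
stenotic simulation takes ~30 s on one CPU, and the whole validation suite
a few minutes. Halving the time step changes region TAWSS by far less than
1% (the cycle-convergence measurement bounds the temporal error). Ties in
peak-systole detection go to the earliest phase; degenerate inputs
(constant waveforms, empty intima, zero-variance groups) return defined
values or explicit missing markers as documented on each function.

## Known limitations

* The axisymmetric reduction cannot represent curvature-induced secondary
  flows or non-circular lumens; transverse WSS components are identically
  zero, so cross-flow multidirectionality indices are meaningless here.
* The plug-inlet corner is a genuine singularity; wall shear within ~2
  diameters of the inlet extension is less accurate (the analysis regions
  never touch it).
* With reverse flow through the inlet plane (waveforms with deep reversal),
  incoming fluid is assumed irrotational; strong sustained reversal would
  need a longer inlet extension.
* Observer-dependent steps of the histology workflow (threshold selection,
  viability flagging) are inputs, not algorithms.
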