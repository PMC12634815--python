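# Methods

This package re-creates, end to end, a computational study of pulsatile
cerebrospinal-fluid (CSF) flow through the cerebral aqueduct: how much
CSF a heartbeat displaces, how the flow is characterized by a Reynolds
number, and how much irreversible mixing the pulsation produces.  The
subject-level MRI data behind the original cohort statistics are not
publicly available, so every stage runs on synthetic subjects whose
statistical structure matches the published summary values.  What the
pipeline can honestly reproduce is therefore *mechanism and method* —
solver correctness against analytic oracles, mesh independence,
statistic definitions, parameter recovery, and the direction of the
Reynolds-mixing relationship — not patient-specific numbers.

## Synthetic cohort

Each subject carries demographics (age, sex, weight), ventricular
volumes (lateral, third, fourth), an aqueduct diameter D, a cardiac
period T_c, a representative velocity U, a stroke volume SV and an
8-phase cardiac-gated flow waveform Q(t).

All marginals are independent truncated Gaussians (only means and SDs
are published, so Gaussian is the minimal assumption); truncation
floors keep every quantity physical (D >= 0.8 mm, T_c >= 0.4 s, ages
>= 18 y, volumes > 0).  Healthy defaults: age 52 +/- 18 y, weight
60 +/- 11 kg, LV/3V/4V volumes 23.3 +/- 11.8 / 1.1 +/- 0.5 /
1.6 +/- 0.3 ml, D = 2.82 +/- 0.56 mm, T_c = 0.9 +/- 0.08 s (cardiac
period is not reported; 0.9 s is a resting heart rate of ~67 bpm).

The healthy group's velocity is functionally tied to diameter through
the inverse relation

    U = a/D + eps,   a = 26.4 mm^2/s,  eps ~ N(0, 4.7 mm/s),

so the maximum Reynolds number Re = rho U D / mu (numerically U*D in
mm units for water-like CSF) is approximately conserved across
subjects: E[Re] ~ a = 26.4, and the noise SD of 4.7 mm/s is chosen so
SD(Re) ~ E[D] * SD(eps) ~ 13, matching the reported healthy spread
(28.6 +/- 13.3).  The iNPH contrast group instead draws Re directly
from N(58.0, 27.6) truncated positive and sets U = Re/D, which breaks
the inverse relation by construction; its aqueduct diameter
(3.1 +/- 0.6 mm) is not reported and is chosen as a plausible mildly
dilated aqueduct.

Stroke volume is **derived**, not drawn: the waveform is a sinusoid
(or an optional two-harmonic "biphasic" shape) with peak flow
Q_peak = U * A, A = pi (D/2)^2, and SV = 0.5 * integral |Q| dt.  For
the sinusoid SV = Q_peak T_c / pi, which puts the implied healthy SV
mean near 16 ul against the reported 15.3 +/- 7.8 ul — inside the
reported spread, and it guarantees that waveform, SV, U and Re are
mutually consistent for every subject.  Waveforms integrate to zero
net volume per cycle by construction (pure sine harmonics).

What the generator does **not** emulate: correlations among age,
weight and ventricular volumes (none are quantified), intra-subject
beat-to-beat variability, respiration-driven flow, and measured
waveform harmonic content (only stroke-volume and Re summaries are
published).  Tests passing on this cohort therefore validate the
machinery under the published first- and second-moment structure, not
the full physiology.

## Flow descriptors

`flow` computes the MRI-style descriptors on a common convention set:

- stroke volume SV = 0.5 * integral |Q| dt (trapezoid on the phase
  grid, periodic closure) — the mean of the systolic and diastolic
  displaced volumes, which reduces to the one-directional volume for a
  pure sinusoid;
- representative velocity U = max over phases of |Q|/A (Re is reported
  as the *maximum* Reynolds number in a cycle, with a fixed D);
- equivalent diameter D = mean over sections of 2 sqrt(A/pi);
- Re = rho U D / mu with rho = 1e3 kg/m^3, mu = 1e-3 Pa s (Newtonian
  CSF); interface units are mm-based and converted to SI internally;
- four evaluation planes at 20/40/60/80% of the aqueduct length; the
  consistency error is max over phases and sections of
  |Q_j(t) - Qbar(t)| normalized by max_t |Qbar| (peak of the mean
  series, so reversal phases with near-zero flow cannot blow up the
  ratio), and a case is excluded when the error strictly exceeds 25%.

## Idealized geometry and meshing

Patient-specific segmentations are replaced by a parametric
axisymmetric idealization: a straight axis z with a smooth radius
profile R(z) — lateral-ventricle chamber (moving wall), third
ventricle, the aqueduct as a circular tube of diameter D and length
12 mm (length is not reported; 12 mm is anatomically plausible and
configurable), and a fourth-ventricle segment shaped as a
volume-matched expanding funnel (smooth expansion then straight duct)
ending at the outflow plane.  Chamber bulge/exit radii are solved by
bisection so each chamber volume matches its target within well under
2%.  The desk-scale default reduces chamber volumes 10x while keeping
the aqueduct at true scale, preserving aqueduct Reynolds number and
dynamics at a fraction of the mesh size.

Meshing is structured: a polar triangulation of the unit disk (ring k
carries 6k nodes) is extruded along z, each cross-section scaled by
R(z), prisms split into tetrahedra by the global-vertex-order rule
(conforming by construction), and every element checked for positive
volume.  The ring count guarantees at least four elements across the
aqueduct diameter for base sizes <= D/4; the axial step grows with
R(z) in the chambers (capped at 4x), shrinks where R'(z) is steep to
bound prism shear, and stays near the base size in the last 3 mm
before the outflow plane.  Optional thin wall-refinement rings stand
in for boundary-layer prisms; they are off by default because the
validation cases meet their tolerances with local ring refinement
alone.

The outflow ("foramina") treatment is a declared design choice.  The
default labels the whole funnel end cap as one 0 Pa outflow plane —
the same single constant-pressure condition the original framework
applies over the foramina cross-sections — because it keeps the
discrete wall/outlet mass balance at ~0.3% of peak Q on the default
mesh.  A more literal variant with two separated foramen-analogue
disks (`outlet_mode="two-disks"`) is retained; its rigid separator
strip obstructs the outflow and costs ~2.5% of peak Q in flux-balance
residual at desk scale, which is why it is not the default.

## Flow solver

Incompressible Navier-Stokes on first-order tetrahedra, incremental
pressure-correction (fractional-step): explicit advection with
streamline-upwind (SUPG) stabilization, Crank-Nicolson implicit
diffusion, a pressure-Poisson projection with p = 0 on the outlet
label and homogeneous Neumann elsewhere, and a lumped-mass velocity
correction.  Velocity and pressure share the P1 basis; the projection
step provides the pressure stabilization, so no inf-sup pair is
needed.  The momentum equation is advanced in kinematic form in mm
units (nu = 1 mm^2/s for CSF); pressure is exported in Pa.

The moving lateral-ventricle wall imposes w(x,t) = alpha(t) n(x) with
a uniform normal speed alpha scaled so the *discrete* wall flux equals
-Q(t) to machine precision (nodal area vectors assembled from the
moving facets).  Wall displacements at cohort conditions are ~0.05 mm
against 0.7 mm elements, so the solver uses the linearized
small-displacement form of the moving-boundary problem: the wall
velocity is Dirichlet data on the fixed reference mesh and the mesh
velocity is neglected in the advection term (at these amplitudes the
ALE correction is two orders of magnitude below the resolved
velocities).  The Laplacian-smoothing mesh-motion operator is
implemented and tested separately and serves to export deformed
configurations.

Time stepping: dt = T_c/400 by default, rounded so stored phases fall
on steps.  At cohort Reynolds numbers this keeps the advective CFL
number far below one; the CFL number is monitored at run time and the
solve aborts with advice if it exceeds 1.5.  Three cycles are run and
the last is stored (40 phases); the L2 difference between cycle start
and end is ~0.2% of the peak velocity norm on the default case, well
inside the 2% periodicity tolerance.  Per-step logs record the
elementwise divergence norm and the wall+outlet flux residual; on the
default run the residual stays below 0.5% of peak Q at every step.

Validation oracles (run in the test suite): Poiseuille steady tube
flow at Re ~ 30 (centerline within 3% of 2Q/(pi R^2) at base D/8) and
Womersley oscillatory flow at alpha = 2 (amplitude and phase within 5%
of the analytic Bessel series; measured ~2.6% amplitude, ~0.005 rad
phase).  The mesh-independency protocol (1.4/0.7/0.35 mm classes,
scaled by D/2.82) gives a medium-vs-fine difference of ~1.2% in peak
area-averaged aqueduct velocity.

## Particle tracking

Massless tracers seed an axis-aligned lattice anchored at the bounding
box minimum corner, keeping points strictly inside the domain
(positive barycentric coordinates).  Desk-scale default spacing is
0.5 mm (~2e4 particles; the full-scale 0.25 mm remains a config
option).  Advection is RK4 (RK2 optional) with 4 substeps per stored
phase through the single stored cycle extended periodically — linear
time interpolation, barycentric (P1-exact) space interpolation, a
uniform-grid cell locator with last-tet caching, all compiled with
numba.  Particles whose next position leaves the mesh are frozen at
their last in-domain position and marked exited; they never re-enter
and count as outside every evaluation subdomain.  Integrator checks:
exactness for uniform fields, closure of solid-body-rotation orbits to
1e-3 of the radius per revolution, and forward/backward reversibility
through a frozen field.

## Mixing statistic

The evaluation region Gamma is the tight axis-aligned bounding box of
the aqueduct.  At scales i in {2, 4, 6, 8, 10} the box is split into
i^3 equal subdomains (half-open binning, top face closed).  Per
subdomain, among the particles whose final position lies inside,
N_in originated in the same subdomain and N_out elsewhere;
c = N_out/(N_in + N_out), and empty subdomains contribute c = 0 (no
evidence of exchange; exclusion from the average is available via
config).  The per-scale degree m_i is the root mean square of c over
the i^3 subdomains and the mix-norm m is the RMS of the five m_i.

Two published-formula ambiguities are resolved by declared decisions.
First, the printed per-scale and aggregate formulas are roots of
*unnormalized* sums, which contradicts both their textual description
("root mean square") and the stated [0, 1] range; this package
implements the true RMS at both levels (the printed variant is
available as `normalization="unnormalized"` for comparison).  Second,
occupancy is decided by final position ("particle exchange ratio"
reading); the alternative initial-residents reading ("particles that
remain") is implemented as `membership="initial"`.  A brute-force
double-loop oracle reproduces the optimized path bit-exactly on
counts and to 1e-12 on norms.

## Statistics layer

Two-tailed Mann-Whitney U tests at alpha = 0.05 (exact permutation
distribution for min(n) <= 8 without ties, tie-corrected normal
approximation otherwise; identical samples return p = 1 by
convention); under the null at the study's group sizes (19, 28) the
measured type-I error over 2000 replicates is ~0.048.  The inverse
regression U = a/D is least squares on the transformed regressor
without intercept, a = sum(U/D)/sum(1/D^2), with R^2 against the
mean-of-U baseline (negative R^2 is admissible and expected for the
iNPH group).  Outliers follow the literal reading of the published
rule — strictly outside [Q1, Q3] with median-exclusive (Tukey hinge)
quartiles — with the conventional 1.5 IQR fences available as
`rule="tukey"`.  Age groups split at 65 years (>= 65 is "older").  No
multiple-testing correction is applied, mirroring the original
analysis; the report metadata says so.

## Orchestration and problem sizes

`pipeline.run_subject`/`run_cohort` chain the stages with per-stage
structured error records (one subject's failure never aborts a
cohort), content-hash caching, and YAML-round-trip run configs.  Two
physics levels: `waveform` computes descriptors analytically from the
waveform (used for population statistics at full cohort size) and
`full` runs geometry -> mesh -> CFD -> tracking -> mixing.

Default problem sizes, chosen as the package's standard desk-scale
study conditions: 0.7 mm base mesh (~8e3 tets), 400 time steps and 3
cycles per solve (~13 s), 40 stored phases, 0.5 mm particle spacing
(~2e4 tracers), 20 tracking cycles, five mixing scales.  The
Reynolds-sweep analysis uses six stroke volumes (7-63 ul) spanning
Re ~ 10-90 on one fixed geometry and observes a monotone increase of
the mix-norm with Re (Spearman rho = 1.00 in the default sweep, OLS
slope ~ 0.004 per Re unit with R^2 ~ 0.76), reproducing the direction
— not the coefficients — of the published Re-mixing relationship.
Absolute mix-norm levels in the idealized geometry run above
patient-specific healthy values; only trends transfer.

## Known limitations

- The idealized axisymmetric geometry cannot reproduce
  subject-specific secondary flows from aqueduct curvature or chamber
  asymmetry; mixing magnitudes are therefore not comparable to
  patient-specific values, only trends are.
- The linearized wall treatment is valid for the small wall
  displacements of cohort-scale stroke volumes; it would need the full
  moving-mesh path for chamber-scale deformations.
- No fluid-structure interaction, non-Newtonian rheology, turbulence
  modelling or respiration forcing (flow is laminar at cohort Re).
- P1/P1 projection controls divergence weakly; the wall/outlet flux
  imbalance is the honest quality metric and is logged every step.
- Exact-permutation Mann-Whitney is limited to small samples; larger
  samples use the standard tie-corrected normal approximation.
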