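# aqflow

Pulsatile cerebrospinal-fluid (CSF) flow and mixing in the cerebral
aqueduct — a tested, reusable pipeline for the computational side of
aqueductal flow studies: synthetic cohorts with MRI-style flow
descriptors, idealized ventricle–aqueduct geometries, a moving-wall
finite-element Navier–Stokes solver, Lagrangian particle tracking, the
multiscale mix-norm mixing statistic, and the population-level
Reynolds-number similarity analysis.

## Who this is for

Researchers in biofluid mechanics and neuroimaging who want to study
aqueductal CSF dynamics — in particular the contrast between healthy
flow and the hyperdynamic flow of idiopathic normal-pressure
hydrocephalus (iNPH) — without access to subject-level 4D-flow MRI.
Every stage runs on synthetic subjects whose statistical structure
matches published cohort summaries, so the machinery is fully testable
offline.

## The science in brief

CSF oscillates through the cerebral aqueduct (the narrow channel
between the third and fourth ventricles) in sync with the heartbeat.
Per subject, the flow is summarized by the stroke volume
SV = ½∫|Q(t)|dt, the representative velocity U = max|Q|/A, and the
maximum Reynolds number

    Re = ρUD/μ        (ρ = 10³ kg/m³, μ = 10⁻³ Pa·s)

with D the aqueduct diameter.  In healthy subjects U and D follow an
inverse relation U = a/D (a ≈ 26.4 mm²/s), so Re is approximately
conserved across the population; iNPH patients break this similarity
(Re ≈ 58 ± 28, no inverse relation).  To quantify what the pulsation
does, tracer particles are advected through the computed velocity
field for 20 cardiac cycles and their exchange is measured by the
mix-norm: the aqueduct bounding box Γ is split into i×i×i subdomains
(i = 2, 4, 6, 8, 10), each subdomain scores c = N_out/(N_in + N_out)
over its final-time occupants, m_i is the RMS of c at scale i, and the
mix-norm m is the RMS of the five m_i — 0 for completely separated,
1 for completely mixed.  Mixing rises with Re.

## Worked example

One subject at the healthy-cohort means (D = 2.82 mm, SV = 15.3 µl,
T_c = 1 s), full chain at desk scale:

```python
import numpy as np
from aqflow import mixing, tracking
from aqflow.cohort import SubjectRecord, generate_waveform
from aqflow.flow import FluidProps, metrics_from_field
from aqflow.geometry import build_geometry, mesh_geometry
from aqflow.solver import SolverConfig, build_wall_program, solve_cycle

subject = SubjectRecord(
    id="S0", group="healthy", sex="M", age=52.0, weight=60.0,
    lv_volume=23.3, v3_volume=1.1, v4_volume=1.6,
    aqueduct_diameter=2.82, aqueduct_length=12.0, cardiac_period=1.0,
    velocity=15.3 * np.pi / 6.246, stroke_volume=15.3,
    waveform=generate_waveform(15.3, 1.0, 8),
)
mesh = mesh_geometry(build_geometry(subject), 0.7)
bc = build_wall_program(mesh, subject.waveform)
field = solve_cycle(mesh, bc, FluidProps(), SolverConfig())
met = metrics_from_field(subject, field)

loc = tracking.build_locator(mesh)
pset = tracking.seed_particles(mesh, 0.5, loc)
out = tracking.advect(pset, field, tracking.TrackingConfig(n_cycles=20), loc)
res = mixing.compute_mixing(out, mixing.build_grid(mesh))
print(f"Re = {met.reynolds:.1f}, consistency error = {met.consistency_error:.3f}")
print(f"mix-norm m = {res.mix_norm:.3f}")
```

This prints

```
Re = 22.0, consistency error = 0.004
mix-norm m = 0.581
```

Re ≈ 22 is the simulated subject's maximum Reynolds number, recovered
from the solved field by the four-section flow metric (it matches the
nominal U·D ≈ 21.7 up to discretization of the section area).  The
consistency error of 0.4% across the four aqueduct sections confirms
the solution conserves flow along the aqueduct (cases above 25% would
be excluded, mirroring the MRI quality rule).  The mix-norm of ≈ 0.58
after 20 cycles says that over half of the aqueduct's occupancy,
averaged across scales, has been exchanged.  Absolute mixing levels in
the idealized geometry run higher than patient-specific healthy values
(its smooth funnel outflow recirculates more tracer through the
aqueduct box); the quantity that carries over is the trend — the
mix-norm rises monotonically with Re, as `06_re_mixing_sweep.py`
shows (Spearman ρ = 1.00 over Re ≈ 10–90).

The numbered drivers under `analysis/` run the full study:
`01_generate_cohort.py` (synthetic healthy + iNPH cohorts),
`02_population_statistics.py` (Mann–Whitney comparisons, inverse
regression per group), `03_mesh_convergence.py` (three-level mesh
independency), `04_solver_validation.py` (Poiseuille and Womersley
oracles), `05_subject_simulation.py` (full chain with VTU export),
`06_re_mixing_sweep.py` (mix-norm vs Re over six stroke volumes).
Each writes its tables under `results/`.

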