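"""Analytic validation of the flow solver on straight-tube benchmarks.

Poiseuille: steady piston-driven flow at Re ~ 30; the centerline
velocity eight diameters downstream is compared with 2Q/(pi R^2).
Womersley: oscillatory flow at Womersley number alpha = 2; amplitude
and phase of the axial velocity are compared with the analytic Bessel
series at several radii.  Writes results/validation/validation.json.
"""

import json
from pathlib import Path

import numpy as np
from scipy.special import jv

from aqflow.cohort import FlowWaveform, generate_waveform
from aqflow.flow import FluidProps
from aqflow.geometry import tube_mesh
from aqflow.solver import SolverConfig, build_wall_program, solve_cycle

OUT = Path("results/validation")


def poiseuille() -> dict:
    R, L = 1.41, 28.0
    area = np.pi * R * R
    q = 10.64 * area
    wf = FlowWaveform(times=np.linspace(0, 5.999, 8), flow_rate=np.full(8, q),
                      period=6.0)
    mesh = tube_mesh(R, L, 0.35)
    bc = build_wall_program(mesh, wf, interp="linear")
    fld = solve_cycle(mesh, bc, FluidProps(), SolverConfig(n_cycles=1))
    zs, npl = mesh.meta["layer_z"], mesh.meta["nodes_per_layer"]
    k = int(np.argmin(np.abs(zs - 8 * 2 * R)))
    vz = float(fld.velocity[-1][k * npl, 2])
    u_exact = 2 * q / area
    return {"re": 30.0, "centerline": vz, "analytic": u_exact,
            "rel_error": abs(vz - u_exact) / u_exact}


def womersley() -> dict:
    R, L = 1.41, 28.0
    area = np.pi * R * R
    alpha, nu = 2.0, 1.0
    om = alpha**2 * nu / R**2
    period = 2 * np.pi / om
    q0 = 10.64 * area
    mesh = tube_mesh(R, L, 0.35)
    bc = build_wall_program(mesh, generate_waveform(q0 * period / np.pi, period, 64))
    fld = solve_cycle(mesh, bc, FluidProps(), SolverConfig(n_cycles=3))
    lam = 1j**1.5 * alpha

    def u_hat(r):
        num = 1 - jv(0, lam * r / R) / jv(0, lam)
        den = 1 - 2 * jv(1, lam) / (lam * jv(0, lam))
        return (q0 / area) * num / den

    zs, npl = mesh.meta["layer_z"], mesh.meta["nodes_per_layer"]
    k = int(np.argmin(np.abs(zs - 8 * 2 * R)))
    t = fld.phase_times
    samples = []
    for node in (0, 1, 7):
        pt = mesh.points[k * npl + node]
        r = float(np.hypot(pt[0], pt[1]))
        sig = fld.velocity[:, k * npl + node, 2]
        c = 2 / len(t) * np.sum(sig * np.exp(-1j * om * t))
        ca = u_hat(r) / 1j
        samples.append({"r": r, "amp_rel_error": float(abs(abs(c) - abs(ca)) / abs(ca)),
                        "phase_error_rad": float(abs(np.angle(c / ca)))})
    return {"alpha": alpha, "samples": samples}


def main() -> None:
    results = {"poiseuille": poiseuille(), "womersley": womersley()}
    OUT.mkdir(parents=True, exist_ok=True)
    (OUT / "validation.json").write_text(json.dumps(results, indent=1))
    p = results["poiseuille"]
    print(f"Poiseuille centerline: {p['centerline']:.2f} vs {p['analytic']:.2f} mm/s "
          f"({100 * p['rel_error']:.2f}% error)")
    for s in results["womersley"]["samples"]:
        print(f"Womersley r={s['r']:.2f} mm: amplitude error "
              f"{100 * s['amp_rel_error']:.2f}%, phase error {s['phase_error_rad']:.4f} rad")
    print(f"\nwritten to {OUT}/")


if __name__ == "__main__":
    main()
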