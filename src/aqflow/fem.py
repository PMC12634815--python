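"""Low-level P1 finite-element operators on tetrahedral meshes.

Everything is assembled in mm units.  Velocity and pressure share the
same first-order nodal basis; the projection step supplies the pressure
stabilization (no inf-sup pair is needed for the incremental
pressure-correction scheme used by the solver).
"""

from __future__ import annotations

import numpy as np
import scipy.sparse as sp

from .mesh import TetMesh, tet_volumes


def p1_gradients(mesh: TetMesh) -> tuple[np.ndarray, np.ndarray]:
    """Constant basis-function gradients per element.

    Returns (grads, vols): grads[e, i, :] is grad(phi_i) on element e,
    vols[e] the (positive) element volume.
    """
    pts, tets = mesh.points, mesh.tets
    vols = tet_volumes(pts, tets)
    M = np.stack(
        [pts[tets[:, i]] - pts[tets[:, 0]] for i in (1, 2, 3)], axis=2
    )  # columns are edge vectors
    Minv = np.linalg.inv(M)
    g = np.empty((tets.shape[0], 4, 3))
    g[:, 1, :] = Minv[:, 0, :]
    g[:, 2, :] = Minv[:, 1, :]
    g[:, 3, :] = Minv[:, 2, :]
    g[:, 0, :] = -g[:, 1:, :].sum(axis=1)
    return g, vols


def lumped_mass(mesh: TetMesh, vols: np.ndarray) -> np.ndarray:
    """Row-sum lumped mass vector (volume units)."""
    ml = np.zeros(mesh.n_points)
    np.add.at(ml, mesh.tets.ravel(), np.repeat(vols / 4.0, 4))
    return ml


def stiffness(mesh: TetMesh, grads: np.ndarray, vols: np.ndarray) -> sp.csr_matrix:
    """Scalar Laplacian K_ij = integral grad(phi_i) . grad(phi_j)."""
    ne = mesh.n_tets
    ke = np.einsum("eid,ejd->eij", grads, grads) * vols[:, None, None]
    rows = np.repeat(mesh.tets, 4, axis=1).ravel()
    cols = np.tile(mesh.tets, (1, 4)).ravel()
    K = sp.coo_matrix(
        (ke.ravel(), (rows, cols)), shape=(mesh.n_points, mesh.n_points)
    )
    return K.tocsr()


def divergence_rhs(mesh, grads, vols, v: np.ndarray) -> np.ndarray:
    """Weak divergence b_i = integral phi_i div(v), v nodal (n, 3)."""
    div_e = np.einsum("eid,eid->e", grads, v[mesh.tets])
    out = np.zeros(mesh.n_points)
    np.add.at(out, mesh.tets.ravel(), np.repeat(div_e * vols / 4.0, 4))
    return out


def element_divergence(mesh, grads, v: np.ndarray) -> np.ndarray:
    """Elementwise constant div(v)."""
    return np.einsum("eid,eid->e", grads, v[mesh.tets])


def pressure_gradient_rhs(mesh, grads, vols, p: np.ndarray) -> np.ndarray:
    """Weak gradient G_i = integral phi_i grad(p), output (n, 3)."""
    gp = np.einsum("eid,ei->ed", grads, p[mesh.tets])  # (ne,3)
    out = np.zeros((mesh.n_points, 3))
    w = vols / 4.0
    for d in range(3):
        np.add.at(out[:, d], mesh.tets.ravel(), np.repeat(gp[:, d] * w, 4))
    return out


def element_sizes(vols: np.ndarray) -> np.ndarray:
    """Isotropic element length scale h_e (regular-tet edge length)."""
    return (12.0 * vols / np.sqrt(2.0)) ** (1.0 / 3.0)


def advection_rhs(
    mesh,
    grads,
    vols,
    h_e,
    v: np.ndarray,
    adv: np.ndarray,
    nu: float,
    dt: float,
    supg: bool = True,
) -> np.ndarray:
    """Galerkin + SUPG advection term, N(adv)v, nodal (n, 3).

    Elementwise-constant advection velocity (nodal mean); the SUPG
    contribution adds tau * (a . grad(phi_i)) (a . grad(v)) streamline
    stabilization with the standard tau combining the time-step,
    advective and diffusive limits.
    """
    tets = mesh.tets
    a_e = adv[tets].mean(axis=1)  # (ne,3)
    gv = np.einsum("eid,eic->ecd", grads, v[tets])  # (ne, comp, dim)
    conv = np.einsum("ed,ecd->ec", a_e, gv)  # (ne, 3)
    out = np.zeros((mesh.n_points, 3))
    w_gal = vols / 4.0
    for c in range(3):
        np.add.at(out[:, c], tets.ravel(), np.repeat(conv[:, c] * w_gal, 4))
    if supg:
        amag = np.linalg.norm(a_e, axis=1)
        inv_tau2 = (2.0 / dt) ** 2 + (2.0 * amag / h_e) ** 2 + (
            4.0 * nu / h_e**2
        ) ** 2 * 9.0
        tau = 1.0 / np.sqrt(inv_tau2)
        a_dot_g = np.einsum("ed,eid->ei", a_e, grads)  # (ne, 4)
        w = tau * vols
        contrib = a_dot_g[:, :, None] * (w[:, None, None] * conv[:, None, :])
        for c in range(3):
            np.add.at(out[:, c], tets.ravel(), contrib[:, :, c].ravel())
    return out


def dirichlet_rows_identity(A: sp.csr_matrix, nodes: np.ndarray) -> sp.csr_matrix:
    """Replace the given rows of A by identity rows (in-place friendly)."""
    A = A.tolil()
    A[nodes, :] = 0.0
    A[nodes, nodes] = 1.0
    return A.tocsr()
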