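"""Linear-elastic boundary-value problem for gel stress reconstruction.

The gel is modelled as an isotropic Hookean solid in static equilibrium,
div T = 0 with T = 2 mu eps + lam tr(eps) I. Displacements interpolated
from bead measurements are imposed on the tissue-matrix interface; the
outer gel boundary is held at zero displacement (the gel is anchored to
the chamber far from the tissue). The solve uses isoparametric 4- or
10-node tetrahedra with a 4-point Gauss rule and a sparse direct solver.
Cauchy stress is evaluated per element and recovered at interface nodes by
volume-weighted averaging; tractions follow as t_i = T_ij n_j with n the
outward unit normal (pointing from the tissue into the gel).

Sign convention: an inward pull on the matrix (beads displaced toward the
tissue) stretches the gel radially, so the interface normal stress t.n is
positive; a positive normal component is labelled tensile.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable, Mapping

import numpy as np
import pandas as pd
from scipy import sparse
from scipy.sparse.linalg import spsolve

from .materials import ElasticMaterial
from .mesh import GelDomainMesh, TET_EDGES

# 4-point Gauss rule on the reference tetrahedron, exact to degree 2
_QA, _QB = 0.5854101966249685, 0.1381966011250105
_QPOINTS = np.array([
    [_QA, _QB, _QB], [_QB, _QA, _QB], [_QB, _QB, _QA], [_QB, _QB, _QB]])
_QWEIGHTS = np.full(4, 1.0 / 24.0)

_DLAM = np.array([[-1.0, -1.0, -1.0],
                  [1.0, 0.0, 0.0],
                  [0.0, 1.0, 0.0],
                  [0.0, 0.0, 1.0]])


_CORNER_REF = np.array([[0.0, 0.0, 0.0], [1.0, 0.0, 0.0],
                        [0.0, 1.0, 0.0], [0.0, 0.0, 1.0]])


def _node_ref_coords(order: int) -> np.ndarray:
    if order == 1:
        return _CORNER_REF
    mids = np.array([0.5 * (_CORNER_REF[i] + _CORNER_REF[j])
                     for i, j in TET_EDGES])
    return np.vstack([_CORNER_REF, mids])


def _shape_grads_at(points: np.ndarray, order: int) -> np.ndarray:
    """dN/dxi at reference points: array (n_pts, n_nodes, 3)."""
    grads = []
    for xi, eta, zeta in points:
        lam = np.array([1.0 - xi - eta - zeta, xi, eta, zeta])
        if order == 1:
            grads.append(_DLAM.copy())
            continue
        g = np.empty((10, 3))
        for a in range(4):
            g[a] = (4.0 * lam[a] - 1.0) * _DLAM[a]
        for k, (i, j) in enumerate(TET_EDGES):
            g[4 + k] = 4.0 * (lam[i] * _DLAM[j] + lam[j] * _DLAM[i])
        grads.append(g)
    return np.asarray(grads)


def _shape_grads(order: int) -> np.ndarray:
    """dN/dxi at each quadrature point: array (n_qp, n_nodes, 3)."""
    return _shape_grads_at(_QPOINTS, order)


@dataclass
class FEMSolution:
    """Nodal displacement solution of the gel boundary-value problem."""

    mesh: GelDomainMesh
    material: ElasticMaterial
    u: np.ndarray  # (n_nodes, 3), um


@dataclass
class StressField:
    """Cauchy stress per element (Pa): element means plus per-element
    values at the element's own nodes, used for boundary recovery."""

    mesh: GelDomainMesh
    element_stress: np.ndarray       # (M, 3, 3) element-mean, symmetric
    element_volume: np.ndarray       # (M,)
    element_nodal_stress: np.ndarray  # (M, nen, 3, 3) at element nodes
    _nodal: np.ndarray | None = field(default=None, repr=False)

    def nodal_stress(self) -> np.ndarray:
        """Stress recovered at mesh nodes: each adjacent element's stress
        evaluated at the node, combined by element-volume weighting.
        Evaluating at the node (rather than averaging element means) keeps
        the steep near-interface stress gradients from being smeared."""
        if self._nodal is None:
            n = self.mesh.n_nodes
            acc = np.zeros((n, 3, 3))
            wacc = np.zeros(n)
            conn = self.mesh.tets
            for a in range(conn.shape[1]):
                np.add.at(acc, conn[:, a],
                          self.element_nodal_stress[:, a]
                          * self.element_volume[:, None, None])
                np.add.at(wacc, conn[:, a], self.element_volume)
            if np.any(wacc[np.unique(conn)] == 0):  # pragma: no cover
                raise ValueError("node without adjacent element volume")
            with np.errstate(invalid="ignore", divide="ignore"):
                self._nodal = acc / np.where(wacc > 0, wacc, 1.0)[:, None, None]
        return self._nodal


@dataclass
class TractionField:
    """Tractions t = T n on the tissue-matrix interface.

    One row per interface node: position, traction vector (Pa), magnitude
    |t|, normal component t.n (positive = tensile: the matrix is pulled
    toward the tissue and the gel is in tension at the interface), outward
    normal and nodal area (um^2).
    """

    node_ids: np.ndarray
    points: np.ndarray
    t: np.ndarray
    magnitude: np.ndarray
    normal_component: np.ndarray
    normals: np.ndarray
    nodal_area: np.ndarray

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({
            "node": self.node_ids,
            "x": self.points[:, 0], "y": self.points[:, 1],
            "z": self.points[:, 2],
            "t_x": self.t[:, 0], "t_y": self.t[:, 1], "t_z": self.t[:, 2],
            "t_mag": self.magnitude, "t_n": self.normal_component,
        })

    def net_force(self) -> np.ndarray:
        """Approximate integral of t over the interface (Pa*um^2); zero in
        continuum equilibrium with no body forces."""
        return (self.t * self.nodal_area[:, None]).sum(axis=0)


def assemble_stiffness(
    mesh: GelDomainMesh, material: ElasticMaterial, chunk: int = 4096
) -> sparse.csr_matrix:
    """Global stiffness matrix for isotropic linear elasticity."""
    mu, lam = material.mu, material.lam
    conn = mesh.tets
    M, nen = conn.shape
    ndof = 3 * mesh.n_nodes
    dN = _shape_grads(mesh.order)  # (Q, nen, 3)
    nq = len(_QWEIGHTS)

    edof = (3 * conn[:, :, None] + np.arange(3)[None, None, :]).reshape(M, 3 * nen)
    rows_all, cols_all, vals_all = [], [], []
    eye3 = np.eye(3)
    for s in range(0, M, chunk):
        e = slice(s, min(s + chunk, M))
        X = mesh.nodes[conn[e]]                      # (m, nen, 3)
        m = X.shape[0]
        Ke = np.zeros((m, 3 * nen, 3 * nen))
        for q in range(nq):
            J = np.einsum("mai,aj->mij", X, dN[q])   # dx_i/dxi_j
            detJ = np.linalg.det(J)
            if np.any(detJ <= 0):
                raise ValueError("non-positive Jacobian in element")
            invJ = np.linalg.inv(J)
            g = np.einsum("aj,mji->mai", dN[q], invJ)  # dN_a/dx_i
            w = _QWEIGHTS[q] * detJ
            t_lam = np.einsum("m,mai,mbj->maibj", w * lam, g, g)
            t_mu = np.einsum("m,maj,mbi->maibj", w * mu, g, g)
            gg = np.einsum("m,mak,mbk->mab", w * mu, g, g)
            t_iso = np.einsum("mab,ij->maibj", gg, eye3)
            Ke += (t_lam + t_mu + t_iso).reshape(m, 3 * nen, 3 * nen)
        ed = edof[e]
        rows_all.append(np.repeat(ed, 3 * nen, axis=1).ravel())
        cols_all.append(np.tile(ed, (1, 3 * nen)).ravel())
        vals_all.append(Ke.ravel())
    K = sparse.coo_matrix(
        (np.concatenate(vals_all),
         (np.concatenate(rows_all), np.concatenate(cols_all))),
        shape=(ndof, ndof)).tocsr()
    return K


def solve_displacement_bvp(
    mesh: GelDomainMesh,
    material: ElasticMaterial,
    interface_displacement_fn: Callable[[np.ndarray], np.ndarray],
    outer_condition: str | Callable[[np.ndarray], np.ndarray] = "zero",
) -> FEMSolution:
    """Solve static linear elasticity with Dirichlet data on both boundaries.

    ``interface_displacement_fn`` maps (k, 3) interface node coordinates to
    (k, 3) displacements (typically the bead-field interpolant from
    :func:`geltrax.kinematics.interpolate`). ``outer_condition`` is "zero"
    (default, gel anchored far away) or a callable like the interface one;
    "free" leaves the outer boundary traction-free.

    Raises on singular or non-finite solves.
    """
    ifc, out = mesh.interface_nodes, mesh.outer_nodes
    n = mesh.n_nodes
    u = np.zeros((n, 3))
    fixed = np.zeros(n, bool)
    u[ifc] = np.asarray(interface_displacement_fn(mesh.nodes[ifc]), float)
    fixed[ifc] = True
    if outer_condition == "zero":
        fixed[out] = True
    elif outer_condition == "free":
        pass
    elif callable(outer_condition):
        u[out] = np.asarray(outer_condition(mesh.nodes[out]), float)
        fixed[out] = True
    else:
        raise ValueError(f"unknown outer_condition: {outer_condition!r}")
    if not np.any(fixed):
        raise ValueError("no Dirichlet constraints: singular system")

    K = assemble_stiffness(mesh, material)
    fixed_dof = np.repeat(fixed, 3)
    free_dof = ~fixed_dof
    uc = u.ravel()[fixed_dof]
    rhs = -K[free_dof][:, fixed_dof] @ uc
    Kff = K[free_dof][:, free_dof]
    uf = spsolve(Kff.tocsc(), rhs)
    if not np.all(np.isfinite(uf)):
        raise ValueError("linear solve failed (singular system?)")
    full = np.empty(3 * n)
    full[fixed_dof] = uc
    full[free_dof] = uf
    return FEMSolution(mesh=mesh, material=material, u=full.reshape(n, 3))


def cauchy_stress(solution: FEMSolution,
                  material: ElasticMaterial | None = None) -> StressField:
    """Element-mean Cauchy stress T = 2 mu eps + lam tr(eps) I."""
    mat = material or solution.material
    mesh = solution.mesh
    conn = mesh.tets
    dN = _shape_grads(mesh.order)
    X = mesh.nodes[conn]
    U = solution.u[conn]                             # (M, nen, 3)
    M, nen = conn.shape
    strain_acc = np.zeros((M, 3, 3))
    vol = np.zeros(M)
    for q in range(len(_QWEIGHTS)):
        J = np.einsum("mai,aj->mij", X, dN[q])
        detJ = np.linalg.det(J)
        invJ = np.linalg.inv(J)
        g = np.einsum("aj,mji->mai", dN[q], invJ)
        gradu = np.einsum("mai,maj->mij", U, g)      # du_i/dx_j
        eps = 0.5 * (gradu + gradu.transpose(0, 2, 1))
        w = (_QWEIGHTS[q] * detJ)[:, None, None]
        strain_acc += w * eps
        vol += _QWEIGHTS[q] * detJ

    def hooke(eps: np.ndarray) -> np.ndarray:
        tr = np.trace(eps, axis1=-2, axis2=-1)
        return 2.0 * mat.mu * eps + mat.lam * tr[..., None, None] * np.eye(3)

    T_mean = hooke(strain_acc / vol[:, None, None])

    dNn = _shape_grads_at(_node_ref_coords(mesh.order), mesh.order)
    T_nodes = np.empty((M, nen, 3, 3))
    for a in range(nen):
        J = np.einsum("mbi,bj->mij", X, dNn[a])
        invJ = np.linalg.inv(J)
        g = np.einsum("bj,mji->mbi", dNn[a], invJ)
        gradu = np.einsum("mbi,mbj->mij", U, g)
        T_nodes[:, a] = hooke(0.5 * (gradu + gradu.transpose(0, 2, 1)))
    return StressField(mesh=mesh, element_stress=T_mean, element_volume=vol,
                       element_nodal_stress=T_nodes)


def surface_tractions(stress: StressField,
                      mesh: GelDomainMesh | None = None) -> TractionField:
    """Traction vectors t_i = T_ij n_j at every interface node."""
    mesh = mesh or stress.mesh
    nodal_T = stress.nodal_stress()
    normals, areas = mesh.interface_normals()
    ids = mesh.interface_nodes
    t = np.einsum("kij,kj->ki", nodal_T[ids], normals)
    mag = np.linalg.norm(t, axis=1)
    tn = np.einsum("ki,ki->k", t, normals)
    return TractionField(node_ids=ids, points=mesh.nodes[ids], t=t,
                         magnitude=mag, normal_component=tn,
                         normals=normals, nodal_area=areas)


def traction_localization_summary(
    tractions: TractionField,
    region_labels: np.ndarray | Mapping[int, str],
) -> pd.DataFrame:
    """Per-region traction statistics on the interface.

    ``region_labels`` assigns every interface node to exactly one region
    (array aligned with the traction rows, or a mapping node id -> label).
    Reports per-region mean and max |t|, the area fraction of the whole
    surface's top-decile-|t| nodes falling in the region, and the tensile
    fraction (share of nodes with negative normal traction).
    """
    if isinstance(region_labels, Mapping):
        labels = np.array([region_labels[int(i)] for i in tractions.node_ids])
    else:
        labels = np.asarray(region_labels)
        if len(labels) != len(tractions.node_ids):
            raise ValueError("region labels must cover every interface node")
    mag, area = tractions.magnitude, tractions.nodal_area
    thresh = np.quantile(mag, 0.9)
    top = mag >= thresh
    top_area_total = float(area[top].sum())
    rows = []
    for lab in np.unique(labels):
        sel = labels == lab
        rows.append({
            "region": lab,
            "n_nodes": int(sel.sum()),
            "mean_t": float(mag[sel].mean()),
            "max_t": float(mag[sel].max()),
            "top_decile_share": float(area[sel & top].sum() / top_area_total)
            if top_area_total > 0 else 0.0,
            "area_fraction_top_decile": float(
                area[sel & top].sum() / area[sel].sum()),
            "tensile_fraction": float(
                (tractions.normal_component[sel] > 0).mean()),
        })
    return pd.DataFrame(rows)
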