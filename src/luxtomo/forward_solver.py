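"""Sparse solves, surface-fluence extraction, sensitivity construction and
multispectral stacking.

Systems are factorized once (SuperLU) and reused; the residual contract
||M x - b|| / ||b|| < tol (default 1e-10) is enforced, with a preconditioned
iterative fallback when the factorization fails.  The sensitivity matrix
A = Q M^-1 F~ (Q the measurement extraction, F~ the source-weight map from
nodal source density to right-hand side) is built by adjoint solves: one
transpose solve per measurable row, which is mathematically identical to
forming M^-1 F densely but avoids the full-dimension dense inverse.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import scipy.sparse as sp
import scipy.sparse.linalg as spla

from .fem_assembly import AssembledSystem
from .hybrid_coupling import COMPOSITE_PHI2_WEIGHT, HybridSystem

__all__ = [
    "SurfaceMeasurement",
    "SensitivityMatrix",
    "FactorizedSystem",
    "solve_forward",
    "composite_fluence",
    "surface_fluence",
    "select_fov_nodes",
    "build_sensitivity",
    "stack_multispectral",
]


@dataclass
class SurfaceMeasurement:
    """Photon fluence at measurable boundary nodes for one wavelength."""

    wavelength: float
    node_indices: np.ndarray  # original-mesh node indices, sorted
    values: np.ndarray
    provenance: str = "solver"

    def __post_init__(self):
        self.node_indices = np.asarray(self.node_indices, dtype=np.int64)
        self.values = np.asarray(self.values, dtype=np.float64)
        if self.node_indices.shape != self.values.shape:
            raise ValueError("indices/values length mismatch")
        if not np.isfinite(self.values).all():
            raise ValueError("non-finite fluence values")

    def to_csv(self, path, nodes_xyz: np.ndarray) -> None:
        data = np.column_stack([
            self.node_indices, nodes_xyz[self.node_indices],
            np.full(len(self.values), self.wavelength), self.values])
        np.savetxt(path, data, delimiter=",",
                   header="node,x,y,z,wavelength,fluence", comments="")

    @classmethod
    def from_csv(cls, path, provenance="file"):
        data = np.loadtxt(path, delimiter=",", skiprows=1, ndmin=2)
        return cls(wavelength=float(data[0, 4]),
                   node_indices=data[:, 0].astype(np.int64),
                   values=data[:, 5], provenance=provenance)


@dataclass
class SensitivityMatrix:
    """Rows = measurable surface nodes (stacked per wavelength), columns =
    source nodes on the original mesh."""

    A: np.ndarray
    node_indices: np.ndarray
    wavelengths: tuple[float, ...]

    @property
    def shape(self):
        return self.A.shape


class FactorizedSystem:
    """One-interface wrapper over direct (SuperLU) and iterative solves."""

    def __init__(self, M: sp.spmatrix, tol: float = 1e-10):
        self.M = M.tocsc()
        self.tol = tol
        try:
            self.lu = spla.splu(self.M)
        except RuntimeError:
            self.lu = None
            self.ilu = spla.spilu(self.M, drop_tol=1e-5, fill_factor=20)

    def solve(self, b: np.ndarray, trans: str = "N") -> np.ndarray:
        b = np.asarray(b, dtype=np.float64)
        if self.lu is not None:
            x = self.lu.solve(b, trans=trans)
        else:
            op = spla.LinearOperator(self.M.shape, self.ilu.solve)
            A = self.M if trans == "N" else self.M.T
            x, info = spla.gmres(A, b, rtol=self.tol / 10, M=op, maxiter=2000)
            if info != 0:
                raise RuntimeError(f"iterative solver failed (info={info})")
        nb = np.linalg.norm(b)
        if nb > 0:
            A = self.M if trans == "N" else self.M.T
            res = np.linalg.norm(A @ x - b) / nb
            if res > self.tol:
                raise RuntimeError(f"solver residual {res:.3e} above {self.tol:.1e}")
        return x


def solve_forward(system: HybridSystem | AssembledSystem, rhs: np.ndarray,
                  tol: float = 1e-10,
                  factorization: FactorizedSystem | None = None) -> np.ndarray:
    """Solve M x = rhs with the residual contract; returns the stacked field."""
    rhs = np.asarray(rhs, dtype=np.float64)
    if not rhs.any():
        return np.zeros_like(rhs)
    fac = factorization or FactorizedSystem(system.M, tol=tol)
    return fac.solve(rhs)


def composite_fluence(system: HybridSystem | AssembledSystem,
                      x: np.ndarray) -> np.ndarray:
    """Per-node physical fluence from a solution vector.

    Diffusion systems return x itself; SP3 systems the composite
    phi1 - (2/3) phi2; hybrid systems the composite on every original node.
    """
    if isinstance(system, HybridSystem):
        return system.composite_fluence(x)
    if system.node_layout == ("phi",):
        return x
    n = system.n_nodes
    return x[:n] + COMPOSITE_PHI2_WEIGHT * x[n:]


def select_fov_nodes(nodes_xyz: np.ndarray, boundary_nodes: np.ndarray,
                     axis=None, half_angle_deg: float = 180.0,
                     center=None) -> np.ndarray:
    """Measurable-node selection by an angular field-of-view predicate.

    Default keeps all boundary nodes.  With ``axis`` given, keeps boundary
    nodes whose direction from ``center`` (domain centroid by default) is
    within ``half_angle_deg`` of the axis.
    """
    boundary_nodes = np.asarray(boundary_nodes, dtype=np.int64)
    if axis is None:
        return np.sort(boundary_nodes)
    axis = np.asarray(axis, dtype=np.float64)
    axis = axis / np.linalg.norm(axis)
    c = nodes_xyz.mean(axis=0) if center is None else np.asarray(center)
    d = nodes_xyz[boundary_nodes] - c
    d /= np.maximum(np.linalg.norm(d, axis=1, keepdims=True), 1e-300)
    keep = d @ axis >= np.cos(np.deg2rad(half_angle_deg))
    return np.sort(boundary_nodes[keep])


def surface_fluence(system, x: np.ndarray, boundary_nodes: np.ndarray,
                    measurable: np.ndarray | None = None,
                    wavelength: float = 0.0) -> SurfaceMeasurement:
    """Composite fluence at the measurable boundary nodes, in sorted node
    order.  Raises when the selection is empty or includes non-boundary nodes.
    """
    sel = np.sort(np.asarray(
        boundary_nodes if measurable is None else measurable, dtype=np.int64))
    if sel.size == 0:
        raise ValueError("empty measurable-node selection")
    if not np.isin(sel, boundary_nodes).all():
        raise ValueError("measurable selection contains non-boundary nodes")
    phi = composite_fluence(system, x)
    return SurfaceMeasurement(wavelength=wavelength, node_indices=sel,
                              values=phi[sel])


def _source_map(system):
    if isinstance(system, HybridSystem):
        return system.source_map()
    return system.source_map()


def _measurement_map(system, sel):
    if isinstance(system, HybridSystem):
        return system.measurement_map(sel)
    n = system.n_nodes
    dim = system.dimension
    if system.node_layout == ("phi",):
        rows = np.arange(sel.size)
        return sp.coo_matrix((np.ones(sel.size), (rows, sel)),
                             shape=(sel.size, dim)).tocsr()
    rows = np.repeat(np.arange(sel.size), 2)
    cols = np.column_stack([sel, n + sel]).ravel()
    vals = np.tile([1.0, COMPOSITE_PHI2_WEIGHT], sel.size)
    return sp.coo_matrix((vals, (rows, cols)), shape=(sel.size, dim)).tocsr()


def build_sensitivity(system, measurable: np.ndarray, wavelength: float = 0.0,
                      factorization: FactorizedSystem | None = None,
                      block: int = 128) -> SensitivityMatrix:
    """Sensitivity A = Q M^-1 F~ by adjoint solves (block transpose solves).

    A[i, k] is the fluence at measurable node i produced by a unit source
    density at node k; A @ S equals the forward-solved surface fluence.
    """
    sel = np.sort(np.asarray(measurable, dtype=np.int64))
    fac = factorization or FactorizedSystem(system.M)
    Q = _measurement_map(system, sel).toarray()
    FP = (system.F @ _source_map(system)).tocsc()
    A = np.empty((sel.size, FP.shape[1]))
    for lo in range(0, sel.size, block):
        hi = min(lo + block, sel.size)
        Y = fac.solve(Q[lo:hi].T, trans="T")  # (dim, nb)
        A[lo:hi] = (FP.T @ Y).T
    return SensitivityMatrix(A=A, node_indices=sel, wavelengths=(wavelength,))


def stack_multispectral(sensitivities: list[SensitivityMatrix],
                        measurements: list[SurfaceMeasurement]
                        ) -> tuple[SensitivityMatrix, np.ndarray]:
    """Vertically stack per-wavelength sensitivity blocks and measurements.

    Blocks keep the order given (the convention lists the later wavelength
    first); all blocks must share the source-node space.
    """
    if len(sensitivities) != len(measurements):
        raise ValueError("need one measurement vector per sensitivity block")
    ncols = {s.A.shape[1] for s in sensitivities}
    if len(ncols) != 1:
        raise ValueError("sensitivity blocks differ in source-node dimension")
    for s, m in zip(sensitivities, measurements):
        if s.A.shape[0] != m.values.size:
            raise ValueError("block row count does not match its measurement")
    A = np.vstack([s.A for s in sensitivities])
    phi = np.concatenate([m.values for m in measurements])
    stacked = SensitivityMatrix(
        A=A,
        node_indices=np.concatenate([s.node_indices for s in sensitivities]),
        wavelengths=tuple(w for s in sensitivities for w in s.wavelengths),
    )
    return stacked, phi
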