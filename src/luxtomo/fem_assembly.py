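"""Linear (P1) finite-element assembly of the diffusion and SP3 systems.

Element integrals on linear tetrahedra have closed forms: the mass matrix is
V/10 on the diagonal and V/20 off it, the stiffness matrix is V g_j . g_k with
g_i the (constant) barycentric gradients, and the boundary-face mass matrix of
a linear triangle is area/6 diagonal, area/12 off-diagonal.  Optical properties
are piecewise constant per tet (organ-wise tables).

The diffusion system is M Phi = F S with
M = sum_e [D_e K_e + mu_a,e M_e] + sum_faces M_f / (2 A_n) and F the global
mass matrix.  The SP3 system is the 2n x 2n block system in the composite
moments (phi1, phi2):

  [ K/(3 mu_a1) + mu_a M + xi11 Bf      -(2/3) mu_a M + xi12 Bf ]
  [ -(2/3) mu_a M + xi21 Bf             K/(7 mu_a3) + ((4/9) mu_a
                                          + (5/9) mu_a2) M + xi22 Bf ]

with right-hand side blocks {S, -(2/3) S} and F = blockdiag(mass, mass).  The
physical fluence is the composite combination Phi = phi1 - (2/3) phi2.  The
-(2/3) mu_a volume coupling appears in both off-diagonal blocks by default
(the canonical SP3 weak form); ``include_m12_volume=False`` restores the
asymmetric variant for sensitivity checks.

Assembly iterates elements in mesh order with duplicate-summing COO
accumulation, so repeated runs produce bit-identical matrices.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import scipy.sparse as sp

from .mesh_core import TetMesh
from .optical_props import OpticalProperties, XI_VACUUM

__all__ = [
    "AssembledSystem",
    "tet_element_matrices",
    "face_element_matrix",
    "assemble_de",
    "assemble_sp3",
    "global_mass_matrix",
    "props_per_tet",
]


@dataclass
class AssembledSystem:
    """A sparse system M x = F s with its node/field row layout.

    ``node_layout`` is ``("phi",)`` for diffusion (row i = fluence at node i)
    or ``("phi1", "phi2")`` for SP3 (rows [0, n) = phi1, rows [n, 2n) = phi2).
    ``source_scale`` gives the per-field scaling of a nodal source before
    multiplication by F (1 for diffusion; (1, -2/3) for SP3).
    """

    M: sp.csr_matrix
    F: sp.csr_matrix
    node_layout: tuple[str, ...]
    n_nodes: int
    source_scale: tuple[float, ...]

    @property
    def dimension(self) -> int:
        return self.M.shape[0]

    def source_map(self) -> sp.csr_matrix:
        """Sparse map P from nodal source density to the stacked field vector,
        so that the right-hand side is F @ (P @ S)."""
        n = self.n_nodes
        eye = sp.identity(n, format="csr")
        return sp.vstack([s * eye for s in self.source_scale], format="csr")

    def rhs(self, S: np.ndarray) -> np.ndarray:
        S = np.asarray(S, dtype=np.float64)
        if S.shape != (self.n_nodes,):
            raise ValueError("source vector length mismatch")
        return self.F @ (self.source_map() @ S)


def tet_element_matrices(coords: np.ndarray) -> tuple[np.ndarray, np.ndarray, float]:
    """Closed-form stiffness, mass and volume of one linear tet.

    ``coords`` is (4, 3).  Returns (stiffness 4x4, mass 4x4, volume).
    """
    K, M, V = _tet_batch(np.asarray(coords, dtype=np.float64)[None])
    if V[0] <= 0:
        raise ValueError("degenerate or negatively oriented tet")
    return K[0], M[0], float(V[0])


def _tet_batch(p: np.ndarray) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Vectorized element integrals for a (t, 4, 3) batch of tets."""
    e = p[:, 1:] - p[:, :1]  # (t, 3, 3): rows are edge vectors
    det = np.linalg.det(e)
    V = det / 6.0
    # gradients of barycentric coords: rows of inv(e), lambda_0 = -sum
    inv = np.linalg.inv(e)  # (t, 3, 3); columns give grad lambda_{1..3}
    g = np.empty((p.shape[0], 4, 3))
    g[:, 1:, :] = np.transpose(inv, (0, 2, 1))
    g[:, 0, :] = -g[:, 1:, :].sum(axis=1)
    K = V[:, None, None] * np.einsum("tid,tjd->tij", g, g)
    base = np.full((4, 4), 1.0 / 20.0)
    np.fill_diagonal(base, 1.0 / 10.0)
    M = V[:, None, None] * base
    return K, M, V


def face_element_matrix(coords: np.ndarray) -> tuple[np.ndarray, float]:
    """Closed-form surface mass matrix and area of one linear triangle."""
    p = np.asarray(coords, dtype=np.float64)
    area = 0.5 * np.linalg.norm(np.cross(p[1] - p[0], p[2] - p[0]))
    if area <= 0.0:
        raise ValueError("degenerate (zero-area) face")
    base = np.full((3, 3), 1.0 / 12.0)
    np.fill_diagonal(base, 1.0 / 6.0)
    return area * base, float(area)


def _face_batch(p: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    area = 0.5 * np.linalg.norm(np.cross(p[:, 1] - p[:, 0], p[:, 2] - p[:, 0]), axis=1)
    base = np.full((3, 3), 1.0 / 12.0)
    np.fill_diagonal(base, 1.0 / 6.0)
    return area[:, None, None] * base, area


def _scatter(tets: np.ndarray, elem: np.ndarray, n: int,
             row_off: int = 0, col_off: int = 0) -> sp.coo_matrix:
    """Scatter (t, k, k) element matrices into an (n, n)-indexed COO block."""
    k = elem.shape[1]
    rows = np.repeat(tets, k, axis=1).ravel() + row_off
    cols = np.tile(tets, (1, k)).ravel() + col_off
    return rows, cols, elem.ravel()


def _accumulate(parts, shape) -> sp.csr_matrix:
    rows = np.concatenate([p[0] for p in parts])
    cols = np.concatenate([p[1] for p in parts])
    vals = np.concatenate([p[2] for p in parts])
    m = sp.coo_matrix((vals, (rows, cols)), shape=shape).tocsr()
    m.sum_duplicates()
    return m


def props_per_tet(mesh: TetMesh, table: dict[str, OpticalProperties] | dict[int, OpticalProperties]
                  ) -> list[OpticalProperties]:
    """Resolve a tissue table (keyed by id or name) to one entry per tet."""
    names = mesh.tissue_names or {}
    resolved: dict[int, OpticalProperties] = {}
    for tid in np.unique(mesh.tissue):
        tid = int(tid)
        key = names.get(tid, tid)
        if key in table:
            resolved[tid] = table[key]
        elif tid in table:
            resolved[tid] = table[tid]
        else:
            raise ValueError(f"no optical properties for tissue {key!r}")
    return [resolved[int(t)] for t in mesh.tissue]


def _per_tet_arrays(mesh, props):
    if isinstance(props, dict):
        props = props_per_tet(mesh, props)
    if len(props) != mesh.n_tets:
        raise ValueError("need optical properties for every tet")
    return props


def global_mass_matrix(mesh: TetMesh) -> sp.csr_matrix:
    p = mesh.nodes[mesh.tets]
    _, Me, _ = _tet_batch(p)
    return _accumulate([_scatter(mesh.tets, Me, mesh.n_nodes)],
                       (mesh.n_nodes, mesh.n_nodes))


def assemble_de(mesh: TetMesh, props, A_n: float | np.ndarray = 1.0) -> AssembledSystem:
    """Assemble the diffusion system on a mesh.

    ``props`` is a per-tet list of :class:`OpticalProperties` or a tissue
    table; ``A_n`` a scalar or per-boundary-face refractive mismatch factor.
    Robin boundary terms are added only on ``mesh.boundary_faces`` (the outer
    surface; regrouped sub-meshes exclude interface faces by construction).
    """
    props = _per_tet_arrays(mesh, props)
    n = mesh.n_nodes
    p = mesh.nodes[mesh.tets]
    Ke, Me, _ = _tet_batch(p)
    D = np.array([1.0 / (3.0 * (pr.mu_a + (1.0 - pr.g) * pr.mu_s)) for pr in props])
    mua = np.array([pr.mu_a for pr in props])
    vol = D[:, None, None] * Ke + mua[:, None, None] * Me
    parts = [_scatter(mesh.tets, vol, n)]
    faces = mesh.boundary_faces
    if faces is not None and len(faces):
        Bf, _ = _face_batch(mesh.nodes[faces])
        An = np.broadcast_to(np.asarray(A_n, dtype=np.float64), (len(faces),))
        parts.append(_scatter(faces, Bf / (2.0 * An[:, None, None]), n))
    M = _accumulate(parts, (n, n))
    F = _accumulate([_scatter(mesh.tets, Me, n)], (n, n))
    return AssembledSystem(M=M, F=F, node_layout=("phi",), n_nodes=n,
                           source_scale=(1.0,))


def assemble_sp3(mesh: TetMesh, props, xi: np.ndarray | None = None,
                 include_m12_volume: bool = True) -> AssembledSystem:
    """Assemble the 2n x 2n SP3 block system on a mesh.

    ``xi`` is the 2x2 boundary coefficient table (per-face (f, 2, 2) arrays are
    accepted); defaults to the matched-boundary table.  The composite fluence
    is recovered downstream as phi1 - (2/3) phi2.
    """
    props = _per_tet_arrays(mesh, props)
    n = mesh.n_nodes
    p = mesh.nodes[mesh.tets]
    Ke, Me, _ = _tet_batch(p)
    mua = np.array([pr.mu_a for pr in props])
    mus = np.array([pr.mu_s for pr in props])
    g = np.array([pr.g for pr in props])
    mua1 = mua + mus * (1.0 - g)
    mua2 = mua + mus * (1.0 - g ** 2)
    mua3 = mua + mus * (1.0 - g ** 3)

    def w(a):
        return a[:, None, None]

    m11 = w(1.0 / (3.0 * mua1)) * Ke + w(mua) * Me
    m22 = w(1.0 / (7.0 * mua3)) * Ke + w(4.0 / 9.0 * mua + 5.0 / 9.0 * mua2) * Me
    m21 = w(-2.0 / 3.0 * mua) * Me
    m12 = m21 if include_m12_volume else np.zeros_like(Me)

    parts = [
        _scatter(mesh.tets, m11, n, 0, 0),
        _scatter(mesh.tets, m12, n, 0, n),
        _scatter(mesh.tets, m21, n, n, 0),
        _scatter(mesh.tets, m22, n, n, n),
    ]
    faces = mesh.boundary_faces
    if faces is not None and len(faces):
        Bf, _ = _face_batch(mesh.nodes[faces])
        x = XI_VACUUM if xi is None else np.asarray(xi, dtype=np.float64)
        if x.ndim == 2:
            x = np.broadcast_to(x, (len(faces), 2, 2))
        for s, off_r in ((0, 0), (1, n)):
            for t, off_c in ((0, 0), (1, n)):
                parts.append(_scatter(faces, x[:, s, t, None, None] * Bf, n,
                                      off_r, off_c))
    M = _accumulate(parts, (2 * n, 2 * n))
    mass = [_scatter(mesh.tets, Me, n, 0, 0), _scatter(mesh.tets, Me, n, n, n)]
    F = _accumulate(mass, (2 * n, 2 * n))
    return AssembledSystem(M=M, F=F, node_layout=("phi1", "phi2"), n_nodes=n,
                           source_scale=(1.0, -2.0 / 3.0))
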