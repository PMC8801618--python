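"""Tetrahedral mesh handling: I/O, boundary extraction, region classification,
and the mesh-regrouping step that underlies the hybrid transport model.

A :class:`TetMesh` is the geometric substrate for everything downstream: a node
cloud, tetrahedral connectivity, per-element tissue labels and (once assigned) a
per-element region label deciding which transport approximation governs the
element (region 1 = diffusion, region 2 = SP3).  :func:`regroup_mesh` splits a
labelled mesh into the two region sub-meshes, duplicating nodes shared between
regions and recording them as interface pairs; the hybrid system is later
coupled exactly at those pairs.

Indexing is 0-based throughout; 1-based indices appear only inside file formats
that require them (Gmsh MSH).  Tetrahedra are canonically reoriented to positive
signed volume on construction, because the finite-element formulas assume
positive Jacobians.
"""

from __future__ import annotations

import os
from dataclasses import dataclass, field, replace

import numpy as np

__all__ = [
    "TetMesh",
    "RegroupedMesh",
    "make_mesh",
    "load_mesh",
    "save_mesh",
    "extract_boundary_faces",
    "classify_regions",
    "regroup_mesh",
    "find_interface_duplicates",
    "merge_regrouped",
]

DE_REGION = 1
SP3_REGION = 2

# local vertex triples of the four faces of a tet; for a positively oriented
# tet (det[v1-v0, v2-v0, v3-v0] > 0) these orderings give outward normals
_TET_FACES = np.array([[1, 2, 3], [0, 3, 2], [0, 1, 3], [0, 2, 1]], dtype=np.int64)


@dataclass
class TetMesh:
    """Tetrahedral volume mesh with per-element tissue/region labels.

    Attributes
    ----------
    nodes : (n, 3) float array of node positions in mm.
    tets : (t, 4) int array of node indices, positively oriented.
    tissue : (t,) int array of tissue identifiers.
    region : (t,) int array with values in {1, 2}, or None before
        classification (1 = diffusion region, 2 = SP3 region).
    boundary_faces : (b, 3) int array of outward-oriented boundary triangles.
    boundary_owner : (b,) int array, owning tet of each boundary face.
    tissue_names : optional map from tissue id to a human-readable name.
    """

    nodes: np.ndarray
    tets: np.ndarray
    tissue: np.ndarray
    region: np.ndarray | None = None
    boundary_faces: np.ndarray | None = None
    boundary_owner: np.ndarray | None = None
    tissue_names: dict[int, str] | None = None

    @property
    def n_nodes(self) -> int:
        return int(self.nodes.shape[0])

    @property
    def n_tets(self) -> int:
        return int(self.tets.shape[0])

    def tet_volumes(self) -> np.ndarray:
        """Signed volumes of all tets (positive after canonical orientation)."""
        p = self.nodes[self.tets]
        e = p[:, 1:] - p[:, :1]
        return np.linalg.det(e) / 6.0

    def total_volume(self) -> float:
        return float(self.tet_volumes().sum())

    def boundary_nodes(self) -> np.ndarray:
        """Sorted unique node indices on the outer boundary."""
        if self.boundary_faces is None:
            raise ValueError("boundary faces not computed")
        return np.unique(self.boundary_faces)

    def mean_edge_length(self) -> float:
        edges = np.concatenate(
            [self.tets[:, [a, b]] for a, b in
             ((0, 1), (0, 2), (0, 3), (1, 2), (1, 3), (2, 3))]
        )
        edges = np.unique(np.sort(edges, axis=1), axis=0)
        d = self.nodes[edges[:, 0]] - self.nodes[edges[:, 1]]
        return float(np.linalg.norm(d, axis=1).mean())


@dataclass
class RegroupedMesh:
    """The pair of region sub-meshes produced by :func:`regroup_mesh`.

    ``interface_pairs[k] = (i1, i2)`` means node ``i1`` of ``mesh1`` and node
    ``i2`` of ``mesh2`` sit at the identical spatial point (the coordinates are
    copied, so they match bitwise); these duplicated nodes are where the hybrid
    system is coupled.  ``orig_in_mesh1``/``orig_in_mesh2`` map original node
    indices to local sub-mesh indices (-1 where absent); interface nodes map
    into both.
    """

    mesh1: TetMesh
    mesh2: TetMesh
    interface_pairs: np.ndarray  # (k, 2) int
    orig_in_mesh1: np.ndarray  # (n,) int, -1 where absent
    orig_in_mesh2: np.ndarray
    boundary_node_order: np.ndarray  # original indices of outer-boundary nodes
    source_n_nodes: int = 0
    source_n_tets: int = 0

    @property
    def n1(self) -> int:
        return self.mesh1.n_nodes

    @property
    def n2(self) -> int:
        return self.mesh2.n_nodes

    @property
    def t1(self) -> int:
        return self.mesh1.n_tets

    @property
    def t2(self) -> int:
        return self.mesh2.n_tets


def make_mesh(nodes, tets, tissue=None, region=None, tissue_names=None,
              compute_boundary=True) -> TetMesh:
    """Build a validated, canonically oriented :class:`TetMesh`.

    Raises ``ValueError`` for out-of-range indices, repeated vertices within a
    tet, or degenerate (zero-volume) tets, naming the offending tet.
    """
    nodes = np.ascontiguousarray(np.asarray(nodes, dtype=np.float64))
    tets = np.ascontiguousarray(np.asarray(tets, dtype=np.int64))
    if nodes.ndim != 2 or nodes.shape[1] != 3:
        raise ValueError("nodes must be (n, 3)")
    if tets.ndim != 2 or tets.shape[1] != 4:
        raise ValueError("tets must be (t, 4)")
    n = nodes.shape[0]
    if tets.size and (tets.min() < 0 or tets.max() >= n):
        raise ValueError("tet refers to node index outside [0, n)")
    s = np.sort(tets, axis=1)
    dup = (s[:, 1:] == s[:, :-1]).any(axis=1)
    if dup.any():
        raise ValueError(f"tet {int(np.nonzero(dup)[0][0])} has repeated vertices")
    # canonical orientation: flip tets with negative signed volume
    p = nodes[tets]
    vol6 = np.linalg.det(p[:, 1:] - p[:, :1])
    neg = vol6 < 0
    if neg.any():
        tets = tets.copy()
        tets[neg] = tets[neg][:, [0, 1, 3, 2]]
        vol6 = np.abs(vol6)
    degen = vol6 == 0.0
    if degen.any():
        raise ValueError(f"tet {int(np.nonzero(degen)[0][0])} is degenerate (zero volume)")
    if tissue is None:
        tissue = np.zeros(tets.shape[0], dtype=np.int64)
    tissue = np.asarray(tissue, dtype=np.int64)
    if tissue.shape != (tets.shape[0],):
        raise ValueError("tissue must have one label per tet")
    if region is not None:
        region = np.asarray(region, dtype=np.int64)
    mesh = TetMesh(nodes=nodes, tets=tets, tissue=tissue, region=region,
                   tissue_names=dict(tissue_names) if tissue_names else None)
    if compute_boundary and tets.size:
        faces, owners = extract_boundary_faces(mesh)
        mesh.boundary_faces = faces
        mesh.boundary_owner = owners
    else:
        mesh.boundary_faces = np.zeros((0, 3), dtype=np.int64)
        mesh.boundary_owner = np.zeros(0, dtype=np.int64)
    return mesh


def extract_boundary_faces(mesh: TetMesh) -> tuple[np.ndarray, np.ndarray]:
    """Faces belonging to exactly one tet, oriented with outward normals.

    Returns ``(faces, owner)`` where ``owner[i]`` is the tet owning face ``i``.
    Raises on non-manifold input (a face shared by more than two tets).
    """
    t = mesh.n_tets
    faces = mesh.tets[:, _TET_FACES].reshape(-1, 3)  # (4t, 3), outward order
    owner = np.repeat(np.arange(t, dtype=np.int64), 4)
    key = np.sort(faces, axis=1)
    _, inv, counts = np.unique(key, axis=0, return_inverse=True, return_counts=True)
    if (counts > 2).any():
        raise ValueError("non-manifold mesh: a face is shared by more than two tets")
    on_boundary = counts[inv] == 1
    return faces[on_boundary], owner[on_boundary]


def boundary_face_normals(mesh: TetMesh) -> tuple[np.ndarray, np.ndarray]:
    """Outward unit normals and areas of the boundary faces."""
    p = mesh.nodes[mesh.boundary_faces]
    cr = np.cross(p[:, 1] - p[:, 0], p[:, 2] - p[:, 0])
    area = 0.5 * np.linalg.norm(cr, axis=1)
    normals = cr / np.linalg.norm(cr, axis=1, keepdims=True)
    # guard: ensure normals point away from the owning tet's centroid
    cent = mesh.nodes[mesh.tets[mesh.boundary_owner]].mean(axis=1)
    fc = p.mean(axis=1)
    flip = np.einsum("ij,ij->i", normals, fc - cent) < 0
    normals[flip] *= -1.0
    return normals, area


def classify_regions(mesh: TetMesh, rule: dict) -> TetMesh:
    """Assign ``region`` per tet from a tissue→region map.

    ``rule`` may be keyed by tissue id or (when the mesh carries
    ``tissue_names``) by tissue name.  Every tissue present must be covered.
    """
    resolved: dict[int, int] = {}
    names = mesh.tissue_names or {}
    name_to_id = {v: k for k, v in names.items()}
    for key, reg in rule.items():
        tid = name_to_id[key] if isinstance(key, str) else int(key)
        if reg not in (DE_REGION, SP3_REGION):
            raise ValueError(f"region must be 1 or 2, got {reg!r}")
        resolved[tid] = int(reg)
    present = np.unique(mesh.tissue)
    missing = [int(t) for t in present if int(t) not in resolved]
    if missing:
        raise ValueError(f"tissue labels {missing} not covered by the region rule")
    lut_max = int(present.max()) + 1
    lut = np.zeros(lut_max, dtype=np.int64)
    for tid, reg in resolved.items():
        if tid < lut_max:
            lut[tid] = reg
    return replace(mesh, region=lut[mesh.tissue])


def _submesh(mesh: TetMesh, tet_mask: np.ndarray) -> tuple[TetMesh, np.ndarray]:
    """Extract the sub-mesh of the masked tets with stable node renumbering.

    Returns the sub-mesh and the (n,) original→local index map (-1 absent).
    Sub-mesh boundary faces are the *original outer* boundary faces owned by
    masked tets — interface faces between regions are deliberately excluded, so
    Robin boundary terms are only ever assembled on the true outer surface.
    """
    tets = mesh.tets[tet_mask]
    used = np.unique(tets)  # sorted => stable relative order
    o2l = np.full(mesh.n_nodes, -1, dtype=np.int64)
    o2l[used] = np.arange(used.size, dtype=np.int64)
    sub = TetMesh(
        nodes=mesh.nodes[used].copy(),
        tets=o2l[tets],
        tissue=mesh.tissue[tet_mask].copy(),
        region=None if mesh.region is None else mesh.region[tet_mask].copy(),
        tissue_names=mesh.tissue_names,
    )
    if mesh.boundary_faces is not None:
        own = tet_mask[mesh.boundary_owner]
        sub.boundary_faces = o2l[mesh.boundary_faces[own]]
        # owner indices in local tet numbering
        tet_o2l = np.full(mesh.n_tets, -1, dtype=np.int64)
        tet_o2l[np.nonzero(tet_mask)[0]] = np.arange(int(tet_mask.sum()))
        sub.boundary_owner = tet_o2l[mesh.boundary_owner[own]]
    return sub, o2l


def regroup_mesh(mesh: TetMesh) -> RegroupedMesh:
    """Split a region-labelled mesh into the two region sub-meshes.

    Nodes shared between the regions are duplicated into both sub-meshes
    (coordinates copied bitwise) and recorded as interface pairs.  Node order
    within each sub-mesh preserves the original relative order, which makes
    regrouping deterministic; the finite-element assembly is order-invariant.
    """
    if mesh.region is None:
        raise ValueError("region labels must be assigned before regrouping")
    if mesh.boundary_faces is None:
        raise ValueError("boundary faces must be computed before regrouping")
    mask1 = mesh.region == DE_REGION
    mask2 = mesh.region == SP3_REGION
    if not (mask1 | mask2).all():
        raise ValueError("every tet must be labelled region 1 or 2")
    mesh1, o2l1 = _submesh(mesh, mask1)
    mesh2, o2l2 = _submesh(mesh, mask2)
    both = np.nonzero((o2l1 >= 0) & (o2l2 >= 0))[0]
    pairs = np.column_stack([o2l1[both], o2l2[both]]) if both.size else \
        np.zeros((0, 2), dtype=np.int64)
    bnodes = np.unique(mesh.boundary_faces)
    return RegroupedMesh(
        mesh1=mesh1, mesh2=mesh2, interface_pairs=pairs,
        orig_in_mesh1=o2l1, orig_in_mesh2=o2l2,
        boundary_node_order=bnodes,
        source_n_nodes=mesh.n_nodes, source_n_tets=mesh.n_tets,
    )


def find_interface_duplicates(mesh1: TetMesh, mesh2: TetMesh,
                              tol: float = 0.0) -> np.ndarray:
    """Node pairs of two sub-meshes sharing a spatial location.

    The default ``tol=0`` matches coordinates bitwise, which is exact for
    sub-meshes produced by :func:`regroup_mesh` (duplicates are created by
    copying, never recomputation).  A positive absolute tolerance is available
    for externally produced mesh pairs.  Raises if distinct nodes of one mesh
    collide at a single point (the pairing would not be one-to-one).
    """
    if mesh1.n_nodes == 0 or mesh2.n_nodes == 0:
        return np.zeros((0, 2), dtype=np.int64)
    if tol == 0.0:
        def keys(m):
            return {m.nodes[i].tobytes(): i for i in range(m.n_nodes)}
        k1 = keys(mesh1)
        k2 = keys(mesh2)
        if len(k1) != mesh1.n_nodes or len(k2) != mesh2.n_nodes:
            raise ValueError("distinct nodes of one sub-mesh share a position")
        pairs = [(i1, k2[b]) for b, i1 in k1.items() if b in k2]
        pairs.sort()
        return np.asarray(pairs, dtype=np.int64).reshape(-1, 2)
    from scipy.spatial import cKDTree

    tree = cKDTree(mesh2.nodes)
    dist, j = tree.query(mesh1.nodes, k=1, distance_upper_bound=tol * (1 + 1e-12))
    hit = np.isfinite(dist) & (dist <= tol)
    j = j[hit]
    if np.unique(j).size != j.size:
        raise ValueError("many-to-one coordinate collision within tolerance")
    return np.column_stack([np.nonzero(hit)[0], j]).astype(np.int64)


def merge_regrouped(rg: RegroupedMesh) -> TetMesh:
    """Fuse the two sub-meshes back into a single mesh (interface duplicates
    merged).  Inverse of :func:`regroup_mesh` up to node/tet relabelling; used
    to verify that regrouping conserves the mesh.
    """
    n1, n2 = rg.n1, rg.n2
    glob2 = np.arange(n2, dtype=np.int64) + n1
    if rg.interface_pairs.size:
        glob2[rg.interface_pairs[:, 1]] = rg.interface_pairs[:, 0]
    keep2 = np.setdiff1d(np.arange(n2, dtype=np.int64),
                         rg.interface_pairs[:, 1] if rg.interface_pairs.size else [])
    # compact the index space
    remap = np.full(n1 + n2, -1, dtype=np.int64)
    remap[:n1] = np.arange(n1)
    remap[n1:][keep2] = n1 + np.arange(keep2.size)
    nodes = np.vstack([rg.mesh1.nodes, rg.mesh2.nodes[keep2]]) if n1 or n2 else \
        np.zeros((0, 3))
    tets = []
    tissue = []
    region = []
    if rg.t1:
        tets.append(remap[rg.mesh1.tets])
        tissue.append(rg.mesh1.tissue)
        region.append(np.full(rg.t1, DE_REGION, dtype=np.int64))
    if rg.t2:
        t2 = remap[glob2[rg.mesh2.tets]]
        tets.append(t2)
        tissue.append(rg.mesh2.tissue)
        region.append(np.full(rg.t2, SP3_REGION, dtype=np.int64))
    return make_mesh(nodes, np.vstack(tets), np.concatenate(tissue),
                     region=np.concatenate(region),
                     tissue_names=rg.mesh1.tissue_names or rg.mesh2.tissue_names)


# ---------------------------------------------------------------------------
# File I/O — legacy VTK ASCII and Gmsh MSH 2.2 ASCII
# ---------------------------------------------------------------------------

def load_mesh(path: str | os.PathLike, tissue_field: str = "tissue") -> TetMesh:
    """Load a tetrahedral mesh from a legacy VTK (.vtk) or Gmsh 2.2 (.msh) file.

    The file must contain only tetrahedral cells and carry an integer per-cell
    tissue field (VTK cell-data array named ``tissue_field``; Gmsh physical
    tag).  Raises for unsupported formats, non-tet cells or a missing field.
    """
    path = os.fspath(path)
    ext = os.path.splitext(path)[1].lower()
    if ext == ".vtk":
        return _read_vtk(path, tissue_field)
    if ext == ".msh":
        return _read_msh(path)
    raise ValueError(f"unsupported mesh format: {ext!r} (use .vtk or .msh)")


def save_mesh(mesh: TetMesh, path: str | os.PathLike,
              point_data: dict[str, np.ndarray] | None = None,
              cell_data: dict[str, np.ndarray] | None = None) -> None:
    """Write a mesh to legacy VTK ASCII or Gmsh MSH 2.2 by extension."""
    path = os.fspath(path)
    ext = os.path.splitext(path)[1].lower()
    if ext == ".vtk":
        _write_vtk(mesh, path, point_data or {}, cell_data or {})
    elif ext == ".msh":
        _write_msh(mesh, path)
    else:
        raise ValueError(f"unsupported mesh format: {ext!r} (use .vtk or .msh)")


def _write_vtk(mesh, path, point_data, cell_data):
    t = mesh.n_tets
    title = "luxtomo mesh"
    if mesh.tissue_names:
        names = ",".join(f"{k}:{v}" for k, v in sorted(mesh.tissue_names.items()))
        title = f"luxtomo mesh tissues={names}"[:255]
    with open(path, "w") as f:
        f.write(f"# vtk DataFile Version 3.0\n{title}\nASCII\n")
        f.write("DATASET UNSTRUCTURED_GRID\n")
        f.write(f"POINTS {mesh.n_nodes} double\n")
        np.savetxt(f, mesh.nodes, fmt="%.17g")
        f.write(f"CELLS {t} {5 * t}\n")
        cells = np.column_stack([np.full(t, 4, dtype=np.int64), mesh.tets])
        np.savetxt(f, cells, fmt="%d")
        f.write(f"CELL_TYPES {t}\n")
        np.savetxt(f, np.full(t, 10, dtype=np.int64), fmt="%d")
        cdata = {"tissue": mesh.tissue}
        if mesh.region is not None:
            cdata["region"] = mesh.region
        cdata.update(cell_data)
        f.write(f"CELL_DATA {t}\n")
        for name, arr in cdata.items():
            arr = np.asarray(arr)
            typ = "int" if np.issubdtype(arr.dtype, np.integer) else "double"
            fmt = "%d" if typ == "int" else "%.17g"
            f.write(f"SCALARS {name} {typ} 1\nLOOKUP_TABLE default\n")
            np.savetxt(f, arr, fmt=fmt)
        if point_data:
            f.write(f"POINT_DATA {mesh.n_nodes}\n")
            for name, arr in point_data.items():
                arr = np.asarray(arr, dtype=np.float64)
                f.write(f"SCALARS {name} double 1\nLOOKUP_TABLE default\n")
                np.savetxt(f, arr, fmt="%.17g")


def _read_vtk(path, tissue_field):
    with open(path) as f:
        text = f.read()
    tissue_names = None
    for line in text.splitlines()[:4]:
        if "tissues=" in line:
            try:
                tissue_names = {
                    int(k): v for k, v in
                    (item.split(":") for item in
                     line.split("tissues=", 1)[1].split(","))}
            except ValueError:
                tissue_names = None
    tokens = text.split()
    tl = [t.lower() for t in tokens]

    def find(word, start=0):
        try:
            return tl.index(word, start)
        except ValueError:
            raise ValueError(f"malformed VTK file: missing {word!r}") from None

    i = find("points")
    n = int(tokens[i + 1])
    coords = np.array(tokens[i + 3:i + 3 + 3 * n], dtype=np.float64).reshape(n, 3)
    i = find("cells")
    t = int(tokens[i + 1])
    total = int(tokens[i + 2])
    raw = np.array(tokens[i + 3:i + 3 + total], dtype=np.int64)
    i = find("cell_types")
    types = np.array(tokens[i + 2:i + 2 + t], dtype=np.int64)
    if (types != 10).any():
        raise ValueError("mesh contains non-tetrahedral cells")
    if total != 5 * t or (raw.reshape(t, 5)[:, 0] != 4).any():
        raise ValueError("malformed tetrahedral CELLS block")
    tets = raw.reshape(t, 5)[:, 1:]
    tissue = None
    j = 0
    while True:
        try:
            j = tl.index("scalars", j)
        except ValueError:
            break
        if tokens[j + 1] == tissue_field:
            k = tl.index("lookup_table", j) + 2
            tissue = np.array(tokens[k:k + t], dtype=np.float64).astype(np.int64)
            break
        j += 1
    if tissue is None:
        raise ValueError(f"cell-data field {tissue_field!r} not found")
    return make_mesh(coords, tets, tissue, tissue_names=tissue_names)


def _write_msh(mesh, path):
    with open(path, "w") as f:
        f.write("$MeshFormat\n2.2 0 8\n$EndMeshFormat\n")
        if mesh.tissue_names:
            f.write(f"$PhysicalNames\n{len(mesh.tissue_names)}\n")
            for k, v in sorted(mesh.tissue_names.items()):
                f.write(f'3 {k} "{v}"\n')
            f.write("$EndPhysicalNames\n")
        f.write(f"$Nodes\n{mesh.n_nodes}\n")
        for i, p in enumerate(mesh.nodes, start=1):
            f.write(f"{i} {p[0]:.17g} {p[1]:.17g} {p[2]:.17g}\n")
        f.write(f"$EndNodes\n$Elements\n{mesh.n_tets}\n")
        for j, (tet, tis) in enumerate(zip(mesh.tets + 1, mesh.tissue), start=1):
            f.write(f"{j} 4 2 {tis} {tis} {tet[0]} {tet[1]} {tet[2]} {tet[3]}\n")
        f.write("$EndElements\n")


def _read_msh(path):
    with open(path) as f:
        lines = f.read().splitlines()
    tissue_names = None
    if "$PhysicalNames" in lines:
        ip = lines.index("$PhysicalNames")
        count = int(lines[ip + 1])
        tissue_names = {}
        for k in range(count):
            parts = lines[ip + 2 + k].split(maxsplit=2)
            tissue_names[int(parts[1])] = parts[2].strip('"')
    try:
        i0 = lines.index("$Nodes")
        n = int(lines[i0 + 1])
        node_id = np.empty(n, dtype=np.int64)
        coords = np.empty((n, 3))
        for k in range(n):
            parts = lines[i0 + 2 + k].split()
            node_id[k] = int(parts[0])
            coords[k] = [float(x) for x in parts[1:4]]
        ie = lines.index("$Elements")
        ne = int(lines[ie + 1])
    except (ValueError, IndexError) as exc:
        raise ValueError("malformed Gmsh 2.2 file") from exc
    id2row = np.full(node_id.max() + 1, -1, dtype=np.int64)
    id2row[node_id] = np.arange(n)
    tets, tissue = [], []
    for k in range(ne):
        parts = lines[ie + 2 + k].split()
        etype = int(parts[1])
        ntags = int(parts[2])
        if etype != 4:
            raise ValueError(f"mesh contains non-tetrahedral element type {etype}")
        phys = int(parts[3]) if ntags >= 1 else 0
        verts = [int(v) for v in parts[3 + ntags:7 + ntags]]
        tets.append(verts)
        tissue.append(phys)
    return make_mesh(coords, id2row[np.asarray(tets, dtype=np.int64)],
                     np.asarray(tissue, dtype=np.int64),
                     tissue_names=tissue_names)
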