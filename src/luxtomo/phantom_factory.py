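"""Deterministic synthetic phantoms: meshes, tissue maps and ground-truth sources.

Meshing is by structured lattice subdivision: the bounding box is split into
cubes of the requested element size and every cube into six tetrahedra (Kuhn
triangulation, face-consistent across neighbouring cubes).  Curved phantoms
(sphere, cylinder) use a blended radial mapping that carries the lattice cube
onto the ball — identity at the centre, exact radial projection at the surface
— so the outer boundary is a smooth chordal approximation of the analytic
shape rather than a voxel staircase; ``surface="voxel"`` keeps the plain
masked-lattice variant (cheaper interiors, ragged surface) for tests that never
look at the surface.  Tissue labels are assigned per tet by centroid-inside
tests against the inclusion list, later inclusions overriding earlier ones.

Everything is deterministic; the only randomness is the optional node jitter,
which is driven entirely by the seed in the spec.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .mesh_core import TetMesh, make_mesh

__all__ = ["Inclusion", "SourceSpec", "PhantomSpec", "build_phantom",
           "mouse_torso_phantom", "MOUSE_REGION_RULE"]

#: organ split of the six-organ mouse phantom: diffusive organs (region 1)
#: versus low-scattering / high-absorption organs modelled with SP3 (region 2)
MOUSE_REGION_RULE = {"adipose": 1, "stomach": 1, "kidneys": 1,
                     "heart": 2, "liver": 2, "lungs": 2}

# Kuhn subdivision of the unit cube: six tets sharing the main diagonal.
# vertex bit codes (x + 2y + 4z)
_KUHN = np.array([
    [0, 1, 3, 7],
    [0, 3, 2, 7],
    [0, 2, 6, 7],
    [0, 6, 4, 7],
    [0, 4, 5, 7],
    [0, 5, 1, 7],
], dtype=np.int64)


@dataclass(frozen=True)
class Inclusion:
    """A tissue compartment: ``shape`` in {sphere, ellipsoid, cylinder}."""

    shape: str
    center: tuple[float, float, float]
    size: tuple[float, ...]  # sphere: (r,); ellipsoid: (a,b,c); cylinder: (r, h)
    tissue: str

    def contains(self, pts: np.ndarray) -> np.ndarray:
        c = np.asarray(self.center)
        d = pts - c
        if self.shape == "sphere":
            return (d ** 2).sum(axis=1) <= self.size[0] ** 2
        if self.shape == "ellipsoid":
            ax = np.asarray(self.size)
            return ((d / ax) ** 2).sum(axis=1) <= 1.0
        if self.shape == "cylinder":
            r, h = self.size
            return ((d[:, 0] ** 2 + d[:, 1] ** 2) <= r ** 2) & \
                (np.abs(d[:, 2]) <= h / 2.0)
        raise ValueError(f"unknown inclusion shape {self.shape!r}")

    def min_extent(self) -> float:
        return 2.0 * min(self.size[:1] if self.shape == "sphere" else self.size)

    def bounding_corners(self) -> np.ndarray:
        c = np.asarray(self.center)
        if self.shape == "sphere":
            half = np.full(3, self.size[0])
        elif self.shape == "ellipsoid":
            half = np.asarray(self.size)
        else:  # cylinder
            r, h = self.size
            half = np.array([r, r, h / 2.0])
        signs = np.array([[sx, sy, sz] for sx in (-1, 1) for sy in (-1, 1)
                          for sz in (-1, 1)], dtype=float)
        return c + signs * half


@dataclass(frozen=True)
class SourceSpec:
    """A spherical luminescent inclusion: nanophosphor density inside it."""

    center: tuple[float, float, float]
    radius: float
    density: float = 1.0


@dataclass
class PhantomSpec:
    """Specification of a synthetic phantom.

    ``geometry`` is sphere (size = (radius,)), cylinder (size = (radius,
    height); the axis is z, spanning [0, height]) or slab (size = (lx, ly,
    lz)).  ``element_size`` is the target lattice spacing in mm.
    """

    geometry: str
    size: tuple[float, ...]
    element_size: float
    tissue: str = "adipose"
    inclusions: list[Inclusion] = field(default_factory=list)
    sources: list[SourceSpec] = field(default_factory=list)
    surface: str = "mapped"
    jitter: float = 0.0
    seed: int = 0


def _lattice(counts, origin, h):
    axes = [origin[k] + h * np.arange(counts[k] + 1) for k in range(3)]
    Z, Y, X = np.meshgrid(axes[2], axes[1], axes[0], indexing="ij")
    nodes = np.column_stack([X.ravel(), Y.ravel(), Z.ravel()])

    def nid(i, j, k):
        return (k * (counts[1] + 1) + j) * (counts[0] + 1) + i

    i, j, k = np.meshgrid(np.arange(counts[0]), np.arange(counts[1]),
                          np.arange(counts[2]), indexing="ij")
    i, j, k = i.ravel(), j.ravel(), k.ravel()
    corners = np.stack([nid(i + (b & 1), j + ((b >> 1) & 1), k + ((b >> 2) & 1))
                        for b in range(8)], axis=1)  # (cells, 8)
    tets = corners[:, _KUHN].reshape(-1, 4)
    return nodes, tets


def _map_to_ball(p: np.ndarray, radius: float, axes=(0, 1, 2)) -> np.ndarray:
    """Blended radial mapping of a lattice cube onto the ball (or disk in the
    given axes): identity at the centre, exact projection at the surface."""
    q = p[:, axes]
    linf = np.abs(q).max(axis=1)
    l2 = np.linalg.norm(q, axis=1)
    with np.errstate(invalid="ignore", divide="ignore"):
        s = np.where(l2 > 0, linf / np.maximum(l2, 1e-300), 1.0)
    w = linf / radius
    f = (1.0 - w) + w * s
    out = p.copy()
    out[:, axes] = q * f[:, None]
    return out


def build_phantom(spec: PhantomSpec):
    """Build (mesh, nodal ground-truth source density, info dict) from a spec.

    Raises when an inclusion pokes outside the outer geometry or is too small
    to be represented (< 2 elements across).
    """
    h = float(spec.element_size)
    if h <= 0:
        raise ValueError("element size must be positive")
    for inc in spec.inclusions:
        if inc.min_extent() < 2.0 * h:
            raise ValueError(
                f"inclusion {inc.tissue!r} is under two elements across")
        if not _inside_domain(inc.bounding_corners(), spec, margin=0.0).all():
            raise ValueError(f"inclusion {inc.tissue!r} lies outside the domain")

    if spec.geometry == "sphere":
        (R,) = spec.size
        m = max(2, round(R / h))
        nodes, tets = _lattice((2 * m, 2 * m, 2 * m), (-R, -R, -R), R / m)
        if spec.surface == "mapped":
            nodes = _map_to_ball(nodes, R)
        else:
            nodes, tets = _mask(nodes, tets, lambda c: (c ** 2).sum(1) <= R ** 2)
    elif spec.geometry == "cylinder":
        R, H = spec.size
        m = max(2, round(R / h))
        nz = max(1, round(H / h))
        # anisotropic spacing: xy uses R/m, z uses H/nz
        ax = np.linspace(-R, R, 2 * m + 1)
        az = np.linspace(0.0, H, nz + 1)
        Z, Y, X = np.meshgrid(az, ax, ax, indexing="ij")
        nodes = np.column_stack([X.ravel(), Y.ravel(), Z.ravel()])
        _, tets = _lattice((2 * m, 2 * m, nz), (0, 0, 0), 1.0)
        if spec.surface == "mapped":
            nodes = _map_to_ball(nodes, R, axes=(0, 1))
        else:
            nodes, tets = _mask(nodes, tets,
                                lambda c: (c[:, 0] ** 2 + c[:, 1] ** 2) <= R ** 2)
    elif spec.geometry == "slab":
        lx, ly, lz = spec.size
        counts = tuple(max(1, round(s / h)) for s in (lx, ly, lz))
        ax = [np.linspace(0, s, c + 1) for s, c in zip((lx, ly, lz), counts)]
        Z, Y, X = np.meshgrid(ax[2], ax[1], ax[0], indexing="ij")
        nodes = np.column_stack([X.ravel(), Y.ravel(), Z.ravel()])
        _, tets = _lattice(counts, (0, 0, 0), 1.0)
    else:
        raise ValueError(f"unknown geometry {spec.geometry!r}")

    if spec.jitter > 0.0:
        rng = np.random.default_rng(spec.seed)
        interior = _inside_domain(nodes, spec, margin=1.5 * h)
        nodes = nodes + spec.jitter * h * interior[:, None] * \
            rng.uniform(-1, 1, nodes.shape)

    tissues = [spec.tissue] + [inc.tissue for inc in spec.inclusions]
    order = {}
    for name in tissues:
        order.setdefault(name, len(order))
    names = {i: n for n, i in order.items()}
    centroids = nodes[tets].mean(axis=1)
    tissue = np.full(len(tets), order[spec.tissue], dtype=np.int64)
    for inc in spec.inclusions:
        tissue[inc.contains(centroids)] = order[inc.tissue]

    mesh = make_mesh(nodes, tets, tissue, tissue_names=names)

    S = np.zeros(mesh.n_nodes)
    for src in spec.sources:
        c = np.asarray(src.center)
        inside = ((mesh.nodes - c) ** 2).sum(axis=1) <= src.radius ** 2
        S[inside] = src.density
    info = {
        "sources": [{"center": list(s.center), "radius": s.radius,
                     "density": s.density} for s in spec.sources],
        "element_size": h,
        "tissue_names": names,
    }
    return mesh, S, info


def _mask(nodes, tets, centroid_pred):
    cent = nodes[tets].mean(axis=1)
    keep = centroid_pred(cent)
    tets = tets[keep]
    used = np.unique(tets)
    remap = np.full(len(nodes), -1, dtype=np.int64)
    remap[used] = np.arange(used.size)
    return nodes[used], remap[tets]


def _inside_domain(pts, spec, margin=0.0):
    if spec.geometry == "sphere":
        (R,) = spec.size
        return np.linalg.norm(pts, axis=1) <= R - margin
    if spec.geometry == "cylinder":
        R, H = spec.size
        return (np.hypot(pts[:, 0], pts[:, 1]) <= R - margin) & \
            (pts[:, 2] >= margin) & (pts[:, 2] <= H - margin)
    lx, ly, lz = spec.size
    lo = np.array([margin] * 3)
    hi = np.array([lx, ly, lz]) - margin
    return ((pts >= lo) & (pts <= hi)).all(axis=1)


def mouse_torso_phantom(element_size: float = 1.0, surface: str = "mapped"):
    """The six-organ mouse-torso stand-in: a 35 mm tall, 10 mm radius cylinder
    of adipose with heart, lungs, liver, stomach and kidney compartments and a
    1 mm spherical luminescent source inside the liver.

    Returns (mesh, nodal ground-truth source density, info); the region split
    of its tissues follows :data:`MOUSE_REGION_RULE`.
    """
    inclusions = [
        Inclusion("sphere", (0.0, 3.0, 26.0), (3.0,), "heart"),
        Inclusion("sphere", (4.5, -2.0, 26.0), (2.8,), "lungs"),
        Inclusion("sphere", (-4.5, -2.0, 26.0), (2.8,), "lungs"),
        Inclusion("ellipsoid", (2.0, 1.0, 14.5), (5.0, 4.0, 5.0), "liver"),
        Inclusion("sphere", (-4.0, 2.0, 9.0), (2.5,), "stomach"),
        Inclusion("sphere", (4.0, -3.0, 6.0), (2.0,), "kidneys"),
        Inclusion("sphere", (-4.0, -3.0, 6.0), (2.0,), "kidneys"),
    ]
    spec = PhantomSpec(
        geometry="cylinder", size=(10.0, 35.0), element_size=element_size,
        tissue="adipose", inclusions=inclusions,
        sources=[SourceSpec(center=(3.0, 1.0, 14.5), radius=1.0, density=1.0)],
        surface=surface,
    )
    return build_phantom(spec)
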