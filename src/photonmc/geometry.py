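"""Scene geometry: nested tissue regions, containment and ray queries.

A :class:`Scene` is a containment tree of :class:`Region` objects rooted at
one outermost region (the organism).  Shapes are either analytic
(axis-aligned cylinder/ellipsoid/sphere/box, exact in queries) or closed
triangle meshes (OFF/PLY/STL via :mod:`trimesh`).  Coordinates are
right-handed, in mm; cylinder axes run along z.

The module answers two questions the transport loop asks constantly: which
region contains a point, and where does a ray next cross a region surface.
Tolerances: containment is strict, points within ~1e-9 mm of a surface may
resolve to either side; after a boundary event callers nudge the position
1e-7 mm along the new direction to avoid re-intersection.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Optional, Union

import numpy as np

from . import _kernels as _k

__all__ = [
    "AMBIENT", "Cylinder", "Ellipsoid", "Sphere", "Box", "TriangleMesh",
    "OpticalProperties", "Region", "Scene", "BoundaryHit",
    "GeometryInconsistencyError", "SceneValidationError",
    "point_in_region", "nearest_boundary_hit", "ray_triangle_intersect",
    "load_mesh",
]

#: Sentinel for the non-scattering space outside the root region.
AMBIENT = None


class SceneValidationError(ValueError):
    """Scene construction failed (open mesh, broken tree, overlap...)."""


class GeometryInconsistencyError(RuntimeError):
    """A query's preconditions were violated (signals upstream corruption)."""


def _as_vec(v) -> np.ndarray:
    a = np.asarray(v, dtype=np.float64)
    if a.shape != (3,):
        raise ValueError(f"expected a 3-vector, got shape {a.shape}")
    return a


@dataclass(frozen=True)
class Cylinder:
    """Circular cylinder with axis along z. Dimensions in mm."""
    center: tuple
    radius: float
    height: float

    def _pack(self):
        c = _as_vec(self.center)
        return _k.SHAPE_CYLINDER, [c[0], c[1], c[2],
                                   self.radius, self.height, 0.0]

    def bbox(self):
        c = _as_vec(self.center)
        r, hh = self.radius, 0.5 * self.height
        return np.array([c[0] - r, c[0] + r, c[1] - r, c[1] + r,
                         c[2] - hh, c[2] + hh])

    def volume(self):
        return math.pi * self.radius ** 2 * self.height


@dataclass(frozen=True)
class Ellipsoid:
    """Axis-aligned ellipsoid with semi-axes ``radii`` (mm)."""
    center: tuple
    radii: tuple

    def _pack(self):
        c = _as_vec(self.center)
        r = _as_vec(self.radii)
        return _k.SHAPE_ELLIPSOID, [c[0], c[1], c[2], r[0], r[1], r[2]]

    def bbox(self):
        c = _as_vec(self.center)
        r = _as_vec(self.radii)
        return np.array([c[0] - r[0], c[0] + r[0], c[1] - r[1], c[1] + r[1],
                         c[2] - r[2], c[2] + r[2]])

    def volume(self):
        r = _as_vec(self.radii)
        return 4.0 / 3.0 * math.pi * r[0] * r[1] * r[2]


@dataclass(frozen=True)
class Sphere:
    center: tuple
    radius: float

    def _pack(self):
        c = _as_vec(self.center)
        return _k.SHAPE_SPHERE, [c[0], c[1], c[2], self.radius, 0.0, 0.0]

    def bbox(self):
        c = _as_vec(self.center)
        r = self.radius
        return np.array([c[0] - r, c[0] + r, c[1] - r, c[1] + r,
                         c[2] - r, c[2] + r])

    def volume(self):
        return 4.0 / 3.0 * math.pi * self.radius ** 3


@dataclass(frozen=True)
class Box:
    """Axis-aligned box with full edge lengths ``size`` (mm)."""
    center: tuple
    size: tuple

    def _pack(self):
        c = _as_vec(self.center)
        s = _as_vec(self.size)
        return _k.SHAPE_BOX, [c[0], c[1], c[2], s[0], s[1], s[2]]

    def bbox(self):
        c = _as_vec(self.center)
        h = 0.5 * _as_vec(self.size)
        return np.array([c[0] - h[0], c[0] + h[0], c[1] - h[1], c[1] + h[1],
                         c[2] - h[2], c[2] + h[2]])

    def volume(self):
        s = _as_vec(self.size)
        return float(s[0] * s[1] * s[2])


class TriangleMesh:
    """Closed, consistently outward-oriented triangle surface.

    Degenerate (zero-area) triangles are dropped with a one-time warning at
    load; an open (non-watertight) mesh raises at scene build.
    """

    def __init__(self, vertices, faces, validate: bool = True):
        import trimesh as _tm
        self._tm = _tm.Trimesh(vertices=np.asarray(vertices, float),
                               faces=np.asarray(faces, np.int64),
                               process=False)
        areas = self._tm.area_faces
        bad = areas <= 1e-14
        if bad.any():
            import warnings
            warnings.warn(f"dropping {int(bad.sum())} degenerate triangle(s)")
            self._tm.update_faces(~bad)
        if validate:
            if not self._tm.is_watertight:
                raise SceneValidationError("mesh is not closed (watertight)")
            self._tm.fix_normals()  # consistent outward orientation
        self.vertices = np.asarray(self._tm.vertices, dtype=np.float64)
        self.faces = np.asarray(self._tm.faces, dtype=np.int64)
        self.triangles = self.vertices[self.faces]  # (m, 3, 3)

    def _pack(self):
        return _k.SHAPE_MESH, [0.0] * 6

    def bbox(self):
        lo = self.vertices.min(axis=0)
        hi = self.vertices.max(axis=0)
        return np.array([lo[0], hi[0], lo[1], hi[1], lo[2], hi[2]])

    def volume(self):
        return float(self._tm.volume)


Shape = Union[Cylinder, Ellipsoid, Sphere, Box, TriangleMesh]


def load_mesh(path) -> TriangleMesh:
    """Load a closed surface mesh from OFF/PLY/STL (ASCII or binary)."""
    import trimesh as _tm
    m = _tm.load_mesh(path)
    return TriangleMesh(m.vertices, m.faces)


@dataclass(frozen=True)
class OpticalProperties:
    """Per-tissue transport coefficients.

    mu_a, mu_s in mm^-1; anisotropy g in (-1, 1); refractive index n >= 1.
    """
    mu_a: float
    mu_s: float
    g: float
    n: float = 1.0

    def __post_init__(self):
        if self.mu_a < 0 or self.mu_s < 0:
            raise ValueError("mu_a and mu_s must be nonnegative")
        if self.mu_a + self.mu_s <= 0:
            raise ValueError("mu_a + mu_s must be positive for a tissue")
        if not -1.0 < self.g < 1.0:
            raise ValueError("anisotropy g must lie in (-1, 1)")
        if self.n < 1.0:
            raise ValueError("refractive index must be >= 1")

    @property
    def mu_t(self) -> float:
        return self.mu_a + self.mu_s

    @property
    def albedo(self) -> float:
        return self.mu_s / (self.mu_a + self.mu_s)


@dataclass
class Region:
    """One tissue region: a shape, its optical properties, and its parent id
    (``None`` marks the root, whose outside is ambient space)."""
    id: int
    shape: Shape
    props: OpticalProperties
    parent: Optional[int] = None


@dataclass
class BoundaryHit:
    """Nearest boundary crossing along a ray."""
    distance: float
    surface_region: Region
    outward_normal: np.ndarray
    next_region: Optional[Region]   # None == AMBIENT
    triangle_index: int = -1


class _ScenePack:
    """Flat array view of a scene consumed by the numba kernels."""

    def __init__(self, scene: "Scene"):
        regions = scene.regions
        n = len(regions)
        self.shape_type = np.empty(n, dtype=np.int64)
        self.prm = np.zeros((n, 6), dtype=np.float64)
        self.parent = np.empty(n, dtype=np.int64)
        self.depth = np.empty(n, dtype=np.int64)
        self.props = np.empty((n, 4), dtype=np.float64)
        tris = []
        self.tri_off = np.zeros(n + 1, dtype=np.int64)
        id2idx = {r.id: i for i, r in enumerate(regions)}
        for i, r in enumerate(regions):
            st, prm = r.shape._pack()
            self.shape_type[i] = st
            self.prm[i] = prm
            self.parent[i] = -1 if r.parent is None else id2idx[r.parent]
            self.props[i] = (r.props.mu_a, r.props.mu_s, r.props.g, r.props.n)
            if isinstance(r.shape, TriangleMesh):
                tris.append(r.shape.triangles)
                self.tri_off[i + 1] = self.tri_off[i] + len(r.shape.triangles)
            else:
                self.tri_off[i + 1] = self.tri_off[i]
        self.tri = (np.concatenate(tris, axis=0) if tris
                    else np.empty((0, 3, 3), dtype=np.float64))
        for i in range(n):
            d, a = 0, self.parent[i]
            while a >= 0:
                d += 1
                a = self.parent[a]
            self.depth[i] = d
        self.id2idx = id2idx


class Scene:
    """Containment tree of regions plus the ambient refractive index."""

    def __init__(self, regions: list[Region], ambient_n: float = 1.0,
                 strict: bool = True, n_validation_samples: int = 2000,
                 validation_seed: int = 12345):
        if not regions:
            raise SceneValidationError("scene needs at least one region")
        ids = [r.id for r in regions]
        if len(set(ids)) != len(ids):
            raise SceneValidationError("region ids must be unique")
        roots = [r for r in regions if r.parent is None]
        if len(roots) != 1:
            raise SceneValidationError(
                f"exactly one root region required, found {len(roots)}")
        by_id = {r.id: r for r in regions}
        for r in regions:
            if r.parent is not None and r.parent not in by_id:
                raise SceneValidationError(
                    f"region {r.id}: unknown parent {r.parent}")
        # acyclicity
        for r in regions:
            seen = set()
            cur = r
            while cur.parent is not None:
                if cur.id in seen:
                    raise SceneValidationError("containment tree has a cycle")
                seen.add(cur.id)
                cur = by_id[cur.parent]
        self.regions = list(regions)
        self.ambient_n = float(ambient_n)
        self.root = roots[0]
        self._pack: Optional[_ScenePack] = None
        self._validate_containment(strict, n_validation_samples,
                                   validation_seed)

    # -- validation ---------------------------------------------------------

    def _validate_containment(self, strict, n_samples, seed):
        """Sampled containment check: children inside parents, siblings
        disjoint.  With ``strict=False`` violations only warn (the printed
        heterogeneous phantom needs this)."""
        rng = np.random.default_rng(seed)
        problems = []
        by_id = {r.id: r for r in self.regions}
        for r in self.regions:
            if r.parent is None:
                continue
            parent = by_id[r.parent]
            pts = _sample_points_in_shape(r.shape, n_samples, rng)
            inside = np.fromiter(
                (point_in_region(p, parent) for p in pts), bool, len(pts))
            frac = inside.mean() if len(pts) else 1.0
            if frac < 1.0:
                problems.append(
                    f"region {r.id} not inside parent {parent.id} "
                    f"(sampled containment {frac:.1%})")
        children: dict = {}
        for r in self.regions:
            children.setdefault(r.parent, []).append(r)
        for sibs in children.values():
            for i in range(len(sibs)):
                for j in range(i + 1, len(sibs)):
                    a, b = sibs[i], sibs[j]
                    pts = _sample_points_in_shape(a.shape, n_samples // 2,
                                                  rng)
                    overlap = np.fromiter(
                        (point_in_region(p, b) for p in pts), bool, len(pts))
                    if overlap.any():
                        problems.append(
                            f"sibling regions {a.id} and {b.id} overlap "
                            f"(sampled overlap {overlap.mean():.1%})")
        if problems:
            msg = "; ".join(problems)
            if strict:
                raise SceneValidationError(msg)
            import warnings
            warnings.warn("scene accepted with clipping semantics: " + msg)

    # -- packing and queries ------------------------------------------------

    def pack(self) -> _ScenePack:
        if self._pack is None:
            self._pack = _ScenePack(self)
        return self._pack

    def region_index(self, region: Optional[Region]) -> int:
        return -1 if region is None else self.pack().id2idx[region.id]

    def locate(self, p) -> Optional[Region]:
        """Deepest region containing p, or ``AMBIENT`` (None)."""
        pk = self.pack()
        p = _as_vec(p)
        i = _k.locate_region(pk.shape_type, pk.prm, pk.parent, pk.depth,
                             pk.tri, pk.tri_off, p[0], p[1], p[2])
        return None if i < 0 else self.regions[i]

    def bbox(self) -> np.ndarray:
        return self.root.shape.bbox()


def _sample_points_in_shape(shape: Shape, n: int, rng) -> np.ndarray:
    """Uniform rejection samples inside a shape (validation helper)."""
    bb = shape.bbox()
    pts = []
    attempts = 0
    while len(pts) < n and attempts < 100 * max(n, 1):
        m = max(n - len(pts), 16)
        cand = np.column_stack([
            rng.uniform(bb[0], bb[1], m),
            rng.uniform(bb[2], bb[3], m),
            rng.uniform(bb[4], bb[5], m)])
        for p in cand:
            if _point_in_shape(shape, p):
                pts.append(p)
                if len(pts) >= n:
                    break
        attempts += m
    return np.array(pts) if pts else np.empty((0, 3))


def _point_in_shape(shape: Shape, p) -> bool:
    st, prm = shape._pack()
    tri = (shape.triangles if isinstance(shape, TriangleMesh)
           else np.empty((0, 3, 3)))
    p = _as_vec(p)
    return bool(_k._shape_contains(st, np.asarray(prm, float), tri,
                                   0, len(tri), p[0], p[1], p[2]))


def point_in_region(p, region: Region) -> bool:
    """Strict point-in-shape test; points within ~1e-9 mm of the surface may
    return either value."""
    return _point_in_shape(region.shape, p)


def ray_triangle_intersect(p, d, tri) -> Optional[float]:
    """Moller-Trumbore positive-distance ray/triangle hit, or None on miss.

    ``tri`` is a (3, 3) array of vertices; edge and vertex grazes resolve by
    a 1e-12 barycentric epsilon.
    """
    p = _as_vec(p)
    d = _as_vec(d)
    tri = np.asarray(tri, dtype=np.float64)
    if tri.shape != (3, 3):
        raise ValueError("tri must be a 3x3 array of vertices")
    t = _k._ray_triangle(p[0], p[1], p[2], d[0], d[1], d[2],
                         tri[0, 0], tri[0, 1], tri[0, 2],
                         tri[1, 0], tri[1, 1], tri[1, 2],
                         tri[2, 0], tri[2, 1], tri[2, 2])
    return None if t >= _k._INF else float(t)


def nearest_boundary_hit(p, d, current: Region, scene: Scene,
                         check: bool = True) -> Optional[BoundaryHit]:
    """Nearest surface crossing seen from inside ``current`` along ``d``.

    Returns the hit distance, the region whose surface is crossed, that
    shape's outward normal at the hit point, and the region on the far side
    (``None`` for ambient).  Raises :class:`GeometryInconsistencyError` when
    ``p`` is not inside ``current`` (tally corruption upstream).
    """
    p = _as_vec(p)
    d = _as_vec(d)
    nrm = np.linalg.norm(d)
    if abs(nrm - 1.0) > 1e-9:
        raise GeometryInconsistencyError("direction must be unit-norm")
    if check and scene.locate(p) is not current:
        raise GeometryInconsistencyError(
            f"point {p} is not inside region {current.id}")
    pk = scene.pack()
    t, reg, nx, ny, nz, tidx = _k.scene_nearest_hit(
        pk.shape_type, pk.prm, pk.tri, pk.tri_off,
        p[0], p[1], p[2], d[0], d[1], d[2])
    if t >= _k._INF:
        return None
    q = p + (t + _k._EPS_NUDGE) * d
    nxt = scene.locate(q)
    return BoundaryHit(distance=float(t),
                       surface_region=scene.regions[reg],
                       outward_normal=np.array([nx, ny, nz]),
                       next_region=nxt,
                       triangle_index=(int(tidx - pk.tri_off[reg])
                                       if tidx >= 0 else -1))
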