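"""Discrete geometry: flagellar grid, ellipsoidal head mesh, wall meshes.

Coordinate convention: the cell swims towards +x, the wall normal is +y, the
beat plane is x-y, and the step edge runs along z with the riser at
``x = x_step`` (default 0). All lengths are in units of the flagellum length L.

Wall features:

* ``strip``     - the plane y = 0 (zero step height);
* ``backstep``  - upper shelf {y=0, x<x_step}, riser {x=x_step, -h<y<0},
  lower floor {y=-h, x>x_step};
* ``cliff``     - the upper shelf only (nothing beyond the edge).

Meshes are flat triangle panels; wall panels are graded geometrically towards
the step edge where the flow varies fastest.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import trimesh

__all__ = [
    "FlagellumGrid",
    "SurfaceMesh",
    "WallGeometry",
    "HeadBody",
    "make_flagellum_grid",
    "make_head_mesh",
    "make_wall",
]


@dataclass(frozen=True)
class FlagellumGrid:
    """Uniform arclength grid on s in [0, 1] with Ns intervals (Ns+1 nodes)."""

    ns: int
    s: np.ndarray
    ds: float

    @property
    def n_nodes(self) -> int:
        return self.ns + 1


def make_flagellum_grid(ns: int) -> FlagellumGrid:
    if ns < 8:
        raise ValueError("need at least 8 arclength intervals")
    return FlagellumGrid(ns=ns, s=np.linspace(0.0, 1.0, ns + 1), ds=1.0 / ns)


@dataclass
class SurfaceMesh:
    """Triangulated surface: node table, connectivity and per-element data.

    ``elem_size`` is a characteristic edge length per element (used for the
    blob size of regularized elements and for near-singular quadrature
    decisions); for a panel of area A it is ``sqrt(2 A)``.
    """

    vertices: np.ndarray  # (Nv, 3)
    faces: np.ndarray  # (Nf, 3) int
    centroids: np.ndarray = field(init=False)
    areas: np.ndarray = field(init=False)
    normals: np.ndarray = field(init=False)
    elem_size: np.ndarray = field(init=False)

    def __post_init__(self) -> None:
        self.vertices = np.asarray(self.vertices, dtype=float)
        self.faces = np.asarray(self.faces, dtype=int)
        self._update_elements()

    def _update_elements(self) -> None:
        tri = self.vertices[self.faces]  # (Nf, 3, 3)
        self.centroids = tri.mean(axis=1)
        cr = np.cross(tri[:, 1] - tri[:, 0], tri[:, 2] - tri[:, 0])
        nrm = np.linalg.norm(cr, axis=1)
        if np.any(nrm == 0):
            raise ValueError("degenerate triangle in mesh")
        self.areas = 0.5 * nrm
        self.normals = cr / nrm[:, None]
        self.elem_size = np.sqrt(2.0 * self.areas)

    @property
    def n_elements(self) -> int:
        return len(self.faces)

    @property
    def total_area(self) -> float:
        return float(self.areas.sum())

    def transformed(self, rotation: np.ndarray, translation: np.ndarray) -> "SurfaceMesh":
        """Rigidly transformed copy: ``v -> rotation @ v + translation``."""
        return SurfaceMesh(self.vertices @ np.asarray(rotation).T + translation, self.faces)

    def export(self, path: str) -> None:
        """Write the mesh as a standard triangle-soup file (format by suffix)."""
        trimesh.Trimesh(self.vertices, self.faces, process=False).export(path)


def make_head_mesh(a_x: float, a_y: float, a_z: float, refinement: int = 3) -> SurfaceMesh:
    """Closed triangulated ellipsoid with semi-axes (a_x, a_y, a_z).

    A subdivided icosahedron is mapped onto the ellipsoid; each refinement
    level quadruples the element count (20 * 4**refinement flat triangles).
    Normals are oriented outward.
    """
    if min(a_x, a_y, a_z) <= 0:
        raise ValueError("semi-axes must be positive")
    ico = trimesh.creation.icosphere(subdivisions=refinement, radius=1.0)
    verts = ico.vertices * np.array([a_x, a_y, a_z])
    mesh = SurfaceMesh(verts, ico.faces)
    # outward orientation: flux of the position field must be positive
    flip = np.einsum("ij,ij->i", mesh.normals, mesh.centroids) < 0
    if np.any(flip):
        mesh.faces[flip] = mesh.faces[flip][:, ::-1]
        mesh._update_elements()
    return mesh


def _graded_breaks(start: float, end: float, n: int, cluster_at_start: bool, beta: float = 1.6) -> np.ndarray:
    """n+1 breakpoints on [start, end], geometrically refined at one end.

    ``beta = 0`` gives uniform breakpoints.
    """
    t = np.linspace(0.0, 1.0, n + 1)
    if abs(beta) < 1e-12:
        g = t
    else:
        g = (np.exp(beta * t) - 1.0) / (np.exp(beta) - 1.0)
    if cluster_at_start:
        return start + (end - start) * g
    return end - (end - start) * g[::-1]


def _quad_patch(xs: np.ndarray, zs: np.ndarray, to_xyz) -> tuple[np.ndarray, np.ndarray]:
    """Triangulate the tensor grid xs x zs; ``to_xyz(u, v)`` maps to 3-space."""
    uu, vv = np.meshgrid(xs, zs, indexing="ij")
    verts = to_xyz(uu.ravel(), vv.ravel())
    nu, nv = len(xs), len(zs)
    idx = np.arange(nu * nv).reshape(nu, nv)
    a = idx[:-1, :-1].ravel()
    b = idx[1:, :-1].ravel()
    c = idx[1:, 1:].ravel()
    d = idx[:-1, 1:].ravel()
    faces = np.concatenate([np.stack([a, b, c], axis=1), np.stack([a, c, d], axis=1)])
    return verts, faces


@dataclass
class WallGeometry:
    """A wall feature with its boundary-element mesh and blob sizes."""

    kind: str
    h: float
    x_step: float
    extents: tuple[float, float]
    mesh: SurfaceMesh
    eps_factor: float = 0.75

    @property
    def eps(self) -> np.ndarray:
        """Per-element regularization length: eps_factor x element size."""
        return self.eps_factor * self.mesh.elem_size


def make_wall(
    kind: str,
    h: float = 0.0,
    x_step: float = 0.0,
    extents: tuple[float, float] = (2.0, 2.0),
    resolution: int = 8,
    eps_factor: float = 0.75,
    grading: float = 1.6,
) -> WallGeometry:
    """Build a strip / backstep / cliff wall mesh.

    ``extents = (ex, ez)`` are half-lengths: shelves span ``x_step +- ex`` in x
    and ``+- ez`` in z. ``resolution`` is the number of x-cells per shelf;
    the z-count is half that (panels roughly square near the edge after
    grading). A backstep with h = 0 degenerates exactly to the strip mesh.
    """
    if h < 0:
        raise ValueError("riser height h must be nonnegative")
    if kind not in ("strip", "backstep", "cliff"):
        raise ValueError(f"unknown wall kind {kind!r}")
    if kind == "strip" and h != 0.0:
        raise ValueError("a strip has h = 0")
    if resolution < 2:
        raise ValueError("resolution must be at least 2")
    ex, ez = extents
    nx = int(resolution)
    nz = max(2, nx // 2)
    zs = np.linspace(-ez, ez, nz + 1)

    patches = []
    # upper shelf: y = 0, x in [x_step - ex, x_step], refined toward the edge
    xs_up = _graded_breaks(x_step - ex, x_step, nx, cluster_at_start=False, beta=grading)
    patches.append(_quad_patch(xs_up, zs, lambda u, v: np.stack([u, 0 * u, v], axis=1)))
    if kind in ("strip", "backstep"):
        # lower floor: y = -h, x in [x_step, x_step + ex]
        xs_lo = _graded_breaks(x_step, x_step + ex, nx, cluster_at_start=True, beta=grading)
        patches.append(
            _quad_patch(xs_lo, zs, lambda u, v: np.stack([u, 0 * u - h, v], axis=1))
        )
        if h > 0:
            # riser: x = x_step, y in [-h, 0]
            ny = max(1, round(nx * h / (2 * ex) * 4))
            ys = np.linspace(-h, 0.0, ny + 1)
            patches.append(
                _quad_patch(
                    ys, zs, lambda u, v: np.stack([0 * u + x_step, u, v], axis=1)
                )
            )

    verts = np.concatenate([p[0] for p in patches])
    offs = np.cumsum([0] + [len(p[0]) for p in patches[:-1]])
    faces = np.concatenate([p[1] + o for p, o in zip(patches, offs)])
    return WallGeometry(
        kind=kind, h=h, x_step=x_step, extents=(ex, ez),
        mesh=SurfaceMesh(verts, faces), eps_factor=eps_factor,
    )


@dataclass
class HeadBody:
    """Rigid ellipsoidal head: reference mesh, semi-axes and current pose.

    The reference (body-frame) mesh is centred at the origin with the long
    semi-axis a_x along +x, which is the swimming direction. The flagellum
    attaches at the -x pole ("junction"); in the world frame the head centre
    sits at ``junction - a_x * tangent`` where ``tangent`` is the proximal
    flagellar tangent X_s(0) (which points tailward, away from the heading).
    """

    semi_axes: tuple[float, float, float]
    base_mesh: SurfaceMesh
    junction: np.ndarray = field(default_factory=lambda: np.zeros(3))
    rotation: np.ndarray = field(default_factory=lambda: np.eye(3))

    @classmethod
    def ellipsoid(
        cls,
        a_x: float = 0.05,
        a_y: float = 0.03,
        a_z: float = 0.04,
        refinement: int = 2,
    ) -> "HeadBody":
        return cls((a_x, a_y, a_z), make_head_mesh(a_x, a_y, a_z, refinement))

    def pose_from_tangent(self, junction: np.ndarray, tangent: np.ndarray) -> None:
        """Clamp the head to the proximal flagellum.

        The body +x axis is the heading ``-tangent``; the body +y axis is the
        in-plane normal (rotation of the heading by +90 degrees about +z), so
        the beat plane is the body x-y plane.
        """
        e1 = -np.asarray(tangent, dtype=float)
        e1 = e1 / np.linalg.norm(e1)
        zhat = np.array([0.0, 0.0, 1.0])
        e2 = np.cross(zhat, e1)
        n2 = np.linalg.norm(e2)
        if n2 < 1e-12:
            raise ValueError("head axis parallel to z: beat-plane frame undefined")
        e2 /= n2
        e3 = np.cross(e1, e2)
        self.rotation = np.stack([e1, e2, e3], axis=1)
        self.junction = np.asarray(junction, dtype=float)

    @property
    def centre(self) -> np.ndarray:
        return self.junction + self.rotation[:, 0] * self.semi_axes[0]

    def world_mesh(self) -> SurfaceMesh:
        return self.base_mesh.transformed(self.rotation, self.centre)
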