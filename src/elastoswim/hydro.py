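"""Non-local hydrodynamics: slender-body and boundary-integral operators.

The flow problem couples three representations:

* the flagellum, through the slender-body velocity expansion — a local
  anisotropic drag term plus a non-local stokeslet line integral outside an
  arclength cutoff ``q``;
* the rigid head, through a single-layer distribution of singular stokeslets
  over a triangulated ellipsoid (self-elements handled by desingularized
  polar-coordinate quadrature);
* the wall, through regularized stokeslets collocated at element centroids
  with traction x area as strengths (Nystrom).

The sign convention follows the model equation
``u(X) = -(1/xi_perp)(I + (gamma-1) s s).f_vis - int S.f_vis
- oiint S.phi_H - oiint S_eps.phi_W``
in which the tractions ``phi`` are those exerted by the fluid on the surface,
so the fluid force on the head is directly ``oiint phi_H dS``.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import scipy.linalg

from .kernels import (
    KernelParams,
    ResistanceCoefficients,
    regularized_stokeslet_matrix,
    stokeslet,
    stokeslet_matrix,
)
from .meshes import HeadBody, SurfaceMesh, WallGeometry

__all__ = [
    "HydroSolution",
    "SurfaceOperator",
    "local_drag_velocity",
    "nonlocal_sbt_velocity",
    "sbt_cutoff_matrix",
    "line_integral_matrix",
    "single_layer_matrix",
    "single_layer_velocity",
    "solve_hydro",
    "grand_resistance",
    "head_load",
]

_GAUSS_N = 12


def local_drag_velocity(f: np.ndarray, tangent: np.ndarray, coeffs: ResistanceCoefficients) -> np.ndarray:
    """Local (resistive-force) part of the slender-body velocity.

    ``-(1/xi_perp) [f + (gamma - 1)(f . s) s]`` for unit tangent ``s``; the
    perpendicular and parallel limits reduce to ``-f/xi_perp`` and
    ``-f/xi_par``.
    """
    f = np.asarray(f, dtype=float)
    t = np.asarray(tangent, dtype=float)
    if abs(np.linalg.norm(t) - 1.0) > 1e-8:
        raise ValueError("tangent must be a unit vector")
    g = coeffs.gamma
    return -(f + (g - 1.0) * (f @ t) * t) / coeffs.xi_perp


def _trapezoid_weights(s: np.ndarray) -> np.ndarray:
    w = np.empty_like(s)
    w[1:-1] = 0.5 * (s[2:] - s[:-2])
    w[0] = 0.5 * (s[1] - s[0])
    w[-1] = 0.5 * (s[-1] - s[-2])
    return w


def sbt_cutoff_matrix(X: np.ndarray, s: np.ndarray, q: float, mu: float) -> np.ndarray:
    """Quadrature matrix W with ``int_{|s-s0|>q} S(X(s0), X(s)) f(s) ds = W f``.

    Composite trapezoid over the nodes outside the cutoff window, with a
    partial-interval trapezoid at the window boundary so the integration
    domain is exactly ``|s - s0| > q`` (positions and force density are
    interpolated linearly to the cut point).
    """
    X = np.asarray(X, dtype=float)
    s = np.asarray(s, dtype=float)
    n = len(s)
    ds = s[1] - s[0]
    if ds > q:
        raise ValueError("node spacing exceeds the cutoff q; refine the grid")
    with np.errstate(divide="ignore", invalid="ignore"):
        Sall = stokeslet_matrix(X, X, mu).reshape(n, 3, n, 3).transpose(0, 2, 1, 3)
    W = np.zeros((n, n, 3, 3))
    tiny = 1e-12
    m_sub = 6  # sub-quadrature near the cutoff, where the kernel varies on scale q
    kk = np.arange(m_sub + 1) / m_sub

    for i in range(n):
        # pieces of sub-quadrature: composite trapezoid on [sa, sb] within
        # interval [s_j, s_{j+1}], positions and force density interpolated
        # linearly between the bracketing nodes; the two to three intervals
        # nearest each cutoff are refined this way, since the kernel there
        # varies on scale q, then plain trapezoid over the remaining nodes
        pieces = []  # (j, sa, sb)
        for sign in (+1, -1):
            sc = s[i] + sign * q
            if sign > 0:
                if sc >= s[-1] - tiny:
                    continue
                j0 = int(np.floor((sc - s[0]) / ds + tiny))
                pieces.append((j0, sc, s[j0 + 1]))
                pieces += [(jr, s[jr], s[jr + 1]) for jr in (j0 + 1, j0 + 2) if jr + 1 <= n - 1]
                jplain = j0 + 3
                if jplain < n - 1:
                    wfull = _trapezoid_weights(s[jplain:])
                    W[i, jplain:] += wfull[:, None, None] * Sall[i, jplain:]
            else:
                if sc <= s[0] + tiny:
                    continue
                j0 = int(np.ceil((sc - s[0]) / ds - tiny))
                pieces.append((j0 - 1, s[j0 - 1], sc))
                pieces += [(jr, s[jr], s[jr + 1]) for jr in (j0 - 2, j0 - 3) if jr >= 0]
                jplain = j0 - 3
                if jplain > 0:
                    wfull = _trapezoid_weights(s[: jplain + 1])
                    W[i, : jplain + 1] += wfull[:, None, None] * Sall[i, : jplain + 1]
        if not pieces:
            continue
        jj = np.array([p[0] for p in pieces])
        sa = np.array([p[1] for p in pieces])
        sb = np.array([p[2] for p in pieces])
        aa = (sa[:, None] + (sb - sa)[:, None] * kk[None, :] - s[jj][:, None]) / ds  # (P, m+1)
        pts = (1.0 - aa[..., None]) * X[jj][:, None, :] + aa[..., None] * X[jj + 1][:, None, :]
        Sk = stokeslet_matrix(X[i][None], pts.reshape(-1, 3), mu).reshape(
            3, len(jj), m_sub + 1, 3
        ).transpose(1, 2, 0, 3)  # (P, m+1, 3, 3)
        wk = np.tile((sb - sa)[:, None] / m_sub, (1, m_sub + 1))
        wk[:, 0] *= 0.5
        wk[:, -1] *= 0.5
        lo = np.einsum("pk,pkab->pab", wk * (1.0 - aa), Sk)
        hi = np.einsum("pk,pkab->pab", wk * aa, Sk)
        np.add.at(W[i], jj, lo)
        np.add.at(W[i], jj + 1, hi)
    return W.transpose(0, 2, 1, 3).reshape(3 * n, 3 * n)


def nonlocal_sbt_velocity(X: np.ndarray, f: np.ndarray, q: float, mu: float, s: np.ndarray | None = None) -> np.ndarray:
    """Non-local slender-body velocity ``-int_{|s-s0|>q} S . f ds`` per node."""
    X = np.asarray(X, dtype=float)
    if s is None:
        s = np.linspace(0.0, 1.0, len(X))
    W = sbt_cutoff_matrix(X, s, q, mu)
    return -(W @ np.asarray(f, dtype=float).ravel()).reshape(-1, 3)


def line_integral_matrix(
    targets: np.ndarray,
    X: np.ndarray,
    s: np.ndarray,
    mu: float,
    refine_dist: float | None = None,
    refine_factor: int = 8,
) -> np.ndarray:
    """Matrix B with ``int_0^1 S(y_i, X(s)) f(s) ds = B f`` for off-filament targets.

    Composite trapezoid over the nodes; for targets closer to the filament
    than ``refine_dist`` (default 2 grid spacings) the nearby intervals are
    subdivided with linear interpolation of position and force density, since
    the kernel then varies on a sub-grid scale.
    """
    t = np.asarray(targets, dtype=float).reshape(-1, 3)
    X = np.asarray(X, dtype=float)
    s = np.asarray(s, dtype=float)
    n = len(s)
    ds = s[1] - s[0]
    if refine_dist is None:
        refine_dist = 2.0 * ds
    w = _trapezoid_weights(s)
    B = stokeslet_matrix(t, X, mu).reshape(len(t), 3, n, 3)
    B *= w[None, None, :, None]
    d = np.linalg.norm(t[:, None, :] - X[None, :, :], axis=2)
    m = refine_factor
    aa = np.arange(m + 1) / m  # refined abscissae within one interval
    wk = np.full(m + 1, ds / m)
    wk[0] *= 0.5
    wk[-1] *= 0.5
    for i in np.nonzero(d.min(axis=1) < refine_dist)[0]:
        jn = int(d[i].argmin())
        jays = np.arange(max(0, jn - 4), min(n - 1, jn + 4))
        if not len(jays):
            continue
        # remove the plain trapezoid contribution of the refined intervals
        Send = stokeslet_matrix(t[i][None], X, mu).reshape(3, n, 3)
        for j in jays:
            B[i, :, j, :] -= 0.5 * ds * Send[:, j]
            B[i, :, j + 1, :] -= 0.5 * ds * Send[:, j + 1]
        # refined composite trapezoid with linear interpolation of X and f
        pts = (1.0 - aa[None, :, None]) * X[jays, None, :] + aa[None, :, None] * X[jays + 1, None, :]
        Sfine = stokeslet_matrix(t[i][None], pts.reshape(-1, 3), mu).reshape(3, len(jays), m + 1, 3)
        lo = np.einsum("k,ckjd->cjd", wk * (1.0 - aa), Sfine.transpose(0, 2, 1, 3))
        hi = np.einsum("k,ckjd->cjd", wk * aa, Sfine.transpose(0, 2, 1, 3))
        for jj, j in enumerate(jays):
            B[i, :, j, :] += lo[:, jj]
            B[i, :, j + 1, :] += hi[:, jj]
    return B.reshape(len(t) * 3, n * 3)


def _tri_self_integral(tri: np.ndarray, x0: np.ndarray, mu: float) -> np.ndarray:
    """``int_T S(x0, y) dS(y)`` for a flat triangle with x0 inside it.

    The 1/r singularity is removed in polar coordinates about x0: the radial
    integral is exact and the angular integral is done by Gauss-Legendre on
    each of the three sub-triangles formed with x0.
    """
    nrm = np.cross(tri[1] - tri[0], tri[2] - tri[0])
    nrm = nrm / np.linalg.norm(nrm)
    t1 = tri[1] - tri[0]
    t1 = t1 / np.linalg.norm(t1)
    t2 = np.cross(nrm, t1)
    xg, wg = np.polynomial.legendre.leggauss(_GAUSS_N)
    out = np.zeros((3, 3))
    for a in range(3):
        v1, v2 = tri[a], tri[(a + 1) % 3]
        p1 = np.array([(v1 - x0) @ t1, (v1 - x0) @ t2])
        p2 = np.array([(v2 - x0) @ t1, (v2 - x0) @ t2])
        th1 = np.arctan2(p1[1], p1[0])
        th2 = np.arctan2(p2[1], p2[0])
        dth = (th2 - th1) % (2.0 * np.pi)
        if dth > np.pi:  # orientation: go the short way around
            th1, th2 = th2, th1
            dth = 2.0 * np.pi - dth
        if dth < 1e-14:
            continue
        # edge line in local 2-d coordinates: point p1, direction e
        e = p2 - p1
        en = np.array([e[1], -e[0]])
        en = en / np.linalg.norm(en)
        dist = p1 @ en  # signed distance from x0 to the edge line
        th = th1 + (xg + 1.0) * 0.5 * dth
        ww = wg * 0.5 * dth
        u2 = np.stack([np.cos(th), np.sin(th)], axis=1)
        R = dist / (u2 @ en)
        u3 = u2[:, 0:1] * t1[None, :] + u2[:, 1:2] * t2[None, :]
        out += np.einsum("k,ki,kj->ij", ww * R, u3, u3)
        out += np.eye(3) * float(ww @ R)
    return out / (8.0 * np.pi * mu)


_SUBDIV_CACHE: dict[int, np.ndarray] = {}


def _subdiv_centroids_bary(depth: int) -> np.ndarray:
    """Barycentric centroids of the 4**depth midpoint-subdivided sub-triangles."""
    if depth in _SUBDIV_CACHE:
        return _SUBDIV_CACHE[depth]
    tris = [np.eye(3)]
    for _ in range(depth):
        nxt = []
        for t in tris:
            m01, m12, m20 = 0.5 * (t[0] + t[1]), 0.5 * (t[1] + t[2]), 0.5 * (t[2] + t[0])
            nxt += [
                np.array([t[0], m01, m20]),
                np.array([m01, t[1], m12]),
                np.array([m20, m12, t[2]]),
                np.array([m01, m12, m20]),
            ]
        tris = nxt
    out = np.array([t.mean(axis=0) for t in tris])
    _SUBDIV_CACHE[depth] = out
    return out


def _tri_subdivided_integral(tri: np.ndarray, x0: np.ndarray, mu: float, depth: int) -> np.ndarray:
    """Centroid-rule quadrature of ``int_T S(x0, y) dS`` on 4**depth sub-triangles.

    Valid for targets off the element (on-element targets use the polar rule).
    """
    return _batch_subdivided_integrals(tri[None], np.asarray(x0, dtype=float)[None], mu, depth)[0]


def _batch_subdivided_integrals(tris: np.ndarray, x0s: np.ndarray, mu: float, depth: int) -> np.ndarray:
    """Subdivided centroid-rule integrals for P (triangle, target) pairs at once."""
    bary = _subdiv_centroids_bary(depth)  # (K, 3)
    pts = np.einsum("kb,pbc->pkc", bary, tris)  # (P, K, 3)
    areas = 0.5 * np.linalg.norm(
        np.cross(tris[:, 1] - tris[:, 0], tris[:, 2] - tris[:, 0]), axis=1
    ) / len(bary)
    r = x0s[:, None, :] - pts  # (P, K, 3)
    rn = np.sqrt(np.einsum("pkc,pkc->pk", r, r))
    S = np.eye(3)[None, None] / rn[:, :, None, None] + (
        r[:, :, :, None] * r[:, :, None, :]
    ) / rn[:, :, None, None] ** 3
    return areas[:, None, None] * S.sum(axis=1) / (8.0 * np.pi * mu)


def single_layer_matrix(
    mesh: SurfaceMesh,
    targets: np.ndarray,
    mu: float,
    kernel: str = "singular",
    eps=None,
    self_map: dict[int, int] | None = None,
    near_factor: float = 4.0,
    max_depth: int = 7,
) -> np.ndarray:
    """Matrix G mapping element tractions to velocities: ``u = G phi``.

    ``u(x_i) = sum_e [int_Te S(x_i, y) dS] phi_e`` for piecewise-constant
    tractions. Far elements use the one-point (centroid) rule with area
    weight; near elements are subdivided to a depth set by the
    distance/element-size ratio; with the singular kernel, a target lying on
    an element (declared via ``self_map: target index -> element index``) uses
    the desingularized polar quadrature.

    With ``kernel='regularized'`` the blob kernel of size ``eps`` (scalar or
    per-element) is used with the centroid rule throughout, including
    coincident points, which are regular.
    """
    t = np.asarray(targets, dtype=float).reshape(-1, 3)
    if kernel == "regularized":
        if eps is None:
            raise ValueError("regularized kernel requires eps")
        G = regularized_stokeslet_matrix(t, mesh.centroids, eps, mu)
        G *= np.repeat(mesh.areas, 3)[None, :]
        return G
    if kernel != "singular":
        raise ValueError(f"unknown kernel {kernel!r}")
    self_map = self_map or {}
    d = np.linalg.norm(t[:, None, :] - mesh.centroids[None, :, :], axis=2)
    for i, j in self_map.items():
        d[i, j] = np.inf  # handled separately below
    if np.any(d == 0):
        raise ValueError(
            "singular kernel collocated on a surface point; declare it via "
            "self_map or use the regularized kernel"
        )
    with np.errstate(divide="ignore", invalid="ignore"):
        G = stokeslet_matrix(t, mesh.centroids, mu)
    G *= np.repeat(mesh.areas, 3)[None, :]
    tri_all = mesh.vertices[mesh.faces]
    ii, jj = np.nonzero(d < near_factor * mesh.elem_size[None, :])
    if len(ii):
        with np.errstate(divide="ignore"):
            depths = np.clip(
                np.ceil(np.log2(mesh.elem_size[jj] / np.maximum(d[ii, jj], 1e-12))) + 4,
                3, max_depth,
            ).astype(int)
        for dep in np.unique(depths):
            sel = depths == dep
            blocks = _batch_subdivided_integrals(tri_all[jj[sel]], t[ii[sel]], mu, dep)
            for (i, j, blk) in zip(ii[sel], jj[sel], blocks):
                G[3 * i : 3 * i + 3, 3 * j : 3 * j + 3] = blk
    for i, j in self_map.items():
        G[3 * i : 3 * i + 3, 3 * j : 3 * j + 3] = _tri_self_integral(tri_all[j], t[i], mu)
    return G


def single_layer_velocity(
    mesh: SurfaceMesh,
    phi: np.ndarray,
    targets: np.ndarray,
    mu: float,
    kernel: str = "singular",
    eps=None,
    self_map: dict[int, int] | None = None,
) -> np.ndarray:
    """Velocity ``sum_e int_Te S(x, y) phi_e dS`` induced at each target."""
    G = single_layer_matrix(mesh, targets, mu, kernel=kernel, eps=eps, self_map=self_map)
    return (G @ np.asarray(phi, dtype=float).ravel()).reshape(-1, 3)


def _check_clearance(head: HeadBody, wall: WallGeometry | None) -> None:
    if wall is None:
        return
    v = head.world_mesh().vertices
    below = np.zeros(len(v), dtype=bool)
    left = v[:, 0] < wall.x_step
    below |= left & (v[:, 1] <= 0.0)
    if wall.kind in ("strip", "backstep"):
        below |= ~left & (v[:, 1] <= -wall.h)
    if np.any(below):
        raise ValueError("head intersects the wall")


class SurfaceOperator:
    """Precomputed single-layer blocks for a head/wall pair at a fixed pose.

    Caches the (pose-independent) wall-wall block across rebuilds and exposes
    the combined surface-surface system used both inside the coupled solve
    and for the grand resistance matrix.
    """

    @staticmethod
    def head_self_block(head: HeadBody, mu: float) -> np.ndarray:
        """Body-frame head-head single-layer matrix (pose independent).

        The stokeslet is rotation equivariant, so the world-frame block is
        obtained from this one by conjugating each 3x3 sub-block with the
        head's rotation matrix — the expensive desingularized quadrature is
        then done once per run instead of once per time step.
        """
        bm = head.base_mesh
        return single_layer_matrix(
            bm, bm.centroids, mu, kernel="singular",
            self_map={i: i for i in range(bm.n_elements)},
        )

    def __init__(
        self,
        head: HeadBody | None,
        wall: WallGeometry | None,
        mu: float,
        _wall_wall_cache: np.ndarray | None = None,
        _head_self_cache: np.ndarray | None = None,
    ):
        self.head = head
        self.wall = wall
        self.mu = mu
        self.head_mesh = head.world_mesh() if head is not None else None
        self.n_h = self.head_mesh.n_elements if head is not None else 0
        self.n_b = wall.mesh.n_elements if wall is not None else 0
        blocks = []
        if head is not None:
            _check_clearance(head, wall)
            hm = self.head_mesh
            if _head_self_cache is None:
                _head_self_cache = self.head_self_block(head, mu)
            Q = head.rotation
            G4 = _head_self_cache.reshape(self.n_h, 3, self.n_h, 3)
            G_hh = np.einsum("ab,ibjd,cd->iajc", Q, G4, Q).reshape(3 * self.n_h, 3 * self.n_h)
            row_h = [G_hh]
            if wall is not None:
                row_h.append(
                    single_layer_matrix(wall.mesh, hm.centroids, mu, kernel="regularized", eps=wall.eps)
                )
            blocks.append(row_h)
        if wall is not None:
            row_w = []
            if head is not None:
                row_w.append(single_layer_matrix(self.head_mesh, wall.mesh.centroids, mu, kernel="singular"))
            if _wall_wall_cache is not None:
                G_ww = _wall_wall_cache
            else:
                G_ww = single_layer_matrix(
                    wall.mesh, wall.mesh.centroids, mu, kernel="regularized", eps=wall.eps
                )
            self.wall_wall = G_ww
            row_w.append(G_ww)
            blocks.append(row_w)
        self.G_ss = np.block(blocks) if blocks else np.zeros((0, 0))
        self._lu = None
        self._resistance = None

    @property
    def surface_centroids(self) -> np.ndarray:
        parts = []
        if self.head is not None:
            parts.append(self.head_mesh.centroids)
        if self.wall is not None:
            parts.append(self.wall.mesh.centroids)
        return np.concatenate(parts) if parts else np.zeros((0, 3))

    def _factorize(self):
        if self._lu is None:
            self._lu = scipy.linalg.lu_factor(-self.G_ss)
        return self._lu

    def resistance(self) -> np.ndarray:
        """Grand resistance matrix R (6x6) of the head near the wall.

        Column j holds minus the total (force; moment about the junction) on
        the head for unit rigid-body mode j with the wall no-slip active, so
        that the fluid load decomposes as ``(F, M) = -R (U, Omega) + (dF, dM)``.
        R is symmetric positive definite up to quadrature error; for an
        isolated sphere the translation block is ``6 pi mu a I``.
        """
        if self.head is None:
            raise ValueError("resistance requires a head")
        if self._resistance is not None:
            return self._resistance
        hm = self.head_mesh
        x0 = self.head.junction
        r = hm.centroids - x0
        rhs = np.zeros((3 * (self.n_h + self.n_b), 6))
        for k in range(3):
            u = np.zeros((self.n_h, 3))
            u[:, k] = 1.0
            rhs[: 3 * self.n_h, k] = u.ravel()
            w = np.cross(np.eye(3)[k], r)
            rhs[: 3 * self.n_h, 3 + k] = w.ravel()
        phi = scipy.linalg.lu_solve(self._factorize(), rhs)
        R = np.zeros((6, 6))
        for k in range(6):
            ph = phi[: 3 * self.n_h, k].reshape(-1, 3)
            F = (ph * hm.areas[:, None]).sum(axis=0)
            M = (np.cross(r, ph) * hm.areas[:, None]).sum(axis=0)
            R[:3, k] = -F
            R[3:, k] = -M
        self._resistance = R
        return R


@dataclass
class HydroSolution:
    """Solved tractions and non-local velocity of one coupled flow problem."""

    f_vis: np.ndarray  # (Ns+1, 3) force per unit length, fluid on flagellum
    phi_head: np.ndarray  # (N_h, 3)
    phi_wall: np.ndarray  # (N_b, 3)
    V: np.ndarray  # (Ns+1, 3) non-local velocity at flagellum nodes
    V_surfaces: np.ndarray  # (Ns+1, 3) head+wall part of V
    F_head: np.ndarray  # (3,) total fluid force on head
    M_head: np.ndarray  # (3,) total fluid moment about the junction
    # exact sensitivities to the head rigid velocities at frozen geometry
    # (effective resistance incl. flagellum/wall screening, and the response
    # of the surface-induced flagellar velocity), or None if not requested
    R_eff: np.ndarray | None = None  # (6, 6)
    V_jac: np.ndarray | None = None  # (3(Ns+1), 6)


def solve_hydro(
    X: np.ndarray,
    Xt: np.ndarray,
    s: np.ndarray,
    params: KernelParams,
    coeffs: ResistanceCoefficients,
    head: HeadBody | None = None,
    rigid_velocity: tuple[np.ndarray, np.ndarray] | None = None,
    wall: WallGeometry | None = None,
    surface_op: SurfaceOperator | None = None,
    sbt_matrix: np.ndarray | None = None,
    rigid_jacobian: bool = False,
) -> HydroSolution:
    """Solve the coupled slender-body / boundary-integral flow problem.

    Collocates the model velocity equation at the flagellum nodes (velocity
    ``Xt``), rigid-body no-slip at head element centroids (``rigid_velocity =
    (U, Omega)`` about the junction) and zero velocity at wall centroids; each
    surface feels the others' induced flow, the flagellum entering the surface
    equations through the full slender-body line integral. Returns all
    tractions, the non-local velocity V at the flagellum nodes and the total
    fluid load on the head.
    """
    X = np.asarray(X, dtype=float)
    Xt = np.asarray(Xt, dtype=float)
    n = len(X)
    mu = params.mu
    if surface_op is None and (head is not None or wall is not None):
        surface_op = SurfaceOperator(head, wall, mu)
    if surface_op is not None:
        head = surface_op.head
        wall = surface_op.wall
    n_h = surface_op.n_h if surface_op is not None else 0
    n_b = surface_op.n_b if surface_op is not None else 0
    n_s = n_h + n_b

    W = sbt_matrix if sbt_matrix is not None else sbt_cutoff_matrix(X, s, params.q, mu)
    tang = np.gradient(X, s, axis=0)
    tang /= np.linalg.norm(tang, axis=1)[:, None]
    g = coeffs.gamma
    Lblk = (np.eye(3)[None] + (g - 1.0) * tang[:, :, None] * tang[:, None, :]) / coeffs.xi_perp
    Lmat = scipy.linalg.block_diag(*Lblk)

    dim = 3 * (n + n_s)
    A = np.zeros((dim, dim))
    b = np.zeros(dim)
    A[: 3 * n, : 3 * n] = -(Lmat + W)
    b[: 3 * n] = Xt.ravel()

    if n_s:
        sc = surface_op.surface_centroids
        # flagellum feels the surfaces
        cols = []
        if n_h:
            hm = surface_op.head_mesh
            cols.append(single_layer_matrix(hm, X, mu, kernel="singular"))
        if n_b:
            cols.append(single_layer_matrix(wall.mesh, X, mu, kernel="regularized", eps=wall.eps))
        G_fs = np.hstack(cols)
        A[: 3 * n, 3 * n :] = -G_fs
        # surfaces feel the flagellum and each other
        B_sf = line_integral_matrix(sc, X, s, mu)
        A[3 * n :, : 3 * n] = -B_sf
        A[3 * n :, 3 * n :] = -surface_op.G_ss
        if n_h:
            if rigid_velocity is None:
                raise ValueError("rigid_velocity (U, Omega) required with a head")
            U, Om = (np.asarray(v, dtype=float) for v in rigid_velocity)
            r = surface_op.head_mesh.centroids - head.junction
            b[3 * n : 3 * (n + n_h)] = (U[None, :] + np.cross(Om, r)).ravel()

    R_eff = None
    V_jac = None
    if rigid_jacobian and n_h:
        # unit-rigid-mode right-hand sides: the same coupled operator gives the
        # exact response of the head load and of the surface-induced flagellar
        # velocity to (U, Omega), so the load decomposition used by the
        # implicit elastic step is exact at frozen geometry
        rhs = np.zeros((dim, 7))
        rhs[:, 0] = b
        r = surface_op.head_mesh.centroids - head.junction
        for k in range(3):
            u = np.zeros((n_h, 3))
            u[:, k] = 1.0
            rhs[3 * n : 3 * (n + n_h), 1 + k] = u.ravel()
            rhs[3 * n : 3 * (n + n_h), 4 + k] = np.cross(np.eye(3)[k], r).ravel()
        lu = scipy.linalg.lu_factor(A)
        sols = scipy.linalg.lu_solve(lu, rhs)
        sol = sols[:, 0]
        R_eff = np.zeros((6, 6))
        hm = surface_op.head_mesh
        for k in range(6):
            ph = sols[3 * n : 3 * (n + n_h), 1 + k].reshape(-1, 3)
            R_eff[:3, k] = -(ph * hm.areas[:, None]).sum(axis=0)
            R_eff[3:, k] = -(np.cross(r, ph) * hm.areas[:, None]).sum(axis=0)
        V_jac = -(G_fs @ sols[3 * n :, 1:])
    else:
        sol = scipy.linalg.solve(A, b)
    f = sol[: 3 * n].reshape(-1, 3)
    phi_h = sol[3 * n : 3 * (n + n_h)].reshape(-1, 3)
    phi_w = sol[3 * (n + n_h) :].reshape(-1, 3)
    V = -(W @ sol[: 3 * n])
    V_surf = np.zeros(3 * n)
    if n_s:
        V_surf = -(G_fs @ sol[3 * n :])
        V = V + V_surf
    F_head = np.zeros(3)
    M_head = np.zeros(3)
    if n_h:
        hm = surface_op.head_mesh
        F_head = (phi_h * hm.areas[:, None]).sum(axis=0)
        M_head = (np.cross(hm.centroids - head.junction, phi_h) * hm.areas[:, None]).sum(axis=0)
    return HydroSolution(
        f_vis=f, phi_head=phi_h, phi_wall=phi_w, V=V.reshape(-1, 3),
        V_surfaces=V_surf.reshape(-1, 3), F_head=F_head, M_head=M_head,
        R_eff=R_eff, V_jac=V_jac,
    )


def grand_resistance(head: HeadBody, wall: WallGeometry | None, mu: float) -> np.ndarray:
    """Grand resistance matrix of the rigid head near the wall (see
    :meth:`SurfaceOperator.resistance`)."""
    return SurfaceOperator(head, wall, mu).resistance()


def head_load(
    sol: HydroSolution,
    R: np.ndarray | None = None,
    rigid_velocity: tuple[np.ndarray, np.ndarray] | None = None,
) -> tuple[tuple[np.ndarray, np.ndarray], tuple[np.ndarray, np.ndarray]]:
    """Total fluid load on the head and its flagellar correction.

    ``(F, M)`` are the surface integrals of the head traction (moments about
    the junction). With the grand resistance matrix and the rigid velocities
    used in the solve, the corrections are
    ``(dF, dM) = (F, M) + R (U, Omega)`` — the part of the load not explained
    by rigid-body drag, i.e. the influence of the flagellum.
    """
    F, M = sol.F_head, sol.M_head
    if R is None:
        return (F, M), (np.zeros(3), np.zeros(3))
    U, Om = (np.asarray(v, dtype=float) for v in rigid_velocity)
    load = np.concatenate([F, M]) + R @ np.concatenate([U, Om])
    return (F, M), (load[:3], load[3:])
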