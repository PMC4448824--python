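"""Synthetic inputs and independent brute-force oracles.

Everything here is deliberately written from scratch with scalar loops and
inline formulas — no code shared with the production operators — so that
agreement between an operator and its oracle is meaningful evidence of
correctness rather than a tautology.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.interpolate import CubicSpline

from .meshes import FlagellumGrid, SurfaceMesh

__all__ = [
    "PrescribedSwimmer",
    "OracleReport",
    "prescribed_wave",
    "sbt_integral_oracle",
    "single_layer_oracle",
    "classical_drag",
]


@dataclass
class OracleReport:
    """Comparison record between a production operator and its oracle."""

    quantity: str
    operator_value: float
    oracle_value: float
    relative_error: float
    tolerance: float

    @property
    def passed(self) -> bool:
        return self.relative_error <= self.tolerance

    @classmethod
    def compare(cls, quantity: str, op, oracle, tol: float) -> "OracleReport":
        op = np.asarray(op, dtype=float)
        oracle = np.asarray(oracle, dtype=float)
        scale = max(float(np.max(np.abs(oracle))), 1e-300)
        rel = float(np.max(np.abs(op - oracle))) / scale
        return cls(quantity, float(np.max(np.abs(op))), float(np.max(np.abs(oracle))), rel, tol)


class PrescribedSwimmer:
    """A travelling sinusoidal waveform with exact unit-speed parametrization.

    The planar curve ``(sigma, a sin(k sigma - t))`` is reparametrized by
    arclength so that ``|X_s| = 1`` to high accuracy; positions, tangents and
    time derivatives are available at any (s, t) without running the elastic
    solver, which lets the hydrodynamic operators be exercised in isolation.
    Requires ``a k < 1`` so the reparametrization is well conditioned.
    """

    def __init__(self, a: float, k: float, n_fine: int = 4000):
        if a < 0 or (a > 0 and a * k >= 1.0):
            raise ValueError("need a k < 1 for a convergent arclength correction")
        self.a = a
        self.k = k
        self._sig = np.linspace(0.0, 1.2, n_fine)

    def _sigma_of_s(self, t: float) -> CubicSpline:
        sig = self._sig
        speed = np.sqrt(1.0 + (self.a * self.k * np.cos(self.k * sig - t)) ** 2)
        ell = np.concatenate([[0.0], np.cumsum(0.5 * (speed[1:] + speed[:-1]) * np.diff(sig))])
        return CubicSpline(ell, sig)

    def positions(self, s: np.ndarray, t: float) -> np.ndarray:
        s = np.asarray(s, dtype=float)
        sig = self._sigma_of_s(t)(s)
        return np.stack([sig, self.a * np.sin(self.k * sig - t), np.zeros_like(sig)], axis=1)

    def tangents(self, s: np.ndarray, t: float) -> np.ndarray:
        sig = self._sigma_of_s(t)(np.asarray(s, dtype=float))
        slope = self.a * self.k * np.cos(self.k * sig - t)
        speed = np.sqrt(1.0 + slope**2)
        return np.stack([1.0 / speed, slope / speed, np.zeros_like(sig)], axis=1)

    def velocities(self, s: np.ndarray, t: float, dt: float = 1e-6) -> np.ndarray:
        return (self.positions(s, t + dt) - self.positions(s, t - dt)) / (2.0 * dt)


def prescribed_wave(a: float, k: float, t: float, grid: FlagellumGrid):
    """Positions and velocities of the arclength-corrected travelling wave."""
    sw = PrescribedSwimmer(a, k)
    return sw.positions(grid.s, t), sw.velocities(grid.s, t)


def _stokeslet_scalar(x, y, mu):
    # written out term by term, independent of the kernels module
    rx, ry, rz = x[0] - y[0], x[1] - y[1], x[2] - y[2]
    r = (rx * rx + ry * ry + rz * rz) ** 0.5
    c = 1.0 / (8.0 * np.pi * mu)
    rr = [[rx * rx, rx * ry, rx * rz], [ry * rx, ry * ry, ry * rz], [rz * rx, rz * ry, rz * rz]]
    out = [[0.0] * 3 for _ in range(3)]
    for j in range(3):
        for kk in range(3):
            out[j][kk] = c * ((1.0 if j == kk else 0.0) / r + rr[j][kk] / r**3)
    return np.array(out)


def _reg_stokeslet_scalar(x, y, eps, mu):
    rx, ry, rz = x[0] - y[0], x[1] - y[1], x[2] - y[2]
    r2 = rx * rx + ry * ry + rz * rz
    den = (r2 + eps * eps) ** 1.5
    c = 1.0 / (8.0 * np.pi * mu)
    rr = [[rx * rx, rx * ry, rx * rz], [ry * rx, ry * ry, ry * rz], [rz * rx, rz * ry, rz * rz]]
    out = [[0.0] * 3 for _ in range(3)]
    for j in range(3):
        for kk in range(3):
            out[j][kk] = c * ((1.0 if j == kk else 0.0) * (r2 + 2.0 * eps * eps) + rr[j][kk]) / den
    return np.array(out)


def sbt_integral_oracle(position_func, force_func, s0: float, q: float, mu: float, n: int = 2000) -> np.ndarray:
    """Brute-force ``-int_{|s-s0|>q} S(X(s0), X(s)) f(s) ds`` by fine trapezoid.

    ``position_func`` / ``force_func`` map an arclength value to a 3-vector;
    each subdomain is integrated with its own composite trapezoid rule on
    ``n`` points, so the cutoff endpoints are hit exactly.
    """
    x0 = position_func(s0)
    total = np.zeros(3)
    for lo, hi in ((0.0, s0 - q), (s0 + q, 1.0)):
        if hi <= lo:
            continue
        ss = np.linspace(lo, hi, n)
        vals = np.zeros((n, 3))
        for i, sv in enumerate(ss):
            vals[i] = _stokeslet_scalar(x0, position_func(sv), mu) @ force_func(sv)
        w = np.full(n, (hi - lo) / (n - 1))
        w[0] *= 0.5
        w[-1] *= 0.5
        total += w @ vals
    return -total


def single_layer_oracle(mesh: SurfaceMesh, phi: np.ndarray, target, mu: float,
                        refine: int = 3, kernel: str = "singular", eps=None) -> np.ndarray:
    """Brute-force single-layer velocity ``sum_e int_Te S(x, y) phi_e dS``.

    Each triangle is split into 4**refine congruent sub-triangles and
    integrated with the centroid rule, in plain scalar loops.
    """
    from scipy.integrate import dblquad

    target = np.asarray(target, dtype=float)
    phi = np.asarray(phi, dtype=float).reshape(-1, 3)
    if kernel == "regularized":
        eps_arr = np.broadcast_to(np.asarray(eps, dtype=float), (mesh.n_elements,))
    out = np.zeros(3)
    for e in range(mesh.n_elements):
        tri = mesh.vertices[mesh.faces[e]]
        # a target lying on this element (singular kernel): adaptive quadrature
        nrm = np.cross(tri[1] - tri[0], tri[2] - tri[0])
        jac = np.linalg.norm(nrm)
        if kernel == "singular" and abs((target - tri[0]) @ nrm) / jac < 1e-12:
            b0 = np.linalg.solve(
                np.stack([tri[1] - tri[0], tri[2] - tri[0], nrm], axis=1),
                target - tri[0],
            )
            if -1e-9 <= b0[0] and -1e-9 <= b0[1] and b0[0] + b0[1] <= 1 + 1e-9:
                for comp in range(3):
                    def f(w, u, comp=comp):
                        y = tri[0] + u * (tri[1] - tri[0]) + w * (tri[2] - tri[0])
                        val = _stokeslet_scalar(target, y, mu) @ phi[e]
                        return val[comp]
                    out[comp] += jac * dblquad(
                        f, 0.0, 1.0, 0.0, lambda u: 1.0 - u, epsabs=1e-10, epsrel=1e-9
                    )[0]
                continue
        stack = [tri]
        for _ in range(refine):
            nxt = []
            for tv in stack:
                m01 = 0.5 * (tv[0] + tv[1])
                m12 = 0.5 * (tv[1] + tv[2])
                m20 = 0.5 * (tv[2] + tv[0])
                nxt += [
                    np.array([tv[0], m01, m20]),
                    np.array([m01, tv[1], m12]),
                    np.array([m20, m12, tv[2]]),
                    np.array([m01, m12, m20]),
                ]
            stack = nxt
        for tv in stack:
            area = 0.5 * np.linalg.norm(np.cross(tv[1] - tv[0], tv[2] - tv[0]))
            c = (tv[0] + tv[1] + tv[2]) / 3.0
            if kernel == "singular":
                S = _stokeslet_scalar(target, c, mu)
            else:
                S = _reg_stokeslet_scalar(target, c, eps_arr[e], mu)
            out += area * (S @ phi[e])
    return out


def classical_drag(shape: str, mu: float, U: float = 1.0, a: float = 1.0,
                   b: float | None = None, L: float | None = None,
                   mode: str = "axial") -> float:
    """Closed-form Stokes drag magnitudes used as validation oracles.

    ``sphere``: Stokes law 6 pi mu a U. ``prolate-spheroid`` (semi-major a,
    semi-minor b): Oberbeck's formulas for axial / transverse translation.
    ``straight-slender-rod``: leading-log slender-body transverse drag
    ``4 pi mu L U / ln(2L/b)``.
    """
    if shape == "sphere":
        return 6.0 * np.pi * mu * a * U
    if shape == "prolate-spheroid":
        if b is None or b >= a:
            raise ValueError("prolate spheroid needs semi-minor b < a")
        e = np.sqrt(1.0 - (b / a) ** 2)
        if e < 1e-8:
            return 6.0 * np.pi * mu * a * U
        Le = np.log((1.0 + e) / (1.0 - e))
        if mode == "axial":
            return 16.0 * np.pi * mu * a * e**3 * U / ((1.0 + e**2) * Le - 2.0 * e)
        if mode == "transverse":
            return 32.0 * np.pi * mu * a * e**3 * U / ((3.0 * e**2 - 1.0) * Le + 2.0 * e)
        raise ValueError(f"unknown mode {mode!r}")
    if shape == "straight-slender-rod":
        if L is None or b is None:
            raise ValueError("slender rod needs L and b")
        return 4.0 * np.pi * mu * L * U / np.log(2.0 * L / b)
    raise ValueError(f"unsupported shape {shape!r}")
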