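"""Closed-form Stokes-flow kernels and slender-body resistance coefficients.

The building blocks of the hydrodynamic model: the singular stokeslet (the
free-space Green's function of the Stokes equations for a point force), its
regularized counterpart (a smoothed point force, finite everywhere, with blob
size ``eps``), and the Gray–Hancock-type resistance coefficients that appear
in the local part of the slender-body velocity expansion.

All kernels are dimensional; the nondimensionalization of the swimmer problem
is handled in one place (:mod:`elastoswim.driver`) by an appropriate choice of
the unit system, so that unit bookkeeping never leaks into the operators.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

__all__ = [
    "KernelParams",
    "ResistanceCoefficients",
    "stokeslet",
    "regularized_stokeslet",
    "stokeslet_matrix",
    "regularized_stokeslet_matrix",
    "drag_coefficients",
    "sperm_number",
]


@dataclass(frozen=True)
class KernelParams:
    """Physical parameters of the slender-body / boundary-integral model.

    Attributes
    ----------
    mu : float
        Dynamic viscosity (Pa s).
    epsilon : float
        Regularization length of the blob kernel (same units as positions).
    b : float
        Flagellar cross-sectional radius.
    q : float
        Slender-body cutoff length separating the local drag term from the
        non-local stokeslet integral; requires ``b < q << L``.
    L : float
        Flagellum length.
    """

    mu: float
    epsilon: float
    b: float
    q: float
    L: float

    def __post_init__(self) -> None:
        if self.mu <= 0:
            raise ValueError("viscosity mu must be positive")
        if self.epsilon <= 0:
            raise ValueError("regularization length epsilon must be positive")
        if not (0 < self.b < self.q < self.L):
            raise ValueError("slender-body lengths must satisfy 0 < b < q < L")


@dataclass(frozen=True)
class ResistanceCoefficients:
    """Anisotropic resistance coefficients of the local drag law.

    ``xi_perp`` and ``xi_par`` are the normal and tangential force-per-length
    coefficients; ``gamma = xi_perp / xi_par`` is the drag anisotropy ratio.
    """

    xi_perp: float
    xi_par: float

    @property
    def gamma(self) -> float:
        return self.xi_perp / self.xi_par


def stokeslet(x, y, mu: float) -> np.ndarray:
    """Velocity-response tensor of a point force at ``y`` evaluated at ``x``.

    Returns the 3x3 tensor ``S`` with
    ``S_jk = (1/8 pi mu) (delta_jk / r + r_j r_k / r^3)``, ``r = x - y``.
    Symmetric in its indices and in (x, y); decays like ``1/|r|``.
    """
    r = np.asarray(x, dtype=float) - np.asarray(y, dtype=float)
    rn = np.linalg.norm(r)
    if rn == 0.0:
        raise ZeroDivisionError("stokeslet is singular at coincident points")
    return (np.eye(3) / rn + np.outer(r, r) / rn**3) / (8.0 * np.pi * mu)


def regularized_stokeslet(x, y, eps: float, mu: float) -> np.ndarray:
    """Regularized (blob) stokeslet; finite for all ``x``, including ``x == y``.

    ``S^eps_jk = (1/8 pi mu) [delta_jk (r^2 + 2 eps^2) + r_j r_k]
    / (r^2 + eps^2)^{3/2}``.
    """
    if eps <= 0:
        raise ValueError("eps must be positive")
    r = np.asarray(x, dtype=float) - np.asarray(y, dtype=float)
    r2 = float(r @ r)
    d = (r2 + eps**2) ** 1.5
    return (np.eye(3) * (r2 + 2.0 * eps**2) + np.outer(r, r)) / (
        8.0 * np.pi * mu * d
    )


def stokeslet_matrix(targets: np.ndarray, sources: np.ndarray, mu: float) -> np.ndarray:
    """Pairwise stokeslet blocks, shape ``(3*N, 3*M)``.

    Row block i, column block j is ``S(targets[i], sources[j], mu)``.
    Coincident target/source pairs are not checked; callers that collocate on
    a surface must supply desingularized self-terms separately.
    """
    t = np.asarray(targets, dtype=float).reshape(-1, 3)
    s = np.asarray(sources, dtype=float).reshape(-1, 3)
    r = t[:, None, :] - s[None, :, :]
    rn = np.sqrt(np.einsum("ijk,ijk->ij", r, r))
    with np.errstate(divide="ignore", invalid="ignore"):
        blocks = np.eye(3)[None, None] / rn[:, :, None, None] + (
            r[:, :, :, None] * r[:, :, None, :]
        ) / rn[:, :, None, None] ** 3
    blocks /= 8.0 * np.pi * mu
    n, m = t.shape[0], s.shape[0]
    return blocks.transpose(0, 2, 1, 3).reshape(3 * n, 3 * m)


def regularized_stokeslet_matrix(
    targets: np.ndarray, sources: np.ndarray, eps, mu: float
) -> np.ndarray:
    """Pairwise regularized-stokeslet blocks, shape ``(3*N, 3*M)``.

    ``eps`` may be a scalar or a per-source array (the blob size belongs to
    the source, as in Nystrom discretizations of the wall integral).
    """
    t = np.asarray(targets, dtype=float).reshape(-1, 3)
    s = np.asarray(sources, dtype=float).reshape(-1, 3)
    e = np.broadcast_to(np.asarray(eps, dtype=float), (s.shape[0],))
    r = t[:, None, :] - s[None, :, :]
    r2 = np.einsum("ijk,ijk->ij", r, r)
    e2 = e[None, :] ** 2
    d = (r2 + e2) ** 1.5
    blocks = (
        np.eye(3)[None, None] * (r2 + 2.0 * e2)[:, :, None, None]
        + r[:, :, :, None] * r[:, :, None, :]
    ) / d[:, :, None, None]
    blocks /= 8.0 * np.pi * mu
    n, m = t.shape[0], s.shape[0]
    return blocks.transpose(0, 2, 1, 3).reshape(3 * n, 3 * m)


def drag_coefficients(params: KernelParams) -> ResistanceCoefficients:
    """Gray–Hancock-type resistance coefficients of the slender-body expansion.

    ``xi_perp = 8 pi mu / (1 + 2 ln(2q/b))``,
    ``xi_par = 8 pi mu / (-2 + 4 ln(2q/b))``.
    The anisotropy ratio ``gamma`` depends only on ``q/b`` and tends to 2 as
    ``2q/b -> infinity``.
    """
    lg = np.log(2.0 * params.q / params.b)
    d_perp = 1.0 + 2.0 * lg
    d_par = -2.0 + 4.0 * lg
    if d_perp <= 0 or d_par <= 0:
        raise ValueError("2q/b too small: resistance denominators nonpositive")
    return ResistanceCoefficients(
        xi_perp=8.0 * np.pi * params.mu / d_perp,
        xi_par=8.0 * np.pi * params.mu / d_par,
    )


def sperm_number(L: float, xi_perp: float, omega: float, E: float) -> float:
    """Sperm number ``Sp = L (xi_perp omega / E)^{1/4}``.

    The dimensionless ratio of viscous to elastic forces for an actively
    beaten filament; Sp ~ 13-17 spans human sperm in high-viscosity medium.
    """
    if L <= 0 or xi_perp <= 0 or E <= 0 or omega < 0:
        raise ValueError("arguments must be positive (omega may be zero)")
    return L * (xi_perp * omega / E) ** 0.25
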