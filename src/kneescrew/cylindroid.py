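"""The cylindroid (Plücker's conoid): the two-system spanned by two screws.

Every screw linearly dependent on two given screws lies on a cubic ruled
surface, the cylindroid.  Its generators are parameterized by a single angle;
the two orthogonal, intersecting screws of extremal pitch are the *principal
screws* p_α, p_β, and in the canonical frame they define (x along p_α, y
along p_β, z along the nodal line) the surface satisfies

    z (x² + y²) = (h_β − h_α) x y ,

with every generator perpendicular to, and meeting, the z-axis.

Composition of two twists applied to one rigid body is linear in the
6-coordinates; the resultant screw always lies on the cylindroid of the two
components.  This is how the instantaneous axis of the knee arises: the
relative twist of thigh with respect to shank lives on the cylindroid of the
two segments' instantaneous screw axes.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
from scipy.linalg import eigh

from .screw_core import (
    Screw,
    ScrewError,
    Twist,
    screw_from_coords,
    transform_screw,
)

__all__ = [
    "Cylindroid",
    "CylindroidFrame",
    "DegenerateCylindroidError",
    "build_cylindroid",
    "screw_at",
    "compose_twists",
    "conoid_samples",
]

#: physiologically feasible thigh-vs-shank transmission-ratio range
DEFAULT_RATIO_RANGE = (0.3, 2.5)

_EPS = 1e-12


class DegenerateCylindroidError(ScrewError):
    """The two generators do not span a proper two-system."""


@dataclass(frozen=True)
class CylindroidFrame:
    """Canonical pose of a cylindroid: ``x_canonical = R.T @ (x_lab - origin)``.

    Columns of ``R`` are the lab-frame directions of the canonical x
    (principal screw p_α), y (p_β) and z (nodal line) axes.
    """

    R: np.ndarray
    origin: np.ndarray

    def to_canonical_point(self, x) -> np.ndarray:
        return self.R.T @ (np.asarray(x, dtype=float) - self.origin)

    def to_canonical_screw(self, s: Screw) -> Screw:
        return transform_screw(s, self.R.T, -self.R.T @ self.origin)

    def from_canonical_screw(self, s: Screw) -> Screw:
        return transform_screw(s, self.R, self.origin)


@dataclass(frozen=True)
class Cylindroid:
    """Two-system of screws spanned by two generators.

    ``p_alpha`` / ``p_beta`` are the principal screws (extremal pitches
    ``h_alpha`` ≤ ``h_beta``); ``b`` and ``sigma`` are half the generators'
    common-perpendicular distance and half the angle between them; ``frame``
    is the canonical pose.  ``generator_coeffs`` holds the (λ_α, λ_β) pairs
    that reproduce each generator through :func:`screw_at`.
    """

    p1: Screw
    p2: Screw
    p_alpha: Screw
    p_beta: Screw
    h_alpha: float
    h_beta: float
    b: float
    sigma: float
    frame: CylindroidFrame
    generator_coeffs: np.ndarray


def _closest_point_between_lines(p1: np.ndarray, d1: np.ndarray,
                                 p2: np.ndarray, d2: np.ndarray) -> np.ndarray:
    """Midpoint of the common perpendicular of two (non-parallel) lines."""
    n = np.cross(d1, d2)
    A = np.stack([d1, -d2, n], axis=1)
    t = np.linalg.solve(A, p2 - p1)
    c1 = p1 + t[0] * d1
    c2 = p2 + t[1] * d2
    return 0.5 * (c1 + c2)


def build_cylindroid(p1: Screw, p2: Screw) -> Cylindroid:
    """Construct the cylindroid of two finite-pitch generators.

    The principal screws are found from first principles: the pitch of
    ``λ1 p1 + λ2 p2`` is the generalized Rayleigh quotient
    ``λᵀA λ / λᵀB λ`` with ``A_ij = (d_i·m_j + d_j·m_i)/2`` and
    ``B_ij = d_i·d_j``, so the extremal pitches and the principal screws are
    the eigenpairs of ``A v = h B v``.  Coaxial or parallel generators do not
    span a proper two-system and raise :class:`DegenerateCylindroidError`.
    """
    if p1.is_infinite_pitch or p2.is_infinite_pitch:
        raise DegenerateCylindroidError(
            "cylindroid construction requires two finite-pitch generators")
    cross = np.cross(p1.d, p2.d)
    if np.linalg.norm(cross) < 1e-9:
        offset = np.linalg.norm(
            (p2.axis_point - p1.axis_point)
            - ((p2.axis_point - p1.axis_point) @ p1.d) * p1.d)
        kind = "coaxial" if offset < 1e-9 else "parallel"
        raise DegenerateCylindroidError(
            f"generators are {kind}: they span a degenerate two-system with "
            "an infinite-pitch principal screw; a proper cylindroid needs "
            "skew or intersecting non-parallel generators")

    d = np.stack([p1.d, p2.d])          # 2 x 3
    m = np.stack([p1.m, p2.m])
    B = d @ d.T
    A = 0.5 * (d @ m.T + m @ d.T)
    h, V = eigh(A, B)                   # ascending eigenvalues
    h_alpha, h_beta = float(h[0]), float(h[1])

    S = np.stack([p1.coords(), p2.coords()])   # 2 x 6
    c_alpha = V[:, 0] @ S
    c_beta = V[:, 1] @ S
    # orient x toward the bisector of the generators, then make (x, y, z)
    # right-handed with z along the nodal line
    if c_alpha[:3] @ (p1.d + p2.d) < 0:
        c_alpha = -c_alpha
    p_alpha = screw_from_coords(c_alpha)
    p_beta = screw_from_coords(c_beta)
    z_dir = np.cross(p_alpha.d, p_beta.d)
    if np.linalg.norm(z_dir) < 0.5:  # should be unit; guards numerical collapse
        raise DegenerateCylindroidError("principal screws failed to separate")

    origin = _closest_point_between_lines(
        p_alpha.axis_point, p_alpha.d, p_beta.axis_point, p_beta.d)
    R = np.stack([p_alpha.d, p_beta.d, z_dir], axis=1)
    frame = CylindroidFrame(R=R, origin=origin)

    # half-distance and half-angle of the generators themselves
    from .screw_core import screw_geometry
    rel = screw_geometry(p1, p2)
    b = 0.5 * rel.a
    sigma = 0.5 * rel.theta

    # coefficients reproducing the generators: S_i = λ_α C_α + λ_β C_β
    basis = np.stack([p_alpha.coords(), p_beta.coords()])  # 2 x 6
    coeffs, *_ = np.linalg.lstsq(basis.T, S.T, rcond=None)
    return Cylindroid(
        p1=p1, p2=p2, p_alpha=p_alpha, p_beta=p_beta,
        h_alpha=h_alpha, h_beta=h_beta, b=b, sigma=sigma,
        frame=frame, generator_coeffs=coeffs.T.copy(),
    )


def screw_at(cyl: Cylindroid, lambda_alpha: float, lambda_beta: float) -> Screw:
    """The screw of the system with principal coordinates (λ_α, λ_β).

    Returns the normalization of ``λ_α p_α + λ_β p_β`` in 6-coordinates;
    its axis is a generator of the conoid surface.
    """
    if abs(lambda_alpha) < _EPS and abs(lambda_beta) < _EPS:
        raise ScrewError("(lambda_alpha, lambda_beta) must not both be zero")
    return screw_from_coords(
        lambda_alpha * cyl.p_alpha.coords() + lambda_beta * cyl.p_beta.coords())


def compose_twists(t1: Twist, t2: Twist) -> Twist:
    """Resultant of two twists applied to one rigid body.

    The three twists close a cycle: the returned twist t satisfies
    ``t.coords() + t1.coords() + t2.coords() = 0``, so its screw is the
    (reversed) resultant and lies on the cylindroid of the two component
    screws.  Exact cancellation returns a flagged null twist.
    """
    total = t1.coords() + t2.coords()
    norm = np.linalg.norm(total)
    if norm < _EPS:
        return Twist(t1.screw, 0.0, flagged=True)
    screw = screw_from_coords(-total)
    nd = np.linalg.norm(total[:3])
    amplitude = nd if nd >= _EPS else np.linalg.norm(total[3:])
    return Twist(screw, amplitude)


def conoid_samples(cyl: Cylindroid,
                   ratio_min: float = DEFAULT_RATIO_RANGE[0],
                   ratio_max: float = DEFAULT_RATIO_RANGE[1],
                   n: int = 100) -> list[tuple[np.ndarray, np.ndarray, float]]:
    """Sample generators of the ruled surface over a transmission-ratio range.

    The transmission ratio is λ_α/λ_β with λ_β = 1; the default range
    0.3–2.5 covers the physiologically feasible thigh-versus-shank span.
    Returns ``n`` tuples ``(axis_point, direction, pitch)`` in the lab frame.
    """
    if not (0 < ratio_min < ratio_max):
        raise ScrewError("need 0 < ratio_min < ratio_max")
    if n < 2:
        raise ScrewError("need at least two samples")
    out = []
    for ratio in np.linspace(ratio_min, ratio_max, n):
        s = screw_at(cyl, float(ratio), 1.0)
        out.append((s.axis_point, s.d, s.pitch))
    return out


def conoid_samples_frame(cyl: Cylindroid, ratio_min: float, ratio_max: float,
                         n: int) -> np.ndarray:
    """Canonical-frame sample table (x, y, z, dx, dy, dz, pitch) for plotting."""
    rows = []
    for point, direction, pitch in conoid_samples(cyl, ratio_min, ratio_max, n):
        pc = cyl.frame.to_canonical_point(point)
        dc = cyl.frame.R.T @ direction
        rows.append([*pc, *dc, pitch])
    return np.asarray(rows)
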