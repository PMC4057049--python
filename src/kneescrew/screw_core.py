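"""Plücker-coordinate screw algebra.

A *screw* is a line in space together with a pitch: the common geometric
carrier for instantaneous rigid-body motions (twists) and force systems
(wrenches).  We store a screw as the six numbers ``(d, m)`` — a direction
3-vector and a moment 3-vector about the lab origin.  Normalisation
conventions:

* finite pitch: ``|d| = 1`` and the pitch is ``h = d·m`` (metres per radian);
* infinite pitch (a pure translation or couple): ``d = 0`` and ``|m| = 1``.

Magnitude information never lives in the screw itself; it is carried by
:class:`Twist.amplitude` (rad/s for rotational twists) and
:class:`Wrench.intensity` (N).

The pairing of two screws used throughout is the *virtual coefficient*

    vc(p, q) = (h + h') cos θ − a sin θ  =  d_p·m_q + d_q·m_p ,

the work rate (per unit amplitude and intensity) a wrench on one screw
performs on a twist about the other.  Two screws with ``vc = 0`` are
*reciprocal*: the wrench cannot disturb the freedom, the constraint does no
work on the motion.  Note this is the full mutual moment of the two unit
screws; Ball's classical virtual coefficient is half this value.  All
lengths are metres, all angles radians.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "Screw",
    "ScrewRelation",
    "Twist",
    "Wrench",
    "screw_from_axis",
    "screw_from_coords",
    "screw_from_points",
    "screw_geometry",
    "virtual_coefficient",
    "is_reciprocal",
    "transform_screw",
    "RECIPROCITY_TOL",
]

#: Default reciprocity tolerance, in metres (screw moments carry length units).
RECIPROCITY_TOL = 1e-9

_EPS = 1e-12


class ScrewError(ValueError):
    """Invalid screw construction or operation."""


@dataclass(frozen=True)
class Screw:
    """A normalized screw in Plücker (ray) coordinates.

    Parameters
    ----------
    d : (3,) array
        Unit direction of the axis; the zero vector for an infinite-pitch
        screw (pure translation / couple).
    m : (3,) array
        Moment about the lab origin.  For a zero-pitch screw this is
        ``point_on_axis × d``; for an infinite-pitch screw it is the unit
        translation / couple direction.
    """

    d: np.ndarray
    m: np.ndarray

    def __post_init__(self) -> None:
        object.__setattr__(self, "d", np.asarray(self.d, dtype=float).reshape(3))
        object.__setattr__(self, "m", np.asarray(self.m, dtype=float).reshape(3))

    # -- derived quantities -------------------------------------------------

    @property
    def pitch(self) -> float:
        """Pitch h in m/rad; ``inf`` for a pure translation/couple."""
        if self.is_infinite_pitch:
            return math.inf
        return float(self.d @ self.m)

    @property
    def is_infinite_pitch(self) -> bool:
        return bool(np.linalg.norm(self.d) < _EPS)

    @property
    def axis_point(self) -> np.ndarray:
        """The point on the axis nearest the origin (undefined direction at ∞ pitch)."""
        if self.is_infinite_pitch:
            raise ScrewError("axis point undefined for an infinite-pitch screw")
        return np.cross(self.d, self.m)

    # -- plumbing -----------------------------------------------------------

    def coords(self) -> np.ndarray:
        """The 6-vector (d, m)."""
        return np.concatenate([self.d, self.m])

    def negated(self) -> "Screw":
        """Same axis, opposite orientation."""
        return Screw(-self.d, -self.m)

    def to_dict(self) -> dict:
        return {"d": self.d.tolist(), "m": self.m.tolist()}

    @classmethod
    def from_dict(cls, rec: dict) -> "Screw":
        return screw_from_coords(np.concatenate([rec["d"], rec["m"]]))

    def __repr__(self) -> str:  # pragma: no cover - cosmetic
        if self.is_infinite_pitch:
            return f"Screw(∞-pitch, m={np.round(self.m, 6).tolist()})"
        return (
            f"Screw(d={np.round(self.d, 6).tolist()}, "
            f"m={np.round(self.m, 6).tolist()}, h={self.pitch:.6g})"
        )


@dataclass(frozen=True)
class ScrewRelation:
    """Relative geometry of a pair of screws.

    ``theta`` is the angle between the axes in [0, π]; ``a`` the length of
    their common perpendicular (0 when the axes meet); ``vc`` the virtual
    coefficient.  ``degenerate`` flags pairs involving an infinite-pitch
    screw, for which ``a`` is undefined (reported as ``nan``).
    """

    theta: float
    a: float
    vc: float
    degenerate: bool = False


@dataclass(frozen=True)
class Twist:
    """An instantaneous motion: a screw plus a scalar amplitude (rad/s, or
    m/s for an infinite-pitch translation)."""

    screw: Screw
    amplitude: float
    #: set when the twist came out of an exact cancellation or a
    #: below-threshold rotation and the axis is not meaningful
    flagged: bool = field(default=False, compare=False)

    def __post_init__(self) -> None:
        if not math.isfinite(self.amplitude):
            raise ScrewError("twist amplitude must be finite")

    @property
    def is_null(self) -> bool:
        return abs(self.amplitude) < _EPS

    def coords(self) -> np.ndarray:
        """Amplitude-weighted 6-vector (ω, v_O)."""
        return self.amplitude * self.screw.coords()

    def negated(self) -> "Twist":
        return Twist(self.screw, -self.amplitude, self.flagged)


@dataclass(frozen=True)
class Wrench:
    """A force system: a screw plus a scalar intensity (N, or N·m for an
    infinite-pitch couple)."""

    screw: Screw
    intensity: float
    flagged: bool = field(default=False, compare=False)

    def __post_init__(self) -> None:
        if not math.isfinite(self.intensity):
            raise ScrewError("wrench intensity must be finite")

    @property
    def is_null(self) -> bool:
        return abs(self.intensity) < _EPS

    def coords(self) -> np.ndarray:
        """Intensity-weighted 6-vector (F, M_O)."""
        return self.intensity * self.screw.coords()


# ---------------------------------------------------------------------------
# construction


def screw_from_axis(point, direction, pitch: float = 0.0) -> Screw:
    """Screw through ``point`` with the given ``direction`` and ``pitch``.

    For a finite pitch the moment is ``point × d̂ + h d̂``.  ``pitch=inf``
    builds a pure translation/couple along ``direction`` (``point`` ignored).
    """
    direction = np.asarray(direction, dtype=float).reshape(3)
    n = np.linalg.norm(direction)
    if math.isinf(pitch):
        if n < _EPS:
            raise ScrewError("infinite-pitch screw needs a nonzero direction for its moment")
        return Screw(np.zeros(3), direction / n)
    if n < _EPS:
        raise ScrewError("zero direction vector with finite pitch")
    d = direction / n
    point = np.asarray(point, dtype=float).reshape(3)
    return Screw(d, np.cross(point, d) + pitch * d)


def screw_from_coords(coords) -> Screw:
    """Normalize a raw 6-vector (d, m) into a :class:`Screw`.

    Divides by ``|d|`` when the direction is nonzero, else by ``|m|``
    (infinite-pitch case).  A zero 6-vector is rejected.
    """
    coords = np.asarray(coords, dtype=float).reshape(6)
    d, m = coords[:3], coords[3:]
    nd = np.linalg.norm(d)
    if nd >= _EPS:
        return Screw(d / nd, m / nd)
    nm = np.linalg.norm(m)
    if nm < _EPS:
        raise ScrewError("cannot normalize the zero 6-vector into a screw")
    return Screw(np.zeros(3), m / nm)


def screw_from_points(origin, insertion) -> Screw:
    """Zero-pitch screw (pure line of action) through two points, oriented
    from ``origin`` toward ``insertion`` — e.g. a ligament's line from its
    femoral origin to its tibial insertion."""
    origin = np.asarray(origin, dtype=float).reshape(3)
    insertion = np.asarray(insertion, dtype=float).reshape(3)
    return screw_from_axis(origin, insertion - origin, 0.0)


# ---------------------------------------------------------------------------
# pairwise geometry


def _axis_angle(u: np.ndarray, v: np.ndarray) -> float:
    """Angle in [0, π] between two unit vectors."""
    return math.atan2(np.linalg.norm(np.cross(u, v)), float(u @ v))


def screw_geometry(p: Screw, q: Screw) -> ScrewRelation:
    """Angle θ, common-perpendicular distance a, and virtual coefficient of a
    screw pair.

    Both quantities are symmetric in (p, q) and invariant under a rigid
    transformation applied to both screws.  If either operand has infinite
    pitch the distance is undefined: θ is then the angle between the finite
    screw's direction and the couple/translation direction, ``a`` is ``nan``
    and the relation is flagged degenerate.
    """
    vc = virtual_coefficient(p, q)
    if p.is_infinite_pitch or q.is_infinite_pitch:
        u = p.m if p.is_infinite_pitch else p.d
        v = q.m if q.is_infinite_pitch else q.d
        return ScrewRelation(theta=_axis_angle(u, v), a=math.nan, vc=vc, degenerate=True)

    theta = _axis_angle(p.d, q.d)
    n = np.cross(p.d, q.d)
    nn = np.linalg.norm(n)
    rp, rq = p.axis_point, q.axis_point
    if nn < 1e-9:  # parallel axes: perpendicular distance between the lines
        delta = rq - rp
        a = float(np.linalg.norm(delta - (delta @ p.d) * p.d))
    else:
        a = abs(float((rq - rp) @ (n / nn)))
    return ScrewRelation(theta=theta, a=a, vc=vc)


def virtual_coefficient(p: Screw, q: Screw) -> float:
    """Mutual moment d_p·m_q + d_q·m_p of two unit screws.

    Equals ``(h + h') cos θ − a sin θ`` with ``a`` signed along
    ``d_p × d_q``.  The coordinate form is authoritative (it stays finite
    for infinite-pitch screws, where it degenerates to the projection of the
    couple onto the other screw's direction).
    """
    return float(p.d @ q.m + q.d @ p.m)


def is_reciprocal(p: Screw, q: Screw, tol: float = RECIPROCITY_TOL) -> bool:
    """True iff the virtual coefficient vanishes within ``tol``.

    A reciprocal pair exchanges no work: a wrench on ``p`` cannot move a
    body whose only freedom is a twist about ``q``, and vice versa.
    """
    if tol <= 0:
        raise ScrewError("tolerance must be positive")
    return abs(virtual_coefficient(p, q)) <= tol


# ---------------------------------------------------------------------------
# rigid transformation


def transform_screw(s: Screw, rotation, translation) -> Screw:
    """Map a screw through the rigid transformation x ↦ R x + t.

    Pitch is invariant; the virtual coefficient of any pair is invariant when
    both members are transformed together.
    """
    R = np.asarray(rotation, dtype=float).reshape(3, 3)
    t = np.asarray(translation, dtype=float).reshape(3)
    if abs(np.linalg.det(R) - 1.0) > 1e-8 or np.linalg.norm(R @ R.T - np.eye(3)) > 1e-8:
        raise ScrewError("pose rotation must be proper orthogonal (det = +1)")
    if s.is_infinite_pitch:
        return Screw(np.zeros(3), R @ s.m)
    d = R @ s.d
    return Screw(d, R @ s.m + np.cross(t, d))
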