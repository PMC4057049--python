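"""Reciprocal screw systems and equilibrium decomposition of the GRF.

A knee that is instantaneously free only to twist about its instantaneous
axis (IAK) is constrained by pure force lines — the cruciate and collateral
ligaments (ACL, PCL, MCL, LCL) and the medial/lateral tibiofemoral contact
normals (P1, P2).  These lines all lie in the fifth-order screw system
reciprocal to the IAK: their reactions do no work on the permitted twist,
so they can neutralize any applied wrench that also lies in that system.

This module computes reciprocal systems by a nullspace operation on the
Plücker coordinates, reduces force-plate records to ground-reaction
wrenches, replaces a wrench by an equivalent one on another screw under the
one-degree-of-freedom equilibrium condition (equal virtual work on the
IAK), and resolves the applied wrench into constraint-line intensities —
the medial and lateral contact forces among them.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
from scipy.linalg import null_space

from .screw_core import (
    Screw,
    ScrewError,
    Twist,
    Wrench,
    screw_from_coords,
    transform_screw,
    virtual_coefficient,
)

__all__ = [
    "ConstraintSet",
    "EquilibriumSolution",
    "SpecialConfigReport",
    "NoLeverageError",
    "InconsistentWrenchError",
    "reciprocal_system",
    "grf_wrench",
    "replace_wrench",
    "decompose_wrench",
    "special_config_ratios",
    "CONSTRAINT_NAMES",
]

#: canonical ordering of the anatomical constraint lines
CONSTRAINT_NAMES = ("ACL", "PCL", "MCL", "LCL", "P1", "P2")

#: relative singular-value cutoff for rank / nullspace decisions
RANK_RTOL = 1e-10

# the 6x6 involution pairing (d, m) <-> (m, d); vc(p, q) = p' Delta q
_DELTA = np.block([[np.zeros((3, 3)), np.eye(3)], [np.eye(3), np.zeros((3, 3))]])


class NoLeverageError(ScrewError):
    """The replacement screw is reciprocal to the IAK: it cannot act on the
    joint's freedom, so no intensity on it can balance the applied wrench."""


class InconsistentWrenchError(ScrewError):
    """The applied wrench has a component outside the constraint span: it
    would move the joint and no static constraint reaction can balance it."""


@dataclass
class ConstraintSet:
    """Named zero-pitch constraint lines of the knee.

    Members are keyed by :data:`CONSTRAINT_NAMES`; P1 is the medial and P2
    the lateral contact normal.  For the reciprocal manifold of a single
    IAK the six lines span a screw space of rank 5 (one linear relation
    among the coefficients).
    """

    screws: dict[str, Screw]
    source: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        missing = [n for n in CONSTRAINT_NAMES if n not in self.screws]
        if missing:
            raise ScrewError(f"constraint set missing lines: {missing}")
        for name, s in self.screws.items():
            if not s.is_infinite_pitch and abs(s.pitch) > 1e-9:
                raise ScrewError(f"constraint line {name} must have zero pitch "
                                 f"(got h={s.pitch:.3g})")

    def __getitem__(self, name: str) -> Screw:
        return self.screws[name]

    def matrix(self) -> np.ndarray:
        """6 × n matrix whose columns are the constraint 6-vectors."""
        return np.stack([self.screws[n].coords() for n in CONSTRAINT_NAMES], axis=1)

    def rank(self, rtol: float = RANK_RTOL) -> int:
        s = np.linalg.svd(self.matrix(), compute_uv=False)
        return int(np.sum(s > rtol * s[0]))

    def transformed(self, rotation, translation) -> "ConstraintSet":
        """The same lines mapped through a rigid pose (e.g. tibia → lab)."""
        return ConstraintSet(
            {n: transform_screw(s, rotation, translation) for n, s in self.screws.items()},
            source=dict(self.source),
        )

    def to_dict(self) -> dict:
        return {n: self.screws[n].to_dict() for n in CONSTRAINT_NAMES}


@dataclass
class EquilibriumSolution:
    """Constraint intensities balancing one applied wrench.

    ``intensities`` maps line name → N; positive values push along the
    line's stored orientation.  ``medial_force``/``lateral_force`` are the
    P1/P2 entries.  Negative contact intensities (tension at a contact) are
    reported as-is and flagged physiologically inconsistent, never clamped.
    """

    intensities: dict[str, float]
    residual: float
    rank: int
    medial_force: float
    lateral_force: float
    inconsistent_contact: bool

    def as_array(self) -> np.ndarray:
        return np.array([self.intensities[n] for n in CONSTRAINT_NAMES])


@dataclass(frozen=True)
class SpecialConfigReport:
    """Diagnostics of a special (control-losing) configuration.

    ratio1 = Σ|actuator twist amplitudes| / |end-effector twist amplitude|
    (→ 0 at the special configuration); ratio2 = Σ|actuator wrench
    intensities| / |end-effector wrench intensity| (→ ∞ there).
    """

    ratio1: float
    ratio2: float
    is_special: bool


# ---------------------------------------------------------------------------
# reciprocal systems


def reciprocal_system(screws: list[Screw], tol: float = 1e-12,
                      rtol: float = RANK_RTOL) -> list[Screw]:
    """Basis of the screw system reciprocal to every input screw.

    The reciprocity conditions are linear in Plücker coordinates, so the
    basis is the nullspace of the input coordinate matrix under the
    (d, m)-swap pairing.  The dimension is ``6 − rank(inputs)``: one generic
    screw leaves a fifth-order system, five independent constraint lines
    leave the single axis they all meet, six spanning screws leave nothing.
    """
    if tol <= 0:
        raise ScrewError("tolerance must be positive")
    if not 1 <= len(screws) <= 6:
        raise ScrewError("need between 1 and 6 input screws")
    S = np.stack([s.coords() for s in screws])        # n x 6
    basis = null_space(S @ _DELTA, rcond=rtol)
    return [screw_from_coords(basis[:, j]) for j in range(basis.shape[1])]


# ---------------------------------------------------------------------------
# force-plate reduction


def grf_wrench(force, cop, free_moment=(0.0, 0.0, 0.0),
               force_floor: float = 1e-12) -> Wrench:
    """Ground-reaction wrench from force, centre of pressure and free moment.

    The wrench line passes through the COP along the force; the free moment
    (vertical torque of a standard plate reduction) folds into the moment
    about the origin, ``M_O = cop × F + T``, giving a generally nonzero
    pitch.  Zero force with a pure free moment is an infinite-pitch couple;
    zero force and zero moment is a flagged null wrench.
    """
    F = np.asarray(force, dtype=float).reshape(3)
    cop = np.asarray(cop, dtype=float).reshape(3)
    T = np.asarray(free_moment, dtype=float).reshape(3)
    M = np.cross(cop, F) + T
    nF = np.linalg.norm(F)
    if nF > force_floor:
        return Wrench(Screw(F / nF, M / nF), float(nF))
    nM = np.linalg.norm(M)
    if nM > force_floor:
        return Wrench(Screw(np.zeros(3), M / nM), float(nM))
    return Wrench(Screw(np.array([0.0, 0.0, 1.0]), np.zeros(3)), 0.0, flagged=True)


# ---------------------------------------------------------------------------
# one-DOF equilibrium


def replace_wrench(phi: Wrench, eta_screw: Screw, iak: Screw,
                   leverage_tol: float = 1e-12) -> float:
    """Intensity η″ on ``eta_screw`` equivalent to ``phi`` about the IAK.

    Under the one-degree-of-freedom equilibrium condition the two wrenches
    must perform equal and opposite virtual work on any twist about the
    IAK:  η″·vc(η, IAK) + φ″·vc(φ, IAK) = 0.  A replacement screw reciprocal
    to the IAK has no leverage on the freedom and raises
    :class:`NoLeverageError`.
    """
    vc_eta = virtual_coefficient(eta_screw, iak)
    if abs(vc_eta) <= leverage_tol:
        raise NoLeverageError(
            "replacement screw is reciprocal to the IAK; it cannot act on "
            "this freedom (virtual coefficient "
            f"{vc_eta:.3g} <= {leverage_tol:.3g})")
    vc_phi = virtual_coefficient(phi.screw, iak)
    return -phi.intensity * vc_phi / vc_eta


def decompose_wrench(w: Wrench, constraints: ConstraintSet, iak: Screw,
                     recip_tol: float = 1e-6,
                     consistency_rtol: float = 1e-6,
                     rank_rtol: float = RANK_RTOL) -> EquilibriumSolution:
    """Resolve an applied wrench into constraint-line intensities.

    Solves ``Σ xᵢ Sᵢ + w = 0`` in 6-coordinates by minimum-norm least
    squares (the six anatomical lines span only rank 5, leaving one
    coefficient combination unresolvable; the minimum-norm representative
    is reported and the rank recorded so a user supplying five independent
    lines gets the unique solution).  Preconditions: every constraint line
    reciprocal to the IAK within ``recip_tol``; the wrench must lie in the
    constraint span within ``consistency_rtol`` — otherwise it would move
    the joint and :class:`InconsistentWrenchError` is raised.
    """
    for name in CONSTRAINT_NAMES:
        vc = virtual_coefficient(constraints[name], iak)
        if abs(vc) > recip_tol:
            raise ScrewError(
                f"constraint line {name} is not reciprocal to the IAK "
                f"(|vc| = {abs(vc):.3g} > {recip_tol:.3g})")

    A = constraints.matrix()
    b = -w.coords()
    x, _, rank, _ = np.linalg.lstsq(A, b, rcond=rank_rtol)
    residual = float(np.linalg.norm(A @ x - b))
    scale = max(np.linalg.norm(b), 1.0)
    if residual > consistency_rtol * scale:
        raise InconsistentWrenchError(
            "applied wrench lies outside the constraint span "
            f"(relative residual {residual / scale:.3g}); equilibrium about "
            "the IAK is impossible")
    intensities = {n: float(x[i]) for i, n in enumerate(CONSTRAINT_NAMES)}
    return EquilibriumSolution(
        intensities=intensities,
        residual=residual,
        rank=int(rank),
        medial_force=intensities["P1"],
        lateral_force=intensities["P2"],
        inconsistent_contact=bool(intensities["P1"] < -1e-9 or intensities["P2"] < -1e-9),
    )


def special_config_ratios(actuator_twists: list[Twist], end_twist: Twist,
                          actuator_wrenches: list[Wrench], end_wrench: Wrench,
                          ratio1_tol: float = 1e-9,
                          ratio2_threshold: float = 1e9) -> SpecialConfigReport:
    """Twist-amplitude and wrench-intensity ratios diagnosing a special
    configuration (actuators losing static control of the end-effector
    freedom: ratio1 → 0 while ratio2 → ∞).  Zero denominators report an
    infinite ratio rather than an error."""
    sum_amp = float(sum(abs(t.amplitude) for t in actuator_twists))
    sum_int = float(sum(abs(wr.intensity) for wr in actuator_wrenches))
    end_amp = abs(end_twist.amplitude)
    end_int = abs(end_wrench.intensity)
    ratio1 = sum_amp / end_amp if end_amp > 0 else math.inf
    ratio2 = sum_int / end_int if end_int > 0 else math.inf
    return SpecialConfigReport(
        ratio1=ratio1,
        ratio2=ratio2,
        is_special=bool(ratio1 <= ratio1_tol and ratio2 >= ratio2_threshold),
    )
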