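"""Segment poses from marker clusters and instantaneous screw axes.

Each body segment (thigh, shank) carries a cluster of ≥ 3 non-collinear
markers.  Per-frame rigid poses are estimated by the least-squares
orthogonal (Kabsch) fit of the cluster to its reference configuration.  The
instantaneous screw axis (ISA) of a segment is extracted from the finite
displacement between neighbouring frames: the relative pose over the
central-difference window ``[t−1, t+1]`` is reduced to its screw — axis,
pitch, and rotation amplitude — which for motion about a fixed axis is
exact regardless of the rate profile.

The instantaneous axis of the knee (IAK) is the relative twist of the thigh
with respect to the shank, obtained by differencing the two segments'
twists in the common lab frame; it lies on the cylindroid of the two ISAs.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

from .screw_core import Screw, ScrewError, Twist, screw_from_axis

__all__ = [
    "MarkerTrajectory",
    "PoseSequence",
    "rigid_fit",
    "fit_pose_sequence",
    "moving_average",
    "twist_from_poses",
    "screw_displacement",
    "relative_twist",
    "ROTATION_GATE_RAD",
]

#: frames whose window rotation falls below this are translation-dominated
#: and excluded from cylindroid construction (0.1 degree)
ROTATION_GATE_RAD = math.radians(0.1)


@dataclass
class MarkerTrajectory:
    """Labelled marker positions over time.

    positions: (n_frames, n_markers, 3) in metres; rate in Hz.
    ``body_reference`` is an optional anatomical calibration: the marker
    coordinates in the segment's body frame (markers × 3).  When present,
    fitted poses map that body frame to the lab — which is what lets
    constraint geometry given in the tibia frame be carried into the lab.
    Without it poses are relative to a chosen frame's marker layout (a
    technical frame).
    """

    labels: list[str]
    positions: np.ndarray
    rate: float
    body_reference: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.positions = np.asarray(self.positions, dtype=float)
        if self.positions.ndim != 3 or self.positions.shape[2] != 3:
            raise ScrewError("positions must have shape (frames, markers, 3)")
        if self.positions.shape[1] != len(self.labels):
            raise ScrewError("label count does not match marker count")
        if self.rate <= 0:
            raise ScrewError("frame rate must be positive")
        if self.body_reference is not None:
            self.body_reference = np.asarray(self.body_reference, dtype=float)
            if self.body_reference.shape != (self.positions.shape[1], 3):
                raise ScrewError("body_reference must be (markers, 3)")

    @property
    def n_frames(self) -> int:
        return self.positions.shape[0]

    def subset(self, labels: list[str]) -> "MarkerTrajectory":
        """Trajectory restricted to the named markers (order preserved)."""
        try:
            idx = [self.labels.index(l) for l in labels]
        except ValueError as exc:
            raise ScrewError(f"unknown marker label: {exc}") from exc
        ref = None if self.body_reference is None else self.body_reference[idx]
        return MarkerTrajectory(list(labels), self.positions[:, idx, :],
                                self.rate, ref)


@dataclass
class PoseSequence:
    """Per-frame rigid poses x_lab = R x_body + t."""

    rotations: np.ndarray    # (n, 3, 3), proper orthogonal
    translations: np.ndarray  # (n, 3) metres
    rate: float
    residual_rms: np.ndarray = field(default=None)  # per-frame fit RMS (m)

    def __post_init__(self) -> None:
        self.rotations = np.asarray(self.rotations, dtype=float)
        self.translations = np.asarray(self.translations, dtype=float)
        if self.residual_rms is None:
            self.residual_rms = np.zeros(len(self.translations))

    def __len__(self) -> int:
        return len(self.translations)


def rigid_fit(reference: np.ndarray, frame: np.ndarray) -> tuple[np.ndarray, np.ndarray, float]:
    """Least-squares rigid pose mapping ``reference`` markers onto ``frame``.

    Kabsch/SVD solution of min Σ‖R x_i + t − y_i‖²; returns (R, t, rms).
    Raises on collinear or degenerate clusters (rank < 2 after centering).
    """
    X = np.asarray(reference, dtype=float)
    Y = np.asarray(frame, dtype=float)
    if X.shape != Y.shape or X.ndim != 2 or X.shape[1] != 3 or X.shape[0] < 3:
        raise ScrewError("need matching (n>=3, 3) marker arrays")
    cx, cy = X.mean(axis=0), Y.mean(axis=0)
    X0, Y0 = X - cx, Y - cy
    H = X0.T @ Y0
    U, s, Vt = np.linalg.svd(H)
    # collinear cluster: centered marker cloud has rank < 2
    if np.linalg.matrix_rank(X0, tol=1e-10 * max(1.0, s[0] if s[0] > 0 else 1.0)) < 2:
        raise ScrewError("marker cluster is collinear or degenerate; rigid fit is rank-deficient")
    D = np.eye(3)
    D[2, 2] = np.sign(np.linalg.det(Vt.T @ U.T))
    R = Vt.T @ D @ U.T
    t = cy - R @ cx
    rms = float(np.sqrt(np.mean(np.sum((Y - (X @ R.T + t)) ** 2, axis=1))))
    return R, t, rms


def fit_pose_sequence(traj: MarkerTrajectory, reference_frame: int = 0) -> PoseSequence:
    """Per-frame rigid poses of a marker cluster.

    With a ``body_reference`` calibration the poses map the segment's body
    frame to the lab; otherwise they are relative to the layout observed at
    ``reference_frame`` (a technical frame, identity there).
    """
    ref = traj.body_reference if traj.body_reference is not None \
        else traj.positions[reference_frame]
    n = traj.n_frames
    Rs = np.empty((n, 3, 3))
    ts = np.empty((n, 3))
    rms = np.empty(n)
    for i in range(n):
        Rs[i], ts[i], rms[i] = rigid_fit(ref, traj.positions[i])
    return PoseSequence(Rs, ts, traj.rate, rms)


def moving_average(traj: MarkerTrajectory, window: int) -> MarkerTrajectory:
    """Centered moving-average smoother on marker positions.

    The window shrinks symmetrically near the ends so no frames are lost.
    ``window`` must be odd; 1 returns the input unchanged.  This is the only
    filtering offered: axis estimation is noise-limited by the rotation
    increment between frames, and a short boxcar trades a little lag for a
    √window reduction in marker noise.
    """
    if window < 1 or window % 2 == 0:
        raise ScrewError("smoothing window must be a positive odd integer")
    if window == 1:
        return traj
    n = traj.n_frames
    half = window // 2
    out = np.empty_like(traj.positions)
    for i in range(n):
        h = min(half, i, n - 1 - i)
        out[i] = traj.positions[i - h:i + h + 1].mean(axis=0)
    return MarkerTrajectory(list(traj.labels), out, traj.rate, traj.body_reference)


# ---------------------------------------------------------------------------
# finite-displacement screws


def _rotation_log(R: np.ndarray) -> tuple[np.ndarray, float]:
    """Axis (unit) and angle in [0, π] of a rotation matrix."""
    cos_phi = np.clip((np.trace(R) - 1.0) / 2.0, -1.0, 1.0)
    phi = math.acos(cos_phi)
    w = 0.5 * np.array([R[2, 1] - R[1, 2], R[0, 2] - R[2, 0], R[1, 0] - R[0, 1]])
    sn = np.linalg.norm(w)
    if sn > 1e-12:
        return w / sn, phi
    if phi < 1e-8:
        return np.array([0.0, 0.0, 1.0]), 0.0
    # angle near pi: axis from the symmetric part
    M = 0.5 * (R + np.eye(3))
    axis = np.sqrt(np.clip(np.diag(M), 0.0, None))
    k = int(np.argmax(axis))
    axis = M[:, k] / axis[k] if axis[k] > 0 else np.array([0.0, 0.0, 1.0])
    return axis / np.linalg.norm(axis), phi


def screw_displacement(R: np.ndarray, p: np.ndarray,
                       rotation_gate: float = ROTATION_GATE_RAD
                       ) -> tuple[Screw, float, bool]:
    """Reduce a rigid displacement x ↦ R x + p to its screw.

    Returns (screw, rotation angle φ, translation_dominated).  For
    ``φ >= rotation_gate`` the screw is the finite-pitch axis with pitch
    ``(u·p)/φ`` and axis point ``½(p⊥ + cot(φ/2) u × p⊥)``; below the gate
    the displacement is reported as an infinite-pitch translation (amplitude
    to be taken as ‖p‖) and flagged.
    """
    p = np.asarray(p, dtype=float)
    u, phi = _rotation_log(np.asarray(R, dtype=float))
    if phi < rotation_gate:
        norm_p = np.linalg.norm(p)
        if norm_p < 1e-15:
            return screw_from_axis(np.zeros(3), np.array([0.0, 0.0, 1.0]), 0.0), phi, True
        return Screw(np.zeros(3), p / norm_p), phi, True
    pitch = float(u @ p) / phi
    p_perp = p - (u @ p) * u
    c = 0.5 * (p_perp + (np.cross(u, p_perp)) / math.tan(phi / 2.0))
    return screw_from_axis(c, u, pitch), phi, False


def twist_from_poses(poses: PoseSequence,
                     rotation_gate: float = ROTATION_GATE_RAD,
                     min_window_rotation: float | None = None) -> list[Twist]:
    """Per-frame twists (rad/s) from finite differences of a pose sequence.

    Interior frames use the displacement over ``[t−1, t+1]``; the end frames
    use one-sided windows.  Frames whose window rotation is below
    ``rotation_gate`` come back as flagged infinite-pitch translation twists
    (amplitude in m/s) and should be excluded from cylindroid construction.

    ``min_window_rotation`` (rad) enables an adaptive window: the symmetric
    differentiation window grows until the rotation across it reaches the
    threshold (or the series is exhausted).  Axis-direction noise scales
    inversely with the rotation increment, so noisy captures benefit from a
    few degrees here; for motion about a fixed axis any window returns the
    exact axis and the mean rate over the window.
    """
    n = len(poses)
    if n < 3:
        raise ScrewError("need at least 3 frames to differentiate poses")
    dt = 1.0 / poses.rate
    twists: list[Twist] = []
    for i in range(n):
        h = 1
        while True:
            j0, j1 = max(i - h, 0), min(i + h, n - 1)
            span = (j1 - j0) * dt
            R0, t0 = poses.rotations[j0], poses.translations[j0]
            R1, t1 = poses.rotations[j1], poses.translations[j1]
            # displacement taking the body from pose j0 to pose j1, in lab frame
            R = R1 @ R0.T
            p = t1 - R @ t0
            screw, phi, translational = screw_displacement(R, p, rotation_gate)
            exhausted = j0 == 0 and j1 == n - 1
            if (min_window_rotation is None or phi >= min_window_rotation
                    or exhausted):
                break
            h += 1
        if translational:
            amp = np.linalg.norm(p) / span
            twists.append(Twist(screw, amp, flagged=True))
        else:
            # a window that ran out of frames before reaching the requested
            # rotation (e.g. at a velocity reversal) is below the reliability
            # threshold: keep the estimate but flag it
            weak = min_window_rotation is not None and phi < min_window_rotation
            twists.append(Twist(screw, phi / span, flagged=weak))
    return twists


def relative_twist(thigh: Twist, shank: Twist) -> Twist:
    """Instantaneous twist of the thigh relative to the shank (the IAK).

    Computed by differencing the amplitude-weighted 6-vectors in the shared
    lab frame; the resulting screw is a linear combination of the two ISAs
    and hence lies on their cylindroid.  Two identical twists give a flagged
    null IAK.
    """
    from .screw_core import screw_from_coords

    rel = thigh.coords() - shank.coords()
    norm = np.linalg.norm(rel)
    if norm < 1e-12:
        return Twist(thigh.screw, 0.0, flagged=True)
    screw = screw_from_coords(rel)
    nd = np.linalg.norm(rel[:3])
    amplitude = nd if nd >= 1e-12 else norm
    return Twist(screw, amplitude)
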