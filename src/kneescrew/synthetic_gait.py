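"""Forward-constructed synthetic trials with exact ground truth.

Every pipeline stage is testable without external data because the trials
are built backwards from the answer:

* marker clouds ride rigidly on screw motions whose axis, pitch and rate
  profile are stored, so the instantaneous-axis estimator has an exact
  target;
* the knee constraint geometry is constructed so that all six anatomical
  lines intersect a chosen flexion axis (femoral attachments idealized
  onto the transepicondylar line), making them exactly reciprocal to the
  IAK and of rank 5 by construction;
* the ground-reaction wrench of each stance frame is assembled as a known
  nonnegative combination of those constraint lines, so the true medial
  and lateral contact forces are stored with the trial.  Because six
  rank-5 lines leave one coefficient combination unidentifiable, the
  stored truth is the minimum-norm representative of the generating
  intensities — the same representative the decomposition reports.

The vertical GRF follows the classic double-hump (M-shaped) stance
profile; defaults emulate an adult walking at a comfortable speed
(stance 0.6 s, peak 1.1 body weight, 70 kg).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, asdict

import numpy as np
import pandas as pd

from .constraint_equilibrium import CONSTRAINT_NAMES, ConstraintSet
from .screw_core import Screw, ScrewError, Twist, screw_from_axis, transform_screw
from .segment_kinematics import MarkerTrajectory

__all__ = [
    "GeometryParams",
    "GaitParams",
    "SyntheticTrial",
    "gen_helical_motion",
    "gen_constraint_geometry",
    "gen_stance_trial",
    "rotation_about_axis",
]

_G = 9.81  # m/s^2


def rotation_about_axis(u: np.ndarray, angle: float) -> np.ndarray:
    """Rodrigues rotation matrix about a unit axis."""
    u = np.asarray(u, dtype=float)
    K = np.array([[0, -u[2], u[1]], [u[2], 0, -u[0]], [-u[1], u[0], 0]])
    return np.eye(3) + math.sin(angle) * K + (1 - math.cos(angle)) * (K @ K)


# ---------------------------------------------------------------------------
# helical marker motion


def gen_helical_motion(seed: int, axis: Screw, pitch: float,
                       amplitude_profile, n_markers: int = 6,
                       noise_sd: float = 0.0, rate: float = 100.0,
                       cluster_radius: float = 0.08,
                       ) -> tuple[MarkerTrajectory, dict]:
    """Markers riding rigidly on a screw motion about a fixed axis.

    ``amplitude_profile`` is the rotation angle per frame (rad, array-like);
    each frame's marker cloud is the reference cloud displaced about
    ``axis`` by that angle with translation ``pitch × angle`` along the
    axis, plus isotropic Gaussian noise of ``noise_sd`` metres.

    The returned truth record stores the generating screw (with pitch) and
    the central-difference amplitude rate per frame — the quantity a
    finite-displacement estimator sees exactly for motion about a fixed
    axis, whatever the rate profile.
    """
    if n_markers < 4:
        raise ScrewError("need at least 4 markers for a robust cluster")
    if noise_sd < 0:
        raise ScrewError("noise_sd must be nonnegative")
    angles = np.asarray(amplitude_profile, dtype=float)
    if angles.ndim != 1 or len(angles) < 3:
        raise ScrewError("amplitude_profile must be a 1-D array of >= 3 frames")
    rng = np.random.default_rng(seed)

    u = axis.d
    c = axis.axis_point
    # non-degenerate cluster: jittered tetrahedron offset from the axis
    base = np.array([[1, 1, 1], [1, -1, -1], [-1, 1, -1], [-1, -1, 1]], dtype=float)
    extra = rng.uniform(-1, 1, size=(max(0, n_markers - 4), 3))
    cloud = np.vstack([base, extra])[:n_markers] * cluster_radius
    cloud += c + 2.0 * cluster_radius * rng.standard_normal(3)
    if np.linalg.matrix_rank(cloud - cloud.mean(axis=0), tol=1e-9) < 2:
        raise ScrewError("degenerate marker layout")  # pragma: no cover

    n = len(angles)
    pos = np.empty((n, n_markers, 3))
    for t, th in enumerate(angles):
        R = rotation_about_axis(u, th)
        pos[t] = (cloud - c) @ R.T + c + pitch * th * u
    if noise_sd > 0:
        pos += noise_sd * rng.standard_normal(pos.shape)

    dt = 1.0 / rate
    rates = np.gradient(angles, dt)  # central differences, one-sided at ends
    truth = {
        "screw": screw_from_axis(c, u, pitch),
        "pitch": pitch,
        "angles": angles.copy(),
        "amplitude_rates": rates,
        "seed": seed,
        "noise_sd": noise_sd,
    }
    labels = [f"M{i + 1}" for i in range(n_markers)]
    return MarkerTrajectory(labels, pos, rate), truth


# ---------------------------------------------------------------------------
# constraint geometry


@dataclass
class GeometryParams:
    """Frontal-plane knee geometry in the tibia frame.

    Tibia frame: origin at the joint centre on the tibial plateau, x medial
    (−) to lateral (+), y anterior, z proximal.  All lengths metres, angles
    radians.  The flexion axis is the x-axis through the origin (the
    transepicondylar line); femoral attachments are idealized onto it so
    every constraint line is exactly reciprocal to that axis.
    """

    contact_offset: float = 0.022      # |x| of each contact point
    contact_tilt: float = math.radians(5.0)  # contact-normal tilt from vertical
    epicondyle_halfwidth: float = 0.045      # collateral femoral |x|
    cruciate_offset: float = 0.008     # cruciate femoral |x| in the notch
    collateral_drop: float = 0.065     # distal distance to collateral insertions
    cruciate_drop: float = 0.025       # distal distance to cruciate insertions
    cruciate_reach: float = 0.022      # anterior/posterior cruciate insertion |y|
    jitter: float = 0.0                # uniform attachment jitter half-range (m)

    def validate(self) -> None:
        if not 0.01 <= self.contact_offset <= 0.05:
            raise ScrewError("contact_offset outside 10-50 mm")
        if not 0.0 <= self.contact_tilt <= math.radians(20):
            raise ScrewError("contact_tilt outside 0-20 degrees")
        if not 0.025 <= self.epicondyle_halfwidth <= 0.07:
            raise ScrewError("epicondyle_halfwidth outside 25-70 mm")
        if not 0.0 <= self.jitter <= 0.01:
            raise ScrewError("jitter outside 0-10 mm")


def knee_flexion_axis() -> Screw:
    """The tibia-frame flexion axis: the x-axis line through the origin."""
    return screw_from_axis([0.0, 0.0, 0.0], [1.0, 0.0, 0.0], 0.0)


def gen_constraint_geometry(seed: int, params: GeometryParams | None = None,
                            max_attempts: int = 8) -> ConstraintSet:
    """Six zero-pitch constraint lines reciprocal to the knee flexion axis.

    P1/P2 are the medial/lateral contact normals (near-vertical lines
    through contact points on the plateau, mirror-symmetric about the
    sagittal plane for the symmetric defaults); ACL/PCL/MCL/LCL run from
    femoral attachments on the flexion axis to jittered tibial insertions.
    The set has rank 5; a degenerate draw is regenerated with diagnostics
    in the metadata.
    """
    params = params or GeometryParams()
    params.validate()
    rng = np.random.default_rng(seed)
    attempts = 0
    while True:
        attempts += 1
        j = (lambda: rng.uniform(-params.jitter, params.jitter, size=3)) if params.jitter > 0 \
            else (lambda: np.zeros(3))
        w = params.contact_offset
        st, ct = math.sin(params.contact_tilt), math.cos(params.contact_tilt)
        # orientation convention: positive intensity is the force the femur
        # exerts on the tibia — contact normals point distally (compression
        # positive), ligament lines point from tibial insertion to femoral
        # origin (tension positive)
        screws = {
            "P1": screw_from_axis(np.array([-w, 0.0, 0.0]) + j() * [1, 0, 0],
                                  [0.0, -st, -ct], 0.0),
            "P2": screw_from_axis(np.array([+w, 0.0, 0.0]) + j() * [1, 0, 0],
                                  [0.0, -st, -ct], 0.0),
            "MCL": _line(np.array([-w - 0.012, 0.008, -params.collateral_drop]) + j(),
                         np.array([-params.epicondyle_halfwidth, 0.0, 0.0])),
            "LCL": _line(np.array([+w + 0.012, 0.004, -params.collateral_drop]) + j(),
                         np.array([+params.epicondyle_halfwidth, 0.0, 0.0])),
            "ACL": _line(np.array([0.002, +params.cruciate_reach,
                                   -params.cruciate_drop]) + j(),
                         np.array([+params.cruciate_offset, 0.0, 0.0])),
            "PCL": _line(np.array([0.002, -params.cruciate_reach,
                                   -params.cruciate_drop - 0.005]) + j(),
                         np.array([-params.cruciate_offset, 0.0, 0.0])),
        }
        cs = ConstraintSet(screws, source={
            "seed": seed, "attempts": attempts, "params": asdict(params),
            "flexion_axis": knee_flexion_axis().to_dict(),
        })
        if cs.rank() == 5:
            return cs
        if attempts >= max_attempts:  # pragma: no cover - defaults never get here
            raise ScrewError(
                f"could not draw a rank-5 constraint geometry in {max_attempts} "
                f"attempts (last rank {cs.rank()}); widen the parameter ranges")


def _line(origin: np.ndarray, insertion: np.ndarray) -> Screw:
    from .screw_core import screw_from_points
    return screw_from_points(origin, insertion)


# ---------------------------------------------------------------------------
# stance trials


@dataclass
class GaitParams:
    """Stance-phase trial parameters (defaults: comfortable adult walking)."""

    stance_duration: float = 0.6   # s, physiological range 0.4-0.8
    rate: float = 100.0            # Hz
    body_mass: float = 70.0        # kg
    grf_peak_bw: float = 1.1       # peak vertical GRF in body weights, 0.8-1.5
    flexion_amplitude: float = math.radians(15.0)  # stance flexion wave
    marker_noise_sd: float = 0.0   # m
    n_markers: int = 4             # per segment
    pad_frames: int = 5            # zero-GRF swing padding at each end
    ligament_load: float = 30.0    # peak ligament-line intensity (N)
    medial_share: float = 0.58     # fraction of contact load on P1
    shank_sway: float = 0.0        # rad, slow whole-leg sway about vertical
    geometry: GeometryParams = field(default_factory=GeometryParams)

    def validate(self) -> None:
        if not 0.4 <= self.stance_duration <= 0.8:
            raise ScrewError("stance_duration outside 0.4-0.8 s")
        if not 0.8 <= self.grf_peak_bw <= 1.5:
            raise ScrewError("grf_peak_bw outside 0.8-1.5 body weights")
        if not 0.0 <= self.medial_share <= 1.0:
            raise ScrewError("medial_share must be a fraction")
        if self.rate < 20:
            raise ScrewError("rate below 20 Hz undersamples stance")
        if self.marker_noise_sd < 0:
            raise ScrewError("marker_noise_sd must be nonnegative")


@dataclass
class SyntheticTrial:
    """A forward-constructed stance trial with stored ground truth."""

    seed: int
    params: GaitParams
    thigh_markers: MarkerTrajectory
    shank_markers: MarkerTrajectory
    grf: pd.DataFrame               # time, Fx..Fz, COPx..COPz, Tz
    geometry: ConstraintSet         # tibia frame
    shank_pose: tuple[np.ndarray, np.ndarray]  # constant (R, t), tibia -> lab
    truth: dict

    def as_bundle(self, stance_threshold: float = 20.0):
        """Package the trial as pipeline input (a :class:`gait_io.TrialBundle`)."""
        from .gait_io import GRFSeries, TrialBundle

        n = len(self.grf)
        force = self.grf[["Fx", "Fy", "Fz"]].to_numpy(float)
        free = np.zeros((n, 3))
        free[:, 2] = self.grf["Tz"].to_numpy(float)
        grf = GRFSeries(
            time=self.grf["time"].to_numpy(float),
            force=force,
            cop=self.grf[["COPx", "COPy", "COPz"]].to_numpy(float),
            free_moment=free,
            stance_mask=force[:, 2] >= stance_threshold,
            threshold=stance_threshold,
        )
        return TrialBundle(
            thigh=self.thigh_markers, shank=self.shank_markers,
            grf=grf, geometry=self.geometry,
            provenance={"synthetic_seed": self.seed},
        )


def _vertical_grf_profile(tau: np.ndarray) -> np.ndarray:
    """Double-hump stance profile on tau in [0, 1], normalized to max 1."""
    g = np.sin(np.pi * tau) + 0.2 * np.sin(3 * np.pi * tau)
    g = np.clip(g, 0.0, None)
    return g / g.max()


def _cop_from_wrench(F: np.ndarray, M: np.ndarray, z0: float
                     ) -> tuple[np.ndarray, float]:
    """Centre of pressure on the plane z = z0 and vertical free moment
    reproducing the wrench (F, M about the origin)."""
    if abs(F[2]) < 1e-9:
        return np.array([0.0, 0.0, z0]), 0.0
    cx = (z0 * F[0] - M[1]) / F[2]
    cy = (M[0] + z0 * F[1]) / F[2]
    tz = M[2] - cx * F[1] + cy * F[0]
    return np.array([cx, cy, z0]), float(tz)


def gen_stance_trial(seed: int, params: GaitParams | None = None) -> SyntheticTrial:
    """One synthetic stance-phase trial with exact decomposition truth.

    The shank is held at a fixed pose (foot planted; an optional slow
    ``shank_sway`` exercises the moving-frame path), the thigh flexes about
    the knee axis with a smooth stance wave, and the GRF wrench is a known
    nonnegative combination of the lab-frame constraint lines.  Stored
    truth: per-frame IAK screw and rate, per-frame constraint intensities
    (minimum-norm representative) and the generating intensities.
    """
    params = params or GaitParams()
    params.validate()
    rng = np.random.default_rng(seed)

    geometry = gen_constraint_geometry(int(rng.integers(2**31 - 1)), params.geometry)

    n_stance = int(round(params.stance_duration * params.rate)) + 1
    pad = params.pad_frames
    n = n_stance + 2 * pad
    dt = 1.0 / params.rate
    time = np.arange(n) * dt
    tau = np.clip((np.arange(n) - pad) / (n_stance - 1), 0.0, 1.0)

    # knee flexion angle: smooth wave, near extension at contact and toe-off
    theta = params.flexion_amplitude * np.sin(np.pi * tau) ** 2

    # constant shank pose: knee centre ~0.45 m above ground, slight toe-out
    R_shank0 = rotation_about_axis([0, 0, 1], math.radians(8.0))
    t_shank0 = np.array([0.05, 0.10, 0.45])
    sway = params.shank_sway * np.sin(np.pi * tau)

    knee_axis_tibia = knee_flexion_axis()

    # marker clouds in the tibia/thigh body frames (jittered tetrahedra)
    base = np.array([[1, 1, 1], [1, -1, -1], [-1, 1, -1], [-1, -1, 1]], float)
    extra_t = rng.uniform(-1, 1, size=(max(0, params.n_markers - 4), 3))
    extra_s = rng.uniform(-1, 1, size=(max(0, params.n_markers - 4), 3))
    thigh_cloud = np.vstack([base, extra_t])[: params.n_markers] * 0.06 \
        + np.array([0.0, 0.02, 0.22])
    shank_cloud = np.vstack([base, extra_s])[: params.n_markers] * 0.05 \
        + np.array([0.0, 0.03, -0.20])

    A_tibia = geometry.matrix()

    # generating intensities: contacts share the vertical profile, ligaments small
    bw = params.body_mass * _G
    g = _vertical_grf_profile(tau)
    g[: pad] = 0.0
    g[n - pad:] = 0.0
    contact_total = params.grf_peak_bw * bw * g
    gen_int = np.zeros((n, 6))
    name_idx = {nm: i for i, nm in enumerate(CONSTRAINT_NAMES)}
    gen_int[:, name_idx["P1"]] = params.medial_share * contact_total
    gen_int[:, name_idx["P2"]] = (1 - params.medial_share) * contact_total
    for nm in ("ACL", "PCL", "MCL", "LCL"):
        gen_int[:, name_idx[nm]] = params.ligament_load * g * rng.uniform(0.5, 1.0)

    # minimum-norm representative: identical wrench, canonical coefficients
    pinv_proj = np.linalg.pinv(A_tibia, rcond=1e-10) @ A_tibia
    truth_int = gen_int @ pinv_proj.T

    thigh_pos = np.empty((n, params.n_markers, 3))
    shank_pos = np.empty((n, params.n_markers, 3))
    grf_rows = []
    iak_screws: list[Screw] = []
    u_t = knee_axis_tibia.d
    c_t = knee_axis_tibia.axis_point
    for k in range(n):
        R_s = rotation_about_axis([0, 0, 1], sway[k]) @ R_shank0
        t_s = t_shank0
        R_knee = rotation_about_axis(u_t, theta[k])
        # thigh pose = shank pose ∘ rotation about the tibia-frame knee axis
        R_t = R_s @ R_knee
        t_t = t_s + R_s @ (c_t - R_knee @ c_t)
        shank_pos[k] = shank_cloud @ R_s.T + t_s
        thigh_pos[k] = thigh_cloud @ R_t.T + t_t

        iak_screws.append(transform_screw(knee_axis_tibia, R_s, t_s))

        w6 = -(A_tibia @ gen_int[k])          # tibia frame
        F_t, M_t = w6[:3], w6[3:]
        F = R_s @ F_t
        M = R_s @ M_t + np.cross(t_s, F)      # lab-frame moment about origin
        cop, tz = _cop_from_wrench(F, M, 0.0)
        grf_rows.append([time[k], *F, *cop, tz])

    if params.marker_noise_sd > 0:
        thigh_pos += params.marker_noise_sd * rng.standard_normal(thigh_pos.shape)
        shank_pos += params.marker_noise_sd * rng.standard_normal(shank_pos.shape)

    labels_t = [f"T{i + 1}" for i in range(params.n_markers)]
    labels_s = [f"S{i + 1}" for i in range(params.n_markers)]
    grf = pd.DataFrame(grf_rows, columns=[
        "time", "Fx", "Fy", "Fz", "COPx", "COPy", "COPz", "Tz"])

    theta_rate = np.gradient(theta, dt)
    truth = {
        "iak_screws": iak_screws,
        "iak_rates": theta_rate,
        "theta": theta,
        "intensities": pd.DataFrame(truth_int, columns=list(CONSTRAINT_NAMES)).assign(time=time),
        "generating_intensities": pd.DataFrame(gen_int, columns=list(CONSTRAINT_NAMES)).assign(time=time),
        "knee_axis_tibia": knee_axis_tibia,
        "stance_mask": g > 0,
        "seed": seed,
    }
    return SyntheticTrial(
        seed=seed, params=params,
        thigh_markers=MarkerTrajectory(labels_t, thigh_pos, params.rate,
                                       body_reference=thigh_cloud),
        shank_markers=MarkerTrajectory(labels_s, shank_pos, params.rate,
                                       body_reference=shank_cloud),
        grf=grf, geometry=geometry,
        shank_pose=(R_shank0, t_shank0),
        truth=truth,
    )
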