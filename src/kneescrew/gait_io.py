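"""Readers, writers and the end-to-end stance pipeline.

Formats (all plain text, SI units after load):

* TRC marker files (tab-separated motion-capture convention; the header's
  units line is honoured, mm converted to m; TRC's 1-based frame numbers
  become 0-based indices internally);
* force-plate CSV with columns time, Fx, Fy, Fz, COPx, COPy, COPz, Tz
  (N, m, N·m);
* constraint-geometry JSON with per-line origin and insertion points in
  the tibia frame (metres).

Readers reject malformed input with the offending line or column named
rather than coercing silently.
"""

from __future__ import annotations

import hashlib
import json
import logging
import time as _time
from dataclasses import dataclass, field, asdict

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .constraint_equilibrium import (
    CONSTRAINT_NAMES,
    ConstraintSet,
    EquilibriumSolution,
    decompose_wrench,
    grf_wrench,
)
from .perception_policy import PolicyStep, stance_policy
from .screw_core import Screw, ScrewError, Twist, screw_from_points
from .segment_kinematics import (
    MarkerTrajectory,
    fit_pose_sequence,
    relative_twist,
    twist_from_poses,
)

__all__ = [
    "ParseError",
    "GRFSeries",
    "PipelineConfig",
    "TrialBundle",
    "PipelineResult",
    "read_trc",
    "write_trc",
    "read_forceplate_csv",
    "write_forceplate_csv",
    "read_geometry_json",
    "write_geometry_json",
    "run_pipeline",
    "write_results",
]

log = logging.getLogger("kneescrew")

#: default vertical-force threshold for stance detection (N); frames with
#: Fz >= threshold (inclusive) count as stance
STANCE_THRESHOLD_N = 20.0

GRF_COLUMNS = ("time", "Fx", "Fy", "Fz", "COPx", "COPy", "COPz", "Tz")


class ParseError(ScrewError):
    """Malformed input file; message names the offending line/column."""


# ---------------------------------------------------------------------------
# TRC marker files


def read_trc(path) -> MarkerTrajectory:
    """Read a TRC marker file into metres.

    Honours the Units field (mm or m).  Frames with empty coordinate cells
    come back as NaN positions.
    """
    with open(path) as fh:
        lines = fh.read().splitlines()
    if len(lines) < 6:
        raise ParseError(f"{path}: truncated TRC file ({len(lines)} lines)")
    header_keys = lines[1].split("\t")
    header_vals = lines[2].split("\t")
    meta = dict(zip(header_keys, header_vals))
    try:
        rate = float(meta["DataRate"])
        n_markers = int(meta["NumMarkers"])
        units = meta["Units"].strip().lower()
    except (KeyError, ValueError) as exc:
        raise ParseError(f"{path}:3: malformed TRC header ({exc})") from exc
    if units not in ("mm", "m"):
        raise ParseError(f"{path}:3: unsupported Units '{units}' (expect mm or m)")
    scale = 1e-3 if units == "mm" else 1.0

    name_cells = lines[3].split("\t")
    labels = [c for c in name_cells[2:] if c.strip()]
    if len(labels) != n_markers:
        raise ParseError(
            f"{path}:4: header promises {n_markers} markers but the name row "
            f"lists {len(labels)}")

    rows = []
    for lineno, line in enumerate(lines[5:], start=6):
        if not line.strip():
            continue
        cells = line.split("\t")
        expected = 2 + 3 * n_markers
        if len(cells) < expected:
            cells = cells + [""] * (expected - len(cells))
        elif len(cells) > expected:
            raise ParseError(
                f"{path}:{lineno}: {len(cells)} columns, expected {expected}")
        try:
            coords = [float(c) if c.strip() else np.nan for c in cells[2:expected]]
        except ValueError as exc:
            raise ParseError(f"{path}:{lineno}: non-numeric cell ({exc})") from exc
        rows.append(coords)
    if not rows:
        raise ParseError(f"{path}: no data rows")
    pos = np.asarray(rows).reshape(len(rows), n_markers, 3) * scale
    return MarkerTrajectory(labels, pos, rate)


def write_trc(path, traj: MarkerTrajectory, units: str = "mm") -> None:
    """Write a MarkerTrajectory as a TRC file (positions converted to ``units``)."""
    if units not in ("mm", "m"):
        raise ScrewError("units must be 'mm' or 'm'")
    scale = 1e3 if units == "mm" else 1.0
    n, nm = traj.positions.shape[:2]
    with open(path, "w") as fh:
        fh.write(f"PathFileType\t4\t(X/Y/Z)\t{path}\n")
        fh.write("DataRate\tCameraRate\tNumFrames\tNumMarkers\tUnits\t"
                 "OrigDataRate\tOrigDataStartFrame\tOrigNumFrames\n")
        fh.write(f"{traj.rate:g}\t{traj.rate:g}\t{n}\t{nm}\t{units}\t"
                 f"{traj.rate:g}\t1\t{n}\n")
        fh.write("Frame#\tTime\t" + "\t\t\t".join(traj.labels) + "\t\t\n")
        fh.write("\t\t" + "\t".join(
            f"X{i + 1}\tY{i + 1}\tZ{i + 1}" for i in range(nm)) + "\n")
        for k in range(n):
            cells = [str(k + 1), f"{k / traj.rate:.8f}"]
            for j in range(nm):
                cells.extend(f"{v * scale:.10g}" for v in traj.positions[k, j])
            fh.write("\t".join(cells) + "\n")


# ---------------------------------------------------------------------------
# force plate


@dataclass
class GRFSeries:
    """Force-plate record in SI units with a stance mask."""

    time: np.ndarray
    force: np.ndarray        # (n, 3) N
    cop: np.ndarray          # (n, 3) m
    free_moment: np.ndarray  # (n, 3) N·m, vertical Tz folded into z
    stance_mask: np.ndarray  # bool, Fz >= threshold (inclusive)
    threshold: float

    @property
    def rate(self) -> float:
        dt = np.diff(self.time)
        return 1.0 / float(np.median(dt)) if len(dt) else 0.0

    def __len__(self) -> int:
        return len(self.time)


def read_forceplate_csv(path, stance_threshold: float = STANCE_THRESHOLD_N) -> GRFSeries:
    """Read a force-plate CSV (columns ``time,Fx,Fy,Fz,COPx,COPy,COPz,Tz``).

    Stance frames are those with vertical force at or above the threshold
    (inclusive at the boundary).
    """
    df = pd.read_csv(path)
    missing = [c for c in GRF_COLUMNS if c not in df.columns]
    if missing:
        raise ParseError(f"{path}: missing force-plate columns {missing}")
    bad = df[list(GRF_COLUMNS)].isna()
    if bad.any().any():
        col = bad.any()[bad.any()].index[0]
        row = int(bad[col][bad[col]].index[0]) + 2  # header + 1-based
        raise ParseError(f"{path}:{row}: non-numeric or empty value in column {col}")
    force = df[["Fx", "Fy", "Fz"]].to_numpy(float)
    free = np.zeros_like(force)
    free[:, 2] = df["Tz"].to_numpy(float)
    return GRFSeries(
        time=df["time"].to_numpy(float),
        force=force,
        cop=df[["COPx", "COPy", "COPz"]].to_numpy(float),
        free_moment=free,
        stance_mask=force[:, 2] >= stance_threshold,
        threshold=stance_threshold,
    )


def write_forceplate_csv(path, grf: pd.DataFrame) -> None:
    grf.to_csv(path, index=False, float_format="%.10g")


# ---------------------------------------------------------------------------
# constraint geometry


def read_geometry_json(path) -> ConstraintSet:
    """Constraint geometry from JSON: per-line origin/insertion points (m,
    tibia frame), e.g. ``{"lines": {"ACL": {"origin": [...], "insertion":
    [...]}, ...}}``."""
    with open(path) as fh:
        doc = json.load(fh)
    if "lines" not in doc:
        raise ParseError(f"{path}: missing top-level 'lines' object")
    screws = {}
    for name in CONSTRAINT_NAMES:
        if name not in doc["lines"]:
            raise ParseError(f"{path}: missing constraint line '{name}'")
        rec = doc["lines"][name]
        try:
            screws[name] = screw_from_points(rec["origin"], rec["insertion"])
        except (KeyError, ScrewError) as exc:
            raise ParseError(f"{path}: line '{name}': {exc}") from exc
    return ConstraintSet(screws, source={"path": str(path),
                                         "frame": doc.get("frame", "tibia")})


def write_geometry_json(path, geometry: ConstraintSet) -> None:
    """Write geometry as origin/insertion records (origin on the axis point,
    insertion one direction-unit along the line)."""
    lines = {}
    for name in CONSTRAINT_NAMES:
        s = geometry[name]
        p = s.axis_point
        lines[name] = {"origin": p.tolist(), "insertion": (p + s.d).tolist()}
    with open(path, "w") as fh:
        json.dump({"frame": geometry.source.get("frame", "tibia"),
                   "lines": lines}, fh, indent=1, sort_keys=True)
        fh.write("\n")


# ---------------------------------------------------------------------------
# pipeline


@dataclass
class PipelineConfig:
    """Tunable pipeline settings (defaults documented in the methods note)."""

    stance_threshold: float = STANCE_THRESHOLD_N  # N, vertical-force cutoff
    rotation_gate_deg: float = 0.1   # window rotation below this -> no ISA
    recip_tol: float = 1e-3          # constraint-vs-IAK reciprocity check (m)
    consistency_rtol: float = 0.05   # wrench-in-span relative residual cap
    reference_frame: int = 0         # cluster layout reference
    smooth_window: int = 1           # odd moving-average width (1 = off)
    min_window_rotation_deg: float = 0.0  # adaptive ISA window (0 = off)
    seed: int = 0                    # recorded in provenance

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        with open(path) as fh:
            doc = yaml.safe_load(fh) or {}
        unknown = set(doc) - set(cls.__dataclass_fields__)
        if unknown:
            raise ParseError(f"{path}: unknown config keys {sorted(unknown)}")
        coerced = {}
        for key, val in doc.items():
            typ = cls.__dataclass_fields__[key].type
            try:
                coerced[key] = int(val) if typ == "int" else float(val)
            except (TypeError, ValueError) as exc:
                raise ParseError(f"{path}: config key {key}: {exc}") from exc
        return cls(**coerced)

    def sha256(self) -> str:
        blob = json.dumps(asdict(self), sort_keys=True).encode()
        return hashlib.sha256(blob).hexdigest()


@dataclass
class TrialBundle:
    """Everything one stance trial needs: markers, plate record, geometry."""

    thigh: MarkerTrajectory
    shank: MarkerTrajectory
    grf: GRFSeries
    geometry: ConstraintSet   # tibia frame
    provenance: dict = field(default_factory=dict)

    def validate(self) -> None:
        if self.thigh.n_frames != self.shank.n_frames:
            raise ScrewError("thigh and shank marker frame counts differ")
        if abs(self.thigh.rate - self.shank.rate) > 1e-9:
            raise ScrewError("thigh and shank marker rates differ")
        if len(self.grf) != self.thigh.n_frames:
            raise ScrewError(
                f"force-plate frames ({len(self.grf)}) do not match marker "
                f"frames ({self.thigh.n_frames}); resample before running")


@dataclass
class PipelineResult:
    """Per-frame IAK track, contact forces, and the policy trace."""

    iak_twists: list[Twist]
    iak_valid: np.ndarray
    solutions: list[EquilibriumSolution | None]
    forces: pd.DataFrame          # time, medial_N, lateral_N, residual, ...
    policy_trace: list[PolicyStep]
    empty_stance: bool
    provenance: dict


def _stage(name: str, t0: float, **info) -> None:
    log.info("stage=%s elapsed=%.3fs %s", name, _time.perf_counter() - t0,
             " ".join(f"{k}={v}" for k, v in info.items()))


def run_pipeline(bundle: TrialBundle, config: PipelineConfig | None = None
                 ) -> PipelineResult:
    """Markers + plate + geometry → IAK track, contact forces, policy trace.

    Deterministic for fixed inputs and config.  Frames outside stance get
    zero intensities; frames whose IAK is translation-dominated are solved
    with the reciprocity pre-check disabled and marked invalid in the
    output.  A stance threshold excluding every frame yields an
    empty-result warning flag rather than an error.
    """
    config = config or PipelineConfig()
    bundle.validate()
    gate = np.radians(config.rotation_gate_deg)
    min_rot = np.radians(config.min_window_rotation_deg) \
        if config.min_window_rotation_deg > 0 else None

    t0 = _time.perf_counter()
    thigh_in, shank_in = bundle.thigh, bundle.shank
    if config.smooth_window > 1:
        from .segment_kinematics import moving_average
        thigh_in = moving_average(thigh_in, config.smooth_window)
        shank_in = moving_average(shank_in, config.smooth_window)
    thigh_poses = fit_pose_sequence(thigh_in, config.reference_frame)
    shank_poses = fit_pose_sequence(shank_in, config.reference_frame)
    _stage("rigid_fit", t0,
           thigh_rms=f"{thigh_poses.residual_rms.max():.2e}",
           shank_rms=f"{shank_poses.residual_rms.max():.2e}")

    t0 = _time.perf_counter()
    thigh_twists = twist_from_poses(thigh_poses, gate, min_rot)
    shank_twists = twist_from_poses(shank_poses, gate, min_rot)
    iak_twists = [relative_twist(th, sh) for th, sh in zip(thigh_twists, shank_twists)]
    iak_valid = np.array([
        not t.flagged and not t.is_null and not t.screw.is_infinite_pitch
        for t in iak_twists])
    # a flagged (translation-dominated or below-threshold-rotation) segment
    # invalidates the relative axis when it dominates the relative motion
    for i, (th, sh) in enumerate(zip(thigh_twists, shank_twists)):
        total = np.linalg.norm(th.coords()) + np.linalg.norm(sh.coords())
        if total <= 0:
            iak_valid[i] = False
            continue
        for seg in (th, sh):
            if seg.flagged and np.linalg.norm(seg.coords()) > 0.05 * total:
                iak_valid[i] = False
    _stage("iak", t0, valid=int(iak_valid.sum()), frames=len(iak_twists))

    stance = bundle.grf.stance_mask
    empty_stance = not bool(stance.any())
    if empty_stance:
        log.warning("stance threshold %.3g N excludes every frame", bundle.grf.threshold)

    t0 = _time.perf_counter()
    solutions: list[EquilibriumSolution | None] = []
    rows = []
    for k in range(len(bundle.grf)):
        if not stance[k]:
            solutions.append(None)
            rows.append([bundle.grf.time[k]] + [0.0] * 6 + [0.0, 0.0, 0.0, False])
            continue
        R_s, t_s = shank_poses.rotations[k], shank_poses.translations[k]
        lab_geom = bundle.geometry.transformed(R_s, t_s)
        w = grf_wrench(bundle.grf.force[k], bundle.grf.cop[k], bundle.grf.free_moment[k])
        recip_tol = config.recip_tol if iak_valid[k] else np.inf
        sol = decompose_wrench(w, lab_geom, iak_twists[k].screw,
                               recip_tol=recip_tol,
                               consistency_rtol=config.consistency_rtol)
        solutions.append(sol)
        rows.append([bundle.grf.time[k], *sol.as_array(), sol.medial_force,
                     sol.lateral_force, sol.residual, bool(iak_valid[k])])
    forces = pd.DataFrame(rows, columns=[
        "time", *CONSTRAINT_NAMES, "medial_N", "lateral_N", "residual", "iak_valid"])
    _stage("decompose", t0, stance_frames=int(stance.sum()))

    t0 = _time.perf_counter()
    candidates = [bundle.geometry[n] for n in CONSTRAINT_NAMES]
    track = [t.screw for t in iak_twists]
    trace = stance_policy(track, candidates)
    _stage("policy", t0, frames=len(trace))

    provenance = {
        "kneescrew_version": __version__,
        "numpy_version": np.__version__,
        "config": asdict(config),
        "config_sha256": config.sha256(),
        "input_sha256": {
            "thigh": hashlib.sha256(bundle.thigh.positions.tobytes()).hexdigest(),
            "shank": hashlib.sha256(bundle.shank.positions.tobytes()).hexdigest(),
            "grf": hashlib.sha256(bundle.grf.force.tobytes()).hexdigest(),
        },
        **bundle.provenance,
    }
    return PipelineResult(
        iak_twists=iak_twists, iak_valid=iak_valid, solutions=solutions,
        forces=forces, policy_trace=trace, empty_stance=empty_stance,
        provenance=provenance,
    )


def write_results(outdir, result: PipelineResult) -> None:
    """Write forces CSV, IAK track CSV, policy trace CSV and provenance JSON."""
    from pathlib import Path

    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    result.forces.to_csv(outdir / "forces.csv", index=False, float_format="%.10g")

    rows = []
    for k, (t, ok) in enumerate(zip(result.iak_twists, result.iak_valid)):
        if t.screw.is_infinite_pitch:
            d, p, h = t.screw.m, [np.nan] * 3, np.inf
        else:
            d, p, h = t.screw.d, t.screw.axis_point, t.screw.pitch
        rows.append([k, *d, *np.asarray(p, float), h, t.amplitude, bool(ok)])
    pd.DataFrame(rows, columns=[
        "frame", "dx", "dy", "dz", "px", "py", "pz", "pitch", "amplitude",
        "valid"]).to_csv(outdir / "iak.csv", index=False, float_format="%.10g")

    pd.DataFrame([asdict(s) for s in result.policy_trace]).to_csv(
        outdir / "policy.csv", index=False, float_format="%.10g")
    with open(outdir / "provenance.json", "w") as fh:
        json.dump(result.provenance, fh, indent=1, sort_keys=True)
        fh.write("\n")
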