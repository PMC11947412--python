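"""Load-case preparation: scaling, re-registration and periodisation.

Standardised tibiofemoral load cases (one cycle of an activity of daily
living, ADL) are recorded in the coordinate system of the implant the data
was measured with.  Before they can drive a different implant design on a
six-DOF joint simulator they pass through a fixed chain:

1. **body-weight scaling** — load channels multiplied by the ratio of target
   to reference body weight (the AVER75 convention normalises to 75 kg);
2. **re-registration** — kinematics and wrenches re-expressed from the source
   implant coordinate system into the target implant's system (a small tilt
   plus an origin shift; the origin shift changes the moments through the
   r × F transport term);
3. **conversion to the Grood–Suntay convention** the simulator uses;
4. **periodisation** — the cycle's waveforms are extended by a fraction of
   the cycle (15 % by default) with a smooth blend so that first and last
   samples match exactly, as required by cyclic (iterative-learning)
   control.

The default registration shipped here tilts the source system by the 6.5°
posterior-slope correction about the medial-lateral axis and shifts the
origin by just under 1 mm.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace

import numpy as np
from scipy.spatial.transform import Rotation as _Rot

from .jcs import RigidPose, jcs_from_pose, jcs_load_from_wrench
from .wrench import FrameMismatchError, Wrench

__all__ = [
    "FrameRegistration", "LoadCaseTrack", "ScalingConfig", "SourceRecording",
    "register_wrench", "register_pose", "scale_loads", "periodise",
    "prepare_load_case", "default_innex_to_pfc_registration",
    "ADL_NAMES", "CHANNELS", "POSITION_CHANNELS", "LOAD_CHANNELS",
]

ADL_NAMES = ("level_walking", "downhill_walking", "stairs_down", "squat",
             "sit_to_stand")

#: simulator track channels, in CSV column order
CHANNELS = ("fe_deg", "ei_deg", "ml_N", "ap_N", "is_N", "abad_Nm")
#: flexion-extension and external-internal rotation are position-controlled
POSITION_CHANNELS = ("fe_deg", "ei_deg")
#: the remaining four degrees of freedom are force/moment-controlled
LOAD_CHANNELS = ("ml_N", "ap_N", "is_N", "abad_Nm")

_GRID_TOL_S = 1e-9


@dataclass(frozen=True)
class FrameRegistration:
    """Rigid re-registration from a source implant frame to a target frame.

    ``rotation`` maps source-frame vector components to target-frame
    components; ``origin_shift_mm`` is the position of the *source* frame's
    origin expressed in the target frame.  A point with source coordinates x
    has target coordinates ``rotation @ x + origin_shift_mm``.
    """

    rotation: np.ndarray
    origin_shift_mm: np.ndarray = field(default_factory=lambda: np.zeros(3))
    source_frame: str = "source"
    target_frame: str = "target"

    def __post_init__(self) -> None:
        R = np.asarray(self.rotation, dtype=float)
        r = np.asarray(self.origin_shift_mm, dtype=float)
        if R.shape != (3, 3) or r.shape != (3,):
            raise ValueError("rotation must be 3×3 and origin_shift_mm a 3-vector")
        if not np.allclose(R @ R.T, np.eye(3), atol=1e-10) or \
                not math.isclose(float(np.linalg.det(R)), 1.0, abs_tol=1e-10):
            raise ValueError("registration rotation must be proper orthogonal")
        object.__setattr__(self, "rotation", R)
        object.__setattr__(self, "origin_shift_mm", r)

    @classmethod
    def identity(cls, source_frame: str = "source",
                 target_frame: str = "target") -> "FrameRegistration":
        return cls(np.eye(3), np.zeros(3), source_frame, target_frame)

    @classmethod
    def from_axis_angle(cls, axis, angle_deg: float, origin_shift_mm=(0, 0, 0),
                        source_frame: str = "source",
                        target_frame: str = "target") -> "FrameRegistration":
        axis = np.asarray(axis, dtype=float)
        n = np.linalg.norm(axis)
        if n == 0:
            raise ValueError("rotation axis must be nonzero")
        R = _Rot.from_rotvec(math.radians(angle_deg) * axis / n).as_matrix()
        return cls(R, np.asarray(origin_shift_mm, dtype=float),
                   source_frame, target_frame)

    def angle_deg(self) -> float:
        """Magnitude of the registration rotation, degrees (axis-angle)."""
        return float(np.degrees(np.linalg.norm(
            _Rot.from_matrix(self.rotation).as_rotvec())))

    def inverse(self) -> "FrameRegistration":
        return FrameRegistration(self.rotation.T,
                                 -self.rotation.T @ self.origin_shift_mm,
                                 self.target_frame, self.source_frame)


def default_innex_to_pfc_registration() -> FrameRegistration:
    """The stock source→target implant registration.

    A 6.5° posterior-slope correction about the medial-lateral axis together
    with an origin shift of just under 1 mm, which is what matching the
    functional surfaces of an ultra-congruent donor design to a
    cruciate-retaining recipient design produces.
    """
    return FrameRegistration.from_axis_angle(
        axis=(1.0, 0.0, 0.0), angle_deg=-6.5,
        origin_shift_mm=(0.0, 0.9, 0.4),
        source_frame="INNEX", target_frame="PFC_Sigma")


def register_wrench(w: Wrench, reg: FrameRegistration) -> Wrench:
    """Re-express a wrench in the registration's target frame.

    The force is rotated; the moment is rotated and picks up the transport
    term ``origin_shift × force`` because the moment is now taken about the
    target frame's origin.  |force| and the resultant invariant force·moment
    are preserved.
    """
    if w.frame_id != reg.source_frame:
        raise FrameMismatchError(
            f"wrench is in frame {w.frame_id!r} but registration maps from "
            f"{reg.source_frame!r}")
    if not np.allclose(w.origin_mm, 0.0, atol=1e-9):
        raise FrameMismatchError(
            "register_wrench expects the wrench about the source frame "
            "origin; re-express it first")
    F = reg.rotation @ w.force_N
    M = reg.rotation @ w.moment_Nm + np.cross(reg.origin_shift_mm, F) * 1e-3
    return Wrench(F, M, reg.target_frame, np.zeros(3))


def register_pose(p: RigidPose, reg_femoral: FrameRegistration,
                  reg_tibial: FrameRegistration | None = None) -> RigidPose:
    """Conjugate a pose by re-registrations of the femoral and tibial frames.

    With matched functional surfaces the same transform applies to both
    component frames, so ``reg_tibial`` defaults to ``reg_femoral``.
    """
    if reg_tibial is None:
        reg_tibial = reg_femoral
    Qf, rf = reg_femoral.rotation, reg_femoral.origin_shift_mm
    Qt, rt = reg_tibial.rotation, reg_tibial.origin_shift_mm
    R = Qf @ p.rotation @ Qt.T
    t = Qf @ p.translation + rf - R @ rt
    return RigidPose(R, t, p.side)


@dataclass(frozen=True)
class ScalingConfig:
    """Body-weight scaling of telemetric load data (AVER75: target 75 kg)."""

    target_body_weight_kg: float = 75.0
    reference_body_weight_kg: float = 75.0

    def __post_init__(self) -> None:
        if self.target_body_weight_kg <= 0 or self.reference_body_weight_kg <= 0:
            raise ValueError("body weights must be positive")

    @property
    def ratio(self) -> float:
        return self.target_body_weight_kg / self.reference_body_weight_kg


class LoadCaseTrack:
    """One ADL cycle on a uniform time grid with six target channels.

    ``fe_deg`` and ``ei_deg`` are position-controlled; ``ml_N``, ``ap_N``,
    ``is_N`` and ``abad_Nm`` are force/moment-controlled.  Compression is a
    negative ``is_N``; a positive ``ap_N`` pushes the tibia anteriorly.
    """

    def __init__(self, adl: str, time_s: np.ndarray,
                 channels: dict[str, np.ndarray], frequency_hz: float,
                 meta: dict | None = None):
        time_s = np.asarray(time_s, dtype=float)
        if time_s.ndim != 1 or time_s.size < 2:
            raise ValueError("time grid needs at least two samples")
        dt = np.diff(time_s)
        if np.any(dt <= 0):
            raise ValueError("time grid must be strictly increasing")
        if np.ptp(dt) > _GRID_TOL_S:
            raise ValueError("time grid must be uniform (within 1e-9 s)")
        if frequency_hz <= 0:
            raise ValueError("frequency_hz must be positive")
        missing = [c for c in CHANNELS if c not in channels]
        if missing:
            raise ValueError(f"missing channels: {missing}")
        self.adl = adl
        self.time_s = time_s
        self.channels = {c: np.asarray(channels[c], dtype=float)
                         for c in CHANNELS}
        for c, y in self.channels.items():
            if y.shape != time_s.shape:
                raise ValueError(f"channel {c} length mismatch")
        self.frequency_hz = float(frequency_hz)
        self.meta = dict(meta or {})

    # -- convenience -------------------------------------------------------
    @property
    def n_samples(self) -> int:
        return self.time_s.size

    @property
    def dt(self) -> float:
        return float(self.time_s[1] - self.time_s[0])

    @property
    def duration_s(self) -> float:
        """Cyclic period implied by the grid: n_samples × dt."""
        return self.n_samples * self.dt

    def is_periodic(self, atol: float = 0.0) -> bool:
        return all(abs(y[0] - y[-1]) <= atol for y in self.channels.values())

    def copy(self) -> "LoadCaseTrack":
        return LoadCaseTrack(self.adl, self.time_s.copy(),
                             {c: y.copy() for c, y in self.channels.items()},
                             self.frequency_hz, dict(self.meta))

    def __eq__(self, other) -> bool:
        if not isinstance(other, LoadCaseTrack):
            return NotImplemented
        return (self.adl == other.adl
                and np.array_equal(self.time_s, other.time_s)
                and all(np.array_equal(self.channels[c], other.channels[c])
                        for c in CHANNELS)
                and self.frequency_hz == other.frequency_hz)


@dataclass
class SourceRecording:
    """Stan-like source data: per-sample pose plus full wrench.

    Kinematics are the pose of the tibial implant frame relative to the
    femoral implant frame; the wrench (all six load components) is expressed
    in the *tibial* implant frame about its origin, which is how instrumented
    implants report loads.
    """

    adl: str
    time_s: np.ndarray
    rotations: np.ndarray        # (N, 3, 3), tibial → femoral
    translations: np.ndarray     # (N, 3) mm
    force_N: np.ndarray          # (N, 3) tibial-frame components
    moment_Nm: np.ndarray        # (N, 3)
    frame_id: str = "INNEX"
    side: str = "right"
    frequency_hz: float = 1.0

    def __post_init__(self) -> None:
        n = np.asarray(self.time_s).size
        for name in ("rotations", "translations", "force_N", "moment_Nm"):
            arr = np.asarray(getattr(self, name), dtype=float)
            setattr(self, name, arr)
            if arr.shape[0] != n:
                raise ValueError(f"{name} length mismatch")

    @property
    def n_samples(self) -> int:
        return np.asarray(self.time_s).size

    def pose(self, i: int) -> RigidPose:
        return RigidPose(self.rotations[i], self.translations[i], self.side)


def scale_loads(track: LoadCaseTrack, cfg: ScalingConfig) -> LoadCaseTrack:
    """Multiply force/moment channels by the body-weight ratio.

    Kinematic (position-controlled) channels and the cycle frequency are
    untouched: lever arms do not scale with body weight, so moments scale by
    the same ratio as forces.
    """
    out = track.copy()
    for c in LOAD_CHANNELS:
        out.channels[c] = out.channels[c] * cfg.ratio
    return out


def scale_recording(rec: SourceRecording, cfg: ScalingConfig) -> SourceRecording:
    """Body-weight scaling of a full source recording (loads only)."""
    return replace(rec, force_N=rec.force_N * cfg.ratio,
                   moment_Nm=rec.moment_Nm * cfg.ratio)


def _quintic_hermite(tau, v0, m0, a0, v1, m1, a1):
    """Quintic Hermite on τ∈[0,1]: values, first and second derivatives set
    at both ends (derivatives per unit τ)."""
    t2, t3 = tau * tau, tau ** 3
    t4, t5 = tau ** 4, tau ** 5
    h0 = 1 - 10 * t3 + 15 * t4 - 6 * t5
    h1 = tau - 6 * t3 + 8 * t4 - 3 * t5
    h2 = 0.5 * t2 - 1.5 * t3 + 1.5 * t4 - 0.5 * t5
    h3 = 10 * t3 - 15 * t4 + 6 * t5
    h4 = -4 * t3 + 7 * t4 - 3 * t5
    h5 = 0.5 * t3 - t4 + 0.5 * t5
    return v0 * h0 + m0 * h1 + a0 * h2 + v1 * h3 + m1 * h4 + a1 * h5


def periodise(track: LoadCaseTrack,
              extension_fraction: float = 0.15) -> LoadCaseTrack:
    """Harmonise cycle start and end by appending a smooth extension.

    The cycle is extended by ``extension_fraction`` of its duration (sample
    count rounded up).  Over the appended segment each channel follows a
    quintic Hermite blend that matches value, slope and curvature at the old
    end and at the cycle start; the final sample is forced exactly (bitwise)
    equal to the first, which cyclic control requires.  All original samples
    are preserved bitwise.
    """
    if not 0 < extension_fraction < 1:
        raise ValueError("extension_fraction must be in (0, 1)")
    n = track.n_samples
    if n < 4:
        raise ValueError("track too short to periodise (need ≥ 4 samples)")
    n_out = math.ceil((1.0 + extension_fraction) * n)
    m = n_out - n
    dt = track.dt
    t0 = track.time_s[0]
    new_time = t0 + dt * np.arange(n_out)
    tau = np.arange(1, m + 1) / m

    out_channels = {}
    for c, y in track.channels.items():
        d_end = (y[-1] - y[-2]) / dt
        d_start = (y[1] - y[0]) / dt
        a_end = (y[-1] - 2 * y[-2] + y[-3]) / dt ** 2
        a_start = (y[2] - 2 * y[1] + y[0]) / dt ** 2
        T = m * dt
        seg = _quintic_hermite(tau, y[-1], d_end * T, a_end * T * T,
                               y[0], d_start * T, a_start * T * T)
        ext = np.concatenate([y, seg])
        ext[-1] = y[0]  # exact endpoint equality
        out_channels[c] = ext

    meta = dict(track.meta)
    meta["periodised"] = True
    meta["extension_fraction"] = extension_fraction
    return LoadCaseTrack(track.adl, new_time, out_channels,
                         track.frequency_hz, meta)


def _track_from_recording(rec: SourceRecording) -> LoadCaseTrack:
    """Convert a (registered) recording to a Grood–Suntay simulator track."""
    n = rec.n_samples
    cols = {c: np.empty(n) for c in CHANNELS}
    for i in range(n):
        pose = rec.pose(i)
        coords = jcs_from_pose(pose)
        # loads: tibial-frame wrench about the tibial origin → femoral
        # components about the same point, then onto the JCS axes
        F = pose.rotation @ rec.force_N[i]
        M = pose.rotation @ rec.moment_Nm[i]
        load = jcs_load_from_wrench(
            Wrench(F, M, "femoral", pose.translation), pose)
        cols["fe_deg"][i] = coords.flexion_deg
        cols["ei_deg"][i] = coords.internal_rot_deg
        cols["ml_N"][i] = load.ml_force_N
        cols["ap_N"][i] = load.ap_force_N
        cols["is_N"][i] = load.is_force_N
        cols["abad_Nm"][i] = load.adduction_moment_Nm
    return LoadCaseTrack(rec.adl, np.asarray(rec.time_s, dtype=float), cols,
                         rec.frequency_hz, meta={"frame": "grood_suntay"})


def prepare_load_case(recording: SourceRecording,
                      registration: FrameRegistration | None = None,
                      scaling: ScalingConfig | None = None,
                      extension_fraction: float = 0.15) -> LoadCaseTrack:
    """Full preparation chain: scale → register → JCS conversion → periodise.

    Stage failures are re-raised with the stage name prefixed so a bad input
    is attributable.
    """
    scaling = scaling or ScalingConfig()
    registration = registration or FrameRegistration.identity(
        recording.frame_id, recording.frame_id)

    def _stage(name, fn):
        try:
            return fn()
        except Exception as exc:  # noqa: BLE001 - annotate and re-raise
            raise type(exc)(f"[stage {name}] {exc}") from exc

    rec = _stage("scale", lambda: scale_recording(recording, scaling))

    def _register():
        rots = np.empty_like(rec.rotations)
        trans = np.empty_like(rec.translations)
        forces = np.empty_like(rec.force_N)
        moments = np.empty_like(rec.moment_Nm)
        for i in range(rec.n_samples):
            p = register_pose(rec.pose(i), registration)
            rots[i], trans[i] = p.rotation, p.translation
            w = register_wrench(
                Wrench(rec.force_N[i], rec.moment_Nm[i], rec.frame_id),
                registration)
            forces[i], moments[i] = w.force_N, w.moment_Nm
        return replace(rec, rotations=rots, translations=trans,
                       force_N=forces, moment_Nm=moments,
                       frame_id=registration.target_frame)

    rec = _stage("register", _register)
    track = _stage("jcs_conversion", lambda: _track_from_recording(rec))
    return _stage("periodise", lambda: periodise(track, extension_fraction))
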