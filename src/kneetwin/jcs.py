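"""Grood–Suntay joint coordinate system for the tibiofemoral joint.

The joint coordinate system (JCS) describes tibiofemoral motion with three
clinically named rotations and three translations.  Its axes are

* ``e1`` — the femoral body-fixed flexion axis (medial–lateral),
* ``e3`` — the tibial body-fixed long axis (distal → proximal),
* ``e2`` — the floating axis, ``e3 × e1`` normalised.

Neutral axis embedding (both frames coincide, all six components zero):
``x`` = medial → lateral (right knee), ``y`` = posterior → anterior,
``z`` = distal → proximal.  With that embedding the JCS decomposition of the
rotation is an intrinsic x–y'–z'' Euler sequence; positive flexion is the
rotation that swings the distal tibia posteriorly (right-hand rule about the
medially directed ``e1`` of a right knee), positive adduction is varus for a
right knee and positive internal rotation turns the tibial tuberosity
medially.  The convention is singular when ``e1`` becomes parallel to ``e3``
(adduction ±90°).

Internally the mathematics is written for a right knee; ``side="left"`` flips
the signs of adduction, internal rotation and the medial-lateral translation
and nothing else.

Angles are degrees and translations millimetres at every public boundary;
radians are used only inside.

Loads are carried by :class:`~kneetwin.wrench.Wrench` objects about the tibial
origin.  :func:`jcs_load_from_wrench` expresses them in the JCS: by default
each component is the projection of the force/moment onto the corresponding
JCS axis (the reading used by six-DOF joint simulators that report loads "in
the origin of the tibial coordinate system"); ``convention="conjugate"``
returns the generalized loads strictly conjugate to the six JCS coordinates,
which differ from the projections in the flexion and adduction moments by a
force-coupling term whenever the joint translation is nonzero.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

from .wrench import FrameMismatchError, Wrench

__all__ = [
    "RigidPose", "JCSCoordinates", "JCSLoad",
    "InvalidPoseError", "GimbalLockError",
    "jcs_from_pose", "pose_from_jcs", "jcs_load_from_wrench",
    "wrench_from_jcs_load", "jcs_axes",
]

#: adduction this close (degrees) to ±90° raises GimbalLockError
GIMBAL_TOL_DEG = 1e-6

_ORTHO_TOL = 1e-9


class InvalidPoseError(ValueError):
    """Rotation matrix is not proper orthogonal."""


class GimbalLockError(ValueError):
    """JCS decomposition attempted too close to the e1 ∥ e3 singularity."""


def _side_sign(side: str) -> float:
    if side == "right":
        return 1.0
    if side == "left":
        return -1.0
    raise ValueError(f"side must be 'right' or 'left', got {side!r}")


@dataclass(frozen=True)
class RigidPose:
    """Pose of the tibial frame relative to the femoral frame.

    ``rotation`` maps tibial-frame vector components into the femoral frame;
    ``translation`` is the tibial origin expressed in the femoral frame (mm).
    """

    rotation: np.ndarray
    translation: np.ndarray
    side: str = "right"

    def __post_init__(self) -> None:
        R = np.asarray(self.rotation, dtype=float)
        t = np.asarray(self.translation, dtype=float)
        if R.shape != (3, 3):
            raise InvalidPoseError(f"rotation must be 3×3, got {R.shape}")
        if t.shape != (3,):
            raise InvalidPoseError(f"translation must be a 3-vector, got {t.shape}")
        if not np.allclose(R @ R.T, np.eye(3), atol=_ORTHO_TOL):
            raise InvalidPoseError("rotation is not orthonormal (R·Rᵀ ≠ I)")
        if not math.isclose(float(np.linalg.det(R)), 1.0, abs_tol=1e-9):
            raise InvalidPoseError("rotation must be proper (det = +1)")
        _side_sign(self.side)
        object.__setattr__(self, "rotation", R)
        object.__setattr__(self, "translation", t)

    @classmethod
    def identity(cls, side: str = "right") -> "RigidPose":
        return cls(np.eye(3), np.zeros(3), side)


@dataclass(frozen=True)
class JCSCoordinates:
    """The six Grood–Suntay motion components (degrees / millimetres)."""

    flexion_deg: float = 0.0
    adduction_deg: float = 0.0
    internal_rot_deg: float = 0.0
    ml_mm: float = 0.0
    ap_mm: float = 0.0
    is_mm: float = 0.0

    def as_array(self) -> np.ndarray:
        return np.array([self.flexion_deg, self.adduction_deg,
                         self.internal_rot_deg, self.ml_mm, self.ap_mm,
                         self.is_mm])

    @classmethod
    def from_array(cls, q) -> "JCSCoordinates":
        q = np.asarray(q, dtype=float)
        return cls(*(float(x) for x in q))


@dataclass(frozen=True)
class JCSLoad:
    """Forces (N) along and moments (N·m) about the JCS axes.

    Sign convention (fixed, matching the load-case data this package
    consumes): a compressive joint load appears as a *negative*
    ``is_force_N`` (the femur presses the tibia inferiorly along −e3); a
    positive ``ap_force_N`` pushes the tibia anteriorly.
    """

    ml_force_N: float = 0.0
    ap_force_N: float = 0.0
    is_force_N: float = 0.0
    flexion_moment_Nm: float = 0.0
    adduction_moment_Nm: float = 0.0
    internal_rot_moment_Nm: float = 0.0

    def as_array(self) -> np.ndarray:
        return np.array([self.ml_force_N, self.ap_force_N, self.is_force_N,
                         self.flexion_moment_Nm, self.adduction_moment_Nm,
                         self.internal_rot_moment_Nm])


# -- internal Euler machinery (right-knee math) ------------------------------

def _euler_xyz_matrix(alpha: float, beta: float, gamma: float) -> np.ndarray:
    """Intrinsic x–y'–z'' rotation matrix Rx(α)·Ry(β)·Rz(γ)."""
    ca, sa = math.cos(alpha), math.sin(alpha)
    cb, sb = math.cos(beta), math.sin(beta)
    cg, sg = math.cos(gamma), math.sin(gamma)
    return np.array([
        [cb * cg, -cb * sg, sb],
        [ca * sg + sa * sb * cg, ca * cg - sa * sb * sg, -sa * cb],
        [sa * sg - ca * sb * cg, sa * cg + ca * sb * sg, ca * cb],
    ])


def _euler_from_matrix(R: np.ndarray) -> tuple[float, float, float]:
    sb = float(np.clip(R[0, 2], -1.0, 1.0))
    beta = math.asin(sb)
    if 90.0 - abs(math.degrees(beta)) <= GIMBAL_TOL_DEG:
        raise GimbalLockError(
            "adduction angle within "
            f"{GIMBAL_TOL_DEG} deg of ±90° (e1 parallel to e3): the "
            "Grood–Suntay decomposition is singular here")
    alpha = math.atan2(-R[1, 2], R[2, 2])
    gamma = math.atan2(-R[0, 1], R[0, 0])
    return alpha, beta, gamma


def _angles_from_coords(coords: JCSCoordinates, sign: float):
    if not -90.0 < coords.adduction_deg < 90.0:
        raise GimbalLockError(
            f"adduction {coords.adduction_deg}° outside the open interval "
            "(−90°, 90°)")
    alpha = math.radians(-coords.flexion_deg)
    beta = math.radians(sign * coords.adduction_deg)
    gamma = math.radians(sign * coords.internal_rot_deg)
    return alpha, beta, gamma


def _translation_basis(alpha: float, R: np.ndarray) -> np.ndarray:
    """Columns: right-knee translation axes (x̂, floating ŷ′, tibial ẑ″)."""
    e_ml = np.array([1.0, 0.0, 0.0])
    e_ap = np.array([0.0, math.cos(alpha), math.sin(alpha)])
    e_is = R[:, 2]
    return np.column_stack([e_ml, e_ap, e_is])


def jcs_axes(pose: RigidPose) -> dict[str, np.ndarray]:
    """Unit JCS axes of *pose* in femoral-frame components.

    Returns a dict with the rotation axes ``e1`` (positive flexion), ``e2``
    (positive adduction) and ``e3`` (positive internal rotation) and the
    translation axes ``ml``, ``ap``, ``is``; all are unit vectors expressed in
    the femoral frame, with the side convention already applied.
    """
    s = _side_sign(pose.side)
    alpha, _, _ = _euler_from_matrix(pose.rotation)
    E = _translation_basis(alpha, pose.rotation)
    return {
        "e1": np.array([-1.0, 0.0, 0.0]),
        "e2": s * E[:, 1],
        "e3": s * E[:, 2],
        "ml": s * E[:, 0],
        "ap": E[:, 1],
        "is": E[:, 2],
    }


# -- public conversions ------------------------------------------------------

def jcs_from_pose(pose: RigidPose) -> JCSCoordinates:
    """Decompose a rigid pose into the six Grood–Suntay components.

    Raises
    ------
    InvalidPoseError
        If the rotation is not proper orthonormal (checked on construction).
    GimbalLockError
        If the adduction angle is within ``GIMBAL_TOL_DEG`` of ±90°.
    """
    s = _side_sign(pose.side)
    alpha, beta, gamma = _euler_from_matrix(pose.rotation)
    E = _translation_basis(alpha, pose.rotation)
    # translations are the contravariant components on (ml, ap, is) axes
    q = np.linalg.solve(E, pose.translation)
    return JCSCoordinates(
        flexion_deg=-math.degrees(alpha),
        adduction_deg=s * math.degrees(beta),
        internal_rot_deg=s * math.degrees(gamma),
        ml_mm=s * float(q[0]),
        ap_mm=float(q[1]),
        is_mm=float(q[2]),
    )


def pose_from_jcs(coords: JCSCoordinates, side: str = "right") -> RigidPose:
    """Build the rigid pose realising the given Grood–Suntay components."""
    s = _side_sign(side)
    alpha, beta, gamma = _angles_from_coords(coords, s)
    R = _euler_xyz_matrix(alpha, beta, gamma)
    E = _translation_basis(alpha, R)
    q = np.array([s * coords.ml_mm, coords.ap_mm, coords.is_mm])
    return RigidPose(R, E @ q, side)


def _check_wrench_at_tibial_origin(wrench: Wrench, pose: RigidPose) -> None:
    if not np.allclose(wrench.origin_mm, pose.translation, atol=1e-9):
        raise FrameMismatchError(
            "wrench must be expressed about the tibial origin "
            f"{pose.translation} (femoral frame); got origin "
            f"{wrench.origin_mm} — re-express the wrench first")


def jcs_load_from_wrench(wrench: Wrench, pose: RigidPose,
                         convention: str = "projection") -> JCSLoad:
    """Express a wrench at the tibial origin in the JCS of *pose*.

    Parameters
    ----------
    wrench
        Force (N) / moment (N·m) in femoral-frame components, taken about the
        tibial origin (``wrench.origin_mm`` must equal ``pose.translation``).
    convention
        ``"projection"`` (default): each component is the dot product of the
        force/moment with the corresponding JCS axis — the conventional
        simulator reading.  ``"conjugate"``: generalized loads strictly
        conjugate to the JCS coordinates (moments per radian, forces per mm),
        which additionally carry the force contribution through the
        translation's dependence on the angles.
    """
    _check_wrench_at_tibial_origin(wrench, pose)
    s = _side_sign(pose.side)
    alpha, beta, _ = _euler_from_matrix(pose.rotation)
    E = _translation_basis(alpha, pose.rotation)
    F, M = wrench.force_N, wrench.moment_Nm

    # force components are identical in both conventions
    ml_f = s * float(F @ E[:, 0])
    ap_f = float(F @ E[:, 1])
    is_f = float(F @ E[:, 2])

    flex_m = float(M @ np.array([-1.0, 0.0, 0.0]))
    add_m = s * float(M @ E[:, 1])
    int_m = s * float(M @ E[:, 2])

    if convention == "conjugate":
        ca, sa = math.cos(alpha), math.sin(alpha)
        cb, sb = math.cos(beta), math.sin(beta)
        q = np.linalg.solve(E, pose.translation)  # (ml', ap, is) right-knee
        ap, is_ = float(q[1]), float(q[2])
        dy_da = np.array([0.0, -sa, ca])
        dz_da = np.array([0.0, -ca * cb, -sa * cb])
        dz_db = np.array([cb, sa * sb, -ca * sb])
        dt_da = ap * dy_da + is_ * dz_da      # mm per rad of α
        dt_db = is_ * dz_db
        # flexion = −α, adduction = s·β; translation arm converted mm → m
        flex_m += -float(F @ dt_da) * 1e-3
        add_m += s * float(F @ dt_db) * 1e-3
        # note: ẑ″ does not depend on γ, so internal rotation is unchanged
    elif convention != "projection":
        raise ValueError(
            f"convention must be 'projection' or 'conjugate', got {convention!r}")

    return JCSLoad(ml_f, ap_f, is_f, flex_m, add_m, int_m)


def wrench_from_jcs_load(load: JCSLoad, pose: RigidPose) -> Wrench:
    """Inverse of :func:`jcs_load_from_wrench` (projection convention).

    Reconstructs the unique wrench at the tibial origin (femoral-frame
    components) whose JCS-axis projections are the given load components.
    """
    s = _side_sign(pose.side)
    alpha, _, _ = _euler_from_matrix(pose.rotation)
    E = _translation_basis(alpha, pose.rotation)
    A_force = np.vstack([s * E[:, 0], E[:, 1], E[:, 2]])
    A_moment = np.vstack([np.array([-1.0, 0.0, 0.0]),
                          s * E[:, 1], s * E[:, 2]])
    F = np.linalg.solve(A_force, np.array([load.ml_force_N,
                                           load.ap_force_N,
                                           load.is_force_N]))
    M = np.linalg.solve(A_moment, np.array([load.flexion_moment_Nm,
                                            load.adduction_moment_Nm,
                                            load.internal_rot_moment_Nm]))
    return Wrench(F, M, "femoral", pose.translation)
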