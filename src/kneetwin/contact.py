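"""Analytic penalty contact between toy condylar surfaces.

The articulating geometry is deliberately simple: each femoral condyle is a
sphere (femoral frame) and each tibial compartment is either a spherical dish
(concave, radius ≥ the sphere's) or a flat plateau at tibial z = 0.  Contact
is frictionless penalty contact: penetration δ from closed-form sphere–dish /
sphere–plane geometry produces a normal force k_c·δⁿ.  This keeps every
contact quantity analytic (and hence testable against closed forms) while
reproducing the load-bearing behaviour a conforming implant pairing gives:
compressive stiffness, medial/lateral load share, and a lateral restoring
stiffness ≈ N/(R_dish − R_sphere) from the ball-in-cup geometry.

Frames follow the package convention: x = medial→lateral (right knee),
y = anterior, z = proximal; the femoral frame origin sits at the level of the
condylar sphere centres, the tibial frame origin on the plateau, so the
touching pose has an inferior-superior translation of about −R_sphere.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

from .jcs import RigidPose
from .wrench import Wrench

__all__ = ["CondyleSurface", "ContactSurface", "ContactParams",
           "CondyleContact", "contact_wrench", "contact_patch",
           "contact_footprint", "touching_is_translation"]


@dataclass(frozen=True)
class CondyleSurface:
    """One condyle pairing: femoral sphere vs tibial dish or plane."""

    sphere_center_femoral_mm: np.ndarray
    sphere_radius_mm: float
    dish_center_tibial_mm: np.ndarray | None = None
    dish_radius_mm: float | None = None   # None → flat plateau at z_t = 0

    def __post_init__(self) -> None:
        c = np.asarray(self.sphere_center_femoral_mm, dtype=float)
        object.__setattr__(self, "sphere_center_femoral_mm", c)
        if self.sphere_radius_mm <= 0:
            raise ValueError("sphere radius must be positive")
        if (self.dish_center_tibial_mm is None) != (self.dish_radius_mm is None):
            raise ValueError("dish centre and radius must be given together")
        if self.dish_radius_mm is not None:
            if self.dish_radius_mm < self.sphere_radius_mm:
                raise ValueError(
                    "dish radius must be ≥ the femoral sphere radius")
            object.__setattr__(self, "dish_center_tibial_mm",
                               np.asarray(self.dish_center_tibial_mm,
                                          dtype=float))

    @property
    def is_dish(self) -> bool:
        return self.dish_radius_mm is not None


@dataclass(frozen=True)
class ContactSurface:
    """Medial and lateral condyle pairings."""

    medial: CondyleSurface
    lateral: CondyleSurface

    def condyles(self):
        return (("medial", self.medial), ("lateral", self.lateral))


@dataclass(frozen=True)
class ContactParams:
    """Penalty-contact parameters: normal force = stiffness · δ^exponent."""

    stiffness: float = 5000.0     # N/mm^n
    exponent: float = 1.0
    frictionless: bool = True     # lubricated metal-on-polyethylene

    def __post_init__(self) -> None:
        if self.stiffness <= 0:
            raise ValueError("penalty stiffness must be positive")
        if self.exponent < 1:
            raise ValueError("penalty exponent must be ≥ 1")
        if not self.frictionless:
            raise NotImplementedError("frictional contact is not modelled")


@dataclass(frozen=True)
class CondyleContact:
    """Per-condyle contact state at one pose."""

    penetration_mm: float
    normal_force_N: float
    contact_point_tibial_mm: np.ndarray = field(
        default_factory=lambda: np.full(3, np.nan))
    normal_femoral: np.ndarray = field(
        default_factory=lambda: np.full(3, np.nan))


def _condyle_contact(pose: RigidPose, cond: CondyleSurface,
                     params: ContactParams) -> CondyleContact:
    R, t = pose.rotation, pose.translation
    c_f = cond.sphere_center_femoral_mm
    if cond.is_dish:
        c_d = R @ cond.dish_center_tibial_mm + t   # dish centre, femoral frame
        u = c_f - c_d
        d = float(np.linalg.norm(u))
        delta = d + cond.sphere_radius_mm - cond.dish_radius_mm
        if delta <= 0.0 or d == 0.0:
            return CondyleContact(max(delta, 0.0), 0.0)
        u = u / d
        # dish pushes the sphere back toward its centre; reaction on tibia
        force_dir_tibia = u
        p_f = c_d + cond.dish_radius_mm * u  # point on the dish surface
        p_t = R.T @ (p_f - t)
        normal = u
    else:
        c_t = R.T @ (c_f - t)                 # sphere centre, tibial frame
        dist = float(c_t[2])                  # plateau plane z_t = 0
        delta = cond.sphere_radius_mm - dist
        if delta <= 0.0:
            return CondyleContact(max(delta, 0.0), 0.0)
        normal = R @ np.array([0.0, 0.0, 1.0])  # plateau normal, femoral
        force_dir_tibia = -normal
        p_t = np.array([c_t[0], c_t[1], 0.0])
    f = params.stiffness * delta ** params.exponent
    return CondyleContact(delta, f,
                          contact_point_tibial_mm=p_t,
                          normal_femoral=np.asarray(normal))


def contact_wrench(pose: RigidPose, surface: ContactSurface,
                   params: ContactParams
                   ) -> tuple[Wrench, dict[str, CondyleContact]]:
    """Total contact wrench on the tibia about the tibial origin.

    Returns the wrench (femoral-frame components) and the per-condyle contact
    states.  Separated condyles contribute zero; separation is a valid state.
    """
    R, t = pose.rotation, pose.translation
    F_total = np.zeros(3)
    M_total = np.zeros(3)
    states: dict[str, CondyleContact] = {}
    for name, cond in surface.condyles():
        st = _condyle_contact(pose, cond, params)
        states[name] = st
        if st.normal_force_N > 0.0:
            if cond.is_dish:
                c_d = R @ cond.dish_center_tibial_mm + t
                u = (cond.sphere_center_femoral_mm - c_d)
                u = u / np.linalg.norm(u)
                force = st.normal_force_N * u
            else:
                force = -st.normal_force_N * st.normal_femoral
            F_total += force
            arm = (R @ st.contact_point_tibial_mm + t) - t
            M_total += np.cross(arm, force) * 1e-3
    return Wrench(F_total, M_total, "femoral", t), states


def touching_is_translation(surface: ContactSurface) -> float:
    """Inferior-superior translation (mm) of the just-touching neutral pose.

    Assumes the mirror-symmetric toy layout (sphere centres at femoral z = 0,
    dish bottoms / plateau at tibial z = 0).
    """
    cond = surface.medial
    return -cond.sphere_radius_mm


def contact_patch(pose: RigidPose, cond: CondyleSurface
                  ) -> tuple[np.ndarray, float] | None:
    """Contact-patch circle on the tibial surface: (centre xy (mm), radius).

    Closed-form: for sphere-on-plane the chord circle radius is
    √(2Rδ − δ²); for sphere-in-dish it is the two-sphere intersection
    circle.  Returns None when separated.
    """
    R, t = pose.rotation, pose.translation
    c_f = cond.sphere_center_femoral_mm
    if cond.is_dish:
        c_d_t = cond.dish_center_tibial_mm
        c_f_t = R.T @ (c_f - t)
        u = c_f_t - c_d_t
        d = float(np.linalg.norm(u))
        if d + cond.sphere_radius_mm - cond.dish_radius_mm <= 0 or d == 0:
            return None
        r1, r2 = cond.sphere_radius_mm, cond.dish_radius_mm
        # two-sphere intersection: distance from dish centre to circle plane
        h = (d * d - r1 * r1 + r2 * r2) / (2 * d)
        a_sq = r2 * r2 - h * h
        if a_sq <= 0:
            return None
        centre = c_d_t + (h / d) * u
        return centre[:2].copy(), math.sqrt(a_sq)
    c_t = R.T @ (c_f - t)
    delta = cond.sphere_radius_mm - float(c_t[2])
    if delta <= 0:
        return None
    a_sq = 2 * cond.sphere_radius_mm * delta - delta * delta
    return c_t[:2].copy(), math.sqrt(a_sq)


def contact_footprint(poses, surface: ContactSurface,
                      grid_res_mm: float = 0.5) -> dict[str, dict]:
    """Union contact footprint over a pose trajectory, per condyle.

    Marks tibial-surface grid cells (cell-centre test) covered by the
    analytic contact patch of any pose; returns per-condyle area (mm²) and
    centroid (tibial x, y in mm).  This is a qualitative analog of the
    scanning-spray footprints used on physical inserts.
    """
    if grid_res_mm <= 0:
        raise ValueError("grid resolution must be positive")
    out: dict[str, dict] = {}
    for name, cond in surface.condyles():
        patches = []
        for pose in poses:
            p = contact_patch(pose, cond)
            if p is not None:
                patches.append(p)
        if not patches:
            out[name] = {"area_mm2": 0.0,
                         "centroid_mm": (float("nan"), float("nan")),
                         "n_poses_in_contact": 0}
            continue
        lo = np.min([c - r for c, r in patches], axis=0) - grid_res_mm
        hi = np.max([c + r for c, r in patches], axis=0) + grid_res_mm
        xs = np.arange(lo[0] + grid_res_mm / 2, hi[0], grid_res_mm)
        ys = np.arange(lo[1] + grid_res_mm / 2, hi[1], grid_res_mm)
        gx, gy = np.meshgrid(xs, ys, indexing="ij")
        covered = np.zeros(gx.shape, dtype=bool)
        for c, r in patches:
            covered |= (gx - c[0]) ** 2 + (gy - c[1]) ** 2 <= r * r
        area = float(covered.sum()) * grid_res_mm ** 2
        cx = float(gx[covered].mean())
        cy = float(gy[covered].mean())
        out[name] = {"area_mm2": area, "centroid_mm": (cx, cy),
                     "n_poses_in_contact": len(patches)}
    return out
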