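"""Synthetic Stan-like load cases, ligament fixtures and toy surfaces.

Every stage of the pipeline is testable without any external download: this
module generates one-cycle load-case tracks for the five activities of daily
living (ADLs), a 12-strand ligament apparatus on a generic-size right knee,
and the toy condylar surfaces the twin articulates.

The waveforms are sums of raised-cosine bumps — smooth (C¹ on the grid),
deterministic given a seed, and pinned to the printed scalar landmarks of
the standardised load cases: level walking is the fastest ADL at 0.625 Hz
and squat the slowest at 0.2 Hz; peak flexion ranges from 49° (level
walking) to 87° (stairs down); the peak compressive forces are 2,943 N
(stairs down), 2,930 N (downhill walking), 2,401 N (level walking) and
2,336 N (squat).  Compression is a negative inferior-superior force.
Landmarks without a printed value (downhill / stairs / sit-to-stand cycle
frequencies, sit-to-stand peak compression, per-ADL peak flexion other than
the two extremes) are fixture defaults chosen once for plausibility; the
waveform *shapes* between the landmarks are likewise invented fixtures, not
digitised curves.

Locomotion ADLs (level walking, downhill walking, stairs down) share the
stance/swing two-hump compression shape and start/end near 0° flexion;
sit-to-stand starts and ends at its flexion maximum.  A configurable
endpoint mismatch (a slow drift over the cycle) is injected so that raw
tracks are non-periodic and the periodisation stage has real work to do.

The ligament fixture is likewise synthetic: 12 strands in the four groups
(4 capsular, 3 medial, 3 lateral, 2 PCL bundles) with anatomically plausible
attachments — the collaterals near-isometric, the posterior capsule taut in
extension and the PCL slack near extension, engaging in deep flexion.  Its
stiffness/pre-strain values are fixture values in the style of the
literature, not measured parameters.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace as _replace

import numpy as np

from .contact import CondyleSurface, ContactSurface
from .jcs import JCSCoordinates, JCSLoad, pose_from_jcs, wrench_from_jcs_load
from .ligament import LigamentApparatus, LigamentLawParams, LigamentStrand
from .transfer import ADL_NAMES, CHANNELS, LoadCaseTrack, SourceRecording

__all__ = ["ADLTemplate", "ADL_TEMPLATES", "generate_load_case",
           "generate_recording", "default_apparatus", "toy_surfaces",
           "neutral_reference_pose"]


def _bump(u: np.ndarray, center: float, width: float) -> np.ndarray:
    """Raised-cosine bump, support (center−width, center+width), peak 1."""
    out = np.zeros_like(u)
    m = np.abs(u - center) < width
    out[m] = 0.5 * (1.0 + np.cos(np.pi * (u[m] - center) / width))
    return out


@dataclass(frozen=True)
class ADLTemplate:
    """Shape parameters of one ADL cycle.

    ``*_bumps`` are lists of (center, width, amplitude) raised-cosine terms
    on the normalised cycle u ∈ [0, 1]; flexion and axial-force channels are
    rescaled after summation so their extrema hit the peak values exactly.
    ``endpoint_mismatch`` is the relative drift injected over the cycle so
    raw endpoints do not match.
    """

    adl: str
    frequency_hz: float
    peak_flexion_deg: float
    peak_compression_N: float
    flexion_bumps: tuple = ()
    flexion_offset: float = 0.0      # relative to peak (sit-to-stand = 1)
    axial_bumps: tuple = ()          # relative amplitudes, made negative
    axial_offset: float = 0.0
    ap_force_bumps: tuple = ()       # absolute N
    ml_force_bumps: tuple = ()
    abad_moment_bumps: tuple = ()    # absolute N·m
    ei_rot_bumps: tuple = ()         # absolute deg
    endpoint_mismatch: float = 0.03


ADL_TEMPLATES: dict[str, ADLTemplate] = {
    "level_walking": ADLTemplate(
        adl="level_walking", frequency_hz=0.625,
        peak_flexion_deg=49.0, peak_compression_N=2401.0,
        flexion_bumps=((0.16, 0.13, 0.35), (0.72, 0.20, 1.0)),
        axial_bumps=((0.15, 0.14, 1.0), (0.45, 0.15, 0.93),
                     (0.72, 0.20, 0.12)),
        ap_force_bumps=((0.12, 0.10, 140.0), (0.55, 0.30, -260.0)),
        ml_force_bumps=((0.40, 0.30, -110.0),),
        abad_moment_bumps=((0.15, 0.14, 8.0), (0.45, 0.15, 7.0)),
        ei_rot_bumps=((0.20, 0.18, 3.0), (0.60, 0.25, -4.0))),
    "downhill_walking": ADLTemplate(
        adl="downhill_walking", frequency_hz=0.5,
        peak_flexion_deg=62.0, peak_compression_N=2930.0,
        flexion_bumps=((0.16, 0.13, 0.40), (0.72, 0.20, 1.0)),
        axial_bumps=((0.15, 0.14, 1.0), (0.46, 0.16, 0.90),
                     (0.72, 0.20, 0.12)),
        ap_force_bumps=((0.12, 0.10, 120.0), (0.56, 0.30, -300.0)),
        ml_force_bumps=((0.40, 0.30, -130.0),),
        abad_moment_bumps=((0.15, 0.14, 9.0), (0.46, 0.16, 8.0)),
        ei_rot_bumps=((0.20, 0.18, 3.0), (0.60, 0.25, -5.0))),
    "stairs_down": ADLTemplate(
        adl="stairs_down", frequency_hz=0.45,
        peak_flexion_deg=87.0, peak_compression_N=2943.0,
        flexion_bumps=((0.16, 0.14, 0.30), (0.70, 0.24, 1.0)),
        axial_bumps=((0.16, 0.15, 1.0), (0.47, 0.16, 0.88),
                     (0.70, 0.22, 0.12)),
        ap_force_bumps=((0.12, 0.10, 110.0), (0.60, 0.30, -320.0)),
        ml_force_bumps=((0.42, 0.30, -120.0),),
        abad_moment_bumps=((0.16, 0.15, 9.0), (0.47, 0.16, 8.0)),
        ei_rot_bumps=((0.22, 0.18, 3.0), (0.62, 0.25, -5.0))),
    "squat": ADLTemplate(
        adl="squat", frequency_hz=0.2,
        peak_flexion_deg=80.0, peak_compression_N=2336.0,
        flexion_bumps=((0.50, 0.40, 1.0),),
        axial_bumps=((0.50, 0.35, 0.80),), axial_offset=0.20,
        ap_force_bumps=((0.50, 0.30, -280.0),),
        ml_force_bumps=((0.50, 0.35, -90.0),),
        abad_moment_bumps=((0.50, 0.35, 6.0),),
        ei_rot_bumps=((0.50, 0.30, -4.0),)),
    "sit_to_stand": ADLTemplate(
        adl="sit_to_stand", frequency_hz=0.25,
        peak_flexion_deg=85.0, peak_compression_N=2200.0,
        flexion_bumps=((0.50, 0.38, -0.94),), flexion_offset=1.0,
        axial_bumps=((0.50, 0.35, -0.80),), axial_offset=1.0,
        ap_force_bumps=((0.15, 0.12, -220.0), (0.85, 0.12, -220.0)),
        ml_force_bumps=((0.50, 0.35, -80.0),),
        abad_moment_bumps=((0.15, 0.12, 5.0), (0.85, 0.12, 5.0)),
        ei_rot_bumps=((0.50, 0.30, 4.0),)),
}


def _sum_bumps(u: np.ndarray, bumps) -> np.ndarray:
    y = np.zeros_like(u)
    for c, w, a in bumps:
        y += a * _bump(u, c, w)
    return y


def _resolve_template(adl: str, overrides: dict | None) -> ADLTemplate:
    if adl not in ADL_TEMPLATES:
        raise ValueError(
            f"unknown ADL {adl!r}; valid names: {', '.join(ADL_NAMES)}")
    tpl = ADL_TEMPLATES[adl]
    if overrides:
        tpl = _replace(tpl, **overrides)
    return tpl


def generate_load_case(adl: str, n_samples: int = 100, seed: int = 0,
                       overrides: dict | None = None) -> LoadCaseTrack:
    """Generate one simulator-ready (but not yet periodised) ADL cycle.

    The flexion channel's maximum equals the template's peak flexion and the
    axial channel's minimum equals minus the peak compression, by
    construction (rescaled after the endpoint-mismatch drift is added, so
    the landmarks survive the drift).  Generation is pure: same
    (adl, n_samples, seed) → bitwise-identical tracks.
    """
    if n_samples < 32:
        raise ValueError("need at least 32 samples per cycle")
    tpl = _resolve_template(adl, overrides)
    rng = np.random.default_rng(seed)
    u = np.linspace(0.0, 1.0, n_samples)
    time_s = u / tpl.frequency_hz

    def drift(scale: float) -> np.ndarray:
        jit = rng.uniform(0.6, 1.0) * rng.choice((-1.0, 1.0))
        return tpl.endpoint_mismatch * scale * jit * u

    fe = tpl.flexion_offset * tpl.peak_flexion_deg \
        + tpl.peak_flexion_deg * _sum_bumps(u, tpl.flexion_bumps)
    fe = fe - np.abs(drift(tpl.peak_flexion_deg))  # keep the start the max
    fe = fe * (tpl.peak_flexion_deg / fe.max())

    ax = tpl.axial_offset + _sum_bumps(u, tpl.axial_bumps)
    ax = ax + np.abs(drift(0.5))
    is_n = -tpl.peak_compression_N * (ax / ax.max())

    ap_n = _sum_bumps(u, tpl.ap_force_bumps) + drift(60.0)
    ml_n = _sum_bumps(u, tpl.ml_force_bumps) + drift(40.0)
    abad = _sum_bumps(u, tpl.abad_moment_bumps) + drift(2.0)
    ei = _sum_bumps(u, tpl.ei_rot_bumps) + drift(1.0)

    channels = {"fe_deg": fe, "ei_deg": ei, "ml_N": ml_n, "ap_N": ap_n,
                "is_N": is_n, "abad_Nm": abad}
    return LoadCaseTrack(adl, time_s, channels, tpl.frequency_hz,
                         meta={"seed": seed, "synthetic": True,
                               "frame": "grood_suntay"})


#: kinematic landmarks for source recordings (mm / deg); AP translation
#: endpoints/mid-cycle values follow the printed squat / sit-to-stand
#: description, abduction ranges the printed per-ADL ranges
_KINEMATIC_TEMPLATES = {
    "level_walking": {"ap": (2.0, -6.0, 0.55, 0.25), "abad_range": 3.2},
    "downhill_walking": {"ap": (2.0, -7.0, 0.58, 0.25), "abad_range": 2.8},
    "stairs_down": {"ap": (2.0, -9.0, 0.60, 0.25), "abad_range": 2.0},
    "squat": {"ap": (-4.2, 8.2, 0.50, 0.40), "abad_range": 1.5},
    "sit_to_stand": {"ap": (7.5, -11.5, 0.50, 0.40), "abad_range": 1.5},
}


def generate_recording(adl: str, n_samples: int = 100, seed: int = 0,
                       overrides: dict | None = None,
                       frame_id: str = "INNEX",
                       side: str = "right") -> SourceRecording:
    """Generate a Stan-like full recording (pose + six-component wrench).

    The wrench is expressed in the tibial implant frame about its origin,
    the way instrumented implants report loads; kinematics are the
    corresponding tibial-relative-to-femoral poses.  This is the input shape
    the preparation chain (scale → register → convert → periodise) consumes.
    """
    track = generate_load_case(adl, n_samples, seed, overrides)
    tpl = _resolve_template(adl, overrides)
    kin = _KINEMATIC_TEMPLATES[adl]
    u = np.linspace(0.0, 1.0, n_samples)

    ap0, ap_amp, ap_c, ap_w = kin["ap"]
    ap_mm = ap0 + ap_amp * _bump(u, ap_c, ap_w)
    abad = kin["abad_range"] * (_bump(u, 0.30, 0.22)
                                - 0.45 * _bump(u, 0.70, 0.20))
    ml_mm = 0.8 * _bump(u, 0.45, 0.30)
    is_mm = -25.0 + 1.2 * _bump(u, 0.40, 0.30)

    fe_nm = -0.012 * tpl.peak_compression_N * _bump(u, 0.45, 0.30) * 1e-0
    ei_sign = 1.0 if adl == "sit_to_stand" else -1.0
    ei_nm = ei_sign * 0.002 * tpl.peak_compression_N * _bump(u, 0.50, 0.30)

    n = n_samples
    rotations = np.empty((n, 3, 3))
    translations = np.empty((n, 3))
    force = np.empty((n, 3))
    moment = np.empty((n, 3))
    ch = track.channels
    for i in range(n):
        coords = JCSCoordinates(
            flexion_deg=float(ch["fe_deg"][i]),
            adduction_deg=float(abad[i]),
            internal_rot_deg=float(ch["ei_deg"][i]),
            ml_mm=float(ml_mm[i]), ap_mm=float(ap_mm[i]),
            is_mm=float(is_mm[i]))
        pose = pose_from_jcs(coords, side)
        rotations[i] = pose.rotation
        translations[i] = pose.translation
        load = JCSLoad(ml_force_N=float(ch["ml_N"][i]),
                       ap_force_N=float(ch["ap_N"][i]),
                       is_force_N=float(ch["is_N"][i]),
                       flexion_moment_Nm=float(fe_nm[i]),
                       adduction_moment_Nm=float(ch["abad_Nm"][i]),
                       internal_rot_moment_Nm=float(ei_nm[i]))
        w = wrench_from_jcs_load(load, pose)
        # femoral components → tibial implant-frame components
        force[i] = pose.rotation.T @ w.force_N
        moment[i] = pose.rotation.T @ w.moment_Nm
    return SourceRecording(adl=adl, time_s=track.time_s,
                           rotations=rotations, translations=translations,
                           force_N=force, moment_Nm=moment,
                           frame_id=frame_id, side=side,
                           frequency_hz=tpl.frequency_hz)


# -- ligament apparatus fixture ---------------------------------------------

# name, group, femoral origin (mm), tibial insertion (mm), k (N/strain), εr.
# Frames: x lateral (+, right knee), y anterior, z proximal; femoral origin
# at condylar-centre level, tibial origin on the plateau.  Values are
# synthetic fixture values in the style of the literature.
_STRAND_TABLE = (
    ("cap_posteromedial", "capsular", (-20.0, -22.0, -2.0), (-20.0, -25.0, -10.0), 1500.0, 0.01),
    ("cap_posterolateral", "capsular", (20.0, -22.0, -2.0), (20.0, -25.0, -10.0), 1500.0, 0.01),
    ("cap_medial_arm", "capsular", (-26.0, -18.0, -2.0), (-26.0, -21.0, -10.0), 1200.0, 0.005),
    ("cap_lateral_arm", "capsular", (26.0, -18.0, -2.0), (26.0, -21.0, -10.0), 1200.0, 0.005),
    ("mcl_anterior", "medial", (-42.0, 6.0, 0.0), (-36.0, 8.0, -55.0), 2750.0, 0.05),
    ("mcl_intermediate", "medial", (-42.0, 0.0, 0.0), (-36.0, 0.0, -58.0), 2750.0, 0.05),
    ("mcl_posterior", "medial", (-42.0, -6.0, 0.0), (-36.0, -8.0, -52.0), 2750.0, 0.04),
    ("lcl_anterior", "lateral", (42.0, 4.0, 0.0), (40.0, 0.0, -42.0), 2000.0, 0.05),
    ("lcl_posterior", "lateral", (42.0, -4.0, 0.0), (40.0, -8.0, -42.0), 2000.0, 0.04),
    ("popliteofibular", "lateral", (38.0, -12.0, -2.0), (36.0, -10.0, -40.0), 1500.0, 0.02),
    # PCL femoral attachments sit close to the flexion axis inside the
    # notch, which is what makes the ligament near-isometric yet tightening
    # with flexion (slack near extension, engaging in deep flexion)
    ("pcl_anterolateral", "PCL", (-6.0, 1.0, -1.2), (-2.0, -20.0, -12.0), 9000.0, 0.0),
    ("pcl_posteromedial", "PCL", (-9.0, 0.0, -2.5), (-4.0, -23.0, -14.0), 9000.0, -0.015),
)


def default_apparatus(seed: int = 0,
                      law: LigamentLawParams | None = None,
                      attachment_jitter_mm: float = 0.5) -> LigamentApparatus:
    """The 12-strand reference ligament apparatus (synthetic fixture).

    Topology (names, groups, stiffnesses, reference strains) is fixed; the
    attachment coordinates are jittered by up to ``attachment_jitter_mm``
    deterministically from *seed*, so different seeds give the same
    apparatus with slightly different anatomy.  The reference pose is not
    set here; call :func:`~kneetwin.ligament.set_reference_pose` (or the
    compliance-compensated variant) before computing forces.
    """
    rng = np.random.default_rng(seed)
    strands = []
    for name, group, origin, insertion, k, er in _STRAND_TABLE:
        jo = rng.uniform(-attachment_jitter_mm, attachment_jitter_mm, 3)
        ji = rng.uniform(-attachment_jitter_mm, attachment_jitter_mm, 3)
        strands.append(LigamentStrand(
            name=name, group=group,
            origin_mm=np.asarray(origin) + jo,
            insertion_mm=np.asarray(insertion) + ji,
            stiffness_N_per_strain=k, reference_strain=er))
    return LigamentApparatus(tuple(strands), law or LigamentLawParams())


def toy_surfaces(condyle_radius_mm: float = 25.0,
                 dish_radius_mm: float | None = 30.0,
                 condyle_spacing_mm: float = 44.0) -> ContactSurface:
    """Mirror-symmetric two-condyle toy surface pair.

    Femoral condyles are spheres centred at ±spacing/2 on the medial-lateral
    axis at the femoral origin's level; tibial compartments are spherical
    dishes whose bottoms lie on the plateau plane (tibial z = 0), or flat
    plateaus when ``dish_radius_mm`` is None.  ``dish_radius_mm`` equal to
    the condyle radius is the fully conforming limit and is accepted.
    """
    if condyle_spacing_mm <= 0:
        raise ValueError("condyle spacing must be positive (a single "
                         "degenerate condyle is not a valid surface)")
    half = condyle_spacing_mm / 2.0

    def condyle(x: float) -> CondyleSurface:
        if dish_radius_mm is None:
            return CondyleSurface(
                sphere_center_femoral_mm=np.array([x, 0.0, 0.0]),
                sphere_radius_mm=condyle_radius_mm)
        return CondyleSurface(
            sphere_center_femoral_mm=np.array([x, 0.0, 0.0]),
            sphere_radius_mm=condyle_radius_mm,
            dish_center_tibial_mm=np.array([x, 0.0, dish_radius_mm]),
            dish_radius_mm=dish_radius_mm)

    return ContactSurface(medial=condyle(-half), lateral=condyle(half))


def neutral_reference_pose(surface: ContactSurface,
                           side: str = "right"):
    """Full-extension pose with the surfaces just touching (the usual
    ligament reference posture)."""
    return pose_from_jcs(
        JCSCoordinates(is_mm=-surface.medial.sphere_radius_mm), side)
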