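"""Virtual ligament apparatus: point-to-point strands with a toe-region law.

Each ligament strand is a tension-only line element between a femoral
attachment (the *origin*) and a tibial attachment (the *insertion*).  Its
force-strain behaviour is the classic nonlinear law with a quadratic toe
region: zero force for negative strain, force ∝ ε² up to twice the toe
strain ε₁, then linear with stiffness k,

    f(ε) = 0                      ε < 0
         = ¼ · k · ε² / ε₁        0 ≤ ε ≤ 2ε₁
         = k · (ε − ε₁)           ε > 2ε₁

with ε₁ = 0.03 by default.  Both branches meet at f(2ε₁) = k·ε₁ with a
continuous slope, so f is C¹ and non-decreasing.

Strain is computed from the strand's reference length lr (its length at a
chosen *reference pose*, usually full extension) and its reference strain εr
(the pre-tension at that pose).  Two strain models are provided:

* ``"blankevoort"`` (default): ε = (l·(1+εr) − lr) / lr, i.e. strain relative
  to the zero-load length lr/(1+εr).  This is the standard literature form:
  a strand shorter than its zero-load length is slack.
* ``"as_printed"``: ε = εr·l/lr, a pure rescaling.  It reproduces εr at the
  reference pose but can never reach zero strain for εr > 0, so it has no
  slack regime; it is retained for fidelity comparisons only.

Stiffness k is in newtons per unit strain (so k·ε is a force).  The strands
are grouped (capsular, medial, lateral, PCL) so whole structures can be
resected or stiffened, which is how soft-tissue variation studies are run.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np

from .jcs import RigidPose
from .wrench import Wrench

__all__ = [
    "STRAND_GROUPS", "LigamentLawParams", "LigamentStrand",
    "LigamentApparatus", "set_reference_pose", "strand_length", "strain",
    "strand_force_magnitude", "apparatus_wrench", "resect_group",
    "scale_group_stiffness",
]

STRAND_GROUPS = ("capsular", "medial", "lateral", "PCL")


@dataclass(frozen=True)
class LigamentLawParams:
    """Parameters of the force-strain law and strain model."""

    toe_strain: float = 0.03
    strain_model: str = "blankevoort"

    def __post_init__(self) -> None:
        if self.toe_strain <= 0:
            raise ValueError("toe_strain must be positive")
        if self.strain_model not in ("blankevoort", "as_printed"):
            raise ValueError(
                f"unknown strain_model {self.strain_model!r}; expected "
                "'blankevoort' or 'as_printed'")


@dataclass(frozen=True)
class LigamentStrand:
    """One point-to-point strand.

    ``origin_mm`` is the femoral attachment (femoral frame), ``insertion_mm``
    the tibial attachment (tibial frame).  ``reference_length_mm`` is derived
    by :func:`set_reference_pose`, not user input.
    """

    name: str
    group: str
    origin_mm: np.ndarray
    insertion_mm: np.ndarray
    stiffness_N_per_strain: float
    reference_strain: float
    reference_length_mm: float | None = None

    def __post_init__(self) -> None:
        if self.group not in STRAND_GROUPS:
            raise ValueError(f"unknown group {self.group!r}; "
                             f"expected one of {STRAND_GROUPS}")
        if self.stiffness_N_per_strain <= 0:
            raise ValueError(f"strand {self.name!r}: stiffness must be positive")
        if self.reference_length_mm is not None and self.reference_length_mm <= 0:
            raise ValueError(f"strand {self.name!r}: reference length must be "
                             "positive")
        object.__setattr__(self, "origin_mm",
                           np.asarray(self.origin_mm, dtype=float))
        object.__setattr__(self, "insertion_mm",
                           np.asarray(self.insertion_mm, dtype=float))


@dataclass(frozen=True)
class LigamentApparatus:
    """An ordered set of strands plus the force law and reference pose."""

    strands: tuple[LigamentStrand, ...]
    law: LigamentLawParams = field(default_factory=LigamentLawParams)
    reference_pose: RigidPose | None = None

    def __post_init__(self) -> None:
        object.__setattr__(self, "strands", tuple(self.strands))

    def groups(self) -> dict[str, int]:
        out: dict[str, int] = {}
        for s in self.strands:
            out[s.group] = out.get(s.group, 0) + 1
        return out

    def __len__(self) -> int:
        return len(self.strands)


def strand_length(strand: LigamentStrand, pose: RigidPose) -> float:
    """Current origin–insertion distance (mm) at *pose*."""
    insertion_femoral = pose.rotation @ strand.insertion_mm + pose.translation
    return float(np.linalg.norm(strand.origin_mm - insertion_femoral))


def set_reference_pose(app: LigamentApparatus,
                       pose: RigidPose) -> LigamentApparatus:
    """Record every strand's reference length at *pose*.

    Idempotent for a fixed pose.  Raises if a strand's attachments coincide
    at the pose (zero reference length), naming the strand.
    """
    strands = []
    for s in app.strands:
        lr = strand_length(s, pose)
        if lr <= 1e-9:
            raise ValueError(
                f"strand {s.name!r}: attachment points coincide at the "
                "reference pose (zero reference length)")
        strands.append(replace(s, reference_length_mm=lr))
    return LigamentApparatus(tuple(strands), app.law, pose)


def strain(strand: LigamentStrand, pose: RigidPose,
           law: LigamentLawParams) -> float:
    """Current strand strain (dimensionless) at *pose*."""
    if strand.reference_length_mm is None:
        raise ValueError(
            f"strand {strand.name!r}: reference length not initialised — "
            "call set_reference_pose first")
    l = strand_length(strand, pose)
    lr = strand.reference_length_mm
    er = strand.reference_strain
    if law.strain_model == "as_printed":
        return er * l / lr
    return (l * (1.0 + er) - lr) / lr


def strand_force_magnitude(eps: float, stiffness_N_per_strain: float,
                           law: LigamentLawParams) -> float:
    """Tension (N) at strain *eps*: slack / quadratic toe / linear."""
    k = stiffness_N_per_strain
    if k <= 0:
        raise ValueError("stiffness must be positive")
    e1 = law.toe_strain
    if eps < 0.0:
        return 0.0
    if eps <= 2.0 * e1:
        return 0.25 * k * eps * eps / e1
    return k * (eps - e1)


def apparatus_wrench(app: LigamentApparatus, pose: RigidPose) -> Wrench:
    """Total ligament wrench on the tibia, about the tibial origin.

    Each taut strand pulls its tibial insertion point toward its femoral
    origin; forces and insertion-arm moments are summed in femoral-frame
    components.  Slack strands contribute nothing.  The reaction on the femur
    is not tracked: the simulator sums ligament loads into the tibial load
    channel only.
    """
    F_total = np.zeros(3)
    M_total = np.zeros(3)
    for s in app.strands:
        eps = strain(s, pose, app.law)
        f = strand_force_magnitude(eps, s.stiffness_N_per_strain, app.law)
        if f == 0.0:
            continue
        insertion_femoral = pose.rotation @ s.insertion_mm + pose.translation
        d = s.origin_mm - insertion_femoral
        n = np.linalg.norm(d)
        direction = d / n
        force = f * direction
        F_total += force
        # arm from tibial origin to the insertion point, femoral components
        arm = insertion_femoral - pose.translation
        M_total += np.cross(arm, force) * 1e-3  # N·mm → N·m
    return Wrench(F_total, M_total, "femoral", pose.translation)


def resect_group(app: LigamentApparatus, group: str) -> LigamentApparatus:
    """Remove a whole ligament group (e.g. the PCL); returns a new apparatus."""
    if group not in STRAND_GROUPS:
        raise ValueError(f"unknown group {group!r}; expected one of "
                         f"{STRAND_GROUPS}")
    if group not in app.groups():
        raise ValueError(f"group {group!r} not present in the apparatus")
    kept = tuple(s for s in app.strands if s.group != group)
    return LigamentApparatus(kept, app.law, app.reference_pose)


def scale_group_stiffness(app: LigamentApparatus, group: str,
                          factor: float) -> LigamentApparatus:
    """Multiply the stiffness of every strand in *group* by *factor*."""
    if factor <= 0:
        raise ValueError("stiffness factor must be positive")
    if group not in STRAND_GROUPS:
        raise ValueError(f"unknown group {group!r}; expected one of "
                         f"{STRAND_GROUPS}")
    if group not in app.groups():
        raise ValueError(f"group {group!r} not present in the apparatus")
    strands = tuple(
        replace(s, stiffness_N_per_strain=s.stiffness_N_per_strain * factor)
        if s.group == group else s
        for s in app.strands)
    return LigamentApparatus(strands, app.law, app.reference_pose)
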