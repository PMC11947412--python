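"""Quasi-static computational twin of a six-DOF joint simulator.

The physical machine runs hybrid control: flexion-extension and
external-internal rotation are position-controlled, while the
anterior-posterior, medial-lateral and inferior-superior directions and the
abduction-adduction rotation are force/moment-controlled.  The target for
the force-controlled channels is the *summed* joint reaction: contact wrench
(what the force transducer sees) plus the virtual ligament wrench.

With no plant dynamics to model there is nothing for an iterative-learning
controller to learn, so the twin replaces it with direct equilibrium
solving: at each time step the two position-controlled coordinates are
clamped to their targets and the remaining four (adduction, medial-lateral,
anterior-posterior, inferior-superior) are found by a damped Newton
iteration such that contact + ligament load matches the target load.  The
machine's 300-cycle convergence protocol is re-interpreted as
cycle-periodicity of the quasi-static solution, reached by the second cycle
because the system has no memory.

Non-convergence of a step is a flagged state, not an exception, mirroring
how a physical run is judged (no unusually high control errors, stumbling or
dislocations); a run with more than 10 % flagged steps is marked failed.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .contact import ContactParams, ContactSurface, contact_wrench
from .jcs import JCSCoordinates, JCSLoad, RigidPose, jcs_load_from_wrench, pose_from_jcs
from .ligament import LigamentApparatus, apparatus_wrench, set_reference_pose
from .transfer import LoadCaseTrack
from .wrench import Wrench

__all__ = [
    "SolverSettings", "EquilibriumStep", "SimulationResult",
    "MachineCompliance", "total_jcs_load", "solve_equilibrium_step",
    "run_load_case", "mean_axial_load", "apply_compliance_compensation",
    "flexion_binned_comparison",
]

#: index order of the free (force-controlled) coordinates
_FREE = ("adduction_deg", "ml_mm", "ap_mm", "is_mm")


@dataclass(frozen=True)
class SolverSettings:
    """Newton-solver knobs.

    ``force_tol_N`` / ``moment_tol_Nm`` are the *convergence criteria* a step
    is flagged against (machine-level tolerances).  The iteration itself
    keeps refining down to ``inner_force_tol_N`` so that re-solving from a
    different warm start lands on the same pose to well below 1e-6.
    """

    force_tol_N: float = 0.5
    moment_tol_Nm: float = 0.05
    inner_force_tol_N: float = 1e-7
    max_iterations: int = 50
    fd_step: float = 1e-5            # mm / deg, central differences
    max_step: float = 5.0            # trust region per iteration (mm / deg)


@dataclass(frozen=True)
class MachineCompliance:
    """Axial frame compliance of the machine (mm of sag per N), default 0."""

    axial_mm_per_N: float = 0.0

    def __post_init__(self) -> None:
        if self.axial_mm_per_N < 0:
            raise ValueError("compliance must be ≥ 0")


@dataclass(frozen=True)
class EquilibriumStep:
    """Solution of one quasi-static step."""

    coords: JCSCoordinates
    converged: bool
    residual_force_N: float          # recomputed max |force residual|
    residual_moment_Nm: float        # recomputed |abad moment residual|
    iterations: int
    contact_load: JCSLoad
    ligament_load: JCSLoad
    condyle_forces_N: dict[str, float]
    condyle_penetrations_mm: dict[str, float]


@dataclass
class SimulationResult:
    """Per-step results of the reported (last) cycle of a run."""

    adl: str
    variant: str
    time_s: np.ndarray
    steps: list[EquilibriumStep]
    cycle_pose_change: float         # max |Δ coords| between last two cycles
    failed: bool
    meta: dict = field(default_factory=dict)

    @property
    def n_steps(self) -> int:
        return len(self.steps)

    @property
    def fraction_converged(self) -> float:
        if not self.steps:
            return 0.0
        return sum(s.converged for s in self.steps) / len(self.steps)

    def coords_array(self) -> np.ndarray:
        return np.array([s.coords.as_array() for s in self.steps])

    def poses(self, side: str = "right") -> list[RigidPose]:
        return [pose_from_jcs(s.coords, side) for s in self.steps]

    def to_dataframe(self) -> pd.DataFrame:
        rows = []
        for t, s in zip(self.time_s, self.steps):
            total = s.contact_load.as_array() + s.ligament_load.as_array()
            rows.append({
                "time_s": t,
                "fe_deg": s.coords.flexion_deg,
                "ad_deg": s.coords.adduction_deg,
                "ei_deg": s.coords.internal_rot_deg,
                "ml_mm": s.coords.ml_mm,
                "ap_mm": s.coords.ap_mm,
                "is_mm": s.coords.is_mm,
                "ml_N": total[0], "ap_N": total[1], "is_N": total[2],
                "abad_Nm": total[4],
                "medial_N": s.condyle_forces_N.get("medial", 0.0),
                "lateral_N": s.condyle_forces_N.get("lateral", 0.0),
                "residual_force_N": s.residual_force_N,
                "residual_moment_Nm": s.residual_moment_Nm,
                "converged": s.converged,
            })
        return pd.DataFrame(rows)

    def summary(self) -> dict:
        df = self.to_dataframe()
        return {
            "adl": self.adl,
            "variant": self.variant,
            "n_steps": self.n_steps,
            "fraction_converged": self.fraction_converged,
            "max_residual_force_N": float(df["residual_force_N"].max()),
            "max_residual_moment_Nm": float(df["residual_moment_Nm"].max()),
            "cycle_pose_change": self.cycle_pose_change,
            "failed": self.failed,
            **self.meta,
        }


def total_jcs_load(coords: JCSCoordinates, app: LigamentApparatus,
                   surface: ContactSurface, params: ContactParams,
                   side: str = "right"):
    """Contact + ligament load in the JCS at *coords*.

    Returns ``(total, contact_load, ligament_load, condyle_states)``.
    """
    pose = pose_from_jcs(coords, side)
    w_c, states = contact_wrench(pose, surface, params)
    w_l = apparatus_wrench(app, pose)
    lc = jcs_load_from_wrench(w_c, pose)
    ll = jcs_load_from_wrench(w_l, pose)
    total = jcs_load_from_wrench(
        Wrench(w_c.force_N + w_l.force_N, w_c.moment_Nm + w_l.moment_Nm,
               "femoral", pose.translation), pose)
    return total, lc, ll, states


def _residual(total: JCSLoad, targets: JCSLoad) -> np.ndarray:
    """Residual on the four force-controlled channels (ml, ap, is, abad)."""
    return np.array([
        total.ml_force_N - targets.ml_force_N,
        total.ap_force_N - targets.ap_force_N,
        total.is_force_N - targets.is_force_N,
        total.adduction_moment_Nm - targets.adduction_moment_Nm,
    ])


def _coords_from_free(flexion: float, internal: float,
                      x: np.ndarray) -> JCSCoordinates:
    return JCSCoordinates(flexion_deg=flexion, adduction_deg=float(x[0]),
                          internal_rot_deg=internal, ml_mm=float(x[1]),
                          ap_mm=float(x[2]), is_mm=float(x[3]))


def _axial_bisect_guess(flexion: float, internal: float, target_is: float,
                        app, surface, params, side: str) -> np.ndarray:
    """1-D bracket/bisect on the IS translation for a cold start."""
    def axial(is_mm: float) -> float:
        c = JCSCoordinates(flexion_deg=flexion, internal_rot_deg=internal,
                           is_mm=is_mm)
        total, *_ = total_jcs_load(c, app, surface, params, side)
        return total.is_force_N - target_is
    r0 = surface.medial.sphere_radius_mm
    hi, lo = -r0 + 10.0, -r0 - 10.0
    f_hi, f_lo = axial(hi), axial(lo)
    # axial load decreases (more compressive) as the tibia moves superiorly;
    # widen the bracket if needed, then bisect
    for _ in range(20):
        if f_hi >= 0 >= f_lo or f_hi <= 0 <= f_lo:
            break
        hi += 5.0
        lo -= 5.0
        f_hi, f_lo = axial(hi), axial(lo)
    for _ in range(60):
        mid = 0.5 * (hi + lo)
        f_mid = axial(mid)
        if (f_mid > 0) == (f_hi > 0):
            hi, f_hi = mid, f_mid
        else:
            lo, f_lo = mid, f_mid
    return np.array([0.0, 0.0, 0.0, 0.5 * (hi + lo)])


def solve_equilibrium_step(position_targets: tuple[float, float],
                           load_targets: JCSLoad,
                           app: LigamentApparatus,
                           surface: ContactSurface,
                           params: ContactParams,
                           guess: JCSCoordinates | None = None,
                           settings: SolverSettings = SolverSettings(),
                           side: str = "right") -> EquilibriumStep:
    """Solve one hybrid-control step.

    ``position_targets`` = (flexion_deg, internal_rot_deg) are clamped; the
    four remaining coordinates are iterated (damped Newton, numerical
    Jacobian by central differences, Levenberg-style damping) until contact +
    ligament load matches ``load_targets`` on the force-controlled channels.
    Non-convergence is reported in the flag, never raised; the residuals are
    recomputed from the returned pose, not taken from solver internals.
    """
    flexion, internal = position_targets
    if guess is None:
        x = _axial_bisect_guess(flexion, internal, load_targets.is_force_N,
                                app, surface, params, side)
    else:
        x = np.array([guess.adduction_deg, guess.ml_mm, guess.ap_mm,
                      guess.is_mm])

    def res(xv: np.ndarray) -> np.ndarray:
        total, *_ = total_jcs_load(_coords_from_free(flexion, internal, xv),
                                   app, surface, params, side)
        return _residual(total, load_targets)

    # moments weighted so the mixed-unit residual norm is balanced at the
    # ratio of the two flag tolerances (0.5 N ↔ 0.05 N·m)
    w = np.array([1.0, 1.0, 1.0,
                  settings.force_tol_N / settings.moment_tol_Nm])
    r = res(x)
    lam = 1e-3
    n_iter = 0
    h = settings.fd_step
    for n_iter in range(1, settings.max_iterations + 1):
        if np.linalg.norm(w * r, np.inf) < settings.inner_force_tol_N:
            break
        J = np.empty((4, 4))
        for j in range(4):
            xp = x.copy(); xp[j] += h
            xm = x.copy(); xm[j] -= h
            J[:, j] = (res(xp) - res(xm)) / (2 * h)
        Jw = w[:, None] * J
        rw = w * r
        improved = False
        for _ in range(12):
            A = Jw.T @ Jw + lam * np.diag(np.diag(Jw.T @ Jw) + 1e-12)
            try:
                step = np.linalg.solve(A, -Jw.T @ rw)
            except np.linalg.LinAlgError:
                lam *= 10
                continue
            s_norm = np.linalg.norm(step, np.inf)
            if s_norm > settings.max_step:
                step *= settings.max_step / s_norm
            x_new = x + step
            r_new = res(x_new)
            if np.linalg.norm(w * r_new) < np.linalg.norm(rw):
                x, r = x_new, r_new
                lam = max(lam / 10, 1e-12)
                improved = True
                break
            lam *= 10
        if not improved:
            break

    coords = _coords_from_free(flexion, internal, x)
    total, lc, ll, states = total_jcs_load(coords, app, surface, params, side)
    r_final = _residual(total, load_targets)
    res_f = float(np.abs(r_final[:3]).max())
    res_m = float(abs(r_final[3]))
    converged = (res_f < settings.force_tol_N
                 and res_m < settings.moment_tol_Nm)
    return EquilibriumStep(
        coords=coords, converged=converged,
        residual_force_N=res_f, residual_moment_Nm=res_m,
        iterations=n_iter, contact_load=lc, ligament_load=ll,
        condyle_forces_N={k: v.normal_force_N for k, v in states.items()},
        condyle_penetrations_mm={k: v.penetration_mm
                                 for k, v in states.items()})


def _targets_at(track: LoadCaseTrack, i: int) -> tuple[tuple, JCSLoad]:
    ch = track.channels
    pos = (float(ch["fe_deg"][i]), float(ch["ei_deg"][i]))
    load = JCSLoad(ml_force_N=float(ch["ml_N"][i]),
                   ap_force_N=float(ch["ap_N"][i]),
                   is_force_N=float(ch["is_N"][i]),
                   adduction_moment_Nm=float(ch["abad_Nm"][i]))
    return pos, load


def run_load_case(track: LoadCaseTrack, app: LigamentApparatus,
                  surface: ContactSurface, params: ContactParams,
                  cycles: int = 2,
                  settings: SolverSettings = SolverSettings(),
                  side: str = "right", variant: str = "reference",
                  require_periodic: bool = True) -> SimulationResult:
    """Run a full load-case cycle to steady state.

    Steps are solved in order with warm starts; ``cycles`` passes are made
    (the first plays the role of the machine's run-in cycles) and the last
    cycle is reported together with the maximum cycle-to-cycle pose change.
    The run is marked failed if more than 10 % of reported steps did not
    converge.
    """
    if require_periodic and not track.is_periodic(atol=1e-9):
        raise ValueError(
            "track endpoints do not match: run the preparation chain "
            "(periodise) before simulating")
    if app.reference_pose is None:
        raise ValueError("ligament apparatus has no reference pose set")
    if cycles < 1:
        raise ValueError("need at least one cycle")

    n = track.n_samples
    guess: JCSCoordinates | None = None
    prev_cycle: np.ndarray | None = None
    cycle_change = math.inf
    steps: list[EquilibriumStep] = []
    for cyc in range(cycles):
        steps = []
        for i in range(n):
            pos, load = _targets_at(track, i)
            st = solve_equilibrium_step(pos, load, app, surface, params,
                                        guess=guess, settings=settings,
                                        side=side)
            steps.append(st)
            guess = st.coords
        this_cycle = np.array([s.coords.as_array() for s in steps])
        if prev_cycle is not None:
            cycle_change = float(np.abs(this_cycle - prev_cycle).max())
        prev_cycle = this_cycle

    frac_bad = 1.0 - sum(s.converged for s in steps) / n
    return SimulationResult(
        adl=track.adl, variant=variant, time_s=track.time_s.copy(),
        steps=steps,
        cycle_pose_change=cycle_change if cycles > 1 else math.nan,
        failed=frac_bad > 0.10,
        meta={"cycles": cycles, "frequency_hz": track.frequency_hz})


def mean_axial_load(track: LoadCaseTrack) -> float:
    """Time-weighted mean of the inferior-superior force over one cycle (N)."""
    if "is_N" not in track.channels:
        raise ValueError("track has no inferior-superior force channel")
    y = track.channels["is_N"]
    t = track.time_s
    return float(np.trapezoid(y, t) / (t[-1] - t[0]))


def apply_compliance_compensation(app: LigamentApparatus,
                                  track: LoadCaseTrack,
                                  compliance: MachineCompliance,
                                  nominal_pose: RigidPose) -> LigamentApparatus:
    """Reference the apparatus with the machine's load-dependent sag removed.

    The machine's frame deforms under load without its sensors registering
    it, so strand reference lengths taken at the nominal pose are wrong by
    the sag under the working load.  Following the mean-compression recipe,
    the reference pose is the nominal pose shifted along the tibial long axis
    by ``compliance × mean axial load`` of the cycle (a compressive mean is
    negative, so the tibia is referenced inferiorly — the joint space the
    machine actually has under load).  With zero compliance this is exactly
    plain referencing at the nominal pose.
    """
    f_mean = mean_axial_load(track)
    sag = compliance.axial_mm_per_N * f_mean
    axis = nominal_pose.rotation @ np.array([0.0, 0.0, 1.0])
    shifted = RigidPose(nominal_pose.rotation,
                        nominal_pose.translation + sag * axis,
                        nominal_pose.side)
    return set_reference_pose(app, shifted)


def flexion_binned_comparison(result_a: SimulationResult,
                              result_b: SimulationResult,
                              bin_deg: float = 10.0) -> pd.DataFrame:
    """Flexion-binned deltas (b − a) of AP translation, adduction, IS force.

    Samples are split into flexion (flexion angle increasing) and extension
    (decreasing) phases by the sign of the flexion rate, binned by flexion
    angle, and the per-bin means are differenced.  Both results must come
    from the same track.
    """
    if result_a.n_steps != result_b.n_steps or \
            not np.allclose(result_a.time_s, result_b.time_s):
        raise ValueError("results come from different tracks")
    if bin_deg <= 0:
        raise ValueError("bin width must be positive")

    def extract(res: SimulationResult) -> pd.DataFrame:
        q = res.coords_array()
        df = pd.DataFrame({
            "fe_deg": q[:, 0], "ad_deg": q[:, 1],
            "ap_mm": q[:, 4],
            "is_N": [s.contact_load.is_force_N + s.ligament_load.is_force_N
                     for s in res.steps],
        })
        rate = np.gradient(df["fe_deg"].to_numpy(), res.time_s)
        df["phase"] = np.where(rate >= 0, "flexion", "extension")
        return df

    da, db = extract(result_a), extract(result_b)
    fe_all = np.concatenate([da["fe_deg"], db["fe_deg"]])
    lo = math.floor(fe_all.min() / bin_deg) * bin_deg
    hi = math.ceil(fe_all.max() / bin_deg) * bin_deg
    edges = np.arange(lo, hi + bin_deg / 2, bin_deg)
    rows = []
    for phase in ("flexion", "extension"):
        sa = da[da["phase"] == phase]
        sb = db[db["phase"] == phase]
        for k in range(len(edges) - 1):
            e0, e1 = edges[k], edges[k + 1]
            ma = sa[(sa["fe_deg"] >= e0) & (sa["fe_deg"] < e1)]
            mb = sb[(sb["fe_deg"] >= e0) & (sb["fe_deg"] < e1)]
            if ma.empty or mb.empty:
                continue
            rows.append({
                "phase": phase, "bin_lo_deg": e0, "bin_hi_deg": e1,
                "bin_mid_deg": 0.5 * (e0 + e1),
                "d_ap_mm": mb["ap_mm"].mean() - ma["ap_mm"].mean(),
                "d_adduction_deg": mb["ad_deg"].mean() - ma["ad_deg"].mean(),
                "d_is_force_N": mb["is_N"].mean() - ma["is_N"].mean(),
                "n_a": len(ma), "n_b": len(mb),
            })
    return pd.DataFrame(rows)
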