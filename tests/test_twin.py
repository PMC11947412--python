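"""Equilibrium solving, load-case runs, compliance and binned comparisons."""

import numpy as np
import pytest

from kneetwin.contact import ContactParams
from kneetwin.jcs import JCSCoordinates, JCSLoad, pose_from_jcs
from kneetwin.ligament import (LigamentApparatus, LigamentLawParams,
                               LigamentStrand, set_reference_pose)
from kneetwin.synthetic import (generate_load_case, neutral_reference_pose,
                                toy_surfaces)
from kneetwin.transfer import CHANNELS, LoadCaseTrack, periodise
from kneetwin.twin import (MachineCompliance, apply_compliance_compensation,
                           flexion_binned_comparison, mean_axial_load,
                           run_load_case, solve_equilibrium_step,
                           total_jcs_load)


def empty_apparatus(surface):
    return set_reference_pose(LigamentApparatus((), LigamentLawParams()),
                              neutral_reference_pose(surface))


class TestEquilibriumStep:
    def test_symmetric_compression_stays_on_midline(self, surface, params,
                                                    apparatus):
        app = empty_apparatus(surface)
        st = solve_equilibrium_step((0.0, 0.0), JCSLoad(is_force_N=-1000.0),
                                    app, surface, params)
        assert st.converged
        assert abs(st.coords.ml_mm) < 1e-6
        assert abs(st.coords.ap_mm) < 1e-6
        assert abs(st.coords.adduction_deg) < 1e-6

    @pytest.mark.parametrize("load", [-200.0, -1000.0, -2500.0])
    def test_analytic_penetration_without_ligaments(self, plane_surface,
                                                    load):
        params = ContactParams(stiffness=5000.0, exponent=1.0)
        app = empty_apparatus(plane_surface)
        st = solve_equilibrium_step((0.0, 0.0), JCSLoad(is_force_N=load),
                                    app, plane_surface, params)
        assert st.converged
        expected = -load / (2 * params.stiffness)  # two condyles share it
        for pen in st.condyle_penetrations_mm.values():
            assert pen == pytest.approx(expected, abs=1e-8)

    def test_residuals_recomputed_from_returned_pose(self, surface, params,
                                                     apparatus):
        target = JCSLoad(is_force_N=-800.0, ap_force_N=-50.0)
        st = solve_equilibrium_step((30.0, 0.0), target, apparatus, surface,
                                    params)
        total, *_ = total_jcs_load(st.coords, apparatus, surface, params)
        recomputed = max(abs(total.ml_force_N - target.ml_force_N),
                         abs(total.ap_force_N - target.ap_force_N),
                         abs(total.is_force_N - target.is_force_N))
        assert st.residual_force_N == pytest.approx(recomputed, abs=1e-12)

    def test_anterior_pulling_strand_shifts_equilibrium_anteriorly(
            self, surface, params):
        app0 = empty_apparatus(surface)
        base = solve_equilibrium_step((0.0, 0.0), JCSLoad(is_force_N=-500.0),
                                      app0, surface, params)
        # stiff strand pulling the tibia anteriorly
        strand = LigamentStrand(
            name="anterior_pull", group="capsular",
            origin_mm=np.array([0.0, 40.0, 0.0]),
            insertion_mm=np.array([0.0, 10.0, -5.0]),
            stiffness_N_per_strain=8000.0, reference_strain=0.05)
        app1 = set_reference_pose(
            LigamentApparatus((strand,), LigamentLawParams()),
            neutral_reference_pose(surface))
        pulled = solve_equilibrium_step((0.0, 0.0),
                                        JCSLoad(is_force_N=-500.0),
                                        app1, surface, params)
        assert pulled.coords.ap_mm > base.coords.ap_mm

    def test_nonconvergence_is_flagged_not_raised(self, surface, apparatus):
        from kneetwin.twin import SolverSettings
        st = solve_equilibrium_step(
            (0.0, 0.0), JCSLoad(is_force_N=-1000.0), apparatus, surface,
            ContactParams(stiffness=5000.0),
            settings=SolverSettings(max_iterations=1))
        assert isinstance(st.converged, bool)


@pytest.fixture(scope="module")
def squat_run(surface, params, apparatus):
    track = periodise(generate_load_case("squat", 48, seed=0))
    return track, run_load_case(track, apparatus, surface, params, cycles=2)


class TestRunLoadCase:
    def test_all_steps_converge_and_cycle_periodicity(self, squat_run):
        _, res = squat_run
        assert not res.failed
        assert res.fraction_converged == 1.0
        assert res.cycle_pose_change < 1e-6

    def test_constant_targets_match_single_step(self, surface, params,
                                                apparatus):
        n = 34
        t = np.arange(n) * 0.05
        channels = {c: np.zeros(n) for c in CHANNELS}
        channels["fe_deg"][:] = 20.0
        channels["is_N"][:] = -600.0
        track = LoadCaseTrack("squat", t, channels, 1.0)
        res = run_load_case(track, apparatus, surface, params, cycles=1)
        single = solve_equilibrium_step((20.0, 0.0),
                                        JCSLoad(is_force_N=-600.0),
                                        apparatus, surface, params)
        for st in res.steps[1:]:
            assert np.allclose(st.coords.as_array(),
                               single.coords.as_array(), atol=1e-7)

    def test_deterministic_bitwise(self, surface, params, apparatus):
        track = periodise(generate_load_case("level_walking", 40, seed=1))
        a = run_load_case(track, apparatus, surface, params, cycles=1)
        b = run_load_case(track, apparatus, surface, params, cycles=1)
        assert np.array_equal(a.coords_array(), b.coords_array())

    def test_non_periodised_track_refused(self, surface, params, apparatus):
        track = generate_load_case("squat", 40, seed=0)
        with pytest.raises(ValueError, match="periodise"):
            run_load_case(track, apparatus, surface, params)


class TestMeanAxialLoad:
    def make_track(self, t, is_n):
        channels = {c: np.zeros_like(t) for c in CHANNELS}
        channels["is_N"] = is_n
        return LoadCaseTrack("squat", t, channels, 1.0)

    def test_constant(self):
        t = np.linspace(0.0, 1.0, 101)
        assert mean_axial_load(self.make_track(t, np.full(101, -1000.0))) == \
            pytest.approx(-1000.0)

    def test_sinusoid_over_full_period_averages_out(self):
        t = np.linspace(0.0, 2.0, 401)  # two full periods of sin(2πt)
        y = -1000.0 + 500.0 * np.sin(2 * np.pi * t)
        assert mean_axial_load(self.make_track(t, y)) == pytest.approx(
            -1000.0, abs=1e-9)

    def test_piecewise_linear_hump_matches_analytic_integral(self):
        t = np.linspace(0.0, 1.0, 501)
        y = np.interp(t, [0.0, 0.25, 0.5, 1.0], [0.0, -400.0, 0.0, 0.0])
        # triangle area: ½·base·height / duration = ½·0.5·(−400) = −100
        assert mean_axial_load(self.make_track(t, y)) == pytest.approx(
            -100.0, abs=1e-9)


class TestComplianceCompensation:
    def test_zero_compliance_is_plain_referencing(self, surface, apparatus):
        track = periodise(generate_load_case("squat", 48, seed=0))
        nominal = neutral_reference_pose(surface)
        from kneetwin.synthetic import default_apparatus
        raw = default_apparatus(seed=0)
        a = apply_compliance_compensation(raw, track, MachineCompliance(0.0),
                                          nominal)
        b = set_reference_pose(raw, nominal)
        for sa, sb in zip(a.strands, b.strands):
            assert sa.reference_length_mm == sb.reference_length_mm

    def test_sag_shifts_reference_lengths_consistently(self, surface):
        from kneetwin.synthetic import default_apparatus
        track = periodise(generate_load_case("squat", 48, seed=0))
        nominal = neutral_reference_pose(surface)
        raw = default_apparatus(seed=0)
        c = 1e-4  # mm per N
        comp = apply_compliance_compensation(raw, track,
                                             MachineCompliance(c), nominal)
        f_mean = mean_axial_load(track)
        shifted = pose_from_jcs(JCSCoordinates(is_mm=-25.0 + c * f_mean))
        expected = set_reference_pose(raw, shifted)
        for sa, sb in zip(comp.strands, expected.strands):
            assert sa.reference_length_mm == pytest.approx(
                sb.reference_length_mm, abs=1e-9)

    def test_depends_only_on_mean_load(self, surface):
        from kneetwin.synthetic import default_apparatus
        nominal = neutral_reference_pose(surface)
        raw = default_apparatus(seed=0)
        n = 64
        t = np.arange(n) * 0.01
        base = {c: np.zeros(n) for c in CHANNELS}
        base["is_N"] = np.full(n, -900.0)
        tr1 = LoadCaseTrack("squat", t, base, 1.0)
        wob = dict(base)
        # full sinusoid period over [t0, t_end]: trapezoid mean vanishes
        wob["is_N"] = -900.0 + 200.0 * np.sin(
            2 * np.pi * np.arange(n) / (n - 1))
        tr2 = LoadCaseTrack("squat", t, wob, 1.0)
        c = MachineCompliance(5e-5)
        a = apply_compliance_compensation(raw, tr1, c, nominal)
        b = apply_compliance_compensation(raw, tr2, c, nominal)
        for sa, sb in zip(a.strands, b.strands):
            assert sa.reference_length_mm == pytest.approx(
                sb.reference_length_mm, abs=1e-6)


class TestFlexionBinnedComparison:
    def test_self_comparison_is_zero(self, surface, params, apparatus):
        track = periodise(generate_load_case("squat", 40, seed=2))
        res = run_load_case(track, apparatus, surface, params, cycles=1)
        table = flexion_binned_comparison(res, res, 10.0)
        assert np.allclose(table["d_ap_mm"], 0.0)
        assert np.allclose(table["d_adduction_deg"], 0.0)

    def test_monotone_ramp_flexion_phase_dominates(self, surface, params,
                                                   apparatus):
        n = 34
        t = np.arange(n) * 0.05
        channels = {c: np.zeros(n) for c in CHANNELS}
        channels["fe_deg"] = np.linspace(0.0, 60.0, n)
        channels["fe_deg"][-1] = 0.0  # wrap sample for periodicity
        channels["is_N"][:] = -500.0
        track = LoadCaseTrack("squat", t, channels, 1.0)
        res = run_load_case(track, apparatus, surface, params, cycles=1)
        table = flexion_binned_comparison(res, res, 10.0)
        flex_bins = table[table["phase"] == "flexion"]
        ext_bins = table[table["phase"] == "extension"]
        assert len(flex_bins) > len(ext_bins)

    def test_mismatched_tracks_rejected(self, surface, params, apparatus):
        t1 = periodise(generate_load_case("squat", 40, seed=2))
        t2 = periodise(generate_load_case("squat", 48, seed=2))
        r1 = run_load_case(t1, apparatus, surface, params, cycles=1)
        r2 = run_load_case(t2, apparatus, surface, params, cycles=1)
        with pytest.raises(ValueError, match="different tracks"):
            flexion_binned_comparison(r1, r2)


class TestLigamentCompressionOpposition:
    def test_pcl_resection_lowers_superior_ligament_pull_in_deep_flexion(
            self, surface, apparatus):
        """At matched deep-flexion kinematics the PCL pulls the tibia
        superiorly (opposing compression); resecting it removes that
        contribution."""
        from kneetwin.ligament import apparatus_wrench, resect_group
        pose = pose_from_jcs(JCSCoordinates(flexion_deg=50.0, is_mm=-25.0))
        intact = apparatus_wrench(apparatus, pose)
        resected = apparatus_wrench(resect_group(apparatus, "PCL"), pose)
        assert intact.force_N[2] > resected.force_N[2]
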