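"""Kinetic simulator: ODE bounds, treatment limits, instrument emulation."""

import dataclasses
from dataclasses import replace

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from ojipkit.features import FeatureConfig, extract_features
from ojipkit.petc import (
    CYANO_PARAMS,
    DEFAULT_PARAMS,
    PFD_REF,
    PROFILES,
    CalibrationError,
    KineticParams,
    TreatmentSpec,
    calibrate_defaults,
    dark_steady_state,
    dcmu_block_from_concentration,
    detected_amplitude,
    emulate_acquisition,
    excitation_attenuation,
    make_grid_dataset,
    make_timecourse_dataset,
    measure_landmarks,
    simulate_trajectory,
    simulate_transient,
)
from ojipkit.transients import AcquisitionMeta, OJIPTransient, SampleOptics


class TestTrajectory:
    def test_no_light_keeps_states_constant(self):
        traj = simulate_trajectory(DEFAULT_PARAMS, TreatmentSpec(), sp_pfd=0.0,
                                   duration_s=0.5)
        t = np.linspace(0.0, 0.5, 20)
        states = traj.state(t)
        np.testing.assert_allclose(states, states[:, :1] * np.ones((1, 20)),
                                   atol=1e-6)
        f = traj.fluorescence_rel(t * 1e3)
        np.testing.assert_allclose(f, DEFAULT_PARAMS.F0_rel, atol=1e-4)

    def test_dcmu_closes_all_centers_monotonically(self):
        traj = simulate_trajectory(DEFAULT_PARAMS, TreatmentSpec(dcmu_block=1.0),
                                   PFD_REF)
        t = np.geomspace(1e-5, 0.6, 400)
        a = traj.state(t)[0]
        assert np.all(np.diff(a) >= -1e-7)
        # saturates at k_L / (k_L + k_rec), i.e. essentially full closure
        assert a[-1] > 0.99

    def test_dcmu_ideal_curve_vj_is_one(self):
        """V_J extracted from the ideal (instrument-free) DCMU curve is 1:
        the fluorescence maximum is reached already at the J step."""
        traj = simulate_trajectory(DEFAULT_PARAMS, TreatmentSpec(dcmu_block=1.0),
                                   PFD_REF)
        t = np.arange(-10.0, 640.0, 0.01)
        tr = OJIPTransient(
            t, traj.fluorescence_rel(t) * 1000.0,
            meta=AcquisitionMeta(detector_max=1e9),
        )
        feats = extract_features(tr, FeatureConfig())
        assert feats.VJ == pytest.approx(1.0, abs=0.01)

    def test_vj_of_ideal_trace_monotone_in_dcmu_block(self):
        vjs = []
        for block in [0.0, 0.5, 0.9, 1.0]:
            traj = simulate_trajectory(DEFAULT_PARAMS,
                                       TreatmentSpec(dcmu_block=block), PFD_REF)
            fm, _ = traj.ideal_maximum()
            f0 = traj.fluorescence_rel(-1.0)
            vjs.append((traj.fluorescence_rel(2.0) - f0) / (fm - f0))
        assert np.all(np.diff(vjs) > 0)

    def test_ga_run_fully_reduces_pool(self):
        params = replace(DEFAULT_PARAMS, k_TO=0.0, k_NDH=0.0)
        treatment = TreatmentSpec(ga_block=True, al_pfd=100.0, al_duration=300.0)
        traj = simulate_trajectory(params, treatment, PFD_REF)
        assert traj.y0[2] > 0.99  # PQ pool reduced at SP onset

    def test_larger_pool_fills_later(self):
        """Time for the pool to reach half reduction grows with pool size."""
        t_half = []
        for n_pq in [2.0, 4.0, 8.0]:
            params = replace(DEFAULT_PARAMS, n_PQ=n_pq, k_TO=0.0, k_NDH=0.0)
            traj = simulate_trajectory(params, TreatmentSpec(ga_block=True), PFD_REF)
            t = np.geomspace(1e-5, 0.6, 4000)
            p = traj.state(t)[2]
            t_half.append(t[np.searchsorted(p > 0.5, True)])
        assert t_half[0] < t_half[1] < t_half[2]

    def test_cyano_mode_raises_dark_pool_reduction_and_f0(self):
        y_alga = dark_steady_state(DEFAULT_PARAMS, TreatmentSpec())
        y_cyano = dark_steady_state(CYANO_PARAMS, TreatmentSpec())
        assert y_cyano[2] > y_alga[2] + 0.1
        tr_a, _ = simulate_transient(DEFAULT_PARAMS)
        tr_c, _ = simulate_transient(CYANO_PARAMS)
        f0_a = extract_features(tr_a).F0
        f0_c = extract_features(tr_c).F0
        assert f0_c > f0_a

    def test_high_light_acclimation_compresses_vjprime_range(self):
        """Pre-reduced Q_A narrows the V_J' spread across pool perturbations."""

        def spread(al_pfd):
            vals = []
            for treat in (TreatmentSpec(), TreatmentSpec(ga_block=True),
                          TreatmentSpec(mv_bypass=True)):
                tr, _ = simulate_transient(
                    DEFAULT_PARAMS,
                    replace(treat, al_pfd=al_pfd, al_duration=120.0),
                )
                f = extract_features(tr, FeatureConfig(mode="light"))
                assert f.VJ is not None
                vals.append(f.VJ)
            return max(vals) - min(vals)

        assert spread(1500.0) < spread(25.0)


@st.composite
def valid_params(draw):
    return KineticParams(
        k_L_ref=draw(st.floats(200.0, 5000.0)),
        k_AB=draw(st.floats(500.0, 10000.0)),
        k_ex=draw(st.floats(100.0, 5000.0)),
        k_b6f=draw(st.floats(10.0, 2000.0)),
        k_FNR=draw(st.floats(10.0, 3000.0)),
        n_D=draw(st.floats(5.0, 150.0)),
        k_TO=draw(st.floats(0.0, 30.0)),
        k_NDH=draw(st.floats(0.0, 30.0)),
        k_rec=draw(st.floats(0.0, 5.0)),
        n_PQ=draw(st.floats(1.0, 20.0)),
        tau_FNR=draw(st.floats(0.05, 5.0)),
        s_dark=draw(st.floats(0.0, 0.3)),
        p_conn=draw(st.floats(0.0, 0.8)),
    )


@st.composite
def valid_treatments(draw):
    return TreatmentSpec(
        dcmu_block=draw(st.floats(0.0, 1.0)),
        ga_block=draw(st.booleans()),
        kcn_block=draw(st.booleans()),
        mv_bypass=draw(st.booleans()),
        al_pfd=draw(st.sampled_from([0.0, 25.0, 100.0, 1500.0])),
        al_duration=draw(st.sampled_from([0.0, 5.0, 60.0])),
        quench_mult=draw(st.floats(0.5, 1.0)),
    )


class TestStateBounds:
    @given(params=valid_params(), treatment=valid_treatments(),
           sp=st.floats(0.0, 8000.0))
    @settings(derandomize=True, max_examples=25, deadline=None)
    def test_bounds_conserved_for_random_valid_inputs(self, params, treatment, sp):
        """a, p, d, s in [0,1] and e_B in [0,2] at all output times."""
        traj = simulate_trajectory(params, treatment, sp, duration_s=0.64)
        t = np.geomspace(1e-6, 0.64, 300)
        raw = traj._sol.sol(t)  # un-clipped solver output
        lo = np.array([0.0, 0.0, 0.0, 0.0, 0.0]) - 1e-6
        hi = np.array([1.0, 2.0, 1.0, 1.0, 1.0]) + 1e-6
        assert np.all(raw >= lo[:, None]) and np.all(raw <= hi[:, None])
        states = traj.state(t)  # public accessor is exactly in bounds
        assert states.min() >= 0.0
        assert np.all(states[0] <= 1.0) and np.all(states[1] <= 2.0)
        f = traj.fluorescence_rel(t * 1e3)
        assert np.all(f >= params.F0_rel - 1e-9)
        assert np.all(f <= params.FM_rel * treatment.quench_mult + 1e-9)


class TestEmulation:
    def test_pam_like_pulse_window_sample_count(self, pam_profile):
        """100 kHz sampling over the 630 ms pulse plus the trailing partial
        interval yields exactly 63 997 pulse-window samples."""
        assert pam_profile.pulse_times_ms().size == 63997
        traj = simulate_trajectory(DEFAULT_PARAMS, TreatmentSpec(), PFD_REF)
        tr, _ = emulate_acquisition(traj, pam_profile)
        assert int(np.count_nonzero(tr.times >= 0)) == 63997

    def test_pea_profiles_sample_counts(self):
        assert PROFILES["pea-coarse"].pulse_times_ms().size == 63
        assert PROFILES["pea-fine"].pulse_times_ms().size == 827

    def test_identical_seeds_are_bitwise_identical(self, fast_profile):
        noisy = dataclasses.replace(fast_profile, noise_sigma_rel=0.02)
        a, _ = simulate_transient(profile=noisy, seed=123)
        b, _ = simulate_transient(profile=noisy, seed=123)
        assert np.array_equal(a.times, b.times)
        assert np.array_equal(a.fluorescence, b.fluorescence)

    def test_different_seeds_differ(self, fast_profile):
        noisy = dataclasses.replace(fast_profile, noise_sigma_rel=0.02)
        a, _ = simulate_transient(profile=noisy, seed=1)
        b, _ = simulate_transient(profile=noisy, seed=2)
        assert not np.array_equal(a.fluorescence, b.fluorescence)

    def test_overdriven_amplitude_clips_and_flags_saturation(self, fast_profile):
        hot = dataclasses.replace(fast_profile, adu_scale=1e5, detector_max=4095.0)
        tr, _ = simulate_transient(profile=hot, seed=0)
        assert np.max(tr.fluorescence) == 4095.0
        feats = extract_features(tr, FeatureConfig())
        assert feats.qc.saturated and feats.qc.excluded

    def test_truth_sidecar_reports_onset_state_and_scaling(self, fast_profile):
        tr, truth = simulate_transient(profile=fast_profile, seed=0)
        assert truth["state_at_onset"]["a"] == pytest.approx(0.0, abs=1e-6)
        assert truth["FM_adu"] > truth["F0_adu"] > 0
        assert 200.0 <= truth["tP_ms"] <= 300.0

    def test_optics_scaling_factors(self):
        assert excitation_attenuation(SampleOptics(chl_conc=0.0)) == 1.0
        g = excitation_attenuation(SampleOptics(chl_conc=10.0))
        assert 0.0 < g < 1.0
        # detected amplitude rises then falls with density
        dens = [0.1, 1.0, 4.0, 16.0, 30.0]
        amps = [detected_amplitude(SampleOptics(chl_conc=c)) for c in dens]
        peak = int(np.argmax(amps))
        assert 0 < peak < len(dens) - 1

    def test_dcmu_binding_fraction(self):
        assert dcmu_block_from_concentration(0.0) == 0.0
        assert dcmu_block_from_concentration(0.1) > 0.98
        assert dcmu_block_from_concentration(1e-3) == pytest.approx(0.5)


class TestDatasets:
    def test_grid_cardinality_and_metadata(self, fast_profile):
        trs = make_grid_dataset([1000.0, 2000.0, 4000.0], [0.2, 0.5, 1.0],
                                profile=fast_profile, seed=0)
        assert len(trs) == 9
        coords = {(t.meta.sp_intensity, t.sample.chl_conc) for t in trs}
        assert len(coords) == 9

    def test_timecourse_counts_and_noiseless_replicates(self, fast_profile):
        groups = make_timecourse_dataset(
            treatment=TreatmentSpec(al_pfd=100.0), profile=fast_profile,
            interval_s=30.0, duration_s=300.0, n_replicates=4, seed=0,
        )
        assert len(groups) == 11
        assert sum(len(reps) for _, reps in groups) == 44
        _, reps = groups[3]
        for other in reps[1:]:
            np.testing.assert_array_equal(reps[0].fluorescence, other.fluorescence)


class TestCalibration:
    def test_shipped_defaults_hit_landmark_targets(self):
        lm = measure_landmarks(DEFAULT_PARAMS)
        assert 1.5 <= lm["t_J"] <= 2.5
        assert 22.0 <= lm["t_I"] <= 38.0
        assert 200.0 <= lm["t_P"] <= 300.0

    def test_calibrate_accepts_defaults_without_search(self):
        result = calibrate_defaults(base=DEFAULT_PARAMS, grid_factors=(1.0,),
                                    polish=False)
        lm = measure_landmarks(result)
        assert 1.5 <= lm["t_J"] <= 2.5 and 22.0 <= lm["t_I"] <= 38.0

    def test_calibrate_rejects_hopeless_base(self):
        broken = replace(DEFAULT_PARAMS, k_L_ref=5.0, k_AB=5.0, k_ex=5.0)
        with pytest.raises(CalibrationError):
            calibrate_defaults(base=broken, grid_factors=(1.0,), polish=False)
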