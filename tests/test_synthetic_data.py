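"""Simulator fidelity: trajectories, rendering, CRC studies, jump responses."""

import math

import numpy as np
import pytest

from glyflip import (AcquisitionConfig, FlipMechanism, JumpProtocol,
                     build_generator, equilibrium_distribution,
                     max_popen_from_efficacy, render_current,
                     sample_trajectory, simulate_cluster_recording,
                     simulate_crc_study, simulate_jump_response)
from glyflip.concentration_response import hill
from glyflip.idealization import CLASS_OPEN, DwellSequence, segment_clusters
from glyflip.mechanism import CLASS_SHUT, GeneratorMatrix
from glyflip.synthetic_data import _concentration_profile, propagate_constant


class TestSampleTrajectory:
    def test_mean_open_dwell_is_inverse_close_rate(self, two_state_generator):
        Q, alpha, _ = two_state_generator
        dwells = sample_trajectory(Q, 300.0, seed=7)
        open_durs = dwells.durations[dwells.classes == CLASS_OPEN][:-1]
        assert open_durs.size > 1e4
        se = open_durs.std(ddof=1) / math.sqrt(open_durs.size)
        assert open_durs.mean() == pytest.approx(1.0 / alpha, abs=3 * se)

    def test_seed_determinism(self, two_state_generator):
        Q, _, _ = two_state_generator
        d1 = sample_trajectory(Q, 5.0, seed=11)
        d2 = sample_trajectory(Q, 5.0, seed=11)
        assert np.array_equal(d1.durations, d2.durations)
        assert np.array_equal(d1.classes, d2.classes)
        d3 = sample_trajectory(Q, 5.0, seed=12)
        assert not np.array_equal(d1.durations, d3.durations)

    def test_total_duration_is_t_max(self, two_state_generator):
        Q, _, _ = two_state_generator
        d = sample_trajectory(Q, 3.7, seed=1)
        assert d.total_duration == pytest.approx(3.7, abs=1e-12)

    def test_open_fraction_matches_equilibrium(self, saturated_core_acidic):
        Q = saturated_core_acidic
        p_eq = float(equilibrium_distribution(Q)[Q.open_states].sum())
        d = sample_trajectory(Q, 30.0, seed=3)
        n_cycles = (d.classes == CLASS_OPEN).sum()
        se = 2 * p_eq * (1 - p_eq) / math.sqrt(n_cycles)
        assert d.open_fraction == pytest.approx(p_eq, abs=3 * se)

    def test_absorbing_state_flagged(self):
        q = np.array([[-1.0, 1.0], [0.0, 0.0]])
        Q = GeneratorMatrix(rates=q, state_classes=[CLASS_SHUT, CLASS_OPEN])
        with pytest.raises(ValueError, match="absorbing"):
            sample_trajectory(Q, 1.0, seed=0)


class TestRenderCurrent:
    def test_plateau_amplitude(self):
        acq = AcquisitionConfig(sample_rate=100e3, filter_corner=3e3,
                                resample_rate=None, noise_sd=0.0,
                                single_channel_current=7.0)
        dwells = DwellSequence(np.array([0.05, 0.1, 0.05]),
                               np.array([CLASS_SHUT, CLASS_OPEN, CLASS_SHUT],
                                        dtype=object))
        trace = render_current(dwells, acq)
        mid = trace.current[int(0.09 * 100e3):int(0.11 * 100e3)]
        assert mid == pytest.approx(7.0, rel=1e-3)

    def test_no_filter_no_noise_two_levels(self):
        acq = AcquisitionConfig(sample_rate=100e3, filter_corner=None,
                                resample_rate=None, noise_sd=0.0,
                                single_channel_current=5.0)
        dwells = DwellSequence(np.array([0.01, 0.01, 0.01]),
                               np.array([CLASS_SHUT, CLASS_OPEN, CLASS_SHUT],
                                        dtype=object))
        trace = render_current(dwells, acq)
        # samples sit at 0 or the open level (boundaries are grid-aligned)
        x = trace.current
        assert np.all(np.isclose(x, 0.0, atol=1e-9) | np.isclose(x, 5.0, atol=1e-9))
        assert np.isclose(x, 5.0, atol=1e-9).any()

    def test_filter_rise_time(self):
        """Step-response rise time of the Gaussian filter.

        Numeric integration of the Gaussian impulse response gives an
        exact 10-90% rise of 2*1.2816*sigma = 0.3396/fc; the field's
        conventional constant 0.3321/fc (the maximum-slope rise time)
        approximates it to ~2.3%.
        """
        fc = 3e3
        fs = 200e3
        acq = AcquisitionConfig(sample_rate=fs, filter_corner=fc,
                                resample_rate=None, noise_sd=0.0,
                                single_channel_current=1.0)
        dwells = DwellSequence(np.array([0.01, 0.01]),
                               np.array([CLASS_SHUT, CLASS_OPEN], dtype=object))
        trace = render_current(dwells, acq)
        seg = (trace.times > 0.0095) & (trace.times < 0.0115)
        x, t = trace.current[seg], trace.times[seg]
        t10 = np.interp(0.1, x, t)
        t90 = np.interp(0.9, x, t)
        sigma = 0.1325 / fc
        exact = 2 * 1.2815516 * sigma  # from the Gaussian quantile function
        assert (t90 - t10) == pytest.approx(exact, rel=0.01)
        assert (t90 - t10) == pytest.approx(0.3321 / fc, rel=0.03)

    def test_noise_sd(self):
        acq = AcquisitionConfig(sample_rate=50e3, filter_corner=3e3,
                                resample_rate=None, noise_sd=2.5,
                                single_channel_current=7.0)
        dwells = DwellSequence(np.array([2.0]), np.array([CLASS_SHUT], dtype=object))
        trace = render_current(dwells, acq, seed=0)
        assert trace.current.std() == pytest.approx(2.5, rel=0.05)

    def test_subsample_dwell_attenuated_not_dropped(self):
        acq = AcquisitionConfig(sample_rate=10e3, filter_corner=None,
                                resample_rate=None, noise_sd=0.0,
                                single_channel_current=10.0)
        # 20 us opening at a 100 us sample interval
        dwells = DwellSequence(np.array([0.01, 20e-6, 0.01]),
                               np.array([CLASS_SHUT, CLASS_OPEN, CLASS_SHUT],
                                        dtype=object))
        trace = render_current(dwells, acq)
        assert trace.current.max() == pytest.approx(10.0 * 0.2, rel=1e-6)


class TestClusterRecording:
    def test_ground_truth_popen_matches_closed_form(self, slow_cluster_mechanism,
                                                    cell_attached_acquisition):
        _, truth = simulate_cluster_recording(
            slow_cluster_mechanism, math.inf, 30,
            cell_attached_acquisition, seed=21)
        clusters = segment_clusters(truth)
        popens = np.array([c.popen for c in clusters])
        expected = slow_cluster_mechanism.max_popen
        se = popens.std(ddof=1) / math.sqrt(popens.size)
        assert popens.mean() == pytest.approx(expected, abs=3 * se)

    def test_cluster_rules_satisfied(self, slow_cluster_mechanism,
                                     cell_attached_acquisition):
        _, truth = simulate_cluster_recording(
            slow_cluster_mechanism, math.inf, 5,
            cell_attached_acquisition, seed=2)
        clusters = segment_clusters(truth, keep_censored=False)
        assert len(clusters) >= 5
        assert all(c.duration >= 0.100 for c in clusters)

    def test_zero_clusters_gives_baseline_noise(self, slow_cluster_mechanism,
                                                cell_attached_acquisition):
        trace, _ = simulate_cluster_recording(
            slow_cluster_mechanism, math.inf, 0,
            cell_attached_acquisition, seed=2)
        assert abs(trace.current.mean()) < 0.5
        assert trace.current.std() == pytest.approx(
            cell_attached_acquisition.noise_sd, rel=0.1)

    def test_requires_desensitization(self, cell_attached_acquisition):
        mech = FlipMechanism.from_equilibrium(E=15.0, F=8.0)
        with pytest.raises(ValueError, match="desensitisation"):
            simulate_cluster_recording(mech, math.inf, 5,
                                       cell_attached_acquisition, seed=0)


class TestCRCStudy:
    def test_noiseless_responses_on_hill_curve(self):
        concs = np.geomspace(20e-6, 10e-3, 8)
        study = simulate_crc_study(8.6, 190e-6, 1.9, concs, 3,
                                   cell_cv=0.0, noise_cv=0.0, seed=0)
        for cell in study.cells:
            expected = hill(cell.concentrations, 8.6, 190e-6, 1.9)
            np.testing.assert_allclose(cell.peak_responses, expected, rtol=1e-12)
            assert cell.reference_saturating_response == pytest.approx(8.6)

    def test_midpoint_response(self):
        study = simulate_crc_study(10.0, 1e-4, 1.5,
                                   [1e-5, 3e-5, 1e-4, 1e-3], 1,
                                   cell_cv=0.0, noise_cv=0.0, seed=0)
        cell = study.cells[0]
        assert cell.peak_responses[2] == pytest.approx(5.0)

    def test_cell_scatter_preserves_mean(self):
        study = simulate_crc_study(8.6, 190e-6, 1.9,
                                   np.geomspace(2e-5, 1e-2, 6), 400,
                                   cell_cv=0.25, noise_cv=0.0, seed=4)
        refs = [c.reference_saturating_response for c in study.cells]
        assert np.mean(refs) == pytest.approx(8.6, rel=0.05)

    def test_seed_determinism(self):
        kw = dict(true_imax=8.6, true_ec50=190e-6, true_nh=1.9,
                  concentrations=np.geomspace(2e-5, 1e-2, 6), n_cells=4,
                  cell_cv=0.2, noise_cv=0.1)
        s1 = simulate_crc_study(**kw, seed=9)
        s2 = simulate_crc_study(**kw, seed=9)
        for c1, c2 in zip(s1.cells, s2.cells):
            np.testing.assert_array_equal(c1.peak_responses, c2.peak_responses)


class TestJumpResponse:
    ACQ = AcquisitionConfig(sample_rate=100e3, filter_corner=None,
                            resample_rate=None, noise_sd=0.0,
                            single_channel_current=-5.0)

    def test_zero_concentration_is_flat(self, reference_mechanism):
        proto = JumpProtocol(pulse_concentration=0.0, duration=0.02)
        trace = simulate_jump_response(reference_mechanism, proto, self.ACQ)
        assert np.abs(trace.current).max() == 0.0

    def test_switch_has_exact_2080_time(self):
        proto = JumpProtocol(exchange_time_2080=150e-6)
        t = np.linspace(0, proto.onset + proto.pulse_duration, 400000)
        c = _concentration_profile(t, proto) / proto.pulse_concentration
        t20 = np.interp(0.2, c, t)
        t80 = np.interp(0.8, c, t)
        assert (t80 - t20) == pytest.approx(150e-6, rel=1e-3)

    def test_two_state_relaxation_closed_form(self, two_state_generator):
        """Piecewise-exponential propagation is exact for a constant
        generator: occupancy relaxes with rate alpha+beta."""
        Q, alpha, beta = two_state_generator
        p_inf = beta / (alpha + beta)
        for t in (1e-3, 5e-3, 2e-2):
            p = propagate_constant(Q, np.array([1.0, 0.0]), t)
            expected = p_inf * (1.0 - math.exp(-(alpha + beta) * t))
            assert p[1] == pytest.approx(expected, rel=1e-6)

    def test_long_saturating_pulse_plateau(self):
        mech = FlipMechanism.from_equilibrium(E=15.0, F=8.0)
        proto = JumpProtocol(pulse_concentration=10.0, pulse_duration=60e-3,
                             duration=80e-3, onset=1e-3)
        trace = simulate_jump_response(mech, proto, self.ACQ)
        popen = trace.current / (proto.n_channels * self.ACQ.single_channel_current)
        plateau = popen[int(50e-3 * 100e3):int(58e-3 * 100e3)].mean()
        assert plateau == pytest.approx(
            max_popen_from_efficacy(mech.E_eff), abs=1e-4)

    def test_peak_bounded_by_channel_count(self, reference_mechanism):
        proto = JumpProtocol(duration=0.05)
        trace = simulate_jump_response(reference_mechanism, proto, self.ACQ)
        assert np.abs(trace.current).max() <= \
            proto.n_channels * abs(self.ACQ.single_channel_current) * (1 + 1e-12)

    def test_deterministic_without_noise(self, reference_mechanism):
        proto = JumpProtocol(duration=0.03)
        t1 = simulate_jump_response(reference_mechanism, proto, self.ACQ)
        t2 = simulate_jump_response(reference_mechanism, proto, self.ACQ)
        np.testing.assert_array_equal(t1.current, t2.current)
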