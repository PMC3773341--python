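"""Generator tests: gating statistics, current synthesis, placement, Fura-2."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from bkcav import sim_channels as sim
from bkcav.sim_channels import (CouplingParams, GatingParamsBK, GatingParamsT,
                                Fura2Calibration, VoltageProtocol,
                                bk_stationary_po, bk_v_half, simulate_cav32,
                                simulate_fura2, simulate_gating,
                                step_protocol, synthesize_current,
                                t_gate_steady_state, unitary_current)

from _helpers import FAST_BK


class TestVoltageProtocol:
    def test_voltage_samples_follow_segments(self):
        p = VoltageProtocol(((-80.0, 1.0), (20.0, 2.0)), 0.5)
        assert p.n_samples == 6
        np.testing.assert_array_equal(p.voltages(),
                                      [-80, -80, 20, 20, 20, 20])

    @pytest.mark.parametrize("segments,dt", [
        ((), 0.1), (((0.0, -1.0),), 0.1), (((0.0, 1.0),), 0.0)])
    def test_invalid_protocols_rejected(self, segments, dt):
        with pytest.raises(ValueError):
            VoltageProtocol(segments, dt)


class TestSimulateGating:
    def test_empty_patch_is_silent(self):
        out = simulate_gating(GatingParamsBK(), step_protocol(-80, 20), 10.0,
                              0, seed=1)
        assert out.counts.sum() == 0

    def test_negative_calcium_rejected(self):
        with pytest.raises(ValueError):
            simulate_gating(GatingParamsBK(), step_protocol(-80, 20), -5.0,
                            1, seed=1)

    def test_seeded_runs_bit_reproducible(self):
        proto = step_protocol(-80, 20, duration=50)
        a = simulate_gating(FAST_BK, proto, 100.0, 3, seed=7)
        b = simulate_gating(FAST_BK, proto, 100.0, 3, seed=7)
        np.testing.assert_array_equal(a.counts, b.counts)
        c = simulate_gating(FAST_BK, proto, 100.0, 3, seed=8)
        assert not np.array_equal(a.counts, c.counts)

    @pytest.mark.parametrize("v,ca", [(0.0, 100.0), (20.0, 10.0),
                                      (-20.0, 1000.0)])
    def test_time_average_matches_stationary_closed_form(self, v, ca):
        """Monte-Carlo open fraction vs alpha/(alpha+beta), 3-sigma band."""
        proto = VoltageProtocol(((v, 2000.0),), 0.5)
        n_ch = 64
        out = simulate_gating(FAST_BK, proto, ca, n_ch, seed=11)
        p = float(bk_stationary_po(FAST_BK, v, ca))
        a, b = sim.bk_rates(FAST_BK, v, ca)
        tau_corr = 1.0 / float(a + b)
        n_eff = n_ch * proto.total_duration / (2.0 * tau_corr)
        se = np.sqrt(p * (1 - p) / n_eff)
        assert abs(out.open_fraction - p) < 3 * se + 1e-12

    def test_calibration_low_ca_activation_range(self):
        """Quiet at -20 mV, mostly open at +60 mV with ~10 nM Ca2+."""
        bk = GatingParamsBK()
        for v, lo, hi in ((-20.0, 0.0, 0.05), (60.0, 0.5, 1.0)):
            proto = VoltageProtocol(((-80.0, 20.0), (v, 500.0)), 0.1)
            out = simulate_gating(bk, proto, 10.0, 32, seed=3)
            frac = out.counts[200:].mean() / 32
            assert lo <= frac <= hi

    def test_calcium_shift_is_exact_on_vhalf_and_recovered_by_fit(self):
        """10 -> 400 nM shifts Vh by ca_shift*log10(40), also in a fit."""
        bk = FAST_BK
        expected = bk.ca_shift_per_decade * np.log10(40.0)
        assert np.isclose(float(bk_v_half(bk, 10.0) - bk_v_half(bk, 400.0)),
                          expected)
        from bkcav.iv_analysis import IVCurve, gv_boltzmann
        fitted = {}
        for ca, seed in ((10.0, 21), (400.0, 22)):
            vh_true = float(bk_v_half(bk, ca))
            vgrid = np.arange(vh_true - 40, vh_true + 41, 8.0)
            g = []
            for v in vgrid:
                proto = VoltageProtocol(((float(v), 600.0),), 0.5)
                out = simulate_gating(bk, proto, ca, 64, seed=seed)
                g.append(out.counts.mean() / 64)
            # treat open fraction as G/Gmax with a unit driving force
            iv = IVCurve(vgrid, np.asarray(g) * 1.0, np.full(vgrid.size, 64),
                         np.zeros(vgrid.size))
            fit = gv_boltzmann(IVCurve(vgrid, np.asarray(g) * (vgrid - (-200)),
                                       np.full(vgrid.size, 64),
                                       np.zeros(vgrid.size)), e_rev=-200.0)
            fitted[ca] = fit["v_half"]
            assert abs(fit["v_half"] - vh_true) < 3.0
        assert abs((fitted[10.0] - fitted[400.0]) - expected) < 3.0


class TestSynthesizeCurrent:
    def test_silent_noiseless_trace_is_zero(self):
        proto = step_protocol(-80, 20, duration=10)
        ser = sim.OpenCountSeries(proto.sampling_interval,
                                  np.zeros(proto.n_samples, int), 1)
        tr = synthesize_current(ser, 186.0, 0.0, proto, 0.0)
        assert np.all(tr.samples == 0)

    def test_unitary_current_at_50mv_is_9_3_pa(self):
        proto = VoltageProtocol(((50.0, 1.0),), 0.5)
        ser = sim.OpenCountSeries(0.5, np.ones(2, int), 1)
        tr = synthesize_current(ser, 186.0, 0.0, proto, 0.0)
        np.testing.assert_allclose(tr.samples, 9.3)

    def test_no_driving_force_at_reversal(self):
        proto = VoltageProtocol(((-80.0, 1.0),), 0.5)
        ser = sim.OpenCountSeries(0.5, np.full(2, 3), 3)
        tr = synthesize_current(ser, 186.0, -80.0, proto, 0.0)
        np.testing.assert_allclose(tr.samples, 0.0)

    def test_length_mismatch_rejected(self):
        ser = sim.OpenCountSeries(0.5, np.ones(5, int), 1)
        with pytest.raises(ValueError):
            synthesize_current(ser, 186.0, 0.0,
                               VoltageProtocol(((0.0, 1.0),), 0.5), 0.0)


class TestCav32:
    def test_inactivated_holding_abolishes_transient(self):
        """Peak current from HP -40 is < 5% of the peak from HP -80."""
        t = GatingParamsT()
        peaks = {}
        for hp in (-80.0, -40.0):
            proto = step_protocol(hp, -20.0, pre=20, duration=200, dt=0.1)
            res = simulate_cav32(t, proto, "macroscopic")
            peaks[hp] = np.abs(res.trace.samples[200:]).max()
        assert peaks[-40.0] < 0.05 * peaks[-80.0]

    def test_transient_decays_toward_zero(self):
        proto = step_protocol(-80.0, -20.0, pre=20, duration=300, dt=0.1)
        res = simulate_cav32(GatingParamsT(), proto, "macroscopic")
        i = res.trace.samples
        peak_idx = np.argmin(i)
        assert i[peak_idx] < 0                       # inward
        assert abs(i[-1]) < 0.05 * abs(i[peak_idx])  # decayed

    def test_default_availability_fully_inactivated_at_minus_40(self):
        _, h = t_gate_steady_state(GatingParamsT(), -40.0)
        assert h < 0.05

    def test_parameter_set_violating_inactivation_rejected(self):
        with pytest.raises(ValueError):
            GatingParamsT(inact_v_half=-40.0, inact_slope=15.0)

    def test_single_channel_unitary_current_about_1_pa(self):
        """7 pS at a 140 mV driving force gives ~1 pA unitary current."""
        assert abs(unitary_current(7.0, -20.0, 120.0)) == pytest.approx(
            0.98, abs=0.01)
        t = GatingParamsT(reversal=120.0)
        proto = step_protocol(-80.0, -20.0, pre=10, duration=150, dt=0.1)
        res = simulate_cav32(t, proto, "single_channel", seed=5, n_channels=6)
        open_mask = res.open_counts.counts > 0
        assert open_mask.any()
        amp = res.trace.samples[open_mask & (res.open_counts.counts == 1)]
        np.testing.assert_allclose(amp, -0.98, atol=0.01)


class TestCoupledPatch:
    def test_no_t_channels_matches_uncoupled_statistics(self):
        bk, c = FAST_BK, CouplingParams(ca_bulk=200.0)
        proto = step_protocol(-80.0, 0.0, duration=400, dt=0.1)
        res = sim.simulate_coupled_patch(bk, GatingParamsT(), c,
                                         n_bk=16, n_t=0, protocol=proto, seed=9)
        assert res.t_counts.counts.sum() == 0
        np.testing.assert_allclose(res.local_ca, 200.0)
        p = float(bk_stationary_po(bk, 0.0, 200.0))
        frac = res.bk_counts.counts[1000:].mean() / 16
        assert abs(frac - p) < 0.08

    def test_hp80_arm_exceeds_hp40_arm(self):
        """BK opening after -80 mV holding vastly exceeds the -40 mV arm."""
        ps = sim.run_paired_hp_protocol(GatingParamsBK(), GatingParamsT(),
                                        CouplingParams(), n_sweeps=100,
                                        test_duration=150.0, seed=13)
        i0 = int(20.0 / 0.05)
        i1 = int(120.0 / 0.05)
        po80 = ps.bk_counts_hp80[i0:i1].mean()
        po40 = ps.bk_counts_hp40[i0:i1].mean()
        assert po80 >= 3 * max(po40, 1e-9)


class TestPatchPlacement:
    def test_zero_channels_all_empty(self):
        t = sim.sample_patch_counts(0, 100.0, 2.0, "uniform", 50, seed=1)
        assert t.counts.sum() == 0

    def test_uniform_mean_matches_binomial(self):
        """6500 channels, 2/6500 um^2 sampling: mean 2.0 +/- 0.02."""
        t = sim.sample_patch_counts(6500, 6500.0, 2.0, "uniform", 10**5,
                                    seed=42)
        assert abs(t.counts.mean() - 2.0) < 0.02

    def test_uniform_distribution_chi_square_uniform_p(self):
        """Chi-square p-values vs the Binomial pmf look uniform."""
        from scipy import stats
        n, p = 6500, 2.0 / 6500.0
        kmax = 9
        pmf = stats.binom.pmf(np.arange(kmax), n, p)
        pmf = np.append(pmf, 1 - pmf.sum())
        pvals = []
        for rep in range(40):
            t = sim.sample_patch_counts(n, 6500.0, 2.0, "uniform", 3000,
                                        seed=1000 + rep)
            obs = np.bincount(np.minimum(t.counts, kmax), minlength=kmax + 1)
            pvals.append(stats.chisquare(obs, pmf * 3000).pvalue)
        assert stats.kstest(pvals, "uniform").pvalue > 0.005

    def test_clustered_tail_exceeds_uniform_at_matched_mean(self):
        from bkcav.cluster_stats import (channel_weighted_distribution,
                                         tail_fraction)
        rate, size, area = 0.28, 4.0, 2.0
        mean_occ = rate * area * size
        clustered = sim.sample_patch_counts(
            10**4, 6500.0, area, "clustered", 2 * 10**4, seed=5,
            cluster_rate=rate, mean_cluster_size=size)
        uniform = sim.sample_patch_counts(
            int(round(mean_occ * 6500 / area)), 6500.0, area, "uniform",
            2 * 10**4, seed=6)
        tc = tail_fraction(channel_weighted_distribution(clustered), 6)
        tu = tail_fraction(channel_weighted_distribution(uniform), 6)
        assert tc > tu

    def test_invalid_areas_rejected(self):
        with pytest.raises(ValueError):
            sim.sample_patch_counts(10, 1.0, 2.0, "uniform", 10, seed=0)


class TestFura2Synthesis:
    def test_limits(self):
        calib = Fura2Calibration()
        assert simulate_fura2(np.array([0.0]), calib)[0] == calib.r_min
        assert simulate_fura2(np.array([1e9]), calib)[0] == pytest.approx(
            calib.r_max, rel=1e-5)

    def test_negative_calcium_rejected(self):
        with pytest.raises(ValueError):
            simulate_fura2(np.array([-1.0]), Fura2Calibration())

    @settings(max_examples=25, derandomize=True)
    @given(st.lists(st.floats(0.0, 1e5), min_size=1, max_size=20))
    def test_ratio_within_calibration_range(self, ca):
        calib = Fura2Calibration()
        r = simulate_fura2(np.array(ca), calib)
        assert np.all(r >= calib.r_min) and np.all(r < calib.r_max + 1e-12)
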