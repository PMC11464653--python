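"""Pressure-trace processing: occlusions, cycles, ΔPes, partitioned mechanics."""

import numpy as np
import pytest

from cralekit import mechanics as mech
from cralekit import synthetic as syn


def _make_trace(paw, pes, fs=100.0, epochs=(), pao=None, pra=None):
    return mech.PressureTrace(
        fs_hz=fs, paw=np.asarray(paw, float), pes=np.asarray(pes, float),
        pao=pao, pra=pra, epochs=tuple(epochs),
    )


class TestUnits:
    def test_roundtrip(self):
        assert mech.mmhg_to_cmh2o(mech.cmh2o_to_mmhg(12.3)) == pytest.approx(12.3)

    def test_magnitude(self):
        # 10 mmHg is about 13.6 cmH2O
        assert mech.mmhg_to_cmh2o(10.0) == pytest.approx(13.6, abs=0.1)


class TestOcclusionTest:
    def _epoch(self, end):
        return mech.Epoch("occl", 0.0, end, "occlusion_test")

    def test_identity_transmission(self):
        t = np.linspace(0, 5, 500)
        p = 10 + 5 * np.sin(2 * np.pi * 1.7 * t)
        trace = _make_trace(p, p, epochs=[self._epoch(5.0)])
        ratio, valid = mech.occlusion_test(trace, trace.epochs[0])
        assert ratio == pytest.approx(1.0)
        assert valid

    def test_low_transmission_invalid(self):
        t = np.linspace(0, 5, 500)
        paw = 10 + 5 * np.sin(2 * np.pi * 1.7 * t)
        pes = 10 + 3 * np.sin(2 * np.pi * 1.7 * t)
        trace = _make_trace(paw, pes, epochs=[self._epoch(5.0)])
        ratio, valid = mech.occlusion_test(trace, trace.epochs[0])
        assert ratio == pytest.approx(0.6)
        assert not valid

    def test_no_compression_rejected(self):
        trace = _make_trace(np.full(500, 10.0), np.full(500, 10.0),
                            epochs=[self._epoch(5.0)])
        with pytest.raises(ValueError, match="no compression"):
            mech.occlusion_test(trace, trace.epochs[0])

    def test_generator_occlusion_near_unity(self):
        params = syn.WaveformParams(
            duration_s=12.0,
            comp_amplitude_cmh2o=15.0,
            occlusions=(syn.OcclusionSpec(start_s=3.0, duration_s=6.0, kind="test"),),
            epochs=(),
            noise_sd_cmh2o=0.05,
            seed=9,
        )
        trace, _ = syn.gen_pressure_traces(params)
        occl = next(e for e in trace.epochs if e.kind == "occlusion_test")
        ratio, valid = mech.occlusion_test(trace, occl)
        assert 0.95 <= ratio <= 1.05
        assert valid


class TestDetectCycles:
    def test_count_at_102_per_min(self, cc_trace):
        trace, _ = cc_trace
        cyc = mech.detect_cc_cycles(trace, trace.epochs[0])
        assert abs(cyc.n_cycles - 102) <= 1
        assert not cyc.rate_warning

    def test_rate_recovery_at_120(self):
        params = syn.WaveformParams(
            duration_s=30.0, comp_rate_per_min=120.0, comp_amplitude_cmh2o=12.0,
            noise_sd_cmh2o=0.2, seed=4,
        )
        trace, _ = syn.gen_pressure_traces(params)
        cyc = mech.detect_cc_cycles(trace, trace.epochs[0])
        assert cyc.rate_per_min == pytest.approx(120.0, rel=0.01)

    def test_zero_amplitude_rejected(self):
        params = syn.WaveformParams(
            duration_s=20.0, comp_amplitude_cmh2o=0.0, noise_sd_cmh2o=0.2, seed=5,
            epochs=(syn.EpochSpec("cc", 0.0, 20.0, "cc_mechanical", 0.0),),
        )
        trace, _ = syn.gen_pressure_traces(params)
        with pytest.raises(ValueError, match="no compression cycles"):
            mech.detect_cc_cycles(trace, trace.epochs[0])

    def test_non_cc_epoch_rejected(self, cc_trace):
        trace, _ = cc_trace
        with pytest.raises(ValueError):
            mech.detect_cc_cycles(
                trace, mech.Epoch("b", 0.0, 10.0, "baseline")
            )


class TestPesSwingStats:
    def test_noiseless_pure_train_swing_equals_amplitude(self):
        params = syn.WaveformParams(
            duration_s=20.0, fs_hz=250.0, comp_amplitude_cmh2o=12.0,
            vt_ml=1e-3, noise_sd_cmh2o=0.0, seed=0,
        )
        trace, _ = syn.gen_pressure_traces(params)
        stats = mech.pes_swing_stats(trace, smooth_s=0.0)
        assert stats.swing == pytest.approx(12.0, rel=1e-3)

    def test_epoch_mean_within_3pct_of_truth(self, cc_trace):
        trace, truth = cc_trace
        stats = mech.pes_swing_stats(trace)
        for label, target in truth.epoch_mean_swing.items():
            assert stats.epoch_mean_swing[label] == pytest.approx(target, rel=0.03)

    def test_amplitude_ordering_across_epochs(self):
        eps = (
            syn.EpochSpec("weak", 0.0, 20.0, "cc_manual", 8.0),
            syn.EpochSpec("strong", 20.0, 40.0, "cc_mechanical", 20.0),
        )
        params = syn.WaveformParams(duration_s=40.0, epochs=eps,
                                    noise_sd_cmh2o=0.2, seed=6)
        trace, _ = syn.gen_pressure_traces(params)
        stats = mech.pes_swing_stats(trace)
        assert stats.epoch_mean_swing["weak"] < stats.epoch_mean_swing["strong"]

    def test_swing_nonnegative_and_consistent(self, cc_trace):
        trace, _ = cc_trace
        stats = mech.pes_swing_stats(trace)
        assert np.all(stats.swing >= 0)
        assert stats.swing == pytest.approx(stats.pes_max - stats.pes_min)

    def test_estimator_nearly_unbiased_over_replicates(self):
        """Mean recovered ΔPes over 50 stochastic replicates stays within
        one replicate standard error of truth (relative bias < 0.5%)."""
        errs = []
        for seed in range(50):
            p = syn.WaveformParams(
                duration_s=30.0, fs_hz=100.0, comp_amplitude_cmh2o=15.0,
                noise_sd_cmh2o=0.2, seed=seed, comp_phase_s=0.011 * seed,
            )
            trace, truth = syn.gen_pressure_traces(p)
            stats = mech.pes_swing_stats(trace)
            errs.append(stats.epoch_mean_swing["cc"] - truth.epoch_mean_swing["cc"])
        errs = np.asarray(errs)
        assert abs(errs.mean()) < errs.std(ddof=1)
        assert abs(errs.mean()) / 15.0 < 0.005


class TestPlateau:
    def _occl(self, dur=5.5):
        return mech.Epoch("occl", 0.0, dur, "occlusion_insp")

    def test_constant_window(self):
        n = 550
        trace = _make_trace(np.full(n, 20.0), np.full(n, 8.0), fs=100.0,
                            epochs=[self._occl()])
        paw, pes = mech.plateau_values(trace, trace.epochs[0])
        assert paw == pytest.approx(20.0)
        assert pes == pytest.approx(8.0)

    def test_exponential_settling(self):
        t = np.arange(0, 5.5, 0.01)
        paw = 15.0 - 5.0 * np.exp(-t / 0.3)
        trace = _make_trace(paw, paw * 0.5, fs=100.0, epochs=[self._occl()])
        paw_p, _ = mech.plateau_values(trace, trace.epochs[0])
        assert paw_p == pytest.approx(15.0, abs=0.1)

    def test_noisy_constant(self):
        rng = np.random.default_rng(1)
        n = 550
        trace = _make_trace(10.0 + rng.normal(0, 0.2, n), np.full(n, 4.0),
                            fs=100.0, epochs=[self._occl()])
        paw, _ = mech.plateau_values(trace, trace.epochs[0])
        assert paw == pytest.approx(10.0, abs=0.2)

    def test_short_window_rejected(self):
        trace = _make_trace(np.full(300, 10.0), np.full(300, 4.0), fs=100.0,
                            epochs=[mech.Epoch("o", 0.0, 3.0, "occlusion_insp")])
        with pytest.raises(ValueError, match="at least 5 s"):
            mech.plateau_values(trace, trace.epochs[0])

    def test_unsettled_window_rejected(self):
        t = np.arange(0, 5.5, 0.01)
        ramp = 5.0 + 3.0 * t  # never settles
        trace = _make_trace(ramp, ramp, fs=100.0, epochs=[self._occl()])
        with pytest.raises(ValueError, match="stable"):
            mech.plateau_values(trace, trace.epochs[0])


class TestPartitionedMechanics:
    def test_worked_example(self):
        # VT=500, Pplat=20, PEEPtot=10, Pes plateaus 8/4
        panel = mech.mechanics_from_plateaus(500.0, 20.0, 10.0, 8.0, 4.0)
        assert panel.dp_rs_cmh2o == pytest.approx(10.0)
        assert panel.dp_cw_cmh2o == pytest.approx(4.0)
        assert panel.dp_l_cmh2o == pytest.approx(6.0)
        assert panel.crs_ml_cmh2o == pytest.approx(50.0)
        assert panel.ccw_ml_cmh2o == pytest.approx(125.0)
        assert panel.cl_ml_cmh2o == pytest.approx(500.0 / 6.0, rel=1e-9)
        # series identity
        assert 1 / panel.crs_ml_cmh2o == pytest.approx(
            1 / panel.cl_ml_cmh2o + 1 / panel.ccw_ml_cmh2o, rel=1e-12
        )

    def test_recovery_from_generator(self, occlusion_trace):
        trace, truth = occlusion_trace
        panel = mech.partitioned_mechanics(
            trace, trace.epoch("occl_insp_0"), trace.epoch("occl_exp_1"), 500.0
        )
        assert panel.cl_ml_cmh2o == pytest.approx(truth.cl_ml_cmh2o, rel=0.01)
        assert panel.ccw_ml_cmh2o == pytest.approx(truth.ccw_ml_cmh2o, rel=0.01)
        assert panel.crs_ml_cmh2o == pytest.approx(truth.crs_ml_cmh2o, rel=0.01)

    def test_equal_pes_plateaus_rejected(self):
        with pytest.raises(ValueError, match="chest wall"):
            mech.mechanics_from_plateaus(500.0, 20.0, 10.0, 6.0, 6.0)

    def test_nonpositive_dp_rejected(self):
        with pytest.raises(ValueError, match="respiratory system"):
            mech.mechanics_from_plateaus(500.0, 10.0, 10.0, 8.0, 4.0)

    def test_recovery_over_random_configs(self):
        """Median relative error of recovered CL/Ccw < 2% over 20 random
        configurations at 0.2 cmH2O noise; series identity to 1e-9."""
        rng = np.random.default_rng(12)
        errs_cl, errs_ccw = [], []
        for _ in range(20):
            cl = float(rng.uniform(20, 80))
            ccw = float(rng.uniform(60, 200))
            vt = float(rng.uniform(300, 600))
            params = syn.WaveformParams(
                duration_s=18.0,
                fs_hz=100.0,
                comp_amplitude_cmh2o=0.0,
                vt_ml=vt,
                resistance_cmh2o_s_l=float(rng.uniform(5, 20)),
                cl_ml_cmh2o=cl,
                ccw_ml_cmh2o=ccw,
                occlusions=(
                    syn.OcclusionSpec(3.0, 5.5, "insp"),
                    syn.OcclusionSpec(11.0, 5.5, "exp"),
                ),
                noise_sd_cmh2o=0.2,
                seed=int(rng.integers(2**31)),
            )
            trace, truth = syn.gen_pressure_traces(params)
            panel = mech.partitioned_mechanics(
                trace, trace.epoch("occl_insp_0"), trace.epoch("occl_exp_1"), vt
            )
            errs_cl.append(abs(panel.cl_ml_cmh2o - cl) / cl)
            errs_ccw.append(abs(panel.ccw_ml_cmh2o - ccw) / ccw)
            assert 1 / panel.crs_ml_cmh2o == pytest.approx(
                1 / panel.cl_ml_cmh2o + 1 / panel.ccw_ml_cmh2o, rel=1e-9
            )
        assert np.median(errs_cl) < 0.02
        assert np.median(errs_ccw) < 0.02


class TestCPP:
    def test_constant_channels(self):
        params = syn.WaveformParams(duration_s=20.0, comp_amplitude_cmh2o=15.0,
                                    noise_sd_cmh2o=0.0, seed=0)
        trace, _ = syn.gen_pressure_traces(params)
        n = trace.n
        flat = mech.PressureTrace(
            fs_hz=trace.fs_hz, paw=trace.paw, pes=trace.pes,
            pao=np.full(n, 40.0), pra=np.full(n, 10.0), epochs=trace.epochs,
        )
        res = mech.coronary_perfusion_pressure(flat, flat.epochs[0])
        assert res.cpp_mmhg == pytest.approx(30.0)
        assert res.mean_mmhg == pytest.approx(30.0)

    def test_equal_channels_zero(self):
        params = syn.WaveformParams(duration_s=20.0, comp_amplitude_cmh2o=15.0,
                                    noise_sd_cmh2o=0.0, seed=0)
        trace, _ = syn.gen_pressure_traces(params)
        same = np.full(trace.n, 25.0)
        flat = mech.PressureTrace(
            fs_hz=trace.fs_hz, paw=trace.paw, pes=trace.pes,
            pao=same, pra=same, epochs=trace.epochs,
        )
        res = mech.coronary_perfusion_pressure(flat, flat.epochs[0])
        assert res.cpp_mmhg == pytest.approx(0.0)

    def test_generator_diastolic_difference(self):
        params = syn.WaveformParams(
            duration_s=30.0, comp_amplitude_cmh2o=15.0, include_vascular=True,
            ao_dia_mmhg=22.0, ra_mean_mmhg=8.0, noise_sd_cmh2o=0.0, seed=1,
        )
        trace, _ = syn.gen_pressure_traces(params)
        res = mech.coronary_perfusion_pressure(trace, trace.epochs[0])
        # decompression minimum of the aortic pulse is its diastolic level
        assert res.mean_mmhg == pytest.approx(22.0 - 8.0, rel=0.01)

    def test_missing_channels_rejected(self, cc_trace):
        trace, _ = cc_trace
        with pytest.raises(ValueError, match="channels"):
            mech.coronary_perfusion_pressure(trace, trace.epochs[0])


class TestTraceValidation:
    def test_epoch_outside_span_rejected(self):
        with pytest.raises(ValueError, match="outside"):
            _make_trace(np.zeros(100), np.zeros(100), fs=100.0,
                        epochs=[mech.Epoch("x", 0.0, 100.0, "baseline")])

    def test_aliasing_sampling_rejected(self):
        with pytest.raises(ValueError, match="alias"):
            syn.WaveformParams(fs_hz=20.0, comp_rate_per_min=102.0)

    def test_occlusion_under_5s_rejected(self):
        with pytest.raises(ValueError, match="5 s"):
            syn.OcclusionSpec(start_s=0.0, duration_s=3.0)
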