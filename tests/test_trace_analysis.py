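"""Detection and measurement rules on constructed sweeps."""

import numpy as np
import pandas as pd
import pytest

from scracm.session import RecordingSession
from scracm.synthetic_data import epsc_kernel
from scracm.trace_analysis import (AnalysisConfig, baseline_and_average,
                                   detection_bias_check, flag_direct_photocurrent,
                                   full_field_charge, measure_all,
                                   measure_response, qc_filter)

FS = 20_000.0
CFG = AnalysisConfig()


def single_spot_session(charges_pc, noise_sd=0.0, offset=0.0, ff_pc=None,
                        rng=None) -> RecordingSession:
    """A 1x1-grid session with one EPSC per trial (and optional full-field)."""
    rng = rng or np.random.default_rng(0)
    kernel = epsc_kernel(FS, 2.0, 15.0)
    n = int(0.4 * FS)
    sweeps, rows = [], []
    for tr, q in enumerate(charges_pc):
        sw = rng.normal(0.0, noise_sd, n) if noise_sd > 0 else np.zeros(n)
        sw += offset
        i0 = int(0.1 * FS)
        sw[i0:i0 + len(kernel)] -= 1000.0 * q * kernel
        rows.append((tr, 0, 100.0, False))
        if ff_pc is not None:
            i1 = int(0.25 * FS)
            sw[i1:i1 + len(kernel)] -= 1000.0 * ff_pc[tr] * kernel
            rows.append((tr, -1, 250.0, True))
        sweeps.append(sw)
    sched = pd.DataFrame(rows, columns=["trial", "spot_index", "t_ms",
                                        "is_full_field"])
    return RecordingSession(sweeps, sched, sample_rate_hz=FS, n_rows=1, n_cols=1,
                            soma_row=0, soma_col=0, soma_depth_um=500.0,
                            series_resistance_mohm=20.0)


class TestBaselineAndAverage:
    def test_constant_offset_removed(self):
        session = single_spot_session([0.0], offset=5.0)
        avg = baseline_and_average(session, CFG)
        np.testing.assert_allclose(avg.segments[0], 0.0, atol=1e-12)

    def test_trial_averaging_is_linear(self):
        session = single_spot_session([1.0, 3.0])
        avg = baseline_and_average(session, CFG)
        r = measure_response(avg.segments[0], CFG, FS, avg.n_baseline)
        assert r.charge_pc == pytest.approx(2.0, rel=1e-9)

    def test_baseline_sd_shrinks_with_sqrt_trials(self):
        """Averaged-trace baseline SD ≈ sd/√5 (800 baseline samples)."""
        rng = np.random.default_rng(42)
        session = single_spot_session([0.0] * 5, noise_sd=2.0, rng=rng)
        avg = baseline_and_average(session, CFG)
        sd = avg.segments[0][:avg.n_baseline].std()
        assert sd == pytest.approx(2.0 / np.sqrt(5), rel=0.2)

    def test_missing_spot_named_in_error(self):
        session = single_spot_session([1.0])
        sched = session.schedule.copy()
        session.schedule = sched  # bypass re-validation; corrupt the lookup
        session.schedule.loc[0, "spot_index"] = 99
        with pytest.raises(ValueError, match="spot 0.*trial 0"):
            baseline_and_average(session, CFG)


class TestMeasureResponse:
    def _segment(self, n_b=800, n_r=1000):
        return np.zeros(n_b + n_r + 1), n_b

    def test_rectangular_pulse_charge_and_peak(self):
        """A -10 pA, 10 ms pulse carries 0.1 pC and peaks at 10 pA."""
        seg, n_b = self._segment()
        seg[n_b:n_b + 201] = -10.0
        r = measure_response(seg, CFG, FS, n_b)
        assert r.peak_pa == pytest.approx(10.0)
        assert r.charge_pc == pytest.approx(0.1, rel=5e-3)

    def test_all_zero_segment(self):
        seg, n_b = self._segment()
        r = measure_response(seg, CFG, FS, n_b)
        assert r.charge_pc == 0.0 and not r.significant

    @pytest.mark.parametrize("mult,expect", [(7.1, True), (6.9, False)])
    def test_seven_sd_detection_boundary(self, mult, expect):
        """Peak at 7.1x baseline SD is significant, at 6.9x it is not."""
        seg, n_b = self._segment()
        sd = 1.5
        seg[:n_b] = sd * np.tile([1.0, -1.0], n_b // 2)  # exact SD, zero mean
        kernel = epsc_kernel(FS, 2.0, 15.0)
        seg[n_b:n_b + len(kernel)] = -kernel / kernel.max() * mult * sd
        r = measure_response(seg, CFG, FS, n_b)
        assert r.baseline_sd_pa == pytest.approx(sd)
        assert r.significant is expect

    def test_empty_response_window_rejected(self):
        with pytest.raises(ValueError, match="response"):
            measure_response(np.zeros(801), CFG, FS, 800)

    def test_scaling_sweeps_scales_charge_exactly(self):
        """Charge is exactly linear in the recorded current."""
        rng = np.random.default_rng(7)
        session = single_spot_session([2.0, 1.0], noise_sd=1.0, rng=rng)
        avg = baseline_and_average(session, CFG)
        r1 = measure_response(avg.segments[0], CFG, FS, avg.n_baseline)
        session.sweeps = [2.5 * s for s in session.sweeps]
        avg2 = baseline_and_average(session, CFG)
        r2 = measure_response(avg2.segments[0], CFG, FS, avg2.n_baseline)
        assert r2.charge_pc == pytest.approx(2.5 * r1.charge_pc, rel=1e-12)


class TestDirectPhotocurrent:
    def test_synaptic_latency_not_flagged(self):
        """An EPSC rising a few ms after the stimulus is synaptic, not direct."""
        seg = np.zeros(1801)
        kernel = epsc_kernel(FS, 2.0, 15.0)
        delay = int(4.0 * FS / 1000.0)
        seg[800 + delay:800 + delay + len(kernel) - delay] = \
            -20.0 * kernel[:len(kernel) - delay] / kernel.max()
        seg[:800] = 0.1 * np.tile([1.0, -1.0], 400)
        r = measure_response(seg, CFG, FS, 800, spot_index=0)
        assert r.significant and r.onset_latency_ms >= 2.0
        assert flag_direct_photocurrent([r], CFG) is False

    def test_step_at_half_ms_flagged(self):
        seg = np.zeros(1801)
        seg[:800] = 0.1 * np.tile([1.0, -1.0], 400)
        seg[800 + 10:] = -30.0  # step 0.5 ms after the stimulus
        r = measure_response(seg, CFG, FS, 800, spot_index=0)
        assert flag_direct_photocurrent([r], CFG) is True

    def test_no_significant_spots_not_flagged(self):
        seg = np.zeros(1801)
        r = measure_response(seg, CFG, FS, 800)
        assert flag_direct_photocurrent([r], CFG) is False


class TestQC:
    @pytest.mark.parametrize("rs,keep", [(39.0, True), (40.0, True), (41.0, False)])
    def test_series_resistance_bound_is_strict(self, rs, keep):
        session = single_spot_session([1.0])
        session.series_resistance_mohm = rs
        assert qc_filter(session, CFG) is keep

    def test_missing_metadata_rejected(self):
        session = single_spot_session([1.0])
        session.series_resistance_mohm = np.nan
        with pytest.raises(ValueError, match="series"):
            qc_filter(session, CFG)


class TestFullField:
    def test_two_trials_average(self):
        session = single_spot_session([0.0, 0.0], ff_pc=[1.0, 3.0])
        assert full_field_charge(session, CFG) == pytest.approx(2.0, rel=1e-9)

    def test_zero_traces_zero_charge(self):
        session = single_spot_session([0.0], ff_pc=[0.0])
        assert full_field_charge(session, CFG) == pytest.approx(0.0, abs=1e-12)

    def test_missing_full_field_rejected(self):
        session = single_spot_session([1.0])
        with pytest.raises(ValueError, match="full-field"):
            full_field_charge(session, CFG)


class TestDetectionBiasCheck:
    def test_identical_depths_degenerate(self):
        rep = detection_bias_check([(100.0, 1.0), (100.0, 2.0), (100.0, 3.0)])
        assert rep.degenerate and np.isnan(rep.r)

    def test_perfectly_linear_pairs(self):
        rep = detection_bias_check([(d, 0.1 + 0.01 * d) for d in (100, 200, 300, 400)])
        assert rep.r == pytest.approx(1.0)

    def test_independent_depth_and_charge_rarely_correlate(self):
        """With depth-independent charge, |r| < 0.45 in ≥ 90% of cohorts."""
        rng = np.random.default_rng(123)
        ok = 0
        for _ in range(20):
            depth = rng.uniform(0, 500, 20)
            charge = rng.lognormal(0.0, 0.5, 20)
            rep = detection_bias_check(list(zip(depth, charge)))
            ok += abs(rep.r) < 0.45
        assert ok >= 18

    def test_too_few_cells_rejected(self):
        with pytest.raises(ValueError, match="3"):
            detection_bias_check([(1.0, 1.0), (2.0, 2.0)])
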