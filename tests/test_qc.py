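import numpy as np
import pytest
from hypothesis import given, strategies as st

from mxfret.presets import get_preset, SimPreset
from mxfret.simulate import simulate_dataset, simulate_trace
from mxfret.traces import FluorTrace
from mxfret.qc import (
    QCParams,
    median_filter,
    estimate_background_sd,
    detect_catastrophic_bleach,
    detect_acceptor_bleach,
    compute_snr,
    donor_acceptor_correlation,
    correct_bleedthrough,
    compute_fret,
    qc_select,
)

from conftest import process_dataset


def make_trace(donor, acceptor, frame_time=0.05, trace_id="t"):
    return FluorTrace(trace_id, frame_time, np.asarray(donor, float), np.asarray(acceptor, float))


class TestMedianFilter:
    def test_constant_series_unchanged(self):
        x = np.full(50, 7.0)
        np.testing.assert_array_equal(median_filter(x, 9), x)

    def test_truncated_edge_windows(self):
        # hand evaluation: edges use the shrinking window
        out = median_filter([1, 9, 1, 9, 1], 3)
        np.testing.assert_array_equal(out, [5, 1, 9, 1, 5])

    def test_impulse_removed(self):
        x = np.zeros(40)
        x[20] = 100.0
        assert np.all(median_filter(x, 9) == 0)

    @pytest.mark.parametrize("window", [0, 2, 4, -1])
    def test_invalid_window(self, window):
        with pytest.raises(ValueError):
            median_filter(np.zeros(20), window)

    @given(st.lists(st.floats(-1e3, 1e3), min_size=5, max_size=60))
    def test_output_length_and_range(self, values):
        out = median_filter(values, 5)
        assert out.size == len(values)
        assert out.min() >= min(values) - 1e-12
        assert out.max() <= max(values) + 1e-12


class TestBackgroundSd:
    def test_normal_tail_recovers_sigma(self):
        rng = np.random.default_rng(0)
        estimates = [
            estimate_background_sd(
                make_trace(rng.normal(0, 25, 200), np.zeros(200)), "donor", 200
            )
            for _ in range(20)
        ]
        assert np.mean(estimates) == pytest.approx(25.0, rel=0.15)

    def test_constant_tail_gives_zero(self):
        t = make_trace(np.full(100, 5.0), np.zeros(100))
        assert estimate_background_sd(t, "donor", 50) == 0.0

    def test_robust_to_single_outlier(self):
        donor = np.full(100, 5.0)
        donor[-3] = 1e6
        t = make_trace(donor, np.zeros(100))
        assert estimate_background_sd(t, "donor", 50) == 0.0

    def test_post_bleach_segment_used_when_supplied(self):
        donor = np.concatenate([np.full(100, 1000.0), np.zeros(100)])
        t = make_trace(donor, np.zeros(200))
        assert estimate_background_sd(t, "donor", 50, bleach_frame=100) == 0.0

    def test_tail_too_short(self):
        with pytest.raises(ValueError):
            estimate_background_sd(make_trace(np.zeros(30), np.zeros(30)), "donor", 5)


class TestBleachDetection:
    def test_single_step_located_within_5_frames(self):
        rng = np.random.default_rng(1)
        signal = np.where(np.arange(120) < 60, 1000.0, 0.0) + rng.normal(0, 10, 120)
        t = make_trace(signal / 2, signal / 2)
        events = detect_catastrophic_bleach(t, bg_sd=10.0)
        assert len(events) == 1
        assert abs(events[0] - 60) <= 5

    def test_constant_trace_has_no_events(self):
        rng = np.random.default_rng(2)
        t = make_trace(rng.normal(500, 10, 200), rng.normal(500, 10, 200))
        assert detect_catastrophic_bleach(t, bg_sd=10.0) == []

    def test_blink_is_not_catastrophic(self):
        # a 5-frame dip that recovers fails the "without returning" clause
        signal = np.full(200, 1000.0)
        signal[100:105] = 0.0
        t = make_trace(signal / 2, signal / 2)
        assert detect_catastrophic_bleach(t, bg_sd=10.0) == []

    def test_two_step_aggregate_yields_two_events(self):
        rng = np.random.default_rng(3)
        signal = np.where(np.arange(300) < 100, 2000.0, np.where(np.arange(300) < 200, 1000.0, 0.0))
        signal = signal + rng.normal(0, 10, 300)
        t = make_trace(signal / 2, signal / 2)
        events = detect_catastrophic_bleach(t, bg_sd=10.0)
        assert len(events) == 2

    def test_too_short_trace_rejected(self):
        with pytest.raises(ValueError):
            detect_catastrophic_bleach(make_trace(np.zeros(20), np.zeros(20)))

    def test_detected_within_5_frames_on_95_percent_of_clean_traces(self):
        # generator/detector round trip at default noise
        ds = simulate_dataset(get_preset("AS_GMPPCP"), 100, seed=21)
        hits, total = 0, 0
        for trace, truth in zip(ds.traces, ds.ground_truths):
            if truth.donor_bleach_frame is None:
                continue
            events = detect_catastrophic_bleach(trace)
            total += 1
            if len(events) >= 1 and abs(events[-1] - truth.donor_bleach_frame) <= 5:
                hits += 1
        assert total > 50
        assert hits / total >= 0.95


class TestAcceptorBleach:
    def test_acceptor_drop_with_donor_rise_detected(self):
        rng = np.random.default_rng(4)
        n = 200
        acceptor = np.where(np.arange(n) < 40, 700.0, 75.0) + rng.normal(0, 10, n)
        donor = np.where(np.arange(n) < 40, 300.0, 1000.0) + rng.normal(0, 10, n)
        t = make_trace(donor, acceptor)
        frame = detect_acceptor_bleach(t, bg_sd_acceptor=10.0, bg_sd_donor=10.0)
        assert frame is not None and abs(frame - 40) <= 5

    def test_joint_drop_is_donor_event_not_acceptor(self):
        rng = np.random.default_rng(5)
        n = 200
        donor = np.where(np.arange(n) < 40, 300.0, 0.0) + rng.normal(0, 10, n)
        acceptor = np.where(np.arange(n) < 40, 700.0, 0.0) + rng.normal(0, 10, n)
        t = make_trace(donor, acceptor)
        assert detect_acceptor_bleach(t, bg_sd_acceptor=10.0, bg_sd_donor=10.0) is None

    def test_flat_trace_has_none(self):
        rng = np.random.default_rng(6)
        t = make_trace(rng.normal(300, 10, 150), rng.normal(700, 10, 150))
        assert detect_acceptor_bleach(t, bg_sd_acceptor=10.0, bg_sd_donor=10.0) is None

    def test_final_fret_transition_not_mistaken_for_bleach(self):
        # high->low transition drops the acceptor and raises the donor, but
        # leaves real acceptor signal: must not truncate the analysis window
        rng = np.random.default_rng(7)
        n = 200
        high = np.arange(n) < 120
        donor = np.where(high, 280.0, 650.0) + rng.normal(0, 10, n)
        acceptor = np.where(high, 720.0, 350.0) + 0.075 * donor + rng.normal(0, 10, n)
        t = make_trace(donor, acceptor)
        assert detect_acceptor_bleach(t, bg_sd_acceptor=10.0, bg_sd_donor=10.0) is None


class TestScalarCriteria:
    def test_snr_arithmetic(self):
        t = make_trace(np.full(100, 300.0), np.full(100, 500.0))
        assert compute_snr(t, 100, 40.0, 60.0) == pytest.approx(8.0)
        assert compute_snr(t, 100, 25.0, 25.0) == pytest.approx(16.0)

    def test_snr_zero_intensity(self):
        t = make_trace(np.zeros(50), np.zeros(50))
        assert compute_snr(t, 50, 25.0, 25.0) == 0.0

    def test_snr_undefined_for_zero_background(self):
        t = make_trace(np.ones(50), np.ones(50))
        assert np.isnan(compute_snr(t, 50, 0.0, 0.0))

    def test_perfect_anticorrelation(self):
        d = np.linspace(0, 1000, 100)
        t = make_trace(d, 1000.0 - d)
        assert donor_acceptor_correlation(t, 100) == pytest.approx(-1.0)

    def test_perfect_correlation(self):
        d = np.linspace(0, 1000, 100)
        t = make_trace(d, d)
        assert donor_acceptor_correlation(t, 100) == pytest.approx(1.0)

    def test_zero_variance_flagged(self):
        t = make_trace(np.ones(50), np.linspace(0, 1, 50))
        assert np.isnan(donor_acceptor_correlation(t, 50))

    def test_dynamic_traces_anticorrelated_in_nearly_all_cases(self):
        ds = simulate_dataset(get_preset("AS_GMPPCP"), 100, seed=22)
        negative = 0
        for trace, truth in zip(ds.traces, ds.ground_truths):
            end = min(
                f for f in (truth.donor_bleach_frame, truth.acceptor_bleach_frame, trace.n_frames)
                if f is not None
            )
            if end < 10:
                negative += 1  # window too short to judge; don't count against
                continue
            if donor_acceptor_correlation(trace, end) < 0:
                negative += 1
        assert negative >= 99


class TestBleedthroughAndFret:
    def test_correction_arithmetic(self):
        t = make_trace(np.full(30, 300.0), np.full(30, 120.0))
        out = correct_bleedthrough(t, 0.075)
        np.testing.assert_allclose(out.acceptor, 97.5)
        np.testing.assert_array_equal(out.donor, t.donor)

    def test_zero_factor_is_identity(self):
        t = make_trace(np.arange(30.0), np.arange(30.0) * 2)
        out = correct_bleedthrough(t, 0.0)
        np.testing.assert_array_equal(out.acceptor, t.acceptor)

    def test_not_idempotent(self):
        t = make_trace(np.full(30, 300.0), np.full(30, 120.0))
        once = correct_bleedthrough(t, 0.075)
        twice = correct_bleedthrough(once, 0.075)
        assert not np.allclose(once.acceptor, twice.acceptor)

    def test_invalid_factor(self):
        t = make_trace(np.zeros(30), np.zeros(30))
        with pytest.raises(ValueError):
            correct_bleedthrough(t, 1.0)

    @pytest.mark.parametrize(
        "donor,acceptor,expected",
        [(0.0, 500.0, 1.0), (500.0, 500.0, 0.5), (300.0, 97.5, 0.2453)],
    )
    def test_fret_arithmetic(self, donor, acceptor, expected):
        t = make_trace(np.full(20, donor), np.full(20, acceptor))
        fret = compute_fret(t, 20)
        assert fret.efficiency[0] == pytest.approx(expected, abs=5e-5)

    def test_low_intensity_frames_marked_invalid(self):
        donor = np.full(30, 500.0)
        donor[10] = 1.0
        acceptor = np.full(30, 500.0)
        acceptor[10] = 1.0
        fret = compute_fret(make_trace(donor, acceptor), 30, 25.0, 25.0)
        assert np.isnan(fret.efficiency[10])
        assert fret.values.size == 29

    def test_round_trip_bias_below_half_percent(self):
        # generator bleed-through at 7.5%, corrected with the same factor:
        # mean FRET of a static 0.5 emitter must come back unbiased
        preset = SimPreset(
            name="half",
            n_states=1,
            state_means=(0.5,),
            state_sigma=0.06,
            mean_dwell_s=(10.0,),
            connectivity=((0,),),
            donor_bleach_mean_s=1e9,
            acceptor_bleach_mean_s=1e9,
            record_len_s=20.0,
        )
        vals = []
        for seed in range(50):
            trace, _ = simulate_trace(preset, seed=seed)
            corrected = correct_bleedthrough(trace, 0.075)
            vals.append(compute_fret(corrected, trace.n_frames).values.mean())
        assert abs(np.mean(vals) - 0.5) < 0.005

    def test_noiseless_fret_recovers_emission_exactly(self):
        preset = SimPreset(
            name="exact",
            n_states=2,
            state_means=(0.3, 0.8),
            state_sigma=0.0,
            mean_dwell_s=(1.0, 1.0),
            connectivity=((0, 1), (1, 0)),
            bg_sigma_donor=0.0,
            bg_sigma_acceptor=0.0,
            donor_bleach_mean_s=1e9,
            acceptor_bleach_mean_s=1e9,
            record_len_s=10.0,
        )
        trace, truth = simulate_trace(preset, seed=1)
        corrected = correct_bleedthrough(trace, preset.bleedthrough)
        fret = compute_fret(corrected, trace.n_frames)
        expected = np.asarray(preset.state_means)[truth.state_path]
        np.testing.assert_allclose(fret.efficiency, expected, atol=1e-9)


class TestQcSelect:
    def test_clean_traces_pass(self, gmppcp_dataset):
        results = [qc_select(t) for t in gmppcp_dataset.traces]
        observable = [
            r
            for r, g in zip(results, gmppcp_dataset.ground_truths)
            if g.kind == "clean" and g.donor_bleach_frame is not None
        ]
        frac = np.mean([r.passed for r in observable])
        assert frac >= 0.95

    def test_unbleached_traces_fail_with_no_bleach_event(self):
        p = get_preset("AS_apo", donor_bleach_mean_s=1e9, acceptor_bleach_mean_s=1e9)
        trace, _ = simulate_trace(p, seed=0)
        r = qc_select(trace)
        assert not r.passed and "no_bleach_event" in r.fail_reasons

    def test_aggregate_fails_with_multiple_events(self):
        p = get_preset("AS_apo", frac_aggregate=0.999, donor_bleach_mean_s=8.0)
        found = 0
        for seed in range(15):
            trace, truth = simulate_trace(p, seed=seed)
            assert truth.kind == "aggregate"
            r = qc_select(trace)
            if r.n_catastrophic_events >= 2:
                found += 1
                assert "multiple_bleach_events" in r.fail_reasons
        assert found >= 10  # both molecules usually bleach at distinct times

    def test_low_snr_fails(self):
        p = get_preset("AS_GMPPCP", bg_sigma_donor=120.0, bg_sigma_acceptor=120.0)
        failed = 0
        for seed in range(10):
            trace, truth = simulate_trace(p, seed=seed)
            if truth.donor_bleach_frame is None:
                continue
            r = qc_select(trace)
            if "low_snr" in r.fail_reasons:
                failed += 1
        assert failed >= 5

    def test_donor_only_fails_on_positive_correlation(self):
        p = get_preset("AS_apo", frac_donor_only=0.999, donor_bleach_mean_s=20.0)
        reasons = []
        for seed in range(20):
            trace, truth = simulate_trace(p, seed=seed)
            if truth.donor_bleach_frame is None:
                continue
            reasons.extend(qc_select(trace).fail_reasons)
        assert reasons.count("positive_correlation") >= 10

    def test_fail_reasons_empty_iff_passed(self, gmppcp_dataset):
        p = get_preset("AS_GMPPCP", frac_aggregate=0.15, frac_donor_only=0.15)
        mixed = simulate_dataset(p, 60, seed=23)
        for trace in list(gmppcp_dataset.traces) + list(mixed.traces):
            r = qc_select(trace)
            assert r.passed == (len(r.fail_reasons) == 0)

    def test_analysis_end_bounded_by_bleaches(self, gmppcp_dataset):
        for trace in gmppcp_dataset.traces:
            r = qc_select(trace)
            for frame in (r.donor_bleach_frame, r.acceptor_bleach_frame):
                if frame is not None:
                    assert r.analysis_end <= frame
            assert r.analysis_end <= trace.n_frames

    def test_order_independence(self, gmppcp_dataset):
        traces = list(gmppcp_dataset.traces)[:20]
        forward = {t.trace_id: qc_select(t) for t in traces}
        backward = {t.trace_id: qc_select(t) for t in reversed(traces)}
        for tid in forward:
            assert forward[tid] == backward[tid]

    def test_qc_gate_passes_95_percent_of_observable_clean_traces(self):
        ds = simulate_dataset(get_preset("AS_apo"), 200, seed=24)
        results = [qc_select(t) for t in ds.traces]
        observable = [
            r.passed
            for r, g in zip(results, ds.ground_truths)
            if g.kind == "clean" and g.donor_bleach_frame is not None
        ]
        assert np.mean(observable) >= 0.95

    def test_aggregate_fraction_round_trip(self):
        # generator/detector round trip: the detected multi-step fraction
        # tracks the simulated aggregate fraction
        p = get_preset("AS_apo", frac_aggregate=0.2, donor_bleach_mean_s=10.0,
                       acceptor_bleach_mean_s=1e9)
        ds = simulate_dataset(p, 300, seed=25)
        multi = np.mean([qc_select(t).n_catastrophic_events >= 2 for t in ds.traces])
        # not every aggregate shows two in-record steps; require the right scale
        assert 0.10 <= multi <= 0.25
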