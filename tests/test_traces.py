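"""Trace analysis: peak detection, event selection, WLC fits, ΔLc."""

import numpy as np
import pytest

from smfskit.polymer import WLCParams, wlc_force, wlc_inverse_extension
from smfskit.synthetic import EventFamily, TraceGenConfig, generate_trace
from smfskit.traces import (
    DetectionParams,
    ForceExtensionTrace,
    analyze_trace,
    detect_peaks,
    fit_wlc_segment,
    read_trace,
    select_events,
    write_events,
    write_trace,
)

# a single sharply defined event family: every peak is unambiguous
CLEAR_CONFIG = TraceGenConfig(
    families=(EventFamily(36.0, 1e-6, 40.0, 1e-6, 1.0),),
    n_events_range=(3, 3),
    noise_sd_pN=0.0,
)


def flat_trace(n=200, force=0.0):
    return ForceExtensionTrace(
        extension_nm=np.arange(n) * 0.5, force_pN=np.full(n, force), trace_id="flat"
    )


class TestDetectPeaks:
    def test_flat_trace_has_no_peaks(self):
        assert detect_peaks(flat_trace(), DetectionParams()) == []

    def test_noiseless_sawtooth_peaks_at_rupture_extensions(self):
        trace, truth = generate_trace(CLEAR_CONFIG, seed=1)
        peaks = detect_peaks(trace, DetectionParams())
        # adhesion + three events + detachment
        assert len(peaks) == len(truth.events) + 2
        lcs = [30.0, 66.0, 102.0]
        expected = [wlc_inverse_extension(40.0, WLCParams(lc)) for lc in lcs]
        found = trace.extension_nm[peaks[1:-1]]
        for x_exp, x_found in zip(expected, found):
            assert abs(x_found - x_exp) <= 0.5 + 1e-9  # within one sample

    def test_inverted_trace_has_no_peaks(self):
        trace, _ = generate_trace(CLEAR_CONFIG, seed=1)
        flipped = ForceExtensionTrace(
            extension_nm=trace.extension_nm,
            force_pN=-trace.force_pN,
            trace_id="flipped",
        )
        assert detect_peaks(flipped, DetectionParams()) == []

    def test_short_trace_rejected(self):
        t = ForceExtensionTrace(
            extension_nm=np.arange(10) * 10.0, force_pN=np.zeros(10)
        )
        with pytest.raises(ValueError):
            detect_peaks(t, DetectionParams(smooth_window_nm=200.0))


class TestSelectEvents:
    @pytest.mark.parametrize(
        "n_peaks, n_kept, accepted",
        [(5, 3, True), (3, 1, False), (2, 0, False), (0, 0, False)],
    )
    def test_first_and_last_excluded(self, n_peaks, n_kept, accepted):
        peaks = list(range(10, 10 + 10 * n_peaks, 10))
        kept, ok = select_events(peaks, flat_trace(), DetectionParams())
        assert len(kept) == n_kept
        assert ok is accepted
        assert kept == peaks[1:-1]


class TestWLCFit:
    def make_branch(self, Lc=36.0, noise=0.0, seed=0, n=60):
        rng = np.random.default_rng(seed)
        x = np.linspace(0.5, 0.9 * Lc, n)
        f = np.array([wlc_force(v, WLCParams(Lc)) for v in x])
        f = f + rng.normal(0, noise, n)
        return ForceExtensionTrace(extension_nm=x, force_pN=f, trace_id="seg")

    def test_noiseless_fit_recovers_contour_length(self):
        t = self.make_branch()
        out = fit_wlc_segment(t, t.n_samples - 1, DetectionParams())
        assert out is not None
        lc, rmse = out
        assert lc == pytest.approx(36.0, abs=0.01)
        assert rmse < 1e-6

    def test_noisy_fit_bias_and_spread(self):
        lcs = []
        for seed in range(100):
            t = self.make_branch(noise=5.0, seed=seed)
            out = fit_wlc_segment(t, t.n_samples - 1, DetectionParams())
            assert out is not None
            lcs.append(out[0])
        lcs = np.array(lcs)
        assert np.all(np.abs(lcs - 36.0) < 1.0)
        assert abs(lcs.mean() - 36.0) < 0.3

    def test_persistence_length_reported_fixed(self):
        trace, _ = generate_trace(CLEAR_CONFIG, seed=3)
        ana = analyze_trace(trace)
        assert all(ev.p_nm == 0.36 for ev in ana.events)

    def test_tiny_window_discards_event(self):
        t = self.make_branch(n=60)
        # peak index 2 leaves a 3-sample window
        assert fit_wlc_segment(t, 2, DetectionParams(engage_threshold_pN=1e-6)) is None


class TestEventMetrics:
    def test_delta_lc_between_sequential_events(self):
        trace, truth = generate_trace(CLEAR_CONFIG, seed=5)
        ana = analyze_trace(trace)
        assert ana.accepted
        assert [round(e.Lc_nm, 1) for e in ana.events] == [30.0, 66.0, 102.0]
        assert np.allclose(ana.delta_Lc_nm, [36.0, 36.0], atol=0.05)

    def test_loading_rate_at_rupture_point(self):
        trace, _ = generate_trace(CLEAR_CONFIG, seed=5)
        ana = analyze_trace(trace)
        for ev in ana.events:
            from smfskit.polymer import loading_rate

            expected = loading_rate(200.0, ev.peak_extension_nm, WLCParams(ev.Lc_nm))
            assert ev.loading_rate_pN_s == pytest.approx(expected, rel=1e-9)

    def test_total_contour_never_exceeds_generator_truth(self):
        for seed in range(10):
            trace, truth = generate_trace(TraceGenConfig(), seed=seed)
            ana = analyze_trace(trace)
            if ana.events:
                assert ana.events[-1].Lc_nm <= truth.total_Lc_nm + 2.0

    def test_analysis_deterministic(self):
        trace, _ = generate_trace(TraceGenConfig(), seed=9)
        a1 = analyze_trace(trace)
        a2 = analyze_trace(trace)
        assert [e.Lc_nm for e in a1.events] == [e.Lc_nm for e in a2.events]


class TestNoiselessClosure:
    def test_every_clear_event_recovered(self):
        """All generator events of unambiguous traces come back, ΔLc to 0.5 nm."""
        cfg = TraceGenConfig(
            families=(EventFamily(36.0, 1e-6, 40.0, 1e-6, 1.0),),
            n_events_range=(2, 4),
            noise_sd_pN=0.0,
        )
        for seed in range(20):
            trace, truth = generate_trace(cfg, seed=seed)
            ana = analyze_trace(trace)
            assert len(ana.events) == len(truth.events)
            for meas, (dlc_true, _) in zip(ana.delta_Lc_nm, truth.events):
                assert abs(meas - dlc_true) < 0.5

    def test_thermal_noise_rarely_changes_event_count(self):
        """Instrument-level force noise leaves event counts intact.

        Noise at the generator default (6 pN, below the ~10 pN cantilever
        thermal RMS) must not create or destroy events on otherwise clear
        sawtooth traces.
        """
        from smfskit.polymer import thermal_force_rms

        noise = 6.0
        assert noise <= thermal_force_rms(0.025)
        base = TraceGenConfig(
            families=(EventFamily(36.0, 1e-6, 40.0, 1e-6, 1.0),),
            n_events_range=(2, 4),
            noise_sd_pN=0.0,
        )
        noisy = TraceGenConfig(
            families=base.families, n_events_range=(2, 4), noise_sd_pN=noise
        )
        same = 0
        n_rep = 200
        for seed in range(n_rep):
            t0, _ = generate_trace(base, seed=seed)
            t1, _ = generate_trace(noisy, seed=seed)
            n0 = len(analyze_trace(t0).events)
            n1 = len(analyze_trace(t1).events)
            same += n0 == n1
        assert same >= 0.95 * n_rep


class TestIO:
    def test_trace_round_trip(self, tmp_path):
        trace, _ = generate_trace(TraceGenConfig(), seed=2)
        path = tmp_path / "t.txt"
        write_trace(trace, path)
        back = read_trace(path)
        assert back.trace_id == trace.trace_id
        assert back.pulling_speed_nm_s == trace.pulling_speed_nm_s
        np.testing.assert_allclose(back.force_pN, trace.force_pN, atol=1e-4)

    def test_events_table_schema(self, tmp_path):
        trace, _ = generate_trace(CLEAR_CONFIG, seed=5)
        frame = write_events([analyze_trace(trace)], tmp_path / "ev.tsv")
        assert list(frame.columns) == [
            "trace_id", "event_index", "peak_force_pN", "rupture_force_pN",
            "peak_extension_nm", "Lc_nm", "loading_rate_pN_s", "fit_rmse_pN",
            "accepted",
        ]
        assert len(frame) == 3
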