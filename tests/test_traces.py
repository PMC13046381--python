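"""Curve analysis: event detection, WLC fits, selection, calibration."""

import numpy as np
import pytest

import polyforce as pf
from polyforce.simulate import ForceExtensionTrace
from polyforce.traces import SelectionCriteria, UnfoldingEvent


def make_trace(extension, force, speed=1000.0):
    return ForceExtensionTrace(
        extension=np.asarray(extension, float),
        force=np.asarray(force, float),
        protocol=pf.PullingProtocol(speed=speed, noise_sigma=0.0),
    )


# --------------------------------------------------------------------------
# Detection
# --------------------------------------------------------------------------

class TestDetectEvents:
    def test_flat_trace_has_no_events(self):
        trace = make_trace(np.linspace(0, 100, 200), np.zeros(200))
        assert pf.detect_events(trace) == []

    def test_window_larger_than_trace_rejected(self):
        trace = make_trace([0, 1, 2], [0, 0, 0])
        with pytest.raises(ValueError):
            pf.detect_events(trace, smoothing_window=10)

    def test_noiseless_events_match_truth_log(self, noiseless_trace):
        events = pf.detect_events(noiseless_trace)
        truth = noiseless_trace.truth_log
        assert len(events) == len(truth)
        dt = noiseless_trace.protocol.dt
        for e, t in zip(events, truth):
            assert e.peak_index == pytest.approx(t.time / dt - 1, abs=1)
            assert e.peak_force == pytest.approx(t.force, abs=1.0)

    def test_noisy_event_count_recovery_rate(self, specai41_construct):
        """With 8 pN noise and a 30 pN drop threshold, the detected event
        count equals the resolvable ground-truth count in >=95% of traces.

        Resolvable means ruptures strong enough to produce a drop above
        the threshold and not coincident with another rupture: the Bell
        model occasionally unfolds a domain at near-zero force or two in
        the same time step (one merged drop), which no drop detector can
        separate."""
        traces = pf.simulate_dfs_dataset(specai41_construct, [1000.0], 100,
                                         base_seed=17)

        def resolvable(trace):
            kept = []
            for e in trace.truth_log:
                if e.force < 45.0:
                    continue
                if kept and (e.time - kept[-1].time) < 10 * trace.protocol.dt:
                    continue
                kept.append(e)
            return kept

        hits = sum(
            len(pf.detect_events(t)) == len(resolvable(t)) for t in traces
        )
        assert hits >= 95


# --------------------------------------------------------------------------
# WLC fitting and increments
# --------------------------------------------------------------------------

class TestFitEventWlc:
    def test_self_fit_recovers_exact_contour_length(self, wlc_model):
        model = pf.WLCModel(persistence_length=0.4, contour_length=60.0)
        x = np.linspace(1.0, 55.0, 120)
        f = pf.wlc_force(x, model)
        trace = make_trace(x, f)
        event = UnfoldingEvent(peak_index=119, peak_force=float(f[-1]),
                               rupture_extension=55.0, segment_start=0)
        lc = pf.fit_event_wlc(trace, event)
        assert lc == pytest.approx(60.0, abs=1e-6)

    def test_noiseless_simulated_contour_lengths(self, noiseless_trace):
        events = pf.detect_events(noiseless_trace)
        construct = pf.construct_preset("specai41")
        # total contour before any unfolding
        lc0 = construct.linker_contour + sum(
            d.folded_length for d in construct.domains
        )
        first = pf.fit_event_wlc(noiseless_trace, events[0])
        assert first == pytest.approx(lc0, abs=0.5)

    def test_noisy_fit_is_unbiased_within_one_percent(self, analyzed_dataset):
        lcs = []
        construct = pf.construct_preset("specai41")
        lc0 = construct.linker_contour + sum(
            d.folded_length for d in construct.domains
        )
        for trace, events in analyzed_dataset:
            if events and len(trace.truth_log) == len(events):
                lcs.append(events[0].fitted_contour_length)
        assert len(lcs) >= 30
        assert np.mean(lcs) == pytest.approx(lc0, rel=0.01)

    def test_short_segment_flagged_unassigned(self):
        trace = make_trace(np.linspace(0, 5, 6), np.linspace(0, 50, 6))
        event = UnfoldingEvent(peak_index=5, peak_force=50.0,
                               rupture_extension=5.0, segment_start=0)
        assert pf.fit_event_wlc(trace, event) is None
        assert event.domain_label == "unassigned"


class TestComputeDeltaLc:
    def _events(self, lcs):
        return [
            UnfoldingEvent(peak_index=i, peak_force=100.0,
                           rupture_extension=lc - 10.0,
                           fitted_contour_length=lc)
            for i, lc in enumerate(lcs)
        ]

    def test_fingerprint_ladder_arithmetic(self):
        events = self._events([40.0, 58.0, 76.0, 94.0])
        pf.compute_delta_lc(events)
        assert [e.delta_lc_to_next for e in events[:-1]] == [
            pytest.approx(18.0)] * 3

    def test_fewer_than_two_events_gives_empty_result(self):
        assert pf.compute_delta_lc(self._events([40.0])) == []

    def test_negative_increment_flags_pair(self):
        events = self._events([40.0, 30.0])
        pf.compute_delta_lc(events)
        assert events[0].domain_label == "unassigned"
        assert events[1].domain_label == "unassigned"

    def test_simulated_construct_increments(self, noiseless_trace):
        events = pf.analyze_trace(noiseless_trace)
        deltas = sorted(
            round(e.delta_lc_to_next) for e in events
            if e.delta_lc_to_next is not None
        )
        assert deltas == [18, 18, 18, 53]


# --------------------------------------------------------------------------
# Selection
# --------------------------------------------------------------------------

def _synthetic_events(deltas, final_force):
    """Events whose increments are ``deltas`` followed by a final rupture."""
    lcs = np.cumsum([60.0] + list(deltas))
    events = [
        UnfoldingEvent(peak_index=i, peak_force=150.0,
                       rupture_extension=lc - 5, fitted_contour_length=float(lc))
        for i, lc in enumerate(lcs)
    ]
    events[-1].peak_force = final_force
    pf.compute_delta_lc(events)
    pf.label_events(events)
    return events


class TestSelectTraces:
    def _trace(self):
        return make_trace([0, 1], [0, 0])

    def test_three_fingerprints_then_handle_accepted(self):
        events = _synthetic_events([18, 18, 18], final_force=390.0)
        assert pf.select_traces([(self._trace(), events)]) != []

    def test_two_fingerprints_rejected(self):
        events = _synthetic_events([18, 18], final_force=390.0)
        assert pf.select_traces([(self._trace(), events)]) == []

    def test_weak_final_rupture_rejected(self):
        events = _synthetic_events([18, 18, 18], final_force=250.0)
        assert pf.select_traces([(self._trace(), events)]) == []

    def test_non_consecutive_fingerprints_rejected(self):
        # 18, 53, 18, 18: the target event splits the fingerprint run
        events = _synthetic_events([18, 53, 18, 18], final_force=390.0)
        assert pf.select_traces([(self._trace(), events)]) == []

    def test_target_after_run_still_accepted(self):
        events = _synthetic_events([18, 18, 18, 53], final_force=390.0)
        assert pf.select_traces([(self._trace(), events)]) != []


# --------------------------------------------------------------------------
# Calibration
# --------------------------------------------------------------------------

class TestCalibration:
    def _dataset(self, scale=1.0, n_events=60, seed=4):
        rng = np.random.default_rng(seed)
        forces = rng.normal(213.0, 25.0, n_events) * scale
        trace = make_trace([0, 1], [0, 0])
        events = [
            UnfoldingEvent(peak_index=i, peak_force=float(f),
                           rupture_extension=50.0, domain_label="fingerprint")
            for i, f in enumerate(forces)
        ]
        return [(trace, events)]

    def test_scale_factor_arithmetic(self):
        # fingerprint mean ~200 pN -> factor ~213/200
        ds = self._dataset(scale=200.0 / 213.0)
        _, factor = pf.calibrate_forces(ds)
        assert factor == pytest.approx(213.0 / 200.0, rel=0.03)

    def test_miscalibrated_dataset_recovers_reference(self):
        ds = self._dataset(scale=0.9)
        ds, _ = pf.calibrate_forces(ds)
        forces = [e.peak_force for _, ev in ds for e in ev]
        fit = pf.gaussian_fit_histogram(forces, 30.0)
        assert fit.mean == pytest.approx(213.0, abs=3 * max(fit.sem, 1.0))

    def test_idempotent(self):
        ds = self._dataset(scale=0.8)
        ds, f1 = pf.calibrate_forces(ds)
        ds, f2 = pf.calibrate_forces(ds)
        assert f2 == pytest.approx(1.0, abs=1e-9)

    def test_too_few_fingerprint_events_error_names_count(self):
        ds = self._dataset(n_events=5)
        with pytest.raises(ValueError, match="found 5"):
            pf.calibrate_forces(ds)

    def test_metadata_records_factor(self):
        ds = self._dataset(scale=0.5)
        ds, factor = pf.calibrate_forces(ds)
        assert ds[0][0].metadata["calibration_factor"] == pytest.approx(factor)


# --------------------------------------------------------------------------
# Loading rate
# --------------------------------------------------------------------------

class TestLoadingRate:
    def test_linear_regime_slope_times_speed(self):
        # a WLC in its low-extension linear regime with dF/dx = 0.05 pN/nm
        # pulled at 1000 nm/s loads at ~50 pN/s (the 50 pN/nm cantilever in
        # series is 1000x stiffer and barely corrects the slope)
        ctx = pf.PhysicalContext()
        lc = ctx.thermal_energy / 0.4 * 1.5 / 0.05
        trace = make_trace([0, 1], [0, 0], speed=1000.0)
        event = UnfoldingEvent(peak_index=1, peak_force=0.1,
                               rupture_extension=0.0,
                               fitted_contour_length=lc)
        assert pf.loading_rate(event, trace) == pytest.approx(50.0, rel=2e-3)

    def test_requires_fitted_contour_length(self):
        trace = make_trace([0, 1], [0, 0])
        event = UnfoldingEvent(peak_index=1, peak_force=1.0,
                               rupture_extension=0.5)
        with pytest.raises(ValueError):
            pf.loading_rate(event, trace)

    def test_doubling_speed_doubles_rate(self):
        event = UnfoldingEvent(peak_index=1, peak_force=100.0,
                               rupture_extension=60.0,
                               fitted_contour_length=80.0)
        r1 = pf.loading_rate(event, make_trace([0, 1], [0, 0], speed=1000.0))
        r2 = pf.loading_rate(event, make_trace([0, 1], [0, 0], speed=2000.0))
        assert r2 == pytest.approx(2 * r1, rel=1e-12)

    def test_analytic_slope_matches_finite_difference(self, noiseless_trace):
        events = pf.detect_events(noiseless_trace)
        e = events[0]
        lc = pf.fit_event_wlc(noiseless_trace, e)
        r = pf.loading_rate(e, noiseless_trace)
        # secant slope of the raw rising segment over the same 3 nm
        # window, composed with the cantilever spring in series
        x = noiseless_trace.extension
        f = noiseless_trace.force
        i = e.peak_index
        j = int(np.searchsorted(x[: i + 1], x[i] - 5.0))
        slope_fd = (f[i] - f[j]) / (x[i] - x[j])
        k = noiseless_trace.protocol.spring_constant
        r_fd = slope_fd * k / (slope_fd + k) * noiseless_trace.protocol.speed
        assert r == pytest.approx(r_fd, rel=0.05)


# --------------------------------------------------------------------------
# Full-chain invariant on noiseless data
# --------------------------------------------------------------------------

def test_noiseless_full_chain_reproduces_truth(specai41_construct):
    proto = pf.PullingProtocol(noise_sigma=0.0, seed=77)
    trace = pf.simulate_trace(specai41_construct, proto)
    events = pf.analyze_trace(trace)
    truth = trace.truth_log
    assert len(events) == len(truth)
    for e, t in zip(events, truth):
        assert e.peak_force == pytest.approx(t.force, abs=1.0)
    deltas = {
        truth[i].domain: events[i].delta_lc_to_next
        for i in range(len(events) - 1)
    }
    for name, delta in deltas.items():
        spec_delta = next(
            d.delta_lc for d in specai41_construct.domains if d.name == name
        )
        assert delta == pytest.approx(spec_delta, abs=0.5)
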