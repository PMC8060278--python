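"""Rip detection, unfolding-extension measurement, classification, binning."""

import numpy as np
import pytest

import aimforce as af
from aimforce.exceptions import ValidationError


def make_pull(presets, name="AIM-A1", state="cooperative", speed=200.0,
              seed=0, noise=0.3, **overrides):
    spec = presets[name]
    cfg = af.SimulationConfig(construct=spec, noise_sigma=noise, seed=seed,
                              **overrides)
    rng = np.random.default_rng(seed)
    return af.simulate_pull(spec, speed, state, rng, cfg)


class TestDetectEvents:
    def test_single_programmed_rupture(self, presets):
        trace, truth, _ = make_pull(presets, seed=3)
        events = af.detect_events(trace)
        assert len(events) == 1
        assert events[0].unfolding_force == pytest.approx(
            truth[0]["rupture_force_pN"], abs=0.5)
        assert abs(events[0].rupture_index - truth[0]["rupture_index"]) <= 2

    def test_featureless_ramp_yields_nothing(self, presets):
        trace, truth, _ = make_pull(presets, state="no_event", seed=4)
        assert truth == []
        assert af.detect_events(trace) == []

    def test_two_sequential_ruptures_in_order(self, presets):
        # find a seed whose two sub-module rips are well separated in force
        for seed in range(30):
            trace, truth, _ = make_pull(presets, state="two_sequential", seed=seed)
            forces = sorted(t["rupture_force_pN"] for t in truth if t["ruptured"])
            if len(forces) == 2 and forces[1] - forces[0] > 2.0 and forces[0] > 4.0:
                break
        events = af.detect_events(trace)
        assert len(events) == 2
        assert events[0].rupture_index < events[1].rupture_index
        got = [e.unfolding_force for e in events]
        assert got == pytest.approx(forces, abs=0.6)

    def test_detection_completeness_and_false_positives(self, presets):
        # >=95% of rips with force drop >= 5*sigma detected; <=1 false
        # positive per 100 rupture-free ramps
        n_hit = n_total = 0
        for seed in range(60):
            trace, truth, _ = make_pull(presets, seed=100 + seed)
            big = [t for t in truth if t["ruptured"]
                   and t["rupture_force_pN"] > 8.0]  # drop ~1.7 pN >= 5*0.3
            if not big:
                continue
            n_total += len(big)
            n_hit += min(len(af.detect_events(trace)), len(big))
        assert n_total >= 30
        assert n_hit / n_total >= 0.95
        fps = 0
        for seed in range(100):
            trace, _, _ = make_pull(presets, state="no_event", seed=500 + seed)
            fps += len(af.detect_events(trace))
        assert fps <= 1

    def test_relax_trace_rejected(self, presets):
        spec = presets["AIM-A1"]
        cfg = af.SimulationConfig(construct=spec, seed=0)
        rng = np.random.default_rng(0)
        relax, _ = af.simulate_relaxation(spec, 200.0, [], False, rng, cfg)
        with pytest.raises(ValidationError):
            af.detect_events(relax)


class TestMeasureUnfoldingExtension:
    @pytest.mark.parametrize("name,lc,lp", [
        ("AIM-A1", 26.6, 0.60),
        ("A1-CAIM", 13.1, 0.72),
    ])
    def test_matches_wlc_of_released_chain(self, presets, name, lc, lp):
        # the unfolding extension equals the WLC extension of the released
        # contour length at the rupture force (independent numerical inverse)
        trace, truth, _ = make_pull(presets, name=name, seed=11, noise=0.0)
        events = af.detect_events(trace)
        assert len(events) == 1
        ext = af.measure_unfolding_extension(trace, events[0])
        f_u = truth[0]["rupture_force_pN"]
        oracle = af.wlc_extension(af.WLCParams(lc, lp), f_u)
        # within two extension sample intervals
        dx = 2 * trace.pulling_speed / trace.sampling_rate
        assert ext == pytest.approx(oracle, abs=max(2 * dx, 0.15))

    def test_noisy_measurement_close(self, presets):
        trace, truth, _ = make_pull(presets, seed=3)
        ev = af.detect_events(trace)[0]
        ext = af.measure_unfolding_extension(trace, ev)
        assert ext == pytest.approx(truth[0]["extension_jump_nm"], abs=1.0)

    def test_force_never_reestablished_flagged(self, presets):
        trace, truth, _ = make_pull(presets, seed=3, noise=0.0)
        ev = af.detect_events(trace)[0]
        short = af.ForceExtensionTrace(
            time=trace.time[:ev.rupture_index + 10],
            force=trace.force[:ev.rupture_index + 10],
            extension=trace.extension[:ev.rupture_index + 10],
            direction="pull", pulling_speed=trace.pulling_speed,
            tether_id="t", cycle=0, sampling_rate=trace.sampling_rate)
        with pytest.raises(af.MeasurementError):
            af.measure_unfolding_extension(short, ev)


class TestClassifyCycle:
    def _event(self, force, ext):
        return af.UnfoldingEvent(rupture_index=100, unfolding_force=force,
                                 loading_rate=20.0, tether_id="t", cycle=0,
                                 unfolding_extension=ext)

    def test_single_long(self):
        # 16.7 nm at 15 pN sits above the ~12.9 nm midpoint-WLC boundary
        assert af.classify_cycle([self._event(15.0, 16.7)]).label == "single_long"

    def test_two_short(self):
        evs = [self._event(10.0, 8.0), self._event(14.0, 8.2)]
        assert af.classify_cycle(evs).label == "two_short"

    def test_single_short(self):
        assert af.classify_cycle([self._event(15.0, 8.5)]).label == "single_short"

    def test_no_event(self):
        assert af.classify_cycle([]).label == "no_event"

    def test_more_than_two_events_unclassified(self):
        evs = [self._event(8.0, 5.0), self._event(10.0, 5.0), self._event(12.0, 5.0)]
        assert af.classify_cycle(evs).label == "unclassified"

    def test_boundary_adapts_to_force(self):
        # 13 nm is long at 10 pN but short at 25 pN (boundary grows with force)
        assert af.classify_cycle([self._event(10.0, 13.0)]).label == "single_long"
        assert af.classify_cycle([self._event(25.0, 13.0)]).label == "single_short"


class TestDetectRefolding:
    def test_programmed_refold_detected(self, presets):
        spec = presets["AIM-A1"]
        cfg = af.SimulationConfig(construct=spec, seed=0)
        rng = np.random.default_rng(1)
        relax, present = af.simulate_relaxation(
            spec, 200.0, [spec.units[0]], True, rng, cfg)
        assert present
        assert af.detect_refolding(relax)

    def test_smooth_relaxation_negative(self, presets):
        spec = presets["AIM-A1"]
        cfg = af.SimulationConfig(construct=spec, seed=0)
        rng = np.random.default_rng(2)
        relax, present = af.simulate_relaxation(
            spec, 200.0, [spec.units[0]], False, rng, cfg)
        assert not present
        assert not af.detect_refolding(relax)

    def test_refold_frequency_recovered(self, presets):
        # Bernoulli refolds at the configured rate are recovered within the
        # exact binomial 95% interval
        spec = presets["AIM-A1"]
        cfg = af.SimulationConfig(construct=spec, seed=0)
        rng = np.random.default_rng(3)
        n, p = 400, spec.refold_probability
        hits = 0
        for _ in range(n):
            refold = bool(rng.random() < p)
            relax, _ = af.simulate_relaxation(
                spec, 400.0, [spec.units[0]], refold, rng, cfg)
            hits += af.detect_refolding(relax)
        from scipy.stats import binom
        lo, hi = binom.interval(0.95, n, p)
        assert lo <= hits <= hi


class TestBinExtensionsByForce:
    def _events(self, forces, exts):
        return [af.UnfoldingEvent(0, f, 20.0, "t", 0, unfolding_extension=e)
                for f, e in zip(forces, exts)]

    def test_identical_extensions(self):
        evs = self._events([15.0] * 50, [16.7] * 50)
        (b,) = af.bin_extensions_by_force(evs, 2.0)
        assert b.peak_extension == pytest.approx(16.7)
        assert b.count == 50
        assert b.uncertainty == pytest.approx(0.0, abs=1e-9)

    def test_gaussian_population(self, rng):
        exts = rng.normal(16.7, 1.0, 200)
        evs = self._events(np.full(200, 15.0), exts)
        (b,) = af.bin_extensions_by_force(evs, 2.0)
        assert b.peak_extension == pytest.approx(16.7, abs=0.2)
        assert b.fwhm == pytest.approx(2.355, abs=0.4)
        assert b.uncertainty == pytest.approx(b.fwhm / np.sqrt(200), rel=1e-9)
        assert not b.low_count

    def test_two_bins_ordered_by_force(self, rng):
        evs = self._events([9.0] * 30 + [15.0] * 30,
                           list(rng.normal(8, 0.5, 30)) + list(rng.normal(16, 0.5, 30)))
        bins = af.bin_extensions_by_force(evs, 2.0)
        assert [b.force_bin_center for b in bins] == [9.0, 15.0]

    def test_low_count_fallback_flagged(self):
        evs = self._events([15.0, 15.2, 15.4], [16.0, 16.5, 17.0])
        (b,) = af.bin_extensions_by_force(evs, 2.0)
        assert b.low_count
        assert b.peak_extension == pytest.approx(16.5)

    def test_empty_rejected(self):
        with pytest.raises(ValidationError):
            af.bin_extensions_by_force([], 2.0)


class TestTraceValidation:
    def test_bad_lengths_rejected(self):
        with pytest.raises(ValidationError):
            af.ForceExtensionTrace(np.arange(10), np.zeros(9), np.zeros(10),
                                   "pull", 200.0, "t", 0, 1000.0)

    def test_nonmonotone_time_rejected(self):
        t = np.arange(10.0)
        t[5] = t[4]
        with pytest.raises(ValidationError):
            af.ForceExtensionTrace(t, np.zeros(10), np.zeros(10),
                                   "pull", 200.0, "t", 0, 1000.0)
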