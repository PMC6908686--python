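"""State classification, event detection, occupancy and the
conformational-selection statistic."""

import warnings

import numpy as np
import pytest

from glycotraj import states, synthetic_data
from glycotraj.profiles import RMSDProfile
from glycotraj.states import (
    BindingEvent,
    BindingStateSeries,
    StateThresholds,
    bound_fraction,
    classify_frames,
    detect_events,
    pre_binding_conformation_fraction,
)


def constant_profiles(value, n=100, dt=1.0):
    times = np.arange(n) * dt
    return {
        "red": RMSDProfile(times, np.full(n, value), ("ligand", "red")),
        "green": RMSDProfile(times, np.full(n, value + 0.3), ("ligand", "green")),
    }


def profile_map_from_min(values, dt=1.0):
    times = np.arange(len(values)) * dt
    return {"red": RMSDProfile(times, np.asarray(values, dtype=float), ("ligand", "red"))}


def series_from_labels(labels, dt=1.0):
    labels = np.asarray(labels, dtype=object).astype(str)
    return BindingStateSeries(
        times=np.arange(len(labels)) * dt,
        state=labels,
        best_subsite=np.full(len(labels), "red"),
    )


class TestClassifyFrames:
    @pytest.mark.parametrize(
        "value,expected",
        [(5.0, "unbound"), (1.5, "nonspecific"), (0.2, "specific")],
    )
    def test_constant_bands(self, value, expected):
        series = classify_frames(constant_profiles(value))
        assert set(series.state) == {expected}

    def test_hysteresis_holds_state_at_boundary(self):
        # dips just past the specific boundary but within the hysteresis band
        values = [0.3, 0.55, 0.3, 0.65, 0.3]
        series = classify_frames(profile_map_from_min(values), StateThresholds(hysteresis=0.1))
        assert list(series.state) == [
            "specific", "specific", "specific", "nonspecific", "specific"
        ]

    def test_best_subsite_tracks_minimum(self):
        times = np.arange(3.0)
        pmap = {
            "red": RMSDProfile(times, np.array([0.1, 2.0, 2.0]), ("ligand", "red")),
            "green": RMSDProfile(times, np.array([2.0, 0.2, 2.0]), ("ligand", "green")),
        }
        series = classify_frames(pmap)
        assert list(series.best_subsite[:2]) == ["red", "green"]

    def test_monotone_lowering_rmsd_never_unbinds(self):
        rng = np.random.default_rng(11)
        values = rng.uniform(0.1, 5.0, size=200)
        base = classify_frames(profile_map_from_min(values))
        lowered = classify_frames(profile_map_from_min(values * 0.5))
        order = {"specific": 0, "nonspecific": 1, "unbound": 2}
        assert all(
            order[lo] <= order[hi] for lo, hi in zip(lowered.state, base.state)
        )

    def test_empty_profiles_rejected(self):
        with pytest.raises(ValueError):
            classify_frames({})


class TestDetectEvents:
    def test_single_sustained_switch(self):
        labels = ["unbound"] * 100 + ["specific"] * 100
        events = detect_events(series_from_labels(labels), min_dwell=10)
        assert len(events) == 1
        assert events[0].kind == "binding"
        assert events[0].time == 100.0

    def test_short_flicker_filtered(self):
        labels = ["nonspecific"] * 50 + ["specific"] * 2 + ["nonspecific"] * 50
        events = detect_events(series_from_labels(labels), min_dwell=10)
        assert events == []

    def test_no_dwell_filter_equals_naive_scan_oracle(self):
        rng = np.random.default_rng(12)
        values = rng.uniform(0.1, 5.0, size=300)
        pmap = profile_map_from_min(values)
        thresholds = StateThresholds(hysteresis=0.0, min_dwell=0.0)
        series = classify_frames(pmap, thresholds)
        events = detect_events(series, min_dwell=0.0)
        # oracle: raw thresholding and a linear scan for specific crossings
        raw = np.where(values <= 0.5, "specific", np.where(values >= 4.0, "unbound", "nonspecific"))
        expected = []
        for i in range(1, len(raw)):
            if raw[i] == raw[i - 1]:
                continue
            if raw[i] == "specific":
                expected.append(("binding", float(i)))
            elif raw[i - 1] == "specific":
                expected.append(("unbinding", float(i)))
        assert [(e.kind, e.time) for e in events] == expected

    def test_ctmc_event_times_within_one_frame(self, toy_system):
        from glycotraj import validation

        trajectory, truth = synthetic_data.simulate_binding_trajectory(
            toy_system, synthetic_data.two_state_scheme(), duration=2000.0, seed=0
        )
        from glycotraj.pipeline import analyze_trajectory

        result = analyze_trajectory(
            trajectory, toy_system.reference, toy_system.moieties,
            StateThresholds(min_dwell=0.0), compute_interactions=False,
        )
        tev = validation.true_events(truth)
        assert len(tev) > 20
        match = validation.event_match_fraction(tev, result.events, tolerance=1.0)
        assert match >= 0.9


class TestBoundFraction:
    def test_all_specific_is_one(self):
        assert bound_fraction(series_from_labels(["specific"] * 10)) == 1.0

    def test_exact_counting(self):
        labels = ["specific"] * 60 + ["unbound"] * 40
        assert bound_fraction(series_from_labels(labels)) == pytest.approx(0.60)

    def test_all_labels_is_exactly_one(self):
        rng = np.random.default_rng(13)
        labels = rng.choice(["specific", "nonspecific", "unbound"], size=50)
        series = series_from_labels(labels)
        assert bound_fraction(series, set(states.STATE_LABELS)) == 1.0

    def test_ctmc_stationary_occupancy_recovered(self, toy_system):
        scheme = synthetic_data.two_state_scheme()
        target = synthetic_data.stationary_occupancy(scheme)
        trajectory, truth = synthetic_data.simulate_binding_trajectory(
            toy_system, scheme, duration=2000.0, seed=5
        )
        # truth path itself must satisfy the tolerance for the analytic target
        empirical = np.mean(truth.frame_states == "specific")
        assert abs(empirical - target) < 0.05


class TestPreBindingFraction:
    def test_constant_low_profile_fraction_one(self):
        profile = RMSDProfile(np.arange(200.0), np.full(200, 0.2), ("binding_residues", "initial"))
        events = [BindingEvent("binding", 150.0, "nonspecific", "specific")]
        assert pre_binding_conformation_fraction(profile, events) == [1.0]

    def test_constant_high_profile_fraction_zero(self):
        profile = RMSDProfile(np.arange(200.0), np.full(200, 0.5), ("binding_residues", "initial"))
        events = [BindingEvent("binding", 150.0, "nonspecific", "specific")]
        assert pre_binding_conformation_fraction(profile, events) == [0.0]

    def test_known_two_state_occupancy_recovered(self):
        rng = np.random.default_rng(14)
        n = 2000
        low = rng.random(n) < 0.7  # closed 70% of the time
        values = np.where(low, 0.15, 0.4)
        profile = RMSDProfile(np.arange(float(n)), values, ("binding_residues", "initial"))
        events = [BindingEvent("binding", t, "nonspecific", "specific") for t in (300.0, 900.0, 1500.0)]
        fractions = pre_binding_conformation_fraction(profile, events, window=200.0)
        assert np.allclose(np.mean(fractions), 0.7, atol=0.1)

    def test_no_binding_events_warns_and_returns_empty(self):
        profile = RMSDProfile(np.arange(10.0), np.full(10, 0.2), ("binding_residues", "initial"))
        with warnings.catch_warnings(record=True) as caught:
            warnings.simplefilter("always")
            assert pre_binding_conformation_fraction(profile, []) == []
        assert any("no binding events" in str(w.message) for w in caught)


class TestConformationalSelectionEndToEnd:
    def test_gated_binding_shows_high_pre_binding_occupancy(self, toy_system):
        from glycotraj.pipeline import analyze_trajectory

        toggle = synthetic_data.ConformationToggle(gates_binding=True)
        trajectory, truth = synthetic_data.simulate_binding_trajectory(
            toy_system, synthetic_data.two_state_scheme(), duration=1500.0,
            seed=21, toggle=toggle,
        )
        result = analyze_trajectory(
            trajectory, toy_system.reference, toy_system.moieties,
            StateThresholds(min_dwell=0.0), compute_interactions=False,
            pre_binding_window=20.0,
        )
        assert len(result.pre_binding_fractions) >= 5
        # binding only happens from the closed conformation, so shortly before
        # each binding event the binding site should mostly look closed
        assert np.mean(result.pre_binding_fractions) > 0.6
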