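import numpy as np
import pandas as pd
import pytest

from ruttrack import bbmm
from ruttrack.evaluation import (
    EventStateSummary,
    EventUDSummary,
    consistency_report,
    event_state_summary,
    event_ud_summary,
    label_event_hours,
    modal_state_agreement,
    permutation_baseline,
)
from ruttrack.hmm import StateSequence
from ruttrack.interaction import InteractionEvent, detect_events
from ruttrack.regularize import interpolate_hourly
from ruttrack.synthetic import Scenario, simulate_pair
from ruttrack.trajectory import align_dyad

from conftest import make_track


def _event(start, end, male="M", female="F", fixes=None, dist=50.0):
    start, end = pd.Timestamp(start), pd.Timestamp(end)
    return InteractionEvent(male, female, start, end,
                            fixes if fixes is not None else pd.DataFrame(),
                            dist, (end - start).total_seconds() / 3600)


def _sequence(states, start="2015-11-01", animal="M"):
    states = np.asarray(states)
    ts = pd.Series(pd.Timestamp(start) + pd.to_timedelta(np.arange(len(states)), unit="h"))
    return StateSequence(animal, ts, states)


class TestLabelEventHours:
    def _reg(self, n=48):
        return interpolate_hourly(
            make_track(np.zeros((n, 2)), start="2015-11-01"), delta=0.0
        )

    def test_inclusive_endpoints(self):
        flags = label_event_hours(_event("2015-11-01 10:00", "2015-11-01 13:00"),
                                  self._reg())
        assert flags.sum() == 4

    def test_single_hour_event(self):
        flags = label_event_hours(_event("2015-11-01 05:00", "2015-11-01 05:00"),
                                  self._reg())
        assert flags.sum() == 1

    def test_outside_span_errors(self):
        with pytest.raises(ValueError, match="outside"):
            label_event_hours(_event("2015-12-01", "2015-12-02"), self._reg())

    def test_dyad_events_never_share_hours(self, distinct_run):
        """Detected events for one dyad are disjoint, so their flagged hour
        sets never intersect."""
        male = distinct_run["male"]
        reg = interpolate_hourly(male, delta=0.0)
        total = np.zeros(len(reg), dtype=int)
        for ev in distinct_run["events"]:
            total += label_event_hours(ev, reg).astype(int)
        assert total.max() <= 1


class TestEventUDSummary:
    def test_mean_of_volumes(self):
        # three cells with known volumes 10/20/30 at x=15/45/75
        mass = np.array([[0.9], [0.09], [0.009], [0.001]])  # cells along x
        vol = bbmm.ud_volume(bbmm.UDGrid((0, 0), 30.0, mass))
        fixes = pd.DataFrame({"xa": [15.0, 45.0, 75.0], "ya": [15.0] * 3,
                              "xb": [0.0] * 3, "yb": [0.0] * 3})
        ev = _event("2015-11-01", "2015-11-01 02:00", fixes=fixes)
        (summary,) = event_ud_summary([ev], {"M": vol}, sex="male")
        np.testing.assert_allclose(summary.volumes, [90.0, 99.0, 99.9])
        assert summary.mean_volume == pytest.approx(np.mean([90.0, 99.0, 99.9]))
        assert summary.mean_distance == 50.0

    def test_fix_at_mode_gets_grid_minimum(self):
        x = np.arange(-5, 6)
        X, Y = np.meshgrid(x, x, indexing="ij")
        mass = np.exp(-(X**2 + Y**2) / 6.0)
        vol = bbmm.ud_volume(bbmm.UDGrid((-165.0, -165.0), 30.0, mass / mass.sum()))
        fixes = pd.DataFrame({"xa": [0.0], "ya": [0.0], "xb": [0.0], "yb": [0.0]})
        (s,) = event_ud_summary([_event("2015-11-01", "2015-11-01", fixes=fixes)],
                                {"M": vol}, sex="male")
        assert s.volumes[0] == pytest.approx(vol.volume.min())

    def test_outside_grid_recorded_missing(self):
        vol = bbmm.ud_volume(bbmm.UDGrid((0, 0), 30.0, np.ones((2, 2)) / 4))
        fixes = pd.DataFrame({"xa": [15.0, 500.0], "ya": [15.0, 15.0],
                              "xb": [0, 0], "yb": [0, 0]})
        with pytest.warns(UserWarning):
            (s,) = event_ud_summary([_event("2015-11-01", "2015-11-01 01:00",
                                            fixes=fixes)], {"M": vol})
        assert np.isnan(s.volumes[1]) and np.isfinite(s.mean_volume)

    def test_tending_male_confined_to_female_core(self):
        """Stationary-female scenario: the male tending at her range core
        concentrates his own UD there, so his per-event mean volume < 50%."""
        scen = Scenario(seed=5, mode="stationary-female", n_events=8)
        male, female, truth = simulate_pair(scen)
        events = detect_events(align_dyad(male, female))
        assert events
        s2 = bbmm.fit_sigma2_m(male, delta=10.0)
        vol = bbmm.ud_volume(bbmm.compute_ud(male, bbmm.BBMMParams(s2, 10.0)))
        summaries = event_ud_summary(events, {male.animal_id: vol}, sex="male")
        assert np.mean([s.mean_volume for s in summaries]) < 50.0


class TestEventStateSummary:
    def test_split_event_ties_to_lower_state(self):
        seq = _sequence([1, 1, 2, 2, 1, 1])
        (s,) = event_state_summary(
            [_event("2015-11-01 00:00", "2015-11-01 03:00")], {"M": seq}, 2)
        np.testing.assert_allclose(s.proportions, [0.5, 0.5])
        assert s.modal_state == 1

    def test_pure_state_event(self):
        seq = _sequence([2, 2, 2, 2])
        (s,) = event_state_summary(
            [_event("2015-11-01 00:00", "2015-11-01 03:00")], {"M": seq}, 2)
        np.testing.assert_allclose(s.proportions, [0.0, 1.0])
        assert s.modal_state == 2

    def test_proportions_sum_to_one(self):
        seq = _sequence(np.r_[np.ones(5, int), 3 * np.ones(4, int), [2]])
        (s,) = event_state_summary(
            [_event("2015-11-01 00:00", "2015-11-01 09:00")], {"M": seq}, 3)
        assert s.proportions.sum() == pytest.approx(1.0)
        assert s.modal_state == 1


class TestConsistencyReport:
    def _ud(self, volumes, eid=0):
        v = np.asarray(volumes, float)
        return EventUDSummary(eid, "M", "male", "season", v, float(v.mean()),
                              50.0, 4.0)

    def _st(self, props, eid=0):
        p = np.asarray(props, float)
        return EventStateSummary(eid, "M", len(p), p, int(np.argmax(p)) + 1)

    def test_all_core_locations_sweep(self):
        """Every volume <= 30 reproduces the success pattern: the 30-contour
        captures all event locations."""
        rep = consistency_report(ud_summaries=[self._ud([5, 12, 28]),
                                               self._ud([22, 30], eid=1)])
        sweep = {row["v"]: row for row in rep["ud"]["threshold_sweep"]}
        assert sweep[30]["frac_le"] == 1.0
        assert sweep[25]["frac_le"] == pytest.approx(3 / 5)

    def test_sweep_monotone(self):
        rng = np.random.default_rng(0)
        summaries = [self._ud(rng.uniform(1, 100, 5), eid=i) for i in range(6)]
        rep = consistency_report(ud_summaries=summaries)
        le = [r["frac_le"] for r in rep["ud"]["threshold_sweep"]]
        ge = [r["frac_ge"] for r in rep["ud"]["threshold_sweep"]]
        assert (np.diff(le) >= 0).all() and (np.diff(ge) <= 0).all()

    def test_modal_agreement(self):
        summaries = [self._st(p, eid=i) for i, p in
                     enumerate([[0.8, 0.2], [0.7, 0.3], [0.2, 0.8], [0.1, 0.9]])]
        rep = consistency_report(state_summaries=summaries)
        assert rep["hmm"]["modal_state_agreement"] == 0.5
        assert modal_state_agreement(summaries) == 0.5

    def test_empty_raises(self):
        with pytest.raises(ValueError):
            consistency_report()


class TestPermutationBaseline:
    def test_null_distribution_covers_random_labels(self):
        """With i.i.d.-ish decoded states, observed agreement from arbitrary
        event placement is typical of the permutation distribution."""
        rng = np.random.default_rng(0)
        seq = _sequence(rng.integers(1, 3, 2000))
        events = [_event(f"2015-11-0{d} 00:00", f"2015-11-0{d} 07:00")
                  for d in range(1, 6)]
        stsum = event_state_summary(events, {"M": seq}, 2)
        obs = modal_state_agreement(stsum)
        null = permutation_baseline(events, {"M": seq}, 2,
                                    n_permutations=199, seed=1)
        assert null.shape == (199,)
        assert (null >= obs - 0.4).mean() > 0.5  # obs well inside the null range
        assert null.min() >= 1 / 2 - 1e-9 and null.max() <= 1.0

    def test_deterministic_given_seed(self):
        seq = _sequence(np.tile([1, 2], 500))
        events = [_event("2015-11-01 00:00", "2015-11-01 05:00")]
        a = permutation_baseline(events, {"M": seq}, 2, n_permutations=50, seed=7)
        b = permutation_baseline(events, {"M": seq}, 2, n_permutations=50, seed=7)
        np.testing.assert_array_equal(a, b)
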