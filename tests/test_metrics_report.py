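"""Walking metrics: distances, shares, weighted quantiles, Kruskal-Wallis."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy import stats

from tripwalk.errors import UndefinedRateError
from tripwalk.metrics_report import (attribution_shares, build_metrics_table,
                                     distance_walked_per_trip, kruskal_wallis,
                                     per_day_cumulations, quantile_summary,
                                     urbanicity_strata, walking_intensity,
                                     weighted_quantiles)
from tripwalk.trip_classification import AnalyzedTrip, classify_trips

from conftest import make_stage, make_transfer


def _trip(modes_lengths, trip_id="T1", pid="P", day=0, start=36_000.0, steps=0.0):
    segs = []
    t = start
    for k, (mode, length) in enumerate(modes_lengths):
        if k > 0:
            segs.append(make_transfer(t, t + 60.0, pid=pid, day=day, trip_id=trip_id,
                                      steps=0.0))
            t += 60.0
        dur = 600.0
        segs.append(make_stage(mode, t, t + dur, length, pid=pid, day=day,
                               trip_id=trip_id, steps=steps))
        t += dur
    return AnalyzedTrip(trip_id, pid, day, segs)


class TestWeightedQuantiles:
    def test_unit_weights_match_type1_quantiles(self):
        rng = np.random.default_rng(0)
        for _ in range(5):
            v = rng.normal(size=17)
            for q in (0.1, 0.25, 0.5, 0.9):
                w = weighted_quantiles(v, np.ones_like(v), [q])[0]
                sv = np.sort(v)
                # inverse-CDF: smallest x with F(x) >= q
                expected = sv[int(np.ceil(q * len(v))) - 1] if q > 0 else sv[0]
                assert w == expected

    def test_degenerate_weight_mass(self):
        v = np.array([5.0, 1.0, 9.0])
        w = np.array([0.0, 1.0, 0.0])
        out = weighted_quantiles(v, w, [0.1, 0.5, 0.9])
        assert (out == 1.0).all()

    @given(st.integers(0, 10_000))
    @settings(max_examples=30, deadline=None)
    def test_matches_weight_expansion_bruteforce(self, seed):
        rng = np.random.default_rng(seed)
        n = int(rng.integers(1, 12))
        v = rng.normal(size=n)
        w = rng.integers(1, 5, size=n)
        probs = [0.1, 0.5, 0.9]
        expanded = np.sort(np.repeat(v, w))
        ours = weighted_quantiles(v, w.astype(float), probs)
        for q, x in zip(probs, ours):
            brute = expanded[int(np.ceil(q * len(expanded))) - 1]
            assert x == brute

    def test_domain_errors(self):
        with pytest.raises(ValueError):
            weighted_quantiles([1.0], [-1.0], [0.5])
        with pytest.raises(ValueError):
            weighted_quantiles([1.0], [0.0], [0.5])
        with pytest.raises(ValueError):
            weighted_quantiles([1.0], [1.0], [1.5])

    def test_summary_ordering_invariant(self):
        s = quantile_summary([3.0, 1.0, 2.0, 5.0], [1, 1, 1, 1])
        assert s.p10 <= s.median <= s.p90


class TestDistanceWalked:
    def test_entirely_walked_trip(self):
        trip = _trip([("walk", 400.0)])
        assert distance_walked_per_trip(trip) == pytest.approx(400.0, rel=1e-6)

    def test_pure_car_trip_walks_nothing(self):
        trip = _trip([("car_driver", 8_000.0)])
        assert distance_walked_per_trip(trip) == 0.0

    def test_pt_trip_sums_access_and_egress_walks(self):
        """walk 0.30 km + metro + walk 0.55 km => 0.85 km walked."""
        trip = _trip([("walk", 300.0), ("metro", 4_000.0), ("walk", 550.0)])
        assert distance_walked_per_trip(trip) == pytest.approx(850.0, rel=1e-6)
        assert trip.distance_m == pytest.approx(4_850.0, rel=1e-6)


class TestAttributionShares:
    def _table(self, trips):
        return build_metrics_table(classify_trips(trips))

    def test_single_class_gets_all(self):
        table = self._table([_trip([("walk", 500.0)])])
        shares = attribution_shares(table, "distance_walked")
        assert shares.to_dict() == {"entirely_walked": 100.0}

    def test_three_to_one_split(self):
        table = self._table([
            _trip([("walk", 3000.0)], trip_id="T1"),
            _trip([("walk", 1000.0), ("metro", 5000.0)], trip_id="T2", start=60_000.0),
        ])
        shares = attribution_shares(table, "distance_walked")
        assert shares["entirely_walked"] == pytest.approx(75.0)
        assert shares["public_transport"] == pytest.approx(25.0)

    def test_shares_sum_to_100(self, noisy_study):
        for metric in ("distance_walked", "steps"):
            for scheme in ("crude", "detailed"):
                shares = attribution_shares(noisy_study.metrics, metric, scheme)
                assert shares.sum() == pytest.approx(100.0, abs=1e-9)

    def test_empty_table_raises(self):
        with pytest.raises(UndefinedRateError):
            attribution_shares(build_metrics_table([]), "distance_walked")

    def test_per_day_cumulations_include_zero_users(self):
        trips = [_trip([("walk", 500.0)], pid="A", trip_id="T1"),
                 _trip([("car_driver", 900.0)], pid="B", trip_id="T2")]
        pv = per_day_cumulations(self._table(trips), "distance_walked_km")
        # participant B never walks entirely: the zero must be present
        assert pv.loc[("B", 0), "entirely_walked"] == 0.0


class TestWalkingIntensity:
    def test_speed_and_cadence_units(self):
        # 1 km in 12 min => 5 km/h; 900 steps in 10 min => 90 steps/min
        segs = [make_stage("walk", 0.0, 720.0, 1000.0, steps=0.0)]
        trip = AnalyzedTrip("T1", "P", 0, segs)
        classify_trips([trip])
        out = walking_intensity([trip])
        assert out.loc["entirely_walked", "speed_median"] == pytest.approx(5.0, rel=1e-6)
        seg2 = [make_stage("walk", 0.0, 600.0, 800.0, steps=900.0)]
        trip2 = AnalyzedTrip("T2", "P", 0, seg2)
        classify_trips([trip2])
        out2 = walking_intensity([trip2])
        assert out2.loc["entirely_walked", "cadence_median"] == pytest.approx(90.0, rel=1e-6)

    def test_pt_access_walks_are_brisker_by_construction(self, noisy_study):
        """The generator walks faster to stations than on errands; the
        distance-weighted speed summary must preserve that ordering."""
        out = walking_intensity(noisy_study.trips)
        assert out.loc["public_transport_all", "speed_median"] > \
            out.loc["entirely_walked", "speed_median"]


class TestKruskalWallis:
    def test_identical_groups_give_zero(self):
        h, p = kruskal_wallis([[2.0, 2.0], [2.0, 2.0]])
        assert h == 0.0 and p == 1.0

    def test_hand_computed_rank_sums(self):
        """{1,2,3} vs {4,5,6}: rank means 2 and 5, H = 12/42 * 2*3*1.5^2."""
        h, p = kruskal_wallis([[1.0, 2.0, 3.0], [4.0, 5.0, 6.0]])
        assert h == pytest.approx(27.0 / 7.0, abs=1e-12)
        assert p == pytest.approx(float(stats.chi2.sf(27.0 / 7.0, 1)), abs=1e-12)

    @pytest.mark.parametrize("seed", [1, 2, 3])
    def test_matches_reference_implementation(self, seed):
        rng = np.random.default_rng(seed)
        groups = [rng.integers(0, 20, size=rng.integers(5, 15)).astype(float)
                  for _ in range(3)]
        h, p = kruskal_wallis(groups)
        ref = stats.kruskal(*groups)
        assert h == pytest.approx(ref.statistic, abs=1e-10)
        assert p == pytest.approx(ref.pvalue, abs=1e-10)

    def test_rejects_degenerate_input(self):
        with pytest.raises(ValueError):
            kruskal_wallis([[1.0]])


class TestUrbanicityStrata:
    def test_single_zone_equals_unstratified(self):
        trips = [_trip([("walk", 500.0)], pid="A", trip_id="T1"),
                 _trip([("walk", 900.0), ("metro", 3000.0)], pid="A", trip_id="T2",
                       start=60_000.0)]
        table = build_metrics_table(classify_trips(trips),
                                    zones={"A": "core_city"})
        out = urbanicity_strata(table)
        assert list(out["zones"]) == ["core_city"]
        overall = attribution_shares(table, "distance_walked")
        assert out["zones"]["core_city"]["shares_pct"] == \
            pytest.approx(overall.to_dict())

    def test_two_zone_toy_medians_equal_hand_computation(self):
        trips = [
            _trip([("walk", 1000.0)], pid="A", trip_id="T1"),
            _trip([("walk", 3000.0)], pid="A", trip_id="T2", start=60_000.0),
            _trip([("walk", 500.0)], pid="B", trip_id="T3"),
        ]
        table = build_metrics_table(classify_trips(trips),
                                    zones={"A": "core_city", "B": "far_suburb"})
        out = urbanicity_strata(table)
        assert out["zones"]["core_city"]["median_distance_walked_km_per_day"] == \
            pytest.approx(4.0)  # one participant-day totalling 4 km
        assert out["zones"]["far_suburb"]["median_distance_walked_km_per_day"] == \
            pytest.approx(0.5)


def test_trip_steps_conserved_across_segments(noise_free_study):
    """Steps over the entire trip equal stage steps plus transfer steps."""
    for trip in noise_free_study.trips:
        if trip.excluded:
            continue
        total = np.nansum([s.steps for s in trip.segments])
        stages = np.nansum([s.steps for s in trip.segments if s.kind == "trip_stage"])
        transfers = np.nansum([s.steps for s in trip.segments if s.kind == "transfer"])
        assert total == pytest.approx(stages + transfers)
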