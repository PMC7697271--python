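"""Nest identity resolution, occupation intervals, Kaplan-Meier and
log-rank comparisons."""

import numpy as np
import pandas as pd
import pytest

from hogwatch import nesting


def nest_records(rows):
    """rows: (individual, date, east, north) or (individual, date, nest)."""
    out = []
    for r in rows:
        if len(r) == 4:
            out.append({"individual_id": r[0], "date": pd.Timestamp(r[1]),
                        "east": float(r[2]), "north": float(r[3])})
        else:
            out.append({"individual_id": r[0], "date": pd.Timestamp(r[1]),
                        "canonical_nest_id": r[2]})
    return pd.DataFrame(out)


def km_oracle(durations, observed):
    """Independent product-limit computation."""
    times = np.unique(durations[observed.astype(bool)])
    s = 1.0
    out = {}
    for t in times:
        n = np.sum(durations >= t)
        d = np.sum((durations == t) & observed.astype(bool))
        s *= 1 - d / n
        out[t] = s
    return out


class TestResolveIdentity:
    @pytest.mark.parametrize("offset,merged", [(1.5, True), (2.0, True),
                                               (2.5, False)])
    def test_two_metre_vicinity_rule(self, offset, merged):
        rec = nest_records([("a", "2016-08-10", 0, 0),
                            ("a", "2016-08-11", offset, 0)])
        out = nesting.resolve_nest_identity(rec)
        same = out["canonical_nest_id"].nunique() == 1
        assert same is merged

    def test_resolution_is_per_individual(self):
        rec = nest_records([("a", "2016-08-10", 0, 0),
                            ("b", "2016-08-10", 0.5, 0)])
        out = nesting.resolve_nest_identity(rec)
        assert out["canonical_nest_id"].nunique() == 2


class TestSparseIndividuals:
    def _with_n_nests(self, n):
        return nest_records([("a", f"2016-08-{10+i:02d}", f"N{i}")
                             for i in range(n)])

    def test_four_nests_removed_five_retained(self):
        kept, removed = nesting.exclude_sparse_individuals(self._with_n_nests(4))
        assert removed == ["a"] and kept.empty
        kept, removed = nesting.exclude_sparse_individuals(self._with_n_nests(5))
        assert removed == [] and len(kept) == 5

    def test_empty_input(self):
        kept, removed = nesting.exclude_sparse_individuals(
            nest_records([]).reindex(columns=["individual_id", "date",
                                              "canonical_nest_id"]))
        assert kept.empty and removed == []


class TestBuildIntervals:
    def test_interior_runs_exact_boundary_runs_censored(self):
        rec = nest_records([("a", "2016-08-11", "A"), ("a", "2016-08-12", "A"),
                            ("a", "2016-08-13", "A"), ("a", "2016-08-14", "B"),
                            ("a", "2016-08-15", "B")])
        iv = nesting.build_intervals(rec, "2016-08-10", "2016-08-15")
        a = iv[iv["nest_id"] == "A"].iloc[0]
        b = iv[iv["nest_id"] == "B"].iloc[0]
        assert a["duration_days"] == 3 and not a["censored"]
        assert b["duration_days"] == 2 and b["censored"]  # touches study end

    def test_run_starting_on_study_start_is_censored(self):
        rec = nest_records([("a", "2016-08-10", "A"), ("a", "2016-08-11", "A"),
                            ("a", "2016-08-12", "B")])
        iv = nesting.build_intervals(rec, "2016-08-10", "2016-08-20")
        assert iv[iv["nest_id"] == "A"].iloc[0]["censored"]

    def test_single_interior_day_exact_duration_one(self):
        rec = nest_records([("a", "2016-08-11", "A"), ("a", "2016-08-12", "B"),
                            ("a", "2016-08-13", "A")])
        iv = nesting.build_intervals(rec, "2016-08-10", "2016-08-20")
        assert (iv["duration_days"] == 1).all()
        assert (~iv["censored"]).all()
        assert len(iv) == 3  # revisits form separate intervals

    def test_tracking_gap_splits_and_censors(self):
        rec = nest_records([("a", "2016-08-11", "A"), ("a", "2016-08-12", "A"),
                            ("a", "2016-08-15", "A"), ("a", "2016-08-16", "A")])
        iv = nesting.build_intervals(rec, "2016-08-10", "2016-08-20")
        assert len(iv) == 2
        assert iv["censored"].all()

    def test_durations_tile_the_tracked_span(self):
        days = pd.date_range("2016-08-11", "2016-08-19")
        nests = ["A", "A", "B", "B", "B", "C", "A", "A", "D"]
        rec = nest_records([("a", d, n) for d, n in zip(days, nests)])
        iv = nesting.build_intervals(rec, "2016-08-10", "2016-08-25")
        assert iv["duration_days"].sum() == len(days)


class TestKaplanMeier:
    def test_hand_computed_product_limit(self):
        iv = pd.DataFrame({"individual_id": "a", "nest_id": list("xyz"),
                           "start_date": pd.Timestamp("2016-08-10"),
                           "duration_days": [1, 2, 3],
                           "censored": [False, False, False]})
        curve = nesting.km_estimate(iv)
        got = dict(zip(curve.times, curve.survival))
        assert got[1] == pytest.approx(2 / 3)
        assert got[2] == pytest.approx(1 / 3)
        assert got[3] == pytest.approx(0.0)

    def test_all_censored_curve_flat_and_flagged(self):
        iv = pd.DataFrame({"individual_id": "a", "nest_id": list("abc"),
                           "start_date": pd.Timestamp("2016-08-10"),
                           "duration_days": [5, 5, 5], "censored": True})
        curve = nesting.km_estimate(iv)
        assert curve.all_censored
        assert np.allclose(curve.survival, 1.0)

    def test_matches_product_limit_oracle_on_random_censored_data(self, rng):
        for _ in range(50):
            n = rng.integers(5, 60)
            durations = rng.integers(1, 15, size=n)
            observed = rng.random(n) < 0.7
            iv = pd.DataFrame({"individual_id": "a",
                               "nest_id": [f"n{i}" for i in range(n)],
                               "start_date": pd.Timestamp("2016-08-10"),
                               "duration_days": durations,
                               "censored": ~observed})
            curve = nesting.km_estimate(iv)
            oracle = km_oracle(durations, observed)
            got = dict(zip(curve.times, curve.survival))
            for t, s in oracle.items():
                assert got[t] == pytest.approx(s, abs=1e-12)

    def test_uncensored_km_equals_empirical_survival(self, rng):
        durations = rng.integers(1, 10, size=100)
        iv = pd.DataFrame({"individual_id": "a",
                           "nest_id": [f"n{i}" for i in range(100)],
                           "start_date": pd.Timestamp("2016-08-10"),
                           "duration_days": durations, "censored": False})
        curve = nesting.km_estimate(iv)
        for t, s in zip(curve.times, curve.survival):
            assert s == pytest.approx((durations > t).mean())

    def test_geometric_switching_median_consistency(self, rng):
        # next-day reuse p => geometric durations; KM median must match
        # ceil(log 0.5 / log p)
        p = 0.661
        durations = rng.geometric(1 - p, size=4000)
        iv = pd.DataFrame({"individual_id": "a",
                           "nest_id": [f"n{i}" for i in range(4000)],
                           "start_date": pd.Timestamp("2016-08-10"),
                           "duration_days": durations, "censored": False})
        curve = nesting.km_estimate(iv)
        median = curve.times[np.searchsorted(-curve.survival, -0.5)]
        assert median == np.ceil(np.log(0.5) / np.log(p))


class TestLogrank:
    def _iv(self, durations, censored=False):
        return pd.DataFrame({"individual_id": "a",
                             "nest_id": [f"n{i}" for i in range(len(durations))],
                             "start_date": pd.Timestamp("2016-08-10"),
                             "duration_days": durations,
                             "censored": censored})

    def test_identical_groups_not_significant(self, rng):
        iv = self._iv(rng.integers(1, 10, 50))
        chi2, p = nesting.logrank_test(iv, iv.copy())
        assert chi2 == pytest.approx(0.0, abs=1e-9) and p == pytest.approx(1.0)

    def test_symmetric_in_group_order(self, rng):
        a = self._iv(rng.integers(1, 10, 40))
        b = self._iv(rng.integers(2, 14, 40))
        assert nesting.logrank_test(a, b) == pytest.approx(
            nesting.logrank_test(b, a))

    def test_power_against_double_hazard(self):
        hits = 0
        for seed in range(20):
            r = np.random.default_rng(seed)
            a = self._iv(np.ceil(r.exponential(8.0, 100)).astype(int))
            b = self._iv(np.ceil(r.exponential(4.0, 100)).astype(int))
            _, p = nesting.logrank_test(a, b)
            hits += p < 0.05
        assert hits >= 16   # >= 80% power

    def test_empty_group_is_an_error(self, rng):
        with pytest.raises(ValueError):
            nesting.logrank_test(self._iv([]), self._iv(rng.integers(1, 5, 5)))


class TestNextDayReuse:
    def test_constant_nest_probability_one(self):
        rec = nest_records([("a", f"2016-08-{10+i:02d}", "A") for i in range(6)])
        assert nesting.next_day_reuse(rec) == 1.0

    def test_alternating_nests_probability_zero(self):
        rec = nest_records([("a", f"2016-08-{10+i:02d}", "AB"[i % 2])
                            for i in range(6)])
        assert nesting.next_day_reuse(rec) == 0.0

    def test_non_consecutive_days_excluded(self):
        rec = nest_records([("a", "2016-08-10", "A"), ("a", "2016-08-12", "A"),
                            ("a", "2016-08-13", "A")])
        # only one usable (consecutive) pair
        assert nesting.next_day_reuse(rec) == 1.0
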