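"""Synthetic telemetry generator: schedule arithmetic, determinism,
calibration targets, ACC burst structure and nest sequences."""

from dataclasses import replace
from datetime import date

import numpy as np
import pandas as pd
import pytest

from hogwatch import synthetic
from hogwatch.preprocess import compute_steps


def one_night_cfg(**kw):
    return synthetic.small_config(
        treatment_calendar=[("pre", (date(2016, 8, 10), date(2016, 8, 10)))],
        n_individuals_per_sex_per_treatment=1, **kw)


class TestConfig:
    def test_empty_calendar_is_a_configuration_error(self):
        cfg = synthetic.small_config(treatment_calendar=[])
        with pytest.raises(synthetic.ConfigurationError):
            cfg.validate()

    @pytest.mark.parametrize("field,value", [
        ("rhythm_disruption", 1.5),
        ("outlier_rate", -0.1),
        ("burst_len_s", 2.553),
    ])
    def test_invariant_violations_rejected(self, field, value):
        cfg = synthetic.small_config(**{field: value})
        with pytest.raises(synthetic.ConfigurationError):
            cfg.validate()

    @pytest.mark.parametrize("burst_len,expected", [(2.5, 250), (2.64, 264)])
    def test_burst_sample_counts(self, burst_len, expected):
        cfg = synthetic.small_config(burst_len_s=burst_len)
        assert cfg.acc_samples_per_burst == expected

    def test_yaml_round_trip(self, tmp_path):
        cfg = synthetic.small_config(seed=5, gps_noise_sd_m=22.0)
        cfg.to_yaml(tmp_path / "cfg.yaml")
        back = synthetic.SimConfig.from_yaml(tmp_path / "cfg.yaml")
        assert back == cfg


class TestTracks:
    def test_gps_schedule_arithmetic(self):
        cfg = one_night_cfg(gps_noise_sd_m=0.0, outlier_rate=0.0, seed=1)
        fixes = synthetic.simulate_tracks(cfg)
        one = fixes[fixes["individual_id"] == "ctrl_f1"]
        hours = pd.DatetimeIndex(one["timestamp"]).hour
        assert ((hours >= 19) | (hours <= 7)).all()
        assert one["burst_id"].nunique() == 73          # 19:00..07:00 at 10 min
        assert (one.groupby("burst_id").size() == 5).all()
        within = one.groupby("burst_id")["timestamp"].agg(
            lambda t: (t.max() - t.min()).total_seconds())
        assert (within == 4).all()                      # 5 fixes, 1 s apart

    def test_fixed_seed_reproduces_byte_identical_output(self, tmp_path):
        cfg = one_night_cfg(seed=3, gps_noise_sd_m=10.0, outlier_rate=0.01)
        p1, p2 = tmp_path / "a.csv", tmp_path / "b.csv"
        synthetic.simulate_tracks(cfg).to_csv(p1, index=False)
        synthetic.simulate_tracks(cfg).to_csv(p2, index=False)
        assert p1.read_bytes() == p2.read_bytes()

    def test_different_seeds_differ(self):
        a = synthetic.simulate_tracks(one_night_cfg(seed=1))
        b = synthetic.simulate_tracks(one_night_cfg(seed=2))
        assert not a["lon"].equals(b["lon"])

    def test_noise_free_speed_matches_configured_mean(self, recovery_records,
                                                      recovery_cfg):
        steps = compute_steps(recovery_records)
        meta = recovery_records[["individual_id", "night_id", "treatment"]
                                ].drop_duplicates()
        merged = steps.merge(meta, on=["individual_id", "night_id"])
        for treat, want in recovery_cfg.mean_speed_m_s.items():
            got = merged.loc[merged["treatment"] == treat, "speed_m_s"].mean()
            assert got == pytest.approx(want, rel=0.05)

    def test_noise_free_mcp95_matches_target_areas(self, recovery_nights,
                                                   recovery_cfg):
        for sex in synthetic.SEXES:
            for treat in ("pre", "festival", "fragmented"):
                sel = recovery_nights[(recovery_nights["sex"] == sex)
                                      & (recovery_nights["treatment"] == treat)]
                want = recovery_cfg.target_mcp95_ha[sex][treat]
                assert sel["mcp95_ha"].mean() == pytest.approx(want, rel=0.15)


class TestScheduleAndAcc:
    def test_resting_quieter_than_walking(self):
        cfg = synthetic.small_config(seed=2)
        minutes = pd.date_range("2016-08-10", periods=120, freq="1min",
                                tz=cfg.timezone)
        base = {"individual_id": "x", "east": 0.0, "north": 0.0,
                "sex": "female", "treatment": "pre"}
        rest = pd.DataFrame([{**base, "timestamp": t, "state": "resting"}
                             for t in minutes])
        walk = pd.DataFrame([{**base, "timestamp": t, "state": "walking"}
                             for t in minutes])
        ir = np.nanstd(synthetic.simulate_acc(rest, cfg).samples, axis=1).sum(axis=1)
        iw = np.nanstd(synthetic.simulate_acc(walk, cfg).samples, axis=1).sum(axis=1)
        assert ir.max() < iw.min()

    def test_264_sample_bursts(self):
        cfg = synthetic.small_config(seed=2, burst_len_s=2.64)
        sched = synthetic.make_schedule(cfg, individuals=["ctrl_f1"], n_days=1)
        bursts = synthetic.simulate_acc(sched[sched["treatment"] == "pre"], cfg)
        assert bursts.samples.shape[1] == 264
        assert (bursts.meta["n_valid"] == 264).all()

    def test_schedule_is_a_complete_minute_grid(self):
        cfg = synthetic.small_config(seed=4)
        sched = synthetic.make_schedule(cfg, individuals=["ctrl_m1"], n_days=2)
        pre = sched[sched["treatment"] == "pre"]
        assert len(pre) == 2 * 1440
        diffs = pd.DatetimeIndex(pre["timestamp"]).to_series().diff().dropna()
        assert (diffs == pd.Timedelta(minutes=1)).all()

    def test_schedule_positions_continuous(self):
        cfg = synthetic.small_config(seed=4)
        sched = synthetic.make_schedule(cfg, individuals=["ctrl_m1"], n_days=3)
        pre = sched[sched["treatment"] == "pre"].sort_values("timestamp")
        step = np.hypot(np.diff(pre["east"]), np.diff(pre["north"]))
        max_step = 3 * cfg.mean_speed_m_s["pre"] * 60
        assert step.max() <= max_step + 1e-9

    def test_gap_in_schedule_raises_listing_the_gap(self):
        cfg = synthetic.small_config(seed=4)
        sched = synthetic.make_schedule(cfg, individuals=["ctrl_f1"], n_days=1)
        sched = sched[sched["treatment"] == "pre"]
        holed = sched.drop(sched.index[100:103])
        with pytest.raises(synthetic.ScheduleGapError, match="missing minutes"):
            synthetic.simulate_acc(holed, cfg)

    def test_truncation_rate_ground_truth(self):
        cfg = synthetic.small_config(seed=6)
        sched = synthetic.make_schedule(cfg, individuals=["ctrl_f1"], n_days=1)
        sched = sched[sched["treatment"] == "pre"]
        bursts = synthetic.simulate_acc(sched, cfg, truncation_rate=0.1)
        short = (bursts.meta["n_valid"] < cfg.acc_samples_per_burst)
        assert 0.05 < short.mean() < 0.2
        nan_tail = np.isnan(bursts.samples[short.to_numpy(), -1, :]).all()
        assert nan_tail


class TestNests:
    def _records(self, reuse, days=40, seed=0):
        from datetime import timedelta

        start = date(2016, 1, 1)
        cfg = synthetic.SimConfig(
            n_individuals_per_sex_per_treatment=2,
            treatment_calendar=[("pre", (start,
                                         start + timedelta(days=days - 1)))],
            next_day_reuse_prob={s: {"pre": reuse} for s in ("female", "male")},
            seed=seed)
        return synthetic.simulate_nests(cfg)

    def test_reuse_one_gives_single_nest_throughout(self):
        rec = self._records(1.0, days=30)
        assert (rec.groupby("individual_id")["nest_id"].nunique() == 1).all()

    def test_reuse_zero_gives_daily_change(self):
        rec = self._records(0.0, days=30)
        per_day = rec.groupby("individual_id")["nest_id"].nunique()
        assert (per_day == 30).all()

    def test_new_nests_are_at_least_10_m_apart(self):
        from hogwatch.telemetry_io import add_planar_coordinates

        cfg = synthetic.small_config(seed=8)
        rec = add_planar_coordinates(synthetic.simulate_nests(cfg),
                                     cfg.site_centre)
        for _ind, grp in rec.groupby("individual_id"):
            pos = grp.drop_duplicates("nest_id")[["east", "north"]].to_numpy()
            if len(pos) < 2:
                continue
            d = np.hypot(*(pos[:, None, :] - pos[None, :, :]).T)
            np.fill_diagonal(d, np.inf)
            assert d.min() >= 10.0 - 1e-6

    def test_deterministic_given_seed(self):
        a = self._records(0.5, seed=9)
        b = self._records(0.5, seed=9)
        pd.testing.assert_frame_equal(a, b)
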