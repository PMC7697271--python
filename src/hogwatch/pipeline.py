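"""End-to-end orchestration: simulate -> preprocess -> space use ->
turning angles -> behaviour -> DFC -> nests -> inference, with a
provenance manifest.

Every stage is deterministic given the run seed; all thresholds are
echoed into the manifest so no default drifts silently.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__, acc, chronorhythm, inference, movement, nesting, preprocess
from . import space_use as su
from . import synthetic, telemetry_io

logger = logging.getLogger(__name__)


@dataclass
class RunConfig:
    """All pipeline thresholds in one place (defaults are the study's
    printed values) plus the simulation conditions."""

    sim: synthetic.SimConfig = field(default_factory=synthetic.SimConfig)
    max_site_distance_m: float = preprocess.MAX_SITE_DISTANCE_M     # 1000
    max_speed_m_s: float = preprocess.MAX_SPEED_M_S                 # 2
    probability_threshold: float = acc.PROBABILITY_THRESHOLD        # 0.7
    min_records_per_day: int = acc.MIN_RECORDS_PER_DAY              # 1430
    nest_merge_radius_m: float = nesting.NEST_MERGE_RADIUS_M        # 2
    min_nests_per_individual: int = nesting.MIN_NESTS_PER_INDIVIDUAL  # 5
    dfc_window_days: int = chronorhythm.WINDOW_DAYS                 # 3
    acc_individuals: int = 4    # animals carried into the ACC stage
    acc_days: int = 4           # days of ACC per animal (>= DFC window)
    seed: int = 0

    def thresholds(self) -> dict:
        d = asdict(self)
        d.pop("sim")
        return d


def summarize_night_counts(nights: pd.DataFrame) -> dict:
    """Night bookkeeping: tracked-night counts per treatment and in total."""
    per_treatment = (nights.groupby("treatment")["night_id"].nunique()
                     if "individual_id" not in nights.columns else
                     nights.groupby("treatment").apply(
                         lambda g: len(g[["individual_id", "night_id"]].drop_duplicates()),
                         include_groups=False))
    counts = {str(k): int(v) for k, v in per_treatment.items()}
    counts["total"] = int(sum(counts.values()))
    return counts


def run_all(config: RunConfig, out_dir) -> Path:
    """Run the whole pipeline into ``out_dir``; returns the directory.

    Writes nights.csv, ranges.geojson, ks.json, labels.csv, budgets.csv,
    dfc.csv, intervals.csv, survival.csv, model_*.json, removals.json and
    manifest.json.
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    sim = config.sim
    if config.seed != sim.seed:
        from dataclasses import replace

        sim = replace(sim, seed=config.seed)
    sim.validate()

    # --- GPS ---------------------------------------------------------------
    fixes = synthetic.simulate_tracks(sim)
    records, report = preprocess.preprocess(
        fixes, sim.site_centre, max_dist_m=config.max_site_distance_m,
        max_speed_m_s=config.max_speed_m_s)
    nights, excluded = su.nightly_summaries(records)
    nights.to_csv(out / "nights.csv", index=False)

    steps = preprocess.compute_steps(records)
    night_speed = (steps.groupby(["individual_id", "night_id"])["speed_m_s"]
                   .mean().rename("mean_speed_m_s").reset_index())
    nights = nights.merge(night_speed, on=["individual_id", "night_id"], how="left")

    features = []
    for row in nights.itertuples():
        pts = records[(records["individual_id"] == row.individual_id)
                      & (records["night_id"] == row.night_id)]
        poly, area = su.mcp_area(pts[["east", "north"]].to_numpy())
        if poly.geom_type == "Polygon":
            features.append(telemetry_io.HomeRangeFeature(
                row.individual_id, str(row.night_id), "mcp95", area, poly))
    telemetry_io.write_home_range_geojson(features, out / "ranges.geojson",
                                          site_centre=sim.site_centre)

    # --- turning angles ----------------------------------------------------
    angles = movement.turning_angle_table(records)
    ks_payload = {}
    for other in ("festival", "fragmented"):
        a = angles.loc[angles["treatment"] == "pre", "angle"].to_numpy()
        b = angles.loc[angles["treatment"] == other, "angle"].to_numpy()
        if len(a) == 0 or len(b) == 0:
            continue
        res = movement.permutation_ks(a, b, seed=config.seed)
        ks_payload[f"pre_vs_{other}"] = {
            "n_iterations": res.n_iterations, "subsample_size": res.subsample_size,
            "fraction_significant": res.fraction_significant, "median_p": res.median_p}
    (out / "ks.json").write_text(json.dumps(ks_payload, indent=2))

    # --- behaviour + rhythm (on an ACC subset of the roster) ---------------
    roster = synthetic.build_individuals(sim)
    acc_ids = [ind.individual_id for ind in roster][:config.acc_individuals]
    schedule = synthetic.make_schedule(sim, individuals=acc_ids, n_days=config.acc_days)
    bursts = synthetic.simulate_acc(schedule, sim)
    bursts, n_bad = acc.validate_bursts(bursts, sim.acc_samples_per_burst)
    feats = acc.extract_features_table(bursts)

    day = pd.DatetimeIndex(feats["start_timestamp"]).date
    train = feats[day == day.min()]
    model = acc.train_classifier(
        train[list(acc.FEATURE_NAMES)].to_numpy(), train["true_state"], seed=config.seed)
    labels = acc.classify(model, feats[list(acc.FEATURE_NAMES)].to_numpy(),
                          timestamps=feats["start_timestamp"],
                          individual_ids=feats["individual_id"],
                          threshold=config.probability_threshold)
    labels.to_csv(out / "labels.csv", index=False)
    complete, _ = acc.filter_complete_days(
        labels.rename(columns={"timestamp": "start_timestamp"}),
        config.min_records_per_day)
    budgets = acc.behaviour_budget(
        complete.rename(columns={"start_timestamp": "timestamp"}))
    budgets.to_csv(out / "budgets.csv", index=False)

    activity = chronorhythm.activity_intensity(bursts)
    dfc_frame = chronorhythm.sliding_dfc(activity, config.dfc_window_days)
    dfc_frame.to_csv(out / "dfc.csv", index=False)

    # --- nesting -----------------------------------------------------------
    nests_raw = synthetic.simulate_nests(sim)
    nests_planar = telemetry_io.add_planar_coordinates(nests_raw, sim.site_centre)
    nests_resolved = nesting.resolve_nest_identity(
        nests_planar, config.nest_merge_radius_m)
    nests_kept, sparse = nesting.exclude_sparse_individuals(
        nests_resolved, config.min_nests_per_individual)
    spans = [(t, s, e) for t, (s, e) in sim.treatment_calendar]
    intervals = []
    for treat, start, end in spans:
        sub = nests_kept[nests_kept["treatment"] == treat]
        if sub.empty:
            continue
        iv = nesting.build_intervals(sub, pd.Timestamp(start), pd.Timestamp(end))
        iv["treatment"] = treat
        iv = iv.merge(nests_kept[["individual_id", "sex"]].drop_duplicates(),
                      on="individual_id")
        intervals.append(iv)
    intervals = pd.concat(intervals, ignore_index=True) if intervals else pd.DataFrame()
    intervals.to_csv(out / "intervals.csv", index=False)

    surv_rows = []
    if not intervals.empty:
        for treat, grp in intervals.groupby("treatment"):
            curve = nesting.km_estimate(grp)
            for t, s, r, e in zip(curve.times, curve.survival, curve.at_risk, curve.events):
                surv_rows.append({"treatment": treat, "time_days": t, "survival": s,
                                  "at_risk": r, "events": e})
    pd.DataFrame(surv_rows).to_csv(out / "survival.csv", index=False)
    reuse = nesting.next_day_reuse(nests_kept, by=["sex", "treatment"])

    # --- inference ---------------------------------------------------------
    model_reports = {}
    for response, transform, weights in (
            ("mcp95_ha", "identity", True),
            ("kde50_ha", "identity", True),
            ("mean_speed_m_s", "identity", False),
            ("search_intensity", "identity", False)):
        try:
            res = inference.fit_group_model(nights.dropna(subset=[response]),
                                            response, transform,
                                            variance_weights=weights)
            model_reports[response] = res.as_dict()
        except ValueError as exc:
            model_reports[response] = {"error": str(exc)}
    deviations = su.centroid_deviation(nights)
    for axis in ("abs_dev_east_m", "abs_dev_north_m"):
        try:
            res = inference.fit_group_model(deviations, axis, "sqrt")
            model_reports[axis] = res.as_dict()
        except ValueError as exc:
            model_reports[axis] = {"error": str(exc)}
    (out / "models.json").write_text(json.dumps(model_reports, indent=2))

    removals = {
        **report.as_dict(),
        "acc_bursts_removed": n_bad,
        "nights_excluded": len(excluded),
        "sparse_nest_individuals": sparse,
        "night_counts": summarize_night_counts(nights),
    }
    (out / "removals.json").write_text(json.dumps(removals, indent=2))

    manifest = {
        "package_version": __version__,
        "numpy": np.__version__, "pandas": pd.__version__,
        "seed": config.seed,
        "thresholds": config.thresholds(),
        "n_fixes": len(fixes), "n_records": len(records),
        "n_nights": len(nights), "n_bursts": len(bursts),
        "n_intervals": len(intervals),
        "next_day_reuse": {f"{k[0]}/{k[1]}": (None if pd.isna(v) else float(v))
                           for k, v in reuse.items()},
        "outputs": {},
    }
    for name in ("nights.csv", "ranges.geojson", "ks.json", "labels.csv",
                 "budgets.csv", "dfc.csv", "intervals.csv", "survival.csv",
                 "models.json", "removals.json"):
        digest = hashlib.sha256((out / name).read_bytes()).hexdigest()
        manifest["outputs"][name] = digest
    (out / "manifest.json").write_text(json.dumps(manifest, indent=2))
    return out
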