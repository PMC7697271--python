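"""Shared fixtures: reduced synthetic studies reused across test modules.

Expensive simulations are session-scoped; every fixture is seeded, so the
suite is deterministic end to end.
"""

from datetime import date

import numpy as np
import pandas as pd
import pytest

from hogwatch import acc, preprocess, space_use, synthetic, telemetry_io


@pytest.fixture(scope="session")
def recovery_cfg():
    """Noise-free study at the printed field parameters: 20-night phases,
    2 animals per sex per site (the parameter-recovery design)."""
    return synthetic.SimConfig(
        n_individuals_per_sex_per_treatment=2,
        treatment_calendar=[
            ("pre", (date(2016, 8, 10), date(2016, 8, 29))),
            ("festival", (date(2016, 8, 30), date(2016, 9, 18))),
            ("fragmented", (date(2017, 8, 14), date(2017, 9, 2))),
        ],
        gps_noise_sd_m=0.0, outlier_rate=0.0, seed=11)


@pytest.fixture(scope="session")
def recovery_records(recovery_cfg):
    fixes = synthetic.simulate_tracks(recovery_cfg)
    fixes = telemetry_io.add_planar_coordinates(fixes, recovery_cfg.site_centre)
    records, _report = preprocess.preprocess(fixes, recovery_cfg.site_centre)
    return records


@pytest.fixture(scope="session")
def recovery_nights(recovery_records):
    nights, _ = space_use.nightly_summaries(recovery_records)
    return nights


@pytest.fixture(scope="session")
def acc_two_days():
    """Two complete days of ACC bursts for one control female, with the
    minute-level ground-truth states attached."""
    cfg = synthetic.small_config(seed=9)
    sched = synthetic.make_schedule(cfg, individuals=["ctrl_f1"], n_days=2)
    sched = sched[sched["treatment"] == "pre"]
    bursts = synthetic.simulate_acc(sched, cfg)
    return cfg, bursts


@pytest.fixture(scope="session")
def trained_behaviour_model(acc_two_days):
    cfg, bursts = acc_two_days
    feats = acc.extract_features_table(bursts)
    day = pd.DatetimeIndex(feats["start_timestamp"]).date
    train = feats[day == day.min()]
    test = feats[day != day.min()]
    model = acc.train_classifier(train[list(acc.FEATURE_NAMES)].to_numpy(),
                                 train["true_state"], seed=0)
    return model, train, test


@pytest.fixture()
def rng():
    return np.random.default_rng(424242)
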