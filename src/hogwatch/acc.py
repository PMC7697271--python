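"""Accelerometer behaviour classification and daily behaviour budgets.

Each validated 100 Hz burst is summarised by a fixed 25-feature vector and
classified into resting / balling / walking by one-vs-rest support-vector
machines with calibrated class probabilities; a burst whose maximum class
probability falls below 0.7 is labelled "other", so behaviours absent from
the training set do not get forced into a known class.  Daily budgets are
the per-class burst fractions over complete recording days.

The 25 features are a standard wildlife-ACC set reconstructed to match the
published constraint that exactly three of the predictors depend on burst
length: per-axis mean, SD, min, max and skewness (15), mean ODBA (1),
pairwise axis correlations (3), per-axis dominant frequency (3, the
burst-length-dependent members) and per-axis spectral entropy (3).
"""

from __future__ import annotations

from dataclasses import dataclass

import joblib
import numpy as np
import pandas as pd
from scipy import stats as sstats
from sklearn.calibration import CalibratedClassifierCV
from sklearn.multiclass import OneVsRestClassifier
from sklearn.preprocessing import StandardScaler
from sklearn.svm import SVC

PROBABILITY_THRESHOLD = 0.7
OTHER_LABEL = "other"
MIN_RECORDS_PER_DAY = 1430   # out of 1440 one-minute slots in 24 h

FEATURE_NAMES = (
    [f"{ax}_{stat}" for stat in ("mean", "sd", "min", "max", "skew") for ax in "xyz"]
    + ["odba_mean"]
    + ["corr_xy", "corr_xz", "corr_yz"]
    + [f"{ax}_domfreq_hz" for ax in "xyz"]
    + [f"{ax}_spec_entropy" for ax in "xyz"]
)


def validate_bursts(burst_table, expected_samples: int):
    """Remove bursts with fewer recorded samples than the logger settings
    intend on any axis.  Returns ``(retained, n_removed)``."""
    n_valid = burst_table.meta["n_valid"].to_numpy() \
        if "n_valid" in burst_table.meta.columns \
        else np.sum(~np.isnan(burst_table.samples[:, :, 0]), axis=1)
    keep = n_valid >= expected_samples
    return burst_table.select(keep), int((~keep).sum())


def filter_complete_days(minute_records: pd.DataFrame,
                         min_per_day: int = MIN_RECORDS_PER_DAY):
    """Keep only calendar days (00:00-23:59) with at least ``min_per_day``
    minute records per individual; incomplete days are dropped entirely so
    no time of day is over-represented.  Returns ``(retained, dropped_days)``."""
    if minute_records.empty:
        return minute_records.copy(), []
    out = minute_records.copy()
    ts = pd.DatetimeIndex(out["start_timestamp" if "start_timestamp" in out.columns
                              else "timestamp"])
    out["_day"] = ts.date
    counts = out.groupby(["individual_id", "_day"])["_day"].transform("size")
    keep = counts >= min_per_day
    dropped = sorted(set(zip(out.loc[~keep, "individual_id"],
                             out.loc[~keep, "_day"])))
    return out.loc[keep].drop(columns="_day").reset_index(drop=True), dropped


# ---------------------------------------------------------------------------
# features
# ---------------------------------------------------------------------------

def extract_features(burst: np.ndarray, sample_rate_hz: float = 100.0):
    """Deterministic 25-vector for one (n_samples, 3) burst.

    ODBA is the mean over samples of the summed per-axis absolute
    deviation from the axis's static (burst-mean) component.  Constant
    axes get correlation features of 0 and raise the ``constant_axis``
    flag; their skewness, dominant frequency and spectral entropy are 0.

    Returns ``(vector, flags)``.
    """
    x = np.asarray(burst, dtype=float)
    if x.ndim != 2 or x.shape[1] != 3:
        raise ValueError("burst must be (n_samples, 3)")
    x = x[~np.isnan(x).any(axis=1)]
    if len(x) < 4:
        raise ValueError("burst too short for feature extraction")
    flags: list[str] = []

    means = x.mean(axis=0)
    sds = x.std(axis=0, ddof=0)
    mins = x.min(axis=0)
    maxs = x.max(axis=0)
    constant = sds == 0
    if constant.any():
        flags.append("constant_axis")
    import warnings as _warnings

    with np.errstate(invalid="ignore", divide="ignore"), \
            _warnings.catch_warnings():
        _warnings.simplefilter("ignore", RuntimeWarning)
        skews = sstats.skew(x, axis=0, bias=True)
    skews = np.where(constant, 0.0, np.nan_to_num(skews))

    odba = float(np.abs(x - means).sum(axis=1).mean())

    corr = np.zeros(3)
    for i, (a, b) in enumerate(((0, 1), (0, 2), (1, 2))):
        if not constant[a] and not constant[b]:
            corr[i] = np.corrcoef(x[:, a], x[:, b])[0, 1]

    domfreq = np.zeros(3)
    entropy = np.zeros(3)
    n = len(x)
    freqs = np.fft.rfftfreq(n, d=1.0 / sample_rate_hz)
    for ax in range(3):
        if constant[ax]:
            continue
        power = np.abs(np.fft.rfft(x[:, ax] - means[ax])) ** 2
        power = power[1:]  # DC already removed by centring; drop the bin anyway
        total = power.sum()
        if total <= 0:
            continue
        domfreq[ax] = freqs[1:][np.argmax(power)]
        p = power / total
        nz = p[p > 0]
        entropy[ax] = float(-(nz * np.log(nz)).sum() / np.log(len(p)))

    vector = np.concatenate([means, sds, mins, maxs, skews, [odba], corr,
                             domfreq, entropy])
    assert vector.shape == (25,)
    return vector, flags


def extract_features_table(burst_table) -> pd.DataFrame:
    """Feature matrix for every burst, with the metadata columns carried."""
    rows = np.empty((len(burst_table), 25))
    for i in range(len(burst_table)):
        rows[i], _ = extract_features(burst_table.samples[i],
                                      burst_table.sample_rate_hz)
    feats = pd.DataFrame(rows, columns=FEATURE_NAMES)
    for col in ("individual_id", "start_timestamp", "true_state"):
        if col in burst_table.meta.columns:
            feats[col] = burst_table.meta[col].to_numpy()
    return feats


# ---------------------------------------------------------------------------
# classifier
# ---------------------------------------------------------------------------

@dataclass
class BehaviourModel:
    """Joined one-vs-rest SVMs plus the training-set standardisation."""

    scaler: StandardScaler
    classifier: OneVsRestClassifier
    classes: np.ndarray
    feature_names: tuple = tuple(FEATURE_NAMES)
    version: str = "1"

    def predict_proba(self, X) -> np.ndarray:
        return self.classifier.predict_proba(self.scaler.transform(X))

    def save(self, path) -> None:
        joblib.dump(self, path)

    @staticmethod
    def load(path) -> "BehaviourModel":
        return joblib.load(path)


def train_classifier(features: np.ndarray, labels, seed: int = 0,
                     C: float = 10.0, gamma: str | float = "scale") -> BehaviourModel:
    """Fit the joined SVMs on standardised features.

    One RBF support-vector machine per class against the rest, with
    Platt-calibrated probabilities normalised across classes.  Training is
    deterministic given ``seed``.  Raises on single-class input.
    """
    X = np.asarray(features, dtype=float)
    y = np.asarray(labels)
    classes = np.unique(y)
    if len(classes) < 2:
        raise ValueError("training needs at least two behaviour classes")
    scaler = StandardScaler().fit(X)
    base = SVC(kernel="rbf", C=C, gamma=gamma, random_state=seed)
    clf = OneVsRestClassifier(
        CalibratedClassifierCV(base, method="sigmoid", ensemble=False, cv=3))
    clf.fit(scaler.transform(X), y)
    return BehaviourModel(scaler=scaler, classifier=clf, classes=clf.classes_)


def classify(model: BehaviourModel, features, timestamps=None,
             individual_ids=None,
             threshold: float = PROBABILITY_THRESHOLD) -> pd.DataFrame:
    """Label bursts; maxima below ``threshold`` become "other".

    The comparison is inclusive: a maximum probability of exactly the
    threshold keeps its class.  Returns a frame with label and
    max_probability (plus timestamp / individual_id when given).
    """
    X = np.asarray(features, dtype=float)
    proba = model.predict_proba(X)
    max_p = proba.max(axis=1)
    labels = model.classes[np.argmax(proba, axis=1)].astype(object)
    labels[max_p < threshold] = OTHER_LABEL
    out = pd.DataFrame({"label": labels, "max_probability": max_p})
    if individual_ids is not None:
        out.insert(0, "individual_id", np.asarray(individual_ids))
    if timestamps is not None:
        out.insert(1 if individual_ids is not None else 0, "timestamp",
                   np.asarray(timestamps))
    return out


def behaviour_budget(labels: pd.DataFrame, by: str = "day") -> pd.DataFrame:
    """Per individual per day: class proportions over all bursts.

    ``labels`` needs individual_id, timestamp and label columns (apply the
    complete-day filter first).  Proportions sum to 1 per row; days with
    zero bursts are simply absent.
    """
    if by != "day":
        raise ValueError("only daily budgets are defined")
    work = labels.copy()
    work["day"] = pd.DatetimeIndex(work["timestamp"]).date
    counts = (work.groupby(["individual_id", "day", "label"])
              .size().unstack(fill_value=0))
    budgets = counts.div(counts.sum(axis=1), axis=0)
    budgets["n_bursts"] = counts.sum(axis=1)
    return budgets.reset_index()
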