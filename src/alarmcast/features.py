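"""The eight-family, 63-feature vector computed from each episode's
pre-alarm window.

Families and cardinalities (frozen column order, summing to 63):

* ``meta`` (3): gestational age at birth, postnatal age and postmenstrual age
  at the anchor alarm;
* ``category`` (1): the anchor yellow-alarm category as an integer code over
  the six-level vocabulary;
* ``alarm_counts`` (2): yellow and red alarms in the pre window (anchor
  excluded);
* ``HR`` / ``BR`` / ``SpO2`` (13 each): whole-window statistics, occurring-
  moment value, trailing-50 s statistics, threshold residence times and
  crossing counts;
* ``corr`` (6): Pearson correlations of the three signal pairs over the full
  window and the final 50 s;
* ``HRV`` (12): windowed SDNN / SDDec / meanNN statistics (evaluated every
  10 s over the trailing 30 s of cleaned NN intervals), areas of the NN curve
  above its 10th-percentile baseline, and the deceleration fraction.

Population (divide-by-n) standard deviations are used throughout.  Missing
values are represented as NaN and handled natively by the tree learners.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .config import AlarmSettings
from .cohort import Episode
from .io import SIGNALS, NNSeries, VitalTrace, YELLOW_CATEGORIES

NN_ARTIFACT_MAX_S = 1.5      # interbeat intervals longer than this are artifacts
HRV_EVAL_STEP_S = 10.0       # HRV statistics evaluated every 10 s ...
HRV_WINDOW_S = 30.0          # ... over the trailing 30 s
HRV_MIN_SAMPLES = 3          # statistics undefined below this NN count
LAST_WINDOW_S = 50.0         # trailing sub-window for slope/mean/correlation
FIRST_WINDOW_S = 30.0        # leading sub-window for the occ-minus-start delta


# ---------------------------------------------------------------------------
# registry
# ---------------------------------------------------------------------------

def _vital_columns(sig: str) -> list[str]:
    return [f"{sig}_occ", f"{sig}_mean", f"{sig}_sd", f"{sig}_min", f"{sig}_max",
            f"{sig}_range", f"{sig}_slope", f"{sig}_slope_last50",
            f"{sig}_mean_last50", f"{sig}_time_beyond_yellow",
            f"{sig}_time_beyond_red", f"{sig}_yellow_crossings",
            f"{sig}_occ_minus_first30_mean"]


FEATURE_FAMILIES: dict[str, list[str]] = {
    "meta": ["meta_gestational_age_wk", "meta_postnatal_age_d", "meta_postmenstrual_age_wk"],
    "category": ["yellow_category_code"],
    "alarm_counts": ["pre_yellow_count", "pre_red_count"],
    "HR": _vital_columns("HR"),
    "BR": _vital_columns("BR"),
    "SpO2": _vital_columns("SpO2"),
    "corr": ["corr_HR_BR", "corr_HR_SpO2", "corr_BR_SpO2",
             "corr_HR_BR_last50", "corr_HR_SpO2_last50", "corr_BR_SpO2_last50"],
    "HRV": ["nn_occ", "sdnn_occ", "sddec_occ", "sdnn_mean", "sdnn_min", "sdnn_max",
            "sddec_mean", "sddec_max", "meannn_slope", "auc_nn", "auc_dec",
            "dec_fraction"],
}

FEATURE_COLUMNS: list[str] = [c for fam in ("meta", "category", "alarm_counts",
                                            "HR", "BR", "SpO2", "corr", "HRV")
                              for c in FEATURE_FAMILIES[fam]]
FAMILY_OF: dict[str, str] = {c: fam for fam, cols in FEATURE_FAMILIES.items() for c in cols}
ALWAYS_FAMILIES = ("meta", "category", "alarm_counts")
SELECTABLE_FAMILIES = ("HR", "BR", "SpO2", "corr", "HRV")

assert len(FEATURE_COLUMNS) == 63


@dataclass(frozen=True)
class InfantMeta:
    """Infant ages at an anchor alarm (postmenstrual = gestational +
    postnatal/7, within rounding)."""

    gestational_age_wk: float
    postnatal_age_d: float

    @property
    def postmenstrual_age_wk(self) -> float:
        return self.gestational_age_wk + self.postnatal_age_d / 7.0


@dataclass(frozen=True)
class SignalThresholds:
    yellow: float
    red: float
    orientation: str  # "low" -> beyond means below; "high" -> above


@dataclass(frozen=True)
class ThresholdSet:
    """Feature thresholds per signal.  BR uses the fixed clinical choices of
    30 (yellow) / 25 (red); HR and SpO2 take the alarm settings in force.
    The anchor category's signal adopts its own orientation; other signals
    default to their low-type orientation."""

    HR: SignalThresholds
    BR: SignalThresholds
    SpO2: SignalThresholds

    def for_signal(self, sig: str) -> SignalThresholds:
        return getattr(self, sig)

    @classmethod
    def from_settings(cls, settings: AlarmSettings, anchor_category: str = "") -> "ThresholdSet":
        hr = SignalThresholds(settings.hr_low_yellow or 100.0,
                              settings.hr_low_red or 80.0, "low")
        if anchor_category == "HR-high":
            hr = SignalThresholds(settings.hr_high_yellow or 200.0,
                                  settings.hr_high_red or 220.0, "high")
        spo2 = SignalThresholds(settings.spo2_low_yellow or 88.0,
                                settings.spo2_low_red or 80.0, "low")
        if anchor_category == "SpO2-high":
            # SpO2-high has no red counterpart; a saturated red bound keeps
            # the time-beyond-red feature well defined (identically zero).
            spo2 = SignalThresholds(settings.spo2_high_yellow or 98.0, 100.0, "high")
        return cls(hr, SignalThresholds(30.0, 25.0, "low"), spo2)


# ---------------------------------------------------------------------------
# NN cleaning and HRV
# ---------------------------------------------------------------------------

def clean_nn(nn: NNSeries, max_nn_s: float = NN_ARTIFACT_MAX_S) -> NNSeries:
    """Drop interbeat intervals longer than ``max_nn_s`` seconds (potential
    R-peak detection artifacts), preserving order."""
    keep = nn.nn <= max_nn_s
    return NNSeries(nn.infant_id, nn.beat_times[keep], nn.nn[keep])


def deceleration_runs(nn_values: np.ndarray) -> list[np.ndarray]:
    """Maximal runs (index arrays, length >= 2) of strictly increasing NN —
    transient heart-rate slowing."""
    runs: list[np.ndarray] = []
    n = nn_values.size
    i = 0
    while i < n - 1:
        if nn_values[i + 1] > nn_values[i]:
            j = i + 1
            while j < n - 1 and nn_values[j + 1] > nn_values[j]:
                j += 1
            runs.append(np.arange(i, j + 1))
            i = j
        else:
            i += 1
    return runs


@dataclass
class HRVSeries:
    """SDNN, SDDec and meanNN evaluated every 10 s across the pre window,
    each over the NN samples in the trailing 30 s ``(t - 30, t]``."""

    eval_times: np.ndarray
    sdnn: np.ndarray
    sddec: np.ndarray
    meannn: np.ndarray


def hrv_series(nn: NNSeries, window: tuple[float, float]) -> HRVSeries:
    """Windowed HRV statistics over a cleaned NN series.

    ``window = (t_start, t_end]``; evaluation times run every 10 s ending at
    ``t_end``.  A statistic is missing when fewer than 3 NN samples fall in
    its trailing 30 s (SDDec additionally requires a deceleration run of
    length >= 2).
    """
    t_start, t_end = window
    n_eval = int(math.floor((t_end - t_start) / HRV_EVAL_STEP_S))
    eval_times = t_end - HRV_EVAL_STEP_S * np.arange(n_eval - 1, -1, -1, dtype=float)
    sdnn = np.full(n_eval, np.nan)
    sddec = np.full(n_eval, np.nan)
    meannn = np.full(n_eval, np.nan)
    for k, t in enumerate(eval_times):
        lo = np.searchsorted(nn.beat_times, t - HRV_WINDOW_S, side="right")
        hi = np.searchsorted(nn.beat_times, t, side="right")
        vals = nn.nn[lo:hi]
        if vals.size < HRV_MIN_SAMPLES:
            continue
        sdnn[k] = vals.std()          # population SD
        meannn[k] = vals.mean()
        runs = deceleration_runs(vals)
        if runs:
            dec_vals = np.concatenate([vals[r] for r in runs])
            sddec[k] = dec_vals.std()
    return HRVSeries(eval_times, sdnn, sddec, meannn)


def _ls_slope(x: np.ndarray, y: np.ndarray) -> float:
    ok = np.isfinite(y)
    if ok.sum() < 2:
        return np.nan
    x, y = x[ok], y[ok]
    if np.ptp(x) == 0:
        return np.nan
    xc = x - x.mean()
    return float((xc @ (y - y.mean())) / (xc @ xc))


def hrv_features(series: HRVSeries, nn: NNSeries, window: tuple[float, float]) -> dict[str, float]:
    """The 12 HRV features; ``nn`` must be cleaned and restricted to the pre
    window, whose end is the anchor instant."""
    t_start, t_end = window
    out: dict[str, float] = {}
    # occurring-moment mean NN: defined for any nonempty trailing-30 s window
    occ = nn.restrict(t_end - HRV_WINDOW_S, t_end).nn
    out["nn_occ"] = float(occ.mean()) if occ.size else np.nan
    out["sdnn_occ"] = series.sdnn[-1] if series.sdnn.size else np.nan
    out["sddec_occ"] = series.sddec[-1] if series.sddec.size else np.nan
    for name, arr, stats in (("sdnn", series.sdnn, ("mean", "min", "max")),
                             ("sddec", series.sddec, ("mean", "max"))):
        ok = np.isfinite(arr)
        for st in stats:
            key = f"{name}_{st}"
            out[key] = float(getattr(np, st)(arr[ok])) if ok.any() else np.nan
    out["meannn_slope"] = _ls_slope(series.eval_times, series.meannn)

    vals, times = nn.nn, nn.beat_times
    if vals.size >= 2:
        q10 = float(np.quantile(vals, 0.10))
        excess = np.clip(vals - q10, 0.0, None)
        out["auc_nn"] = float(np.trapezoid(excess, times))
        auc_dec = 0.0
        for r in deceleration_runs(vals):
            auc_dec += float(np.trapezoid(excess[r], times[r]))
        out["auc_dec"] = auc_dec
        out["dec_fraction"] = float(np.mean(np.diff(vals) > 0))
    else:
        out["auc_nn"] = out["auc_dec"] = out["dec_fraction"] = np.nan
    return out


# ---------------------------------------------------------------------------
# vital-sign and correlation features
# ---------------------------------------------------------------------------

def _beyond(values: np.ndarray, threshold: float, orientation: str) -> np.ndarray:
    with np.errstate(invalid="ignore"):
        b = values < threshold if orientation == "low" else values > threshold
    return b & np.isfinite(values)


def vital_features(trace: VitalTrace, thresholds: SignalThresholds) -> dict[str, float]:
    """The 13 per-signal features on a 1 Hz pre-window trace whose final grid
    point is the anchor instant.  Statistics run over present samples only;
    the occurring-moment value is the last non-missing sample."""
    sig = trace.signal
    t, v = trace.times, trace.values
    ok = np.isfinite(v)
    cols = _vital_columns(sig)
    if not ok.any():
        return {c: np.nan for c in cols}
    t_end = t[-1]
    vp = v[ok]
    tp = t[ok]
    occ = float(vp[-1])
    last = tp > t_end - LAST_WINDOW_S
    first = tp < t[0] + FIRST_WINDOW_S
    beyond_y = _beyond(v, thresholds.yellow, thresholds.orientation)
    beyond_r = _beyond(v, thresholds.red, thresholds.orientation)
    # excursions: number of maximal runs of beyond-yellow present samples
    runs_y = np.diff(np.concatenate(([0], beyond_y[ok].astype(np.int8))))
    out = {
        cols[0]: occ,
        cols[1]: float(vp.mean()),
        cols[2]: float(vp.std()),
        cols[3]: float(vp.min()),
        cols[4]: float(vp.max()),
        cols[5]: float(vp.max() - vp.min()),
        cols[6]: _ls_slope(t, v),
        cols[7]: _ls_slope(tp[last], vp[last]),
        cols[8]: float(vp[last].mean()) if last.any() else np.nan,
        cols[9]: float(beyond_y.sum()),
        cols[10]: float(beyond_r.sum()),
        cols[11]: float((runs_y == 1).sum()),
        cols[12]: occ - float(vp[first].mean()) if first.any() else np.nan,
    }
    return out


def correlation_features(traces: Mapping[str, VitalTrace]) -> dict[str, float]:
    """Pearson correlations of (HR,BR), (HR,SpO2), (BR,SpO2) over the full
    pre window and the final 50 s; missing when fewer than 3 pairwise-complete
    samples or a signal has zero variance."""
    pairs = (("HR", "BR"), ("HR", "SpO2"), ("BR", "SpO2"))
    t_end = traces["HR"].times[-1]
    out: dict[str, float] = {}
    for suffix, restrict in (("", None), ("_last50", t_end - LAST_WINDOW_S)):
        for a, b in pairs:
            va, vb = traces[a].values, traces[b].values
            tt = traces[a].times
            m = np.isfinite(va) & np.isfinite(vb)
            if restrict is not None:
                m &= tt > restrict
            key = f"corr_{a}_{b}{suffix}"
            if m.sum() < 3 or va[m].std() == 0 or vb[m].std() == 0:
                out[key] = np.nan
            else:
                out[key] = float(np.corrcoef(va[m], vb[m])[0, 1])
    return out


# ---------------------------------------------------------------------------
# context features and the full matrix
# ---------------------------------------------------------------------------

def category_code(category: str) -> int:
    return YELLOW_CATEGORIES.index(category)


def context_features(episode: Episode, meta: InfantMeta) -> dict[str, float]:
    """Anchor category code, pre-window alarm counts (anchor excluded) and
    the 3 metadata values."""
    pre = episode.pre_alarms
    return {
        "meta_gestational_age_wk": meta.gestational_age_wk,
        "meta_postnatal_age_d": meta.postnatal_age_d,
        "meta_postmenstrual_age_wk": meta.postmenstrual_age_wk,
        "yellow_category_code": float(category_code(episode.anchor_category)),
        "pre_yellow_count": float((pre["color"] == "yellow").sum()) if len(pre) else 0.0,
        "pre_red_count": float((pre["color"] == "red").sum()) if len(pre) else 0.0,
    }


def episode_features(episode: Episode, meta: InfantMeta,
                     settings: AlarmSettings) -> dict[str, float]:
    """The full 63-value feature dict for one episode."""
    thr = ThresholdSet.from_settings(settings, episode.anchor_category)
    row = context_features(episode, meta)
    for sig in SIGNALS:
        row.update(vital_features(episode.pre_vitals[sig], thr.for_signal(sig)))
    row.update(correlation_features(episode.pre_vitals))
    window = (episode.anchor_time - episode.window_spec.pre_s, episode.anchor_time)
    nn_clean = clean_nn(episode.pre_nn)
    series = hrv_series(nn_clean, window)
    row.update(hrv_features(series, nn_clean, window))
    return row


def build_matrix(episodes: Sequence[Episode], meta_table: pd.DataFrame,
                 settings: AlarmSettings) -> tuple[pd.DataFrame, pd.Series]:
    """One row per episode, 63 columns in the frozen order, plus the label
    vector (1 = YtR case, 0 = YtnR control)."""
    meta_idx = meta_table.set_index("infant_id")
    missing = sorted({ep.infant_id for ep in episodes} - set(meta_idx.index))
    if missing:
        raise ValueError(f"metadata missing for infant(s): {missing}")
    rows, labels = [], []
    for ep in episodes:
        m = meta_idx.loc[ep.infant_id]
        postnatal = float(m["postnatal_age_start_d"]) + ep.anchor_time / 86400.0
        meta = InfantMeta(float(m["gestational_age_wk"]), postnatal)
        rows.append(episode_features(ep, meta, settings))
        labels.append(1 if ep.is_case else 0)
    X = pd.DataFrame(rows, columns=FEATURE_COLUMNS)
    y = pd.Series(labels, name="label", dtype=int)
    return X, y


def feature_schema() -> list[dict]:
    """Sidecar schema: name, family and missing policy per feature."""
    units = {"meta_gestational_age_wk": "weeks", "meta_postnatal_age_d": "days",
             "meta_postmenstrual_age_wk": "weeks", "yellow_category_code": "code",
             "pre_yellow_count": "count", "pre_red_count": "count"}
    schema = []
    for name in FEATURE_COLUMNS:
        fam = FAMILY_OF[name]
        unit = units.get(name)
        if unit is None:
            if fam in ("HR",):
                unit = "bpm or derived"
            elif fam == "BR":
                unit = "breaths/min or derived"
            elif fam == "SpO2":
                unit = "% or derived"
            elif fam == "corr":
                unit = "dimensionless"
            else:
                unit = "s or derived"
        schema.append({"name": name, "family": fam, "unit": unit,
                       "missing_policy": "NaN routed by tree default direction"})
    return schema


def write_feature_table(X: pd.DataFrame, y: pd.Series, path) -> None:
    out = X.copy()
    out["label"] = y.to_numpy()
    out.to_csv(path, index=False)
    Path(str(path)).with_suffix(".schema.json").write_text(
        json.dumps(feature_schema(), indent=2) + "\n", encoding="utf-8")
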