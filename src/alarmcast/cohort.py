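"""Cohort construction: yellow-to-red episode labeling, the yellow-to-red
transition-time CDF, and stratified train/test splits with CV folds.

A yellow alarm anchors one candidate *episode*.  Its pre-alarm window is the
closed 1 Hz grid ``[t_alarm - pre_s + 1, t_alarm]`` (the alarm instant is the
final grid point); its post-alarm window is the half-open interval
``(t_alarm, t_alarm + post_s]``.  The episode is a case (YtR) iff at least
one red alarm of any category falls in the post window, otherwise a control
(YtnR).  Splitting is at the episode level irrespective of infant.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from sklearn.model_selection import StratifiedKFold, train_test_split

from .io import (DEFAULT_GAP_MAX_S, SIGNALS, AlarmLog, NNSeries, VitalTrace,
                 resample_1hz, sufficiency_filter)

#: the window-length grid studied: pre-alarm fixed at 3 min while the post
#: window shrinks, then the pre window shrinks at a 1 min post window.
WINDOW_GRID = ((180, 180), (180, 120), (180, 60), (120, 60), (60, 60))


@dataclass(frozen=True)
class WindowSpec:
    pre_s: int
    post_s: int

    def __post_init__(self):
        if self.pre_s <= 0 or self.post_s <= 0:
            raise ValueError("window lengths must be positive")

    def __str__(self) -> str:
        return f"pre{self.pre_s}_post{self.post_s}"


@dataclass
class Episode:
    """One yellow-alarm anchor with its pre-alarm data and YtR/YtnR label."""

    infant_id: str
    anchor_time: float
    anchor_category: str
    window_spec: WindowSpec
    pre_vitals: dict[str, VitalTrace]
    pre_nn: NNSeries
    pre_alarms: pd.DataFrame          # alarms in the pre window, anchor excluded
    post_reds: pd.DataFrame           # red alarms in (anchor, anchor + post_s]
    label: str                        # "YtR" | "YtnR"
    lead_times_s: np.ndarray          # anchor-to-red delays, in (0, post_s]

    @property
    def is_case(self) -> bool:
        return self.label == "YtR"


def _label_one(anchor_t: float, infant_log: pd.DataFrame, post_s: float
               ) -> tuple[str, np.ndarray, pd.DataFrame]:
    reds = infant_log[(infant_log["color"] == "red")
                      & (infant_log["time_s"] > anchor_t)
                      & (infant_log["time_s"] <= anchor_t + post_s)]
    leads = (reds["time_s"] - anchor_t).to_numpy()
    return ("YtR" if len(reds) else "YtnR"), leads, reds


def label_episodes(log: AlarmLog,
                   vitals: Mapping[str, Mapping[str, VitalTrace]],
                   nn: Mapping[str, NNSeries],
                   spec: WindowSpec,
                   gap_max_s: float = DEFAULT_GAP_MAX_S,
                   ) -> tuple[list[Episode], pd.DataFrame]:
    """Build one candidate episode per yellow alarm and label it YtR/YtnR.

    Episodes are excluded (with a reason) when the pre-alarm window extends
    outside the vital-sign record, fails the missing-data sufficiency filter,
    or contains no NN samples.  Post-window alarm coverage is taken as
    complete, so labels are always assigned from the log.
    """
    episodes: list[Episode] = []
    exclusions: list[dict] = []
    for iid in log.infants():
        infant_log = log.df[log.df["infant_id"] == iid]
        yellows = infant_log[infant_log["color"] == "yellow"]
        if yellows.empty:
            continue
        if iid not in vitals:
            for row in yellows.itertuples(index=False):
                exclusions.append({"infant_id": iid, "anchor_time": row.time_s,
                                   "category": row.category, "reason": "no vital-sign record"})
            continue
        tr3 = vitals[iid]
        nn_ser = nn.get(iid)
        for row in yellows.itertuples(index=False):
            t_a = row.time_s
            grid_start = t_a - spec.pre_s + 1
            rec = {"infant_id": iid, "anchor_time": t_a, "category": row.category}
            # window must lie inside the record of every signal
            outside = any(grid_start < tr3[s].times[0] or t_a > tr3[s].times[-1]
                          for s in SIGNALS if len(tr3[s]))
            if outside or any(len(tr3[s]) == 0 for s in SIGNALS):
                exclusions.append({**rec, "reason": "pre window outside record"})
                continue
            window = {s: _resample_window(tr3[s], grid_start, spec.pre_s, gap_max_s)
                      for s in SIGNALS}
            ok = sufficiency_filter(window)
            if not ok:
                exclusions.append({**rec, "reason": f"insufficient data ({ok.reason})"})
                continue
            pre_nn = (nn_ser.restrict(t_a - spec.pre_s, t_a) if nn_ser is not None
                      else NNSeries(iid, np.empty(0), np.empty(0)))
            if len(pre_nn) == 0:
                exclusions.append({**rec, "reason": "no NN samples in pre window"})
                continue
            label, leads, reds = _label_one(t_a, infant_log, spec.post_s)
            pre_alarms = infant_log[(infant_log["time_s"] >= t_a - spec.pre_s)
                                    & (infant_log["time_s"] < t_a)]
            episodes.append(Episode(iid, t_a, row.category, spec, window, pre_nn,
                                    pre_alarms.reset_index(drop=True),
                                    reds.reset_index(drop=True), label, leads))
    excl_df = pd.DataFrame(exclusions, columns=["infant_id", "anchor_time",
                                                "category", "reason"])
    return episodes, excl_df


def _resample_window(trace: VitalTrace, grid_start: float, grid_len: int,
                     gap_max_s: float) -> VitalTrace:
    # restrict to the window plus margin before spline fitting: cheap and
    # numerically identical at the knots
    lo = np.searchsorted(trace.times, grid_start - 4 * gap_max_s)
    hi = np.searchsorted(trace.times, grid_start + grid_len + 4 * gap_max_s)
    sub = VitalTrace(trace.infant_id, trace.signal, trace.times[lo:hi], trace.values[lo:hi])
    return resample_1hz(sub, grid_start, grid_len, gap_max_s)


# ---------------------------------------------------------------------------
# transition CDF
# ---------------------------------------------------------------------------

@dataclass
class TransitionCDF:
    """Empirical CDF of yellow-to-red transition times, censored at
    ``censor_s``: each red alarm with a preceding yellow within the censor
    horizon (same infant) contributes the delay from the *most recent* such
    yellow."""

    support: np.ndarray       # sorted unique delays (s)
    probs: np.ndarray         # F(support), right-continuous, ends at 1
    n_transitions: int
    censor_s: float

    @property
    def empty(self) -> bool:
        return self.n_transitions == 0

    def evaluate(self, t) -> np.ndarray | float:
        """F(t) = fraction of transition delays <= t."""
        t = np.asarray(t, dtype=float)
        if self.empty:
            out = np.full(t.shape, np.nan)
            return float(out) if out.ndim == 0 else out
        idx = np.searchsorted(self.support, t, side="right")
        f = np.concatenate(([0.0], self.probs))[idx]
        return float(f) if f.ndim == 0 else f

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({"delay_s": self.support, "cdf": self.probs})


def transition_cdf(log: AlarmLog, censor_s: float = 180.0) -> TransitionCDF:
    delays = []
    for iid in log.infants():
        sub = log.df[log.df["infant_id"] == iid]
        yt = sub.loc[sub["color"] == "yellow", "time_s"].to_numpy()
        rt = sub.loc[sub["color"] == "red", "time_s"].to_numpy()
        if yt.size == 0 or rt.size == 0:
            continue
        idx = np.searchsorted(yt, rt, side="left") - 1   # most recent strictly earlier yellow
        for r, j in zip(rt, idx):
            if j >= 0 and 0 < r - yt[j] <= censor_s:
                delays.append(r - yt[j])
    if not delays:
        return TransitionCDF(np.empty(0), np.empty(0), 0, censor_s)
    d = np.sort(np.asarray(delays, dtype=float))
    support, counts = np.unique(d, return_counts=True)
    probs = np.cumsum(counts) / d.size
    return TransitionCDF(support, probs, d.size, censor_s)


# ---------------------------------------------------------------------------
# splits and folds
# ---------------------------------------------------------------------------

@dataclass
class SplitPlan:
    """Episode-level train/test split with optional CV folds inside train."""

    train_idx: np.ndarray
    test_idx: np.ndarray
    seed: int
    cv_folds: list[tuple[np.ndarray, np.ndarray]] = field(default_factory=list)

    def __post_init__(self):
        self.train_idx = np.asarray(self.train_idx, dtype=int)
        self.test_idx = np.asarray(self.test_idx, dtype=int)
        if np.intersect1d(self.train_idx, self.test_idx).size:
            raise ValueError("train and test sets overlap")

    def to_json(self, path=None) -> str:
        d = {"seed": int(self.seed),
             "train_idx": self.train_idx.tolist(),
             "test_idx": self.test_idx.tolist(),
             "cv_folds": [[tr.tolist(), va.tolist()] for tr, va in self.cv_folds]}
        text = json.dumps(d, sort_keys=True)
        if path is not None:
            Path(path).write_text(text + "\n", encoding="utf-8")
        return text

    @classmethod
    def from_json(cls, source) -> "SplitPlan":
        if isinstance(source, (str, Path)) and Path(source).exists():
            d = json.loads(Path(source).read_text(encoding="utf-8"))
        else:
            d = json.loads(source)
        plan = cls(np.array(d["train_idx"]), np.array(d["test_idx"]), d["seed"])
        plan.cv_folds = [(np.array(tr), np.array(va)) for tr, va in d["cv_folds"]]
        return plan


def split_train_test(labels: Sequence[str], frac: float = 0.8, seed: int = 0) -> SplitPlan:
    """Stratified episode-level 80/20 split, deterministic for a fixed seed."""
    y = np.asarray(labels)
    idx = np.arange(y.size)
    train, test = train_test_split(idx, train_size=frac, stratify=y, random_state=int(seed))
    return SplitPlan(np.sort(train), np.sort(test), int(seed))


def make_cv_folds(plan: SplitPlan, labels: Sequence[str], k: int = 5,
                  seed: int | None = None) -> SplitPlan:
    """Attach ``k`` stratified CV folds partitioning the training set.

    Fold indices refer to positions in the *full* episode list.
    """
    y = np.asarray(labels)[plan.train_idx]
    counts = pd.Series(y).value_counts()
    if (counts < k).any():
        small = counts[counts < k]
        raise ValueError(
            f"class(es) {dict(small)} have fewer than k={k} training episodes; "
            f"use a smaller k")
    seed = plan.seed if seed is None else int(seed)
    skf = StratifiedKFold(n_splits=k, shuffle=True, random_state=seed)
    folds = [(plan.train_idx[tr], plan.train_idx[va]) for tr, va in skf.split(y, y)]
    return SplitPlan(plan.train_idx, plan.test_idx, plan.seed, folds)


# ---------------------------------------------------------------------------
# episode persistence
# ---------------------------------------------------------------------------

def save_episodes(episodes: Sequence[Episode], exclusions: pd.DataFrame, out_dir) -> None:
    """Persist episodes as a directory: ``episodes.csv`` plus per-episode
    window files in the vitals / NN CSV dialects."""
    from .io import write_nn, write_vitals

    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    rows = []
    for k, ep in enumerate(episodes):
        rows.append({"episode": k, "infant_id": ep.infant_id,
                     "anchor_time": ep.anchor_time, "category": ep.anchor_category,
                     "pre_s": ep.window_spec.pre_s, "post_s": ep.window_spec.post_s,
                     "label": ep.label,
                     "lead_times_s": ";".join(repr(float(t)) for t in ep.lead_times_s)})
        write_vitals([ep.pre_vitals[s] for s in SIGNALS], out / f"ep{k:06d}_vitals.csv")
        write_nn([ep.pre_nn], out / f"ep{k:06d}_nn.csv")
        ep.pre_alarms.to_csv(out / f"ep{k:06d}_prealarms.csv", index=False)
    pd.DataFrame(rows).to_csv(out / "episodes.csv", index=False)
    exclusions.to_csv(out / "exclusions.csv", index=False)


def load_episodes(ep_dir) -> tuple[list[Episode], pd.DataFrame]:
    from .io import read_nn, read_vitals

    out = Path(ep_dir)
    table = pd.read_csv(out / "episodes.csv", dtype={"infant_id": str})
    episodes = []
    for row in table.itertuples(index=False):
        k = int(row.episode)
        traces = read_vitals(out / f"ep{k:06d}_vitals.csv")
        window = {tr.signal: tr for tr in traces}
        nn_list = read_nn(out / f"ep{k:06d}_nn.csv")
        pre_nn = nn_list[0] if nn_list else NNSeries(row.infant_id, np.empty(0), np.empty(0))
        pre_alarms = pd.read_csv(out / f"ep{k:06d}_prealarms.csv", dtype={"infant_id": str})
        leads = (np.array([float(x) for x in str(row.lead_times_s).split(";") if x and x != "nan"])
                 if isinstance(row.lead_times_s, str) or not pd.isna(row.lead_times_s)
                 else np.empty(0))
        spec = WindowSpec(int(row.pre_s), int(row.post_s))
        reds = pd.DataFrame({"infant_id": row.infant_id,
                             "time_s": row.anchor_time + leads,
                             "color": "red", "category": "desaturation"})
        episodes.append(Episode(row.infant_id, float(row.anchor_time), row.category,
                                spec, window, pre_nn, pre_alarms, reds, row.label, leads))
    exclusions = (pd.read_csv(out / "exclusions.csv", dtype={"infant_id": str})
                  if (out / "exclusions.csv").exists() else pd.DataFrame())
    return episodes, exclusions
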