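"""Report rendering: group-mean overlays, transition-CDF tables and the
per-window performance summary, all as plain CSV/JSON derived solely from
persisted artifacts."""

from __future__ import annotations

from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from .cohort import Episode, TransitionCDF
from .features import clean_nn, hrv_series
from .io import SIGNALS


def overlay_table(episodes: Sequence[Episode], step_s: float = 10.0) -> pd.DataFrame:
    """Case/control group means +- SD of HR, BR, SpO2, SDNN and SDDec at
    ``step_s`` resolution across the pre-alarm window (offset 0 = anchor)."""
    if not episodes:
        return pd.DataFrame(columns=["series", "offset_s", "label", "mean", "sd", "n"])
    pre_s = episodes[0].window_spec.pre_s
    n_pts = int(pre_s // step_s)
    offsets = -step_s * np.arange(n_pts - 1, -1, -1)  # ... -20, -10, 0
    rows = []
    stacks: dict[tuple[str, str], list[np.ndarray]] = {}
    for ep in episodes:
        for sig in SIGNALS:
            tr = ep.pre_vitals[sig]
            idx = np.searchsorted(tr.times, ep.anchor_time + offsets)
            idx = np.clip(idx, 0, len(tr) - 1)
            stacks.setdefault((sig, ep.label), []).append(tr.values[idx])
        window = (ep.anchor_time - pre_s, ep.anchor_time)
        series = hrv_series(clean_nn(ep.pre_nn), window)
        take = series.eval_times - ep.anchor_time
        sd = np.interp(offsets, take, series.sdnn, left=np.nan, right=np.nan)
        dd = np.interp(offsets, take, series.sddec, left=np.nan, right=np.nan)
        stacks.setdefault(("SDNN", ep.label), []).append(sd)
        stacks.setdefault(("SDDec", ep.label), []).append(dd)
    for (name, label), arrs in sorted(stacks.items()):
        m = np.vstack(arrs)
        with np.errstate(invalid="ignore"):
            mean = np.nanmean(m, axis=0)
            sd = np.nanstd(m, axis=0)
        n = np.isfinite(m).sum(axis=0)
        for off, mu, s, k in zip(offsets, mean, sd, n):
            rows.append({"series": name, "offset_s": float(off), "label": label,
                         "mean": float(mu) if np.isfinite(mu) else np.nan,
                         "sd": float(s) if np.isfinite(s) else np.nan, "n": int(k)})
    return pd.DataFrame(rows)


def cdf_table(cdf: TransitionCDF) -> pd.DataFrame:
    df = cdf.to_frame()
    df["n_transitions"] = cdf.n_transitions
    df["censor_s"] = cdf.censor_s
    return df


def performance_summary(report_frames: dict[str, pd.DataFrame]) -> pd.DataFrame:
    """Pivot per-window report rows into a models x windows table with
    ``AUROC (sensitivity)`` cells for both train-CV and test."""
    frames = []
    for window, df in report_frames.items():
        d = df.copy()
        d["window"] = window
        frames.append(d)
    if not frames:
        return pd.DataFrame()
    allrows = pd.concat(frames, ignore_index=True)

    def cell(r, prefix):
        return f"{r[f'{prefix}_auroc']:.3f} ({r[f'{prefix}_sensitivity']:.3f})"

    allrows["train_cell"] = [cell(r, "train_cv") for _, r in allrows.iterrows()]
    allrows["test_cell"] = [cell(r, "test") for _, r in allrows.iterrows()]
    out = allrows.pivot_table(index="model", columns="window",
                              values=["train_cell", "test_cell"],
                              aggfunc="first", sort=False)
    out.columns = [f"{a}:{b}" for a, b in out.columns]
    return out.reset_index()


def write_reports(out_dir, *, summary: pd.DataFrame | None = None,
                  overlays: pd.DataFrame | None = None,
                  cdf: pd.DataFrame | None = None) -> list[Path]:
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    written = []
    if summary is not None:
        p = out / "performance_summary.csv"
        summary.to_csv(p, index=False)
        written.append(p)
    if overlays is not None:
        p = out / "overlays.csv"
        overlays.to_csv(p, index=False)
        written.append(p)
    if cdf is not None:
        p = out / "transition_cdf.csv"
        cdf.to_csv(p, index=False)
        written.append(p)
    return written
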