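"""File formats, containers, 1 Hz resampling and the data-sufficiency filter.

Vital-sign streams, beat-interval (NN) series and monitor alarm logs are
exchanged as plain CSV:

* vitals:    ``infant_id,time_s,signal,value``   (empty value = missing sample)
* NN series: ``infant_id,beat_time_s,nn_s``
* alarm log: ``infant_id,time_s,color,category``

Times are real-valued seconds from a per-infant epoch.  Pre-alarm windows are
anchored so that the final 1 Hz grid point coincides with the alarm instant.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Iterator, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy.interpolate import CubicSpline

from .errors import ParseError

SIGNALS = ("HR", "BR", "SpO2")

YELLOW_CATEGORIES = ("HR-low", "HR-high", "SpO2-low", "SpO2-high", "BP-low", "BP-high")
RED_CATEGORIES = ("desaturation", "bradycardia", "apnea", "tachycardia", "BP", "fibrillation")

#: cubic-spline interpolation bridges gaps up to this many seconds; longer
#: holes stay missing so the sufficiency filter, not the interpolant, governs
#: large dropouts.
DEFAULT_GAP_MAX_S = 5.0


# ---------------------------------------------------------------------------
# containers
# ---------------------------------------------------------------------------

@dataclass
class VitalTrace:
    """One signal's timestamped ~1 Hz series with explicit missingness (NaN)."""

    infant_id: str
    signal: str
    times: np.ndarray
    values: np.ndarray

    def __post_init__(self):
        self.times = np.asarray(self.times, dtype=float)
        self.values = np.asarray(self.values, dtype=float)
        if self.signal not in SIGNALS:
            raise ValueError(f"unknown signal {self.signal!r}; expected one of {SIGNALS}")
        if self.times.shape != self.values.shape:
            raise ValueError("times and values must have equal length")
        if self.times.size > 1 and not np.all(np.diff(self.times) > 0):
            raise ValueError(f"times must be strictly increasing ({self.infant_id}/{self.signal})")
        present = np.isfinite(self.values)
        if np.any(np.isinf(self.values)):
            raise ValueError("values must be finite or NaN")
        if self.signal == "SpO2" and present.any():
            v = self.values[present]
            if v.min() < 0 or v.max() > 100:
                raise ValueError("SpO2 values must lie in [0, 100]")

    def __len__(self) -> int:
        return self.times.size

    @property
    def missing(self) -> np.ndarray:
        return ~np.isfinite(self.values)


@dataclass
class NNSeries:
    """Normal-to-normal interbeat intervals: each ``nn[i]`` is the interval
    ending at ``beat_times[i]`` (seconds)."""

    infant_id: str
    beat_times: np.ndarray
    nn: np.ndarray

    def __post_init__(self):
        self.beat_times = np.asarray(self.beat_times, dtype=float)
        self.nn = np.asarray(self.nn, dtype=float)
        if self.beat_times.shape != self.nn.shape:
            raise ValueError("beat_times and nn must have equal length")
        if self.beat_times.size > 1 and not np.all(np.diff(self.beat_times) > 0):
            raise ValueError(f"beat_times must be strictly increasing ({self.infant_id})")
        if self.nn.size and not np.all(self.nn > 0):
            raise ValueError("nn intervals must be positive")

    def __len__(self) -> int:
        return self.beat_times.size

    def restrict(self, t_start: float, t_end: float) -> "NNSeries":
        """Beats with ``t_start < beat_time <= t_end``."""
        lo = np.searchsorted(self.beat_times, t_start, side="right")
        hi = np.searchsorted(self.beat_times, t_end, side="right")
        return NNSeries(self.infant_id, self.beat_times[lo:hi], self.nn[lo:hi])


@dataclass(frozen=True)
class AlarmEvent:
    infant_id: str
    time: float
    color: str
    category: str

    def __post_init__(self):
        if self.color == "yellow":
            vocab = YELLOW_CATEGORIES
        elif self.color == "red":
            vocab = RED_CATEGORIES
        else:
            raise ValueError(f"unknown alarm color {self.color!r}")
        if self.category not in vocab:
            raise ValueError(f"category {self.category!r} not valid for {self.color} alarms")


class AlarmLog:
    """Ordered collection of alarm events, sorted by (infant_id, time)."""

    COLUMNS = ("infant_id", "time_s", "color", "category")

    def __init__(self, events: Iterable[AlarmEvent] | pd.DataFrame = ()):
        if isinstance(events, pd.DataFrame):
            df = events.copy()
        else:
            rows = [(e.infant_id, e.time, e.color, e.category) for e in events]
            df = pd.DataFrame(rows, columns=list(self.COLUMNS))
        if df.empty:
            df = pd.DataFrame(columns=list(self.COLUMNS))
        df["infant_id"] = df["infant_id"].astype(str)
        df["time_s"] = df["time_s"].astype(float)
        self._validate(df)
        self.df = df.sort_values(["infant_id", "time_s"], kind="mergesort").reset_index(drop=True)

    @staticmethod
    def _validate(df: pd.DataFrame) -> None:
        yellow_bad = (df["color"] == "yellow") & ~df["category"].isin(YELLOW_CATEGORIES)
        red_bad = (df["color"] == "red") & ~df["category"].isin(RED_CATEGORIES)
        color_bad = ~df["color"].isin(("yellow", "red"))
        bad = yellow_bad | red_bad | color_bad
        if bad.any():
            i = int(np.flatnonzero(bad.to_numpy())[0])
            raise ValueError(
                f"invalid alarm row {i}: color={df['color'].iat[i]!r} "
                f"category={df['category'].iat[i]!r}"
            )

    def __len__(self) -> int:
        return len(self.df)

    def __iter__(self) -> Iterator[AlarmEvent]:
        for row in self.df.itertuples(index=False):
            yield AlarmEvent(row.infant_id, row.time_s, row.color, row.category)

    def yellows(self) -> pd.DataFrame:
        return self.df[self.df["color"] == "yellow"]

    def reds(self) -> pd.DataFrame:
        return self.df[self.df["color"] == "red"]

    def for_infant(self, infant_id: str) -> "AlarmLog":
        return AlarmLog(self.df[self.df["infant_id"] == str(infant_id)])

    def infants(self) -> list[str]:
        return sorted(self.df["infant_id"].unique())


# ---------------------------------------------------------------------------
# CSV readers / writers
# ---------------------------------------------------------------------------

def _read_rows(path) -> tuple[list[str], list[list[str]]]:
    text = Path(path).read_text(encoding="utf-8")
    lines = [ln for ln in text.splitlines()]
    if not lines:
        raise ParseError("empty file", path=path)
    header = [c.strip() for c in lines[0].split(",")]
    rows = []
    for ln in lines[1:]:
        if ln.strip() == "":
            rows.append(None)  # keep line numbering
        else:
            rows.append([c.strip() for c in ln.split(",")])
    return header, rows


def _parse_float(cell: str, path, line, column: str, allow_empty=False) -> float:
    if cell == "":
        if allow_empty:
            return np.nan
        raise ParseError(f"empty {column} field", path=path, line=line)
    try:
        return float(cell)
    except ValueError:
        raise ParseError(f"non-numeric {column} value {cell!r}", path=path, line=line) from None


def read_vitals(path) -> list[VitalTrace]:
    """Parse a vitals CSV into one :class:`VitalTrace` per (infant, signal).

    Raises :class:`ParseError` naming the first offending line for unknown
    signal names, malformed numbers or non-monotone timestamps.
    """
    header, rows = _read_rows(path)
    if header != ["infant_id", "time_s", "signal", "value"]:
        raise ParseError(f"unexpected vitals header {header}", path=path, line=1)
    series: dict[tuple[str, str], tuple[list, list, list]] = {}
    order: list[tuple[str, str]] = []
    for i, row in enumerate(rows):
        if row is None:
            continue
        line = i + 2
        if len(row) != 4:
            raise ParseError(f"expected 4 fields, got {len(row)}", path=path, line=line)
        infant, t_s, signal, value = row
        if signal not in SIGNALS:
            raise ParseError(f"unknown signal name {signal!r}", path=path, line=line)
        t = _parse_float(t_s, path, line, "time_s")
        v = _parse_float(value, path, line, "value", allow_empty=True)
        key = (infant, signal)
        if key not in series:
            series[key] = ([], [], [])
            order.append(key)
        ts, vs, lns = series[key]
        if ts and t <= ts[-1]:
            raise ParseError(f"non-monotone time_s for {infant}/{signal}", path=path, line=line)
        ts.append(t)
        vs.append(v)
        lns.append(line)
    return [VitalTrace(inf, sig, np.array(ts), np.array(vs))
            for (inf, sig), (ts, vs, _) in ((k, series[k]) for k in order)]


def write_vitals(traces: Sequence[VitalTrace], path) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        fh.write("infant_id,time_s,signal,value\n")
        for tr in traces:
            for t, v in zip(tr.times, tr.values):
                cell = "" if not np.isfinite(v) else repr(float(v))
                fh.write(f"{tr.infant_id},{float(t)!r},{tr.signal},{cell}\n")


def read_nn(path) -> list[NNSeries]:
    header, rows = _read_rows(path)
    if header != ["infant_id", "beat_time_s", "nn_s"]:
        raise ParseError(f"unexpected NN header {header}", path=path, line=1)
    series: dict[str, tuple[list, list]] = {}
    for i, row in enumerate(rows):
        if row is None:
            continue
        line = i + 2
        if len(row) != 3:
            raise ParseError(f"expected 3 fields, got {len(row)}", path=path, line=line)
        infant, bt_s, nn_s = row
        bt = _parse_float(bt_s, path, line, "beat_time_s")
        nn = _parse_float(nn_s, path, line, "nn_s")
        if nn <= 0:
            raise ParseError(f"non-positive nn_s {nn!r}", path=path, line=line)
        ts, nns = series.setdefault(infant, ([], []))
        if ts and bt <= ts[-1]:
            raise ParseError(f"non-monotone beat_time_s for {infant}", path=path, line=line)
        ts.append(bt)
        nns.append(nn)
    return [NNSeries(inf, np.array(ts), np.array(nns)) for inf, (ts, nns) in series.items()]


def write_nn(series: Sequence[NNSeries], path) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        fh.write("infant_id,beat_time_s,nn_s\n")
        for s in series:
            for t, nn in zip(s.beat_times, s.nn):
                fh.write(f"{s.infant_id},{float(t)!r},{float(nn)!r}\n")


def read_alarms(path) -> AlarmLog:
    header, rows = _read_rows(path)
    if header != ["infant_id", "time_s", "color", "category"]:
        raise ParseError(f"unexpected alarm header {header}", path=path, line=1)
    events = []
    for i, row in enumerate(rows):
        if row is None:
            continue
        line = i + 2
        if len(row) != 4:
            raise ParseError(f"expected 4 fields, got {len(row)}", path=path, line=line)
        infant, t_s, color, category = row
        t = _parse_float(t_s, path, line, "time_s")
        try:
            events.append(AlarmEvent(infant, t, color, category))
        except ValueError as exc:
            raise ParseError(str(exc), path=path, line=line) from None
    return AlarmLog(events)


def write_alarms(log: AlarmLog, path) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        fh.write("infant_id,time_s,color,category\n")
        for row in log.df.itertuples(index=False):
            fh.write(f"{row.infant_id},{float(row.time_s)!r},{row.color},{row.category}\n")


# ---------------------------------------------------------------------------
# 1 Hz resampling
# ---------------------------------------------------------------------------

def resample_1hz(trace: VitalTrace, grid_start: float, grid_len: int,
                 gap_max_s: float = DEFAULT_GAP_MAX_S) -> VitalTrace:
    """Resample a trace onto the exact 1 Hz grid ``grid_start, grid_start+1, ...``
    by cubic-spline interpolation through the non-missing samples.

    Grid points outside the span of the non-missing input, or strictly inside
    an input gap longer than ``gap_max_s`` seconds, remain missing.  Fewer
    than four usable samples yields an all-missing trace (cubic minimum).
    """
    grid = grid_start + np.arange(int(grid_len), dtype=float)
    present = np.isfinite(trace.values)
    t_ok = trace.times[present]
    v_ok = trace.values[present]
    out = np.full(grid.shape, np.nan)
    if t_ok.size >= 4:
        spline = CubicSpline(t_ok, v_ok)
        inside = (grid >= t_ok[0]) & (grid <= t_ok[-1])
        out[inside] = spline(grid[inside])
        gaps = np.diff(t_ok)
        for j in np.flatnonzero(gaps > gap_max_s):
            in_gap = (grid > t_ok[j]) & (grid < t_ok[j + 1])
            out[in_gap] = np.nan
        if trace.signal == "SpO2":
            np.clip(out, 0.0, 100.0, out=out)
    return VitalTrace(trace.infant_id, trace.signal, grid, out)


# ---------------------------------------------------------------------------
# sufficiency filter
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class SufficiencyResult:
    keep: bool
    reason: str | None = None
    signal: str | None = None

    def __bool__(self) -> bool:
        return self.keep


def longest_missing_run(missing: np.ndarray) -> int:
    """Length (in samples) of the longest run of consecutive missing samples."""
    best = run = 0
    for m in missing:
        run = run + 1 if m else 0
        best = max(best, run)
    return best


def _longest_run_fast(missing: np.ndarray) -> int:
    if not missing.any():
        return 0
    padded = np.concatenate(([False], missing, [False]))
    d = np.diff(padded.astype(np.int8))
    starts = np.flatnonzero(d == 1)
    ends = np.flatnonzero(d == -1)
    return int((ends - starts).max())


def sufficiency_filter(window: Mapping[str, VitalTrace],
                       missing_frac_max: float = 0.30,
                       consecutive_frac_max: float = 0.10) -> SufficiencyResult:
    """Keep/discard decision for a pre-alarm window of HR, BR and SpO2 traces
    on a shared 1 Hz grid.

    A window is discarded if, for any one signal, the missing fraction is
    ``>= missing_frac_max`` or the longest run of consecutive missing samples
    is ``>= consecutive_frac_max`` of the grid length (inclusive boundaries).
    """
    grids = [window[s].times for s in SIGNALS]
    for g in grids[1:]:
        if g.shape != grids[0].shape or not np.allclose(g, grids[0]):
            raise ValueError("sufficiency_filter requires all signals on the same grid")
    n = grids[0].size
    for sig in SIGNALS:
        missing = window[sig].missing
        frac = missing.mean() if n else 1.0
        if frac >= missing_frac_max:
            return SufficiencyResult(False, f"{sig}: missing fraction {frac:.3f} >= {missing_frac_max}", sig)
        run = _longest_run_fast(missing)
        if run >= consecutive_frac_max * n:
            return SufficiencyResult(False, f"{sig}: longest missing run {run} >= {consecutive_frac_max:g} x {n}", sig)
    return SufficiencyResult(True)
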