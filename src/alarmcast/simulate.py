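"""Seeded synthetic generator of neonatal vital signs, NN-interval series and
threshold-based yellow/red alarm logs.

The generator emulates the measurement context the downstream analysis
assumes: ~1 Hz vital-sign streams (HR, BR, SpO2) with dropout, a beat-interval
series consistent with 60/HR plus variability (including detection artifacts
longer than 1.5 s), and a monitor that fires a yellow or red alarm when a
signal stays beyond the corresponding threshold for a persistence delay.

Desaturation events are deliberately two-phased: every event first falls to a
*common* sub-yellow plateau (so the trajectory observed up to the advisory
alarm is identically distributed for mild and severe events), and only after
the advisory alarm does a red-crossing event continue down through the
critical threshold.  The learnable pre-alarm signal is a slow precursor drift
in SpO2 and HR that precedes red-crossing events only — mirroring the
empirical observation that case/control vital signs diverge in the final
minute before the advisory alarm.
"""

from __future__ import annotations

import hashlib
import json
import math
from dataclasses import dataclass
from pathlib import Path
from typing import Mapping

import numpy as np
import pandas as pd
from scipy.signal import lfilter

from .config import AlarmSettings, SimConfig
from .errors import ConfigurationError
from .io import (AlarmEvent, AlarmLog, NNSeries, VitalTrace, resample_1hz,
                 write_alarms, write_nn, write_vitals)

__all__ = [
    "GroundTruth", "simulate_infant", "infant_meta_table", "apply_alarm_logic",
    "generate_cohort", "load_cohort", "infant_label",
]


@dataclass
class GroundTruth:
    """Per-infant event bookkeeping for label-recovery tests."""

    infant_id: str
    onset_s: np.ndarray
    depth: np.ndarray
    duration_s: np.ndarray
    is_red: np.ndarray          # depth crosses the red SpO2 threshold
    coupled_brady: np.ndarray

    def __post_init__(self):
        self.onset_s = np.asarray(self.onset_s, dtype=float)
        self.depth = np.asarray(self.depth, dtype=float)
        self.duration_s = np.asarray(self.duration_s, dtype=float)
        self.is_red = np.asarray(self.is_red, dtype=bool)
        self.coupled_brady = np.asarray(self.coupled_brady, dtype=bool)
        if self.onset_s.size > 1 and not np.all(np.diff(self.onset_s) > 0):
            raise ValueError("event onset times must be strictly increasing")

    @property
    def n_events(self) -> int:
        return self.onset_s.size

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({
            "infant_id": self.infant_id,
            "onset_s": self.onset_s,
            "depth": self.depth,
            "duration_s": self.duration_s,
            "is_red": self.is_red.astype(int),
            "coupled_brady": self.coupled_brady.astype(int),
        })


def infant_label(index: int) -> str:
    return f"I{index:03d}"


# ---------------------------------------------------------------------------
# deterministic event-shape primitives (deviations from baseline, <= 0)
# ---------------------------------------------------------------------------

def _fall_recover(t: np.ndarray, t_start: float, start_depth: float,
                  target_depth: float, tau_f: float, tau_r: float,
                  hold_s: float) -> np.ndarray:
    """Exponential fall from ``-start_depth`` toward ``-target_depth`` (time
    constant ``tau_f``), held near nadir for ``hold_s`` beyond 3 fall time
    constants, then exponential recovery toward zero (``tau_r``)."""
    dev = np.zeros_like(t)
    t_rec = t_start + 3.0 * tau_f + hold_s
    m_fall = (t >= t_start) & (t < t_rec)
    dev[m_fall] = -(target_depth - (target_depth - start_depth)
                    * np.exp(-(t[m_fall] - t_start) / tau_f))
    v_rec = -(target_depth - (target_depth - start_depth)
              * math.exp(-(t_rec - t_start) / tau_f))
    m_rec = t >= t_rec
    dev[m_rec] = v_rec * np.exp(-(t[m_rec] - t_rec) / tau_r)
    return dev


def _onset_phase(t: np.ndarray, t0: float, depth: float, tau_f: float) -> np.ndarray:
    dev = np.zeros_like(t)
    m = t >= t0
    dev[m] = -depth * (1.0 - np.exp(-(t[m] - t0) / tau_f))
    return dev


def _precursor_ramp(t: np.ndarray, t0: float, lead_s: float, drop: float,
                    tau_r: float) -> np.ndarray:
    dev = np.zeros_like(t)
    if drop <= 0:
        return dev
    if lead_s > 0:
        m1 = (t >= t0 - lead_s) & (t < t0)
        dev[m1] = -drop * (t[m1] - (t0 - lead_s)) / lead_s
    m2 = t >= t0
    dev[m2] = -drop * np.exp(-(t[m2] - t0) / tau_r)
    return dev


def _spo2_event_dev(t: np.ndarray, cfg: SimConfig, t0: float, depth: float,
                    is_red: bool) -> np.ndarray:
    """Two-phase dip: common onset fall to the shared plateau, then (red
    events only) a post-advisory fall to the full depth before recovery."""
    tau_f, tau_r = cfg.dip_fall_tau_s, cfg.dip_recovery_tau_s
    t_b = t0 + cfg.phase_a_dur_s
    # depth actually reached at the end of the common phase
    plateau = cfg.dip_common_depth * (1.0 - math.exp(-cfg.phase_a_dur_s / tau_f))
    dev = np.zeros_like(t)
    m_a = (t >= t0) & (t < t_b)
    dev[m_a] = -cfg.dip_common_depth * (1.0 - np.exp(-(t[m_a] - t0) / tau_f))
    if is_red:
        dev += _fall_recover(t, t_b, plateau, depth, tau_f, tau_r, cfg.nadir_hold_s)
    else:
        m_r = t >= t_b
        dev[m_r] = -plateau * np.exp(-(t[m_r] - t_b) / tau_r)
    return dev


def _event_duration(cfg: SimConfig, is_red: bool) -> float:
    tail = 5.0 * cfg.dip_recovery_tau_s
    if is_red:
        return cfg.phase_a_dur_s + 3.0 * cfg.dip_fall_tau_s + cfg.nadir_hold_s + tail
    return cfg.phase_a_dur_s + tail


def _ar1(rng: np.random.Generator, n: int, sd: float, phi: float) -> np.ndarray:
    """Stationary AR(1) noise with the given stationary standard deviation."""
    if n == 0 or sd == 0:
        return np.zeros(n)
    innov_sd = sd * math.sqrt(1.0 - phi * phi)
    eps = rng.normal(0.0, innov_sd, size=n)
    eps[0] = rng.normal(0.0, sd)  # stationary start
    return lfilter([1.0], [1.0, -phi], eps)


def _missing_mask(rng: np.random.Generator, n: int, cfg: SimConfig) -> np.ndarray:
    mask = rng.random(n) < cfg.missing_rate
    if cfg.burst_missing_rate > 0:
        starts = np.flatnonzero(rng.random(n) < cfg.burst_missing_rate)
        blen = max(1, int(round(cfg.burst_length_s)))
        for s in starts:
            mask[s:s + blen] = True
    return mask


# ---------------------------------------------------------------------------
# simulate_infant
# ---------------------------------------------------------------------------

def simulate_infant(config: SimConfig, infant_index: int
                    ) -> tuple[dict[str, VitalTrace], NNSeries, GroundTruth]:
    """Simulate one infant's three vital-sign traces, NN series and ground
    truth.  Fully reproducible from ``(config.seed, infant_index)``."""
    config.validate()
    if not 0 <= infant_index < config.n_infants:
        raise ConfigurationError(
            f"infant_index {infant_index} out of range for n_infants={config.n_infants}")
    infant_id = infant_label(infant_index)
    rng = np.random.default_rng(np.random.SeedSequence([int(config.seed), int(infant_index), 7]))

    n = int(config.duration_s)
    grid = np.arange(n, dtype=float)
    jitter = rng.uniform(-config.sample_jitter_s, config.sample_jitter_s, size=n)
    times = grid + jitter

    # -- events --------------------------------------------------------------
    lo = config.event_margin_start_s + config.precursor_lead_s
    hi = config.duration_s - config.event_margin_end_s
    usable_s = max(0.0, hi - lo)
    k = rng.poisson(config.event_rate_per_h * usable_s / 3600.0) if usable_s > 0 else 0
    onsets = np.sort(rng.uniform(lo, hi, size=k))
    # strictly increasing onsets (ties have measure zero; nudge if they occur)
    for i in range(1, onsets.size):
        if onsets[i] <= onsets[i - 1]:
            onsets[i] = onsets[i - 1] + 1e-6
    depths = rng.lognormal(config.depth_log_mean, config.depth_log_sd, size=k)
    red_depth = (config.spo2_baseline - config.thresholds.spo2_low_red
                 if config.thresholds.spo2_low_red is not None else np.inf)
    is_red = depths > red_depth
    coupled = is_red & (rng.random(k) < config.brady_coupling_prob)
    durations = np.array([_event_duration(config, bool(r)) for r in is_red])

    # -- deterministic signal components ------------------------------------
    spo2_det = np.full(n, config.spo2_baseline)
    hr_det = np.full(n, config.hr_baseline)
    tau_r = config.dip_recovery_tau_s
    for t0, depth, red, cpl in zip(onsets, depths, is_red, coupled):
        a = max(0, int(t0 - config.precursor_lead_s) - 2)
        b = min(n, int(t0 + _event_duration(config, bool(red))) + 2)
        tt = times[a:b]
        spo2_det[a:b] += _spo2_event_dev(tt, config, t0, depth, bool(red))
        if red:
            spo2_det[a:b] += _precursor_ramp(tt, t0, config.precursor_lead_s,
                                             config.precursor_spo2_drop, tau_r)
            hr_det[a:b] += _precursor_ramp(tt, t0, config.precursor_lead_s,
                                           config.precursor_hr_drop, tau_r)
        if cpl:
            brady_depth = config.hr_baseline - config.brady_hr_nadir
            hr_det[a:b] += _fall_recover(tt, t0 + config.phase_a_dur_s, 0.0,
                                         brady_depth, config.dip_fall_tau_s,
                                         tau_r, config.nadir_hold_s)

    spo2 = np.clip(spo2_det + _ar1(rng, n, config.spo2_noise_sd, config.ar_coef), 0.0, 100.0)
    hr = np.maximum(hr_det + _ar1(rng, n, config.hr_noise_sd, config.ar_coef), 30.0)
    br = np.maximum(config.br_baseline + _ar1(rng, n, config.br_noise_sd, config.ar_coef), 5.0)

    # -- NN series from integrated heart rate --------------------------------
    # beats occur where the cardiac phase crosses integers; NN ~ 60/HR(t)
    phase = np.concatenate(([0.0], np.cumsum((hr[:-1] + hr[1:]) / 2.0 / 60.0)))
    n_beats = int(math.floor(phase[-1]))
    if n_beats >= 2:
        beat_t = np.interp(np.arange(1, n_beats + 1, dtype=float), phase, grid)
        beat_t = beat_t + rng.normal(0.0, config.nn_jitter_sd_s, size=n_beats)
        d = np.maximum(np.diff(beat_t), 0.05)
        beat_t = np.concatenate(([beat_t[0]], beat_t[0] + np.cumsum(d)))
        nn_vals = np.diff(beat_t)
        art = rng.random(nn_vals.size) < config.nn_artifact_rate
        nn_vals[art] = rng.uniform(1.6, 2.5, size=int(art.sum()))
        nn = NNSeries(infant_id, beat_t[1:], nn_vals)
    else:
        nn = NNSeries(infant_id, np.empty(0), np.empty(0))

    # -- missingness ----------------------------------------------------------
    traces: dict[str, VitalTrace] = {}
    for sig, vals in (("HR", hr), ("BR", br), ("SpO2", spo2)):
        v = vals.copy()
        v[_missing_mask(rng, n, config)] = np.nan
        traces[sig] = VitalTrace(infant_id, sig, times, v)

    gt = GroundTruth(infant_id, onsets, depths, durations, is_red, coupled)
    return traces, nn, gt


def infant_meta_table(config: SimConfig) -> pd.DataFrame:
    """Per-infant metadata (gestational age at birth; postnatal age at the
    start of the record), drawn independently of the signal streams."""
    rows = []
    for i in range(config.n_infants):
        rng = np.random.default_rng(np.random.SeedSequence([int(config.seed), int(i), 11]))
        ga = rng.uniform(*config.gestational_age_range_wk)
        pn0 = rng.uniform(*config.postnatal_age_range_d)
        rows.append((infant_label(i), ga, pn0))
    return pd.DataFrame(rows, columns=["infant_id", "gestational_age_wk",
                                       "postnatal_age_start_d"])


# ---------------------------------------------------------------------------
# threshold alarm logic
# ---------------------------------------------------------------------------

def _threshold_rules(settings: AlarmSettings):
    return [
        ("SpO2", "low", "yellow", "SpO2-low", settings.spo2_low_yellow),
        ("SpO2", "low", "red", "desaturation", settings.spo2_low_red),
        ("SpO2", "high", "yellow", "SpO2-high", settings.spo2_high_yellow),
        ("HR", "low", "yellow", "HR-low", settings.hr_low_yellow),
        ("HR", "low", "red", "bradycardia", settings.hr_low_red),
        ("HR", "high", "yellow", "HR-high", settings.hr_high_yellow),
        ("HR", "high", "red", "tachycardia", settings.hr_high_red),
    ]


def _runs(mask: np.ndarray) -> list[tuple[int, int]]:
    """Maximal runs of True as (start, length)."""
    if not mask.any():
        return []
    padded = np.concatenate(([False], mask, [False]))
    d = np.diff(padded.astype(np.int8))
    starts = np.flatnonzero(d == 1)
    ends = np.flatnonzero(d == -1)
    return list(zip(starts.tolist(), (ends - starts).tolist()))


def apply_alarm_logic(traces: Mapping[str, VitalTrace], settings: AlarmSettings) -> AlarmLog:
    """Emit one alarm event per continuous threshold excursion of at least
    ``delay_s`` seconds, timestamped at excursion start + delay.

    SpO2 is smoothed with a trailing moving average of ``spo2_averaging_s``
    seconds before thresholding; missing samples break excursions.
    """
    settings.validate()
    events: list[AlarmEvent] = []
    on_grid: dict[str, VitalTrace] = {}
    for sig, tr in traces.items():
        if len(tr) == 0:
            continue
        gs = math.ceil(tr.times[0])
        ge = math.floor(tr.times[-1])
        if ge < gs:
            continue
        on_grid[sig] = resample_1hz(tr, float(gs), int(ge - gs) + 1)

    for sig, direction, color, category, thr in _threshold_rules(settings):
        if thr is None or sig not in on_grid:
            continue
        tr = on_grid[sig]
        vals = tr.values
        if sig == "SpO2":
            w = max(1, int(round(settings.spo2_averaging_s)))
            if w > 1:
                avg = pd.Series(vals).rolling(w, min_periods=1).mean().to_numpy()
                avg[~np.isfinite(vals)] = np.nan
                vals = avg
        with np.errstate(invalid="ignore"):
            beyond = vals < thr if direction == "low" else vals > thr
        beyond &= np.isfinite(vals)
        for start, length in _runs(beyond):
            if length >= settings.delay_s:
                events.append(AlarmEvent(tr.infant_id, tr.times[start] + settings.delay_s,
                                         color, category))
    return AlarmLog(events)


# ---------------------------------------------------------------------------
# cohort generation and persistence
# ---------------------------------------------------------------------------

def _sha256(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()


def generate_cohort(config: SimConfig, out_dir) -> dict:
    """Simulate every infant and persist vitals, NN, alarm logs, metadata,
    ground truth, the config and a manifest.  Idempotent for a fixed config:
    rerunning produces byte-identical artifacts."""
    config.validate()
    out = Path(out_dir)
    try:
        out.mkdir(parents=True, exist_ok=True)
    except OSError as exc:
        raise OSError(f"cannot create output directory {out}: {exc}") from exc

    files: list[Path] = []
    gt_frames = []
    for i in range(config.n_infants):
        traces, nn, gt = simulate_infant(config, i)
        iid = gt.infant_id
        for sig in ("HR", "BR", "SpO2"):
            p = out / f"{iid}_{sig}.csv"
            write_vitals([traces[sig]], p)
            files.append(p)
        p = out / f"{iid}_nn.csv"
        write_nn([nn], p)
        files.append(p)
        log = apply_alarm_logic(traces, config.thresholds)
        p = out / f"{iid}_alarms.csv"
        write_alarms(log, p)
        files.append(p)
        gt_frames.append(gt.to_frame())

    meta = infant_meta_table(config)
    p = out / "infants.csv"
    meta.to_csv(p, index=False)
    files.append(p)
    gt_all = (pd.concat(gt_frames, ignore_index=True) if gt_frames
              else pd.DataFrame(columns=["infant_id", "onset_s", "depth",
                                         "duration_s", "is_red", "coupled_brady"]))
    p = out / "ground_truth.csv"
    gt_all.to_csv(p, index=False)
    files.append(p)
    p = out / "config.yaml"
    config.to_yaml(p)
    files.append(p)

    manifest = {
        "seed": int(config.seed),
        "n_infants": int(config.n_infants),
        "config_hash": config.content_hash(),
        "files": {f.name: _sha256(f) for f in sorted(files)},
    }
    (out / "manifest.json").write_text(json.dumps(manifest, indent=2, sort_keys=True) + "\n",
                                       encoding="utf-8")
    return manifest


def load_cohort(cohort_dir) -> tuple[dict[str, dict[str, VitalTrace]],
                                     dict[str, NNSeries], AlarmLog,
                                     pd.DataFrame, pd.DataFrame]:
    """Read back a persisted cohort directory.

    Returns (vitals by infant by signal, NN by infant, pooled alarm log,
    infant metadata table, ground-truth table).
    """
    from .io import read_alarms, read_nn, read_vitals  # local import keeps io lazy

    out = Path(cohort_dir)
    manifest = json.loads((out / "manifest.json").read_text(encoding="utf-8"))
    vitals: dict[str, dict[str, VitalTrace]] = {}
    nn: dict[str, NNSeries] = {}
    logs = []
    for i in range(manifest["n_infants"]):
        iid = infant_label(i)
        vitals[iid] = {}
        for sig in ("HR", "BR", "SpO2"):
            (tr,) = read_vitals(out / f"{iid}_{sig}.csv")
            vitals[iid][sig] = tr
        series = read_nn(out / f"{iid}_nn.csv")
        nn[iid] = series[0] if series else NNSeries(iid, np.empty(0), np.empty(0))
        logs.append(read_alarms(out / f"{iid}_alarms.csv").df)
    log = AlarmLog(pd.concat(logs, ignore_index=True) if logs else ())
    meta = pd.read_csv(out / "infants.csv", dtype={"infant_id": str})
    gt = pd.read_csv(out / "ground_truth.csv", dtype={"infant_id": str})
    return vitals, nn, log, meta, gt
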