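"""Alarm-burden projection: translate classifier operating characteristics
and baseline alarm counts into projected alarm counts.

Under the proposed scheme all advisory (yellow) alarms become non-auditory
and a red alarm is generated preemptively whenever the classifier predicts
one.  True positives preempt reds that would have fired anyway; false
positives add new reds.  Count products are truncated (floored) to whole
alarms — the declared integer convention of this module.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np


def _round_half_up(x: float) -> int:
    return int(math.floor(x + 0.5))


@dataclass(frozen=True)
class BurdenInputs:
    """Baseline alarm counts plus the classifier's operating characteristics.

    ``red_in_ytr`` counts red alarms inside case post-windows and may exceed
    the number of case episodes (several reds can follow one yellow).
    """

    yellow_total: int
    red_total: int
    n_ytnr: int
    red_in_ytr: int
    sensitivity: float
    specificity: float

    def __post_init__(self):
        for name in ("yellow_total", "red_total", "n_ytnr", "red_in_ytr"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")
        for name in ("sensitivity", "specificity"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must lie in [0, 1]")


@dataclass(frozen=True)
class BurdenProjection:
    tp_red: int                      # preempted (correctly predicted) red alarms
    fp_red: int                      # falsely predicted red alarms
    projected_red_total: int         # red_total + fp_red
    pct_red_increase: int | None     # integer %, None when red_total == 0
    tp_fp_ratio: int | None          # N in "N:1", None when fp_red == 0
    pct_auditory_reduction: float    # % of auditory alarms removed
    flags: tuple[str, ...] = field(default=())


def project_burden(inputs: BurdenInputs) -> BurdenProjection:
    """Pure integer/rational burden arithmetic; bitwise reproducible."""
    tp = int(math.floor(inputs.red_in_ytr * inputs.sensitivity))
    fp = int(math.floor(inputs.n_ytnr * (1.0 - inputs.specificity)))
    projected = inputs.red_total + fp
    flags: list[str] = []
    if inputs.red_total > 0:
        pct_increase = _round_half_up(100.0 * fp / inputs.red_total)
    else:
        pct_increase = None
        flags.append("pct_red_increase undefined: red_total == 0")
    if fp > 0:
        ratio = _round_half_up(tp / fp)
    else:
        ratio = None
        flags.append("tp_fp_ratio undefined: fp_red == 0")
    total_auditory = inputs.yellow_total + inputs.red_total
    reduction = (100.0 * (total_auditory - projected) / total_auditory
                 if total_auditory > 0 else 0.0)
    return BurdenProjection(tp, fp, projected, pct_increase, ratio, reduction,
                            tuple(flags))


def lead_time_summary(lead_times_s: Sequence[float]) -> tuple[float, tuple[float, float]]:
    """Median and interquartile range (linear interpolation between order
    statistics) of anchor-to-red delays over true-positive episodes."""
    arr = np.asarray(list(lead_times_s), dtype=float)
    if arr.size == 0:
        raise ValueError("no lead times supplied")
    q25, med, q75 = np.percentile(arr, [25, 50, 75])
    return float(med), (float(q25), float(q75))


def projection_report(inputs: BurdenInputs, proj: BurdenProjection,
                      lead_summary: tuple[float, tuple[float, float]] | None = None) -> dict:
    d = {
        "inputs": {"yellow_total": inputs.yellow_total, "red_total": inputs.red_total,
                   "n_ytnr": inputs.n_ytnr, "red_in_ytr": inputs.red_in_ytr,
                   "sensitivity": inputs.sensitivity, "specificity": inputs.specificity},
        "tp_red": proj.tp_red, "fp_red": proj.fp_red,
        "projected_red_total": proj.projected_red_total,
        "pct_red_increase": proj.pct_red_increase,
        "tp_fp_ratio": proj.tp_fp_ratio,
        "pct_auditory_reduction": proj.pct_auditory_reduction,
        "flags": list(proj.flags),
    }
    if lead_summary is not None:
        med, (q25, q75) = lead_summary
        d["median_lead_s"] = med
        d["lead_iqr_s"] = [q25, q75]
    return d


def format_summary(inputs: BurdenInputs, proj: BurdenProjection,
                   lead_summary=None) -> str:
    lines = [
        "Alarm-burden projection",
        "=======================",
        f"baseline: {inputs.yellow_total:,} yellow + {inputs.red_total:,} red alarms",
        f"controls (YtnR): {inputs.n_ytnr:,}; reds inside case post-windows: {inputs.red_in_ytr:,}",
        f"operating point: sensitivity {inputs.sensitivity:.2f}, specificity {inputs.specificity:.2f}",
        "",
        f"preempted (true-positive) red alarms: {proj.tp_red:,}",
        f"false-positive red alarms:            {proj.fp_red:,}",
        f"projected red alarms generated:       {proj.projected_red_total:,}",
    ]
    if proj.tp_fp_ratio is not None:
        lines.append(f"true:false positive ratio:            {proj.tp_fp_ratio}:1")
    if proj.pct_red_increase is not None:
        lines.append(f"red-alarm increase:                   {proj.pct_red_increase}%")
    lines.append(f"auditory-alarm reduction:             {proj.pct_auditory_reduction:.1f}%")
    if lead_summary is not None:
        med, (q25, q75) = lead_summary
        lines.append(f"median lead time:                     {med:.1f} s (IQR {q25:.1f}-{q75:.1f})")
    for f in proj.flags:
        lines.append(f"note: {f}")
    return "\n".join(lines) + "\n"


def save_projection(inputs: BurdenInputs, proj: BurdenProjection, json_path,
                    text_path=None, lead_summary=None) -> None:
    with open(json_path, "w", encoding="utf-8") as fh:
        json.dump(projection_report(inputs, proj, lead_summary), fh, indent=2)
        fh.write("\n")
    if text_path is not None:
        with open(text_path, "w", encoding="utf-8") as fh:
            fh.write(format_summary(inputs, proj, lead_summary))
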