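"""Configuration dataclasses for the synthetic neonatal-monitor generator.

Alarm thresholds, persistence delays and averaging times are monitor
*settings*, not claims about any particular unit: every value here is
configurable and the defaults are typical NICU choices.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import math
from dataclasses import dataclass, field

import yaml

from .errors import ConfigurationError


@dataclass
class AlarmSettings:
    """Threshold-alarm settings: yellow (advisory) thresholds sit strictly
    between the baseline and the corresponding red (critical) threshold.

    ``None`` disables a threshold.  ``delay_s`` is the persistence a breach
    must sustain before the alarm fires; SpO2 is smoothed with a trailing
    moving average of ``spo2_averaging_s`` seconds before thresholding.
    """

    spo2_low_yellow: float | None = 88.0
    spo2_low_red: float | None = 80.0        # red category: desaturation
    spo2_high_yellow: float | None = None    # SpO2-high has no red counterpart
    hr_low_yellow: float | None = 100.0
    hr_low_red: float | None = 80.0          # red category: bradycardia
    hr_high_yellow: float | None = 200.0
    hr_high_red: float | None = 220.0        # red category: tachycardia
    bp_low_yellow: float | None = None       # BP alarms off by default
    bp_high_yellow: float | None = None
    delay_s: float = 10.0
    spo2_averaging_s: float = 8.0

    def validate(self) -> None:
        if self.delay_s < 0:
            raise ConfigurationError("delay_s must be >= 0")
        if self.spo2_averaging_s < 1:
            raise ConfigurationError("spo2_averaging_s must be >= 1")
        for y, r, name in [
            (self.spo2_low_yellow, self.spo2_low_red, "spo2_low"),
            (self.hr_low_yellow, self.hr_low_red, "hr_low"),
        ]:
            if y is not None and r is not None and not y > r:
                raise ConfigurationError(f"{name}_yellow must exceed {name}_red")
        if (self.hr_high_yellow is not None and self.hr_high_red is not None
                and not self.hr_high_yellow < self.hr_high_red):
            raise ConfigurationError("hr_high_yellow must be below hr_high_red")


@dataclass
class SimConfig:
    """Study conditions for the synthetic cohort.

    Desaturation events arrive as a homogeneous Poisson process at
    ``event_rate_per_h`` within a margin-trimmed window of the record; depths
    are lognormal; dips fall with a 5 s time constant and recover with a 20 s
    one.  Red-crossing events (depth below the red SpO2 threshold) carry a
    linear precursor drift starting ``precursor_lead_s`` before onset — the
    learnable pre-alarm signal — and couple to a bradycardia dip with
    probability ``brady_coupling_prob``.
    """

    n_infants: int = 20
    duration_s: float = 6 * 3600.0
    seed: int = 0

    # baselines and AR(1) noise (noise_sd = stationary standard deviation)
    hr_baseline: float = 150.0
    br_baseline: float = 50.0
    spo2_baseline: float = 96.0
    hr_noise_sd: float = 4.0
    br_noise_sd: float = 3.0
    spo2_noise_sd: float = 1.0
    ar_coef: float = 0.95

    # desaturation events
    event_rate_per_h: float = 8.0
    depth_log_mean: float = math.log(12.0)   # lognormal depth law (% SpO2)
    depth_log_sd: float = 0.5
    dip_fall_tau_s: float = 5.0
    dip_recovery_tau_s: float = 20.0
    dip_common_depth: float = 11.0           # shared onset-phase plateau depth
    phase_a_dur_s: float = 30.0              # common phase before divergence
    nadir_hold_s: float = 15.0
    event_margin_start_s: float = 300.0      # no events before / after margins
    event_margin_end_s: float = 200.0

    # precursor drift (red-crossing events only)
    precursor_lead_s: float = 60.0
    precursor_spo2_drop: float = 4.0
    precursor_hr_drop: float = 6.0

    # bradycardia coupling for deep (red-crossing) desaturations
    brady_coupling_prob: float = 0.3
    brady_hr_nadir: float = 65.0

    # missingness
    missing_rate: float = 0.01
    burst_missing_rate: float = 5e-4         # burst starts per sample
    burst_length_s: float = 20.0

    # NN-interval series
    nn_jitter_sd_s: float = 0.01
    nn_artifact_rate: float = 0.002          # probability an interval > 1.5 s
    sample_jitter_s: float = 0.2

    # infant metadata
    gestational_age_range_wk: tuple[float, float] = (24.0, 32.0)
    postnatal_age_range_d: tuple[float, float] = (1.0, 60.0)

    thresholds: AlarmSettings = field(default_factory=AlarmSettings)

    def validate(self) -> None:
        if self.n_infants < 1:
            raise ConfigurationError("n_infants must be >= 1")
        if self.duration_s <= 0:
            raise ConfigurationError("duration_s must be > 0")
        if self.precursor_lead_s < 0:
            raise ConfigurationError("precursor_lead_s must be >= 0")
        if self.event_rate_per_h < 0:
            raise ConfigurationError("event_rate_per_h must be >= 0")
        for name in ("brady_coupling_prob", "missing_rate", "burst_missing_rate",
                     "nn_artifact_rate"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ConfigurationError(f"{name} must lie in [0, 1]")
        if not 0.0 <= self.ar_coef < 1.0:
            raise ConfigurationError("ar_coef must lie in [0, 1)")
        if self.sample_jitter_s < 0 or self.sample_jitter_s > 0.2:
            raise ConfigurationError("sample_jitter_s must lie in [0, 0.2]")
        self.thresholds.validate()

    # -- (de)serialisation ---------------------------------------------------

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d["gestational_age_range_wk"] = list(d["gestational_age_range_wk"])
        d["postnatal_age_range_d"] = list(d["postnatal_age_range_d"])
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "SimConfig":
        d = dict(d)
        thr = d.pop("thresholds", {})
        if isinstance(thr, AlarmSettings):
            settings = thr
        else:
            unknown = set(thr) - {f.name for f in dataclasses.fields(AlarmSettings)}
            if unknown:
                raise ConfigurationError(f"unknown alarm settings: {sorted(unknown)}")
            settings = AlarmSettings(**thr)
        unknown = set(d) - {f.name for f in dataclasses.fields(cls)}
        if unknown:
            raise ConfigurationError(f"unknown simulation settings: {sorted(unknown)}")
        for key in ("gestational_age_range_wk", "postnatal_age_range_d"):
            if key in d:
                d[key] = tuple(d[key])
        return cls(thresholds=settings, **d)

    def to_yaml(self, path=None) -> str:
        text = yaml.safe_dump(self.to_dict(), sort_keys=True)
        if path is not None:
            with open(path, "w", encoding="utf-8") as fh:
                fh.write(text)
        return text

    @classmethod
    def from_yaml(cls, path) -> "SimConfig":
        with open(path, encoding="utf-8") as fh:
            return cls.from_dict(yaml.safe_load(fh) or {})

    def content_hash(self) -> str:
        blob = json.dumps(self.to_dict(), sort_keys=True).encode()
        return hashlib.sha256(blob).hexdigest()
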