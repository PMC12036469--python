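"""Synthetic PSG cohorts with planted group structure.

Two generators make the full pipeline testable without clinical data:

* ``generate_recording`` — one night of multichannel PSG: a Markov-chain
  hypnogram with a controllable stage-transition rate, stage-dependent
  signal content per channel (e.g. elevated 0.5–2 Hz amplitude in N3,
  airflow collapse during respiratory events, SpO2 dips during
  desaturations), and Poisson-placed event annotations restricted to sleep.

* ``generate_cohort`` — a subject table with group labels, covariates and
  right-censored survival outcomes drawn from an exponential
  proportional-hazards model, so Cox/KM stages have known ground truth.

Both are deterministic given their spec's seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .containers import (
    EPOCH_SECONDS,
    STAGE_TO_CODE,
    STAGES,
    EventAnnotation,
    Hypnogram,
    PsgRecording,
)
from .preprocess import DEFAULT_CHANNEL_CLASS

#: Native sampling rate per channel used by the generator (Hz).
DEFAULT_CHANNEL_RATES: dict[str, float] = {
    "C4": 128.0, "F4": 128.0, "O2-M2": 128.0, "E1": 128.0, "E2": 128.0,
    "chin EMG": 128.0, "EKG": 128.0, "nasal pressure": 32.0, "AIRFLOW": 32.0,
    "chest": 32.0, "abdomen": 32.0, "snore": 32.0, "EtCO2": 32.0, "SpO2": 8.0,
}

#: A light 4-channel montage used for desk-scale end-to-end runs.
SMALL_MONTAGE: tuple[str, ...] = ("C4", "AIRFLOW", "SpO2", "chin EMG")

# per-stage EEG-like carrier frequency (Hz) and amplitude; N3 carries large
# slow-wave (delta band) amplitude, W carries alpha
_EEG_FREQ = np.array([10.0, 7.0, 12.0, 1.2, 6.0])
_EEG_AMP = np.array([8.0, 10.0, 15.0, 40.0, 10.0])
_EMG_AMP = np.array([20.0, 8.0, 8.0, 8.0, 2.0])

# stage-switch preference rows (self-transitions excluded, renormalized);
# order W, N1, N2, N3, REM
_STAGE_PREF = np.array(
    [
        [0.0, 0.60, 0.30, 0.02, 0.08],
        [0.20, 0.0, 0.60, 0.05, 0.15],
        [0.10, 0.25, 0.0, 0.40, 0.25],
        [0.05, 0.10, 0.70, 0.0, 0.15],
        [0.20, 0.30, 0.40, 0.10, 0.0],
    ]
)
_STAGE_START = np.array([0.10, 0.10, 0.45, 0.20, 0.15])


@dataclass(frozen=True)
class RecordingSpec:
    """Generator parameters for one synthetic PSG night.

    Rates are per hour: ``stage_transition_rate`` is the expected number of
    stage switches per hour of recording; event rates are per hour of sleep.
    ``spo2_baseline`` is the resting saturation in percent.
    """

    n_epochs: int = 960
    channel_set: tuple[str, ...] = tuple(DEFAULT_CHANNEL_RATES)
    stage_transition_rate: float = 10.0
    respiratory_event_rate: float = 5.0
    desaturation_event_rate: float = 5.0
    spo2_baseline: float = 96.0
    include_wake: bool = True
    stage_weights: tuple[float, ...] | None = None
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_epochs < 2:
            raise ValueError(f"n_epochs must be >= 2, got {self.n_epochs}")
        if not self.channel_set:
            raise ValueError("channel_set must be non-empty")
        unknown = [c for c in self.channel_set if c not in DEFAULT_CHANNEL_RATES]
        if unknown:
            raise ValueError(
                f"unknown channel names {unknown}; valid channels: "
                f"{sorted(DEFAULT_CHANNEL_RATES)}"
            )
        for name in ("stage_transition_rate", "respiratory_event_rate",
                     "desaturation_event_rate"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")
        if self.stage_weights is not None:
            w = np.asarray(self.stage_weights, dtype=float)
            if w.shape != (len(STAGES),) or (w < 0).any() or w.sum() <= 0:
                raise ValueError(
                    "stage_weights must be 5 non-negative numbers (W,N1,N2,N3,REM)"
                )


def _generate_hypnogram(spec: RecordingSpec, rng: np.random.Generator) -> Hypnogram:
    """Epoch-resolution stage Markov chain.

    The per-epoch switch probability is ``rate / 120`` (120 epochs per
    hour), capped at 0.95; on a switch the next stage is drawn from a
    stage-preference row with self-transitions excluded.
    """
    p_switch = min(spec.stage_transition_rate / 120.0, 0.95)
    stages = np.empty(spec.n_epochs, dtype=np.int64)
    start = _STAGE_START.copy()
    pref = _STAGE_PREF.copy()
    if spec.stage_weights is not None:
        w = np.asarray(spec.stage_weights, dtype=float)
        start = start * w
        pref = pref * w[None, :]
    if not spec.include_wake:
        start[STAGE_TO_CODE["W"]] = 0.0
        pref[:, STAGE_TO_CODE["W"]] = 0.0
    start /= start.sum()
    pref /= pref.sum(axis=1, keepdims=True)

    stages[0] = rng.choice(len(STAGES), p=start)
    switches = rng.random(spec.n_epochs) < p_switch
    for t in range(1, spec.n_epochs):
        if switches[t]:
            stages[t] = rng.choice(len(STAGES), p=pref[stages[t - 1]])
        else:
            stages[t] = stages[t - 1]
    return Hypnogram(stages)


def _place_events(
    hyp: Hypnogram, rate_per_hour: float, kind: str, rng: np.random.Generator
) -> list[EventAnnotation]:
    """Homogeneous Poisson placement restricted to sleep epochs.

    Durations are uniform on [10, 60] s; intervals are clipped to the
    recording span so annotations never extend past the end.
    """
    sleep_idx = np.flatnonzero(hyp.is_sleep())
    if sleep_idx.size == 0 or rate_per_hour == 0:
        return []
    sleep_hours = sleep_idx.size * EPOCH_SECONDS / 3600.0
    n = rng.poisson(rate_per_hour * sleep_hours)
    events = []
    for _ in range(n):
        epoch = rng.choice(sleep_idx)
        start = epoch * EPOCH_SECONDS + rng.uniform(0.0, EPOCH_SECONDS)
        dur = rng.uniform(10.0, 60.0)
        dur = min(dur, hyp.duration_s - start)
        if dur > 0:
            events.append(EventAnnotation(start, dur, kind))
    return sorted(events, key=lambda e: e.start_s)


def _event_mask(
    events: list[EventAnnotation], kind: str, n_samples: int, rate: float
) -> np.ndarray:
    mask = np.zeros(n_samples, dtype=bool)
    for ev in events:
        if ev.type == kind:
            i0 = int(ev.start_s * rate)
            i1 = min(int(ev.end_s * rate), n_samples)
            mask[i0:i1] = True
    return mask


def _synthesize_channel(
    name: str,
    hyp: Hypnogram,
    events: list[EventAnnotation],
    spec: RecordingSpec,
    rng: np.random.Generator,
) -> np.ndarray:
    rate = DEFAULT_CHANNEL_RATES[name]
    n = int(round(hyp.n_epochs * EPOCH_SECONDS * rate))
    t = np.arange(n) / rate
    stage = np.repeat(hyp.stages, int(EPOCH_SECONDS * rate))
    cls = DEFAULT_CHANNEL_CLASS[name]
    noise = rng.standard_normal(n)

    if name == "SpO2":
        x = spec.spo2_baseline + 0.3 * noise
        for ev in events:
            if ev.type != "desaturation":
                continue
            i0, i1 = int(ev.start_s * rate), min(int(ev.end_s * rate), n)
            if i1 <= i0:
                continue
            depth = rng.uniform(4.0, 10.0)
            # smooth vee-shaped dip co-occurring with the annotation
            w = np.sin(np.linspace(0.0, np.pi, i1 - i0))
            x[i0:i1] -= depth * w
        return np.clip(x, 50.0, 100.0)

    phase = rng.uniform(0.0, 2 * np.pi)
    if cls in ("eeg", "eog"):
        if cls == "eog":
            amp = np.where(stage == STAGE_TO_CODE["REM"], 30.0, 5.0)
            freq = 0.3
        else:
            amp = _EEG_AMP[stage]
            freq = _EEG_FREQ[stage]
        return amp * np.sin(2 * np.pi * freq * t + phase) + 5.0 * noise
    if cls == "emg":
        return _EMG_AMP[stage] * noise
    if cls == "ekg":
        # spiky ~66 bpm carrier
        return 50.0 * np.sin(2 * np.pi * 1.1 * t + phase) ** 21 + 2.0 * noise
    # respiratory family: breathing carrier that collapses during events
    resp_mask = _event_mask(events, "respiratory", n, rate)
    amp = np.where(resp_mask, 2.0, 20.0)
    carrier = amp * np.sin(2 * np.pi * 0.25 * t + phase)
    if name == "snore":
        return np.where(stage != STAGE_TO_CODE["W"], 4.0, 1.0) * noise + 0.2 * carrier
    return carrier + 2.0 * noise


def generate_recording(
    spec: RecordingSpec, include_signals: bool = True
) -> tuple[PsgRecording | None, Hypnogram, list[EventAnnotation]]:
    """Generate one synthetic night: signals, hypnogram and annotations.

    With ``include_signals=False`` only the hypnogram and annotations are
    produced (cheap path for metric-level analyses); the random stream is
    shared so the hypnogram/events are identical either way.
    """
    rng = np.random.default_rng(spec.seed)
    hyp = _generate_hypnogram(spec, rng)
    events = _place_events(hyp, spec.respiratory_event_rate, "respiratory", rng)
    events += _place_events(hyp, spec.desaturation_event_rate, "desaturation", rng)
    events.sort(key=lambda e: e.start_s)
    if not include_signals:
        return None, hyp, events
    channels = {
        name: _synthesize_channel(name, hyp, events, spec, rng)
        for name in spec.channel_set
    }
    rates = {name: DEFAULT_CHANNEL_RATES[name] for name in spec.channel_set}
    rec = PsgRecording(
        channels=channels, rates=rates, n_epochs=spec.n_epochs,
        recording_id=f"synthetic-{spec.seed}",
    )
    return rec, hyp, events


# ---------------------------------------------------------------------------
# survival cohort
# ---------------------------------------------------------------------------

#: Comorbidity flags carried by every subject table.
COMORBIDITIES: tuple[str, ...] = (
    "hypertension", "diabetes_type2", "heart_failure", "atrial_fibrillation",
    "coronary_artery_disease", "hyperlipidemia",
)


@dataclass(frozen=True)
class CovariateSpec:
    """Baseline covariate distributions (independent of group by default)."""

    age_mean: float = 52.0
    age_sd: float = 13.0
    sex_p: float = 0.5
    bmi_mean: float = 31.0
    bmi_sd: float = 6.0
    comorbidity_prevalence: dict = field(
        default_factory=lambda: {
            "hypertension": 0.45, "diabetes_type2": 0.20, "heart_failure": 0.08,
            "atrial_fibrillation": 0.08, "coronary_artery_disease": 0.12,
            "hyperlipidemia": 0.40,
        }
    )


@dataclass(frozen=True)
class CohortSpec:
    """Generator parameters for a survival cohort with planted group hazards.

    ``group_log_hazard_ratios`` has one entry per group with the reference
    group first and fixed at 0; the hazard of subject i in group g is
    ``baseline_hazard * exp(log_hr[g] + sum_c beta_c * (x_ic - mean_c))``.
    ``censoring_rate`` is an independent exponential dropout rate; everyone
    still at risk at ``followup_horizon`` years is administratively censored.
    """

    n_subjects: int = 1000
    group_proportions: tuple[float, ...] = (0.35, 0.25, 0.20, 0.13, 0.07)
    group_log_hazard_ratios: tuple[float, ...] = (0.0, 0.0, 0.0, 0.0, 0.0)
    baseline_hazard: float = 0.01
    censoring_rate: float = 0.0
    covariate_spec: CovariateSpec = field(default_factory=CovariateSpec)
    covariate_log_hazards: dict = field(default_factory=dict)
    followup_horizon: float = 20.0
    seed: int = 0

    def __post_init__(self) -> None:
        props = np.asarray(self.group_proportions, dtype=float)
        if (props < 0).any():
            raise ValueError("group_proportions must be non-negative")
        if abs(props.sum() - 1.0) > 1e-9:
            raise ValueError(
                f"group_proportions must sum to 1 (got {props.sum():.12f})"
            )
        if len(self.group_log_hazard_ratios) != len(props):
            raise ValueError(
                "group_log_hazard_ratios must match group_proportions in length"
            )
        if self.group_log_hazard_ratios[0] != 0.0:
            raise ValueError("group_log_hazard_ratios: reference (first) must be 0")
        if self.baseline_hazard <= 0:
            raise ValueError("baseline_hazard must be > 0")
        if self.censoring_rate < 0:
            raise ValueError("censoring_rate must be >= 0")
        if self.n_subjects < 1:
            raise ValueError("n_subjects must be >= 1")
        if self.followup_horizon <= 0:
            raise ValueError("followup_horizon must be > 0")

    @property
    def n_groups(self) -> int:
        return len(self.group_proportions)


def generate_cohort(spec: CohortSpec) -> pd.DataFrame:
    """Draw a subject table with exponential proportional-hazards outcomes.

    Columns: ``id, group, age, sex, bmi`` + comorbidity flags +
    ``ahi, pap_prescribed, history_years, time_years, event``.  ``event`` is
    1 when death precedes both random censoring and the follow-up horizon.
    AHI is drawn with a mild upward shift per group so AHI-adjusted models
    have signal to adjust for; all other covariates are group-independent
    unless ``covariate_log_hazards`` says otherwise.
    """
    rng = np.random.default_rng(spec.seed)
    n = spec.n_subjects
    cov = spec.covariate_spec

    group = rng.choice(spec.n_groups, size=n, p=np.asarray(spec.group_proportions))
    df = pd.DataFrame(
        {
            "id": [f"S{i:06d}" for i in range(n)],
            "group": group,
            "age": rng.normal(cov.age_mean, cov.age_sd, n).clip(18.0, 95.0),
            "sex": rng.binomial(1, cov.sex_p, n),
            "bmi": rng.normal(cov.bmi_mean, cov.bmi_sd, n).clip(15.0, 70.0),
        }
    )
    for name in COMORBIDITIES:
        df[name] = rng.binomial(1, cov.comorbidity_prevalence[name], n)
    df["ahi"] = np.exp(rng.normal(1.5 + 0.35 * group, 0.6, n))
    df["pap_prescribed"] = rng.binomial(1, 0.3, n)
    df["history_years"] = rng.gamma(4.0, 2.4, n)

    log_hr = np.asarray(spec.group_log_hazard_ratios)[group].astype(float)
    for name, beta in spec.covariate_log_hazards.items():
        x = df[name].to_numpy(dtype=float)
        log_hr += beta * (x - x.mean())
    hazard = spec.baseline_hazard * np.exp(log_hr)
    death_time = rng.exponential(1.0 / hazard)
    if spec.censoring_rate > 0:
        censor_time = rng.exponential(1.0 / spec.censoring_rate, n)
    else:
        censor_time = np.full(n, np.inf)
    censor_time = np.minimum(censor_time, spec.followup_horizon)
    df["time_years"] = np.minimum(death_time, censor_time)
    df["event"] = (death_time <= censor_time).astype(int)
    return df
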