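"""Standard PSG summary metrics and the spectral sleep-fragmentation statistic.

Sleep fragmentation is defined as the fraction of the hypnogram's power
spectral density lying at frequencies above 1/(10 min) — i.e. the share of
stage-switching activity faster than a 10-minute cycle.  A hypnogram sampled
every 30 s has Nyquist frequency 1/60 Hz, so the statistic contrasts
sub-10-minute switching against slower sleep-cycle structure.
"""

from __future__ import annotations

from dataclasses import dataclass, asdict
from typing import Iterable, Sequence

import numpy as np
from scipy import signal as sps

from .containers import EPOCH_SECONDS, STAGES, STAGE_TO_CODE, EventAnnotation, Hypnogram

#: Default numeric depth code per stage for the PSD: W=0, N1=1, N2=2, N3=3,
#: REM=1.5 (REM sits between N1 and N2 in depth).  Configurable because the
#: statistic is only invariant to affine recodings.
DEFAULT_STAGE_ENCODING: dict[str, float] = {
    "W": 0.0, "N1": 1.0, "N2": 2.0, "N3": 3.0, "REM": 1.5,
}

#: Fragmentation cutoff frequency: transitions faster than 10 minutes.
FAST_CUTOFF_HZ: float = 1.0 / 600.0

#: AHI severity band edges (events per hour of sleep).
AHI_BANDS: tuple[tuple[float, str], ...] = (
    (30.0, "severe"), (15.0, "moderate"), (5.0, "mild"), (0.0, "normal"),
)


def ahi_severity(ahi: float) -> str:
    """Severity label: normal <5, mild 5-<15, moderate 15-<30, severe >=30."""
    for edge, label in AHI_BANDS:
        if ahi >= edge:
            return label
    return "normal"


def encode_hypnogram(
    hyp: Hypnogram, encoding: dict[str, float] | None = None
) -> np.ndarray:
    """Numeric series at one sample per 30-s epoch under a stage encoding."""
    encoding = encoding or DEFAULT_STAGE_ENCODING
    lut = np.array([encoding[s] for s in STAGES], dtype=float)
    return lut[hyp.stages]


def sleep_fragmentation(
    hyp: Hypnogram,
    encoding: dict[str, float] | None = None,
    use_transitions: bool = False,
) -> float:
    """Fraction of hypnogram PSD power above 1/(10 min).

    The encoded stage series (one sample per 30 s) is mean-removed and a
    rectangular-window periodogram computed; the statistic is the power sum
    at frequencies strictly above 1/600 Hz divided by the total power sum.
    A constant hypnogram has zero variance and returns 0 by convention.

    ``use_transitions=True`` substitutes the binary stage-change indicator
    series for the encoded hypnogram (alternative definition; the encoded
    variant is the default).
    """
    if len(hyp) < 2:
        raise ValueError("fragmentation needs at least 2 epochs")
    x = encode_hypnogram(hyp, encoding)
    if use_transitions:
        x = np.concatenate([[0.0], (np.diff(x) != 0).astype(float)])
    x = x - x.mean()
    if np.allclose(x, 0.0):
        return 0.0
    fs = 1.0 / EPOCH_SECONDS
    freqs, psd = sps.periodogram(x, fs=fs, window="boxcar", detrend=False)
    total = psd.sum()
    if total <= 0:
        return 0.0
    return float(psd[freqs > FAST_CUTOFF_HZ].sum() / total)


@dataclass
class SummaryMetrics:
    """Per-recording PSG summary used for cluster predictability analysis."""

    total_sleep_time_min: float
    stage_percent: dict[str, float]
    ahi: float | None
    arousal_index: float | None
    ahi_severity: str | None
    spo2_min: float | None
    spo2_mean: float | None
    fragmentation: float
    tst_undefined: bool

    def to_row(self) -> dict[str, float]:
        """Flat numeric feature row (None -> NaN) for model input."""
        row = {
            "total_sleep_time_min": self.total_sleep_time_min,
            "ahi": np.nan if self.ahi is None else self.ahi,
            "arousal_index": np.nan if self.arousal_index is None else self.arousal_index,
            "spo2_min": np.nan if self.spo2_min is None else self.spo2_min,
            "spo2_mean": np.nan if self.spo2_mean is None else self.spo2_mean,
            "fragmentation": self.fragmentation,
        }
        for stage, pct in self.stage_percent.items():
            row[f"pct_{stage}"] = pct
        return row


def summarize_psg(
    hyp: Hypnogram,
    events: Iterable[EventAnnotation] = (),
    spo2: np.ndarray | None = None,
    encoding: dict[str, float] | None = None,
) -> SummaryMetrics:
    """Compute TST, stage percentages, AHI, arousal index and fragmentation.

    TST counts non-wake epochs at 0.5 min each; AHI and the arousal index
    divide respiratory/arousal annotation counts by TST in hours.  When TST
    is zero these indices are undefined and reported as ``None`` with
    ``tst_undefined=True`` rather than infinity.
    """
    events = list(events)
    for ev in events:
        if ev.end_s > hyp.duration_s + 1e-9:
            raise ValueError(
                f"event [{ev.start_s}, {ev.end_s}) outside recording span "
                f"[0, {hyp.duration_s})"
            )
    sleep_epochs = int(hyp.is_sleep().sum())
    tst_min = sleep_epochs * EPOCH_SECONDS / 60.0
    tst_hours = tst_min / 60.0

    stage_percent: dict[str, float] = {}
    for name in STAGES:
        if name == "W":
            continue
        count = int((hyp.stages == STAGE_TO_CODE[name]).sum())
        stage_percent[name] = 100.0 * count / sleep_epochs if sleep_epochs else 0.0

    n_resp = sum(1 for ev in events if ev.type == "respiratory")
    n_arousal = sum(1 for ev in events if ev.type == "arousal")
    if tst_hours > 0:
        ahi = n_resp / tst_hours
        arousal_index = n_arousal / tst_hours
        severity = ahi_severity(ahi)
        undefined = False
    else:
        ahi = arousal_index = severity = None
        undefined = True

    spo2_min = spo2_mean = None
    if spo2 is not None and len(spo2):
        spo2_min = float(np.min(spo2))
        spo2_mean = float(np.mean(spo2))

    return SummaryMetrics(
        total_sleep_time_min=tst_min,
        stage_percent=stage_percent,
        ahi=ahi,
        arousal_index=arousal_index,
        ahi_severity=severity,
        spo2_min=spo2_min,
        spo2_mean=spo2_mean,
        fragmentation=sleep_fragmentation(hyp, encoding),
        tst_undefined=undefined,
    )


def metrics_table(
    items: Sequence[tuple[str, Hypnogram, Iterable[EventAnnotation], np.ndarray | None]],
):
    """Build a per-recording feature table (one row per recording id)."""
    import pandas as pd

    rows = {}
    for rec_id, hyp, events, spo2 in items:
        rows[rec_id] = summarize_psg(hyp, events, spo2).to_row()
    return pd.DataFrame.from_dict(rows, orient="index")
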