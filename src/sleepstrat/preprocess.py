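"""Signal conditioning: resampling, zero-phase elliptic filtering, normalization.

All channels are brought to a common 128 Hz rate, filtered with zero-phase
(forward-backward) elliptic IIR filters whose passband depends on the channel
class, and amplitude-normalized so that the 5th and 95th percentiles map to
-1 and +1.  Oxygen saturation is the exception: it is left unfiltered and
mapped affinely so that 60% -> -1 and 100% -> +1.

The elliptic designs use order 16, at most 1 dB passband ripple and at least
40 dB stopband attenuation as single-pass targets; forward-backward
application doubles the attenuation in dB and cancels phase distortion.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass
from fractions import Fraction

import numpy as np
from scipy import signal as sps

from .containers import PsgRecording

logger = logging.getLogger(__name__)

#: Common output sampling rate after preprocessing (Hz).
TARGET_RATE_HZ: float = 128.0

#: SpO2 affine normalization anchors: 60% -> -1, 100% -> +1.
SPO2_LOW, SPO2_HIGH = 60.0, 100.0


@dataclass(frozen=True)
class FilterSpec:
    """Single-pass elliptic filter design targets for one channel class.

    ``kind`` is one of ``"band-pass"``, ``"high-pass"``, ``"none"``.
    ``order`` is the total filter order (a band-pass of total order 16 is
    designed as an order-8 prototype, since the band transform doubles it).
    """

    kind: str
    low_cut_hz: float | None = None
    high_cut_hz: float | None = None
    order: int = 16
    passband_ripple_db: float = 1.0
    stopband_attenuation_db: float = 40.0

    def __post_init__(self) -> None:
        if self.kind not in ("band-pass", "high-pass", "none"):
            raise ValueError(f"unknown filter kind {self.kind!r}")
        if self.kind != "none":
            if self.order <= 0:
                raise ValueError("filter order must be positive")
            if self.passband_ripple_db <= 0 or self.stopband_attenuation_db <= 0:
                raise ValueError("ripple and attenuation must be positive dB")
        if self.kind == "band-pass" and (
            self.low_cut_hz is None or self.high_cut_hz is None
        ):
            raise ValueError("band-pass requires low_cut_hz and high_cut_hz")
        if self.kind == "high-pass" and self.low_cut_hz is None:
            raise ValueError("high-pass requires low_cut_hz")


#: Channel classes understood by the default filter table.
CHANNEL_CLASSES: tuple[str, ...] = (
    "eeg", "eog", "emg", "ekg", "nasal_pressure", "airflow", "effort", "spo2",
)

#: Per-class single-pass design targets.
DEFAULT_FILTER_TABLE: dict[str, FilterSpec] = {
    "eeg": FilterSpec("band-pass", 0.3, 45.0),
    "eog": FilterSpec("band-pass", 0.3, 45.0),
    "emg": FilterSpec("high-pass", 10.0),
    "ekg": FilterSpec("high-pass", 0.3),
    "nasal_pressure": FilterSpec("high-pass", 0.1),
    "airflow": FilterSpec("band-pass", 0.1, 15.0),
    "effort": FilterSpec("band-pass", 0.1, 15.0),
    "spo2": FilterSpec("none"),
}

#: The full 14-channel montage: channel name -> channel class.
#: Snore and EtCO2 are assigned the airflow band-pass (no class of their own).
DEFAULT_CHANNEL_CLASS: dict[str, str] = {
    "C4": "eeg",
    "F4": "eeg",
    "O2-M2": "eeg",
    "E1": "eog",
    "E2": "eog",
    "chin EMG": "emg",
    "EKG": "ekg",
    "nasal pressure": "nasal_pressure",
    "AIRFLOW": "airflow",
    "chest": "effort",
    "abdomen": "effort",
    "snore": "airflow",
    "EtCO2": "airflow",
    "SpO2": "spo2",
}


@dataclass(frozen=True)
class ChannelFilterTable:
    """Maps channel names to classes and classes to filter specs."""

    channel_class: dict[str, str] = None  # type: ignore[assignment]
    class_filters: dict[str, FilterSpec] = None  # type: ignore[assignment]

    def __post_init__(self) -> None:
        if self.channel_class is None:
            object.__setattr__(self, "channel_class", dict(DEFAULT_CHANNEL_CLASS))
        if self.class_filters is None:
            object.__setattr__(self, "class_filters", dict(DEFAULT_FILTER_TABLE))
        missing = set(self.channel_class.values()) - set(self.class_filters)
        if missing:
            raise ValueError(f"no filter spec for channel classes: {sorted(missing)}")

    def spec_for(self, channel_name: str) -> tuple[str, FilterSpec]:
        try:
            cls = self.channel_class[channel_name]
        except KeyError:
            raise KeyError(
                f"channel {channel_name!r} has no class mapping; "
                f"known channels: {sorted(self.channel_class)}"
            ) from None
        return cls, self.class_filters[cls]


def design_filter(spec: FilterSpec, sample_rate_hz: float):
    """Design the elliptic filter for ``spec`` at ``sample_rate_hz``.

    Returns second-order sections (shape ``(n_sections, 6)``), or ``None``
    for ``kind="none"``.  Raises ``ValueError`` when a cutoff is at or above
    the Nyquist frequency.
    """
    if spec.kind == "none":
        return None
    nyq = sample_rate_hz / 2.0
    cuts = [c for c in (spec.low_cut_hz, spec.high_cut_hz) if c is not None]
    for c in cuts:
        if not 0 < c < nyq:
            raise ValueError(
                f"cutoff {c} Hz outside (0, Nyquist={nyq}) at {sample_rate_hz} Hz"
            )
    if spec.kind == "band-pass":
        if spec.order % 2:
            raise ValueError("band-pass total order must be even")
        # the low-pass -> band-pass transform doubles the prototype order
        n = spec.order // 2
        wn = [spec.low_cut_hz / nyq, spec.high_cut_hz / nyq]
        btype = "bandpass"
    else:
        n = spec.order
        wn = spec.low_cut_hz / nyq
        btype = "highpass"
    return sps.ellip(
        n,
        spec.passband_ripple_db,
        spec.stopband_attenuation_db,
        wn,
        btype=btype,
        output="sos",
    )


def filter_response_db(sos, sample_rate_hz: float, freqs_hz: np.ndarray) -> np.ndarray:
    """Single-pass magnitude response in dB at the given frequencies."""
    _, h = sps.sosfreqz(sos, worN=freqs_hz, fs=sample_rate_hz)
    return 20.0 * np.log10(np.maximum(np.abs(h), 1e-300))


def measure_design(
    spec: FilterSpec,
    sample_rate_hz: float,
    transition_octaves: float = 0.35,
    n_grid: int = 20001,
) -> dict[str, float]:
    """Numerically measure ripple and attenuation of a realized design.

    Passband ripple is the largest dip below 0 dB inside the passband.
    Stopband attenuation is measured outside a transition margin of
    ``transition_octaves`` octaves beyond each cutoff (an elliptic design
    meets its attenuation only past a finite transition band).
    """
    sos = design_filter(spec, sample_rate_hz)
    nyq = sample_rate_hz / 2.0
    lo = spec.low_cut_hz if spec.low_cut_hz is not None else 0.0
    hi = spec.high_cut_hz if spec.high_cut_hz is not None else nyq
    ratio = 2.0 ** transition_octaves

    pass_f = np.linspace(lo, hi if spec.kind == "band-pass" else nyq * 0.999, n_grid)
    pass_db = filter_response_db(sos, sample_rate_hz, pass_f)
    out = {"passband_ripple_db": float(-pass_db.min())}

    stop_db = []
    if lo > 0:
        f = np.linspace(1e-4, lo / ratio, n_grid)
        stop_db.append(filter_response_db(sos, sample_rate_hz, f))
    if spec.kind == "band-pass" and hi * ratio < nyq:
        f = np.linspace(hi * ratio, nyq * 0.9999, n_grid)
        stop_db.append(filter_response_db(sos, sample_rate_hz, f))
    out["stopband_attenuation_db"] = float(-np.concatenate(stop_db).max())
    return out


def resample_to_target(
    x: np.ndarray, native_rate_hz: float, target_rate_hz: float = TARGET_RATE_HZ
) -> np.ndarray:
    """Polyphase rational resampling with anti-aliasing."""
    if native_rate_hz == target_rate_hz:
        return np.asarray(x, dtype=float)
    frac = Fraction(target_rate_hz / native_rate_hz).limit_denominator(1000)
    # padtype="line" avoids the large edge transients zero-padding would
    # create on channels with a non-zero baseline (SpO2, EtCO2)
    return sps.resample_poly(
        np.asarray(x, dtype=float), frac.numerator, frac.denominator,
        padtype="line",
    )


def normalize_percentile(x: np.ndarray) -> np.ndarray:
    """Affine map sending the 5th percentile to -1 and the 95th to +1.

    A degenerate amplitude distribution (equal percentiles) yields an
    all-zero output with a logged warning.
    """
    p5, p95 = np.percentile(x, [5.0, 95.0])
    if math.isclose(p5, p95, rel_tol=0.0, abs_tol=0.0) or p95 - p5 == 0:
        logger.warning(
            "degenerate amplitude distribution (5th pct == 95th pct == %g); "
            "returning zeros", p5,
        )
        return np.zeros_like(x, dtype=float)
    return 2.0 * (x - p5) / (p95 - p5) - 1.0


def normalize_spo2(x: np.ndarray) -> np.ndarray:
    """Map saturation percent so that 60 -> -1 and 100 -> +1."""
    return 2.0 * (np.asarray(x, dtype=float) - SPO2_LOW) / (SPO2_HIGH - SPO2_LOW) - 1.0


def preprocess_channel(
    x: np.ndarray,
    native_rate_hz: float,
    spec: FilterSpec,
    channel_class: str,
    apply_filter: bool = True,
) -> np.ndarray:
    """Resample to 128 Hz, zero-phase filter, and normalize one channel.

    SpO2 (``channel_class="spo2"``) skips filtering and uses the fixed
    60/100 anchors; every other class uses the 5th/95th percentile map.
    ``apply_filter=False`` bypasses filtering (for already-clean inputs or
    normalization-only use); resampling and normalization still run.
    """
    y = resample_to_target(x, native_rate_hz)
    if channel_class == "spo2":
        return normalize_spo2(y)
    sos = design_filter(spec, TARGET_RATE_HZ) if apply_filter else None
    if sos is not None:
        padlen = min(3 * sos.shape[0] * 2, y.size - 1)
        y = sps.sosfiltfilt(sos, y, padlen=padlen)
    return normalize_percentile(y)


def preprocess_recording(
    rec: PsgRecording, table: ChannelFilterTable | None = None
) -> PsgRecording:
    """Apply the per-class preprocessing to every channel of a recording.

    Every channel must have a class mapping in ``table``; the epoch grid is
    preserved and all output channels are at 128 Hz.
    """
    table = table or ChannelFilterTable()
    channels: dict[str, np.ndarray] = {}
    rates: dict[str, float] = {}
    for name in rec.channel_names():
        cls, spec = table.spec_for(name)
        channels[name] = preprocess_channel(rec.channels[name], rec.rates[name], spec, cls)
        rates[name] = TARGET_RATE_HZ
    return PsgRecording(
        channels=channels, rates=rates, n_epochs=rec.n_epochs,
        recording_id=rec.recording_id,
    )
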