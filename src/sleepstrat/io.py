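"""Plain-text and array-container persistence for pipeline objects.

CSV schemas:

* hypnogram: columns ``epoch_index, stage`` with stage names W/N1/N2/N3/REM;
* events: columns ``start_s, duration_s, type`` with type in
  respiratory/desaturation/arousal;
* subjects: the column schema produced by ``synthetic.generate_cohort``.

Recordings are stored in an NPZ array container with one array per channel
plus a ``rates`` record — a documented alternative to EDF.
"""

from __future__ import annotations

from pathlib import Path

import numpy as np
import pandas as pd

from .containers import STAGE_TO_CODE, STAGES, EventAnnotation, Hypnogram, PsgRecording


def write_hypnogram_csv(hyp: Hypnogram, path: str | Path) -> None:
    pd.DataFrame(
        {"epoch_index": np.arange(len(hyp)), "stage": hyp.stage_names()}
    ).to_csv(path, index=False)


def read_hypnogram_csv(path: str | Path) -> Hypnogram:
    df = pd.read_csv(path)
    df = df.sort_values("epoch_index")
    return Hypnogram(np.array([STAGE_TO_CODE[s] for s in df["stage"]]))


def write_events_csv(events: list[EventAnnotation], path: str | Path) -> None:
    pd.DataFrame(
        [{"start_s": e.start_s, "duration_s": e.duration_s, "type": e.type}
         for e in events]
    ).to_csv(path, index=False, float_format="%.17g")


def read_events_csv(path: str | Path) -> list[EventAnnotation]:
    df = pd.read_csv(path, float_precision="round_trip")
    return [
        EventAnnotation(float(r.start_s), float(r.duration_s), str(r.type))
        for r in df.itertuples()
    ]


def write_recording_npz(rec: PsgRecording, path: str | Path) -> None:
    names = rec.channel_names()
    np.savez_compressed(
        path,
        __names=np.array(names),
        __rates=np.array([rec.rates[n] for n in names]),
        __n_epochs=np.array(rec.n_epochs),
        __recording_id=np.array(rec.recording_id),
        **{f"ch_{i}": rec.channels[n] for i, n in enumerate(names)},
    )


def read_recording_npz(path: str | Path) -> PsgRecording:
    with np.load(path, allow_pickle=False) as z:
        names = [str(n) for n in z["__names"]]
        rates = {n: float(r) for n, r in zip(names, z["__rates"])}
        channels = {n: z[f"ch_{i}"] for i, n in enumerate(names)}
        return PsgRecording(
            channels=channels,
            rates=rates,
            n_epochs=int(z["__n_epochs"]),
            recording_id=str(z["__recording_id"]),
        )


def write_subjects_csv(subjects: pd.DataFrame, path: str | Path) -> None:
    subjects.to_csv(path, index=False)


def read_subjects_csv(path: str | Path) -> pd.DataFrame:
    return pd.read_csv(path)
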