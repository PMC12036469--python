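"""Core data containers shared across the pipeline.

The pipeline moves through a small set of in-memory objects: a multichannel
overnight recording on a 30-second epoch grid (:class:`PsgRecording`), its
per-epoch stage sequence (:class:`Hypnogram`) and timed event annotations
(:class:`EventAnnotation`), the per-epoch label table used for multi-task
training (:class:`EpochLabelTable`), the stacked per-epoch CLS embeddings of
one recording (:class:`EmbeddingMatrix`), and clustering outputs
(:class:`ClusterSolution`, :class:`ConsensusMatrix`).

Subject-level covariate/outcome tables are plain :class:`pandas.DataFrame`
objects with the column schema documented in :mod:`sleepstrat.synthetic`.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

#: Sleep stages in ordinal code order: codes 0..4.
STAGES: tuple[str, ...] = ("W", "N1", "N2", "N3", "REM")
STAGE_TO_CODE: dict[str, int] = {s: i for i, s in enumerate(STAGES)}

#: Recognized event annotation types.
EVENT_TYPES: tuple[str, ...] = ("respiratory", "desaturation", "arousal")

#: Duration of one scoring epoch in seconds.
EPOCH_SECONDS: float = 30.0


@dataclass(frozen=True)
class EventAnnotation:
    """A timed annotation interval ``[start_s, start_s + duration_s)``."""

    start_s: float
    duration_s: float
    type: str

    def __post_init__(self) -> None:
        if self.duration_s < 0:
            raise ValueError(f"negative duration: {self.duration_s}")
        if self.start_s < 0:
            raise ValueError(f"negative start: {self.start_s}")
        if self.type not in EVENT_TYPES:
            raise ValueError(
                f"unknown event type {self.type!r}; expected one of {EVENT_TYPES}"
            )

    @property
    def end_s(self) -> float:
        return self.start_s + self.duration_s


class Hypnogram:
    """Per-epoch sleep stage sequence, stored as integer codes 0..4."""

    def __init__(self, stages: np.ndarray | list[int]):
        stages = np.asarray(stages, dtype=np.int64)
        if stages.ndim != 1:
            raise ValueError("hypnogram must be one-dimensional")
        if stages.size and (stages.min() < 0 or stages.max() >= len(STAGES)):
            raise ValueError("stage codes must lie in 0..4 (W,N1,N2,N3,REM)")
        self.stages = stages

    def __len__(self) -> int:
        return int(self.stages.size)

    def __eq__(self, other: object) -> bool:
        return isinstance(other, Hypnogram) and np.array_equal(
            self.stages, other.stages
        )

    @property
    def n_epochs(self) -> int:
        return len(self)

    @property
    def duration_s(self) -> float:
        return len(self) * EPOCH_SECONDS

    def stage_names(self) -> list[str]:
        return [STAGES[s] for s in self.stages]

    def is_sleep(self) -> np.ndarray:
        """Boolean mask of non-wake epochs."""
        return self.stages != STAGE_TO_CODE["W"]


@dataclass
class PsgRecording:
    """Named multichannel recording with per-channel sampling rates.

    ``channels`` maps channel name to a 1-D float array; ``rates`` maps the
    same names to sampling rates in Hz.  Every channel must span exactly
    ``n_epochs`` 30-second epochs.
    """

    channels: dict[str, np.ndarray]
    rates: dict[str, float]
    n_epochs: int
    recording_id: str = ""

    def __post_init__(self) -> None:
        if not self.channels:
            raise ValueError("recording has no channels")
        if set(self.channels) != set(self.rates):
            raise ValueError("channels and rates must list the same names")
        for name, sig in self.channels.items():
            expected = int(round(self.n_epochs * EPOCH_SECONDS * self.rates[name]))
            if sig.ndim != 1 or sig.size != expected:
                raise ValueError(
                    f"channel {name!r}: expected {expected} samples "
                    f"({self.n_epochs} epochs at {self.rates[name]} Hz), "
                    f"got shape {sig.shape}"
                )

    @property
    def duration_s(self) -> float:
        return self.n_epochs * EPOCH_SECONDS

    def channel_names(self) -> list[str]:
        return list(self.channels)

    def epoch_signal(self, name: str, epoch: int) -> np.ndarray:
        """Samples of one channel within one 30-s epoch."""
        rate = self.rates[name]
        n = int(round(EPOCH_SECONDS * rate))
        return self.channels[name][epoch * n : (epoch + 1) * n]


@dataclass
class EpochLabelTable:
    """Per-epoch stage code plus binary respiratory/desaturation flags."""

    stage: np.ndarray
    respiratory_flag: np.ndarray
    desaturation_flag: np.ndarray

    def __post_init__(self) -> None:
        n = self.stage.size
        for name in ("respiratory_flag", "desaturation_flag"):
            arr = getattr(self, name)
            if arr.size != n:
                raise ValueError(f"{name} length {arr.size} != n_epochs {n}")
            if arr.size and not np.isin(arr, (0, 1)).all():
                raise ValueError(f"{name} must be binary")

    @property
    def n_epochs(self) -> int:
        return int(self.stage.size)


@dataclass
class EmbeddingMatrix:
    """One recording's stacked per-epoch CLS embeddings.

    ``values`` has shape (embed_dim, n_epochs); the epoch count varies per
    recording, which is why downstream clustering works with distributional
    distances rather than fixed-length vectors.
    """

    values: np.ndarray
    recording_id: str = ""

    def __post_init__(self) -> None:
        if self.values.ndim != 2:
            raise ValueError("embedding matrix must be 2-D (embed_dim, n_epochs)")
        if not np.isfinite(self.values).all():
            raise ValueError("embedding matrix contains non-finite entries")

    @property
    def embed_dim(self) -> int:
        return int(self.values.shape[0])

    @property
    def n_epochs(self) -> int:
        return int(self.values.shape[1])


@dataclass
class ClusterSolution:
    """A k-means partition of recordings, optionally with ordinal risk labels.

    ``assignment`` maps sample id -> cluster id (0..k-1).  ``risk_labels``
    maps cluster id -> 'RG1'..'RGk', assigned a posteriori by observed
    mortality (RG1 lowest); absent until ``label_risk_groups`` runs.
    """

    k: int
    assignment: dict[str, int]
    silhouette: float
    seed: int
    risk_labels: dict[int, str] | None = None

    def __post_init__(self) -> None:
        clusters = set(self.assignment.values())
        if not clusters <= set(range(self.k)):
            raise ValueError("cluster ids must lie in 0..k-1")
        if self.risk_labels is not None:
            expected = {f"RG{i}" for i in range(1, self.k + 1)}
            if set(self.risk_labels.values()) != expected:
                raise ValueError("risk labels must be a bijection onto RG1..RGk")

    def risk_label_of(self, sample_id: str) -> str:
        if self.risk_labels is None:
            raise ValueError("risk labels not assigned; run label_risk_groups first")
        return self.risk_labels[self.assignment[sample_id]]


@dataclass
class ConsensusMatrix:
    """Pairwise co-clustering frequencies across subsampled k-means runs.

    ``values[i, j]`` is the fraction of iterations in which samples i and j
    were assigned to the same cluster, among iterations where both were
    subsampled; ``co_occurrence_counts[i, j]`` is that denominator.  Pairs
    never co-sampled are 0 and flagged in ``undefined_mask``.
    ``ward_order`` is the leaf permutation from Ward hierarchical clustering
    of 1 - consensus, for block-structured heatmap rendering.
    """

    values: np.ndarray
    co_occurrence_counts: np.ndarray
    n_iterations: int
    subsample_fraction: float
    sample_ids: list[str]
    ward_order: np.ndarray
    undefined_mask: np.ndarray = field(default=None)  # type: ignore[assignment]

    def __post_init__(self) -> None:
        if self.undefined_mask is None:
            self.undefined_mask = self.co_occurrence_counts == 0
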