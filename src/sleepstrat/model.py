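"""Patch-tokenized multi-task epoch encoder.

Each 30-second epoch of a preprocessed (128 Hz) recording is cut, per
channel, into ten non-overlapping 3-second patches of 384 samples.  Patches
are linearly projected to the embedding dimension; the per-channel token
blocks are concatenated with a learned SEP token after every block and a
learned CLS token appended at the end (sequence length 11*C + 1 for C
channels).  Learned absolute position embeddings supply both order and
channel identity.  The sequence passes through a bidirectional transformer
encoder, and the CLS output feeds three linear heads: 5-class sleep stage,
binary respiratory event, binary desaturation event.  The training loss is
the arithmetic mean of the stage cross-entropy and the two binary
cross-entropies, optimized with Adam.

Per-epoch CLS outputs stacked over a night form the recording's embedding
matrix (embed_dim x n_epochs), the input to distributional clustering.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from sklearn.metrics import average_precision_score, f1_score

from . import nn
from .containers import (
    EPOCH_SECONDS,
    STAGES,
    EpochLabelTable,
    EmbeddingMatrix,
    EventAnnotation,
    Hypnogram,
    PsgRecording,
)

#: Minimum annotation overlap with an epoch for the epoch to carry the flag.
LABEL_OVERLAP_SECONDS: float = 5.0


def derive_epoch_labels(
    hyp: Hypnogram, events: list[EventAnnotation]
) -> EpochLabelTable:
    """Label each 30-s epoch from the hypnogram and raw annotation intervals.

    An epoch's respiratory (or desaturation) flag is 1 iff the total overlap
    of annotations of that type with the epoch is at least 5 seconds.
    Overlap is evaluated per epoch on the raw intervals, so one long event
    can flag several consecutive epochs.  Arousal annotations do not
    produce flags.  The result is independent of annotation order.
    """
    n = hyp.n_epochs
    flags = {"respiratory": np.zeros(n), "desaturation": np.zeros(n)}
    overlap = {k: np.zeros(n) for k in flags}
    for ev in events:
        if ev.type == "arousal":
            continue
        if ev.type not in flags:
            raise ValueError(f"unknown event type {ev.type!r}")
        first = max(int(ev.start_s // EPOCH_SECONDS), 0)
        last = min(int(np.ceil(ev.end_s / EPOCH_SECONDS)), n)
        for e in range(first, last):
            lo = max(ev.start_s, e * EPOCH_SECONDS)
            hi = min(ev.end_s, (e + 1) * EPOCH_SECONDS)
            overlap[ev.type][e] += max(hi - lo, 0.0)
    for kind in flags:
        flags[kind] = (overlap[kind] >= LABEL_OVERLAP_SECONDS).astype(np.int64)
    return EpochLabelTable(
        stage=hyp.stages.copy(),
        respiratory_flag=flags["respiratory"],
        desaturation_flag=flags["desaturation"],
    )


@dataclass(frozen=True)
class ModelConfig:
    """Architecture and training hyperparameters.

    The full-scale configuration (768-dim, 12 layers, learning rate 1e-5,
    batch 500, 50 training epochs) is constructible via ``full_scale()``;
    ``tiny()`` is the desk-scale default actually trained in tests and
    examples.  ``sep_after_last`` keeps a SEP after the final channel block
    before CLS (sequence length 11*C + 1); flipping it drops that fence-post
    SEP.  ``mask_wake`` removes wake epochs from the stage loss for the
    four-stage training variant.
    """

    embed_dim: int = 64
    n_layers: int = 2
    n_heads: int = 4
    patch_seconds: float = 3.0
    patches_per_epoch: int = 10
    sample_rate_hz: float = 128.0
    channel_order: tuple[str, ...] = ("C4", "AIRFLOW", "SpO2", "chin EMG")
    n_stage_classes: int = 5
    learning_rate: float = 1e-3
    batch_size: int = 250
    n_epochs_train: int = 5
    sep_after_last: bool = True
    per_channel_projection: bool = False
    mask_wake: bool = False
    seed: int = 0

    def __post_init__(self) -> None:
        if abs(self.patch_seconds * self.patches_per_epoch - EPOCH_SECONDS) > 1e-9:
            raise ValueError("patch_seconds * patches_per_epoch must equal 30 s")
        if self.embed_dim % self.n_heads:
            raise ValueError("embed_dim must be divisible by n_heads")
        if not self.channel_order:
            raise ValueError("channel_order must be non-empty")

    @property
    def patch_samples(self) -> int:
        return int(round(self.patch_seconds * self.sample_rate_hz))

    @property
    def epoch_samples(self) -> int:
        return int(round(EPOCH_SECONDS * self.sample_rate_hz))

    @property
    def n_channels(self) -> int:
        return len(self.channel_order)

    @property
    def sequence_length(self) -> int:
        per_channel = self.patches_per_epoch + 1  # tokens + SEP
        n = self.n_channels * per_channel + 1  # + CLS
        if not self.sep_after_last:
            n -= 1
        return n

    @classmethod
    def tiny(cls, **overrides) -> "ModelConfig":
        return cls(**overrides)

    @classmethod
    def full_scale(cls, channel_order=None, **overrides) -> "ModelConfig":
        from .preprocess import DEFAULT_CHANNEL_CLASS

        return cls(
            embed_dim=768,
            n_layers=12,
            n_heads=12,
            channel_order=tuple(channel_order or DEFAULT_CHANNEL_CLASS),
            learning_rate=1e-5,
            batch_size=500,
            n_epochs_train=50,
            **overrides,
        )


def sequence_length(n_channels: int, patches_per_epoch: int = 10,
                    sep_after_last: bool = True) -> int:
    """Token count for a C-channel epoch: 11*C + 1 under the default layout."""
    n = n_channels * (patches_per_epoch + 1) + 1
    return n if sep_after_last else n - 1


class SleepTokenizerModel:
    """Transformer epoch encoder with stage/respiratory/desaturation heads."""

    def __init__(self, cfg: ModelConfig):
        self.cfg = cfg
        rng = np.random.default_rng(cfg.seed)
        d = cfg.embed_dim
        if cfg.per_channel_projection:
            self.patch_proj = [
                nn.Dense(rng, cfg.patch_samples, d, f"proj[{name}]")
                for name in cfg.channel_order
            ]
        else:
            self.patch_proj = [nn.Dense(rng, cfg.patch_samples, d, "proj")]
        self.sep = nn.Parameter(nn.init_normal(rng, (d,)), "sep")
        self.cls = nn.Parameter(nn.init_normal(rng, (d,)), "cls")
        self.pos = nn.Parameter(nn.init_normal(rng, (cfg.sequence_length, d)), "pos")
        self.encoder = nn.TransformerEncoder(rng, d, cfg.n_layers, cfg.n_heads)
        self.head_stage = nn.Dense(rng, d, cfg.n_stage_classes, "head_stage")
        self.head_resp = nn.Dense(rng, d, 1, "head_resp")
        self.head_desat = nn.Dense(rng, d, 1, "head_desat")
        self._cache = None

    # -- parameter plumbing -------------------------------------------------
    def parameters(self) -> list[nn.Parameter]:
        params: list[nn.Parameter] = []
        for proj in self.patch_proj:
            params += proj.parameters()
        params += [self.sep, self.cls, self.pos]
        params += self.encoder.parameters()
        params += (
            self.head_stage.parameters()
            + self.head_resp.parameters()
            + self.head_desat.parameters()
        )
        return params

    def n_parameters(self) -> int:
        return sum(p.value.size for p in self.parameters())

    # -- checkpointing ------------------------------------------------------
    def save(self, path) -> None:
        """Single-file checkpoint: all parameters plus the config."""
        import dataclasses
        import json

        arrays = {f"p{i}": p.value for i, p in enumerate(self.parameters())}
        cfg = dataclasses.asdict(self.cfg)
        np.savez_compressed(path, __config=np.array(json.dumps(cfg)), **arrays)

    @classmethod
    def load(cls, path) -> "SleepTokenizerModel":
        import json

        with np.load(path, allow_pickle=False) as z:
            cfg_dict = json.loads(str(z["__config"]))
            cfg_dict["channel_order"] = tuple(cfg_dict["channel_order"])
            model = cls(ModelConfig(**cfg_dict))
            for i, p in enumerate(model.parameters()):
                p.value[...] = z[f"p{i}"]
        return model

    # -- tokenization -------------------------------------------------------
    def build_token_sequence(self, batch: np.ndarray) -> np.ndarray:
        """Assemble the embedded token sequence for a batch of epochs.

        ``batch`` has shape (B, C, 3840) with channels in
        ``cfg.channel_order``.  Returns (B, L, d) with position embeddings
        added, L = ``cfg.sequence_length``.
        """
        cfg = self.cfg
        b, c, s = batch.shape
        if c != cfg.n_channels or s != cfg.epoch_samples:
            raise ValueError(
                f"expected batch (B, {cfg.n_channels}, {cfg.epoch_samples}), "
                f"got {batch.shape}"
            )
        patches = batch.reshape(b, c, cfg.patches_per_epoch, cfg.patch_samples)
        self._patches = patches
        blocks = []
        sep = np.broadcast_to(self.sep.value, (b, 1, cfg.embed_dim))
        for ci in range(c):
            proj = self.patch_proj[ci if cfg.per_channel_projection else 0]
            tok = proj.forward(patches[:, ci])  # (B, P, d)
            blocks.append(tok)
            if cfg.sep_after_last or ci < c - 1:
                blocks.append(sep)
        blocks.append(np.broadcast_to(self.cls.value, (b, 1, cfg.embed_dim)))
        seq = np.concatenate(blocks, axis=1)
        return seq + self.pos.value

    def _backward_tokens(self, dseq: np.ndarray) -> None:
        """Route sequence gradients to projections, SEP, CLS and positions."""
        cfg = self.cfg
        b = dseq.shape[0]
        self.pos.grad += dseq.sum(axis=0)
        p = cfg.patches_per_epoch
        pos = 0
        sep_grad = np.zeros_like(self.sep.value)
        for ci in range(cfg.n_channels):
            proj = self.patch_proj[ci if cfg.per_channel_projection else 0]
            proj._x = self._patches[:, ci]
            proj.backward(dseq[:, pos : pos + p])
            pos += p
            if cfg.sep_after_last or ci < cfg.n_channels - 1:
                sep_grad += dseq[:, pos].sum(axis=0)
                pos += 1
        self.sep.grad += sep_grad
        self.cls.grad += dseq[:, pos].sum(axis=0)

    # -- forward / loss -----------------------------------------------------
    def forward(self, batch: np.ndarray) -> dict[str, np.ndarray]:
        """Return CLS representation and task logits for a batch of epochs."""
        seq = self.build_token_sequence(batch)
        enc = self.encoder.forward(seq)
        cls_out = enc[:, -1]  # CLS is the final position
        return {
            "cls": cls_out,
            "stage_logits": self.head_stage.forward(cls_out),
            "resp_logit": self.head_resp.forward(cls_out)[:, 0],
            "desat_logit": self.head_desat.forward(cls_out)[:, 0],
        }

    @staticmethod
    def _bce_with_logits(logit: np.ndarray, y: np.ndarray):
        p = 1.0 / (1.0 + np.exp(-logit))
        eps = 1e-12
        loss = -(y * np.log(p + eps) + (1 - y) * np.log(1 - p + eps)).mean()
        grad = (p - y) / y.size
        return loss, grad

    def loss_and_grads(self, batch, y_stage, y_resp, y_desat) -> dict[str, float]:
        """Forward + backward pass; returns per-task and total losses.

        Total loss is the arithmetic mean of the three task losses.
        Parameter gradients are accumulated in place (call ``zero_grad``
        on the optimizer between batches).
        """
        out = self.forward(batch)
        b = batch.shape[0]

        probs = nn.softmax(out["stage_logits"])
        if self.cfg.mask_wake:
            keep = y_stage != 0
        else:
            keep = np.ones(b, dtype=bool)
        n_keep = max(int(keep.sum()), 1)
        picked = probs[np.arange(b), y_stage]
        ce = -np.log(np.maximum(picked, 1e-12))
        loss_stage = float(ce[keep].sum() / n_keep)
        dstage = probs.copy()
        dstage[np.arange(b), y_stage] -= 1.0
        dstage[~keep] = 0.0
        dstage /= n_keep

        loss_resp, dresp = self._bce_with_logits(out["resp_logit"], y_resp)
        loss_desat, ddesat = self._bce_with_logits(out["desat_logit"], y_desat)

        total = (loss_stage + loss_resp + loss_desat) / 3.0
        if not np.isfinite(total):
            raise FloatingPointError(
                f"non-finite loss: stage={loss_stage} resp={loss_resp} "
                f"desat={loss_desat}"
            )

        dcls = self.head_stage.backward(dstage / 3.0)
        dcls = dcls + self.head_resp.backward((dresp / 3.0)[:, None])
        dcls = dcls + self.head_desat.backward((ddesat / 3.0)[:, None])
        denc = np.zeros((b, self.cfg.sequence_length, self.cfg.embed_dim))
        denc[:, -1] = dcls
        dseq = self.encoder.backward(denc)
        self._backward_tokens(dseq)
        return {
            "stage": loss_stage,
            "respiratory": loss_resp,
            "desaturation": float(loss_desat),
            "total": float(total),
        }

    def eval_loss(self, batch, y_stage, y_resp, y_desat) -> float:
        """Total loss without gradient accumulation (for checks/monitoring)."""
        out = self.forward(batch)
        b = batch.shape[0]
        probs = nn.softmax(out["stage_logits"])
        keep = (y_stage != 0) if self.cfg.mask_wake else np.ones(b, dtype=bool)
        picked = np.maximum(probs[np.arange(b), y_stage], 1e-12)
        loss_stage = float(-np.log(picked)[keep].sum() / max(int(keep.sum()), 1))
        loss_resp, _ = self._bce_with_logits(out["resp_logit"], y_resp)
        loss_desat, _ = self._bce_with_logits(out["desat_logit"], y_desat)
        return (loss_stage + loss_resp + loss_desat) / 3.0


def epoch_tensor(rec: PsgRecording, channel_order: tuple[str, ...]) -> np.ndarray:
    """Stack a preprocessed 128 Hz recording into (n_epochs, C, 3840)."""
    n_samples = int(EPOCH_SECONDS * 128.0)
    arrs = []
    for name in channel_order:
        if name not in rec.channels:
            raise KeyError(f"recording is missing channel {name!r}")
        if rec.rates[name] != 128.0:
            raise ValueError(f"channel {name!r} not at 128 Hz; preprocess first")
        arrs.append(rec.channels[name].reshape(rec.n_epochs, n_samples))
    return np.stack(arrs, axis=1)


def train_multitask(
    dataset: dict[str, np.ndarray],
    cfg: ModelConfig,
    model: SleepTokenizerModel | None = None,
) -> tuple[SleepTokenizerModel, list[dict[str, float]]]:
    """Train the multi-task encoder; returns the model and per-epoch losses.

    ``dataset`` maps ``"X"`` -> (N, C, 3840) float array and ``"stage"``,
    ``"respiratory"``, ``"desaturation"`` -> (N,) label arrays.  Batches are
    drawn by seeded shuffling; the optimizer is Adam at
    ``cfg.learning_rate``.  Loss history holds the mean per-task and total
    losses of each training epoch.
    """
    X = dataset["X"]
    if X.shape[0] == 0:
        raise ValueError("empty training dataset")
    y_stage = np.asarray(dataset["stage"], dtype=np.int64)
    y_resp = np.asarray(dataset["respiratory"], dtype=np.float64)
    y_desat = np.asarray(dataset["desaturation"], dtype=np.float64)

    model = model or SleepTokenizerModel(cfg)
    opt = nn.Adam(model.parameters(), cfg.learning_rate)
    rng = np.random.default_rng(cfg.seed + 1)
    history: list[dict[str, float]] = []
    n = X.shape[0]
    for _ in range(cfg.n_epochs_train):
        order = rng.permutation(n)
        sums = {"stage": 0.0, "respiratory": 0.0, "desaturation": 0.0, "total": 0.0}
        n_batches = 0
        for start in range(0, n, cfg.batch_size):
            idx = order[start : start + cfg.batch_size]
            opt.zero_grad()
            losses = model.loss_and_grads(
                X[idx], y_stage[idx], y_resp[idx], y_desat[idx]
            )
            opt.step()
            for k in sums:
                sums[k] += losses[k]
            n_batches += 1
        history.append({k: v / n_batches for k, v in sums.items()})
    return model, history


def predict_epochs(
    model: SleepTokenizerModel, X: np.ndarray, batch_size: int = 500
) -> dict[str, np.ndarray]:
    """Deterministic forward pass over (N, C, 3840): probabilities + CLS."""
    stages, resp, desat, cls = [], [], [], []
    for start in range(0, X.shape[0], batch_size):
        out = model.forward(X[start : start + batch_size])
        stages.append(nn.softmax(out["stage_logits"]))
        resp.append(1.0 / (1.0 + np.exp(-out["resp_logit"])))
        desat.append(1.0 / (1.0 + np.exp(-out["desat_logit"])))
        cls.append(out["cls"])
    return {
        "stage_probs": np.concatenate(stages),
        "resp_prob": np.concatenate(resp),
        "desat_prob": np.concatenate(desat),
        "cls": np.concatenate(cls),
    }


def task_metrics_from_predictions(
    y_stage: np.ndarray,
    stage_probs: np.ndarray,
    y_resp: np.ndarray,
    resp_prob: np.ndarray,
    y_desat: np.ndarray,
    desat_prob: np.ndarray,
    threshold: float = 0.5,
) -> dict[str, float]:
    """Macro/micro F1 and average precision for staging; F1/AP per flag task.

    F1 per class comes from the confusion matrix; macro is the unweighted
    class mean, micro pools counts.  AP is the step-wise area under the
    precision-recall curve.  Stage classes absent from both truth and
    prediction are excluded from the macro means with a warning.  Binary
    flags threshold at ``threshold`` for F1; AP is threshold-free.
    """
    n_classes = stage_probs.shape[1]
    y_hat = stage_probs.argmax(axis=1)
    present = sorted(set(np.unique(y_stage)) | set(np.unique(y_hat)))
    if len(present) < n_classes:
        missing = [STAGES[c] if c < len(STAGES) else str(c)
                   for c in range(n_classes) if c not in present]
        warnings.warn(
            f"stage classes absent from truth and prediction: {missing}; "
            "excluded from macro averages"
        )
    metrics = {
        "stage_f1_macro": f1_score(y_stage, y_hat, labels=present, average="macro"),
        "stage_f1_micro": f1_score(y_stage, y_hat, labels=present, average="micro"),
    }
    onehot = np.zeros((y_stage.size, n_classes))
    onehot[np.arange(y_stage.size), y_stage] = 1.0
    ap_classes = [c for c in present if onehot[:, c].any()]
    metrics["stage_ap_macro"] = float(np.mean([
        average_precision_score(onehot[:, c], stage_probs[:, c])
        for c in ap_classes
    ]))
    metrics["stage_ap_micro"] = average_precision_score(
        onehot[:, ap_classes].ravel(), stage_probs[:, ap_classes].ravel()
    )
    for task, y, p in (
        ("respiratory", y_resp, resp_prob),
        ("desaturation", y_desat, desat_prob),
    ):
        metrics[f"{task}_f1"] = f1_score(y, p >= threshold, zero_division=0)
        metrics[f"{task}_ap"] = (
            average_precision_score(y, p) if np.any(y) else float("nan")
        )
    return {k: float(v) for k, v in metrics.items()}


def evaluate_tasks(
    model: SleepTokenizerModel,
    X: np.ndarray,
    y_stage: np.ndarray,
    y_resp: np.ndarray,
    y_desat: np.ndarray,
    threshold: float = 0.5,
) -> dict[str, float]:
    """Run the model on a labeled test set and score all three tasks."""
    pred = predict_epochs(model, X)
    return task_metrics_from_predictions(
        y_stage, pred["stage_probs"], y_resp, pred["resp_prob"],
        y_desat, pred["desat_prob"], threshold=threshold,
    )


def embed_recording(
    model: SleepTokenizerModel, rec: PsgRecording, batch_size: int = 500
) -> EmbeddingMatrix:
    """Stack per-epoch CLS outputs into the recording's embedding matrix.

    The result has shape (embed_dim, n_epochs); evaluation is deterministic,
    so embedding the same recording twice yields identical matrices.
    """
    X = epoch_tensor(rec, model.cfg.channel_order)
    cls = predict_epochs(model, X, batch_size=batch_size)["cls"]
    return EmbeddingMatrix(values=cls.T.copy(), recording_id=rec.recording_id)
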