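"""Train the desk-scale multi-task epoch encoder and embed a night.

Epochs are labeled with the 5-second overlap rule, the transformer is
trained on the stage/respiratory/desaturation tasks (loss = mean of the
three task losses), and the trained encoder turns each 30-s epoch into a
CLS vector; stacking them gives the night's embedding matrix.
"""

import numpy as np

from sleepstrat import (
    ModelConfig,
    RecordingSpec,
    SMALL_MONTAGE,
    derive_epoch_labels,
    embed_recording,
    evaluate_tasks,
    generate_recording,
    preprocess_recording,
    train_multitask,
)
from sleepstrat.model import epoch_tensor

cfg = ModelConfig(n_epochs_train=3, batch_size=120, seed=0)

X_parts, stage, resp, desat = [], [], [], []
for seed in range(6):
    rec, hyp, events = generate_recording(
        RecordingSpec(n_epochs=60, channel_set=SMALL_MONTAGE,
                      respiratory_event_rate=15.0, seed=seed)
    )
    proc = preprocess_recording(rec)
    X_parts.append(epoch_tensor(proc, cfg.channel_order))
    lab = derive_epoch_labels(hyp, events)
    stage.append(lab.stage)
    resp.append(lab.respiratory_flag)
    desat.append(lab.desaturation_flag)

dataset = {
    "X": np.concatenate(X_parts),
    "stage": np.concatenate(stage),
    "respiratory": np.concatenate(resp),
    "desaturation": np.concatenate(desat),
}
model, history = train_multitask(dataset, cfg)
print("training loss by epoch:",
      [round(h["total"], 3) for h in history])

metrics = evaluate_tasks(model, dataset["X"], dataset["stage"],
                         dataset["respiratory"], dataset["desaturation"])
print(f"stage F1 (macro/micro): {metrics['stage_f1_macro']:.2f} / "
      f"{metrics['stage_f1_micro']:.2f}")

rec, _, _ = generate_recording(
    RecordingSpec(n_epochs=60, channel_set=SMALL_MONTAGE, seed=99)
)
emb = embed_recording(model, preprocess_recording(rec))
print(f"embedding matrix: {emb.values.shape[0]} dims x "
      f"{emb.values.shape[1]} epochs")
# A falling loss shows the three heads learn jointly; the embedding matrix
# (embed_dim x n_epochs) is the unit that downstream clustering consumes.
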