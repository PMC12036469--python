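"""Predict cluster membership from standard PSG summary metrics.

A gradient-boosted decision-tree classifier is trained on the per-recording
summary metrics (AHI, arousal index, total sleep time, stage percentages,
oxygen saturation summaries, fragmentation); features are ranked by total
gain, and the model is refit using only the top-1 and top-5 features to
measure how much of the cluster structure plain PSG metrics can recover.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.metrics import accuracy_score
from sklearn.model_selection import train_test_split
from xgboost import XGBClassifier

#: Fixed boosting hyperparameters (recorded, not tuned per run).
XGB_PARAMS = dict(
    n_estimators=300,
    max_depth=4,
    learning_rate=0.1,
    tree_method="hist",
    n_jobs=1,
    verbosity=0,
)


@dataclass
class PredictabilityReport:
    """Held-out accuracy with all, top-1 and top-5 features, per solution."""

    k: int
    full_accuracy: float
    top1_accuracy: float
    top5_accuracy: float
    ranked_features: list[str]
    split_fraction: float
    seed: int
    per_feature_gain: dict[str, float] = field(default_factory=dict)

    @property
    def top1_feature(self) -> str:
        return self.ranked_features[0]

    @property
    def top5_features(self) -> list[str]:
        return self.ranked_features[:5]


def _fit_and_score(X_train, y_train, X_test, y_test, seed: int) -> float:
    clf = XGBClassifier(random_state=seed, **XGB_PARAMS)
    clf.fit(X_train, y_train)
    return float(accuracy_score(y_test, clf.predict(X_test)))


def predict_clusters_from_metrics(
    metrics: pd.DataFrame,
    labels: pd.Series,
    split_fraction: float = 0.2,
    seed: int = 0,
) -> PredictabilityReport:
    """Train, rank features by total gain, and refit on top-1/top-5 features.

    ``metrics`` is one row per recording id; ``labels`` maps the same index
    to cluster ids (any hashable labels).  The split is stratified at
    ``split_fraction`` held out.  Raises if a class is missing from the
    training split.
    """
    metrics = metrics.loc[labels.index]
    y, classes = pd.factorize(labels, sort=True)
    if len(classes) < 2:
        raise ValueError("need at least 2 classes to predict")
    X = metrics.to_numpy(dtype=float)
    idx_train, idx_test = train_test_split(
        np.arange(len(y)), test_size=split_fraction, stratify=y, random_state=seed
    )
    if len(set(y[idx_train])) < len(classes):
        raise ValueError(
            "a class is missing from the training split; use a larger cohort"
        )

    clf = XGBClassifier(random_state=seed, **XGB_PARAMS)
    clf.fit(X[idx_train], y[idx_train])
    full_acc = float(accuracy_score(y[idx_test], clf.predict(X[idx_test])))

    booster = clf.get_booster()
    booster.feature_names = list(metrics.columns)
    gain = booster.get_score(importance_type="total_gain")
    ranked = sorted(metrics.columns, key=lambda f: gain.get(f, 0.0), reverse=True)

    def subset_acc(feats: list[str]) -> float:
        cols = [metrics.columns.get_loc(f) for f in feats]
        return _fit_and_score(
            X[np.ix_(idx_train, cols)], y[idx_train],
            X[np.ix_(idx_test, cols)], y[idx_test], seed,
        )

    return PredictabilityReport(
        k=len(classes),
        full_accuracy=full_acc,
        top1_accuracy=subset_acc(ranked[:1]),
        top5_accuracy=subset_acc(ranked[:5]),
        ranked_features=ranked,
        split_fraction=split_fraction,
        seed=seed,
        per_feature_gain={f: float(gain.get(f, 0.0)) for f in metrics.columns},
    )
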