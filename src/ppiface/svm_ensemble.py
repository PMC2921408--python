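"""SVM ensemble over balanced subset pairs with threshold-vote combination.

One binary RBF-kernel SVM is trained per (positive subset i, negative
subset j) pair of a :class:`~ppiface.dataset.TrainingPartition`, giving
K = M x N members whose training sets do not overlap within a class. Each
member standardizes features on its own training pair. At prediction time
every member casts a hard 0/1 vote per residue; the ensemble calls a
residue an interface residue when at least ``TH`` of the K votes are
positive, for a threshold TH ranging from 1 to K.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import List, Optional, Tuple

import joblib
import numpy as np
import pandas as pd
from sklearn.pipeline import Pipeline
from sklearn.preprocessing import StandardScaler
from sklearn.svm import SVC

from .dataset import TrainingPartition
from .evaluation import confusion, metrics

__all__ = [
    "SVMConfig",
    "EnsembleModel",
    "VoteMatrix",
    "train_ensemble",
    "predict_votes",
    "combine_votes",
    "threshold_sweep",
    "save_model",
    "load_model",
]


@dataclass(frozen=True)
class SVMConfig:
    """Member hyperparameters. gamma=None means 1/L (sklearn "auto")."""

    kernel: str = "rbf"
    C: float = 1.0
    gamma: Optional[float] = None
    standardize: bool = True
    store_decision: bool = False


@dataclass
class EnsembleModel:
    members: List[Tuple[int, int, Pipeline]]  # (pos_subset, neg_subset, fitted)
    feature_dim: int
    config: SVMConfig
    seed: int
    partition_meta: dict = field(default_factory=dict)

    @property
    def K(self) -> int:
        return len(self.members)


@dataclass
class VoteMatrix:
    """Per-member hard votes (n x K) with optional decision values."""

    votes: np.ndarray
    decision_values: Optional[np.ndarray] = None

    @property
    def K(self) -> int:
        return self.votes.shape[1]


def _make_member(config: SVMConfig) -> Pipeline:
    gamma = config.gamma if config.gamma is not None else "auto"  # 1/n_features
    steps = []
    if config.standardize:
        steps.append(("scale", StandardScaler()))
    steps.append(("svc", SVC(kernel=config.kernel, C=config.C, gamma=gamma)))
    return Pipeline(steps)


def train_ensemble(
    features: np.ndarray,
    labels: np.ndarray,
    partition: TrainingPartition,
    config: SVMConfig | None = None,
    seed: int = 0,
) -> EnsembleModel:
    """Fit one member per (positive subset, negative subset) pair."""
    X = np.asarray(features, dtype=float)
    y = np.asarray(labels, dtype=int)
    if X.ndim != 2 or len(X) != len(y):
        raise ValueError("features must be n x L aligned with labels")
    config = config or SVMConfig()
    members: List[Tuple[int, int, Pipeline]] = []
    for i, pos_idx in enumerate(partition.pos_subsets):
        for j, neg_idx in enumerate(partition.neg_subsets):
            if len(pos_idx) == 0 or len(neg_idx) == 0:
                raise ValueError(f"subset pair ({i}, {j}) has an empty class")
            idx = np.concatenate([pos_idx, neg_idx])
            if idx.max() >= len(X):
                raise ValueError("partition indices exceed the feature matrix")
            member = _make_member(config)
            member.fit(X[idx], y[idx])
            members.append((i, j, member))
    return EnsembleModel(
        members=members,
        feature_dim=X.shape[1],
        config=config,
        seed=seed,
        partition_meta={
            "strategy": partition.strategy,
            "seed": partition.seed,
            "M": partition.M,
            "N": partition.N,
        },
    )


def predict_votes(model: EnsembleModel, features: np.ndarray) -> VoteMatrix:
    """Hard 0/1 vote of every member for every input residue."""
    X = np.asarray(features, dtype=float)
    if X.ndim != 2 or X.shape[1] != model.feature_dim:
        raise ValueError(
            f"feature dimension mismatch: expected {model.feature_dim}"
        )
    n = X.shape[0]
    votes = np.zeros((n, model.K), dtype=np.int8)
    decisions = (
        np.zeros((n, model.K), dtype=float) if model.config.store_decision else None
    )
    if n:
        for k, (_, _, member) in enumerate(model.members):
            votes[:, k] = member.predict(X)
            if decisions is not None:
                decisions[:, k] = member.decision_function(X)
    return VoteMatrix(votes=votes, decision_values=decisions)


def combine_votes(votes: np.ndarray | VoteMatrix, TH: int) -> np.ndarray:
    """Ensemble call: 1 iff at least TH of the K member votes are positive."""
    if isinstance(votes, VoteMatrix):
        votes = votes.votes
    votes = np.asarray(votes)
    K = votes.shape[1]
    if not 1 <= TH <= K:
        raise ValueError(f"threshold TH must lie in 1..{K}, got {TH}")
    return (votes.sum(axis=1) >= TH).astype(int)


def threshold_sweep(
    votes: np.ndarray | VoteMatrix, labels: np.ndarray
) -> pd.DataFrame:
    """Six evaluation measures for every vote threshold TH in 1..K.

    Returns one row per TH with Sen/Spec/Acc/Prec/F1 as fractions and MCC,
    plus boolean ``best_mcc`` / ``best_f1`` columns marking the arg-max rows.
    """
    if isinstance(votes, VoteMatrix):
        votes = votes.votes
    votes = np.asarray(votes)
    y = np.asarray(labels, dtype=int)
    if len(votes) != len(y):
        raise ValueError("votes and labels must be aligned")
    rows = []
    for TH in range(1, votes.shape[1] + 1):
        pred = combine_votes(votes, TH)
        m = metrics(confusion(pred, y))
        rows.append(
            {
                "TH": TH,
                "sen": m.sen,
                "spec": m.spec,
                "acc": m.acc,
                "mcc": m.mcc,
                "prec": m.prec,
                "f1": m.f1,
                "n_predicted_positive": int(pred.sum()),
            }
        )
    table = pd.DataFrame(rows)
    table["best_mcc"] = table["mcc"] == table["mcc"].max()
    table["best_f1"] = table["f1"] == table["f1"].max()
    return table


def save_model(model: EnsembleModel, path) -> None:
    """Serialize members, scalers, partition metadata, seed and config."""
    joblib.dump(model, path)


def load_model(path) -> EnsembleModel:
    model = joblib.load(path)
    if not isinstance(model, EnsembleModel):
        raise ValueError(f"{path} does not contain an ensemble model")
    return model
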