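"""Interface labelling and training-set construction.

A residue is an *interface residue* when its accessible surface area drops
by strictly more than 1 A^2 upon complex formation (unbound minus bound,
dASA). Interface residues are a minority class (~28% in hetero-complex
datasets), so training data are split into M positive and N negative
non-overlapping subsets of near-equal size — either in dASA order (the
default: positives sorted ascending by dASA; negatives with dASA == 0
shuffled, the few with 0 < dASA <= 1 kept in dASA order) or uniformly at
random. Each (positive, negative) subset pair later trains one ensemble
member. Cross-validation splits are made at the protein-chain level.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, List, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "INTERFACE_DASA_THRESHOLD",
    "LabeledResidue",
    "TrainingPartition",
    "CVSplit",
    "label_interface",
    "partition_by_dasa",
    "partition_random",
    "make_cv_folds",
]

#: dASA (A^2) above which a residue counts as interface (strict inequality).
INTERFACE_DASA_THRESHOLD = 1.0


@dataclass
class LabeledResidue:
    chain_id: str
    position: int
    delta_asa: float
    label: int

    def __post_init__(self) -> None:
        if self.delta_asa < 0:
            raise ValueError("delta_asa must be non-negative")
        if self.label not in (0, 1):
            raise ValueError("label must be 0 or 1")


@dataclass
class TrainingPartition:
    """Disjoint, exhaustive M x N subset partition of training sample indices."""

    pos_subsets: List[np.ndarray]
    neg_subsets: List[np.ndarray]
    strategy: str
    seed: int

    @property
    def M(self) -> int:
        return len(self.pos_subsets)

    @property
    def N(self) -> int:
        return len(self.neg_subsets)


@dataclass
class CVSplit:
    """Chain-level fold assignment, folds numbered 1..k."""

    fold_assignments: Dict[str, int]
    k: int = field(default=0)

    def __post_init__(self) -> None:
        if not self.k:
            self.k = max(self.fold_assignments.values(), default=0)

    def chains_in_fold(self, fold: int) -> List[str]:
        return [c for c, f in self.fold_assignments.items() if f == fold]


def label_interface(delta_asa):
    """Binary interface label(s) from dASA: 1 iff dASA > 1 A^2 (strict).

    Accepts a scalar or array; negative dASA raises.
    """
    arr = np.asarray(delta_asa, dtype=float)
    if np.any(arr < 0):
        raise ValueError("delta_asa must be non-negative")
    labels = (arr > INTERFACE_DASA_THRESHOLD).astype(int)
    if np.isscalar(delta_asa) or arr.ndim == 0:
        return int(labels)
    return labels


def _extract(samples) -> tuple[np.ndarray, np.ndarray]:
    """(delta_asa, label) arrays from a LabeledResidue list or a DataFrame."""
    if isinstance(samples, pd.DataFrame):
        return (
            samples["delta_asa"].to_numpy(dtype=float),
            samples["label"].to_numpy(dtype=int),
        )
    return (
        np.array([s.delta_asa for s in samples], dtype=float),
        np.array([s.label for s in samples], dtype=int),
    )


def _near_equal_blocks(indices: np.ndarray, k: int) -> List[np.ndarray]:
    """Split an index array into k contiguous blocks whose sizes differ by <= 1,
    earlier blocks taking the remainder."""
    n = len(indices)
    base, rem = divmod(n, k)
    blocks, start = [], 0
    for b in range(k):
        size = base + (1 if b < rem else 0)
        blocks.append(indices[start : start + size])
        start += size
    return blocks


def partition_by_dasa(samples, M: int, N: int, seed: int = 0) -> TrainingPartition:
    """dASA-ordered balanced partition.

    Positives are sorted ascending by dASA and cut into M contiguous blocks;
    negatives are listed as seed-shuffled dASA==0 samples followed by the
    (few) 0 < dASA <= 1 samples in ascending order, then cut into N blocks.
    """
    return _partition(samples, M, N, seed, "dasa_ordered")


def partition_random(samples, M: int, N: int, seed: int = 0) -> TrainingPartition:
    """Random balanced partition: both classes shuffled, then split."""
    return _partition(samples, M, N, seed, "random")


def _partition(samples, M: int, N: int, seed: int, strategy: str) -> TrainingPartition:
    if M < 1 or N < 1:
        raise ValueError("subset counts M and N must be >= 1")
    dasa, labels = _extract(samples)
    pos = np.flatnonzero(labels == 1)
    neg = np.flatnonzero(labels == 0)
    if len(pos) == 0 or len(neg) == 0:
        raise ValueError("both classes must be present to build a partition")
    rng = np.random.default_rng(seed)
    if strategy == "dasa_ordered":
        pos_order = pos[np.argsort(dasa[pos], kind="stable")]
        zeros = neg[dasa[neg] == 0.0]
        nonzeros = neg[dasa[neg] > 0.0]
        zeros = rng.permutation(zeros)
        nonzeros = nonzeros[np.argsort(dasa[nonzeros], kind="stable")]
        neg_order = np.concatenate([zeros, nonzeros])
    elif strategy == "random":
        pos_order = rng.permutation(pos)
        neg_order = rng.permutation(neg)
    else:  # pragma: no cover - internal
        raise ValueError(f"unknown strategy {strategy!r}")
    return TrainingPartition(
        pos_subsets=_near_equal_blocks(pos_order, M),
        neg_subsets=_near_equal_blocks(neg_order, N),
        strategy=strategy,
        seed=seed,
    )


def make_cv_folds(chain_ids: Sequence[str], k: int = 5, seed: int = 0) -> CVSplit:
    """Assign whole chains to k near-equal cross-validation folds (1..k)."""
    chain_ids = list(chain_ids)
    if len(set(chain_ids)) != len(chain_ids):
        raise ValueError("chain ids must be unique")
    if k < 2:
        raise ValueError("need at least 2 folds")
    if len(chain_ids) < k:
        raise ValueError(f"need at least {k} chains for {k}-fold CV")
    rng = np.random.default_rng(seed)
    order = rng.permutation(len(chain_ids))
    blocks = _near_equal_blocks(order, k)
    assignments = {}
    for fold, block in enumerate(blocks, start=1):
        for idx in block:
            assignments[chain_ids[idx]] = fold
    return CVSplit(fold_assignments=assignments, k=k)
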