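"""Modified self-organizing map used to gate training/testing samples.

An N x N Kohonen map with hexagonal layer topology is trained on the
feature vectors (batch updates, neighbourhood radius decaying linearly
over the training steps, weights initialized by seeded sampling of data
points). Samples are softly assigned to neurons and two pruning rules are
then applied before classification:

1. neurons attracting fewer than ``min_count`` samples are deleted, and
2. neurons whose per-neuron entropy — computed from the soft membership
   matrix via the validation index E = -(1/n) sum_n sum_r U_rn ln U_rn —
   is relatively large are deleted (default: above the median).

Samples mapping to removed neurons are excluded from downstream SVM
training and testing. The closer E is to 0, the more distinct the
clusters; E = ln(R) indicates no clustering structure at all.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Optional, Set, Tuple

import numpy as np

__all__ = [
    "SOMGrid",
    "ClusterAssignment",
    "ClusterSelection",
    "train_som",
    "assign_clusters",
    "entropy_index",
    "select_clusters",
    "retained_mask",
]


def hex_layout(N: int) -> np.ndarray:
    """Cartesian coordinates of an N x N hexagonal neuron layer.

    Odd rows are offset by half a unit; row spacing is sqrt(3)/2, so the
    six neighbours of an interior neuron are equidistant.
    """
    coords = np.empty((N * N, 2))
    for row in range(N):
        for col in range(N):
            coords[row * N + col] = (col + 0.5 * (row % 2), row * math.sqrt(3) / 2)
    return coords


@dataclass
class SOMGrid:
    N: int
    weights: np.ndarray  # (N*N, L)
    steps: int
    seed: int
    topology: str = "hexagonal"

    @property
    def R(self) -> int:
        return self.N * self.N

    def __post_init__(self) -> None:
        if self.weights.shape[0] != self.R:
            raise ValueError("weight count must be N*N")
        if not np.all(np.isfinite(self.weights)):
            raise ValueError("weights must be finite")


@dataclass
class ClusterAssignment:
    """Soft (column-stochastic U) and hard per-sample neuron assignments."""

    U: np.ndarray  # (R, n), columns sum to 1
    hard_cluster: np.ndarray  # (n,)
    counts: np.ndarray  # (R,)

    @property
    def n(self) -> int:
        return self.U.shape[1]

    @property
    def R(self) -> int:
        return self.U.shape[0]


@dataclass
class ClusterSelection:
    retained: Set[int]
    removed_small: Set[int]
    removed_entropy: Set[int]
    index_values: np.ndarray  # per-neuron entropy contributions
    E: float


def _sq_dists(X: np.ndarray, W: np.ndarray) -> np.ndarray:
    """(n, R) squared Euclidean distances."""
    return (
        np.sum(X * X, axis=1)[:, None]
        - 2.0 * X @ W.T
        + np.sum(W * W, axis=1)[None, :]
    )


def train_som(
    features: np.ndarray, N: int, steps: int = 20, seed: int = 0
) -> SOMGrid:
    """Train an N x N hexagonal SOM by seeded batch updates.

    Each step assigns every sample to its best-matching neuron and moves
    each weight to the neighbourhood-weighted mean of the data, with the
    Gaussian neighbourhood radius shrinking linearly from N/2 to 0.5 over
    the ``steps`` training steps. Fully deterministic under ``seed``.
    """
    X = np.asarray(features, dtype=float)
    if X.ndim != 2 or X.shape[1] < 1:
        raise ValueError("features must be a 2-D n x L matrix")
    n = X.shape[0]
    R = N * N
    if n < R:
        raise ValueError(f"need at least N*N={R} samples to train the map, got {n}")
    rng = np.random.default_rng(seed)
    init_idx = rng.choice(n, size=R, replace=False)
    W = X[init_idx].copy()
    if steps == 0:
        return SOMGrid(N=N, weights=W, steps=0, seed=seed)
    coords = hex_layout(N)
    grid_d2 = _sq_dists(coords, coords)  # (R, R) squared layer distances
    sigma0, sigma_end = max(N / 2.0, 0.5), 0.5
    for step in range(steps):
        frac = step / max(steps - 1, 1)
        sigma = sigma0 + (sigma_end - sigma0) * frac
        bmu = np.argmin(_sq_dists(X, W), axis=1)
        H = np.exp(-grid_d2 / (2.0 * sigma * sigma))  # (R, R) neighbourhood
        influence = H[:, bmu]  # (R, n)
        mass = influence.sum(axis=1)
        numer = influence @ X
        nonzero = mass > 0
        W[nonzero] = numer[nonzero] / mass[nonzero, None]
    return SOMGrid(N=N, weights=W, steps=steps, seed=seed)


def _membership_temperature(W: np.ndarray) -> float:
    """Median nearest-neighbour distance between neuron weights."""
    d2 = _sq_dists(W, W)
    np.fill_diagonal(d2, np.inf)
    nn = np.sqrt(np.min(d2, axis=1))
    tau = float(np.median(nn))
    return tau if tau > 0 else 1e-12


def assign_clusters(grid: SOMGrid, features: np.ndarray) -> ClusterAssignment:
    """Hard best-matching-neuron and soft Gaussian-kernel memberships.

    ``U_rn`` is proportional to ``exp(-||x_n - w_r||^2 / (2 tau^2))`` with
    ``tau`` the median nearest-neighbour distance between neuron weights,
    normalized so every column sums to 1.
    """
    X = np.asarray(features, dtype=float)
    if X.ndim != 2 or X.shape[1] != grid.weights.shape[1]:
        raise ValueError(
            f"feature dimension {X.shape[-1] if X.ndim == 2 else '?'} does not "
            f"match grid dimension {grid.weights.shape[1]}"
        )
    d2 = _sq_dists(X, grid.weights)  # (n, R)
    hard = np.argmin(d2, axis=1)
    tau = _membership_temperature(grid.weights)
    logits = -d2 / (2.0 * tau * tau)
    logits -= logits.max(axis=1, keepdims=True)
    U = np.exp(logits)
    U /= U.sum(axis=1, keepdims=True)
    counts = np.bincount(hard, minlength=grid.R)
    return ClusterAssignment(U=U.T, hard_cluster=hard, counts=counts)


def entropy_index(assignment: ClusterAssignment) -> Tuple[float, np.ndarray]:
    """Validation index E and per-neuron entropy contributions.

    ``E = -(1/n) sum_n sum_r U_rn ln U_rn`` (with 0*ln 0 := 0), bounded by
    [0, ln R]: 0 for crisp memberships, ln R for a structureless uniform
    assignment. The per-neuron value is the mean column entropy over the
    samples hard-assigned to that neuron (0 for empty neurons).
    """
    U = assignment.U
    if U.size == 0 or U.shape[1] == 0:
        raise ValueError("assignment is empty")
    with np.errstate(divide="ignore", invalid="ignore"):
        plogp = np.where(U > 0, U * np.log(U), 0.0)
    col_entropy = -plogp.sum(axis=0)  # (n,)
    E = float(col_entropy.mean())
    R = assignment.R
    per_neuron = np.zeros(R)
    for r in range(R):
        mask = assignment.hard_cluster == r
        if np.any(mask):
            per_neuron[r] = col_entropy[mask].mean()
    return E, per_neuron


def default_min_count(n: int, R: int) -> int:
    return max(2, math.ceil(0.01 * n / R))


def select_clusters(
    grid: SOMGrid,
    assignment: ClusterAssignment,
    min_count: Optional[int] = None,
    entropy_rule: str | float | None = "median",
) -> ClusterSelection:
    """Apply the two pruning modifications and return the retained neurons.

    ``min_count`` defaults to max(2, 1% of n/R). ``entropy_rule`` is
    ``"median"`` (remove neurons whose per-neuron entropy is strictly above
    the median of the surviving neurons), a float cutoff (remove strictly
    above it; ``float('inf')`` retains all), or ``None`` to skip the rule.
    """
    if min_count is None:
        min_count = default_min_count(assignment.n, grid.R)
    E, per_neuron = entropy_index(assignment)
    all_neurons = set(range(grid.R))
    removed_small = {r for r in all_neurons if assignment.counts[r] < min_count}
    surviving = sorted(all_neurons - removed_small)
    if not surviving:
        raise ValueError("min_count removed every neuron; lower it or retrain")
    if entropy_rule is None:
        cutoff = math.inf
    elif entropy_rule == "median":
        cutoff = float(np.median(per_neuron[surviving]))
    else:
        cutoff = float(entropy_rule)
    removed_entropy = {r for r in surviving if per_neuron[r] > cutoff}
    retained = all_neurons - removed_small - removed_entropy
    if not retained:
        raise ValueError("entropy rule removed every surviving neuron")
    if not np.any(np.isin(assignment.hard_cluster, sorted(retained))):
        raise ValueError(
            "cluster selection would exclude every sample; relax min_count or "
            "the entropy rule"
        )
    return ClusterSelection(
        retained=retained,
        removed_small=removed_small,
        removed_entropy=removed_entropy,
        index_values=per_neuron,
        E=E,
    )


def retained_mask(
    selection: ClusterSelection, assignment: ClusterAssignment
) -> np.ndarray:
    """Boolean mask of samples whose hard cluster was retained."""
    return np.isin(assignment.hard_cluster, sorted(selection.retained))
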