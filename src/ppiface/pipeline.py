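"""End-to-end cross-validated runs tying all stages together.

``run_cross_validation`` performs a chain-level k-fold experiment: encode
residues with the configured profile mode, optionally gate samples with
the SOM filter (trained per fold on the training features only), build
the balanced M x N subset partition, train the SVM ensemble, vote on the
held-out chains, and pool the confusion counts across folds into one
threshold-sweep table. Every run is reproducible from its manifest
(config + seed + input hashes); all per-stage seeds are derived from the
single run seed.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import asdict, dataclass, field
from typing import Dict, List, Optional, Sequence

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .dataset import make_cv_folds, partition_by_dasa, partition_random
from .evaluation import confusion, metrics
from .profile_features import (
    ENCODING_MODES,
    KYTE_DOOLITTLE,
    ChainProfile,
    encode_chain,
    gaussian_coefficients,
)
from .som_filter import assign_clusters, retained_mask, select_clusters, train_som
from .svm_ensemble import SVMConfig, predict_votes, threshold_sweep, train_ensemble

__all__ = ["RunConfig", "CVResult", "run_cross_validation", "compare_models", "child_seed"]


def child_seed(seed: int, *tags) -> int:
    """Stable per-stage seed below 2^31 derived from the run seed and tags."""
    digest = hashlib.blake2s(
        ("|".join([str(seed), *map(str, tags)])).encode(), digest_size=4
    ).digest()
    return int.from_bytes(digest, "big") % (2**31)


@dataclass
class RunConfig:
    """Validated configuration for a cross-validated run."""

    L: int = 19
    mode: str = "integrative"
    M: int = 2
    N: int = 5
    strategy: str = "dasa_ordered"
    som_size: Optional[int] = None  # map side; None disables the SOM stage
    som_steps: int = 20
    som_min_count: Optional[int] = None
    som_entropy_rule: str | float | None = "median"
    svm: SVMConfig = field(default_factory=SVMConfig)
    threshold: int | str = "sweep"
    k_folds: int = 5
    variance_divisor: str = "unbiased"
    profile_scale: str = "fraction"
    seed: int = 0

    def __post_init__(self) -> None:
        if isinstance(self.svm, dict):
            self.svm = SVMConfig(**self.svm)
        if self.L < 1 or self.L % 2 == 0:
            raise ValueError("window length L must be odd and positive")
        if self.mode not in ENCODING_MODES:
            raise ValueError(f"mode must be one of {ENCODING_MODES}")
        if self.strategy not in ("dasa_ordered", "random"):
            raise ValueError("strategy must be 'dasa_ordered' or 'random'")
        if self.M < 1 or self.N < 1:
            raise ValueError("M and N must be >= 1")
        if self.k_folds < 2:
            raise ValueError("k_folds must be >= 2")
        if self.som_size is not None and self.som_size < 1:
            raise ValueError("som_size must be a positive map side")
        if self.threshold != "sweep" and not (
            isinstance(self.threshold, int) and 1 <= self.threshold <= self.M * self.N
        ):
            raise ValueError("threshold must be 'sweep' or an integer in 1..M*N")

    def to_dict(self) -> dict:
        d = asdict(self)
        return d

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        return cls(**data)


@dataclass
class CVResult:
    """Pooled cross-validation outputs: votes, labels, sweep and metadata."""

    votes: np.ndarray  # (n_tested, K)
    labels: np.ndarray  # (n_tested,)
    meta: pd.DataFrame  # chain_id, position, fold per tested residue
    sweep: pd.DataFrame  # pooled TH sweep with best-row markers
    fold_sweeps: Dict[int, pd.DataFrame]
    member_table: pd.DataFrame  # pooled per-member (individual SVM) metrics
    manifest: dict
    cluster_reports: Dict[int, pd.DataFrame] = field(default_factory=dict)

    @property
    def best_mcc(self) -> float:
        return float(self.sweep["mcc"].max())

    @property
    def best_f1(self) -> float:
        return float(self.sweep["f1"].max())

    @property
    def best_individual_mcc(self) -> float:
        return float(self.member_table["mcc"].max())


def _input_hash(chains: Sequence[ChainProfile], labels: pd.DataFrame) -> str:
    h = hashlib.sha256()
    for chain in chains:
        h.update(chain.chain_id.encode())
        h.update(chain.sequence.encode())
        h.update(np.ascontiguousarray(chain.sp_matrix()).tobytes())
    h.update(labels.to_csv(index=False).encode())
    return h.hexdigest()


def _member_metrics(votes: np.ndarray, labels: np.ndarray) -> pd.DataFrame:
    rows = []
    for k in range(votes.shape[1]):
        m = metrics(confusion(votes[:, k], labels))
        rows.append(
            {"member": k + 1, "sen": m.sen, "spec": m.spec, "acc": m.acc,
             "mcc": m.mcc, "prec": m.prec, "f1": m.f1}
        )
    return pd.DataFrame(rows)


def run_cross_validation(
    config: RunConfig,
    chains: Sequence[ChainProfile],
    labels: pd.DataFrame,
) -> CVResult:
    """Run the full chain-level k-fold experiment described in the module docs."""
    chains = list(chains)
    chain_ids = [c.chain_id for c in chains]
    label_idx = labels.set_index(["chain_id", "position"])
    if set(labels["chain_id"].astype(str)) != set(chain_ids):
        raise ValueError("chain ids in the label table do not match the chains")

    coeffs = gaussian_coefficients(config.L, config.variance_divisor)
    # encoding is fold-independent: compute once for all residues
    X_rows, y_rows, meta_rows = [], [], []
    for chain in chains:
        for fv in encode_chain(chain, coeffs, KYTE_DOOLITTLE, config.mode):
            X_rows.append(fv.v)
            row = label_idx.loc[(chain.chain_id, fv.position)]
            y_rows.append(int(row["label"]))
            meta_rows.append(
                {
                    "chain_id": chain.chain_id,
                    "position": fv.position,
                    "delta_asa": float(row["delta_asa"]),
                }
            )
    X = np.vstack(X_rows)
    y = np.array(y_rows, dtype=int)
    meta = pd.DataFrame(meta_rows)

    split = make_cv_folds(chain_ids, k=config.k_folds, seed=child_seed(config.seed, "cv"))
    sample_fold = meta["chain_id"].map(split.fold_assignments).to_numpy()

    partition_fn = partition_by_dasa if config.strategy == "dasa_ordered" else partition_random
    all_votes, all_labels, all_meta, fold_sweeps, cluster_reports = [], [], [], {}, {}
    for fold in range(1, config.k_folds + 1):
        train_mask = sample_fold != fold
        test_mask = ~train_mask
        X_tr, y_tr = X[train_mask], y[train_mask]
        X_te, y_te = X[test_mask], y[test_mask]
        meta_tr = meta[train_mask].reset_index(drop=True)
        meta_te = meta[test_mask].reset_index(drop=True)

        if config.som_size is not None:
            grid = train_som(
                X_tr,
                N=config.som_size,
                steps=config.som_steps,
                seed=child_seed(config.seed, "som", fold),
            )
            assign_tr = assign_clusters(grid, X_tr)
            selection = select_clusters(
                grid,
                assign_tr,
                min_count=config.som_min_count,
                entropy_rule=config.som_entropy_rule,
            )
            keep_tr = retained_mask(selection, assign_tr)
            assign_te = assign_clusters(grid, X_te)
            keep_te = retained_mask(selection, assign_te)
            cluster_reports[fold] = pd.DataFrame(
                {
                    "neuron": np.arange(grid.R),
                    "count": assign_tr.counts,
                    "entropy": selection.index_values,
                    "status": [
                        "removed_small"
                        if r in selection.removed_small
                        else "removed_entropy"
                        if r in selection.removed_entropy
                        else "retained"
                        for r in range(grid.R)
                    ],
                }
            )
            X_tr, y_tr, meta_tr = X_tr[keep_tr], y_tr[keep_tr], meta_tr[keep_tr].reset_index(drop=True)
            X_te, y_te, meta_te = X_te[keep_te], y_te[keep_te], meta_te[keep_te].reset_index(drop=True)

        train_df = meta_tr.assign(label=y_tr)
        partition = partition_fn(
            train_df, config.M, config.N, seed=child_seed(config.seed, "partition", fold)
        )
        model = train_ensemble(X_tr, y_tr, partition, config.svm, seed=config.seed)
        votes = predict_votes(model, X_te).votes
        if len(y_te):
            fold_sweeps[fold] = threshold_sweep(votes, y_te)
        all_votes.append(votes)
        all_labels.append(y_te)
        all_meta.append(meta_te.assign(fold=fold))

    votes = np.vstack(all_votes)
    y_pooled = np.concatenate(all_labels)
    meta_pooled = pd.concat(all_meta, ignore_index=True)[
        ["chain_id", "position", "fold"]
    ]
    sweep = threshold_sweep(votes, y_pooled)
    member_table = _member_metrics(votes, y_pooled)
    manifest = {
        "package_version": __version__,
        "config": _jsonable(config.to_dict()),
        "seed": config.seed,
        "input_hash": _input_hash(chains, labels),
        "n_chains": len(chains),
        "n_residues_tested": int(len(y_pooled)),
        "positive_rate_tested": float(np.mean(y_pooled)) if len(y_pooled) else 0.0,
    }
    return CVResult(
        votes=votes,
        labels=y_pooled,
        meta=meta_pooled,
        sweep=sweep,
        fold_sweeps=fold_sweeps,
        member_table=member_table,
        manifest=manifest,
        cluster_reports=cluster_reports,
    )


def _jsonable(obj):
    return json.loads(json.dumps(obj, default=str))


def compare_models(results: Dict[str, "CVResult | pd.DataFrame"]) -> pd.DataFrame:
    """Side-by-side per-TH table for several runs sharing the same TH grid.

    Best-MCC and best-F1 rows are re-marked per model from the aligned
    table. Raises when the TH grids are incompatible.
    """
    if len(results) < 1:
        raise ValueError("nothing to compare")
    sweeps = {
        name: (r.sweep if isinstance(r, CVResult) else r) for name, r in results.items()
    }
    grids = [tuple(s["TH"]) for s in sweeps.values()]
    if len(set(grids)) != 1:
        raise ValueError("reports do not share the same TH grid")
    out = pd.DataFrame({"TH": list(grids[0])})
    for name, s in sweeps.items():
        for col in ("sen", "spec", "acc", "mcc", "prec", "f1"):
            out[f"{col}_{name}"] = s[col].to_numpy()
        out[f"best_mcc_{name}"] = out[f"mcc_{name}"] == out[f"mcc_{name}"].max()
        out[f"best_f1_{name}"] = out[f"f1_{name}"] == out[f"f1_{name}"].max()
    return out
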