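"""Readers and writers for the tab-separated pipeline formats.

Formats (all TSV with a header row):

- profile table: ``chain_id, position, aa, A, R, N, D, C, Q, E, G, H, I,
  L, K, M, F, P, S, T, W, Y, V`` — one row per residue, columns in the
  canonical amino-acid order shared with the hydropathy scale;
- dASA/label table: ``chain_id, position, aa, delta_asa[, label]`` — the
  label column is derived from dASA (> 1 A^2) when absent;
- feature matrix: ``chain_id, position, v_1..v_L[, target]``;
- CV split: ``chain_id, fold``;
- SOM cluster report: ``neuron, count, entropy, status``.

Chain sequences travel as plain FASTA (Biopython).
"""

from __future__ import annotations

from pathlib import Path
from typing import Dict, Iterable, List, Sequence

import numpy as np
import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from .dataset import CVSplit, label_interface
from .profile_features import AMINO_ACIDS, ChainProfile, FeatureVector
from .som_filter import ClusterSelection

__all__ = [
    "read_fasta",
    "write_fasta",
    "read_profiles",
    "write_profiles",
    "read_labels",
    "write_features",
    "read_features",
    "write_cv_split",
    "write_cluster_report",
    "write_metrics_report",
    "write_predictions",
    "load_dataset",
]

PROFILE_COLUMNS = ["chain_id", "position", "aa"] + list(AMINO_ACIDS)


def read_fasta(path) -> Dict[str, str]:
    """Chain id -> sequence from a FASTA file."""
    return {rec.id: str(rec.seq) for rec in SeqIO.parse(str(path), "fasta")}


def write_fasta(chains: Iterable[ChainProfile], path) -> None:
    records = [
        SeqRecord(Seq(c.sequence), id=c.chain_id, description="") for c in chains
    ]
    SeqIO.write(records, str(path), "fasta")


def read_profiles(path, profile_scale: str = "fraction") -> List[ChainProfile]:
    """Parse a residue profile table into per-chain profile containers.

    ``profile_scale="percent"`` divides the 20 frequency columns by 100
    (HSSP stores percentages); ``"fraction"`` (default) takes them as-is.
    """
    if profile_scale not in ("fraction", "percent"):
        raise ValueError(f"unknown profile_scale {profile_scale!r}")
    df = pd.read_csv(path, sep="\t")
    missing = set(PROFILE_COLUMNS) - set(df.columns)
    if missing:
        raise ValueError(f"profile table is missing columns: {sorted(missing)}")
    scale = 0.01 if profile_scale == "percent" else 1.0
    chains = []
    for chain_id, group in df.groupby("chain_id", sort=False):
        group = group.sort_values("position")
        if not np.array_equal(group["position"].to_numpy(), np.arange(1, len(group) + 1)):
            raise ValueError(f"chain {chain_id}: positions must run 1..n without gaps")
        sp = group[list(AMINO_ACIDS)].to_numpy(dtype=float) * scale
        chains.append(
            ChainProfile.from_arrays(str(chain_id), "".join(group["aa"]), sp)
        )
    return chains


def write_profiles(chains: Iterable[ChainProfile], path) -> None:
    rows = []
    for chain in chains:
        for res in chain.residues:
            row = {"chain_id": chain.chain_id, "position": res.position, "aa": res.amino_acid}
            row.update({aa: res.sp[i] for i, aa in enumerate(AMINO_ACIDS)})
            rows.append(row)
    pd.DataFrame(rows, columns=PROFILE_COLUMNS).to_csv(path, sep="\t", index=False)


def read_labels(path) -> pd.DataFrame:
    """dASA/label table; the label column is derived from dASA when absent."""
    df = pd.read_csv(path, sep="\t")
    required = {"chain_id", "position", "aa", "delta_asa"}
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"label table is missing columns: {sorted(missing)}")
    if np.any(df["delta_asa"].to_numpy(dtype=float) < 0):
        raise ValueError("delta_asa must be non-negative")
    if "label" not in df.columns:
        df = df.copy()
        df["label"] = label_interface(df["delta_asa"].to_numpy(dtype=float))
    return df


def write_features(features: Sequence[FeatureVector], path) -> None:
    if not features:
        raise ValueError("no feature vectors to write")
    L = len(features[0].v)
    cols = ["chain_id", "position"] + [f"v_{j}" for j in range(1, L + 1)] + ["target"]
    rows = []
    for f in features:
        row = {"chain_id": f.chain_id, "position": f.position, "target": f.target}
        row.update({f"v_{j + 1}": f.v[j] for j in range(L)})
        rows.append(row)
    pd.DataFrame(rows, columns=cols).to_csv(path, sep="\t", index=False)


def read_features(path):
    """(X, meta) from a feature matrix file; meta holds chain_id/position/target."""
    df = pd.read_csv(path, sep="\t")
    vcols = [c for c in df.columns if c.startswith("v_")]
    X = df[vcols].to_numpy(dtype=float)
    meta = df[[c for c in df.columns if not c.startswith("v_")]]
    return X, meta


def write_cv_split(split: CVSplit, path) -> None:
    pd.DataFrame(
        {"chain_id": list(split.fold_assignments), "fold": list(split.fold_assignments.values())}
    ).to_csv(path, sep="\t", index=False)


def write_cluster_report(selection: ClusterSelection, counts: np.ndarray, path) -> None:
    rows = []
    for r in range(len(selection.index_values)):
        if r in selection.removed_small:
            status = "removed_small"
        elif r in selection.removed_entropy:
            status = "removed_entropy"
        else:
            status = "retained"
        rows.append(
            {
                "neuron": r,
                "count": int(counts[r]),
                "entropy": selection.index_values[r],
                "status": status,
            }
        )
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False)


def write_metrics_report(sweep: pd.DataFrame, path) -> None:
    """TH sweep in the conventional layout: percentages except MCC."""
    out = pd.DataFrame(
        {
            "TH": sweep["TH"],
            "Sen": (100 * sweep["sen"]).round(2),
            "Spec": (100 * sweep["spec"]).round(2),
            "Acc": (100 * sweep["acc"]).round(2),
            "MCC": sweep["mcc"].round(4),
            "Prec": (100 * sweep["prec"]).round(2),
            "F1": (100 * sweep["f1"]).round(2),
        }
    )
    out.to_csv(path, sep="\t", index=False)


def write_predictions(meta: pd.DataFrame, votes: np.ndarray, TH: int, path) -> None:
    """Per-residue vote counts and the ensemble call at threshold TH."""
    out = meta.copy()
    out["votes"] = votes.sum(axis=1)
    out[f"predicted_label@TH={TH}"] = (out["votes"] >= TH).astype(int)
    out.to_csv(path, sep="\t", index=False)


def load_dataset(fasta_path, profiles_path, labels_path, profile_scale="fraction"):
    """Load and cross-validate the three input files.

    Returns (chains, labels DataFrame). Chain ids must agree across files
    and sequences must match the profile table's aa column.
    """
    sequences = read_fasta(fasta_path)
    chains = read_profiles(profiles_path, profile_scale=profile_scale)
    labels = read_labels(labels_path)
    chain_ids = {c.chain_id for c in chains}
    if set(sequences) != chain_ids or set(labels["chain_id"].astype(str)) != chain_ids:
        raise ValueError("chain ids disagree between FASTA, profile and label files")
    for chain in chains:
        if sequences[chain.chain_id] != chain.sequence:
            raise ValueError(f"sequence mismatch for chain {chain.chain_id}")
        sub = labels[labels["chain_id"].astype(str) == chain.chain_id]
        if len(sub) != len(chain):
            raise ValueError(f"label rows for chain {chain.chain_id} do not cover the chain")
    return chains, labels
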