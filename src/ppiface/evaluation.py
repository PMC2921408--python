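"""Six-measure evaluation, amino-acid propensities and curve tables.

Interface prediction is a heavily imbalanced binary problem, so no single
statistic suffices; the standard suite here is sensitivity, specificity,
accuracy, precision, F-measure and the Matthews correlation coefficient
(MCC: +1 perfect, 0 random, -1 inverse). Degenerate denominators are
reported as 0 and flagged rather than NaN so tables stay machine-readable.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Dict, Sequence

import numpy as np
import pandas as pd

from .profile_features import AMINO_ACIDS

__all__ = [
    "ConfusionCounts",
    "MetricSet",
    "confusion",
    "metrics",
    "propensity",
    "curve_table",
]


@dataclass(frozen=True)
class ConfusionCounts:
    TP: int
    FP: int
    TN: int
    FN: int

    def __post_init__(self) -> None:
        if min(self.TP, self.FP, self.TN, self.FN) < 0:
            raise ValueError("confusion counts must be non-negative")

    @property
    def total(self) -> int:
        return self.TP + self.FP + self.TN + self.FN


@dataclass
class MetricSet:
    """Sen/Spec/Acc/Prec/F1 as fractions in [0, 1]; MCC in [-1, 1]."""

    sen: float
    spec: float
    acc: float
    prec: float
    f1: float
    mcc: float
    defined: Dict[str, bool] = field(default_factory=dict)

    def as_percent_row(self) -> Dict[str, float]:
        """Table row with percentages (2 decimals) and raw MCC (4 decimals)."""
        return {
            "Sen": round(100 * self.sen, 2),
            "Spec": round(100 * self.spec, 2),
            "Acc": round(100 * self.acc, 2),
            "MCC": round(self.mcc, 4),
            "Prec": round(100 * self.prec, 2),
            "F1": round(100 * self.f1, 2),
        }


def confusion(pred: Sequence[int], truth: Sequence[int]) -> ConfusionCounts:
    """Count TP/FP/TN/FN between binary prediction and truth vectors."""
    p = np.asarray(pred, dtype=int)
    t = np.asarray(truth, dtype=int)
    if p.shape != t.shape or p.ndim != 1:
        raise ValueError("pred and truth must be 1-D vectors of equal length")
    if p.size == 0:
        raise ValueError("cannot evaluate empty vectors")
    return ConfusionCounts(
        TP=int(np.sum((p == 1) & (t == 1))),
        FP=int(np.sum((p == 1) & (t == 0))),
        TN=int(np.sum((p == 0) & (t == 0))),
        FN=int(np.sum((p == 0) & (t == 1))),
    )


def _ratio(num: float, den: float) -> tuple[float, bool]:
    return (num / den, True) if den > 0 else (0.0, False)


def metrics(c: ConfusionCounts) -> MetricSet:
    """The six evaluation measures from a confusion table.

    Sen = TP/(TP+FN), Spec = TN/(TN+FP), Acc = (TP+TN)/total,
    Prec = TP/(TP+FP), F1 = 2*Sen*Prec/(Sen+Prec) and
    MCC = (TP*TN - FP*FN) / sqrt((TP+FP)(TP+FN)(TN+FP)(TN+FN)).
    A zero denominator yields value 0 with the measure flagged undefined
    (MCC := 0 matches the random-guess interpretation).
    """
    if c.total == 0:
        raise ValueError("confusion table is empty")
    TP, FP, TN, FN = c.TP, c.FP, c.TN, c.FN
    sen, sen_ok = _ratio(TP, TP + FN)
    spec, spec_ok = _ratio(TN, TN + FP)
    acc = (TP + TN) / c.total
    prec, prec_ok = _ratio(TP, TP + FP)
    if sen_ok and prec_ok and (sen + prec) > 0:
        f1, f1_ok = 2 * sen * prec / (sen + prec), True
    else:
        f1, f1_ok = 0.0, False
    denom = (
        float(TP + FP) * float(TP + FN) * float(TN + FP) * float(TN + FN)
    )
    if denom > 0:
        mcc = (float(TP) * TN - float(FP) * FN) / math.sqrt(denom)
        mcc_ok = True
    else:
        mcc, mcc_ok = 0.0, False
    return MetricSet(
        sen=sen,
        spec=spec,
        acc=acc,
        prec=prec,
        f1=f1,
        mcc=mcc,
        defined={
            "sen": sen_ok,
            "spec": spec_ok,
            "acc": True,
            "prec": prec_ok,
            "f1": f1_ok,
            "mcc": mcc_ok,
        },
    )


def propensity(labels: Sequence[int], aas: Sequence[str]) -> pd.DataFrame:
    """Per-amino-acid interface propensity, log2(freq(a|pos) / freq(a|neg)).

    Frequencies are normalized within class over the 20 standard amino
    acids. Any amino acid with a zero count in either class is computed
    with add-one smoothing on the counts (in both classes) and flagged.
    """
    y = np.asarray(labels, dtype=int)
    aas = np.asarray(list(aas))
    if y.shape != aas.shape:
        raise ValueError("labels and amino acids must be aligned")
    standard = np.isin(aas, list(AMINO_ACIDS))
    y, aas = y[standard], aas[standard]
    if not np.any(y == 1) or not np.any(y == 0):
        raise ValueError("both classes must be non-empty")
    rows = []
    pos_aas, neg_aas = aas[y == 1], aas[y == 0]
    pos_counts = {a: int(np.sum(pos_aas == a)) for a in AMINO_ACIDS}
    neg_counts = {a: int(np.sum(neg_aas == a)) for a in AMINO_ACIDS}
    n_pos, n_neg = len(pos_aas), len(neg_aas)
    for a in AMINO_ACIDS:
        cp, cn = pos_counts[a], neg_counts[a]
        smoothed = cp == 0 or cn == 0
        if smoothed:
            fp = (cp + 1) / (n_pos + 20)
            fn = (cn + 1) / (n_neg + 20)
        else:
            fp = cp / n_pos
            fn = cn / n_neg
        rows.append(
            {
                "aa": a,
                "log2_propensity": math.log2(fp / fn),
                "count_interface": cp,
                "count_non_interface": cn,
                "smoothed": smoothed,
            }
        )
    return pd.DataFrame(rows)


def curve_table(sweep: pd.DataFrame) -> Dict[str, pd.DataFrame]:
    """Sensitivity-precision and sensitivity-MCC tables from a TH sweep.

    Rows are sorted by sensitivity (no interpolation); the TH column is
    preserved so the TH -> metrics mapping stays bijective.
    """
    if len(sweep) == 0:
        raise ValueError("sweep table is empty")
    ordered = sweep.sort_values(["sen", "TH"], kind="stable").reset_index(drop=True)
    return {
        "sen_prec": ordered[["TH", "sen", "prec"]].copy(),
        "sen_mcc": ordered[["TH", "sen", "mcc"]].copy(),
    }
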