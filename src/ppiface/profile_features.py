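"""Integrative per-residue profile features.

A residue is described by the *integrative profile*: the unbiased standard
deviation of the elementwise product of its 20-value evolutionary sequence
profile (alignment-derived amino-acid frequencies, HSSP-style) with the
Kyte-Doolittle hydropathy scale. This scalar captures how strongly the
residue's evolutionary context fluctuates with respect to hydrophobicity.
A sliding window of odd length ``L`` centred on the residue then yields a
1-by-L feature vector, each window slot weighted by a Gaussian influence
coefficient that peaks at the centre residue.

Two ablation encodings are provided for comparison: ``profile_only`` (the
standard deviation of the sequence profile alone) and ``hydropathy_only``
(the residue's own Kyte-Doolittle value), windowed identically.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field
from typing import Iterable, List, Mapping, Sequence

import numpy as np

__all__ = [
    "AMINO_ACIDS",
    "KYTE_DOOLITTLE",
    "HydropathyScale",
    "ResidueProfile",
    "ChainProfile",
    "WindowCoefficients",
    "FeatureVector",
    "gaussian_coefficients",
    "integrative_sd",
    "profile_sd",
    "encode_residue",
    "encode_chain",
    "stack_features",
    "ENCODING_MODES",
]

#: Canonical amino-acid ordering shared by sequence profiles and the
#: hydropathy scale (classic PAM/HSSP column order).
AMINO_ACIDS = "ARNDCQEGHILKMFPSTWYV"

_AA_INDEX = {aa: i for i, aa in enumerate(AMINO_ACIDS)}

ENCODING_MODES = ("integrative", "profile_only", "hydropathy_only")


@dataclass(frozen=True)
class HydropathyScale:
    """Per-amino-acid hydrophobicity values (positive = hydrophobic)."""

    values: Mapping[str, float]

    def __post_init__(self) -> None:
        if set(self.values) != set(AMINO_ACIDS):
            raise ValueError(
                "hydropathy scale must define exactly the 20 standard amino acids"
            )
        if not all(math.isfinite(v) for v in self.values.values()):
            raise ValueError("hydropathy values must be finite")

    def vector(self) -> np.ndarray:
        """Scale as a length-20 array in canonical amino-acid order."""
        return np.array([self.values[aa] for aa in AMINO_ACIDS], dtype=float)

    def of(self, amino_acid: str) -> float:
        """Value for one residue; non-standard codes map to 0 with a warning."""
        try:
            return self.values[amino_acid]
        except KeyError:
            warnings.warn(
                f"non-standard residue {amino_acid!r} assigned hydropathy 0",
                stacklevel=2,
            )
            return 0.0


#: Kyte & Doolittle (1982) hydropathy scale.
KYTE_DOOLITTLE = HydropathyScale(
    {
        "I": 4.5, "V": 4.2, "L": 3.8, "F": 2.8, "C": 2.5,
        "M": 1.9, "A": 1.8, "G": -0.4, "T": -0.7, "S": -0.8,
        "W": -0.9, "Y": -1.3, "P": -1.6, "H": -3.2, "E": -3.5,
        "Q": -3.5, "D": -3.5, "N": -3.5, "K": -3.9, "R": -4.5,
    }
)


@dataclass
class ResidueProfile:
    """One residue's identity plus its 20-value sequence profile."""

    amino_acid: str
    position: int  # 1-based index in the chain
    sp: np.ndarray  # alignment frequencies, canonical order

    def __post_init__(self) -> None:
        self.sp = np.asarray(self.sp, dtype=float)
        if self.sp.shape != (20,):
            raise ValueError("sequence profile must have exactly 20 entries")
        if not np.all(np.isfinite(self.sp)):
            raise ValueError("sequence profile entries must be finite")
        if np.any(self.sp < 0):
            raise ValueError("sequence profile entries must be non-negative")


@dataclass
class ChainProfile:
    """A protein chain: sequence plus per-residue profiles, 1-based positions."""

    chain_id: str
    residues: List[ResidueProfile]
    sequence: str = field(default="")

    def __post_init__(self) -> None:
        if not self.sequence:
            self.sequence = "".join(r.amino_acid for r in self.residues)
        if len(self.sequence) != len(self.residues):
            raise ValueError("sequence length must equal number of residues")
        for k, res in enumerate(self.residues):
            if res.position != k + 1:
                raise ValueError(
                    f"residue at index {k} has position {res.position}, expected {k + 1}"
                )
            if res.amino_acid != self.sequence[k]:
                raise ValueError(
                    f"residue {k + 1} amino acid {res.amino_acid!r} does not match "
                    f"sequence letter {self.sequence[k]!r}"
                )

    def __len__(self) -> int:
        return len(self.residues)

    @classmethod
    def from_arrays(
        cls, chain_id: str, sequence: str, sp_matrix: np.ndarray
    ) -> "ChainProfile":
        sp_matrix = np.asarray(sp_matrix, dtype=float)
        if sp_matrix.shape != (len(sequence), 20):
            raise ValueError("profile matrix must be len(sequence) x 20")
        residues = [
            ResidueProfile(aa, k + 1, sp_matrix[k]) for k, aa in enumerate(sequence)
        ]
        return cls(chain_id, residues, sequence)

    def sp_matrix(self) -> np.ndarray:
        return np.vstack([r.sp for r in self.residues])


@dataclass(frozen=True)
class WindowCoefficients:
    """Gaussian influence coefficients for a sliding window of odd length L.

    Slot positions are 1..L; the centre ``mu = (L+1)/2`` is the target
    residue and receives the maximal coefficient.
    """

    L: int
    mu: float
    sigma2: float
    p: np.ndarray

    def __post_init__(self) -> None:
        if self.p.shape != (self.L,):
            raise ValueError("coefficient vector length must equal L")


def gaussian_coefficients(
    L: int, variance_divisor: str = "unbiased"
) -> WindowCoefficients:
    """Normal-density influence coefficients over window slots 1..L.

    The influence of window neighbours on the central target residue is
    modelled as a normal density centred at ``mu = (L+1)/2`` with variance
    the sample variance of the slot positions about the centre:
    ``sigma2 = sum_i (i - mu)^2 / (L - 1)`` (``variance_divisor="unbiased"``,
    default) or divisor ``L`` (``"population"``).

    Parameters
    ----------
    L:
        Odd window length in residues, ``L >= 1``.
    variance_divisor:
        ``"unbiased"`` (divide by L-1) or ``"population"`` (divide by L).
    """
    if not isinstance(L, (int, np.integer)) or L < 1 or L % 2 == 0:
        raise ValueError(f"window length must be an odd positive integer, got {L!r}")
    if variance_divisor not in ("unbiased", "population"):
        raise ValueError(f"unknown variance_divisor {variance_divisor!r}")
    mu = (L + 1) / 2.0
    positions = np.arange(1, L + 1, dtype=float)
    if L == 1:
        sigma2 = 1.0  # degenerate single-slot window; density at the centre
    else:
        divisor = L - 1 if variance_divisor == "unbiased" else L
        sigma2 = float(np.sum((positions - mu) ** 2) / divisor)
    p = np.exp(-((positions - mu) ** 2) / (2.0 * sigma2)) / math.sqrt(
        2.0 * math.pi * sigma2
    )
    return WindowCoefficients(L=int(L), mu=mu, sigma2=sigma2, p=p)


def _check_20(vec: np.ndarray, name: str) -> np.ndarray:
    vec = np.asarray(vec, dtype=float)
    if vec.shape != (20,):
        raise ValueError(f"{name} must have exactly 20 entries, got shape {vec.shape}")
    if not np.all(np.isfinite(vec)):
        raise ValueError(f"{name} entries must be finite")
    return vec


def integrative_sd(sp: Sequence[float], kd: Sequence[float]) -> float:
    """Unbiased standard deviation of the elementwise profile-hydropathy product.

    ``sqrt( sum_k (sp_k*kd_k - mean(sp*kd))^2 / 19 )`` — the integrative
    profile value for one residue.
    """
    sp = _check_20(sp, "sequence profile")
    kd = _check_20(kd, "hydropathy vector")
    prod = sp * kd
    return float(np.std(prod, ddof=1))


def profile_sd(sp: Sequence[float]) -> float:
    """Unbiased standard deviation of the sequence profile alone."""
    sp = _check_20(sp, "sequence profile")
    return float(np.std(sp, ddof=1))


@dataclass
class FeatureVector:
    """Windowed feature vector for one residue, with optional binary target."""

    chain_id: str
    position: int
    v: np.ndarray
    target: int | None = None

    def __post_init__(self) -> None:
        self.v = np.asarray(self.v, dtype=float)
        if not np.all(np.isfinite(self.v)):
            raise ValueError("feature entries must be finite")


def _residue_values(
    chain: ChainProfile, kd: HydropathyScale, mode: str
) -> np.ndarray:
    """Per-residue scalar value under the chosen encoding mode."""
    if mode == "integrative":
        kd_vec = kd.vector()
        return np.array([integrative_sd(r.sp, kd_vec) for r in chain.residues])
    if mode == "profile_only":
        return np.array([profile_sd(r.sp) for r in chain.residues])
    if mode == "hydropathy_only":
        return np.array([kd.of(r.amino_acid) for r in chain.residues])
    raise ValueError(f"unknown encoding mode {mode!r}; expected one of {ENCODING_MODES}")


def encode_chain(
    chain: ChainProfile,
    coeffs: WindowCoefficients,
    kd: HydropathyScale = KYTE_DOOLITTLE,
    mode: str = "integrative",
) -> List[FeatureVector]:
    """Encode every residue of a chain as a 1-by-L windowed feature vector.

    Window slot ``j`` (1-based) of residue ``i`` holds the per-residue value
    of chain position ``i - mu + j`` times the influence coefficient ``p_j``;
    slots falling outside the chain contribute 0.
    """
    values = _residue_values(chain, kd, mode)
    n, L = len(values), coeffs.L
    half = (L - 1) // 2
    padded = np.zeros(n + 2 * half)
    padded[half : half + n] = values
    out = []
    matrix = np.empty((n, L))
    for j in range(L):
        matrix[:, j] = padded[j : j + n] * coeffs.p[j]
    for i in range(n):
        out.append(FeatureVector(chain.chain_id, i + 1, matrix[i]))
    return out


def encode_residue(
    chain: ChainProfile,
    position: int,
    coeffs: WindowCoefficients,
    kd: HydropathyScale = KYTE_DOOLITTLE,
    mode: str = "integrative",
) -> FeatureVector:
    """Windowed feature vector for a single 1-based chain position."""
    if not 1 <= position <= len(chain):
        raise ValueError(
            f"position {position} out of range for chain of length {len(chain)}"
        )
    return encode_chain(chain, coeffs, kd, mode)[position - 1]


def stack_features(features: Iterable[FeatureVector]):
    """Stack feature vectors into (X, meta) where meta is a DataFrame of
    chain_id/position rows aligned with X."""
    import pandas as pd

    features = list(features)
    X = np.vstack([f.v for f in features]) if features else np.empty((0, 0))
    meta = pd.DataFrame(
        {
            "chain_id": [f.chain_id for f in features],
            "position": [f.position for f in features],
        }
    )
    return X, meta
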