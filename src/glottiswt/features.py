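"""Per-sub-band energy/statistical descriptors and feature-table scaling.

Seven descriptors are computed for every approximation and detail band of
the wavelet decomposition: energy, power entropy ("Pentropy"), mean,
variance, standard deviation, kurtosis and skewness.  At decomposition
level 4 this yields the 56-dimensional feature vector
``{Energy|Pentropy|Mean|Variance|Std-Dev|Kurtosis|Skewness}-{A|D}{1..4}``.

Conventions
-----------
* Entropy is the Shannon entropy (base 2) of the normalized squared
  coefficients ``p_k = W_k^2 / sum W^2`` — the relative sub-band energy
  distribution.  This is well defined for the signed coefficients a
  wavelet transform produces; a literal ``-sum |W| log2 |W|`` variant
  (zero taps skipped) is available via ``entropy_mode="literal"``.
* Variance and standard deviation use the unbiased ``L-1`` denominator.
* Kurtosis and skewness use 1/L central moments normalized by powers of
  the (L-1)-denominator standard deviation; a constant band (sigma = 0)
  yields 0 for both rather than an error.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .errors import DegenerateInputError, SchemaError
from .swt import SubbandSet

STAT_NAMES = ("Energy", "Pentropy", "Mean", "Variance", "Std-Dev", "Kurtosis", "Skewness")

#: The three descriptors that generalize across cohorts (the "common" subset).
COMMON3 = ("Mean-D2", "Mean-D3", "Mean-D4")


def subband_energy(coeffs: np.ndarray) -> float:
    """Total energy ``sum W^2`` of a coefficient array."""
    w = np.asarray(coeffs, dtype=np.float64)
    if w.size == 0:
        raise DegenerateInputError("empty coefficient array")
    return float(np.sum(w * w))


def subband_entropy(coeffs: np.ndarray, mode: str = "power") -> float:
    """Sub-band entropy in bits.

    ``mode="power"`` (default): Shannon entropy of ``p_k = W_k^2 / sum W^2``.
    ``mode="literal"``: ``-sum |W| log2 |W|`` with zero coefficients skipped.
    An all-zero band returns 0.0.
    """
    w = np.asarray(coeffs, dtype=np.float64)
    if w.size == 0:
        raise DegenerateInputError("empty coefficient array")
    if mode == "power":
        e = w * w
        total = e.sum()
        if total == 0.0:
            return 0.0
        p = e[e > 0] / total
        return float(-np.sum(p * np.log2(p)))
    if mode == "literal":
        a = np.abs(w)
        a = a[a > 0]
        if a.size == 0:
            return 0.0
        return float(-np.sum(a * np.log2(a)))
    raise ValueError(f"unknown entropy mode: {mode!r}")


def subband_moments(coeffs: np.ndarray):
    """(mean, variance, std_dev, kurtosis, skewness) of a coefficient array.

    Variance/std use the L-1 denominator; kurtosis = m4/sigma^4 and
    skewness = m3/sigma^3 with 1/L central moments and the L-1 sigma.
    """
    w = np.asarray(coeffs, dtype=np.float64)
    if w.size == 0:
        raise DegenerateInputError("empty coefficient array")
    mean = float(np.mean(w))
    if w.size < 2:
        return mean, 0.0, 0.0, 0.0, 0.0
    dev = w - mean
    variance = float(np.sum(dev * dev) / (w.size - 1))
    std = float(np.sqrt(variance))
    if std == 0.0 or std ** 4 == 0.0:  # exact or underflowing-to-degenerate spread
        return mean, variance, std, 0.0, 0.0
    m3 = float(np.mean(dev ** 3))
    m4 = float(np.mean(dev ** 4))
    return mean, variance, std, m4 / std ** 4, m3 / std ** 3


def band_descriptors(coeffs: np.ndarray, entropy_mode: str = "power") -> dict:
    """All seven descriptors of one sub-band, keyed by stat name."""
    mean, var, std, kurt, skew = subband_moments(coeffs)
    return {
        "Energy": subband_energy(coeffs),
        "Pentropy": subband_entropy(coeffs, mode=entropy_mode),
        "Mean": mean,
        "Variance": var,
        "Std-Dev": std,
        "Kurtosis": kurt,
        "Skewness": skew,
    }


def feature_names(levels: int = 4) -> list:
    """Canonical ordered names: stats nested in branch nested in level."""
    names = []
    for level in range(1, levels + 1):
        for branch in ("A", "D"):
            for stat in STAT_NAMES:
                names.append(f"{stat}-{branch}{level}")
    return names


@dataclass
class FeatureVector:
    """Named descriptor values for one recording (56 entries at level 4)."""

    values: dict
    recording_id: str = ""
    label: str | None = None

    def __len__(self) -> int:
        return len(self.values)

    def as_series(self) -> pd.Series:
        return pd.Series(self.values)


def extract_feature_vector(
    subbands: SubbandSet,
    recording_id: str = "",
    label: str | None = None,
    entropy_mode: str = "power",
) -> FeatureVector:
    """Assemble the 7 x 2 x levels descriptor vector from a sub-band set."""
    values = {}
    for level in range(1, subbands.levels + 1):
        for branch, bands in (("A", subbands.approx), ("D", subbands.detail)):
            stats = band_descriptors(bands[level - 1], entropy_mode=entropy_mode)
            for stat, val in stats.items():
                values[f"{stat}-{branch}{level}"] = val
    vec = FeatureVector(values=values, recording_id=recording_id, label=label)
    if not all(np.isfinite(list(values.values()))):
        raise ValueError("non-finite descriptor value")
    return vec


def feature_table(vectors) -> pd.DataFrame:
    """Stack feature vectors into a DataFrame with ``id`` and ``label`` columns."""
    rows = []
    for v in vectors:
        row = dict(v.values)
        row["id"] = v.recording_id
        row["label"] = v.label
        rows.append(row)
    return pd.DataFrame(rows)


class MinMaxScaler:
    """Train-derived per-column min/max mapping to [0, 1].

    Test values are mapped with the *training* bounds and may fall outside
    [0, 1]; they are deliberately not clipped.  A constant training column
    maps to 0 everywhere (flagged in ``degenerate_columns``).
    """

    def __init__(self) -> None:
        self.min_ = None
        self.max_ = None
        self.columns_ = None
        self.degenerate_columns = []

    def fit(self, table: pd.DataFrame) -> "MinMaxScaler":
        if table.empty:
            raise SchemaError("cannot fit scaler on an empty table")
        self.columns_ = list(table.columns)
        self.min_ = table.min(axis=0)
        self.max_ = table.max(axis=0)
        span = self.max_ - self.min_
        self.degenerate_columns = list(span.index[span == 0])
        return self

    def transform(self, table: pd.DataFrame) -> pd.DataFrame:
        if self.min_ is None:
            raise SchemaError("scaler not fitted")
        if list(table.columns) != self.columns_:
            raise SchemaError("column mismatch between scaler and table")
        span = (self.max_ - self.min_).replace(0.0, 1.0)
        out = (table - self.min_) / span
        for col in self.degenerate_columns:
            out[col] = 0.0
        return out

    def to_dict(self) -> dict:
        return {
            "columns": self.columns_,
            "min": [float(v) for v in self.min_],
            "max": [float(v) for v in self.max_],
        }


def minmax_scale(train_table: pd.DataFrame, test_table: pd.DataFrame | None = None):
    """Scale train columns to [0, 1]; map test columns with the train bounds.

    Returns ``(scaled_train, scaled_test, scaler)``; ``scaled_test`` is
    None when no test table is given.
    """
    scaler = MinMaxScaler().fit(train_table)
    train_scaled = scaler.transform(train_table)
    test_scaled = scaler.transform(test_table) if test_table is not None else None
    return train_scaled, test_scaled, scaler
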