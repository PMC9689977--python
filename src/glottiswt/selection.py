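"""Information-gain feature ranking and per-class density diagnostics.

A descriptor's discriminating power is scored by the reduction in class
label entropy obtained by conditioning on the discretized descriptor:
``IG = H(labels) - sum_b p(b) H(labels | bin b)`` with base-2 logs, so
0 <= IG <= H(labels).  Equal-width binning over [min, max] with 10 bins
is the default; quantile binning is available for monotone-invariant
scoring.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.stats import gaussian_kde

from .errors import SchemaError


def _entropy_bits(labels: np.ndarray) -> float:
    _, counts = np.unique(labels, return_counts=True)
    p = counts / counts.sum()
    return float(-np.sum(p * np.log2(p)))


def label_entropy(labels) -> float:
    """Base-2 Shannon entropy of a label sequence."""
    return _entropy_bits(np.asarray(labels))


def _bin_assignments(values: np.ndarray, bins: int, strategy: str) -> np.ndarray:
    if strategy == "equal_width":
        lo, hi = values.min(), values.max()
        if hi == lo:
            return np.zeros(len(values), dtype=int)
        edges = np.linspace(lo, hi, bins + 1)
        # right edge inclusive so the maximum lands in the top bin
        return np.clip(np.digitize(values, edges[1:-1], right=False), 0, bins - 1)
    if strategy == "quantile":
        edges = np.unique(np.quantile(values, np.linspace(0, 1, bins + 1)[1:-1]))
        return np.digitize(values, edges, right=True)
    raise ValueError(f"unknown binning strategy: {strategy!r}")


def information_gain(
    values, labels, bins: int = 10, strategy: str = "equal_width"
) -> float:
    """Information gain (bits) of a discretized feature about class labels."""
    values = np.asarray(values, dtype=np.float64)
    labels = np.asarray(labels)
    if len(values) != len(labels):
        raise SchemaError("values and labels must have equal length")
    if bins < 2:
        raise ValueError("bins must be >= 2")
    if len(np.unique(labels)) < 2:
        warnings.warn("single-class labels: information gain is 0", stacklevel=2)
        return 0.0
    h_labels = _entropy_bits(labels)
    assign = _bin_assignments(values, bins, strategy)
    n = len(values)
    h_cond = 0.0
    for b in np.unique(assign):
        mask = assign == b
        h_cond += (mask.sum() / n) * _entropy_bits(labels[mask])
    return float(max(0.0, h_labels - h_cond))


@dataclass
class FeatureRanking:
    """Descending (feature, IG-bits) ranking with its discretization spec."""

    ranking: list  # list of (name, ig) tuples, sorted descending
    bins: int
    strategy: str

    @property
    def names(self) -> list:
        return [name for name, _ in self.ranking]

    def top(self, k: int) -> list:
        return self.names[:k]

    def as_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "rank": np.arange(1, len(self.ranking) + 1),
                "parameter": self.names,
                "ig_value": [ig for _, ig in self.ranking],
            }
        )


def rank_features(
    table: pd.DataFrame, labels, bins: int = 10, strategy: str = "equal_width"
) -> FeatureRanking:
    """IG-rank every column of a feature table; ties broken by column name."""
    if table.empty:
        raise SchemaError("cannot rank an empty feature table")
    scores = {
        col: information_gain(table[col].to_numpy(), labels, bins, strategy)
        for col in table.columns
    }
    ordered = sorted(scores.items(), key=lambda kv: (-kv[1], kv[0]))
    return FeatureRanking(ranking=ordered, bins=bins, strategy=strategy)


def common_top_features(rankings, k_pool: int = 5, k_pick: int = 3) -> list:
    """Features shared across several cohorts' top-``k_pool`` lists.

    Candidates present in every cohort's top ``k_pool`` are preferred;
    ordering is by mean rank across cohorts.  If fewer than ``k_pick``
    candidates intersect, the pool is filled by best overall mean rank.
    """
    rank_maps = [{n: i for i, n in enumerate(r.names)} for r in rankings]
    pools = [set(r.top(k_pool)) for r in rankings]
    shared = set.intersection(*pools) if pools else set()
    all_names = rankings[0].names

    def mean_rank(name):
        return np.mean([m.get(name, len(m)) for m in rank_maps])

    picked = sorted(shared, key=lambda n: (mean_rank(n), n))[:k_pick]
    if len(picked) < k_pick:
        rest = sorted(
            (n for n in all_names if n not in picked), key=lambda n: (mean_rank(n), n)
        )
        picked += rest[: k_pick - len(picked)]
    return picked


def density_curves(values, labels, grid_size: int = 256):
    """Per-class Gaussian-KDE density curves on a shared grid.

    Returns a DataFrame with columns ``x`` and one density column per class
    (each curve integrates to ~1).  Classes with fewer than 5 points are
    skipped with a warning.
    """
    values = np.asarray(values, dtype=np.float64)
    labels = np.asarray(labels)
    classes = np.unique(labels)
    lo, hi = values.min(), values.max()
    span = hi - lo if hi > lo else 1.0
    grid = np.linspace(lo - 0.1 * span, hi + 0.1 * span, grid_size)
    out = {"x": grid}
    for cls in classes:
        pts = values[labels == cls]
        if len(pts) < 5:
            warnings.warn(f"class {cls!r} has fewer than 5 points; skipped", stacklevel=2)
            continue
        if np.ptp(pts) == 0:
            warnings.warn(f"class {cls!r} is constant; skipped", stacklevel=2)
            continue
        out[str(cls)] = gaussian_kde(pts)(grid)
    return pd.DataFrame(out)
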