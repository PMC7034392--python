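"""Cross-tabulation and chance-corrected agreement between labelings.

Two statistics cover the two distinct questions in the evaluation:

* **Cohen's kappa** (unweighted) asks whether two labelings agree *on the
  same named levels*: kappa = (p_o - p_e) / (1 - p_e), with p_o the
  observed diagonal proportion and p_e the agreement expected from the
  marginals. Used for clustering-vs-norm correspondence.
* **Adjusted Rand index** (Hubert-Arabie permutation model) asks whether
  two *partitions* coincide, ignoring label identities entirely. Used for
  resampling robustness, where cluster numbering is arbitrary.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
from sklearn.metrics import adjusted_rand_score

__all__ = [
    "ConfusionMatrix",
    "cross_tabulate",
    "cohen_kappa",
    "adjusted_rand",
]


@dataclass(frozen=True)
class ConfusionMatrix:
    """A k_a x k_b cross-tabulation of two labelings of the same units."""

    counts: np.ndarray
    row_labels: tuple
    col_labels: tuple

    def __post_init__(self):
        counts = np.asarray(self.counts, dtype=np.int64)
        if counts.ndim != 2 or np.any(counts < 0):
            raise ValueError("counts must be a 2-D non-negative integer matrix")
        if counts.shape != (len(self.row_labels), len(self.col_labels)):
            raise ValueError("label lists must match the counts shape")
        object.__setattr__(self, "counts", counts)

    @property
    def n(self) -> int:
        return int(self.counts.sum())

    def to_dataframe(self, totals: bool = True) -> pd.DataFrame:
        df = pd.DataFrame(self.counts, index=list(self.row_labels),
                          columns=list(self.col_labels))
        if totals:
            df["Total"] = df.sum(axis=1)
            df.loc["Total"] = df.sum(axis=0)
        return df

    def to_markdown(self) -> str:
        return self.to_dataframe().to_markdown()


def cross_tabulate(labels_a, labels_b, level_names=None) -> ConfusionMatrix:
    """counts[i][j] = units labeled level i by `a` and level j by `b`."""
    a = np.asarray(labels_a)
    b = np.asarray(labels_b)
    if a.shape != b.shape or a.ndim != 1:
        raise ValueError("labelings must be 1-D and of equal length")
    if level_names is not None:
        levels = list(level_names)
    else:
        levels = sorted(set(a.tolist()) | set(b.tolist()))
    index = {lv: i for i, lv in enumerate(levels)}
    counts = np.zeros((len(levels), len(levels)), dtype=np.int64)
    for x, y in zip(a, b):
        counts[index[x], index[y]] += 1
    return ConfusionMatrix(counts=counts, row_labels=tuple(levels),
                           col_labels=tuple(levels))


def cohen_kappa(cm: ConfusionMatrix) -> float:
    """Unweighted Cohen's kappa from a square confusion matrix.

    Returns NaN (the explicit "undefined agreement" marker) when the
    chance agreement p_e equals 1, i.e. all mass sits in a single
    row-column pair and the statistic has no information to correct.
    """
    counts = cm.counts
    if counts.shape[0] != counts.shape[1]:
        raise ValueError("kappa requires a square confusion matrix")
    n = cm.n
    if n < 1:
        raise ValueError("empty confusion matrix")
    p_o = np.trace(counts) / n
    p_e = float(counts.sum(axis=1) @ counts.sum(axis=0)) / (n * n)
    if p_e >= 1.0:
        return math.nan
    return float((p_o - p_e) / (1.0 - p_e))


def adjusted_rand(labels_a, labels_b) -> float:
    """Hubert-Arabie adjusted Rand index between two partitions.

    Invariant to relabeling either side; 1 for identical partitions,
    around 0 for chance-level agreement.
    """
    a = np.asarray(labels_a)
    b = np.asarray(labels_b)
    if a.shape != b.shape or a.ndim != 1:
        raise ValueError("labelings must be 1-D and of equal length")
    if a.size < 2:
        raise ValueError("ARI needs at least two units")
    return float(adjusted_rand_score(a, b))
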