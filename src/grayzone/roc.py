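"""Empirical ROC curve, per-threshold likelihood ratios, and AUC.

Orientation is fixed package-wide: a subject is test-positive when the
marker value is at least the threshold (``x >= c``), matching markers where
higher values indicate the condition. At each candidate threshold ``c``:

    Se(c) = P(X >= c | condition present)       sensitivity
    Sp(c) = P(X <  c | condition absent)        specificity
    LR+(c) = Se / (1 - Sp)                      positive likelihood ratio
    LR-(c) = (1 - Se) / Sp                      negative likelihood ratio

Degenerate thresholds follow fixed conventions rather than raising:
``LR+`` is ``+inf`` when ``Sp == 1`` and ``Se > 0``, and 0 when ``Se == 0``
(the 0/0 case, a threshold above all observations); ``LR-`` is ``+inf``
whenever ``Sp == 0``.

The AUC is the trapezoidal area under the empirical (Se, 1-Sp) step curve,
which is identical to the tie-corrected Mann-Whitney statistic: the
probability that a random diseased subject outscores a random non-diseased
subject, ties counted 1/2.
"""

from __future__ import annotations

import dataclasses
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import stats

from .dataset import MarkerDataset


def threshold_grid(dataset: MarkerDataset) -> np.ndarray:
    """Sorted unique observed values plus one sentinel above the maximum.

    The sentinel (max + 1) realises the "nobody positive" rule; at the
    smallest observed value everybody is positive.
    """
    uniq = np.unique(dataset.values)
    return np.append(uniq, uniq[-1] + 1.0)


@dataclasses.dataclass(frozen=True)
class ThresholdStats:
    """Operating characteristics of the rule ``positive iff x >= threshold``."""

    threshold: float
    se: float
    sp: float
    lr_pos: float
    lr_neg: float


@dataclasses.dataclass(frozen=True)
class RocCurve:
    """Empirical ROC over the observed-value threshold grid."""

    thresholds: np.ndarray  # ascending candidate cutoffs
    se: np.ndarray          # sensitivity at each threshold (non-increasing)
    sp: np.ndarray          # specificity at each threshold (non-decreasing)
    auc: float

    @property
    def lr_pos(self) -> np.ndarray:
        return _lr_pos(self.se, self.sp)

    @property
    def lr_neg(self) -> np.ndarray:
        return _lr_neg(self.se, self.sp)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "threshold": self.thresholds,
                "se": self.se,
                "sp": self.sp,
                "lr_pos": self.lr_pos,
                "lr_neg": self.lr_neg,
            }
        )

    def to_csv(self, path: str | Path) -> None:
        self.to_frame().to_csv(path, index=False)


def _lr_pos(se: np.ndarray, sp: np.ndarray) -> np.ndarray:
    se = np.atleast_1d(np.asarray(se, dtype=float))
    sp = np.atleast_1d(np.asarray(sp, dtype=float))
    fpr = 1.0 - sp
    out = np.empty_like(se)
    with np.errstate(divide="ignore", invalid="ignore"):
        np.divide(se, fpr, out=out, where=fpr > 0)
    out[(fpr == 0) & (se > 0)] = np.inf
    out[(fpr == 0) & (se == 0)] = 0.0  # threshold above all data
    return out


def _lr_neg(se: np.ndarray, sp: np.ndarray) -> np.ndarray:
    se = np.atleast_1d(np.asarray(se, dtype=float))
    sp = np.atleast_1d(np.asarray(sp, dtype=float))
    out = np.empty_like(se)
    with np.errstate(divide="ignore", invalid="ignore"):
        np.divide(1.0 - se, sp, out=out, where=sp > 0)
    out[sp == 0] = np.inf
    return out


def se_sp_at(dataset: MarkerDataset, thresholds: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Vectorised Se/Sp for the ``x >= c`` rule at each threshold."""
    pos = np.sort(dataset.pos_values)
    neg = np.sort(dataset.neg_values)
    thresholds = np.atleast_1d(np.asarray(thresholds, dtype=float))
    # side='left' counts strictly-below; #pos >= c = n_pos - (#pos < c)
    se = 1.0 - np.searchsorted(pos, thresholds, side="left") / pos.size
    sp = np.searchsorted(neg, thresholds, side="left") / neg.size
    return se, sp


def empirical_roc(dataset: MarkerDataset) -> RocCurve:
    """ROC curve over observed thresholds with trapezoidal AUC."""
    dataset.require_both_classes()
    thresholds = threshold_grid(dataset)
    se, sp = se_sp_at(dataset, thresholds)
    # thresholds ascend, so fpr descends from 1 to 0; integrate in fpr order
    fpr = 1.0 - sp
    auc = float(np.trapezoid(se[::-1], fpr[::-1]))
    return RocCurve(thresholds=thresholds, se=se, sp=sp, auc=auc)


def auc_mann_whitney(dataset: MarkerDataset) -> float:
    """AUC as the tie-corrected pair-counting (Mann-Whitney) statistic.

    Proportion of (diseased, non-diseased) pairs where the diseased value is
    larger, ties counted 1/2. Identical to the trapezoidal AUC of
    :func:`empirical_roc`.
    """
    dataset.require_both_classes()
    u = stats.mannwhitneyu(
        dataset.pos_values, dataset.neg_values, alternative="two-sided"
    ).statistic
    return float(u) / (dataset.n_pos * dataset.n_neg)


def stats_at_threshold(dataset: MarkerDataset, c: float) -> ThresholdStats:
    """Se, Sp and likelihood ratios of the rule ``positive iff x >= c``."""
    dataset.require_both_classes()
    se, sp = se_sp_at(dataset, np.asarray([c], dtype=float))
    return ThresholdStats(
        threshold=float(c),
        se=float(se[0]),
        sp=float(sp[0]),
        lr_pos=float(_lr_pos(se, sp)[0]),
        lr_neg=float(_lr_neg(se, sp)[0]),
    )
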