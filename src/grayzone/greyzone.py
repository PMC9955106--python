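"""Likelihood-ratio ("grey zone") trichotomization of a continuous marker.

The grey-zone approach of Coste and Pouchot turns required post-test
probabilities into likelihood-ratio targets through Bayes' theorem in odds
form:

    post-test odds of condition            = pre-test odds   * LR+
    post-test odds of no condition (given
    a negative result)                     = pre-test odds of
                                             no condition    * 1 / LR-

Given a pre-test probability ``p`` (here the sample prevalence of
no-reflow, 110/510) and required predictive values PPV and NPV, the
targets are

    LR+_target = [PPV / (1 - PPV)] / [p / (1 - p)]
    LR-_target = [(1 - p) / p] / [NPV / (1 - NPV)]

A marker value at or above the upper limit (smallest threshold whose
empirical LR+ reaches the LR+ target) is called positive; a value below
the lower limit (largest threshold whose empirical LR- is at or below the
LR- target) is called negative; values in between fall in the gray zone,
where neither call reaches the required predictive value.
"""

from __future__ import annotations

import dataclasses
import json
from pathlib import Path

import numpy as np

from .roc import RocCurve

#: required post-test probability of the condition given a positive call
DEFAULT_PPV_TARGET = 0.6
#: required post-test probability of no condition given a negative call
DEFAULT_NPV_TARGET = 0.95


def _odds(p: float) -> float:
    return p / (1.0 - p)


@dataclasses.dataclass(frozen=True)
class BayesSpec:
    """Pre-test probability plus required post-test predictive values."""

    pretest_prob: float
    ppv_target: float = DEFAULT_PPV_TARGET
    npv_target: float = DEFAULT_NPV_TARGET

    def __post_init__(self) -> None:
        for name in ("pretest_prob", "ppv_target", "npv_target"):
            v = getattr(self, name)
            if not 0.0 < v < 1.0:
                raise ValueError(f"{name} must lie strictly in (0, 1), got {v}")


@dataclasses.dataclass(frozen=True)
class LrTargets:
    """Likelihood-ratio levels that guarantee the requested PPV / NPV."""

    lr_pos_target: float  # minimum LR+ for a positive call
    lr_neg_target: float  # maximum LR- for a negative call


@dataclasses.dataclass(frozen=True)
class GrayZone:
    """An inconclusive interval ``[lower, upper)`` on the marker scale.

    Classification convention: ``x < lower`` is negative, ``x >= upper`` is
    positive, anything in between is gray. ``lower == upper`` is an empty
    zone, i.e. ordinary binary classification at that cutoff.
    """

    lower: float
    upper: float
    method: str  # "grey_zone" | "uncertain_interval"
    lower_attainable: bool = True
    upper_attainable: bool = True
    degenerate: bool = False

    def __post_init__(self) -> None:
        if self.lower > self.upper:
            raise ValueError("zone lower limit must not exceed the upper limit")

    @property
    def width(self) -> float:
        return self.upper - self.lower

    @property
    def is_empty(self) -> bool:
        return self.lower == self.upper

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)

    def to_json(self, path: str | Path, extra: dict | None = None) -> None:
        payload = self.to_dict()
        if extra:
            payload.update(extra)
        Path(path).write_text(json.dumps(payload, indent=2))


def pretest_from_counts(n_pos: int, n_neg: int,
                        ppv_target: float = DEFAULT_PPV_TARGET,
                        npv_target: float = DEFAULT_NPV_TARGET) -> BayesSpec:
    """Pre-test probability from the sample prevalence of the condition."""
    if n_pos <= 0 or n_neg <= 0:
        raise ValueError("both class counts must be positive")
    return BayesSpec(
        pretest_prob=n_pos / (n_pos + n_neg),
        ppv_target=ppv_target,
        npv_target=npv_target,
    )


def lr_targets(spec: BayesSpec) -> LrTargets:
    """Solve the pre-test/post-test odds relation for the LR targets.

    Both targets are returned at full precision; any rounding is a
    presentation concern.
    """
    p = spec.pretest_prob
    lr_pos = _odds(spec.ppv_target) / _odds(p)
    # odds of NO condition given negative = pre-test odds of no condition / LR-
    lr_neg = _odds(1.0 - p) / _odds(spec.npv_target)
    return LrTargets(lr_pos_target=lr_pos, lr_neg_target=lr_neg)


def _isotonic_increasing(x: np.ndarray, y: np.ndarray) -> np.ndarray:
    """Monotone-increasing fit of y over x; infinite entries pass through."""
    from sklearn.isotonic import IsotonicRegression

    out = y.copy()
    finite = np.isfinite(y)
    if finite.sum() >= 2:
        out[finite] = IsotonicRegression(increasing=True).fit_transform(
            x[finite], y[finite]
        )
    return out


def grey_zone_bounds(
    roc: RocCurve, targets: LrTargets, smooth: str = "none"
) -> GrayZone:
    """Scan the threshold grid for the likelihood-ratio zone limits.

    upper = smallest threshold with ``LR+ >= lr_pos_target``;
    lower = largest threshold with ``LR- <= lr_neg_target``.

    By default the scan runs on the raw empirical LR sequences, which keeps
    the PPV/NPV guarantee exact on the fitting data. ``smooth="isotonic"``
    first monotonizes both LR sequences (increasing in the threshold),
    which damps sampling spikes and widens the zone towards its population
    limits, at the price of the exact finite-sample guarantee.

    If a target is attained nowhere, the corresponding limit is pushed to
    the grid extreme (lowest threshold for the lower limit, sentinel for the
    upper) and flagged unattainable. If the scan yields ``lower > upper``
    (possible with non-monotone empirical LR sequences), both limits
    collapse onto the upper threshold and the zone is flagged degenerate.
    """
    grid = np.asarray(roc.thresholds, dtype=float)
    lr_pos = roc.lr_pos
    lr_neg = roc.lr_neg
    if smooth == "isotonic":
        lr_pos = _isotonic_increasing(grid, lr_pos)
        lr_neg = _isotonic_increasing(grid, lr_neg)
    elif smooth != "none":
        raise ValueError("smooth must be 'none' or 'isotonic'")

    pos_ok = np.flatnonzero(lr_pos >= targets.lr_pos_target)
    neg_ok = np.flatnonzero(lr_neg <= targets.lr_neg_target)

    upper_attainable = pos_ok.size > 0
    lower_attainable = neg_ok.size > 0
    upper = float(grid[pos_ok[0]]) if upper_attainable else float(grid[-1])
    lower = float(grid[neg_ok[-1]]) if lower_attainable else float(grid[0])

    degenerate = False
    if lower > upper:
        lower = upper
        degenerate = True
    return GrayZone(
        lower=lower,
        upper=upper,
        method="grey_zone",
        lower_attainable=lower_attainable,
        upper_attainable=upper_attainable,
        degenerate=degenerate,
    )
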