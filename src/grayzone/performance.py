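"""Zone performance: trichotomized classification and its diagnostic yield.

Once a gray zone is fixed, every subject falls into one of three classes —
negative (below the lower limit), gray (inside the zone), positive (at or
above the upper limit). Diagnostic performance is then assessed on the
subjects *outside* the zone: accuracy, sensitivity and specificity of the
binary call, each with an exact Clopper-Pearson 95% confidence interval on
its own denominator. The count and composition of the inside-zone group
quantify the price of abstaining.

Two zones (e.g. the two trichotomization approaches) are compared metric
by metric with an unpaired two-proportion pooled z-test by default; a
paired bootstrap that resamples subjects and recomputes both zones'
metrics is available as a labelled alternative.
"""

from __future__ import annotations

import dataclasses

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.proportion import proportion_confint

from .dataset import MarkerDataset
from .greyzone import GrayZone

#: trichotomized class labels
NEGATIVE, GRAY, POSITIVE = "negative", "gray", "positive"


def trichotomize(dataset: MarkerDataset, zone: GrayZone) -> np.ndarray:
    """Per-subject class: ``x < lower`` negative, ``x >= upper`` positive, else gray."""
    out = np.full(dataset.n, GRAY, dtype=object)
    out[dataset.values < zone.lower] = NEGATIVE
    out[dataset.values >= zone.upper] = POSITIVE
    return out


@dataclasses.dataclass(frozen=True)
class ZoneReport:
    """Inside-zone composition and outside-zone diagnostic performance.

    Metrics whose denominator is empty (no outside-zone subjects of the
    relevant kind) are ``None`` — undefined, never silently 0.
    """

    zone: GrayZone
    width: float
    n_inside: int
    n_inside_pos: int
    n_inside_neg: int
    tp: int
    fp: int
    tn: int
    fn: int
    accuracy: float | None
    sensitivity: float | None
    specificity: float | None
    ci_accuracy: tuple[float, float] | None
    ci_sensitivity: tuple[float, float] | None
    ci_specificity: tuple[float, float] | None

    def metric(self, name: str) -> tuple[float | None, int, int]:
        """(estimate, successes, denominator) for a named metric."""
        if name == "accuracy":
            return self.accuracy, self.tp + self.tn, self.tp + self.tn + self.fp + self.fn
        if name == "sensitivity":
            return self.sensitivity, self.tp, self.tp + self.fn
        if name == "specificity":
            return self.specificity, self.tn, self.tn + self.fp
        raise ValueError(f"unknown metric {name!r}")


def _exact_ci(successes: int, total: int) -> tuple[float, float] | None:
    if total == 0:
        return None
    lo, hi = proportion_confint(successes, total, alpha=0.05, method="beta")
    return float(lo), float(hi)


def zone_report(dataset: MarkerDataset, zone: GrayZone) -> ZoneReport:
    """Count the inside-zone group and score the outside-zone binary calls."""
    calls = trichotomize(dataset, zone)
    labels = dataset.labels
    inside = calls == GRAY
    pos_call = calls == POSITIVE
    neg_call = calls == NEGATIVE

    tp = int(np.sum(pos_call & (labels == 1)))
    fp = int(np.sum(pos_call & (labels == 0)))
    tn = int(np.sum(neg_call & (labels == 0)))
    fn = int(np.sum(neg_call & (labels == 1)))

    n_out = tp + fp + tn + fn
    n_se = tp + fn
    n_sp = tn + fp
    return ZoneReport(
        zone=zone,
        width=zone.width,
        n_inside=int(inside.sum()),
        n_inside_pos=int(np.sum(inside & (labels == 1))),
        n_inside_neg=int(np.sum(inside & (labels == 0))),
        tp=tp, fp=fp, tn=tn, fn=fn,
        accuracy=(tp + tn) / n_out if n_out else None,
        sensitivity=tp / n_se if n_se else None,
        specificity=tn / n_sp if n_sp else None,
        ci_accuracy=_exact_ci(tp + tn, n_out),
        ci_sensitivity=_exact_ci(tp, n_se),
        ci_specificity=_exact_ci(tn, n_sp),
    )


@dataclasses.dataclass(frozen=True)
class ComparisonResult:
    metric: str
    estimate_a: float
    estimate_b: float
    p_value: float
    method: str


def compare_zone_metrics(
    report_a: ZoneReport, report_b: ZoneReport, metric: str
) -> ComparisonResult:
    """Unpaired two-proportion pooled z-test on one outside-zone metric."""
    est_a, k_a, n_a = report_a.metric(metric)
    est_b, k_b, n_b = report_b.metric(metric)
    if est_a is None or est_b is None:
        raise ValueError(f"metric {metric!r} is undefined for one of the reports")
    pooled = (k_a + k_b) / (n_a + n_b)
    var = pooled * (1.0 - pooled) * (1.0 / n_a + 1.0 / n_b)
    if var == 0.0:
        p = 1.0  # both proportions pinned at the same boundary
    else:
        z = (est_a - est_b) / np.sqrt(var)
        p = float(2.0 * stats.norm.sf(abs(z)))
    return ComparisonResult(metric=metric, estimate_a=float(est_a),
                            estimate_b=float(est_b), p_value=p,
                            method="two_proportion_z")


def bootstrap_compare(
    dataset: MarkerDataset,
    zone_a: GrayZone,
    zone_b: GrayZone,
    metric: str,
    n_boot: int = 2000,
    seed: int = 0,
) -> ComparisonResult:
    """Paired bootstrap comparison: resample subjects, rescore both zones.

    The zones themselves stay fixed (they are the object under comparison);
    only the cohort is resampled. Replicates where either metric is
    undefined are dropped. The two-sided p-value is the doubled tail
    proportion of the bootstrap difference distribution around zero.
    """
    base_a, _, _ = zone_report(dataset, zone_a).metric(metric)
    base_b, _, _ = zone_report(dataset, zone_b).metric(metric)
    if base_a is None or base_b is None:
        raise ValueError(f"metric {metric!r} is undefined on the full cohort")

    rng = np.random.default_rng(seed)
    diffs = []
    for _ in range(n_boot):
        idx = rng.integers(0, dataset.n, size=dataset.n)
        boot = MarkerDataset(dataset.values[idx], dataset.labels[idx],
                             dataset.marker_name)
        m_a, _, _ = zone_report(boot, zone_a).metric(metric)
        m_b, _, _ = zone_report(boot, zone_b).metric(metric)
        if m_a is not None and m_b is not None:
            diffs.append(m_a - m_b)
    d = np.asarray(diffs)
    if d.size == 0:
        raise ValueError("no bootstrap replicate had both metrics defined")
    p = 2.0 * min(np.mean(d <= 0.0), np.mean(d >= 0.0))
    return ComparisonResult(metric=metric, estimate_a=float(base_a),
                            estimate_b=float(base_b),
                            p_value=float(min(p, 1.0)),
                            method=f"paired_bootstrap({d.size})")


@dataclasses.dataclass(frozen=True)
class DescriptiveSummary:
    """Per-class median (Q1-Q3) plus the Mann-Whitney two-group comparison."""

    marker_name: str
    median_neg: float
    q1_neg: float
    q3_neg: float
    median_pos: float
    q1_pos: float
    q3_pos: float
    u_statistic: float
    p_value: float


def descriptive_summary(dataset: MarkerDataset) -> DescriptiveSummary:
    """Quartile summaries per class and a two-sided Mann-Whitney U test.

    Quantiles use linear interpolation; the U test uses the normal
    approximation with tie correction and continuity correction. The U
    statistic is oriented to the diseased class (number of pairs, ties 1/2,
    where the diseased value is larger).
    """
    dataset.require_both_classes()
    pos, neg = dataset.pos_values, dataset.neg_values
    q_neg = np.quantile(neg, [0.25, 0.5, 0.75])
    q_pos = np.quantile(pos, [0.25, 0.5, 0.75])
    res = stats.mannwhitneyu(pos, neg, alternative="two-sided",
                             method="asymptotic")
    return DescriptiveSummary(
        marker_name=dataset.marker_name,
        median_neg=float(q_neg[1]), q1_neg=float(q_neg[0]), q3_neg=float(q_neg[2]),
        median_pos=float(q_pos[1]), q1_pos=float(q_pos[0]), q3_pos=float(q_pos[2]),
        u_statistic=float(res.statistic),
        p_value=float(res.pvalue),
    )


def reports_to_table(reports: dict[str, ZoneReport]) -> pd.DataFrame:
    """Zone-comparison table, one row per approach."""
    rows = []
    for name, r in reports.items():
        def ci(pair):  # noqa: B023 — evaluated immediately
            return (np.nan, np.nan) if pair is None else pair
        acc_ci, se_ci, sp_ci = ci(r.ci_accuracy), ci(r.ci_sensitivity), ci(r.ci_specificity)
        rows.append({
            "approach": name,
            "lower": r.zone.lower,
            "upper": r.zone.upper,
            "width": r.width,
            "n_inside": r.n_inside,
            "n_inside_no_reflow": r.n_inside_pos,
            "n_inside_normal": r.n_inside_neg,
            "accuracy": np.nan if r.accuracy is None else r.accuracy,
            "acc_lo": acc_ci[0], "acc_hi": acc_ci[1],
            "sensitivity": np.nan if r.sensitivity is None else r.sensitivity,
            "se_lo": se_ci[0], "se_hi": se_ci[1],
            "specificity": np.nan if r.specificity is None else r.specificity,
            "sp_lo": sp_ci[0], "sp_hi": sp_ci[1],
        })
    return pd.DataFrame(rows)
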