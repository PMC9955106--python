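"""Uncertain-interval trichotomization: the widest near-chance interval.

Where the grey-zone approach works outward from required post-test
probabilities, the uncertain-interval approach looks directly for the
region where the test is uninformative: an interval around the crossing
point of the two class densities within which the marker discriminates no
better than (almost) chance.

Concretely, with the density-intersection point as a fixed inner cutoff,
the within-interval sensitivity and specificity

    ui_se = P(x >= cut | condition,    lower <= x < upper)
    ui_sp = P(x <  cut | no condition, lower <= x < upper)

must both stay at or below a pre-selected ceiling (0.55 by default, i.e.
at most marginally better than coin-flipping). Among all feasible
intervals the widest in subject count is returned: maximise the number of
subjects inside, ties broken by smaller marker-scale width, then by the
smaller lower limit. The search is exhaustive over the observed-value
threshold grid, which keeps it verifiable against a brute-force oracle.
"""

from __future__ import annotations

import dataclasses

import numpy as np
from scipy import optimize, stats

from .dataset import MarkerDataset
from .greyzone import GrayZone
from .roc import threshold_grid

#: default within-interval sensitivity/specificity ceiling
DEFAULT_UI_TARGET = 0.55


@dataclasses.dataclass(frozen=True)
class UiSpec:
    """Ceilings for within-interval sensitivity and specificity.

    Values at or below 0.5 would demand the interval perform at or below
    chance, which the density-crossing cutoff rules out by construction,
    so both ceilings must lie in (0.5, 1).
    """

    se_target: float = DEFAULT_UI_TARGET
    sp_target: float = DEFAULT_UI_TARGET

    def __post_init__(self) -> None:
        for name in ("se_target", "sp_target"):
            v = getattr(self, name)
            if not 0.5 < v < 1.0:
                raise ValueError(f"{name} must lie in (0.5, 1), got {v}")


@dataclasses.dataclass(frozen=True)
class IntersectionEstimate:
    """Estimated crossing point of the two class densities.

    ``fell_back`` marks the degenerate case where no usable crossing lies
    between the class medians (e.g. fully separated groups); the midpoint
    of the class medians is returned instead.
    """

    point: float
    fell_back: bool = False

    def __float__(self) -> float:
        return self.point


@dataclasses.dataclass(frozen=True)
class UiSeSp:
    """Within-interval operating characteristics at a fixed inner cutoff."""

    ui_se: float
    ui_sp: float
    n_inside_pos: int
    n_inside_neg: int

    @property
    def se_defined(self) -> bool:
        return self.n_inside_pos > 0

    @property
    def sp_defined(self) -> bool:
        return self.n_inside_neg > 0


@dataclasses.dataclass(frozen=True)
class UiDiagnostics:
    """How the returned uncertain interval behaves on the fitting data."""

    intersection: float
    intersection_fell_back: bool
    ui_se: float
    ui_sp: float
    n_inside: int
    feasible: bool  # False when no non-degenerate feasible interval existed


def intersection_point(dataset: MarkerDataset) -> IntersectionEstimate:
    """Crossing point of Gaussian KDEs of the two classes.

    For positive-valued markers the KDEs are fitted on the natural-log
    scale (Silverman bandwidth); a crossing of the log-scale densities is a
    crossing of the original-scale densities, since the Jacobian 1/x is
    common to both. The search runs between the two class medians; with
    several crossings the one closest to the midpoint of the medians wins.
    A crossing whose density is negligible next to the class density peaks
    (separated groups) is treated as absent; the midpoint of the class
    medians is then returned, flagged.
    """
    dataset.require_both_classes()
    pos, neg = dataset.pos_values, dataset.neg_values
    if np.unique(pos).size < 2 or np.unique(neg).size < 2:
        raise ValueError("each class needs at least 2 distinct values for a KDE")

    use_log = bool(np.all(dataset.values > 0))
    t = np.log if use_log else np.asarray
    back = np.exp if use_log else float
    y_pos, y_neg = t(pos), t(neg)

    kde_pos = stats.gaussian_kde(y_pos, bw_method="silverman")
    kde_neg = stats.gaussian_kde(y_neg, bw_method="silverman")

    m_neg, m_pos = float(np.median(y_neg)), float(np.median(y_pos))
    lo, hi = sorted((m_neg, m_pos))
    midpoint_raw = (float(np.median(neg)) + float(np.median(pos))) / 2.0
    if lo == hi:
        return IntersectionEstimate(point=midpoint_raw, fell_back=True)

    grid = np.linspace(lo, hi, 512)
    diff = kde_pos(grid) - kde_neg(grid)
    sign = np.sign(diff)
    flips = np.flatnonzero(sign[:-1] * sign[1:] < 0)

    roots = [grid[i] for i in np.flatnonzero(sign == 0)]
    for i in flips:
        roots.append(
            optimize.brentq(lambda y: kde_pos(y)[0] - kde_neg(y)[0],
                            grid[i], grid[i + 1])
        )
    if not roots:
        return IntersectionEstimate(point=midpoint_raw, fell_back=True)

    mid = (lo + hi) / 2.0
    root = min(roots, key=lambda r: abs(r - mid))
    # a crossing buried in a density valley between separated clusters is
    # no real overlap — fall back rather than report a spurious point
    peak = max(float(kde_pos(y_pos).max()), float(kde_neg(y_neg).max()))
    if float(kde_pos(root)[0]) < 1e-3 * peak:
        return IntersectionEstimate(point=midpoint_raw, fell_back=True)
    return IntersectionEstimate(point=float(back(root)), fell_back=False)


def ui_se_sp(dataset: MarkerDataset, lower: float, upper: float, cut: float) -> UiSeSp:
    """Within-interval Se/Sp for ``[lower, upper)`` at inner cutoff ``cut``.

    An empty class denominator yields 0 for that proportion; the
    ``se_defined`` / ``sp_defined`` properties flag it.
    """
    if not lower <= cut <= upper:
        raise ValueError("cut must lie within [lower, upper]")
    pos, neg = dataset.pos_values, dataset.neg_values
    pos_in = pos[(pos >= lower) & (pos < upper)]
    neg_in = neg[(neg >= lower) & (neg < upper)]
    se = float(np.mean(pos_in >= cut)) if pos_in.size else 0.0
    sp = float(np.mean(neg_in < cut)) if neg_in.size else 0.0
    return UiSeSp(ui_se=se, ui_sp=sp,
                  n_inside_pos=int(pos_in.size), n_inside_neg=int(neg_in.size))


def uncertain_interval_bounds(
    dataset: MarkerDataset, spec: UiSpec = UiSpec()
) -> tuple[GrayZone, UiDiagnostics]:
    """Exhaustive search for the largest near-chance interval.

    Candidate limits come from the observed-value grid (plus the sentinel
    above the maximum); a pair ``(l, u)`` with ``l <= intersection <= u``
    is feasible when both classes are represented inside ``[l, u)`` and the
    within-interval Se/Sp at the intersection cutoff respect the ceilings.
    Returns the feasible pair with the most subjects inside (ties: smaller
    width, then smaller lower limit). With no feasible pair the zone
    collapses onto the grid point nearest above the intersection.
    """
    dataset.require_both_classes()
    ix = intersection_point(dataset)
    cut = ix.point

    grid = threshold_grid(dataset)
    lowers = grid[grid <= cut]
    uppers = grid[grid >= cut]
    if lowers.size == 0 or uppers.size == 0:
        # intersection outside the observed range (fallback midpoint only)
        snap = float(grid[min(np.searchsorted(grid, cut), grid.size - 1)])
        zone = GrayZone(lower=snap, upper=snap, method="uncertain_interval",
                        degenerate=True)
        return zone, UiDiagnostics(cut, ix.fell_back, 0.0, 0.0, 0, feasible=False)

    pos = np.sort(dataset.pos_values)
    neg = np.sort(dataset.neg_values)

    def count_below(sorted_vals: np.ndarray, x: np.ndarray | float) -> np.ndarray:
        return np.searchsorted(sorted_vals, x, side="left")

    pos_lo = count_below(pos, lowers)[:, None]   # #pos < l
    pos_hi = count_below(pos, uppers)[None, :]   # #pos < u
    neg_lo = count_below(neg, lowers)[:, None]
    neg_hi = count_below(neg, uppers)[None, :]
    pos_cut = int(count_below(pos, cut))
    neg_cut = int(count_below(neg, cut))

    n_pos_in = pos_hi - pos_lo                   # pos inside [l, u)
    n_neg_in = neg_hi - neg_lo
    pos_ge_cut = pos_hi - pos_cut                # pos inside with x >= cut
    neg_lt_cut = neg_cut - neg_lo                # neg inside with x < cut

    with np.errstate(invalid="ignore", divide="ignore"):
        se = np.where(n_pos_in > 0, pos_ge_cut / np.maximum(n_pos_in, 1), 0.0)
        sp = np.where(n_neg_in > 0, neg_lt_cut / np.maximum(n_neg_in, 1), 0.0)

    feasible = (
        (n_pos_in > 0)
        & (n_neg_in > 0)
        & (se <= spec.se_target)
        & (sp <= spec.sp_target)
    )

    if not feasible.any():
        snap = float(grid[min(np.searchsorted(grid, cut), grid.size - 1)])
        zone = GrayZone(lower=snap, upper=snap, method="uncertain_interval",
                        degenerate=True)
        return zone, UiDiagnostics(cut, ix.fell_back, 0.0, 0.0, 0, feasible=False)

    n_inside = n_pos_in + n_neg_in
    width = uppers[None, :] - lowers[:, None]
    # lexicographic objective: max n_inside, then min width, then min lower
    li, ui = np.nonzero(feasible)
    order = np.lexsort((lowers[li], width[li, ui], -n_inside[li, ui]))
    best_l, best_u = li[order[0]], ui[order[0]]

    zone = GrayZone(
        lower=float(lowers[best_l]),
        upper=float(uppers[best_u]),
        method="uncertain_interval",
    )
    diag = UiDiagnostics(
        intersection=cut,
        intersection_fell_back=ix.fell_back,
        ui_se=float(se[best_l, best_u]),
        ui_sp=float(sp[best_l, best_u]),
        n_inside=int(n_inside[best_l, best_u]),
        feasible=True,
    )
    return zone, diag
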