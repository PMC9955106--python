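"""Independent brute-force oracles used only by the tests.

Everything here is deliberately naive pure Python (explicit loops over
pairs and thresholds) so that it shares no code path — and no vectorised
shortcut — with the package implementation it checks.
"""

from __future__ import annotations

import math


def pair_counting_auc(pos: list[float], neg: list[float]) -> float:
    """Proportion of (diseased, non-diseased) pairs won by the diseased
    value, ties counted 1/2."""
    wins = 0.0
    for p in pos:
        for q in neg:
            if p > q:
                wins += 1.0
            elif p == q:
                wins += 0.5
    return wins / (len(pos) * len(neg))


def naive_se_sp(pos: list[float], neg: list[float], c: float) -> tuple[float, float]:
    se = sum(1 for x in pos if x >= c) / len(pos)
    sp = sum(1 for x in neg if x < c) / len(neg)
    return se, sp


def naive_lr_pos(se: float, sp: float) -> float:
    if sp == 1.0:
        return math.inf if se > 0 else 0.0
    return se / (1.0 - sp)


def naive_lr_neg(se: float, sp: float) -> float:
    if sp == 0.0:
        return math.inf
    return (1.0 - se) / sp


def grid_of(values: list[float]) -> list[float]:
    uniq = sorted(set(values))
    return uniq + [uniq[-1] + 1.0]


def grey_zone_oracle(
    pos: list[float],
    neg: list[float],
    lr_pos_target: float,
    lr_neg_target: float,
) -> dict:
    """First-attainment scan over an explicitly enumerated LR table."""
    grid = grid_of(pos + neg)
    upper = None
    for c in grid:  # smallest threshold attaining the LR+ target
        se, sp = naive_se_sp(pos, neg, c)
        if naive_lr_pos(se, sp) >= lr_pos_target:
            upper = c
            break
    lower = None
    for c in reversed(grid):  # largest threshold attaining the LR- target
        se, sp = naive_se_sp(pos, neg, c)
        if naive_lr_neg(se, sp) <= lr_neg_target:
            lower = c
            break
    upper_attainable = upper is not None
    lower_attainable = lower is not None
    if upper is None:
        upper = grid[-1]
    if lower is None:
        lower = grid[0]
    degenerate = lower > upper
    if degenerate:
        lower = upper
    return {
        "lower": lower,
        "upper": upper,
        "lower_attainable": lower_attainable,
        "upper_attainable": upper_attainable,
        "degenerate": degenerate,
    }


def uncertain_interval_oracle(
    pos: list[float],
    neg: list[float],
    cut: float,
    se_target: float,
    sp_target: float,
) -> tuple[float, float] | None:
    """Exhaustive search over all (lower, upper) grid pairs straddling cut.

    Feasible: both classes inside [lower, upper) and within-interval Se/Sp
    at the cut at or below the ceilings. Objective: most subjects inside,
    ties by smaller width, then smaller lower. None when nothing feasible.
    """
    grid = grid_of(pos + neg)
    best = None
    best_key = None
    for lo in grid:
        if lo > cut:
            continue
        for up in grid:
            if up < cut or up < lo:
                continue
            pos_in = [x for x in pos if lo <= x < up]
            neg_in = [x for x in neg if lo <= x < up]
            if not pos_in or not neg_in:
                continue
            ui_se = sum(1 for x in pos_in if x >= cut) / len(pos_in)
            ui_sp = sum(1 for x in neg_in if x < cut) / len(neg_in)
            if ui_se > se_target or ui_sp > sp_target:
                continue
            n_inside = len(pos_in) + len(neg_in)
            key = (-n_inside, up - lo, lo)
            if best_key is None or key < best_key:
                best_key = key
                best = (lo, up)
    return best


def naive_confusion(
    pos: list[float], neg: list[float], lower: float, upper: float
) -> dict:
    """Trichotomized confusion counts by a literal per-subject loop."""
    out = {"tp": 0, "fp": 0, "tn": 0, "fn": 0, "gray_pos": 0, "gray_neg": 0}
    for x in pos:
        if x >= upper:
            out["tp"] += 1
        elif x < lower:
            out["fn"] += 1
        else:
            out["gray_pos"] += 1
    for x in neg:
        if x >= upper:
            out["fp"] += 1
        elif x < lower:
            out["tn"] += 1
        else:
            out["gray_neg"] += 1
    return out
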