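"""Risk-group stratification and contingency-table statistics.

Covers tertile-adapted cut-points on a discrete score distribution, the
per-group PAR / non-PAR contingency table, odds ratios against the low-risk
reference group (Woolf intervals by default), two-group classification
metrics (sensitivity, specificity, PPV, NPV), and observed versus mean
predicted risk per group.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.stats import norm

from .score_model import RISK_GROUPS, RiskThresholds
from .validation_stats import LogisticFit

__all__ = [
    "StrataTable",
    "GroupComparison",
    "tertile_thresholds",
    "build_strata_table",
    "group_odds_ratios",
    "pairwise_classification_metrics",
    "observed_vs_predicted",
]


@dataclass(frozen=True)
class StrataTable:
    """PAR / non-PAR counts per risk group."""

    counts: dict[str, tuple[int, int]]   # group -> (n_par, n_nonpar)

    def __post_init__(self) -> None:
        for g in RISK_GROUPS:
            if g not in self.counts:
                raise ValueError(f"missing group {g!r}")
            a, b = self.counts[g]
            if a < 0 or b < 0:
                raise ValueError(f"negative count in group {g!r}")

    @property
    def total(self) -> int:
        return sum(a + b for a, b in self.counts.values())

    def group_n(self, group: str) -> int:
        a, b = self.counts[group]
        return a + b


@dataclass(frozen=True)
class GroupComparison:
    """One risk group compared against the low-risk reference."""

    label: str
    odds_ratio: float
    ci_low: float
    ci_high: float
    sensitivity: float
    specificity: float
    ppv: float
    npv: float


def tertile_thresholds(scores) -> RiskThresholds:
    """Integer cut pair splitting the cohort into near-equal thirds.

    On a discrete score distribution exact tertiles rarely exist; the cut
    pair ``(c1, c2)`` is chosen by exhaustive search over attained score
    values to minimise the maximum deviation of the three group sizes from
    n/3, breaking ties towards the smaller ``c1`` and then the smaller
    ``c2``.  Deterministic for a fixed input.
    """
    scores = np.asarray(scores)
    if len(scores) < 3:
        raise ValueError("tertiles require at least 3 subjects")
    values, counts = np.unique(scores, return_counts=True)
    if len(values) < 3:
        raise ValueError(
            f"tertiles undefined: only {len(values)} distinct score values"
        )
    n = len(scores)
    target = n / 3.0
    cum = np.cumsum(counts)

    best = None
    for i, c1 in enumerate(values):
        low = cum[i - 1] if i > 0 else 0            # scores < c1
        for j in range(i, len(values)):
            c2 = values[j]
            med = cum[j] - low                       # c1 <= s <= c2
            high = n - cum[j]                        # s > c2
            cost = max(abs(low - target), abs(med - target), abs(high - target))
            key = (cost, c1, c2)
            if best is None or key < best[0]:
                best = (key, RiskThresholds(int(c1), int(c2)))
    return best[1]


def build_strata_table(groups, y) -> StrataTable:
    """Cross-tabulate risk group against outcome; empty groups keep zero rows."""
    groups = np.asarray(groups)
    y = np.asarray(y).astype(int)
    if len(groups) != len(y):
        raise ValueError("groups and outcomes must be aligned")
    counts = {}
    for g in RISK_GROUPS:
        mask = groups == g
        n_par = int(y[mask].sum())
        counts[g] = (n_par, int(mask.sum()) - n_par)
    return StrataTable(counts)


def _cells(table: StrataTable, comparison: str) -> tuple[int, int, int, int]:
    a, b = table.counts[comparison]   # PAR / non-PAR in the comparison group
    c, d = table.counts["low"]        # PAR / non-PAR in the reference group
    return a, b, c, d


def group_odds_ratios(
    table: StrataTable, *, continuity_correction: bool = False
) -> dict[str, tuple[float, float, float]]:
    """Odds ratio of each non-reference group versus low risk.

    OR = (a d)/(b c) on the 2x2 restricted to the two groups, with a Woolf
    interval exp(ln OR +/- 1.96 sqrt(1/a + 1/b + 1/c + 1/d)).  A zero cell is
    an error unless ``continuity_correction`` adds 0.5 to all four cells.
    """
    c_ref, d_ref = table.counts["low"]
    if (c_ref == 0 or d_ref == 0) and not continuity_correction:
        raise ValueError(
            "reference (low) group needs at least one PAR and one non-PAR; "
            "enable continuity_correction to add 0.5 to all four cells"
        )
    out = {}
    for group in ("medium", "high"):
        a, b, c, d = _cells(table, group)
        if min(a, b, c, d) == 0 and not continuity_correction:
            raise ValueError(
                f"zero cell in {group}-vs-low table; enable "
                "continuity_correction to add 0.5 to all four cells"
            )
        if continuity_correction:
            a, b, c, d = a + 0.5, b + 0.5, c + 0.5, d + 0.5
        odds_ratio = (a * d) / (b * c)
        se = np.sqrt(1.0 / a + 1.0 / b + 1.0 / c + 1.0 / d)
        zcrit = norm.ppf(0.975)
        lo = float(odds_ratio * np.exp(-zcrit * se))
        hi = float(odds_ratio * np.exp(zcrit * se))
        out[f"{group}_vs_low"] = (float(odds_ratio), lo, hi)
    return out


def pairwise_classification_metrics(
    table: StrataTable, comparison: str
) -> dict[str, float]:
    """Sensitivity, specificity, PPV and NPV of the two-group restriction.

    Subjects outside {low, comparison} are dropped; membership of the
    comparison group is the positive test, PAR the condition.  Returned as
    proportions in [0, 1].
    """
    if comparison not in ("medium", "high"):
        raise ValueError(f"comparison must be 'medium' or 'high', got {comparison!r}")
    a, b, c, d = _cells(table, comparison)
    if table.group_n(comparison) == 0 or table.group_n("low") == 0:
        raise ValueError("both groups must be non-empty")
    if a + c == 0:
        raise ValueError("no PAR cases in the two groups: sensitivity undefined")
    return {
        "sensitivity": a / (a + c),
        "specificity": d / (b + d),
        "ppv": a / (a + b),
        "npv": d / (c + d),
    }


def observed_vs_predicted(
    table: StrataTable,
    groups,
    scores,
    fit: LogisticFit | None = None,
    external_coefficients: tuple[float, float] | None = None,
) -> pd.DataFrame:
    """Observed event proportion and mean predicted risk per risk group.

    Predicted risks are per-subject probabilities from either the internal
    univariable fit on the raw score or an external ``(intercept, slope)``
    pair on the log-odds scale (e.g. the development study's published
    scoring), averaged within each group.  Empty groups are omitted with a
    warning.
    """
    import warnings

    groups = np.asarray(groups)
    scores = np.asarray(scores, dtype=float)
    if external_coefficients is not None:
        alpha, beta = external_coefficients
        probs = 1.0 / (1.0 + np.exp(-(alpha + beta * scores)))
    elif fit is not None:
        probs = fit.predict(scores[:, None])
    else:
        raise ValueError("need an internal fit or external coefficients")

    rows = []
    for g in RISK_GROUPS:
        n_par, n_non = table.counts[g]
        n = n_par + n_non
        if n == 0:
            warnings.warn(f"risk group {g!r} is empty; row omitted")
            continue
        mask = groups == g
        rows.append(
            {
                "group": g,
                "n": n,
                "observed": n_par / n,
                "predicted": float(probs[mask].mean()),
            }
        )
    return pd.DataFrame(rows)
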