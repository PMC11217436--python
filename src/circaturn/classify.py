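"""Rhythmicity classification and overlap/amplitude statistics.

Each protein with heavy detection yields two p-values per detector: one
for its synthesis series, one for its total-abundance series. At a
threshold alpha (strict inequality, p < alpha) these define four
categories — rhythmic in both, in synthesis only, in abundance only, or
neither. Classification is computed separately per detector (umbrella
and ANOVA), never mixed. The association between the two rhythm calls
is tested with Fisher's exact test, and the amplitude (peak/trough fold
change) distributions of the two rhythmic sets compared with a
Mann–Whitney test.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "CATEGORIES",
    "classify_rhythmicity",
    "category_counts",
    "category_percentages",
    "overlap_fisher",
    "compare_fold_change_distributions",
    "phase_histogram",
]

CATEGORIES = ("both", "synthesis_only", "abundance_only", "neither")


def classify_rhythmicity(p_synth: float, p_abund: float, alpha: float = 0.05) -> str:
    """Four-way category from the two rhythm p-values at threshold alpha.

    Strict inequality: a p-value exactly equal to alpha counts as not
    rhythmic. Missing p-values are a caller error (proteins without
    heavy detection are excluded upstream).
    """
    if not (np.isfinite(p_synth) and np.isfinite(p_abund)):
        raise ValueError("classification requires finite p-values for both metrics")
    s, a = p_synth < alpha, p_abund < alpha
    if s and a:
        return "both"
    if s:
        return "synthesis_only"
    if a:
        return "abundance_only"
    return "neither"


def category_counts(categories) -> dict[str, int]:
    ser = pd.Series(list(categories))
    return {c: int((ser == c).sum()) for c in CATEGORIES}


def category_percentages(categories) -> dict[str, float]:
    """Category percentages over classified proteins; sums to 100."""
    counts = category_counts(categories)
    n = sum(counts.values())
    if n == 0:
        return {c: float("nan") for c in CATEGORIES}
    return {c: 100.0 * v / n for c, v in counts.items()}


def overlap_fisher(categories) -> tuple[np.ndarray, float]:
    """2x2 synthesis-rhythmic x abundance-rhythmic table and two-sided Fisher p.

    The two-sided p sums the probabilities of all tables (at fixed
    margins) no more probable than the observed one — the standard
    exact convention. A degenerate margin (all-zero row or column)
    returns p = 1.
    """
    counts = category_counts(categories)
    table = np.array(
        [
            [counts["both"], counts["synthesis_only"]],
            [counts["abundance_only"], counts["neither"]],
        ]
    )
    if table.sum(axis=0).min() == 0 or table.sum(axis=1).min() == 0:
        return table, 1.0
    _, p = stats.fisher_exact(table, alternative="two-sided")
    return table, float(p)


def compare_fold_change_distributions(
    fc_synth, fc_abund, exact_max_n: int = 20
) -> float:
    """Two-sided Mann–Whitney p comparing two fold-change distributions.

    The exact null distribution is used when the combined sample size is
    at most ``exact_max_n`` and there are no ties; otherwise the normal
    approximation with tie and continuity correction applies.
    """
    x = np.asarray(list(fc_synth), dtype=float)
    y = np.asarray(list(fc_abund), dtype=float)
    if x.size == 0 or y.size == 0:
        raise ValueError("both fold-change samples must be non-empty")
    pooled = np.concatenate([x, y])
    has_ties = np.unique(pooled).size < pooled.size
    method = "exact" if (pooled.size <= exact_max_n and not has_ties) else "asymptotic"
    res = stats.mannwhitneyu(x, y, alternative="two-sided", method=method, use_continuity=True)
    return float(min(res.pvalue, 1.0))


def phase_histogram(phases_h, period_h: float, n_bins: int) -> tuple[np.ndarray, np.ndarray]:
    """Counts of phases per equal-width circular bin over [0, period).

    Bins are half-open [lo, hi); phases outside [0, period) are wrapped
    modulo the period with a warning. Returns (counts, bin_edges).
    """
    phases = np.asarray(list(phases_h), dtype=float)
    if phases.size and (phases.min() < 0 or phases.max() >= period_h):
        warnings.warn("phases outside [0, period) wrapped modulo period", RuntimeWarning, stacklevel=2)
        phases = np.mod(phases, period_h)
    edges = np.linspace(0.0, period_h, n_bins + 1)
    counts, _ = np.histogram(phases, bins=edges)
    return counts, edges
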