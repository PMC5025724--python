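"""Region-of-interest electrode-count statistics and behavioral comparison.

For each (condition, hemisphere, roi, band, window) the number of electrodes
with a significant ERD (low bands) or ERS (gamma bands) is expressed as a
fraction of that region's electrode total.  Fractions are compared with 2×2
count tests — Pearson chi-square when every expected count exceeds 5,
otherwise Fisher's exact test — uncorrected at P < 0.05, for
three contrast families: task vs task, left vs right hemisphere, and right
SPL vs right IPL.  Behavioral response times / hit rates are compared with a
two-sided Wilcoxon rank-sum test.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
import scipy.stats

from .atlas import ElectrodeAtlas
from .bands import BAND_NAMES, ERD_BANDS
from .aggregate import WINDOW_ONSETS_MS

FRACTION_COLUMNS = [
    "condition", "hemisphere", "roi", "band", "window_ms",
    "effect", "n_significant", "n_total", "fraction",
]


@dataclass
class ContrastResult:
    """A 2×2 electrode-count comparison between two groups."""

    contrast: str  # 'task' | 'hemisphere' | 'SPL_vs_IPL' | free-form
    group_a: str
    group_b: str
    table: np.ndarray  # [[sig_a, nonsig_a], [sig_b, nonsig_b]]
    test: str  # 'chi-square' | 'fisher'
    p_value: float
    alpha: float = 0.05

    @property
    def significant(self) -> bool:
        return bool(self.p_value < self.alpha)


def count_fractions(
    labels: np.ndarray, atlas: ElectrodeAtlas, condition: str
) -> pd.DataFrame:
    """Tally significant electrodes per ROI × band × window.

    ``labels`` is (n_electrodes, 5, 8) of 'ERD'/'ERS'/'none' from
    :func:`~ersp_attn.aggregate.classify_electrode`, rows aligned with the
    atlas.  The counted effect per band follows the quantification rule:
    ERD in theta/alpha/beta, ERS in the gamma bands.
    """
    labels = np.asarray(labels)
    if labels.shape != (atlas.n_channels, len(BAND_NAMES), len(WINDOW_ONSETS_MS)):
        raise ValueError(
            f"labels must be (n_electrodes={atlas.n_channels}, "
            f"{len(BAND_NAMES)}, {len(WINDOW_ONSETS_MS)})"
        )
    rows = []
    for hemi, roi in sorted(atlas.group_counts().index):
        idx = atlas.channels_in(hemi, roi)
        for bi, band in enumerate(BAND_NAMES):
            effect = "ERD" if band in ERD_BANDS else "ERS"
            for wi, onset in enumerate(WINDOW_ONSETS_MS):
                n_sig = int(np.sum(labels[idx, bi, wi] == effect))
                rows.append(
                    {
                        "condition": condition,
                        "hemisphere": hemi,
                        "roi": roi,
                        "band": band,
                        "window_ms": f"{onset:.0f}-{onset + 200:.0f}",
                        "effect": effect,
                        "n_significant": n_sig,
                        "n_total": len(idx),
                        "fraction": n_sig / len(idx),
                    }
                )
    return pd.DataFrame(rows, columns=FRACTION_COLUMNS)


def contrast(
    sig_a: int, total_a: int, sig_b: int, total_b: int,
    contrast_type: str = "task", group_a: str = "A", group_b: str = "B",
    alpha: float = 0.05, method: str = "auto",
) -> ContrastResult:
    """Compare two significant-electrode fractions with a 2×2 count test.

    ``method='auto'`` picks Pearson chi-square (no continuity correction)
    when every expected count exceeds 5, otherwise Fisher's exact test, both
    two-sided.  The uncorrected chi-square keeps the null rejection rate at
    the nominal level for the moderate electrode counts typical here (the
    Yates correction over-deflates it); ``method`` may force either test.
    """
    if total_a <= 0 or total_b <= 0:
        raise ValueError("both groups must contain electrodes")
    if not 0 <= sig_a <= total_a or not 0 <= sig_b <= total_b:
        raise ValueError("significant counts must be within group totals")
    if method not in ("auto", "chi-square", "fisher"):
        raise ValueError("method must be auto|chi-square|fisher")
    table = np.array([[sig_a, total_a - sig_a], [sig_b, total_b - sig_b]])
    expected = scipy.stats.contingency.expected_freq(table)
    if method == "auto":
        method = "chi-square" if (expected > 5).all() else "fisher"
    if method == "chi-square":
        test = "chi-square"
        _, p, _, _ = scipy.stats.chi2_contingency(table, correction=False)
    else:
        test = "fisher"
        _, p = scipy.stats.fisher_exact(table, alternative="two-sided")
    return ContrastResult(
        contrast=contrast_type, group_a=group_a, group_b=group_b,
        table=table, test=test, p_value=float(p), alpha=alpha,
    )


def _row(table: pd.DataFrame, **filters) -> pd.Series:
    sel = table
    for col, val in filters.items():
        sel = sel[sel[col] == val]
    if len(sel) != 1:
        raise ValueError(f"expected exactly one fraction row for {filters}, got {len(sel)}")
    return sel.iloc[0]


def task_contrast(
    fractions: pd.DataFrame, condition_a: str, condition_b: str,
    hemisphere: str, roi: str, band: str, window_ms: str,
) -> ContrastResult:
    """Fraction comparison between the two attention conditions in one cell."""
    a = _row(fractions, condition=condition_a, hemisphere=hemisphere, roi=roi,
             band=band, window_ms=window_ms)
    b = _row(fractions, condition=condition_b, hemisphere=hemisphere, roi=roi,
             band=band, window_ms=window_ms)
    return contrast(
        a["n_significant"], a["n_total"], b["n_significant"], b["n_total"],
        contrast_type="task", group_a=condition_a, group_b=condition_b,
    )


def hemisphere_contrast(
    fractions: pd.DataFrame, condition: str, roi: str, band: str, window_ms: str
) -> ContrastResult:
    """Left vs right fraction comparison for one ROI within one condition."""
    left = _row(fractions, condition=condition, hemisphere="L", roi=roi,
                band=band, window_ms=window_ms)
    right = _row(fractions, condition=condition, hemisphere="R", roi=roi,
                 band=band, window_ms=window_ms)
    return contrast(
        left["n_significant"], left["n_total"],
        right["n_significant"], right["n_total"],
        contrast_type="hemisphere", group_a=f"L {roi}", group_b=f"R {roi}",
    )


def spl_ipl_contrast(
    fractions: pd.DataFrame, condition: str, band: str, window_ms: str
) -> ContrastResult:
    """Right superior vs inferior parietal fraction comparison."""
    spl = _row(fractions, condition=condition, hemisphere="R",
               roi="superior_parietal", band=band, window_ms=window_ms)
    ipl = _row(fractions, condition=condition, hemisphere="R",
               roi="inferior_parietal", band=band, window_ms=window_ms)
    return contrast(
        spl["n_significant"], spl["n_total"], ipl["n_significant"], ipl["n_total"],
        contrast_type="SPL_vs_IPL", group_a="R SPL", group_b="R IPL",
    )


def compare_behavior(values_a, values_b) -> float:
    """Two-sided Wilcoxon rank-sum p-value for behavior (RT or hit rate).

    Exact rank permutation null for small tie-free samples (n ≤ 25 per
    group), normal approximation with tie correction otherwise.  Identical
    constant data in both groups yields p = 1 with a warning.
    """
    a = np.asarray(values_a, float)
    b = np.asarray(values_b, float)
    if len(a) < 3 or len(b) < 3:
        raise ValueError("need at least 3 observations per group")
    pooled = np.concatenate([a, b])
    if np.all(pooled == pooled[0]):
        warnings.warn("all values identical across both groups", RuntimeWarning,
                      stacklevel=2)
        return 1.0
    has_ties = len(np.unique(pooled)) < len(pooled)
    method = "exact" if (max(len(a), len(b)) <= 25 and not has_ties) else "asymptotic"
    res = scipy.stats.mannwhitneyu(a, b, alternative="two-sided", method=method)
    return float(res.pvalue)
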