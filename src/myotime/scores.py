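"""Composite gene-set scores, trend tests, ORA and the qPCR fold change.

A composite score is the per-sample mean of z-scored member-gene expression
(so set size does not change scale); trends over differentiation day are
ordinary least squares on numeric day; transfer scores apply a cluster gene
set to an external two-group dataset and test the group difference; ORA is
the hypergeometric overlap test with a detected-gene background and BH
correction across sets.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
import scipy.stats
import statsmodels.api as sm

from .io_formats import GeneSet


def composite_score(z: pd.DataFrame, gene_set: GeneSet) -> tuple[pd.Series, list[str]]:
    """Per-sample mean of z-scored member genes; returns (scores, absent members)."""
    present = sorted(gene_set.members & set(z.index))
    absent = sorted(gene_set.members - set(z.index))
    if not present:
        raise ValueError(f"no members of {gene_set.name!r} present in matrix")
    scores = z.loc[present].mean(axis=0)
    scores.name = gene_set.name
    return scores, absent


def trend_test(
    scores: pd.Series, days: pd.Series, window: tuple[int, int] | None = None
) -> dict:
    """OLS of score on numeric day; returns beta (score units/day), p, window."""
    days = days.loc[scores.index].astype(float)
    if window is not None:
        lo, hi = window
        sel = (days >= lo) & (days <= hi)
        scores, days = scores[sel], days[sel]
    if days.nunique() < 3:
        raise ValueError("trend test needs >=3 distinct days in window")
    X = sm.add_constant(days.to_numpy())
    fit = sm.OLS(scores.to_numpy(), X).fit()
    return {
        "beta": float(fit.params[1]),
        "p": float(fit.pvalues[1]),
        "window": window,
    }


def transfer_score(
    z_external: pd.DataFrame, gene_set: GeneSet, group_labels: pd.Series
) -> dict:
    """Apply a cluster gene set to an external dataset and test two groups.

    Scores are computed as in :func:`composite_score`; the difference between
    the two groups is assessed with a two-sided Welch t-test.
    """
    scores, absent = composite_score(z_external, gene_set)
    groups = group_labels.loc[scores.index]
    levels = list(pd.unique(groups))
    if len(levels) != 2:
        raise ValueError("transfer score needs exactly two groups")
    a = scores[groups == levels[0]]
    b = scores[groups == levels[1]]
    if len(a) < 2 or len(b) < 2:
        raise ValueError("each group needs >=2 samples")
    t, p = scipy.stats.ttest_ind(a, b, equal_var=False)
    return {
        "scores": scores,
        "difference": float(a.mean() - b.mean()),
        "groups": (levels[0], levels[1]),
        "t": float(t),
        "p": float(p),
        "absent_members": absent,
    }


def ora(
    foreground: set[str],
    background: set[str],
    gene_sets: list[GeneSet],
    padj_threshold: float = 0.05,
) -> pd.DataFrame:
    """Hypergeometric over-representation of each set in the foreground.

    Sets are intersected with the background universe; p is the upper-tail
    probability of an overlap at least as large as observed, BH-adjusted
    across sets.
    """
    from .diffexp import bh_adjust

    foreground = set(foreground)
    background = set(background)
    if not foreground:
        raise ValueError("empty foreground")
    if not foreground <= background:
        raise ValueError("foreground must be a subset of the background")
    N, n = len(background), len(foreground)
    rows = []
    for s in gene_sets:
        members = s.members & background
        K = len(members)
        k = len(members & foreground)
        p = scipy.stats.hypergeom.sf(k - 1, N, K, n) if K else 1.0
        rows.append((s.name, k, K, n, N, p))
    out = pd.DataFrame(
        rows, columns=["set", "overlap", "set_size", "foreground", "background", "p"]
    ).set_index("set")
    out["padj"] = bh_adjust(out["p"])
    out["significant"] = out["padj"] < padj_threshold
    return out


def qpcr_fold_change(
    ct_target: float,
    ct_reference: float,
    ct_target_calibrator: float,
    ct_reference_calibrator: float,
) -> float:
    """Relative quantification by the 2^-ddCt method (reference-gene normalized)."""
    ddct = (ct_target - ct_reference) - (ct_target_calibrator - ct_reference_calibrator)
    return float(2.0 ** (-ddct))
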