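"""Normalization chain: TMM factors, (log) CPM, batch removal, gene z-scores.

The chain mirrors the standard bulk RNA-seq recipe — trimmed-mean-of-M-values
scaling factors, counts per million on effective library sizes, log2
transform, removal of the cell-line batch component by per-gene least
squares, and per-gene z-scoring so genes contribute on a common scale to
composite set scores.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .io_formats import CountMatrix


@dataclass
class NormalizedMatrix:
    """Float gene/isoform x sample matrix with a processing-stage tag."""

    values: pd.DataFrame
    stage: str  # cpm | logcpm | batch_removed | zscored
    factors: pd.Series | None = None
    constant_rows: list[str] = field(default_factory=list)


def tmm_factors(
    cm: CountMatrix,
    ref_sample: str | None = None,
    logratio_trim: float = 0.3,
    abs_trim: float = 0.05,
) -> pd.Series:
    """Trimmed mean of M-values scaling factors, geometric mean rescaled to 1.

    Per sample, the log2 factor is the weighted mean of gene-wise log ratios
    against the reference sample, after discarding the most extreme
    ``logratio_trim`` fraction of M-values and ``abs_trim`` fraction of
    A-values (genes must be nonzero in both samples).  Weights are the
    usual delta-method inverse variances.
    """
    counts = cm.counts.to_numpy(dtype=float)
    lib = cm.library_sizes.to_numpy(dtype=float)
    if counts.shape[1] < 2:
        raise ValueError("TMM needs at least two samples")
    if (counts.sum(axis=0) == 0).any():
        bad = cm.sample_ids[int(np.argmax(counts.sum(axis=0) == 0))]
        raise ValueError(f"all-zero sample: {bad!r}")

    p = counts / lib  # per-sample proportions
    if ref_sample is None:
        # reference = sample whose 75th percentile of nonzero proportions is
        # closest to the across-sample mean (edgeR-style choice)
        uq = np.array([np.quantile(p[:, j][counts[:, j] > 0], 0.75)
                       for j in range(counts.shape[1])])
        ref_j = int(np.argmin(np.abs(uq - uq.mean())))
    else:
        ref_j = cm.sample_ids.index(ref_sample)

    log_factors = np.zeros(counts.shape[1])
    for j in range(counts.shape[1]):
        if j == ref_j:
            continue
        ok = (counts[:, j] > 0) & (counts[:, ref_j] > 0)
        if not ok.any():
            raise ValueError(
                f"no gene expressed in both {cm.sample_ids[j]!r} and reference"
            )
        y, r = counts[ok, j], counts[ok, ref_j]
        m = np.log2((y / lib[j]) / (r / lib[ref_j]))
        a = 0.5 * np.log2((y / lib[j]) * (r / lib[ref_j]))
        w = 1.0 / (1 / y - 1 / lib[j] + 1 / r - 1 / lib[ref_j])
        n = len(m)
        lo_m, hi_m = np.floor(n * logratio_trim) + 1, n - np.floor(n * logratio_trim)
        lo_a, hi_a = np.floor(n * abs_trim) + 1, n - np.floor(n * abs_trim)
        rank_m = pd.Series(m).rank().to_numpy()
        rank_a = pd.Series(a).rank().to_numpy()
        keep = (rank_m >= lo_m) & (rank_m <= hi_m) & (rank_a >= lo_a) & (rank_a <= hi_a)
        if not keep.any():
            keep = np.ones(n, dtype=bool)
        log_factors[j] = np.sum(w[keep] * m[keep]) / np.sum(w[keep])

    f = np.power(2.0, log_factors)
    f /= np.exp(np.mean(np.log(f)))  # geometric mean 1
    return pd.Series(f, index=cm.sample_ids, name="tmm_factor")


def effective_library_sizes(cm: CountMatrix, factors: pd.Series | None = None) -> pd.Series:
    if factors is None:
        factors = tmm_factors(cm)
    return cm.library_sizes * factors


def cpm(
    cm: CountMatrix,
    factors: pd.Series | None = None,
    log: bool = False,
    prior_count: float = 0.5,
) -> NormalizedMatrix:
    """Counts per million on effective (TMM-scaled) library sizes.

    The log variant follows the standard convention of adding a
    library-size-scaled prior count before taking log2, which maps an
    all-zero feature to the same log-CPM in every sample regardless of
    depth differences.
    """
    if factors is None:
        factors = pd.Series(1.0, index=cm.sample_ids)
    factors = factors.loc[cm.sample_ids]
    if (factors <= 0).any():
        raise ValueError("normalization factors must be positive")
    eff = (cm.library_sizes * factors).to_numpy(dtype=float)
    if (eff <= 0).any():
        raise ValueError("zero effective library size")
    counts = cm.counts.to_numpy(dtype=float)
    if not log:
        vals = counts / eff * 1e6
        stage = "cpm"
    else:
        prior = prior_count * eff / eff.mean()
        vals = np.log2((counts + prior) / (eff + 2 * prior) * 1e6)
        stage = "logcpm"
    return NormalizedMatrix(
        pd.DataFrame(vals, index=cm.feature_ids, columns=cm.sample_ids),
        stage,
        factors,
    )


def remove_batch(
    nm: NormalizedMatrix,
    batch: pd.Series,
    preserve: pd.DataFrame | None = None,
) -> NormalizedMatrix:
    """Subtract the batch-attributable component of each gene by OLS.

    Fits ``value ~ [intercept | preserve columns | batch contrasts]`` per gene
    and subtracts only the fitted batch term, leaving preserved (e.g. time)
    effects untouched.  With a single batch level the input is returned
    unchanged.
    """
    values = nm.values
    batch = batch.loc[values.columns]
    levels = pd.unique(batch)
    if len(levels) < 2:
        return NormalizedMatrix(values.copy(), "batch_removed", nm.factors)

    n = values.shape[1]
    cols = [np.ones(n)]
    if preserve is not None:
        cols.extend(preserve.loc[values.columns].to_numpy(dtype=float).T)
    n_keep = len(cols)
    # sum-to-zero batch contrasts so the subtracted term has mean ~0
    for lev in levels[1:]:
        contrast = np.where(batch == lev, 1.0, 0.0) - np.where(
            batch == levels[0], 1.0, 0.0
        )
        cols.append(contrast)
    X = np.column_stack(cols)
    if np.linalg.matrix_rank(X) < X.shape[1]:
        raise ValueError("batch is confounded with the preserved design")

    Y = values.to_numpy(dtype=float).T  # samples x genes
    coef, *_ = np.linalg.lstsq(X, Y, rcond=None)
    batch_part = X[:, n_keep:] @ coef[n_keep:]
    out = values - batch_part.T
    return NormalizedMatrix(out, "batch_removed", nm.factors)


def zscore_genes(nm: NormalizedMatrix) -> NormalizedMatrix:
    """Per-gene z-score (n-1 denominator); constant rows map to 0 and are flagged."""
    values = nm.values
    if values.shape[1] < 2:
        raise ValueError("z-scoring needs >=2 samples")
    arr = values.to_numpy(dtype=float)
    mean = arr.mean(axis=1, keepdims=True)
    sd = arr.std(axis=1, ddof=1, keepdims=True)
    constant = sd[:, 0] == 0
    sd[constant] = 1.0
    z = (arr - mean) / sd
    z[constant] = 0.0
    return NormalizedMatrix(
        pd.DataFrame(z, index=values.index, columns=values.columns),
        "zscored",
        nm.factors,
        constant_rows=[values.index[i] for i in np.flatnonzero(constant)],
    )


def normalize_chain(
    cm: CountMatrix,
    batch_column: str | None = "cell_line",
    preserve_day: bool = True,
) -> NormalizedMatrix:
    """TMM -> logCPM -> batch removal -> per-gene z-score, the score pipeline."""
    factors = tmm_factors(cm)
    nm = cpm(cm, factors, log=True)
    if batch_column is not None and batch_column in cm.metadata.columns:
        preserve = None
        if preserve_day:
            preserve = pd.DataFrame(
                {"day": cm.metadata["day"].astype(float)}, index=cm.metadata.index
            )
        nm = remove_batch(nm, cm.metadata[batch_column], preserve)
    return zscore_genes(nm)
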