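"""Negative-binomial time-course tests at gene and isoform level.

Two flavors reproduce the analysis design of the myogenesis time course:

* windowed trend tests — NB regression on numeric day within a window
  (canonical differentiation days 0-3, post-differentiation days 3-5),
  adjusted for cell line, with the slope reported in log2 units per day;
* the full likelihood-ratio test — day as a 6-level factor plus cell line
  against a cell-line-only reduced model, chi-square with |days|-1 degrees
  of freedom.  Significant features feed the temporal clustering step.

Per-feature NB dispersions are method-of-moments estimates shrunk toward a
mean-dispersion trend; the negative-binomial likelihoods themselves are
maximized with statsmodels GLM.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
import scipy.stats
import statsmodels.api as sm

from .io_formats import CountMatrix
from .normalization import tmm_factors

LOG2 = np.log(2.0)


def bh_adjust(p: np.ndarray | pd.Series) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values; NaNs pass through."""
    p = np.asarray(p, dtype=float)
    out = np.full(p.shape, np.nan)
    ok = ~np.isnan(p)
    pv = p[ok]
    m = len(pv)
    if m == 0:
        return out
    order = np.argsort(pv, kind="mergesort")
    ranked = pv[order] * m / np.arange(1, m + 1)
    ranked = np.minimum.accumulate(ranked[::-1])[::-1]
    adj = np.empty(m)
    adj[order] = np.minimum(ranked, 1.0)
    out[ok] = adj
    return out


def aggregate_to_genes(cm: CountMatrix, t2g: pd.Series) -> CountMatrix:
    """Gene-level matrix as the sum of member isoform counts."""
    genes = cm.counts.groupby(t2g.loc[cm.feature_ids].to_numpy()).sum()
    genes.index.name = "feature_id"
    return CountMatrix(genes, cm.metadata.copy(), cm.library_sizes)


def _condition_groups(meta: pd.DataFrame) -> np.ndarray:
    key = meta["day"].astype(str) + "|" + meta["cell_line"].astype(str)
    return pd.factorize(key)[0]


@dataclass
class DispersionEstimates:
    alpha: pd.Series         # shrunk estimate per feature
    alpha_raw: pd.Series     # unshrunk method-of-moments value (may be < 0)
    base_mean: pd.Series     # mean normalized count
    excluded: list[str]      # all-zero features with undefined dispersion
    trend: tuple[float, float]  # (a0, a1) of alpha(mu) = a0 + a1/mu


def estimate_dispersions(
    cm: CountMatrix,
    factors: pd.Series | None = None,
    shrink_weight: float = 0.6,
) -> DispersionEstimates:
    """Method-of-moments NB dispersions shrunk toward a mean-dispersion trend.

    Per feature the raw estimate solves E[(y - mu_g)^2] = mu_g + alpha*mu_g^2
    over the residuals of condition-group (day x cell line) means on
    depth-normalized counts, with a Bessel-type small-group correction.  A
    trend alpha(mu) = a0 + a1/mu is fit across features by least squares on
    the raw (possibly negative) values, and the reported estimate is the
    trend-weighted average floored at zero.
    """
    if factors is None:
        factors = tmm_factors(cm)
    eff = (cm.library_sizes * factors).to_numpy(dtype=float)
    s = eff / np.exp(np.mean(np.log(eff)))  # size factors, geometric mean 1
    y = cm.counts.to_numpy(dtype=float) / s  # normalized counts

    groups = _condition_groups(cm.metadata)
    n_groups = groups.max() + 1
    n = y.shape[1]

    num = np.zeros(y.shape[0])
    den = np.zeros(y.shape[0])
    mu_all = np.zeros(y.shape[0])
    for g in range(n_groups):
        sel = groups == g
        ng = sel.sum()
        mu_g = y[:, sel].mean(axis=1)
        mu_all += mu_g * ng
        if ng < 2:
            continue
        bessel = ng / (ng - 1)
        resid2 = bessel * (y[:, sel] - mu_g[:, None]) ** 2
        # sampling variance of a normalized NB count: mu/s + alpha*mu^2
        num += (resid2 - mu_g[:, None] / s[None, sel]).sum(axis=1)
        den += ng * mu_g**2
    base_mean = mu_all / n

    excluded = base_mean == 0
    raw = np.full(y.shape[0], np.nan)
    nz = ~excluded & (den > 0)
    raw[nz] = num[nz] / den[nz]

    # trend fit on raw values against 1/mu
    if nz.sum() >= 2 and np.ptp(base_mean[nz]) > 0:
        X = np.column_stack([np.ones(nz.sum()), 1.0 / base_mean[nz]])
        coef, *_ = np.linalg.lstsq(X, raw[nz], rcond=None)
        a0, a1 = float(coef[0]), float(coef[1])
    else:
        a0, a1 = float(np.nanmean(raw)) if nz.any() else 0.0, 0.0
    trend_vals = np.maximum(a0 + a1 / np.where(base_mean > 0, base_mean, 1.0), 0.0)

    shrunk = np.maximum(
        (1 - shrink_weight) * raw + shrink_weight * trend_vals, 0.0
    )
    idx = cm.counts.index
    return DispersionEstimates(
        alpha=pd.Series(shrunk, index=idx),
        alpha_raw=pd.Series(raw, index=idx),
        base_mean=pd.Series(base_mean, index=idx),
        excluded=[idx[i] for i in np.flatnonzero(excluded)],
        trend=(a0, a1),
    )


def _design_matrices(meta: pd.DataFrame, day_factor: bool, window=None):
    """(full, reduced) design matrices; reduced = intercept + cell line."""
    sel = np.ones(len(meta), dtype=bool)
    if window is not None:
        lo, hi = window
        sel = (meta["day"] >= lo) & (meta["day"] <= hi)
        sel = sel.to_numpy()
    m = meta.loc[sel]
    cols = [np.ones(sel.sum())]
    names = ["intercept"]
    lines = pd.unique(m["cell_line"])
    for lev in lines[1:]:
        cols.append((m["cell_line"] == lev).to_numpy(dtype=float))
        names.append(f"cell_line[{lev}]")
    reduced = np.column_stack(cols)
    if day_factor:
        days = sorted(pd.unique(m["day"]))
        for d in days[1:]:
            cols.append((m["day"] == d).to_numpy(dtype=float))
            names.append(f"day[{d}]")
    else:
        cols.append(m["day"].to_numpy(dtype=float))
        names.append("day")
    full = np.column_stack(cols)
    return full, reduced, names, sel


def _glm_fit(y, X, offset, alpha):
    fam = (
        sm.families.Poisson()
        if alpha < 1e-8
        else sm.families.NegativeBinomial(alpha=alpha)
    )
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        model = sm.GLM(y, X, family=fam, offset=offset)
        res = model.fit(maxiter=100, tol=1e-8)
    return res


def nb_lrt(
    cm: CountMatrix,
    factors: pd.Series | None = None,
    dispersions: DispersionEstimates | None = None,
) -> pd.DataFrame:
    """Full-model likelihood-ratio test: day factor + cell line vs cell line.

    Returns a frame with statistic, df, p and BH-adjusted p per feature;
    non-converged or excluded features carry NaN p-values and a flag.
    """
    if factors is None:
        factors = tmm_factors(cm)
    if dispersions is None:
        dispersions = estimate_dispersions(cm, factors)
    eff = (cm.library_sizes * factors).to_numpy(dtype=float)
    offset = np.log(eff / np.exp(np.mean(np.log(eff))))
    full, reduced, _, _ = _design_matrices(cm.metadata, day_factor=True)
    df = full.shape[1] - reduced.shape[1]

    rows = []
    counts = cm.counts.to_numpy()
    for i, fid in enumerate(cm.feature_ids):
        y = counts[i]
        alpha = dispersions.alpha.iloc[i]
        if fid in dispersions.excluded or y.sum() == 0:
            rows.append((fid, np.nan, df, np.nan, "excluded"))
            continue
        try:
            res_f = _glm_fit(y, full, offset, alpha)
            res_r = _glm_fit(y, reduced, offset, alpha)
            stat = max(0.0, 2.0 * (res_f.llf - res_r.llf))
            p = scipy.stats.chi2.sf(stat, df)
            rows.append((fid, stat, df, p, "ok"))
        except Exception:
            rows.append((fid, np.nan, df, np.nan, "failed"))
    out = pd.DataFrame(
        rows, columns=["feature_id", "stat", "df", "p", "status"]
    ).set_index("feature_id")
    out["padj"] = bh_adjust(out["p"])
    out["model"] = "lrt_full"
    return out


def nb_trend(
    cm: CountMatrix,
    window: tuple[int, int],
    factors: pd.Series | None = None,
    dispersions: DispersionEstimates | None = None,
) -> pd.DataFrame:
    """Windowed NB trend test on numeric day, adjusted for cell line.

    ``beta`` is the fitted slope in log2 fold change per day; p is the
    two-sided Wald test of the day coefficient, BH-adjusted across features.
    """
    lo, hi = window
    days_in = sorted(d for d in pd.unique(cm.metadata["day"]) if lo <= d <= hi)
    if len(days_in) < 3:
        raise ValueError("window must contain >=3 distinct days")
    if factors is None:
        factors = tmm_factors(cm)
    if dispersions is None:
        dispersions = estimate_dispersions(cm, factors)
    eff = (cm.library_sizes * factors).to_numpy(dtype=float)
    offset_all = np.log(eff / np.exp(np.mean(np.log(eff))))
    full, _, names, sel = _design_matrices(cm.metadata, day_factor=False, window=window)
    day_col = names.index("day")
    offset = offset_all[sel]

    rows = []
    counts = cm.counts.to_numpy()[:, sel]
    for i, fid in enumerate(cm.feature_ids):
        y = counts[i]
        alpha = dispersions.alpha.iloc[i]
        if fid in dispersions.excluded or y.sum() == 0:
            rows.append((fid, np.nan, np.nan, np.nan, "excluded"))
            continue
        try:
            res = _glm_fit(y, full, offset, alpha)
            beta = res.params[day_col] / LOG2
            z = res.params[day_col] / res.bse[day_col]
            p = 2 * scipy.stats.norm.sf(abs(z))
            rows.append((fid, beta, z, p, "ok"))
        except Exception:
            rows.append((fid, np.nan, np.nan, np.nan, "failed"))
    out = pd.DataFrame(
        rows, columns=["feature_id", "beta", "stat", "p", "status"]
    ).set_index("feature_id")
    out["padj"] = bh_adjust(out["p"])
    out["model"] = f"window_{lo}_{hi}"
    return out
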