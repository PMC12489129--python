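"""Differential transcript usage with stage-wise error control.

The usage question — does an isoform's share of its gene's output change
with differentiation day, irrespective of total abundance — is answered in
four steps:

1. expression/proportion filtering with the six study thresholds
   (minimum feature count 5 in >=18 samples, minimum within-gene proportion
   0.05 in >=18 samples, minimum gene count 10 in >=18 samples);
2. per-isoform beta-binomial regression of (isoform count, gene total) with
   a logit-linear predictor in day (factor) plus cell line, likelihood-ratio
   p for the day terms;
3. gene-level screening p as the Sidak-corrected minimum member p;
4. two-stage decisions at overall alpha 0.05: Benjamini-Hochberg screening
   on gene p, then Holm confirmation of member isoforms at the stage-wise
   adjusted level (R * alpha / G for R of G screened genes rejected).

Replicate-level proportion overdispersion is modeled by a per-gene
Dirichlet-multinomial precision gamma; the operating characteristics of the
whole procedure (overall FDR across both stages, screening power) are
established by simulation rather than assumed.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import scipy.optimize
import scipy.special
import scipy.stats

from .io_formats import CountMatrix


@dataclass(frozen=True)
class FilterParams:
    """Expression/proportion filter thresholds (study defaults)."""

    min_samples_feature_expr: int = 18
    min_samples_feature_prop: int = 18
    min_samples_gene_expr: int = 18
    min_feature_expr: float = 5
    min_feature_prop: float = 0.05
    min_gene_expr: float = 10

    def __post_init__(self) -> None:
        if min(
            self.min_samples_feature_expr,
            self.min_samples_feature_prop,
            self.min_samples_gene_expr,
        ) < 0:
            raise ValueError("sample thresholds must be nonnegative")
        if not 0 <= self.min_feature_prop <= 1:
            raise ValueError("min_feature_prop must lie in [0, 1]")
        if self.min_feature_expr < 0 or self.min_gene_expr < 0:
            raise ValueError("count thresholds must be nonnegative")


def filter_features(
    cm: CountMatrix, t2g: pd.Series, params: FilterParams = FilterParams()
) -> tuple[CountMatrix, pd.DataFrame]:
    """Apply the usage filter; returns the kept matrix and a removal report.

    Proportions are computed per sample from raw counts; samples whose gene
    total is zero count as failing the proportion rule.  Genes reduced to
    fewer than two surviving isoforms are dropped.
    """
    for thr in (
        params.min_samples_feature_expr,
        params.min_samples_feature_prop,
        params.min_samples_gene_expr,
    ):
        if thr > cm.n_samples:
            raise ValueError("sample threshold exceeds total samples")
    counts = cm.counts
    genes = t2g.loc[counts.index]
    gene_tot = counts.groupby(genes.to_numpy()).transform("sum")
    with np.errstate(invalid="ignore", divide="ignore"):
        prop = counts.to_numpy() / gene_tot.to_numpy()
    prop = np.nan_to_num(prop, nan=0.0)

    removals: list[tuple[str, str]] = []
    iso_expr_ok = (counts.to_numpy() >= params.min_feature_expr).sum(axis=1) >= (
        params.min_samples_feature_expr
    )
    iso_prop_ok = (prop >= params.min_feature_prop).sum(axis=1) >= (
        params.min_samples_feature_prop
    )
    keep_iso = iso_expr_ok & iso_prop_ok
    for i in np.flatnonzero(~iso_expr_ok):
        removals.append((counts.index[i], "min_samples_feature_expr"))
    for i in np.flatnonzero(iso_expr_ok & ~iso_prop_ok):
        removals.append((counts.index[i], "min_samples_feature_prop"))

    gene_sum = counts.groupby(genes.to_numpy()).sum()
    gene_ok = (gene_sum.to_numpy() >= params.min_gene_expr).sum(axis=1) >= (
        params.min_samples_gene_expr
    )
    ok_genes = set(gene_sum.index[gene_ok])
    for g in gene_sum.index[~gene_ok]:
        removals.append((g, "min_samples_gene_expr"))

    keep = keep_iso & genes.isin(ok_genes).to_numpy()
    surv_counts = genes[keep].value_counts()
    single = set(surv_counts.index[surv_counts < 2])
    for g in sorted(single):
        removals.append((g, "fewer_than_2_isoforms"))
    keep &= ~genes.isin(single).to_numpy()

    kept_ids = list(counts.index[keep])
    if not kept_ids:
        raise ValueError("no features survive the usage filter")
    report = pd.DataFrame(removals, columns=["id", "failed_rule"])
    return cm.subset_features(kept_ids), report


# ---------------------------------------------------------------------------
# Beta-binomial regression
# ---------------------------------------------------------------------------


def _bb_negll_grad(params, X, y, n):
    """Negative beta-binomial log-likelihood and gradient.

    params = [coefs..., log gamma]; logit mu = X @ coefs; shape a = gamma*mu,
    b = gamma*(1-mu).  The binomial coefficient term is dropped (constant).
    """
    coefs, log_gamma = params[:-1], params[-1]
    gamma = np.exp(log_gamma)
    eta = X @ coefs
    mu = scipy.special.expit(eta)
    mu = np.clip(mu, 1e-10, 1 - 1e-10)
    a = gamma * mu
    b = gamma * (1 - mu)
    lg = scipy.special.gammaln
    ll = np.sum(
        lg(gamma) - lg(gamma + n) + lg(a + y) - lg(a) + lg(b + n - y) - lg(b)
    )
    psi = scipy.special.digamma
    da = psi(a + y) - psi(a)
    db = psi(b + n - y) - psi(b)
    dmu = gamma * (da - db)
    grad_coefs = X.T @ (dmu * mu * (1 - mu))
    dgamma = np.sum(psi(gamma) - psi(gamma + n) + mu * da + (1 - mu) * db)
    grad = np.append(grad_coefs, dgamma * gamma)
    return -ll, -grad


def fit_beta_binomial(
    y: np.ndarray, n: np.ndarray, X: np.ndarray, gamma_init: float = 50.0
) -> tuple[np.ndarray, float, float, bool]:
    """Maximize the beta-binomial likelihood; returns (coefs, gamma, llf, ok)."""
    ok = n > 0
    y, n, X = y[ok], n[ok], X[ok]
    frac = (y.sum() + 0.5) / (n.sum() + 1.0)
    x0 = np.zeros(X.shape[1] + 1)
    x0[0] = scipy.special.logit(frac)
    x0[-1] = np.log(gamma_init)
    res = scipy.optimize.minimize(
        _bb_negll_grad,
        x0,
        args=(X, y, n),
        jac=True,
        method="L-BFGS-B",
        bounds=[(None, None)] * X.shape[1] + [(np.log(1e-3), np.log(1e7))],
        options={"maxiter": 200},
    )
    return res.x[:-1], float(np.exp(res.x[-1])), -float(res.fun), bool(res.success)


def _fit_bb_fixed_gamma(
    y: np.ndarray, n: np.ndarray, X: np.ndarray, gamma: float
) -> tuple[float, bool]:
    """Maximize beta-binomial coefficients at fixed precision; returns (llf, ok)."""

    def f(b):
        nll, g = _bb_negll_grad(np.append(b, np.log(gamma)), X, y, n)
        return nll, g[:-1]

    frac = (y.sum() + 0.5) / (n.sum() + 1.0)
    x0 = np.zeros(X.shape[1])
    x0[0] = scipy.special.logit(frac)
    res = scipy.optimize.minimize(
        f, x0, jac=True, method="L-BFGS-B", options={"maxiter": 200}
    )
    return -float(res.fun), bool(res.success)


def _usage_designs(meta: pd.DataFrame) -> tuple[np.ndarray, np.ndarray, int]:
    n = len(meta)
    cols = [np.ones(n)]
    for lev in pd.unique(meta["cell_line"])[1:]:
        cols.append((meta["cell_line"] == lev).to_numpy(dtype=float))
    reduced = np.column_stack(cols)
    days = sorted(pd.unique(meta["day"]))
    for d in days[1:]:
        cols.append((meta["day"] == d).to_numpy(dtype=float))
    full = np.column_stack(cols)
    return full, reduced, len(days) - 1


def test_usage(
    cm: CountMatrix, t2g: pd.Series, moderation: float = 0.8
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Per-isoform usage LRT (day factor, cell-line adjusted) + gene screening p.

    Dispersion is handled in two passes.  First each isoform's beta-binomial
    precision is estimated under the reduced (no-day) model; the implied
    intraclass correlations get a residual-degrees-of-freedom correction,
    are pooled per gene by the median, and are shrunk on the log scale
    toward the across-gene median with weight ``moderation`` (per-isoform
    plug-in dispersions at typical sample counts are noisy enough to
    visibly distort the null distribution of the LRT).  Second, both mean
    models are refit at the fixed moderated precision and compared by a
    chi-square LRT with |days|-1 degrees of freedom.

    Returns (isoform frame with p per isoform, gene frame with screening p).
    The gene screening p is the Sidak-corrected minimum member p,
    1 - (1 - min p)^m for m member isoforms.
    """
    genes = t2g.loc[cm.feature_ids]
    full, reduced, df = _usage_designs(cm.metadata)
    counts = cm.counts.to_numpy()
    gene_tot = cm.counts.groupby(genes.to_numpy()).transform("sum").to_numpy()

    # pass 1: per-isoform precision under the reduced model
    rho = np.full(len(cm.feature_ids), np.nan)
    testable = np.zeros(len(cm.feature_ids), dtype=bool)
    for i in range(len(cm.feature_ids)):
        y, n = counts[i].astype(float), gene_tot[i].astype(float)
        ok = n > 0
        if ok.sum() < full.shape[1] + 1:
            continue
        _, gam, _, conv = fit_beta_binomial(y, n, reduced)
        if conv:
            nobs = int(ok.sum())
            rho[i] = 1.0 / (gam + 1.0) * nobs / (nobs - reduced.shape[1])
            testable[i] = True
    rho_iso = pd.Series(rho, index=cm.feature_ids)
    rho_gene = rho_iso.groupby(genes.to_numpy()).median().dropna()
    if rho_gene.empty:
        gamma_gene = pd.Series(dtype=float)
    else:
        log_common = float(np.median(np.log(rho_gene)))
        rho_shrunk = np.exp(
            (1 - moderation) * np.log(rho_gene) + moderation * log_common
        )
        gamma_gene = (1.0 / rho_shrunk - 1.0).clip(1e-3, 1e7)

    # pass 2: fixed-precision LRT per isoform
    iso_rows = []
    for i, fid in enumerate(cm.feature_ids):
        g = genes.iloc[i]
        if not testable[i] or g not in gamma_gene.index:
            reason = "too_few_samples" if not testable[i] else "no_dispersion"
            iso_rows.append((fid, g, np.nan, reason))
            continue
        y, n = counts[i].astype(float), gene_tot[i].astype(float)
        ok = n > 0
        gam = float(gamma_gene[g])
        ll_f, ok_f = _fit_bb_fixed_gamma(y[ok], n[ok], full[ok], gam)
        ll_r, ok_r = _fit_bb_fixed_gamma(y[ok], n[ok], reduced[ok], gam)
        if not (ok_r and ok_f):
            iso_rows.append((fid, g, np.nan, "non_convergence"))
            continue
        stat = max(0.0, 2.0 * (ll_f - ll_r))
        p = scipy.stats.chi2.sf(stat, df)
        iso_rows.append((fid, g, p, "ok"))
    iso = pd.DataFrame(
        iso_rows, columns=["isoform_id", "gene_id", "p", "status"]
    ).set_index("isoform_id")

    gene_rows = []
    for g, grp in iso.groupby("gene_id"):
        pv = grp["p"].dropna()
        if pv.empty:
            gene_rows.append((g, np.nan, len(grp)))
            continue
        m = len(pv)
        p_screen = 1.0 - (1.0 - pv.min()) ** m
        gene_rows.append((g, p_screen, m))
    gene = pd.DataFrame(
        gene_rows, columns=["gene_id", "p_screen", "n_isoforms"]
    ).set_index("gene_id")
    return iso, gene


def _holm(p: np.ndarray) -> np.ndarray:
    m = len(p)
    order = np.argsort(p, kind="mergesort")
    adj = np.maximum.accumulate(p[order] * (m - np.arange(m)))
    out = np.empty(m)
    out[order] = np.minimum(adj, 1.0)
    return out


@dataclass
class UsageResult:
    gene: pd.DataFrame       # p_screen, padj_screen, screened
    isoform: pd.DataFrame    # p, p_holm, confirmed
    alpha: float
    stage2_level: float


def stagewise_adjust(
    gene: pd.DataFrame, iso: pd.DataFrame, alpha: float = 0.05
) -> UsageResult:
    """Two-stage decisions: BH screening on genes, Holm confirmation within.

    Stage II evaluates Holm-adjusted member p-values at the stage-wise
    significance level alpha * R / G, where G is the number of screened
    genes (those with a defined screening p) and R the number rejected by
    BH at ``alpha``.  Isoforms of unscreened genes are never confirmed.
    """
    from .diffexp import bh_adjust

    gene = gene.copy()
    gene["padj_screen"] = bh_adjust(gene["p_screen"])
    gene["screened"] = gene["padj_screen"] <= alpha
    G = int(gene["p_screen"].notna().sum())
    R = int(gene["screened"].sum())
    level = alpha * R / G if G else 0.0

    iso = iso.copy()
    iso["p_holm"] = np.nan
    iso["confirmed"] = False
    for g in gene.index[gene["screened"]]:
        members = iso.index[(iso["gene_id"] == g) & iso["p"].notna()]
        if len(members) == 0:
            continue
        holm = _holm(iso.loc[members, "p"].to_numpy())
        iso.loc[members, "p_holm"] = holm
        iso.loc[members, "confirmed"] = holm <= level
    assert not iso.loc[
        iso["confirmed"], "gene_id"
    ].map(lambda g: not gene.loc[g, "screened"]).any(), (
        "confirmed isoform in unscreened gene"
    )
    return UsageResult(gene, iso, alpha, level)


def run_dtu(
    cm: CountMatrix,
    t2g: pd.Series,
    alpha: float = 0.05,
    params: FilterParams = FilterParams(),
) -> tuple[UsageResult, pd.DataFrame]:
    """Filter -> usage tests -> stage-wise decisions; returns result + filter report."""
    filtered, report = filter_features(cm, t2g, params)
    iso, gene = test_usage(filtered, t2g)
    return stagewise_adjust(gene, iso, alpha), report


# ---------------------------------------------------------------------------
# Dirichlet-multinomial proportions
# ---------------------------------------------------------------------------


def fit_dm(
    counts: np.ndarray, groups: np.ndarray
) -> tuple[pd.DataFrame, float, bool]:
    """Maximum-likelihood Dirichlet-multinomial fit with a shared precision.

    ``counts`` is isoform x sample; ``groups`` assigns each sample to a
    condition.  Returns per-group proportion estimates (group x isoform),
    the shared precision gamma, and a convergence flag.  Zero-total samples
    are excluded.
    """
    counts = np.asarray(counts, dtype=float)
    K = counts.shape[0]
    if K < 2:
        raise ValueError("Dirichlet-multinomial fit needs >=2 isoforms")
    totals = counts.sum(axis=0)
    keep = totals > 0
    counts, groups = counts[:, keep], np.asarray(groups)[keep]
    levels = list(pd.unique(groups))
    lg = scipy.special.gammaln

    def unpack(theta):
        gamma = np.exp(theta[-1])
        pis = []
        for gi in range(len(levels)):
            logits = np.concatenate([theta[gi * (K - 1) : (gi + 1) * (K - 1)], [0.0]])
            e = np.exp(logits - logits.max())
            pis.append(e / e.sum())
        return np.array(pis), gamma

    def negll(theta):
        pis, gamma = unpack(theta)
        ll = 0.0
        for gi, lev in enumerate(levels):
            sel = groups == lev
            y = counts[:, sel]
            n = y.sum(axis=0)
            a = gamma * np.clip(pis[gi], 1e-12, None)
            ll += np.sum(lg(gamma) - lg(gamma + n))
            ll += np.sum(lg(a[:, None] + y) - lg(a)[:, None])
        return -ll

    x0 = []
    for lev in levels:
        pooled = counts[:, groups == lev].sum(axis=1) + 0.5
        pooled /= pooled.sum()
        x0.extend(np.log(pooled[:-1] / pooled[-1]))
    x0.append(np.log(50.0))
    res = scipy.optimize.minimize(
        negll, np.array(x0), method="L-BFGS-B",
        bounds=[(None, None)] * (len(levels) * (K - 1)) + [(np.log(1e-3), np.log(1e7))],
        options={"maxiter": 500},
    )
    pis, gamma = unpack(res.x)
    return (
        pd.DataFrame(pis, index=levels),
        float(gamma),
        bool(res.success),
    )


def usage_proportions(
    cm: CountMatrix, t2g: pd.Series
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Observed per-sample and per-day mean isoform proportions.

    Per sample, pi = isoform count / gene total; zero-total samples are
    excluded from the day means (their count is reported in the tidy frame
    as NaN).  Within each day the proportions of a gene's isoforms average
    to a composition summing to 1.
    """
    genes = t2g.loc[cm.feature_ids]
    gene_tot = cm.counts.groupby(genes.to_numpy()).transform("sum").to_numpy()
    with np.errstate(invalid="ignore", divide="ignore"):
        prop = cm.counts.to_numpy() / gene_tot
    per_sample = pd.DataFrame(prop, index=cm.feature_ids, columns=cm.sample_ids)
    day = cm.metadata["day"]
    per_day = pd.DataFrame(
        {d: per_sample.loc[:, (day == d).to_numpy()].mean(axis=1)
         for d in sorted(pd.unique(day))}
    )
    return per_sample, per_day


# ---------------------------------------------------------------------------
# Isoform-expression decomposition of significant genes
# ---------------------------------------------------------------------------


def classify_die_dynamics(
    iso_traj: pd.DataFrame,
    t2g: pd.Series,
    window: tuple[int, int] = (0, 3),
    dominance_fraction: float = 0.75,
    theta: float = 0.0,
) -> pd.Series:
    """Classify how member isoforms compose each gene's aggregate change.

    Over the window, with per-isoform changes d_i and aggregate change
    D = sum d_i: ``inverse`` if some isoform opposes an aggregate change
    exceeding ``theta``; else ``single_dominant`` if one isoform carries at
    least ``dominance_fraction`` of |D|; else ``cumulative`` if >=2 isoforms
    each contribute >=25% of D with matching sign; else ``other``.
    """
    lo, hi = window
    delta = iso_traj[hi] - iso_traj[lo]
    genes = t2g.loc[iso_traj.index]
    out = {}
    for g, d in delta.groupby(genes.to_numpy()):
        if len(d) < 2:
            out[g] = "other"
            continue
        D = d.sum()
        if abs(D) <= theta:
            out[g] = "other"
            continue
        if ((np.sign(d) == -np.sign(D)) & (d.abs() > 1e-12)).any():
            out[g] = "inverse"
        elif (d.abs() >= dominance_fraction * abs(D)).any():
            out[g] = "single_dominant"
        elif ((np.sign(d) == np.sign(D)) & (d.abs() >= 0.25 * abs(D))).sum() >= 2:
            out[g] = "cumulative"
        else:
            out[g] = "other"
    return pd.Series(out, name="die_dynamics")
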