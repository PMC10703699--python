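"""Per-gRNA paired differential abundance between sort bins.

Guide counts from the LOW and HIGH sort bins of each donor are modelled as
negative binomial with a log link:

    K_gj ~ NB(mean = s_j * q_gj,  variance = mu + alpha_g * mu^2)
    log q_gj = beta_g0 + sum_d beta_gd * donor_dj + beta_g,bin * bin_j

with median-of-ratios size factors s_j, per-guide dispersions alpha_g
moderated toward a 1/mu trend, and a Wald test on the bin coefficient.
Donor indicators enter each guide's model, so donor-specific abundance
differences are blocked out (the paired design).  The bin coefficient is
reported as an *unshrunk* log2 fold change HIGH vs LOW, with one-sided
p-values for enrichment in either bin and Benjamini-Hochberg adjustment of
the two-sided p.

The model surface is :class:`GuideEnrichment` (built from a count matrix
and sample sheet) whose :meth:`GuideEnrichment.fit` returns
:class:`GuideEnrichmentResults`; the individual stages are module-level
functions.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import optimize, special, stats

from .quantify import CountMatrix, validate_paired_design

LN2 = np.log(2.0)

__all__ = [
    "size_factors",
    "fit_dispersions",
    "paired_nb_wald",
    "bh_adjust",
    "DispersionModel",
    "GuideEnrichment",
    "GuideEnrichmentResults",
]


def size_factors(counts: np.ndarray | pd.DataFrame) -> np.ndarray:
    """Median-of-ratios size factors.

    s_j = median over guides g (restricted to rows with all-positive
    counts) of K_gj / geomean_j(K_gj).
    """
    K = np.asarray(counts, dtype=float)
    if K.ndim != 2:
        raise ValueError("counts must be a 2-D matrix")
    allpos = (K > 0).all(axis=1)
    if not allpos.any():
        raise ValueError(
            "no guide has positive counts in every sample; cannot form the "
            "median-of-ratios reference (consider a pseudo-reference fallback)"
        )
    logK = np.log(K[allpos])
    log_geomean = logK.mean(axis=1, keepdims=True)
    s = np.exp(np.median(logK - log_geomean, axis=0))
    return s


def design_matrix(samples: pd.DataFrame) -> tuple[np.ndarray, list[str]]:
    """Intercept + donor indicators (first donor as reference) + HIGH-bin
    indicator, in that column order.  The bin column is last."""
    donors = sorted(samples["donor"].unique())
    cols = [np.ones(len(samples))]
    names = ["intercept"]
    for d in donors[1:]:
        cols.append((samples["donor"] == d).to_numpy(float))
        names.append(f"donor[{d}]")
    cols.append((samples["bin"] == "HIGH").to_numpy(float))
    names.append("bin[HIGH]")
    return np.column_stack(cols), names


def _nb_irls(
    Y: np.ndarray,
    X: np.ndarray,
    offset: np.ndarray,
    alpha: np.ndarray,
    max_iter: int = 100,
    tol: float = 1e-10,
    ridge: float = 1e-8,
    eta_cap: float = 30.0,
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Vectorised IRLS for per-guide NB log-link regressions sharing X.

    Y: (G, n) counts; X: (n, p); offset: (n,); alpha: (G,) dispersions.
    Returns (beta (G, p), cov (G, p, p), converged (G,)).  A tiny ridge
    keeps separated fits (all-zero bins) finite; the linear predictor is
    capped so beta stays bounded under separation.
    """
    G, n = Y.shape
    p = X.shape[1]
    a = alpha[:, None]
    # init: flat fit through the intercept
    beta = np.zeros((G, p))
    beta[:, 0] = np.log(np.maximum(Y.mean(axis=1), 0.1)) - offset.mean()
    converged = np.zeros(G, dtype=bool)
    I = np.eye(p) * ridge
    for _ in range(max_iter):
        eta = np.clip(beta @ X.T + offset, -eta_cap, eta_cap)
        mu = np.exp(eta)
        W = mu / (1.0 + a * mu)  # NB working weights, log link
        z = (eta - offset) + (Y - mu) / mu
        A = np.einsum("ni,gn,nj->gij", X, W, X) + I
        b = np.einsum("ni,gn->gi", X, W * z)
        new = np.linalg.solve(A, b[..., None])[..., 0]
        delta = np.max(np.abs(new - beta), axis=1)
        step_ok = delta < tol * (1.0 + np.max(np.abs(new), axis=1))
        converged |= step_ok
        beta = new
        if step_ok.all():
            break
    eta = np.clip(beta @ X.T + offset, -eta_cap, eta_cap)
    mu = np.exp(eta)
    W = mu / (1.0 + a * mu)
    A = np.einsum("ni,gn,nj->gij", X, W, X) + I
    cov = np.linalg.inv(A)
    return beta, cov, converged


def _nb_loglik(Y: np.ndarray, mu: np.ndarray, alpha: np.ndarray) -> np.ndarray:
    """Per-guide NB log-likelihood summed over samples.

    Y, mu: (G, n); alpha: (G,) or (G, 1).  Parameterisation
    var = mu + alpha * mu^2; alpha -> 0 recovers Poisson.
    """
    a = np.atleast_1d(alpha)[:, None]
    r = 1.0 / np.maximum(a, 1e-300)
    mu = np.maximum(mu, 1e-300)
    # stable in both the NB and near-Poisson regimes
    ll = (
        special.gammaln(Y + r)
        - special.gammaln(r)
        - special.gammaln(Y + 1.0)
        + Y * np.log(a * mu / (1.0 + a * mu))
        - r * np.log1p(a * mu)
    )
    small = a[:, 0] < 1e-12
    if small.any():
        # Poisson limit
        Ys, mus = Y[small], mu[small]
        ll[small] = Ys * np.log(mus) - mus - special.gammaln(Ys + 1.0)
    return ll.sum(axis=1)


def _cr_adjustment(mu: np.ndarray, alpha: np.ndarray, X: np.ndarray) -> np.ndarray:
    """Cox-Reid adjustment -0.5 log det(X' W X) per guide.

    Profiling out the fitted means biases the dispersion MLE downward when
    residual degrees of freedom are few; the adjusted profile likelihood
    removes most of that bias.
    """
    W = mu / (1.0 + alpha[:, None] * mu)
    A = np.einsum("ni,gn,nj->gij", X, W, X)
    _, logdet = np.linalg.slogdet(A + np.eye(X.shape[1]) * 1e-12)
    return -0.5 * logdet


def _profile_alpha(
    Y: np.ndarray,
    mu: np.ndarray,
    X: np.ndarray,
    log10_lo: float = -8.0,
    log10_hi: float = 2.0,
    coarse: int = 41,
    refine_rounds: int = 3,
) -> np.ndarray:
    """Per-guide dispersion estimate maximising the Cox-Reid adjusted
    profile likelihood on a refined log10 grid, means held fixed.  Guides
    maximised at the lower boundary return the floor."""
    G = Y.shape[0]
    lo = np.full(G, log10_lo)
    hi = np.full(G, log10_hi)
    best = np.full(G, log10_lo)
    npts = coarse
    for _ in range(refine_rounds):
        grid = lo[:, None] + (hi - lo)[:, None] * np.linspace(0, 1, npts)[None, :]
        ll = np.empty((G, npts))
        for k in range(npts):
            a = 10.0 ** grid[:, k]
            ll[:, k] = _nb_loglik(Y, mu, a) + _cr_adjustment(mu, a, X)
        idx = np.argmax(ll, axis=1)
        best = np.take_along_axis(grid, idx[:, None], axis=1)[:, 0]
        span = (hi - lo) / (npts - 1)
        lo = np.maximum(best - span, log10_lo)
        hi = np.minimum(best + span, log10_hi)
        npts = 17
    return 10.0 ** best


@dataclass
class DispersionModel:
    """Raw, trended and shrunken per-guide NB dispersions."""

    alpha_raw: np.ndarray
    alpha_final: np.ndarray
    trend_a0: float
    trend_a1: float
    base_mean: np.ndarray
    prior_var: float
    alpha_floor: float
    excluded: np.ndarray  # all-zero guides, undefined dispersion

    def trend(self, mu: np.ndarray) -> np.ndarray:
        return self.trend_a0 + self.trend_a1 / np.maximum(mu, 1e-12)


def fit_dispersions(
    counts: np.ndarray | pd.DataFrame,
    norm: np.ndarray,
    samples: pd.DataFrame,
    prior_var: float = 0.25,
    alpha_floor: float = 1e-8,
) -> DispersionModel:
    """Estimate per-guide NB dispersions with trend and shrinkage.

    Per guide: profile the NB likelihood in alpha at fitted means from the
    donor+bin model; fit a robust mean-dispersion trend
    alpha_tr(mu) = a0 + a1/mu over guides; then maximise the log-likelihood
    penalised by a normal prior on log(alpha) centred at the trend
    (variance ``prior_var``).  The shrunken value is clipped to lie between
    the raw and trend values in log space; values within a decade of
    ``alpha_floor`` snap to the floor (numerically Poisson).
    """
    Y = np.asarray(counts, dtype=float)
    X, _ = design_matrix(samples)
    if Y.shape[0] and Y.shape[1] - X.shape[1] < 1:
        raise ValueError("no residual degrees of freedom in the design")
    G = Y.shape[0]
    excluded = (Y.sum(axis=1) == 0)
    offset = np.log(norm)
    base_mean = (Y / norm).mean(axis=1)

    work = ~excluded
    alpha_raw = np.full(G, np.nan)
    if work.any():
        Yw = Y[work]
        # initial means from a Poisson fit, then one alternation
        beta, _, _ = _nb_irls(Yw, X, offset, np.full(work.sum(), 1e-8))
        mu = np.exp(np.clip(beta @ X.T + offset, -30, 30))
        a1 = _profile_alpha(Yw, mu, X)
        beta, _, _ = _nb_irls(Yw, X, offset, a1)
        mu = np.exp(np.clip(beta @ X.T + offset, -30, 30))
        a_raw = np.maximum(_profile_alpha(Yw, mu, X), alpha_floor)
        alpha_raw[work] = a_raw

        # mean-dispersion trend over informative guides.  Per-guide
        # estimates are right-skewed, so the fit minimises gamma deviance
        # (mean-targeting, not median-targeting), with one round of
        # extreme-outlier exclusion.
        bm = base_mean[work]
        informative = (a_raw > 10 * alpha_floor) & (bm > 0)
        # when most guides show no estimable overdispersion the counts are
        # numerically Poisson: the surviving nonzero estimates are pure
        # selection noise and must not define a trend
        majority_poisson = np.median(a_raw) <= 10 * alpha_floor
        if informative.sum() >= 10 and not majority_poisson:
            x_bm, y_a = bm[informative], a_raw[informative]

            def gamma_dev(theta, x, y):
                m = np.exp(theta[0]) + np.exp(theta[1]) / x
                r = y / m
                return np.sum(r - 1.0 - np.log(r))

            def fit_trend(x, y):
                m0 = float(np.mean(y))
                sol = optimize.minimize(
                    gamma_dev, x0=np.log([max(m0, 1e-8), max(m0, 1e-8)]),
                    args=(x, y), method="Nelder-Mead",
                    options={"xatol": 1e-8, "fatol": 1e-12, "maxiter": 2000},
                )
                return np.exp(sol.x)

            trend_a0, trend_a1 = fit_trend(x_bm, y_a)
            resid = np.log(y_a) - np.log(trend_a0 + trend_a1 / x_bm)
            keep = np.abs(resid) < 3.0
            if keep.sum() >= 10 and not keep.all():
                trend_a0, trend_a1 = fit_trend(x_bm[keep], y_a[keep])
        else:
            # dispersion signal indistinguishable from Poisson noise
            trend_a0, trend_a1 = alpha_floor, 0.0

        # shrink: maximise profile loglik + normal prior on log alpha
        log_tr = np.log(trend_a0 + trend_a1 / np.maximum(bm, 1e-12))
        grid = np.linspace(np.log(alpha_floor), np.log(100.0), 121)
        post = np.empty((work.sum(), grid.size))
        for k, la in enumerate(grid):
            a = np.full(work.sum(), np.exp(la))
            ll = _nb_loglik(Yw, mu, a) + _cr_adjustment(mu, a, X)
            post[:, k] = ll - (la - log_tr) ** 2 / (2.0 * prior_var)
        a_map = np.exp(grid[np.argmax(post, axis=1)])
        lo = np.minimum(np.log(a_raw), log_tr)
        hi = np.maximum(np.log(a_raw), log_tr)
        a_final = np.exp(np.clip(np.log(a_map), lo, hi))
        a_final[a_final < 10 * alpha_floor] = alpha_floor
        alpha_final = np.full(G, np.nan)
        alpha_final[work] = a_final
    else:
        trend_a0, trend_a1 = alpha_floor, 0.0
        alpha_final = np.full(G, np.nan)

    return DispersionModel(
        alpha_raw=alpha_raw,
        alpha_final=alpha_final,
        trend_a0=float(trend_a0),
        trend_a1=float(trend_a1),
        base_mean=base_mean,
        prior_var=prior_var,
        alpha_floor=alpha_floor,
        excluded=excluded,
    )


def paired_nb_wald(
    counts: pd.DataFrame,
    norm: np.ndarray,
    disp: DispersionModel,
    samples: pd.DataFrame,
    gene_map: pd.Series | None = None,
) -> pd.DataFrame:
    """Donor-blocked NB Wald test of HIGH vs LOW per guide.

    Returns a frame with unshrunk log2FC, SE, Wald statistic, two-sided and
    one-sided p-values and BH-adjusted p.  All-zero or non-converged guides
    carry NaN statistics and ``excluded=True``.
    """
    validate_paired_design(samples)
    Y = counts.to_numpy(dtype=float)
    X, names = design_matrix(samples)
    offset = np.log(norm)
    G = Y.shape[0]
    bin_ix = len(names) - 1

    excluded = disp.excluded.copy()
    beta2 = np.full(G, np.nan)
    se2 = np.full(G, np.nan)
    stat = np.full(G, np.nan)
    work = ~excluded
    if work.any():
        alpha = disp.alpha_final[work]
        beta, cov, ok = _nb_irls(Y[work], X, offset, alpha)
        b = beta[:, bin_ix]
        v = cov[:, bin_ix, bin_ix]
        se = np.sqrt(np.maximum(v, 1e-300))
        widx = np.where(work)[0]
        beta2[widx] = b / LN2
        se2[widx] = se / LN2
        stat[widx] = b / se
        excluded[widx[~ok]] = True
        beta2[widx[~ok]] = np.nan
        se2[widx[~ok]] = np.nan
        stat[widx[~ok]] = np.nan

    p_high = stats.norm.sf(stat)
    p_low = stats.norm.cdf(stat)
    pvalue = 2.0 * np.minimum(p_high, p_low)
    out = pd.DataFrame(
        {
            "guide_id": counts.index,
            "baseMean": disp.base_mean,
            "log2FC": beta2,
            "SE": se2,
            "stat": stat,
            "pvalue": pvalue,
            "p_high": p_high,
            "p_low": p_low,
            "dispersion": disp.alpha_final,
            "excluded": excluded,
        }
    ).set_index("guide_id")
    out.loc[excluded, ["pvalue", "p_high", "p_low"]] = np.nan
    out["padj"] = bh_adjust(out["pvalue"].to_numpy())
    if gene_map is not None:
        out.insert(0, "target_gene", gene_map.reindex(out.index))
    return out


def bh_adjust(p) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values.

    Missing values are propagated and excluded from the family size.
    """
    p = np.asarray(p, dtype=float)
    out = np.full(p.shape, np.nan)
    ok = ~np.isnan(p)
    m = int(ok.sum())
    if m == 0:
        return out
    ps = p[ok]
    order = np.argsort(ps, kind="mergesort")
    ranked = ps[order] * m / np.arange(1, m + 1)
    adj = np.minimum.accumulate(ranked[::-1])[::-1]
    vals = np.empty(m)
    vals[order] = np.minimum(adj, 1.0)
    out[ok] = vals
    return out


class GuideEnrichment:
    """Paired NB enrichment model for a sorted-bin screen.

    Parameters
    ----------
    counts
        Guide x sample integer counts (DataFrame, guides as the index).
    samples
        Sample sheet with ``sample_id``, ``donor`` and ``bin`` columns;
        every donor must appear in both LOW and HIGH bins.
    gene_map
        Optional guide_id -> gene symbol mapping carried into the results.
    """

    def __init__(
        self,
        counts: pd.DataFrame,
        samples: pd.DataFrame,
        gene_map: pd.Series | None = None,
        prior_var: float = 0.25,
        alpha_floor: float = 1e-8,
    ):
        samples = samples.reset_index(drop=True)
        validate_paired_design(samples)
        self.counts = counts.loc[:, samples["sample_id"]]
        self.samples = samples
        self.gene_map = gene_map
        self.prior_var = prior_var
        self.alpha_floor = alpha_floor

    @classmethod
    def from_count_matrix(cls, cm: CountMatrix, library=None, **kwargs):
        gene_map = library.gene_map() if library is not None else None
        return cls(cm.counts, cm.samples, gene_map=gene_map, **kwargs)

    def fit(self) -> "GuideEnrichmentResults":
        s = size_factors(self.counts)
        disp = fit_dispersions(
            self.counts, s, self.samples,
            prior_var=self.prior_var, alpha_floor=self.alpha_floor,
        )
        guide_stats = paired_nb_wald(
            self.counts, s, disp, self.samples, gene_map=self.gene_map
        )
        return GuideEnrichmentResults(self, s, disp, guide_stats)


class GuideEnrichmentResults:
    """Fitted per-guide enrichment statistics.

    Attributes
    ----------
    guide_stats : pandas.DataFrame
        One row per guide: baseMean, unshrunk log2FC (HIGH vs LOW), SE,
        Wald statistic, two-sided/one-sided p, BH-adjusted p, dispersion,
        exclusion flag.
    size_factors : pandas.Series
    dispersion : DispersionModel
    """

    def __init__(self, model, s, disp, guide_stats):
        self.model = model
        self.size_factors = pd.Series(s, index=model.samples["sample_id"])
        self.dispersion = disp
        self.guide_stats = guide_stats

    @property
    def n_excluded(self) -> int:
        return int(self.guide_stats["excluded"].sum())

    def summary(self, alpha: float = 0.05) -> str:
        gs = self.guide_stats
        tested = gs[~gs["excluded"]]
        up = int(((tested["padj"] < alpha) & (tested["log2FC"] > 0)).sum())
        dn = int(((tested["padj"] < alpha) & (tested["log2FC"] < 0)).sum())
        lines = [
            "Paired NB guide enrichment (HIGH vs LOW)",
            "=" * 44,
            f"guides:               {len(gs)}",
            f"tested:               {len(tested)}",
            f"excluded:             {self.n_excluded}",
            f"samples:              {len(self.model.samples)} "
            f"({self.model.samples['donor'].nunique()} donors)",
            f"size factors:         {self.size_factors.min():.3f} .. "
            f"{self.size_factors.max():.3f}",
            f"median dispersion:    {np.nanmedian(self.dispersion.alpha_final):.4g}",
            f"enriched in HIGH:     {up}  (padj < {alpha})",
            f"enriched in LOW:      {dn}  (padj < {alpha})",
        ]
        return "\n".join(lines)

    def plot_volcano(self, ax=None, alpha: float = 0.05):
        """log2FC vs -log10 p, significant guides highlighted."""
        import matplotlib.pyplot as plt

        if ax is None:
            _, ax = plt.subplots()
        gs = self.guide_stats.dropna(subset=["pvalue"])
        sig = gs["padj"] < alpha
        ax.scatter(gs["log2FC"][~sig], -np.log10(gs["pvalue"][~sig]),
                   s=6, c="0.6", label="n.s.")
        ax.scatter(gs["log2FC"][sig], -np.log10(gs["pvalue"][sig]),
                   s=8, c="firebrick", label=f"padj < {alpha}")
        ax.set_xlabel("log2 fold change (HIGH vs LOW)")
        ax.set_ylabel("-log10 p")
        ax.legend(frameon=False)
        return ax

    def to_tsv(self, path) -> None:
        self.guide_stats.to_csv(path, sep="\t")
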