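"""Statistical analyses for band morphometrics.

Nonparametric group comparisons (Mann-Whitney, Kruskal-Wallis with Dunn's
pairwise follow-up and Benjamini-Hochberg adjustment, mean-centered
Kolmogorov-Smirnov, Wilcoxon signed-rank), the band/gap correlation
matrix, Bland-Altman method agreement, one-dimensional Gaussian-mixture
modality selection by BIC, and linear-mixed-model machinery: AIC model-set
averaging with full (zero-substitution) coefficients, fixed-effect
deletion likelihood-ratio tests, and least-square means with Tukey-
adjusted pairwise contrasts.

Conventions: all tests are two-sided unless stated otherwise; the
Mann-Whitney statistic is reported in the rank-sum-derived W convention
(``W = R_x - n_x (n_x + 1) / 2``, identical to the U count of ``x_i <
y_j`` pairs with half-credit for ties); BIC here is ``2 logL - k ln n``
and is maximized.
"""

from __future__ import annotations

import itertools
import math
import warnings
from dataclasses import dataclass, field
from typing import Iterable, Optional, Sequence

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.mixture import GaussianMixture
import statsmodels.api as sm
import statsmodels.formula.api as smf
from statsmodels.stats.multitest import multipletests
from statsmodels.tools.sm_exceptions import ConvergenceWarning

__all__ = [
    "TestResult",
    "BlandAltmanResult",
    "MixtureResult",
    "ModelAverageRow",
    "mann_whitney",
    "kruskal_wallis",
    "dunn_bh",
    "bh_adjust",
    "ks_centered",
    "wilcoxon_signed_rank",
    "band_gap_correlations",
    "bland_altman",
    "gmm_1d",
    "aic_model_average",
    "lrt_fixed",
    "emmeans_tukey",
]


@dataclass
class TestResult:
    """A single test statistic with raw (and optionally adjusted) p-value."""

    statistic: str  # W | H | Z | D | V | chi_sq | R ...
    value: float
    p: float
    df: Optional[float] = None
    p_adjusted: Optional[float] = None
    group_sizes: tuple[int, ...] = ()
    note: str = ""
    extra: dict = field(default_factory=dict)

    def __repr__(self) -> str:  # compact, paper-style
        s = f"{self.statistic} = {self.value:.4g}"
        if self.df is not None:
            s += f", df = {self.df:g}"
        s += f", p = {self.p:.4g}"
        if self.p_adjusted is not None:
            s += f" (adj {self.p_adjusted:.4g})"
        return f"<{s}>"


# ---------------------------------------------------------------------------
# rank-based tests

def mann_whitney(x, y, alternative: str = "two-sided") -> TestResult:
    """Mann-Whitney U test, reported in the W (rank-sum) convention.

    ``W = U = #{(i, j): x_i < y_j} + ties/2``.  The p-value is exact (by
    enumeration over rank assignments) when both groups have at most 8
    observations and there are no ties, otherwise the normal approximation
    with tie and continuity corrections is used.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size == 0 or y.size == 0:
        raise ValueError("both samples must be non-empty")
    has_ties = len(np.unique(np.concatenate([x, y]))) < x.size + y.size
    exact = x.size <= 8 and y.size <= 8 and not has_ties
    res = stats.mannwhitneyu(
        x, y, alternative=alternative, method="exact" if exact else "asymptotic"
    )
    # scipy's statistic is R_x - n_x(n_x+1)/2, the rank-sum W convention;
    # the complementary count of (x_i < y_j) pairs is also reported
    w = float(res.statistic)
    return TestResult(
        statistic="W",
        value=w,
        p=float(res.pvalue),
        group_sizes=(x.size, y.size),
        note="exact" if exact else "normal approximation",
        extra={"U": x.size * y.size - w},
    )


def kruskal_wallis(*groups) -> TestResult:
    """Kruskal-Wallis H with tie correction and chi-squared p-value."""
    if len(groups) == 1 and isinstance(groups[0], (list, tuple)) and not np.isscalar(groups[0][0]):
        groups = tuple(groups[0])
    if len(groups) < 2:
        raise ValueError("need at least two groups")
    arrays = [np.asarray(g, dtype=float) for g in groups]
    if np.ptp(np.concatenate(arrays)) == 0:
        # every observation identical: H = 0 by convention
        return TestResult(
            statistic="H",
            value=0.0,
            p=1.0,
            df=len(arrays) - 1,
            group_sizes=tuple(a.size for a in arrays),
            note="all values identical",
        )
    h, p = stats.kruskal(*arrays)
    return TestResult(
        statistic="H",
        value=float(h),
        p=float(p),
        df=len(arrays) - 1,
        group_sizes=tuple(a.size for a in arrays),
    )


def dunn_bh(*groups, labels: Optional[Sequence[str]] = None) -> list[tuple[str, str, TestResult]]:
    """Dunn's pairwise z-tests after Kruskal-Wallis, BH-adjusted.

    ``Z_ij = (rbar_i - rbar_j) / sqrt[(N(N+1)/12 - T)(1/n_i + 1/n_j)]``
    with the tie term ``T = sum(t^3 - t) / (12 (N - 1))``; two-sided
    normal p-values are Benjamini-Hochberg adjusted across the family of
    all pairs from one omnibus test.
    """
    if len(groups) == 1 and isinstance(groups[0], (list, tuple)) and not np.isscalar(groups[0][0]):
        groups = tuple(groups[0])
    if len(groups) < 2:
        raise ValueError("need at least two groups")
    arrays = [np.asarray(g, dtype=float) for g in groups]
    if labels is None:
        labels = [f"group{i + 1}" for i in range(len(arrays))]
    pooled = np.concatenate(arrays)
    n_total = pooled.size
    ranks = stats.rankdata(pooled)
    mean_ranks = []
    start = 0
    for a in arrays:
        mean_ranks.append(ranks[start : start + a.size].mean())
        start += a.size
    _, tie_counts = np.unique(pooled, return_counts=True)
    tie_term = np.sum(tie_counts**3 - tie_counts) / (12.0 * (n_total - 1))
    var_base = n_total * (n_total + 1) / 12.0 - tie_term

    results = []
    zs, ps = [], []
    for i, j in itertools.combinations(range(len(arrays)), 2):
        se = math.sqrt(var_base * (1.0 / arrays[i].size + 1.0 / arrays[j].size))
        z = (mean_ranks[i] - mean_ranks[j]) / se
        p = 2.0 * stats.norm.sf(abs(z))
        zs.append(z)
        ps.append(p)
        results.append((labels[i], labels[j], i, j, z, p))
    adj = bh_adjust(ps)
    out = []
    for (li, lj, i, j, z, p), pa in zip(results, adj):
        out.append(
            (
                li,
                lj,
                TestResult(
                    statistic="Z",
                    value=float(z),
                    p=float(p),
                    p_adjusted=float(pa),
                    group_sizes=(arrays[i].size, arrays[j].size),
                ),
            )
        )
    return out


def bh_adjust(pvals) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values, clipped at 1."""
    p = np.asarray(pvals, dtype=float)
    if np.any((p < 0) | (p > 1)):
        raise ValueError("p-values must lie in [0, 1]")
    if p.size == 0:
        return p.copy()
    return multipletests(p, method="fdr_bh")[1]


def ks_centered(x, y) -> TestResult:
    """Two-sample Kolmogorov-Smirnov after subtracting each sample's mean.

    Removes a pure location difference so the test compares distribution
    shape and spread; degenerate zero-variance inputs give D = 0, flagged.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size < 2 or y.size < 2:
        raise ValueError("need at least two observations per sample")
    xc, yc = x - x.mean(), y - y.mean()
    if np.ptp(xc) == 0 and np.ptp(yc) == 0:
        return TestResult(
            statistic="D",
            value=0.0,
            p=1.0,
            group_sizes=(x.size, y.size),
            note="degenerate: both samples constant",
        )
    res = stats.ks_2samp(xc, yc, method="asymp")
    return TestResult(
        statistic="D",
        value=float(res.statistic),
        p=float(res.pvalue),
        group_sizes=(x.size, y.size),
    )


def _signed_rank_exact_p(ranks: np.ndarray, v: float, alternative: str) -> float:
    """Exact signed-rank p by enumerating all 2^n sign assignments."""
    n = ranks.size
    signs = np.array(
        np.meshgrid(*[[0.0, 1.0]] * n, indexing="ij")
    ).reshape(n, -1)
    v_all = ranks @ signs
    p_ge = np.mean(v_all >= v - 1e-12)
    p_le = np.mean(v_all <= v + 1e-12)
    if alternative == "greater":
        return float(p_ge)
    if alternative == "less":
        return float(p_le)
    return float(min(1.0, 2.0 * min(p_ge, p_le)))


def wilcoxon_signed_rank(
    differences, alternative: str = "two-sided"
) -> TestResult:
    """Wilcoxon signed-rank test on paired differences.

    ``V`` is the sum of ranks of the positive differences after dropping
    zeros.  The p-value is exact (enumeration of all sign assignments) for
    n <= 15, else a normal approximation with tie correction and
    continuity correction.  All-zero differences give a flagged degenerate
    result rather than raising.
    """
    d = np.asarray(differences, dtype=float)
    d = d[d != 0]
    n = d.size
    if n == 0:
        return TestResult(
            statistic="V",
            value=0.0,
            p=1.0,
            group_sizes=(0,),
            note="degenerate: all differences zero",
        )
    ranks = stats.rankdata(np.abs(d))
    v = float(ranks[d > 0].sum())
    if n <= 15:
        p = _signed_rank_exact_p(ranks, v, alternative)
        note = "exact"
    else:
        mu = n * (n + 1) / 4.0
        _, tie_counts = np.unique(np.abs(d), return_counts=True)
        sigma2 = n * (n + 1) * (2 * n + 1) / 24.0 - np.sum(
            tie_counts**3 - tie_counts
        ) / 48.0
        sigma = math.sqrt(sigma2)
        if alternative == "greater":
            p = stats.norm.sf((v - mu - 0.5) / sigma)
        elif alternative == "less":
            p = stats.norm.cdf((v - mu + 0.5) / sigma)
        else:
            z = (v - mu - 0.5 * np.sign(v - mu)) / sigma
            p = 2.0 * stats.norm.sf(abs(z))
        note = "normal approximation"
    return TestResult(
        statistic="V", value=v, p=float(min(p, 1.0)), group_sizes=(n,), note=note
    )


# ---------------------------------------------------------------------------
# correlation structure and method agreement

def band_gap_correlations(
    table: pd.DataFrame, columns: Optional[Sequence[str]] = None, adjust: bool = False
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Pearson correlations between all band widths and gap widths.

    *table* is a standardized analysis table; by default the 11 columns
    ``b1_w..b5_w, g1_w..g6_w`` are used.  Pairwise deletion handles
    missing values; cells with fewer than 3 complete pairs are NaN.
    Returns ``(R, p)`` as symmetric DataFrames with unit diagonal; raw
    p-values by default, BH-adjusted (off-diagonal family) if *adjust*.
    """
    if columns is None:
        columns = [f"b{i}_w" for i in range(1, 6)] + [f"g{j}_w" for j in range(1, 7)]
    k = len(columns)
    r_mat = np.full((k, k), np.nan)
    p_mat = np.full((k, k), np.nan)
    np.fill_diagonal(r_mat, 1.0)
    np.fill_diagonal(p_mat, 0.0)
    pairs = []
    for i, j in itertools.combinations(range(k), 2):
        xi = table[columns[i]].to_numpy(dtype=float)
        xj = table[columns[j]].to_numpy(dtype=float)
        ok = np.isfinite(xi) & np.isfinite(xj)
        if ok.sum() < 3:
            continue
        r, p = stats.pearsonr(xi[ok], xj[ok])
        r_mat[i, j] = r_mat[j, i] = r
        p_mat[i, j] = p_mat[j, i] = p
        pairs.append((i, j, p))
    if adjust and pairs:
        adj = bh_adjust([p for _, _, p in pairs])
        for (i, j, _), pa in zip(pairs, adj):
            p_mat[i, j] = p_mat[j, i] = pa
    return (
        pd.DataFrame(r_mat, index=columns, columns=columns),
        pd.DataFrame(p_mat, index=columns, columns=columns),
    )


@dataclass
class BlandAltmanResult:
    """Bias and 95% limits of agreement between two measurement methods."""

    bias: float
    sd: float
    loa_lower: float
    loa_upper: float
    n: int
    table: pd.DataFrame = field(repr=False, default=None)

    def plot(self, path=None):
        """Bland-Altman scatter with bias and limits of agreement."""
        import matplotlib

        matplotlib.use("Agg")
        import matplotlib.pyplot as plt

        fig, ax = plt.subplots(figsize=(6, 4))
        ax.scatter(self.table["mean"], self.table["difference"], s=12, alpha=0.6)
        ax.axhline(self.bias, color="k", linestyle="--", label=f"bias = {self.bias:.3f}")
        for loa in (self.loa_lower, self.loa_upper):
            ax.axhline(loa, color="r", linestyle=":")
        ax.set_xlabel("mean of methods")
        ax.set_ylabel("difference (a - b)")
        ax.legend()
        if path is not None:
            fig.savefig(path, dpi=150, bbox_inches="tight")
            plt.close(fig)
        return fig


def bland_altman(method_a, method_b) -> BlandAltmanResult:
    """Bland-Altman agreement: bias = mean(a - b), LoA = bias +/- 1.96 sd.

    The standard deviation of the differences uses n - 1; the per-pair
    (mean, difference) table is kept for plotting.
    """
    a = np.asarray(method_a, dtype=float)
    b = np.asarray(method_b, dtype=float)
    if a.shape != b.shape or a.ndim != 1:
        raise ValueError("method_a and method_b must be equal-length 1-D arrays")
    if a.size < 2:
        raise ValueError("need at least two pairs")
    diff = a - b
    bias = float(diff.mean())
    sd = float(diff.std(ddof=1))
    table = pd.DataFrame({"mean": (a + b) / 2.0, "difference": diff})
    return BlandAltmanResult(
        bias=bias,
        sd=sd,
        loa_lower=bias - 1.96 * sd,
        loa_upper=bias + 1.96 * sd,
        n=a.size,
        table=table,
    )


# ---------------------------------------------------------------------------
# Gaussian mixture modality

@dataclass
class MixtureResult:
    """BIC-selected univariate Gaussian mixture over k = 1..k_max.

    ``bic_table`` has one row per (k, family) with log-likelihood and
    ``BIC = 2 logL - n_params ln n`` (maximize); families are "equal"
    (shared variance) and "free" (per-component variance).
    """

    bic_table: pd.DataFrame
    selected_k: int
    selected_family: str
    means: np.ndarray
    sds: np.ndarray
    weights: np.ndarray


def gmm_1d(x, k_max: int = 3, seed: int = 0, n_restarts: int = 5) -> MixtureResult:
    """Fit 1-D Gaussian mixtures for k = 1..k_max and select by BIC.

    Each (k, family) model is fitted by EM with k-quantile mean
    initialization plus jittered restarts; deterministic for a given seed.
    The selected model maximizes ``2 logL - n_params ln n``.
    """
    x = np.asarray(x, dtype=float).reshape(-1, 1)
    n = x.shape[0]
    if n < 10:
        raise ValueError("need at least 10 observations")
    rng = np.random.default_rng(seed)
    sd0 = x.std()
    rows = []
    best = None
    for k in range(1, k_max + 1):
        base_means = np.quantile(x, (np.arange(k) + 0.5) / k).reshape(-1, 1)
        for family, cov_type in (("equal", "tied"), ("free", "full")):
            best_fit = None
            for j in range(1 + n_restarts):
                means_init = base_means.copy()
                if j > 0:
                    means_init = means_init + rng.normal(0, 0.1 * sd0, means_init.shape)
                gm = GaussianMixture(
                    n_components=k,
                    covariance_type=cov_type,
                    means_init=means_init,
                    random_state=int(rng.integers(2**31 - 1)),
                    max_iter=500,
                    n_init=1,
                )
                try:
                    with warnings.catch_warnings():
                        warnings.simplefilter("ignore")
                        gm.fit(x)
                except Exception:
                    continue
                if not gm.converged_ and k > 1:
                    continue
                if best_fit is None or gm.score(x) > best_fit.score(x):
                    best_fit = gm
            if best_fit is None:
                continue
            logl = float(best_fit.score(x) * n)
            # free params: k means + weights (k-1) + variances (1 or k)
            n_params = k + (k - 1) + (1 if family == "equal" else k)
            bic = 2.0 * logl - n_params * math.log(n)
            rows.append((k, family, logl, n_params, bic))
            if best is None or bic > best[4]:
                best = (k, family, logl, n_params, bic, best_fit)
    if best is None:
        raise RuntimeError("no mixture fit converged")
    table = pd.DataFrame(rows, columns=["k", "family", "logL", "n_params", "bic"])
    k, family, *_rest, fit = best
    if fit.covariance_type == "tied":
        variances = np.repeat(float(np.ravel(fit.covariances_)[0]), k)
    else:
        variances = np.ravel(fit.covariances_)
    order = np.argsort(fit.means_.ravel())
    return MixtureResult(
        bic_table=table,
        selected_k=int(k),
        selected_family=family,
        means=fit.means_.ravel()[order],
        sds=np.sqrt(variances[order]),
        weights=fit.weights_[order],
    )


# ---------------------------------------------------------------------------
# mixed-model machinery: AIC averaging, deletion tests, ls-means

@dataclass
class ModelAverageRow:
    """One term of an AIC-averaged model (full/zero-substitution average)."""

    term: str
    coefficient: float
    ci_lower: float
    ci_upper: float
    weight: float  # summed Akaike weight of models containing the term


def _admissible_models(fixed_terms: Sequence[str], interactions: bool) -> list[tuple[str, ...]]:
    """All fixed-effect subsets; interactions only when both parents present."""
    models = []
    mains = list(fixed_terms)
    for r in range(len(mains) + 1):
        for main_set in itertools.combinations(mains, r):
            if not interactions:
                models.append(tuple(main_set))
                continue
            pairs = list(itertools.combinations(main_set, 2))
            for rr in range(len(pairs) + 1):
                for inter_set in itertools.combinations(pairs, rr):
                    terms = tuple(main_set) + tuple(f"{a}:{b}" for a, b in inter_set)
                    models.append(terms)
    return models


def _fit_mixed(table: pd.DataFrame, response: str, terms: Sequence[str], random: Optional[str]):
    """ML fit of a linear (mixed) model; returns the results object."""
    rhs = " + ".join(terms) if terms else "1"
    formula = f"{response} ~ {rhs}"
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", ConvergenceWarning)
        warnings.simplefilter("ignore", RuntimeWarning)
        warnings.simplefilter("ignore", UserWarning)
        if random is None:
            return smf.ols(formula, data=table).fit()
        model = smf.mixedlm(formula, data=table, groups=table[random])
        return model.fit(reml=False)


def _model_aic(result) -> float:
    """AIC from the ML log-likelihood, counting all estimated parameters.

    ``result.params`` holds the fixed effects (plus the random-intercept
    variance for mixed fits); the residual variance adds one more.
    """
    k = len(result.params) + 1
    return float(-2.0 * result.llf + 2.0 * k)


def aic_model_average(
    table: pd.DataFrame,
    response: str,
    fixed_terms: Sequence[str] = ("shape", "height_mm", "weight_g"),
    random: Optional[str] = "population",
    interactions: bool = True,
    delta_max: float = 2.0,
) -> list[ModelAverageRow]:
    """Fit all admissible fixed-effect subsets and average the top AIC set.

    Every combination of the fixed terms (pairwise interactions included
    only when both parents are present) is fitted as a linear mixed model
    with a random intercept for *random* (ML, so AICs are comparable).
    Models within *delta_max* AIC of the best are averaged with Akaike
    weights; full-coefficient averaging assigns zero to a term in models
    that exclude it.  Reported per term: averaged coefficient, 95% CI from
    the unconditional (model-averaged) variance, and the summed weight of
    models containing the term.
    """
    data = table.dropna(subset=[response, *fixed_terms]).copy()
    fits = []
    for terms in _admissible_models(fixed_terms, interactions):
        try:
            res = _fit_mixed(data, response, terms, random)
        except Exception:
            continue
        if not np.isfinite(res.llf):
            continue
        fits.append((terms, res, _model_aic(res)))
    if not fits:
        raise RuntimeError("all candidate models failed to fit")
    aics = np.array([a for _, _, a in fits])
    best_aic = aics.min()
    selected = [(t, r, a) for (t, r, a) in fits if a - best_aic <= delta_max]
    deltas = np.array([a - best_aic for _, _, a in selected])
    w = np.exp(-deltas / 2.0)
    w = w / w.sum()

    all_terms: list[str] = ["Intercept"]
    for terms, res, _ in selected:
        for name in res.params.index if hasattr(res.params, "index") else []:
            if name not in all_terms and name not in ("Group Var",):
                all_terms.append(name)

    rows = []
    for term in all_terms:
        betas = np.zeros(len(selected))
        variances = np.zeros(len(selected))
        contains = np.zeros(len(selected), dtype=bool)
        for i, (terms, res, _) in enumerate(selected):
            params = res.params
            if term in params.index:
                betas[i] = params[term]
                se = res.bse[term]
                variances[i] = se**2
                contains[i] = True
        beta_avg = float(np.sum(w * betas))
        var_avg = float(np.sum(w * (variances + (betas - beta_avg) ** 2)))
        se_avg = math.sqrt(var_avg)
        rows.append(
            ModelAverageRow(
                term=term,
                coefficient=beta_avg,
                ci_lower=beta_avg - 1.96 * se_avg,
                ci_upper=beta_avg + 1.96 * se_avg,
                weight=float(w[contains].sum()),
            )
        )
    return rows


def lrt_fixed(
    table: pd.DataFrame,
    response: str,
    fixed: Sequence[str],
    drop: str,
    random: Optional[str] = "population",
) -> TestResult:
    """Likelihood-ratio test of deleting one fixed term from an ML fit.

    Returns chi-squared = 2 * delta logL with df = the number of design
    columns removed, plus the AIC change of the deletion (positive delta
    AIC means the term improves the model).
    """
    if drop not in fixed:
        raise ValueError(f"term {drop!r} not among fixed terms {list(fixed)}")
    reduced_terms = [t for t in fixed if t != drop]
    data = table.dropna(subset=[response, *_term_columns(fixed)]).copy()
    full = _fit_mixed(data, response, fixed, random)
    reduced = _fit_mixed(data, response, reduced_terms, random)
    df = int(_n_fixed_params(full) - _n_fixed_params(reduced))
    chi2 = max(0.0, 2.0 * (full.llf - reduced.llf))
    p = float(stats.chi2.sf(chi2, df)) if df > 0 else 1.0
    delta_aic = _model_aic(reduced) - _model_aic(full)
    return TestResult(
        statistic="chi_sq",
        value=float(chi2),
        p=p,
        df=df,
        group_sizes=(len(data),),
        extra={"delta_aic": float(delta_aic)},
    )


def _term_columns(terms: Sequence[str]) -> list[str]:
    cols = []
    for t in terms:
        for part in t.split(":"):
            base = part
            if base.startswith("C(") and base.endswith(")"):
                base = base[2:-1]
            if base not in cols:
                cols.append(base)
    return cols


def _n_fixed_params(result) -> int:
    names = list(result.params.index)
    return sum(1 for n in names if n != "Group Var")


def emmeans_tukey(
    table: pd.DataFrame,
    response: str,
    factor: str,
    random: Optional[str] = None,
) -> pd.DataFrame:
    """Least-square means and Tukey-adjusted pairwise contrasts.

    Fits ``response ~ C(factor)`` (with an optional random intercept) by
    ML, computes each level's marginal mean, and tests all pairwise
    differences with the studentized-range adjustment.  Returns one row
    per pair: estimate, SE, df, t-ratio and adjusted p.
    """
    data = table.dropna(subset=[response, factor]).copy()
    res = _fit_mixed(data, response, [f"C({factor})"], random)
    levels = sorted(data[factor].unique())
    k = len(levels)
    if k < 2:
        raise ValueError("factor needs at least two levels")

    names = [n for n in res.params.index if n != "Group Var"]
    params = np.asarray([res.params[n] for n in names])
    cov = np.asarray(res.cov_params().loc[names, names])

    def level_vector(level):
        v = np.zeros(len(names))
        for i, name in enumerate(names):
            if name == "Intercept":
                v[i] = 1.0
            elif name == f"C({factor})[T.{level}]":
                v[i] = 1.0
        return v

    n_obs = len(data)
    df_resid = float(n_obs - len(names))
    rows = []
    for la, lb in itertools.combinations(levels, 2):
        c = level_vector(la) - level_vector(lb)
        est = float(c @ params)
        se = float(math.sqrt(c @ cov @ c))
        if se == 0:
            t = 0.0
            p = 1.0
        else:
            t = est / se
            p = float(stats.studentized_range.sf(abs(t) * math.sqrt(2.0), k, df_resid))
        rows.append((la, lb, est, se, df_resid, t, min(p, 1.0)))
    return pd.DataFrame(
        rows, columns=["level_a", "level_b", "estimate", "se", "df", "t_ratio", "p_tukey"]
    )
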