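"""Hypothesis-testing layer for the conformity measures.

Nonparametric tests with rank-based effect sizes and bootstrap confidence
intervals, Dunn-type post-hoc comparisons with Holm correction, Huber robust
regression with a nested-model deviance test, Jeffreys-Zellner-Siow Bayes
factors by numerical integration over the Cauchy effect-size prior, the
noncentral-t power analysis, and the per-allocation norm-rating battery.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import integrate, stats

__all__ = [
    "TestResult",
    "wilcoxon_signed",
    "rank_sum",
    "kruskal_with_posthoc",
    "spearman_assoc",
    "robust_linreg",
    "jzs_bayes_factor",
    "jzs_bayes_factor_from_t",
    "required_sample_size",
    "norm_rating_battery",
    "holm",
]

DEFAULT_RSCALE = math.sqrt(2.0) / 2.0
BOOTSTRAP_REPS = 2000


@dataclass
class TestResult:
    """One test's report: statistic, p, effect size with 95% CI, optional BF."""

    name: str
    statistic_name: str
    statistic: float
    p_value: float
    tails: int
    n: int
    effect_size_name: str | None = None
    effect_size: float | None = None
    ci_low: float | None = None
    ci_high: float | None = None
    bayes_factor: float | None = None
    bayes_factor_kind: str | None = None
    extras: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if not 0.0 <= self.p_value <= 1.0:
            raise ValueError("p-value outside [0, 1]")
        if self.bayes_factor is not None and self.bayes_factor <= 0:
            raise ValueError("Bayes factors are positive")
        if (self.effect_size is not None and self.ci_low is not None
                and not (self.ci_low - 1e-9 <= self.effect_size <= self.ci_high + 1e-9)):
            raise ValueError("effect size outside its confidence interval")

    def to_dict(self) -> dict:
        d = {k: v for k, v in vars(self).items() if k != "extras"}
        d.update(self.extras)
        return d


def holm(pvals: Sequence[float]) -> np.ndarray:
    """Holm step-down adjusted p-values."""
    p = np.asarray(pvals, float)
    order = np.argsort(p)
    adj = np.empty_like(p)
    running = 0.0
    m = len(p)
    for rank, idx in enumerate(order):
        running = max(running, (m - rank) * p[idx])
        adj[idx] = min(1.0, running)
    return adj


def _bootstrap_ci(stat_fn, rng, n, reps=BOOTSTRAP_REPS, level=0.95):
    """Percentile CI over resampled index matrices [reps, n]."""
    idx = rng.integers(0, n, size=(reps, n))
    vals = stat_fn(idx)
    lo, hi = np.nanpercentile(vals, [100 * (1 - level) / 2, 100 * (1 + level) / 2])
    return float(lo), float(hi)


# ---------------------------------------------------------------------------
# Wilcoxon signed-rank

def _signed_rank_stats(v: np.ndarray) -> tuple[float, float]:
    """(T+, T-) with mid-ranks of |v|, zeros dropped beforehand."""
    r = stats.rankdata(np.abs(v))
    t_plus = float(np.sum(r[v > 0]))
    return t_plus, float(np.sum(r) - t_plus)


def _matched_rank_biserial_rows(values: np.ndarray, idx: np.ndarray) -> np.ndarray:
    v = values[idx]
    r = stats.rankdata(np.abs(v), axis=1)
    tot = r.sum(axis=1)
    t_plus = np.sum(r, axis=1, where=v > 0)
    with np.errstate(invalid="ignore"):
        return np.where(tot > 0, (2 * t_plus - tot) / tot, np.nan)


def wilcoxon_signed(
    values: Sequence[float],
    mu0: float = 0.0,
    alternative: str = "two-sided",
    seed: int | np.random.Generator = 0,
    name: str = "wilcoxon_signed",
    ci_reps: int = BOOTSTRAP_REPS,
) -> TestResult:
    """One-sample Wilcoxon signed-rank test against ``mu0``.

    Exact null distribution for n <= 25 (without ties), otherwise a normal
    approximation with continuity correction.  The effect size is the matched
    rank-biserial correlation (T+ - T-)/(T+ + T-) with a seeded percentile
    bootstrap CI, and ``extras["log_V"]`` reports the natural log of the
    signed-rank statistic V = T+ as in the field's reporting convention.
    """
    v = np.asarray(values, float) - mu0
    v = v[v != 0]
    n = len(v)
    if n < 5:
        raise ValueError("need at least 5 nonzero values")
    has_ties = len(np.unique(np.abs(v))) < n
    method = "exact" if (n <= 25 and not has_ties) else "approx"
    res = stats.wilcoxon(v, alternative=alternative, method=method,
                         correction=(method == "approx"))
    t_plus, t_minus = _signed_rank_stats(v)
    r = (t_plus - t_minus) / (t_plus + t_minus)
    lo = hi = None
    if ci_reps > 0:
        rng = np.random.default_rng(seed)
        lo, hi = _bootstrap_ci(lambda idx: _matched_rank_biserial_rows(v, idx),
                               rng, n, reps=ci_reps)
        lo, hi = min(lo, r), max(hi, r)
    return TestResult(
        name=name, statistic_name="V", statistic=t_plus,
        p_value=float(res.pvalue), tails=2 if alternative == "two-sided" else 1,
        n=n, effect_size_name="rank_biserial", effect_size=float(r),
        ci_low=lo, ci_high=hi,
        extras={"log_V": math.log(t_plus) if t_plus > 0 else -math.inf,
                "method": method},
    )


def rank_sum(
    x: Sequence[float], y: Sequence[float],
    alternative: str = "two-sided",
    seed: int | np.random.Generator = 0,
    name: str = "rank_sum",
) -> TestResult:
    """Wilcoxon rank-sum (Mann-Whitney) with Glass rank-biserial effect size."""
    x, y = np.asarray(x, float), np.asarray(y, float)
    res = stats.mannwhitneyu(x, y, alternative=alternative)
    n1, n2 = len(x), len(y)
    r = 1.0 - 2.0 * float(res.statistic) / (n1 * n2)

    rng = np.random.default_rng(seed)
    reps = 500
    boots = np.empty(reps)
    for b in range(reps):
        xb = x[rng.integers(0, n1, n1)]
        yb = y[rng.integers(0, n2, n2)]
        u = stats.mannwhitneyu(xb, yb).statistic
        boots[b] = 1.0 - 2.0 * float(u) / (n1 * n2)
    lo, hi = map(float, np.percentile(boots, [2.5, 97.5]))
    lo, hi = min(lo, r), max(hi, r)
    return TestResult(
        name=name, statistic_name="U", statistic=float(res.statistic),
        p_value=float(res.pvalue), tails=2 if alternative == "two-sided" else 1,
        n=n1 + n2, effect_size_name="rank_biserial", effect_size=r,
        ci_low=lo, ci_high=hi,
        extras={"log_W": math.log(res.statistic) if res.statistic > 0 else -math.inf},
    )


# ---------------------------------------------------------------------------
# Kruskal-Wallis + Dunn post-hoc

def _epsilon_squared(h: float, n: int) -> float:
    return h / (n - 1)


def _dunn_pairwise(groups: Sequence[np.ndarray], correction: str = "holm"
                   ) -> pd.DataFrame:
    pooled = np.concatenate(groups)
    n = len(pooled)
    ranks = stats.rankdata(pooled)
    # tie correction to the rank variance
    _, counts = np.unique(pooled, return_counts=True)
    tie = np.sum(counts ** 3 - counts) / (12.0 * (n - 1))
    var_base = n * (n + 1) / 12.0 - tie
    means, sizes = [], []
    pos = 0
    for g in groups:
        means.append(ranks[pos:pos + len(g)].mean())
        sizes.append(len(g))
        pos += len(g)
    rows = []
    for i in range(len(groups)):
        for j in range(i + 1, len(groups)):
            se = math.sqrt(var_base * (1.0 / sizes[i] + 1.0 / sizes[j]))
            z = (means[i] - means[j]) / se
            rows.append({"group_i": i, "group_j": j, "z": z,
                         "p_raw": 2.0 * stats.norm.sf(abs(z))})
    df = pd.DataFrame(rows)
    if correction == "holm":
        df["p_corrected"] = holm(df["p_raw"].to_numpy())
    elif correction == "bonferroni":
        df["p_corrected"] = np.minimum(1.0, df["p_raw"] * len(df))
    else:
        raise ValueError(f"unknown correction {correction!r}")
    return df


def kruskal_with_posthoc(
    groups: Sequence[Sequence[float]],
    correction: str = "holm",
    seed: int | np.random.Generator = 0,
    name: str = "kruskal",
    ci_reps: int = BOOTSTRAP_REPS,
) -> tuple[TestResult, pd.DataFrame]:
    """Tie-corrected Kruskal-Wallis H with epsilon-squared effect size and
    Dunn-type pairwise z tests under the requested multiplicity correction."""
    gs = [np.asarray(g, float) for g in groups]
    if len(gs) < 2 or any(len(g) < 3 for g in gs):
        raise ValueError("need >= 2 groups of >= 3 observations")
    h, p = stats.kruskal(*gs)
    n = sum(len(g) for g in gs)
    eps2 = _epsilon_squared(float(h), n)

    lo = hi = None
    if ci_reps > 0:
        rng = np.random.default_rng(seed)
        boots = np.empty(ci_reps)
        for b in range(ci_reps):
            res = [g[rng.integers(0, len(g), len(g))] for g in gs]
            try:
                hb, _ = stats.kruskal(*res)
            except ValueError:  # all values identical in a resample
                hb = 0.0
            boots[b] = _epsilon_squared(float(hb), n)
        lo, hi = np.percentile(boots, [2.5, 97.5])
        lo, hi = min(float(lo), eps2), max(float(hi), eps2)

    result = TestResult(
        name=name, statistic_name="H", statistic=float(h), p_value=float(p),
        tails=2, n=n, effect_size_name="epsilon_squared", effect_size=eps2,
        ci_low=lo, ci_high=hi, extras={"df": len(gs) - 1},
    )
    return result, _dunn_pairwise(gs, correction)


# ---------------------------------------------------------------------------
# Spearman

def _spearman_rows(x, y, idx):
    xr = stats.rankdata(x[idx], axis=1)
    yr = stats.rankdata(y[idx], axis=1)
    xr = xr - xr.mean(axis=1, keepdims=True)
    yr = yr - yr.mean(axis=1, keepdims=True)
    num = np.sum(xr * yr, axis=1)
    den = np.sqrt(np.sum(xr ** 2, axis=1) * np.sum(yr ** 2, axis=1))
    with np.errstate(invalid="ignore"):
        return np.where(den > 0, num / den, np.nan)


def spearman_assoc(
    x: Sequence[float], y: Sequence[float],
    alternative: str = "two-sided",
    seed: int | np.random.Generator = 0,
    name: str = "spearman",
    ci_reps: int = BOOTSTRAP_REPS,
) -> TestResult:
    """Tie-aware Spearman rank correlation with a bootstrap CI."""
    x, y = np.asarray(x, float), np.asarray(y, float)
    if len(x) != len(y) or len(x) < 5:
        raise ValueError("need paired samples of size >= 5")
    rho, p = stats.spearmanr(x, y, alternative=alternative)
    lo = hi = None
    if ci_reps > 0:
        rng = np.random.default_rng(seed)
        lo, hi = _bootstrap_ci(lambda idx: _spearman_rows(x, y, idx), rng,
                               len(x), reps=ci_reps)
        lo, hi = min(lo, float(rho)), max(hi, float(rho))
    return TestResult(
        name=name, statistic_name="rho", statistic=float(rho),
        p_value=float(p), tails=2 if alternative == "two-sided" else 1,
        n=len(x), effect_size_name="rho", effect_size=float(rho),
        ci_low=lo, ci_high=hi,
    )


# ---------------------------------------------------------------------------
# Robust regression (Huber M-estimation)

HUBER_C = 1.345


def _huber_rho(u: np.ndarray, c: float = HUBER_C) -> np.ndarray:
    a = np.abs(u)
    return np.where(a <= c, 0.5 * u ** 2, c * a - 0.5 * c ** 2)


def robust_linreg(
    response: Sequence[float],
    design: pd.DataFrame | np.ndarray,
    reduced_design: pd.DataFrame | np.ndarray | None = None,
) -> dict:
    """Huber M-estimated linear regression with per-coefficient t tests.

    When ``reduced_design`` (a nested specification) is given, a deviance
    difference 2 * [sum rho(r_reduced/s) - sum rho(r_full/s)] at the full
    model's scale is referred to chi-squared with df = rank difference.
    Returns a dict with a coefficient table and, if applicable, the test.
    """
    import statsmodels.api as sm

    y = np.asarray(response, float)
    X = pd.DataFrame(design)
    if np.linalg.matrix_rank(X.to_numpy()) < X.shape[1]:
        raise ValueError("design matrix is rank deficient")
    fit = sm.RLM(y, X, M=sm.robust.norms.HuberT(t=HUBER_C)).fit()
    dof = len(y) - X.shape[1]
    tvals = fit.params / fit.bse
    pvals = 2.0 * stats.t.sf(np.abs(tvals), dof)
    coef = pd.DataFrame({
        "coef": fit.params, "se": fit.bse, "t": tvals, "p": pvals,
        "ci_low": fit.params - stats.t.ppf(0.975, dof) * fit.bse,
        "ci_high": fit.params + stats.t.ppf(0.975, dof) * fit.bse,
    })
    out = {"coefficients": coef, "scale": float(fit.scale), "df_resid": dof,
           "fitted": np.asarray(fit.fittedvalues), "weights": np.asarray(fit.weights)}
    if reduced_design is not None:
        Xr = pd.DataFrame(reduced_design)
        fit_r = sm.RLM(y, Xr, M=sm.robust.norms.HuberT(t=HUBER_C)).fit()
        s = float(fit.scale)
        dev_full = 2.0 * float(np.sum(_huber_rho((y - fit.fittedvalues) / s)))
        dev_red = 2.0 * float(np.sum(_huber_rho((y - fit_r.fittedvalues) / s)))
        df_diff = X.shape[1] - Xr.shape[1]
        if df_diff <= 0:
            raise ValueError("reduced design must be nested with fewer columns")
        chi2 = max(0.0, dev_red - dev_full)
        out["deviance_test"] = {
            "chi2": chi2, "df": df_diff, "p": float(stats.chi2.sf(chi2, df_diff)),
        }
    return out


# ---------------------------------------------------------------------------
# JZS Bayes factor

def jzs_bayes_factor_from_t(
    t: float,
    nx: int,
    ny: int | None = None,
    rscale: float = DEFAULT_RSCALE,
    alternative: str = "two-sided",
) -> float:
    """JZS Bayes factor from a t statistic.

    The standardised effect delta carries a Cauchy(0, rscale) prior; the
    marginal likelihood under H1 integrates the noncentral-t density over the
    prior via the substitution delta = r*tan(u) (finite interval, smooth).
    ``alternative`` "greater"/"less" use the prior truncated to the
    corresponding half-line (reported as BF+0 / BF-0).
    """
    if ny is None:
        neff, df = float(nx), nx - 1
    else:
        neff, df = nx * ny / (nx + ny), nx + ny - 2
    if df < 1:
        raise ValueError("not enough observations")
    sqrt_neff = math.sqrt(neff)

    def integrand(u):
        delta = rscale * math.tan(u)
        return stats.nct.pdf(t, df, delta * sqrt_neff)

    if alternative == "two-sided":
        num, _ = integrate.quad(integrand, -math.pi / 2, math.pi / 2, limit=200)
        num /= math.pi
    elif alternative == "greater":
        num, _ = integrate.quad(integrand, 0.0, math.pi / 2, limit=200)
        num *= 2.0 / math.pi
    elif alternative == "less":
        num, _ = integrate.quad(integrand, -math.pi / 2, 0.0, limit=200)
        num *= 2.0 / math.pi
    else:
        raise ValueError(f"unknown alternative {alternative!r}")
    den = stats.t.pdf(t, df)
    return float(num / den)


def jzs_bayes_factor(
    x: Sequence[float],
    y: Sequence[float] | None = None,
    mu0: float = 0.0,
    rscale: float = DEFAULT_RSCALE,
    alternative: str = "two-sided",
) -> float:
    """BF10 (or directional BF+0/BF-0) for one- or two-sample designs."""
    x = np.asarray(x, float)
    if len(x) < 3:
        raise ValueError("need at least 3 observations")
    if y is None:
        t = float(stats.ttest_1samp(x, mu0).statistic)
        return jzs_bayes_factor_from_t(t, len(x), None, rscale, alternative)
    y = np.asarray(y, float)
    t = float(stats.ttest_ind(x, y).statistic)
    return jzs_bayes_factor_from_t(t, len(x), len(y), rscale, alternative)


# ---------------------------------------------------------------------------
# Power analysis

def _achieved_power(n: int, d: float, alpha: float, test: str, tails: int) -> float:
    if test == "one-sample":
        df, nc = n - 1, d * math.sqrt(n)
    elif test == "two-sample":
        df, nc = 2 * n - 2, d * math.sqrt(n / 2.0)
    else:
        raise ValueError(f"unknown test {test!r}")
    if df < 1:
        return 0.0
    if tails == 1:
        crit = stats.t.ppf(1 - alpha, df)
        return float(1.0 - stats.nct.cdf(crit, df, nc))
    crit = stats.t.ppf(1 - alpha / 2, df)
    return float(1.0 - stats.nct.cdf(crit, df, nc) + stats.nct.cdf(-crit, df, nc))


def required_sample_size(
    effect_d: float,
    alpha: float = 0.05,
    power: float = 0.95,
    test: str = "one-sample",
    tails: int = 1,
) -> int:
    """Smallest n (per group for two-sample) with noncentral-t power >= target.

    Floor of n = 2 (a t test needs at least two observations)."""
    if not (0 < alpha < 1 and 0 < power < 1):
        raise ValueError("alpha and power are probabilities in (0, 1)")
    if effect_d <= 0:
        raise ValueError("effect size must be positive")
    # bracket by doubling, then bisect on the monotone power curve
    n_hi = 2
    while _achieved_power(n_hi, effect_d, alpha, test, tails) < power:
        n_hi *= 2
        if n_hi > 10_000_000:
            raise RuntimeError("sample size bracket exceeded")
    n_lo = max(2, n_hi // 2)
    while n_lo < n_hi:
        mid = (n_lo + n_hi) // 2
        if _achieved_power(mid, effect_d, alpha, test, tails) >= power:
            n_hi = mid
        else:
            n_lo = mid + 1
    return n_hi


# ---------------------------------------------------------------------------
# Norm-rating battery

def norm_rating_battery(
    ratings_by_group: Mapping[str, np.ndarray],
    rscale: float = 2.0,
    seed: int | np.random.Generator = 0,
) -> tuple[pd.DataFrame, dict]:
    """Per-allocation Kruskal-Wallis over groups of Likert ratings.

    ``ratings_by_group`` maps group label to an array [participants, probes].
    The Kruskal-Wallis p-values are Holm-corrected across probes; when there
    are exactly two groups a JZS Bayes factor with a wide Cauchy prior
    (default spread 2) is attached per probe.  The summary counts probes
    whose BF favours the null (BF10 < 1/3) or the alternative (BF10 > 3).
    """
    labels = list(ratings_by_group)
    arrays = [np.asarray(ratings_by_group[g], float) for g in labels]
    n_probes = arrays[0].shape[1]
    if any(a.shape[1] != n_probes for a in arrays):
        raise ValueError("all groups must rate the same probes")
    rows = []
    for j in range(n_probes):
        cols = [a[:, j] for a in arrays]
        try:
            h, p = stats.kruskal(*cols)
        except ValueError:  # all ratings identical across every group
            h, p = 0.0, 1.0
        row = {"probe": j, "H": float(h), "p_raw": float(p)}
        if len(cols) == 2:
            try:
                row["bf10"] = jzs_bayes_factor(cols[0], cols[1], rscale=rscale)
            except (ValueError, ZeroDivisionError):
                row["bf10"] = np.nan
        rows.append(row)
    df = pd.DataFrame(rows)
    df["p_corrected"] = holm(df["p_raw"].to_numpy())
    summary = {
        "n_probes": n_probes,
        "n_significant_raw": int((df["p_raw"] < 0.05).sum()),
        "n_significant_corrected": int((df["p_corrected"] < 0.05).sum()),
    }
    if "bf10" in df:
        bf = df["bf10"].dropna()
        summary["n_favour_null"] = int((bf < 1 / 3).sum())
        summary["n_favour_alternative"] = int((bf > 3).sum())
    return df, summary
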