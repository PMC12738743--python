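"""Statistical layer: exact paired Wilcoxon signed-rank tests, bootstrapped
standardized mean differences, TOST equivalence, z-scored correlation and
regression, and change-score coupling.

Choices that the analyses pin down:

* Wilcoxon p-values are two-sided and exact; the reported statistic W is
  the smaller of the positive/negative rank sums. Zero differences are
  dropped (reducing n); ties receive mid-ranks and the exact null
  distribution is computed over the observed mid-ranks.
* The SMD is paired Cohen's d_z (mean of differences over their SD) with
  a seeded percentile bootstrap over pairs.
* No multiple-testing correction is applied; every p-value is raw.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Dict, Iterable, Optional, Sequence, Tuple

import numpy as np
from scipy import stats as spstats

__all__ = [
    "WilcoxonExactResult",
    "PairedStatResult",
    "CouplingResult",
    "TostResult",
    "RegressionSummary",
    "wilcoxon_exact",
    "smd_bootstrap",
    "tost_equivalence",
    "zscore_and_correlate",
    "regression_with_task",
    "change_score_analysis",
    "analysis_sets",
]


@dataclass(frozen=True)
class WilcoxonExactResult:
    w: float           # min of positive/negative rank sums
    p: float           # exact two-sided
    n: int             # non-zero differences used
    w_plus: float
    w_minus: float


@dataclass(frozen=True)
class PairedStatResult:
    metric: str
    analysis_set: str
    n: int
    w: float
    p: float
    smd: float
    smd_ci: Tuple[float, float]


@dataclass(frozen=True)
class CouplingResult:
    rho: float
    ci: Tuple[float, float]
    p: float
    n: int
    method: str
    model_r2: Optional[float] = None


@dataclass(frozen=True)
class TostResult:
    p_lower: float
    p_upper: float
    bound: float
    n: int

    @property
    def p_max(self) -> float:
        return max(self.p_lower, self.p_upper)

    @property
    def equivalent(self) -> bool:
        return self.p_max < 0.05


@dataclass(frozen=True)
class RegressionSummary:
    r2: float
    f_stat: float
    df_model: int
    df_resid: int
    slope: float
    slope_ci: Tuple[float, float]
    slope_p: float
    task_p: Optional[float]
    interaction_p: Optional[float]


def _signed_rank_null_cdf(ranks2: np.ndarray) -> np.ndarray:
    """Counts of the positive-rank-sum null distribution over doubled ranks.

    ``ranks2`` are the observed mid-ranks times two (integers). Returns an
    array ``dist`` where ``dist[s]`` counts sign assignments with doubled
    positive-rank sum ``s``; total mass is 2^n.
    """
    total = int(ranks2.sum())
    dist = np.zeros(total + 1)
    dist[0] = 1.0
    for r in ranks2:
        new = dist.copy()
        new[r:] += dist[: total + 1 - r]
        dist = new
    return dist


def wilcoxon_exact(pre: Sequence[float], post: Sequence[float]) -> WilcoxonExactResult:
    """Exact two-sided paired Wilcoxon signed-rank test.

    Differences are post - pre; zeros are dropped. The two-sided p-value
    doubles the smaller exact tail (capped at 1), computed by a dynamic
    program over the observed (mid-)ranks — with ties this is the exact
    permutation distribution given the tied rank pattern.
    """
    pre = np.asarray(pre, dtype=float)
    post = np.asarray(post, dtype=float)
    if pre.shape != post.shape:
        raise ValueError("pre and post must be paired (equal length)")
    d = post - pre
    d = d[d != 0.0]
    n = len(d)
    if n == 0:
        raise ValueError("degenerate pairing: all differences are zero")
    ranks = spstats.rankdata(np.abs(d))
    ranks2 = np.round(2.0 * ranks).astype(int)  # mid-ranks are multiples of 1/2
    w_plus = float(ranks[d > 0].sum())
    w_minus = float(ranks[d < 0].sum())
    dist = _signed_rank_null_cdf(ranks2)
    total = 2.0 ** n
    cdf = np.cumsum(dist)
    k_plus = int(round(2.0 * w_plus))
    k_minus = int(round(2.0 * w_minus))
    tail = min(cdf[k_plus], cdf[k_minus]) / total
    p = min(2.0 * tail, 1.0)
    return WilcoxonExactResult(w=min(w_plus, w_minus), p=float(p), n=n,
                               w_plus=w_plus, w_minus=w_minus)


def smd_bootstrap(
    pre: Sequence[float],
    post: Sequence[float],
    B: int = 5000,
    seed: Optional[int] = None,
    rng: Optional[np.random.Generator] = None,
) -> Tuple[float, Tuple[float, float]]:
    """Paired Cohen's d_z with a percentile bootstrap 95% CI over pairs."""
    pre = np.asarray(pre, dtype=float)
    post = np.asarray(post, dtype=float)
    d = post - pre
    n = len(d)
    if n < 3:
        raise ValueError("need at least 3 pairs")
    sd = d.std(ddof=1)
    if sd == 0.0:
        raise ValueError("zero variance of paired differences")
    smd = float(d.mean() / sd)
    if rng is None:
        rng = np.random.default_rng(seed)
    idx = rng.integers(0, n, size=(B, n))
    db = d[idx]
    sds = db.std(axis=1, ddof=1)
    ok = sds > 0
    smds = db[ok].mean(axis=1) / sds[ok]
    lo, hi = np.percentile(smds, [2.5, 97.5])
    return smd, (float(lo), float(hi))


def tost_equivalence(
    pre: Sequence[float], post: Sequence[float], sesoi_factor: float = 0.3
) -> TostResult:
    """Paired TOST with equivalence bounds +/- sesoi_factor * SD(pre).

    Two one-sided paired t-tests against each bound; equivalence is
    declared when the larger of the two one-sided p-values is below 0.05.
    """
    pre = np.asarray(pre, dtype=float)
    post = np.asarray(post, dtype=float)
    n = len(pre)
    if n < 3:
        raise ValueError("need at least 3 pairs")
    sd_pre = pre.std(ddof=1)
    if sd_pre == 0.0:
        raise ValueError("zero variance of pre values")
    bound = sesoi_factor * sd_pre
    d = post - pre
    se = d.std(ddof=1) / np.sqrt(n)
    df = n - 1
    if se == 0.0:
        inside = abs(d.mean()) < bound
        p_lower = p_upper = 0.0 if inside else 1.0
    else:
        t_lower = (d.mean() + bound) / se   # H0: mean <= -bound
        t_upper = (d.mean() - bound) / se   # H0: mean >= +bound
        p_lower = float(spstats.t.sf(t_lower, df))
        p_upper = float(spstats.t.cdf(t_upper, df))
    return TostResult(p_lower=p_lower, p_upper=p_upper, bound=float(bound), n=n)


def _zscore(x: np.ndarray) -> np.ndarray:
    sd = x.std(ddof=1)
    if sd == 0.0:
        raise ValueError("constant input cannot be z-scored")
    return (x - x.mean()) / sd


def _bootstrap_corr(
    x: np.ndarray, y: np.ndarray, method: str, B: int, rng: np.random.Generator
) -> Tuple[float, float]:
    n = len(x)
    idx = rng.integers(0, n, size=(B, n))
    xb, yb = x[idx], y[idx]
    if method == "spearman":
        xb = spstats.rankdata(xb, axis=1)
        yb = spstats.rankdata(yb, axis=1)
    xb = xb - xb.mean(axis=1, keepdims=True)
    yb = yb - yb.mean(axis=1, keepdims=True)
    denom = np.sqrt((xb ** 2).sum(axis=1) * (yb ** 2).sum(axis=1))
    ok = denom > 0
    rhos = (xb * yb).sum(axis=1)[ok] / denom[ok]
    lo, hi = np.percentile(rhos, [2.5, 97.5])
    return float(lo), float(hi)


def zscore_and_correlate(
    beta: Sequence[float],
    speed: Sequence[float],
    method: str = "spearman",
    B: int = 5000,
    seed: Optional[int] = None,
) -> CouplingResult:
    """Correlate z-scored beta-power against a movement metric.

    Returns the coefficient with its asymptotic p-value and a percentile
    bootstrap CI over paired resampling (B resamples).
    """
    x = _zscore(np.asarray(beta, dtype=float))
    y = _zscore(np.asarray(speed, dtype=float))
    if len(x) != len(y):
        raise ValueError("beta and speed must be paired")
    if len(x) < 3:
        raise ValueError("need at least 3 observations")
    if method == "pearson":
        rho, p = spstats.pearsonr(x, y)
    elif method == "spearman":
        rho, p = spstats.spearmanr(x, y)
    else:
        raise ValueError("method must be 'pearson' or 'spearman'")
    rng = np.random.default_rng(seed)
    ci = _bootstrap_corr(x, y, method, B, rng)
    return CouplingResult(rho=float(rho), ci=ci, p=float(p), n=len(x), method=method)


def regression_with_task(
    beta: Sequence[float],
    speed: Sequence[float],
    task_labels: Sequence[str],
) -> RegressionSummary:
    """OLS of speed on beta, plus task-factor and interaction model tests.

    Fits the simple model, then augments with the task phase as a
    categorical factor and with beta-by-task interactions; reports
    nested-model comparison p-values (None when only one task level is
    present, in which case the model reduces to the simple regression).
    """
    import pandas as pd
    import statsmodels.formula.api as smf
    from statsmodels.stats.anova import anova_lm

    df = pd.DataFrame({
        "beta": np.asarray(beta, dtype=float),
        "speed": np.asarray(speed, dtype=float),
        "task": list(task_labels),
    })
    if df["beta"].var() == 0:
        raise ValueError("rank-deficient design: constant beta")
    m0 = smf.ols("speed ~ beta", data=df).fit()
    ci = m0.conf_int().loc["beta"]
    task_p = interaction_p = None
    if df["task"].nunique() >= 2:
        m1 = smf.ols("speed ~ beta + C(task)", data=df).fit()
        m2 = smf.ols("speed ~ beta * C(task)", data=df).fit()
        task_p = float(anova_lm(m0, m1).iloc[1]["Pr(>F)"])
        interaction_p = float(anova_lm(m1, m2).iloc[1]["Pr(>F)"])
    return RegressionSummary(
        r2=float(m0.rsquared),
        f_stat=float(m0.fvalue),
        df_model=int(m0.df_model),
        df_resid=int(m0.df_resid),
        slope=float(m0.params["beta"]),
        slope_ci=(float(ci[0]), float(ci[1])),
        slope_p=float(m0.pvalues["beta"]),
        task_p=task_p,
        interaction_p=interaction_p,
    )


def change_score_analysis(
    beta_pre: Sequence[float],
    beta_post: Sequence[float],
    speed_pre: Sequence[float],
    speed_post: Sequence[float],
    B: int = 5000,
    seed: Optional[int] = None,
) -> CouplingResult:
    """Correlate per-participant change scores.

    Delta-beta = beta_pre - beta_post (positive = beta reduction);
    Delta-speed = speed_post - speed_pre (positive = speed gain).
    Spearman's rho with a percentile bootstrap CI.
    """
    beta_pre = np.asarray(beta_pre, dtype=float)
    beta_post = np.asarray(beta_post, dtype=float)
    speed_pre = np.asarray(speed_pre, dtype=float)
    speed_post = np.asarray(speed_post, dtype=float)
    n = len(beta_pre)
    if not (len(beta_post) == len(speed_pre) == len(speed_post) == n):
        raise ValueError("all inputs must be paired per participant")
    if n < 3:
        raise ValueError("need at least 3 participants")
    dbeta = beta_pre - beta_post
    dspeed = speed_post - speed_pre
    rho, p = spstats.spearmanr(dbeta, dspeed)
    rng = np.random.default_rng(seed)
    ci = _bootstrap_corr(dbeta, dspeed, "spearman", B, rng)
    return CouplingResult(rho=float(rho), ci=ci, p=float(p), n=n, method="spearman")


def analysis_sets(
    pre_by_pid: Dict[str, float],
    post_by_pid: Dict[str, float],
    non_responders: Iterable[str],
    metric: str = "metric",
    B: int = 5000,
    seed: Optional[int] = None,
) -> Dict[str, PairedStatResult]:
    """Run the Wilcoxon + SMD battery on the prespecified analysis sets.

    Sets: all participants; responders only; and each non-responder
    excluded individually. Sets with fewer than 3 members are skipped
    with a warning.
    """
    import warnings

    pids = sorted(pre_by_pid)
    if sorted(post_by_pid) != pids:
        raise ValueError("pre and post must cover the same participants")
    non_responders = sorted(set(non_responders))
    sets = {"all": pids, "responders": [p for p in pids if p not in non_responders]}
    for nr in non_responders:
        sets[f"excl_{nr}"] = [p for p in pids if p != nr]
    out: Dict[str, PairedStatResult] = {}
    rng = np.random.default_rng(seed)
    for name, members in sets.items():
        if len(members) < 3:
            warnings.warn(f"analysis set {name!r} has fewer than 3 members; skipped")
            continue
        pre = np.array([pre_by_pid[p] for p in members])
        post = np.array([post_by_pid[p] for p in members])
        wres = wilcoxon_exact(pre, post)
        smd, ci = smd_bootstrap(pre, post, B=B, rng=rng)
        out[name] = PairedStatResult(metric=metric, analysis_set=name,
                                     n=len(members), w=wres.w, p=wres.p,
                                     smd=smd, smd_ci=ci)
    return out
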