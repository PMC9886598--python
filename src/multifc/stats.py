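"""Nonparametric multisite statistical battery.

Rank-based tests are implemented from their defining formulas (with tie
corrections) rather than delegated, so each can be validated against an
independent reference implementation: Kruskal-Wallis across sites, Dunn's
pairwise post hoc with Bonferroni adjustment, Fligner-Killeen variance
homogeneity, Wilcoxon rank-sum for two-group comparisons, Pearson's
chi-squared for contingency tables (no continuity correction), Welch's t,
one-way ANOVA, per-site covariate adjustment by linear regression, and the
FD/DVARS-versus-feature correlation screen with Bonferroni control over
all tests performed.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats as sps

from .core import FEATURE_COLUMNS

__all__ = [
    "TestResult",
    "adjust_linear",
    "kruskal_wallis",
    "dunn_posthoc",
    "fligner_killeen",
    "wilcoxon_ranksum",
    "chi2_independence",
    "welch_t",
    "welch_t_summary",
    "anova_oneway",
    "correlation_screen",
    "bonferroni",
]

ALPHA = 0.05


@dataclass
class TestResult:
    statistic: float
    p_raw: float
    method: str
    df: float | tuple[float, float] | None = None
    p_adjusted: float | None = None
    group_sizes: tuple[int, ...] = field(default_factory=tuple)
    extra: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if not (0.0 <= self.p_raw <= 1.0):
            raise ValueError("p_raw outside [0, 1]")
        if self.p_adjusted is not None and self.p_adjusted < self.p_raw - 1e-15:
            raise ValueError("adjusted p may not be smaller than the raw p")


def bonferroni(p: float, m: int) -> float:
    return float(min(1.0, m * p))


def _tie_term(pooled: np.ndarray) -> float:
    """sum over tie groups of (t^3 - t)."""
    _, counts = np.unique(pooled, return_counts=True)
    return float((counts**3 - counts).sum())


def adjust_linear(
    features: pd.DataFrame,
    covariates: tuple[str, ...] = ("age", "sex", "fd_mean"),
    per_site: bool = True,
    feature_names: tuple[str, ...] = FEATURE_COLUMNS,
) -> pd.DataFrame:
    """Regress covariates out of each feature, within each site by default;
    residuals are re-centered on the (site) feature mean."""
    out = features.copy()
    groups = out.groupby("site").groups.items() if per_site else [("all", out.index)]
    for site, idx in groups:
        sub = out.loc[idx]
        if len(sub) <= len(covariates) + 1:
            raise ValueError(
                f"site {site!r} has {len(sub)} subjects; need more than "
                f"{len(covariates) + 1} to adjust for {list(covariates)}"
            )
        cols = []
        for name in covariates:
            v = sub[name]
            if name == "sex" and v.dtype == object:
                v = v.map({"F": 0, "M": 1})
            cols.append(v.to_numpy(dtype=float))
        design = np.column_stack([np.ones(len(sub))] + cols)
        Y = sub.loc[:, list(feature_names)].to_numpy(dtype=float)
        coef, *_ = np.linalg.lstsq(design, Y, rcond=None)
        resid = Y - design @ coef
        out.loc[idx, list(feature_names)] = resid + Y.mean(axis=0, keepdims=True)
    return out


def kruskal_wallis(*groups: np.ndarray) -> TestResult:
    """Kruskal-Wallis H with tie correction; p from chi-squared (k-1 df)."""
    groups = [np.asarray(g, dtype=float) for g in groups]
    if len(groups) < 2:
        raise ValueError("need at least 2 groups")
    sizes = [len(g) for g in groups]
    if min(sizes) < 1 or sum(sizes) < 3:
        raise ValueError("each group needs n >= 1 and total N >= 3")
    pooled = np.concatenate(groups)
    N = len(pooled)
    ranks = sps.rankdata(pooled)
    H = 0.0
    start = 0
    for g in groups:
        r = ranks[start : start + len(g)]
        H += len(g) * r.mean() ** 2
        start += len(g)
    H = 12.0 / (N * (N + 1)) * H - 3.0 * (N + 1)
    correction = 1.0 - _tie_term(pooled) / (N**3 - N)
    if correction == 0:  # all values identical
        return TestResult(0.0, 1.0, "kruskal-wallis", df=len(groups) - 1, group_sizes=tuple(sizes))
    H /= correction
    df = len(groups) - 1
    p = float(sps.chi2.sf(H, df))
    return TestResult(float(H), p, "kruskal-wallis", df=df, group_sizes=tuple(sizes))


def dunn_posthoc(
    *groups: np.ndarray, adjust: str = "bonferroni"
) -> dict[tuple[int, int], TestResult]:
    """Dunn's pairwise rank comparisons after Kruskal-Wallis; two-sided z
    tests with tie-corrected variance, Bonferroni-adjusted over all pairs."""
    groups = [np.asarray(g, dtype=float) for g in groups]
    if len(groups) < 2:
        raise ValueError("need at least 2 groups")
    pooled = np.concatenate(groups)
    N = len(pooled)
    ranks = sps.rankdata(pooled)
    mean_ranks = []
    start = 0
    for g in groups:
        mean_ranks.append(ranks[start : start + len(g)].mean())
        start += len(g)
    var_term = N * (N + 1) / 12.0 - _tie_term(pooled) / (12.0 * (N - 1))
    n_pairs = len(groups) * (len(groups) - 1) // 2
    results = {}
    for i in range(len(groups)):
        for j in range(i + 1, len(groups)):
            se = np.sqrt(var_term * (1.0 / len(groups[i]) + 1.0 / len(groups[j])))
            z = 0.0 if se == 0 else (mean_ranks[i] - mean_ranks[j]) / se
            p = float(2.0 * sps.norm.sf(abs(z)))
            p_adj = bonferroni(p, n_pairs) if adjust == "bonferroni" else p
            results[(i, j)] = TestResult(
                float(z), p, "dunn", p_adjusted=p_adj,
                group_sizes=(len(groups[i]), len(groups[j])),
            )
    return results


def fligner_killeen(*groups: np.ndarray) -> TestResult:
    """Fligner-Killeen test of variance homogeneity with normal scores
    a = Phi^-1(0.5 + rank / (2 (N + 1))) of |x - group median|."""
    groups = [np.asarray(g, dtype=float) for g in groups]
    if len(groups) < 2:
        raise ValueError("need at least 2 groups")
    if min(len(g) for g in groups) < 2:
        raise ValueError("each group needs n >= 2")
    devs = [np.abs(g - np.median(g)) for g in groups]
    pooled = np.concatenate(devs)
    N = len(pooled)
    ranks = sps.rankdata(pooled)
    a = sps.norm.ppf(0.5 + ranks / (2.0 * (N + 1.0)))
    abar = a.mean()
    v2 = a.var(ddof=1)
    if v2 == 0:
        return TestResult(0.0, 1.0, "fligner-killeen", df=len(groups) - 1,
                          group_sizes=tuple(len(g) for g in groups))
    stat = 0.0
    start = 0
    for g in groups:
        aj = a[start : start + len(g)].mean()
        stat += len(g) * (aj - abar) ** 2
        start += len(g)
    stat /= v2
    df = len(groups) - 1
    return TestResult(float(stat), float(sps.chi2.sf(stat, df)), "fligner-killeen",
                      df=df, group_sizes=tuple(len(g) for g in groups))


def wilcoxon_ranksum(a: np.ndarray, b: np.ndarray) -> TestResult:
    """Wilcoxon rank-sum (Mann-Whitney) with tie-corrected normal
    approximation and continuity correction; two-sided."""
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if len(a) < 1 or len(b) < 1:
        raise ValueError("both samples need n >= 1")
    n1, n2 = len(a), len(b)
    N = n1 + n2
    pooled = np.concatenate([a, b])
    ranks = sps.rankdata(pooled)
    W = float(ranks[:n1].sum())
    U = W - n1 * (n1 + 1) / 2.0
    mu = n1 * n2 / 2.0
    tie = _tie_term(pooled)
    var = n1 * n2 / 12.0 * ((N + 1.0) - tie / (N * (N - 1.0)))
    if var <= 0:
        return TestResult(W, 1.0, "wilcoxon-ranksum", group_sizes=(n1, n2), extra={"U": U})
    num = U - mu
    num -= np.sign(num) * 0.5  # continuity correction
    z = num / np.sqrt(var)
    p = float(min(1.0, 2.0 * sps.norm.sf(abs(z))))
    return TestResult(W, p, "wilcoxon-ranksum", group_sizes=(n1, n2),
                      extra={"U": U, "z": float(z)})


def chi2_independence(table: np.ndarray) -> TestResult:
    """Pearson chi-squared for an R x C contingency table, no continuity
    correction."""
    table = np.asarray(table, dtype=float)
    if table.ndim != 2:
        raise ValueError("contingency table must be 2D")
    if np.any(table < 0):
        raise ValueError("counts must be non-negative")
    row = table.sum(axis=1, keepdims=True)
    col = table.sum(axis=0, keepdims=True)
    total = table.sum()
    expected = row @ col / total
    if np.any(expected <= 0):
        raise ValueError("all expected counts must be positive")
    stat = float(((table - expected) ** 2 / expected).sum())
    df = (table.shape[0] - 1) * (table.shape[1] - 1)
    return TestResult(stat, float(sps.chi2.sf(stat, df)), "chi2", df=df,
                      group_sizes=tuple(int(n) for n in table.sum(axis=1)))


def welch_t_summary(
    mean_a: float, sd_a: float, n_a: int, mean_b: float, sd_b: float, n_b: int
) -> TestResult:
    """Welch's t from summary statistics with Satterthwaite df."""
    if n_a < 2 or n_b < 2:
        raise ValueError("need n >= 2 per group")
    if sd_a <= 0 or sd_b <= 0:
        raise ValueError("sds must be positive")
    va, vb = sd_a**2 / n_a, sd_b**2 / n_b
    t = (mean_a - mean_b) / np.sqrt(va + vb)
    df = (va + vb) ** 2 / (va**2 / (n_a - 1) + vb**2 / (n_b - 1))
    p = float(2.0 * sps.t.sf(abs(t), df))
    return TestResult(float(t), p, "welch-t", df=float(df), group_sizes=(n_a, n_b))


def welch_t(a: np.ndarray, b: np.ndarray) -> TestResult:
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    return welch_t_summary(
        a.mean(), a.std(ddof=1), len(a), b.mean(), b.std(ddof=1), len(b)
    )


def anova_oneway(*groups: np.ndarray) -> TestResult:
    """Classical one-way ANOVA F test."""
    groups = [np.asarray(g, dtype=float) for g in groups]
    if len(groups) < 2 or min(len(g) for g in groups) < 2:
        raise ValueError("need k >= 2 groups with n >= 2 each")
    N = sum(len(g) for g in groups)
    k = len(groups)
    grand = np.concatenate(groups).mean()
    ssb = sum(len(g) * (g.mean() - grand) ** 2 for g in groups)
    ssw = sum(((g - g.mean()) ** 2).sum() for g in groups)
    df1, df2 = k - 1, N - k
    if ssw == 0:
        if ssb == 0:
            return TestResult(0.0, 1.0, "anova", df=(df1, df2),
                              group_sizes=tuple(len(g) for g in groups))
        import warnings

        warnings.warn("zero within-group variance; F is infinite, reporting p = 0")
        return TestResult(float("inf"), 0.0, "anova", df=(df1, df2),
                          group_sizes=tuple(len(g) for g in groups))
    F = (ssb / df1) / (ssw / df2)
    return TestResult(float(F), float(sps.f.sf(F, df1, df2)), "anova",
                      df=(df1, df2), group_sizes=tuple(len(g) for g in groups))


def _pearson(x: np.ndarray, y: np.ndarray) -> tuple[float, float]:
    n = len(x)
    xc = x - x.mean()
    yc = y - y.mean()
    denom = np.sqrt((xc**2).sum() * (yc**2).sum())
    if denom == 0:
        return float("nan"), float("nan")
    r = float(np.clip((xc * yc).sum() / denom, -1.0, 1.0))
    if abs(r) == 1.0:
        return r, 0.0
    t = r * np.sqrt((n - 2) / (1.0 - r**2))
    return r, float(2.0 * sps.t.sf(abs(t), n - 2))


def correlation_screen(
    features: pd.DataFrame,
    metrics: tuple[str, ...] = ("fd_mean",),
    feature_names: tuple[str, ...] = FEATURE_COLUMNS,
    per_site: bool = True,
    alpha: float = ALPHA,
) -> pd.DataFrame:
    """Pearson correlations between quality metrics and features, per site,
    Bonferroni-corrected over all site x feature x metric tests performed."""
    groups = features.groupby("site").groups.items() if per_site else [("all", features.index)]
    rows = []
    for site, idx in groups:
        sub = features.loc[idx]
        if len(sub) < 4:
            raise ValueError(f"site {site!r} has n < 4; correlation screen undefined")
        for metric in metrics:
            m = sub[metric].to_numpy(dtype=float)
            for feat in feature_names:
                y = sub[feat].to_numpy(dtype=float)
                if np.std(m) == 0 or np.std(y) == 0:
                    rows.append((site, metric, feat, np.nan, np.nan, np.nan))
                    continue
                r, p = _pearson(y, m)
                rows.append((site, metric, feat, r, r**2, p))
    out = pd.DataFrame(rows, columns=["site", "metric", "feature", "r", "r2", "p_raw"])
    n_tests = int(out["p_raw"].notna().sum())
    out["p_bonferroni"] = np.minimum(1.0, out["p_raw"] * n_tests)
    out["significant"] = out["p_bonferroni"] < alpha
    return out
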