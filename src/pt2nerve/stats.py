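"""Inferential layer on the cohort table.

Implements the study-style analyses: covariate-adjusted group comparisons
(ordinary least squares on measure ~ group + age + sex), plain two-sample
tests (Welch t and Mann-Whitney U), a three-stratum severity analysis
(one-way ANOVA omnibus with Dunn rank-based pairwise post hoc tests), and
Pearson/Spearman correlations with optional partial correlation by
residualisation on covariates.

Notes on choices the source analyses leave open: the t-test is Welch
(unequal variances) by default; pairing a parametric omnibus ANOVA with
the rank-based Dunn post hoc is heterodox but both are reported side by
side; post hoc p-values are unadjusted by default with Holm adjustment
always included in the output table; "controlling for sex and age" is
partial correlation (residualisation) for correlations and a fixed-effects
linear model for group contrasts — with one observation per subject a
mixed-effects model has no identifiable random effect.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import stats as sps

from .config import GROUP_ATTRV, GROUP_HC

__all__ = [
    "StatResult",
    "severity_stratum",
    "add_severity_column",
    "adjusted_group_comparison",
    "two_sample_tests",
    "dunn_test",
    "severity_anova",
    "correlate",
]

# NIS-LL severity bands: mild 1-20, moderate 21-61, severe 62-88.
NIS_LL_MILD_MAX = 20.0
NIS_LL_MODERATE_MAX = 61.0


@dataclass
class StatResult:
    """One test's outcome in a uniform shape."""

    test: str
    estimate: float
    coefficient: float
    p_value: float
    n: int
    covariates: tuple[str, ...] = ()
    extra: dict = field(default_factory=dict)

    def as_row(self) -> dict:
        return {
            "test": self.test,
            "estimate": self.estimate,
            "coefficient": self.coefficient,
            "p": self.p_value,
            "n": self.n,
            "covariates": "+".join(self.covariates),
        }


def severity_stratum(group: str, nis_ll: float) -> str:
    """Severity stratum from the NIS-LL score: healthy controls form their
    own stratum; patients are mild (NIS-LL <= 20) or moderate/severe
    (> 20; the moderate and severe bands are pooled)."""
    if group == GROUP_HC:
        return "HC"
    return "mild" if nis_ll <= NIS_LL_MILD_MAX else "moderate_severe"


def add_severity_column(table: pd.DataFrame) -> pd.DataFrame:
    out = table.copy()
    out["severity"] = [
        severity_stratum(g, s) for g, s in zip(out["group"], out["nis_ll"])
    ]
    return out


def adjusted_group_comparison(
    table: pd.DataFrame,
    measure: str,
    group_col: str = "group",
    covariates: Sequence[str] = ("age", "sex"),
) -> StatResult:
    """Least-squares fit of measure ~ group + covariates.

    Returns the group-term coefficient (ATTRv minus HC) and p-value, and
    the model's multiple correlation coefficient R = sqrt(R^2).
    """
    cols = [measure, group_col, *covariates]
    data = table.dropna(subset=[c for c in cols if c in table.columns])
    groups = data[group_col].unique()
    if len(groups) != 2:
        raise ValueError(f"expected exactly two groups, found {sorted(map(str, groups))}")
    for g in (GROUP_ATTRV, GROUP_HC):
        if (data[group_col] == g).sum() < 3:
            raise ValueError(f"need >= 3 subjects in group {g}")
    y = data[measure].to_numpy(dtype=float)
    g01 = (data[group_col] == GROUP_ATTRV).to_numpy(dtype=float)
    X = np.column_stack([g01] + [data[c].to_numpy(dtype=float) for c in covariates])
    X = sm.add_constant(X, has_constant="add")
    if np.linalg.matrix_rank(X) < X.shape[1]:
        raise ValueError(
            "singular design matrix (e.g. a constant covariate such as a "
            "single-sex cohort); drop the offending covariate"
        )
    fit = sm.OLS(y, X).fit()
    return StatResult(
        test=f"OLS {measure} ~ group + {'+'.join(covariates) if covariates else '1'}",
        estimate=float(fit.params[1]),
        coefficient=float(np.sqrt(max(fit.rsquared, 0.0))),
        p_value=float(fit.pvalues[1]),
        n=int(fit.nobs),
        covariates=tuple(covariates),
        extra={"fvalue": float(fit.fvalue), "r_squared": float(fit.rsquared)},
    )


def two_sample_tests(
    table: pd.DataFrame,
    measure: str,
    group_col: str = "group",
    alternative: str = "two-sided",
) -> dict[str, StatResult]:
    """Welch t-test and Mann-Whitney U between ATTRv and HC.

    ``alternative`` follows scipy conventions with ATTRv as the first
    sample, so "greater" tests for larger values in patients (the
    one-tailed direction used for nerve caliber).
    """
    a = table.loc[table[group_col] == GROUP_ATTRV, measure].dropna().to_numpy(dtype=float)
    h = table.loc[table[group_col] == GROUP_HC, measure].dropna().to_numpy(dtype=float)
    if len(a) < 2 or len(h) < 2:
        raise ValueError("need at least 2 subjects per group")
    t = sps.ttest_ind(a, h, equal_var=False, alternative=alternative)
    u = sps.mannwhitneyu(a, h, alternative=alternative)
    n = len(a) + len(h)
    return {
        "welch_t": StatResult(
            test=f"Welch t ({alternative})",
            estimate=float(a.mean() - h.mean()),
            coefficient=float(t.statistic),
            p_value=float(t.pvalue),
            n=n,
            extra={"mean_attrv": float(a.mean()), "mean_hc": float(h.mean())},
        ),
        "mannwhitney_u": StatResult(
            test=f"Mann-Whitney U ({alternative})",
            estimate=float(u.statistic),
            coefficient=float(u.statistic),
            p_value=float(u.pvalue),
            n=n,
        ),
    }


def dunn_test(samples: dict[str, np.ndarray]) -> pd.DataFrame:
    """Dunn's rank-based pairwise z-tests over all strata pairs.

    Pools all observations, ranks them once (mid-ranks for ties), and for
    each pair (i, j) computes

        z = (Rbar_i - Rbar_j) / sqrt((N(N+1)/12 - T) (1/n_i + 1/n_j))

    with the tie correction T = sum(t^3 - t) / (12 (N - 1)). Two-sided
    p-values are reported unadjusted and Holm-adjusted.
    """
    names = list(samples)
    arrays = [np.asarray(samples[k], dtype=float) for k in names]
    pooled = np.concatenate(arrays)
    N = pooled.size
    ranks = sps.rankdata(pooled)
    offsets = np.cumsum([0] + [len(x) for x in arrays])
    mean_ranks = {
        k: ranks[offsets[i]: offsets[i + 1]].mean() for i, k in enumerate(names)
    }
    _, counts = np.unique(pooled, return_counts=True)
    tie_term = float((counts**3 - counts).sum()) / (12.0 * (N - 1)) if N > 1 else 0.0
    var_base = N * (N + 1) / 12.0 - tie_term

    rows = []
    for i, j in itertools.combinations(range(len(names)), 2):
        ni, nj = len(arrays[i]), len(arrays[j])
        se = np.sqrt(var_base * (1.0 / ni + 1.0 / nj))
        z = (mean_ranks[names[i]] - mean_ranks[names[j]]) / se
        p = 2.0 * sps.norm.sf(abs(z))
        rows.append({"group_a": names[i], "group_b": names[j], "z": z, "p_unadjusted": p})
    out = pd.DataFrame(rows)
    # Holm step-down adjustment
    order = np.argsort(out["p_unadjusted"].to_numpy())
    m = len(out)
    adj = np.empty(m)
    running = 0.0
    for rank, idx in enumerate(order):
        running = max(running, (m - rank) * out["p_unadjusted"].iloc[idx])
        adj[idx] = min(running, 1.0)
    out["p_holm"] = adj
    return out


def severity_anova(
    table: pd.DataFrame,
    measure: str,
    severity_col: str = "severity",
) -> tuple[StatResult, pd.DataFrame]:
    """One-way ANOVA across severity strata plus Dunn pairwise post hoc.

    Requires at least three non-empty strata with >= 2 subjects each.
    Returns the omnibus F/p and the pairwise table (z, unadjusted p,
    Holm-adjusted p).
    """
    data = table.dropna(subset=[measure, severity_col])
    strata = {k: g[measure].to_numpy(dtype=float) for k, g in data.groupby(severity_col)}
    strata = {k: v for k, v in strata.items() if len(v) > 0}
    if len(strata) < 3:
        raise ValueError(f"need 3 non-empty strata, found {sorted(strata)}")
    if any(len(v) < 2 for v in strata.values()):
        raise ValueError("every stratum needs >= 2 subjects")
    f, p = sps.f_oneway(*strata.values())
    omnibus = StatResult(
        test="one-way ANOVA (severity strata)",
        estimate=float(f),
        coefficient=float(f),
        p_value=float(p),
        n=int(sum(len(v) for v in strata.values())),
        extra={"strata_n": {k: len(v) for k, v in strata.items()}},
    )
    return omnibus, dunn_test(strata)


def _residualize(y: np.ndarray, covs: np.ndarray) -> np.ndarray:
    X = sm.add_constant(covs, has_constant="add")
    beta, *_ = np.linalg.lstsq(X, y, rcond=None)
    return y - X @ beta


def correlate(
    x: np.ndarray | pd.Series,
    y: np.ndarray | pd.Series,
    method: str = "pearson",
    covariates: np.ndarray | pd.DataFrame | None = None,
) -> StatResult:
    """Pearson or Spearman correlation, optionally partial.

    With covariates, the partial correlation is computed by residualising
    both variables on the covariates and correlating the residuals; for
    the Spearman flavour all columns are rank-transformed first. The
    p-value uses the t-distribution with n - 2 - n_covariates degrees of
    freedom.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if method not in ("pearson", "spearman"):
        raise ValueError(f"unknown method {method!r}")
    keep = np.isfinite(x) & np.isfinite(y)
    ncov = 0
    covs = None
    if covariates is not None:
        covs = np.asarray(covariates, dtype=float)
        if covs.ndim == 1:
            covs = covs[:, None]
        keep &= np.isfinite(covs).all(axis=1)
    x, y = x[keep], y[keep]
    n = x.size
    if n < 4:
        raise ValueError("need n >= 4 observations")
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        raise ValueError("zero variance in a correlated column")

    if covs is None:
        if method == "pearson":
            r, p = sps.pearsonr(x, y)
        else:
            r, p = sps.spearmanr(x, y)
        return StatResult(
            test=f"{method} correlation",
            estimate=float(r),
            coefficient=float(r),
            p_value=float(p),
            n=n,
        )

    covs = covs[keep]
    ncov = covs.shape[1]
    if method == "spearman":
        x = sps.rankdata(x)
        y = sps.rankdata(y)
        covs = np.column_stack([sps.rankdata(covs[:, j]) for j in range(ncov)])
    rx = _residualize(x, covs)
    ry = _residualize(y, covs)
    r = float(np.corrcoef(rx, ry)[0, 1])
    df = n - 2 - ncov
    if df <= 0:
        raise ValueError("not enough observations for the covariate count")
    tstat = r * np.sqrt(df / max(1.0 - r * r, np.finfo(float).tiny))
    p = float(2.0 * sps.t.sf(abs(tstat), df))
    return StatResult(
        test=f"partial {method} correlation",
        estimate=r,
        coefficient=r,
        p_value=p,
        n=n,
        covariates=tuple(f"c{j}" for j in range(ncov)),
        extra={"df": df},
    )
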