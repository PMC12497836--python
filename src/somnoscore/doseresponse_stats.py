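"""Within-subject dose-response statistics.

Implements the tests applied to the pipeline's per-animal summaries:

* paired t-tests (vehicle vs. a single dose);
* within-subject simple linear regression reporting R^2 and the exact F
  identity F = (n - 2) R^2 / (1 - R^2) on (1, n - 2) df;
* classical one-way repeated-measures ANOVA with Greenhouse-Geisser
  sphericity correction (the documented, testable analogue of commercial
  mixed-effects fits — no numeric identity with REML output is claimed);
* Dunnett-style many-to-one comparisons of each dose against vehicle, with
  the family-wise adjustment taken from the Monte Carlo distribution of the
  maximum absolute paired-t statistic under the estimated within-subject
  correlation.

All tests are two-sided.  Missing cells are tolerated: Dunnett comparisons
use pairwise-complete subjects per comparison and the ANOVA/epsilon use
complete cases.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .errors import ValidationError

__all__ = [
    "RegressionResult",
    "AnovaResult",
    "DunnettComparison",
    "paired_t",
    "linear_regression",
    "gg_epsilon",
    "rm_anova_oneway",
    "dunnett_many_to_one",
]

DEFAULT_MC_REPLICATES = 100_000
DEFAULT_MC_SEED = 20_260_101


@dataclass(frozen=True)
class RegressionResult:
    slope: float
    intercept: float
    r_squared: float
    f_stat: float
    df: tuple[int, int]
    p_value: float
    perfect_fit: bool = False


@dataclass(frozen=True)
class DunnettComparison:
    condition: str
    mean_difference: float
    t_stat: float
    df: int
    p_raw: float
    p_adjusted: float


@dataclass(frozen=True)
class AnovaResult:
    f_stat: float
    df_num: float
    df_den: float
    epsilon: float
    p_value: float
    p_uncorrected: float
    n_subjects: int
    comparisons: tuple[DunnettComparison, ...] = ()


def paired_t(x, y) -> tuple[float, int, float]:
    """Two-sided paired t-test; returns (t, df, p) with df = n - 1."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1:
        raise ValidationError("x and y must be equal-length 1-D vectors")
    ok = np.isfinite(x) & np.isfinite(y)
    x, y = x[ok], y[ok]
    n = x.size
    if n < 3:
        raise ValidationError(f"need >= 3 complete pairs, got {n}")
    d = x - y
    sd = d.std(ddof=1)
    if sd == 0:
        raise ValidationError("zero variance of paired differences: t undefined")
    t = d.mean() / (sd / np.sqrt(n))
    p = 2.0 * stats.t.sf(abs(t), n - 1)
    return float(t), n - 1, float(p)


def linear_regression(x, y) -> RegressionResult:
    """Ordinary least squares of y on x with the regression F identity.

    R^2 = 1 - SSE/SST; F = (n - 2) R^2 / (1 - R^2) on (1, n - 2) df; p from
    the F distribution.  A perfect fit (R^2 = 1) reports p = 0 with
    ``perfect_fit=True``; constant x raises.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1:
        raise ValidationError("x and y must be equal-length 1-D vectors")
    ok = np.isfinite(x) & np.isfinite(y)
    x, y = x[ok], y[ok]
    n = x.size
    if n < 3:
        raise ValidationError(f"need n >= 3, got {n}")
    if np.ptp(x) == 0:
        raise ValidationError("x is constant: slope undefined")
    fit = stats.linregress(x, y)
    sst = float(np.sum((y - y.mean()) ** 2))
    resid = y - (fit.intercept + fit.slope * x)
    sse = float(np.sum(resid**2))
    r2 = 1.0 - sse / sst if sst > 0 else 1.0
    r2 = min(max(r2, 0.0), 1.0)
    df = (1, n - 2)
    if r2 >= 1.0 - 1e-14:
        return RegressionResult(
            slope=float(fit.slope),
            intercept=float(fit.intercept),
            r_squared=1.0,
            f_stat=float("inf"),
            df=df,
            p_value=0.0,
            perfect_fit=True,
        )
    f = (n - 2) * r2 / (1.0 - r2)
    p = float(stats.f.sf(f, *df))
    return RegressionResult(
        slope=float(fit.slope),
        intercept=float(fit.intercept),
        r_squared=r2,
        f_stat=float(f),
        df=df,
        p_value=p,
    )


def _design_matrix(design: pd.DataFrame) -> pd.DataFrame:
    if not isinstance(design, pd.DataFrame):
        design = pd.DataFrame(design)
    if design.shape[1] < 2:
        raise ValidationError("need >= 2 conditions")
    enough = design.notna().sum(axis=1) >= 2
    if not enough.all():
        raise ValidationError("every subject needs >= 2 non-missing cells")
    return design.astype(float)


def gg_epsilon(design: pd.DataFrame) -> float:
    """Greenhouse-Geisser sphericity correction from complete cases.

    Computed from the k x k sample covariance of conditions:
    epsilon = (sum of centered-covariance diagonal)^2 /
              ((k - 1) * sum of squared centered-covariance entries),
    bounded in [1/(k - 1), 1]; exactly 1 when k = 2.
    """
    design = _design_matrix(design)
    complete = design.dropna()
    k = design.shape[1]
    if complete.shape[0] < 2:
        raise ValidationError("need >= 2 complete subjects for epsilon")
    if k == 2:
        return 1.0
    cov = np.cov(complete.to_numpy(), rowvar=False, ddof=1)
    # double-center: covariance of deviations from the subject mean
    row_means = cov.mean(axis=1, keepdims=True)
    centered = cov - row_means - row_means.T + cov.mean()
    num = np.trace(centered) ** 2
    den = (k - 1) * np.sum(centered**2)
    if den == 0:
        return 1.0
    eps = float(num / den)
    return float(min(max(eps, 1.0 / (k - 1)), 1.0))


def rm_anova_oneway(
    design: pd.DataFrame,
    control: str | None = None,
    mc_replicates: int = DEFAULT_MC_REPLICATES,
    seed: int = DEFAULT_MC_SEED,
) -> AnovaResult:
    """One-way repeated-measures ANOVA with Greenhouse-Geisser correction.

    ``design`` is subjects x conditions.  F = MS_condition / MS_(subject x
    condition) on complete cases; corrected df = epsilon x uncorrected df and
    p comes from the corrected F distribution.  When ``control`` names a
    condition, Dunnett many-to-one comparisons against it are attached.
    """
    design = _design_matrix(design)
    complete = design.dropna()
    n, k = complete.shape
    if n < 2:
        raise ValidationError("need >= 2 complete subjects")
    data = complete.to_numpy()
    grand = data.mean()
    ss_cond = n * np.sum((data.mean(axis=0) - grand) ** 2)
    ss_subj = k * np.sum((data.mean(axis=1) - grand) ** 2)
    ss_tot = np.sum((data - grand) ** 2)
    ss_err = ss_tot - ss_cond - ss_subj
    df_num = k - 1
    df_den = (k - 1) * (n - 1)
    ms_cond = ss_cond / df_num
    ms_err = ss_err / df_den
    if ms_err == 0:
        raise ValidationError("zero within-subject error variance: F undefined")
    f = float(ms_cond / ms_err)
    eps = gg_epsilon(design)
    p_corr = float(stats.f.sf(f, eps * df_num, eps * df_den))
    p_unc = float(stats.f.sf(f, df_num, df_den))
    comparisons: tuple[DunnettComparison, ...] = ()
    if control is not None:
        comparisons = dunnett_many_to_one(
            design, control, mc_replicates=mc_replicates, seed=seed
        )
    return AnovaResult(
        f_stat=f,
        df_num=eps * df_num,
        df_den=eps * df_den,
        epsilon=eps,
        p_value=p_corr,
        p_uncorrected=p_unc,
        n_subjects=n,
        comparisons=comparisons,
    )


def dunnett_many_to_one(
    design: pd.DataFrame,
    control: str,
    mc_replicates: int = DEFAULT_MC_REPLICATES,
    seed: int = DEFAULT_MC_SEED,
) -> tuple[DunnettComparison, ...]:
    """Paired many-to-one comparisons against a shared control condition.

    Each non-control condition is compared to the control by a paired t
    statistic over pairwise-complete subjects.  Family-wise adjusted p-values
    come from the Monte Carlo null distribution of the maximum absolute
    statistic: difference-score vectors are correlated across comparisons
    (they share the control), so the null is simulated as a parametric
    bootstrap — multivariate-normal difference-score matrices at the
    estimated within-subject correlation, with the t-vector recomputed per
    replicate so variance estimation is part of the null.

    Adjusted p >= raw p always, with equality (up to Monte Carlo error) for
    a single-comparison family.
    """
    design = _design_matrix(design)
    if control not in design.columns:
        raise ValidationError(f"control {control!r} not among conditions")
    others = [c for c in design.columns if c != control]
    if not others:
        raise ValidationError("need >= 1 non-control condition")
    if design[control].isna().all():
        raise ValidationError("control column is entirely missing")

    diffs = design[others].sub(design[control], axis=0)
    stats_obs, dfs, raws = [], [], []
    for c in others:
        d = diffs[c].dropna().to_numpy()
        if d.size < 2:
            raise ValidationError(f"condition {c!r}: < 2 pairwise-complete subjects")
        sd = d.std(ddof=1)
        if sd == 0:
            raise ValidationError(f"condition {c!r}: zero variance of differences")
        t = d.mean() / (sd / np.sqrt(d.size))
        stats_obs.append(float(t))
        dfs.append(d.size - 1)
        raws.append(float(2.0 * stats.t.sf(abs(t), d.size - 1)))

    m = len(others)
    if m == 1:
        corr = np.ones((1, 1))
    else:
        corr = diffs.corr(min_periods=2).to_numpy()
        corr = np.where(np.isfinite(corr), corr, 0.5)
        np.fill_diagonal(corr, 1.0)
        # nearest PSD projection in case pairwise estimation broke positivity
        w, v = np.linalg.eigh(corr)
        corr = (v * np.clip(w, 1e-6, None)) @ v.T
        d = np.sqrt(np.diag(corr))
        corr = corr / np.outer(d, d)

    n_mc = int(min(dfs)) + 1
    rng = np.random.default_rng(seed)
    chol = np.linalg.cholesky(corr + 1e-10 * np.eye(m))
    z = rng.standard_normal((mc_replicates, n_mc, m)) @ chol.T
    t_null = z.mean(axis=1) / (z.std(axis=1, ddof=1) / np.sqrt(n_mc))
    max_abs = np.abs(t_null).max(axis=1)

    out = []
    for c, t, df, raw in zip(others, stats_obs, dfs, raws):
        p_adj = float((np.count_nonzero(max_abs >= abs(t)) + 1) / (mc_replicates + 1))
        d = diffs[c].dropna()
        out.append(
            DunnettComparison(
                condition=str(c),
                mean_difference=float(d.mean()),
                t_stat=t,
                df=df,
                p_raw=raw,
                p_adjusted=max(p_adj, raw),
            )
        )
    return tuple(out)
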