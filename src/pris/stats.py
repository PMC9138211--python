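"""Statistical battery: power analysis, regression, and the two ANOVAs.

The sample-size calculation uses the Fisher z approximation for a two-tailed
test of a Pearson correlation: with effect size r, significance level alpha
and target power 1-beta,

    n = ceil( ((z_{1-alpha/2} + z_{power}) / atanh(r))^2 + 3 ).

The repeated-measures one-way ANOVA is the classical within-subject
sum-of-squares partition (subjects x timepoints, no between factor), with an
optional Greenhouse-Geisser correction; post-hoc timepoint contrasts are
paired t tests with a configurable correction.  The between-group one-way
ANOVA on dMSS-24 by PRIS band delegates to scipy, with Tukey HSD (default)
or Bonferroni-corrected pairwise t tests as post-hoc.
"""

from __future__ import annotations

import dataclasses
import itertools
import math
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from scipy import stats as sps

from .errors import DegenerateDesignError, ValidationError


@dataclasses.dataclass(frozen=True)
class PowerSpec:
    """Target effect size (correlation), two-tailed alpha, and power."""

    r: float = 0.3
    alpha: float = 0.05
    power: float = 0.80

    def __post_init__(self) -> None:
        if not 0 < self.r < 1:
            raise ValidationError(f"r must lie in (0, 1), got {self.r}")
        if not 0 < self.alpha < 1:
            raise ValidationError(f"alpha must lie in (0, 1), got {self.alpha}")
        if not 0 < self.power < 1:
            raise ValidationError(f"power must lie in (0, 1), got {self.power}")


@dataclasses.dataclass(frozen=True)
class RegressionResult:
    slope: float
    intercept: float
    r: float  # correlation magnitude
    f_stat: float
    df: tuple[int, int]
    p_value: float
    component_betas: Optional[pd.DataFrame] = None
    note: Optional[str] = None


@dataclasses.dataclass(frozen=True)
class AnovaResult:
    f_stat: float
    df: tuple[float, float]
    p_value: float
    pairwise: tuple[tuple[str, float], ...] = ()


# ---------------------------------------------------------------------------
# Power / sample size for Pearson's correlation
# ---------------------------------------------------------------------------


def power_pearson(n: int, r: float, alpha: float = 0.05) -> float:
    """Analytic power of the two-tailed test of rho = 0 at sample size ``n``.

    Uses the Fisher z approximation; both rejection tails are included
    (the far tail is negligible for r well away from 0).
    """
    if n < 4:
        raise ValidationError(f"need n >= 4 for the Fisher z approximation, got {n}")
    if not 0 <= r < 1:
        raise ValidationError(f"r must lie in [0, 1), got {r}")
    z_crit = sps.norm.ppf(1 - alpha / 2)
    shift = math.atanh(r) * math.sqrt(n - 3)
    return float(sps.norm.cdf(shift - z_crit) + sps.norm.cdf(-shift - z_crit))


def sample_size_pearson(spec: PowerSpec) -> int:
    """Smallest n whose analytic power reaches the target.

    Starts from the closed-form Fisher z solution and steps to the smallest
    integer n with ``power_pearson(n) >= spec.power``.
    """
    z_a = sps.norm.ppf(1 - spec.alpha / 2)
    z_b = sps.norm.ppf(spec.power)
    n = math.ceil(((z_a + z_b) / math.atanh(spec.r)) ** 2 + 3)
    n = max(n, 4)
    while power_pearson(n, spec.r, spec.alpha) < spec.power:
        n += 1
    while n > 4 and power_pearson(n - 1, spec.r, spec.alpha) >= spec.power:
        n -= 1
    return n


def monte_carlo_power_pearson(
    n: int,
    r: float,
    alpha: float = 0.05,
    n_reps: int = 20_000,
    rng: Optional[np.random.Generator] = None,
) -> float:
    """Empirical power by simulating bivariate-normal cohorts (vectorized)."""
    if rng is None:
        rng = np.random.default_rng()
    x = rng.standard_normal((n_reps, n))
    y = r * x + math.sqrt(1 - r * r) * rng.standard_normal((n_reps, n))
    xc = x - x.mean(axis=1, keepdims=True)
    yc = y - y.mean(axis=1, keepdims=True)
    rhat = (xc * yc).sum(axis=1) / np.sqrt(
        (xc**2).sum(axis=1) * (yc**2).sum(axis=1)
    )
    t = rhat * np.sqrt((n - 2) / (1 - rhat**2))
    t_crit = sps.t.ppf(1 - alpha / 2, n - 2)
    return float(np.mean(np.abs(t) > t_crit))


# ---------------------------------------------------------------------------
# Regression
# ---------------------------------------------------------------------------


def simple_regression(x: Sequence[float], y: Sequence[float]) -> RegressionResult:
    """Ordinary least squares of y on x with the F test of the slope.

    Reports R as the correlation magnitude; F = R^2/(1-R^2) * (n-2) on
    df (1, n-2) with a two-sided p from the F distribution.
    """
    xa = np.asarray(x, dtype=float)
    ya = np.asarray(y, dtype=float)
    if xa.shape != ya.shape or xa.ndim != 1:
        raise ValidationError("x and y must be equal-length 1-D sequences")
    n = xa.size
    if n < 3:
        raise DegenerateDesignError(f"need at least 3 observations, got {n}")
    if np.ptp(xa) == 0:
        raise DegenerateDesignError("constant predictor: regression undefined")
    fit = sps.linregress(xa, ya)
    r2 = fit.rvalue**2
    df2 = n - 2
    if r2 >= 1.0:
        f_stat, p = math.inf, 0.0
    else:
        f_stat = r2 / (1 - r2) * df2
        p = float(sps.f.sf(f_stat, 1, df2))
    return RegressionResult(
        slope=float(fit.slope),
        intercept=float(fit.intercept),
        r=float(abs(fit.rvalue)),
        f_stat=float(f_stat),
        df=(1, df2),
        p_value=p,
        note="denominator df = n - 2",
    )


def component_regression(
    frame: pd.DataFrame,
    outcome: str = "delta24_pct",
    parameters: Optional[Sequence[str]] = None,
) -> dict[str, RegressionResult]:
    """Per-parameter dummy regressions of the outcome on score categories.

    For each PRIS parameter the outcome (rescaled to a 0-1 proportion) is
    regressed on indicator variables for the parameter's observed score
    categories, with the lowest-scoring observed category as reference.
    Returns one result per parameter whose ``component_betas`` frame carries
    beta, 95% CI and the category score — reference rows show NaN betas, as
    a dash would in a printed table.  Parameters with a single observed
    category are skipped.
    """
    import statsmodels.api as sm

    if parameters is None:
        parameters = [
            "age_score",
            "clinical_score",
            "onset_score",
            "sensitization_score",
            "exposure_score",
            "ratio_score",
            "crd_score",
            "dominance_score",
        ]
    y = frame[outcome].to_numpy(dtype=float) / 100.0
    results: dict[str, RegressionResult] = {}
    for param in parameters:
        levels = sorted(frame[param].unique())
        if len(levels) < 2:
            continue
        reference, others = levels[0], levels[1:]
        X = np.column_stack(
            [np.ones(len(frame))]
            + [(frame[param] == lev).to_numpy(dtype=float) for lev in others]
        )
        fit = sm.OLS(y, X).fit()
        conf = fit.conf_int(alpha=0.05)
        rows = [
            {
                "score": reference,
                "beta": np.nan,
                "ci_low": np.nan,
                "ci_high": np.nan,
                "reference": True,
            }
        ]
        for i, lev in enumerate(others, start=1):
            rows.append(
                {
                    "score": lev,
                    "beta": float(fit.params[i]),
                    "ci_low": float(conf[i, 0]),
                    "ci_high": float(conf[i, 1]),
                    "reference": False,
                }
            )
        betas = pd.DataFrame(rows)
        r = math.sqrt(max(fit.rsquared, 0.0))
        results[param] = RegressionResult(
            slope=math.nan,
            intercept=float(fit.params[0]),
            r=r,
            f_stat=float(fit.fvalue),
            df=(int(fit.df_model), int(fit.df_resid)),
            p_value=float(fit.f_pvalue),
            component_betas=betas,
        )
    return results


# ---------------------------------------------------------------------------
# ANOVA
# ---------------------------------------------------------------------------


def _gg_epsilon(data: np.ndarray) -> float:
    """Greenhouse-Geisser epsilon from the sample covariance of timepoints."""
    k = data.shape[1]
    S = np.cov(data, rowvar=False)
    mean_diag = np.trace(S) / k
    grand = S.mean()
    row_means = S.mean(axis=1)
    num = (k * (mean_diag - grand)) ** 2
    den = (k - 1) * (
        (S**2).sum() - 2 * k * (row_means**2).sum() + k * k * grand**2
    )
    return float(num / den) if den > 0 else 1.0


def rm_anova(
    data: pd.DataFrame | np.ndarray,
    correction: str = "none",
    posthoc: str = "uncorrected",
) -> AnovaResult:
    """One-way repeated-measures ANOVA over timepoint columns.

    ``data`` is a complete subjects x timepoints matrix (completers only;
    any missing cell is an error directing to completer filtering).
    ``correction`` is ``"none"`` or ``"gg"`` (Greenhouse-Geisser).
    Post-hoc paired t tests between all timepoint pairs use ``posthoc``:
    ``"uncorrected"``, ``"bonferroni"`` or ``"none"`` (skip pairwise).
    """
    if isinstance(data, pd.DataFrame):
        labels = [str(c) for c in data.columns]
        mat = data.to_numpy(dtype=float)
    else:
        mat = np.asarray(data, dtype=float)
        labels = [f"level{i}" for i in range(mat.shape[1])]
    if mat.ndim != 2 or mat.shape[1] < 2:
        raise ValidationError("need a 2-D matrix with >= 2 within-subject levels")
    if np.isnan(mat).any():
        raise DegenerateDesignError(
            "missing timepoint cell: restrict the matrix to completers first"
        )
    n, k = mat.shape
    if n < 2:
        raise DegenerateDesignError("need at least 2 subjects")

    grand = mat.mean()
    ss_time = n * ((mat.mean(axis=0) - grand) ** 2).sum()
    ss_subj = k * ((mat.mean(axis=1) - grand) ** 2).sum()
    ss_total = ((mat - grand) ** 2).sum()
    ss_err = ss_total - ss_time - ss_subj
    df_time, df_err = k - 1.0, (n - 1.0) * (k - 1.0)
    if correction == "gg":
        eps = _gg_epsilon(mat)
        df_time *= eps
        df_err *= eps
    elif correction != "none":
        raise ValidationError(f"unknown sphericity correction {correction!r}")
    ms_time = ss_time / (k - 1)
    ms_err = ss_err / ((n - 1) * (k - 1))
    f_stat = ms_time / ms_err if ms_err > 0 else (0.0 if ss_time == 0 else math.inf)
    p = float(sps.f.sf(f_stat, df_time, df_err)) if math.isfinite(f_stat) else 0.0

    pairs: list[tuple[str, float]] = []
    m = k * (k - 1) // 2
    pair_iter = [] if posthoc == "none" else itertools.combinations(range(k), 2)
    for i, j in pair_iter:
        diff = mat[:, i] - mat[:, j]
        if np.allclose(diff.std(ddof=1), 0):
            p_ij = 1.0 if np.allclose(diff.mean(), 0) else 0.0
        else:
            p_ij = float(sps.ttest_rel(mat[:, i], mat[:, j]).pvalue)
        if posthoc == "bonferroni":
            p_ij = min(1.0, p_ij * m)
        elif posthoc != "uncorrected":
            raise ValidationError(f"unknown post-hoc correction {posthoc!r}")
        pairs.append((f"{labels[i]}-vs-{labels[j]}", p_ij))

    return AnovaResult(
        f_stat=float(f_stat), df=(df_time, df_err), p_value=p, pairwise=tuple(pairs)
    )


def oneway_anova_posthoc(
    values: Sequence[float],
    groups: Sequence[str],
    posthoc: str = "tukey",
) -> AnovaResult:
    """Between-group one-way ANOVA with pairwise post-hoc comparisons.

    ``posthoc`` is ``"tukey"`` (Tukey HSD), ``"bonferroni"`` or ``"none"``;
    pairwise p-values are reported only when three or more groups are present.
    """
    va = np.asarray(values, dtype=float)
    ga = np.asarray(groups)
    labels = sorted(set(ga.tolist()))
    samples = [va[ga == g] for g in labels]
    if len(labels) < 2:
        raise DegenerateDesignError("need at least 2 non-empty groups")
    f_stat, p = sps.f_oneway(*samples)
    n = va.size
    df = (len(labels) - 1, n - len(labels))

    pairs: list[tuple[str, float]] = []
    if len(labels) >= 3 and posthoc != "none":
        if posthoc == "tukey":
            res = sps.tukey_hsd(*samples)
            for i, j in itertools.combinations(range(len(labels)), 2):
                pairs.append((f"{labels[i]}-vs-{labels[j]}", float(res.pvalue[i, j])))
        elif posthoc == "bonferroni":
            m = len(labels) * (len(labels) - 1) // 2
            for i, j in itertools.combinations(range(len(labels)), 2):
                p_ij = float(sps.ttest_ind(samples[i], samples[j]).pvalue)
                pairs.append((f"{labels[i]}-vs-{labels[j]}", min(1.0, p_ij * m)))
        else:
            raise ValidationError(f"unknown post-hoc method {posthoc!r}")

    return AnovaResult(
        f_stat=float(f_stat), df=df, p_value=float(p), pairwise=tuple(pairs)
    )
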