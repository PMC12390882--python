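"""Accuracy, reproducibility and factorial analysis of BV/TV measurements.

All quantities in this module are in percent BV/TV.  The error of a
measurement is its signed delta to the reference standard,

    delta_i^n = BVTV_method,i^n - BVTV_reference,i

for sample ``i`` and repetition ``n``.  Accuracy is the mean over samples of
the per-sample repetition-averaged error, tested against zero with a
two-sided one-sample t-test.  Reproducibility follows the short-term
precision-error convention of densitometry: the root mean square of the
per-sample standard deviations over repeated measurements.

Factorial comparisons (fluid, measurement, dose, tube voltage) use ordinary
least squares ANOVA (Type II sums of squares, identical to Type I/III on the
balanced designs produced here) with Bonferroni-adjusted pairwise contrasts
on estimated marginal means, plus the usual assumption checks (boxplot-rule
outliers, Shapiro-Wilk on residuals, Levene across groups).
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats
import statsmodels.api as sm
import statsmodels.formula.api as smf
from statsmodels.stats.anova import anova_lm

__all__ = [
    "EvaluationRecord",
    "AccuracyReport",
    "PrecisionReport",
    "PrecisionUnavailableError",
    "UnbalancedDesignError",
    "AnovaResult",
    "records_to_frame",
    "accuracy",
    "precision",
    "anova",
    "significance_stars",
]


@dataclass(frozen=True)
class EvaluationRecord:
    """One BV/TV measurement of one sample under one condition (percent)."""

    sample_id: str
    method: str
    fluid: str
    ctdi: float
    voltage: float | str
    repetition: int
    bvtv_estimate: float
    bvtv_reference: float

    @property
    def delta(self) -> float:
        return self.bvtv_estimate - self.bvtv_reference


def records_to_frame(records: Sequence[EvaluationRecord]) -> pd.DataFrame:
    df = pd.DataFrame([vars(r) for r in records])
    df["delta"] = df["bvtv_estimate"] - df["bvtv_reference"]
    return df


class PrecisionUnavailableError(ValueError):
    """Precision needs repeated measurements; the cell has only one."""


class UnbalancedDesignError(ValueError):
    """The factorial design has missing or unequal cells."""


@dataclass(frozen=True)
class AccuracyReport:
    """Mean error of a measurement cell and its one-sample t-test."""

    per_sample_errors: pd.Series  # repetition-averaged error per sample
    per_repetition_means: dict[int, float]  # mean delta per repetition
    mean_error: float
    t_statistic: float | None
    p_value: float | None
    degenerate: bool = False


@dataclass(frozen=True)
class PrecisionReport:
    per_sample_abs_mean_delta: pd.Series
    per_sample_sd: pd.Series
    precision_sd: float  # root mean square of per-sample SDs


def _deltas(df: pd.DataFrame) -> pd.DataFrame:
    df = df.copy()
    if "delta" not in df:
        df["delta"] = df["bvtv_estimate"] - df["bvtv_reference"]
    return df


def accuracy(df: pd.DataFrame) -> AccuracyReport:
    """Accuracy of one measurement cell (method x fluid x dose).

    Every sample needs at least one repetition; cells measured once use the
    single delta as the per-sample error.  The t-test is two-sided against a
    hypothesised mean error of zero with n_samples - 1 degrees of freedom; a
    zero-variance cell is reported as degenerate rather than an error.
    """
    df = _deltas(df)
    per_sample = df.groupby("sample_id")["delta"].mean()
    per_rep = df.groupby("repetition")["delta"].mean().to_dict()
    mean_error = float(per_sample.mean())
    if per_sample.size < 2 or np.allclose(per_sample, per_sample.iloc[0]):
        return AccuracyReport(per_sample, per_rep, mean_error, None, None, degenerate=True)
    t, p = stats.ttest_1samp(per_sample, 0.0)
    return AccuracyReport(per_sample, per_rep, mean_error, float(t), float(p))


def precision(df: pd.DataFrame) -> PrecisionReport:
    """Short-term precision error from exactly two repetitions per sample.

    For n = 2 the per-sample SD reduces to |delta_rep1 - delta_rep2| / sqrt(2);
    the overall precision error is the RMS of the per-sample SDs.
    """
    df = _deltas(df)
    counts = df.groupby("sample_id")["repetition"].nunique()
    if (counts < 2).any():
        raise PrecisionUnavailableError(
            "the measurement was done only once for some samples; "
            "precision cannot be calculated"
        )
    if (counts != 2).any():
        raise ValueError("precision expects exactly 2 repetitions per sample")
    wide = df.pivot_table(index="sample_id", columns="repetition", values="delta")
    d1, d2 = wide.iloc[:, 0], wide.iloc[:, 1]
    sd = (d1 - d2).abs() / np.sqrt(2.0)
    abs_mean = (d1.abs() + d2.abs()) / 2.0
    return PrecisionReport(
        per_sample_abs_mean_delta=abs_mean,
        per_sample_sd=sd,
        precision_sd=float(np.sqrt((sd**2).mean())),
    )


# --------------------------------------------------------------------------
# factorial ANOVA


@dataclass
class AssumptionChecks:
    shapiro_statistic: float
    shapiro_p: float
    levene_statistic: float
    levene_p: float
    outliers: pd.DataFrame  # rows flagged by the 1.5x / 3x IQR boxplot rule


@dataclass
class AnovaResult:
    table: pd.DataFrame
    pairwise: dict[str, pd.DataFrame]
    assumptions: AssumptionChecks | None
    residual_df: int
    mse: float


def _check_balanced(df: pd.DataFrame, factors: Sequence[str]) -> None:
    levels = [sorted(df[f].unique()) for f in factors]
    counts = df.groupby(list(factors), observed=True).size()
    missing = [
        combo
        for combo in itertools.product(*levels)
        if combo not in (counts.index if len(factors) > 1 else [(i,) for i in counts.index])
    ]
    if len(factors) == 1:
        missing = [c for c in itertools.product(*levels) if c[0] not in counts.index]
    if missing:
        raise UnbalancedDesignError(f"missing design cells: {missing}")
    if counts.nunique() != 1:
        raise UnbalancedDesignError(f"unequal cell sizes: {counts.to_dict()}")


def _pairwise_emmeans(
    df: pd.DataFrame,
    dv: str,
    group_cols: Sequence[str],
    mse: float,
    df_resid: int,
    alpha: float,
) -> pd.DataFrame:
    """Bonferroni-adjusted pairwise contrasts on estimated marginal means.

    On a balanced design the marginal means equal the cell means; the
    standard error of each contrast uses the pooled residual variance of the
    fitted model, mirroring the usual emmeans machinery.
    """
    groups = df.groupby(list(group_cols), observed=True)[dv]
    means, ns = groups.mean(), groups.size()
    keys = list(means.index)
    rows = []
    pairs = list(itertools.combinations(keys, 2))
    for a, b in pairs:
        diff = means[a] - means[b]
        se = np.sqrt(mse * (1 / ns[a] + 1 / ns[b]))
        t = diff / se
        p = 2 * stats.t.sf(abs(t), df_resid)
        rows.append(
            {
                "group_a": a,
                "group_b": b,
                "estimate": diff,
                "se": se,
                "t": t,
                "p_unadjusted": p,
                "p_bonferroni": min(1.0, p * len(pairs)),
            }
        )
    out = pd.DataFrame(rows)
    out["significant"] = out["p_bonferroni"] < alpha
    return out


def anova(
    df: pd.DataFrame,
    factors: Sequence[str],
    dv: str = "delta",
    *,
    alpha: float = 0.05,
    checks: bool = True,
    pairwise: bool = True,
) -> AnovaResult:
    """Full-factorial ANOVA of ``dv`` over ``factors`` with follow-up contrasts.

    Requires a balanced complete design (the study generator guarantees one);
    an unbalanced input raises :class:`UnbalancedDesignError` naming the
    missing cells.  Significant effects (p < alpha) are followed by
    Bonferroni-adjusted pairwise comparisons on the marginal means of the
    factor (or, for interactions, of the crossed cells).
    """
    factors = list(factors)
    df = df.copy().reset_index(drop=True)
    _check_balanced(df, factors)
    # map factor names to patsy-safe categorical terms
    terms = [f"C({f})" for f in factors]
    formula = f"{dv} ~ " + " * ".join(terms)
    model = smf.ols(formula, data=df).fit()
    table = anova_lm(model, typ=2)
    mse = float(table.loc["Residual", "sum_sq"] / table.loc["Residual", "df"])
    df_resid = int(table.loc["Residual", "df"])

    pw: dict[str, pd.DataFrame] = {}
    if pairwise:
        for effect in table.index:
            if effect == "Residual" or not np.isfinite(table.loc[effect, "PR(>F)"]):
                continue
            if table.loc[effect, "PR(>F)"] >= alpha:
                continue
            cols = [f for f in factors if f"C({f})" in effect.split(":")]
            if len(df.groupby(cols, observed=True)) > 1:
                pw[":".join(cols)] = _pairwise_emmeans(df, dv, cols, mse, df_resid, alpha)

    assumptions = None
    if checks:
        resid = model.resid
        sh_w, sh_p = stats.shapiro(resid) if 3 <= resid.size <= 5000 else (np.nan, np.nan)
        cells = [g[dv].to_numpy() for _, g in df.groupby(factors, observed=True)]
        lv_w, lv_p = stats.levene(*cells) if len(cells) > 1 else (np.nan, np.nan)
        flagged = []
        for key, g in df.groupby(factors, observed=True):
            q1, q3 = np.percentile(g[dv], [25, 75])
            iqr = q3 - q1
            mild = (g[dv] < q1 - 1.5 * iqr) | (g[dv] > q3 + 1.5 * iqr)
            extreme = (g[dv] < q1 - 3 * iqr) | (g[dv] > q3 + 3 * iqr)
            sub = g.loc[mild].copy()
            if not sub.empty:
                sub["extreme"] = extreme[mild]
                flagged.append(sub)
        outliers = pd.concat(flagged) if flagged else df.iloc[0:0].copy()
        assumptions = AssumptionChecks(
            shapiro_statistic=float(sh_w),
            shapiro_p=float(sh_p),
            levene_statistic=float(lv_w),
            levene_p=float(lv_p),
            outliers=outliers,
        )
    return AnovaResult(
        table=table, pairwise=pw, assumptions=assumptions, residual_df=df_resid, mse=mse
    )


def significance_stars(p: float | None) -> str:
    """Conventional star coding at 0.05 / 0.01 / 1e-3 / 1e-4."""
    if p is None or not np.isfinite(p):
        return ""
    for thresh, stars in ((1e-4, "****"), (1e-3, "***"), (0.01, "**"), (0.05, "*")):
        if p < thresh:
            return stars
    return ""
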