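"""Cohort-comparison statistics.

The comparison machinery used throughout the analysis:

- a *normality gate*: a sample is treated as non-Gaussian when either
  the Shapiro-Wilk or D'Agostino K-squared test rejects at alpha=0.05;
- a *dual test* for non-Gaussian indices: a difference is claimed only
  when both the Mann-Whitney U test and Mood's median test give
  p < 0.05 (a conjunction that is never less conservative than either
  component);
- Kruskal-Wallis H for diagnosis subgroups;
- per-(feature, stage) Mann-Whitney U tests between concordant and
  discordant sleep at alpha=0.01;
- LASSO-penalized multilinear regression of the log-transformed
  discordant proportion on 24-h-segment features, with an OLS refit on
  the selected support for r-squared and F statistics;
- Pearson + Spearman dose/severity correlations.

No multiple-testing correction is applied anywhere: alphas are per-test
by design (0.01 for the feature screen, 0.05 elsewhere).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import stats
from sklearn.linear_model import LassoCV
from sklearn.model_selection import KFold
from sklearn.preprocessing import StandardScaler

__all__ = [
    "DualTestResult",
    "DiscordanceModel",
    "normality_gate",
    "dual_test",
    "kruskal_subgroups",
    "feature_discordance_tests",
    "discordance_regression",
    "dose_correlations",
    "breathing_cohort_compare",
]

LOG_EPSILON = 1e-3  # added before log: fully-concordant segments have y = 0


@dataclass
class DualTestResult:
    p_mwu: float
    p_mood: float
    medians: tuple[float, float]
    significant: bool
    degenerate: bool = False


@dataclass
class DiscordanceModel:
    selected_features: list[str]
    coefficients: dict[str, float]
    r_squared: float
    f_stat: float
    f_p: float
    alpha: float = np.nan


def normality_gate(x: np.ndarray, alpha: float = 0.05) -> bool:
    """True when the sample should be treated as non-Gaussian.

    Rejection by *either* Shapiro-Wilk or D'Agostino's K-squared test at
    ``alpha`` flags non-normality.  Requires n >= 8 (the K-squared test
    is invalid below that).  A constant sample is degenerate and is
    flagged non-Gaussian.
    """
    x = np.asarray(x, dtype=float)
    x = x[np.isfinite(x)]
    if len(x) < 8:
        raise ValueError("normality_gate requires n >= 8")
    if np.ptp(x) == 0:
        return True  # degenerate: constant sample, flagged non-Gaussian
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        p_sw = stats.shapiro(x).pvalue
        p_dk = stats.normaltest(x).pvalue
    return (p_sw < alpha) or (p_dk < alpha)


def dual_test(x: np.ndarray, y: np.ndarray, alpha: float = 0.05) -> DualTestResult:
    """Two-sided Mann-Whitney U plus Mood's median test.

    The difference is significant only if both p-values are below
    ``alpha``.  Observations tied at the grand median are pooled into
    the "<= median" cell of Mood's test.  Fully tied data yields p = 1
    and a degenerate flag.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    x, y = x[np.isfinite(x)], y[np.isfinite(y)]
    if len(x) < 3 or len(y) < 3:
        raise ValueError("dual_test requires n >= 3 per group")
    medians = (float(np.median(x)), float(np.median(y)))
    if np.ptp(np.concatenate([x, y])) == 0:
        return DualTestResult(1.0, 1.0, medians, False, degenerate=True)
    p_mwu = float(stats.mannwhitneyu(x, y, alternative="two-sided").pvalue)
    try:
        p_mood = float(stats.median_test(x, y, ties="below").pvalue)
    except ValueError:
        # everything on one side of the grand median
        return DualTestResult(p_mwu, 1.0, medians, False, degenerate=True)
    return DualTestResult(
        p_mwu=p_mwu,
        p_mood=p_mood,
        medians=medians,
        significant=(p_mwu < alpha) and (p_mood < alpha),
    )


def kruskal_subgroups(groups: dict[str, np.ndarray]) -> tuple[float, float]:
    """Kruskal-Wallis H test (tie-corrected) across named subgroups."""
    if len(groups) < 2:
        raise ValueError("need at least 2 groups")
    samples = []
    for name, g in groups.items():
        g = np.asarray(g, dtype=float)
        g = g[np.isfinite(g)]
        if len(g) < 2:
            raise ValueError(f"group {name!r} has fewer than 2 observations")
        samples.append(g)
    res = stats.kruskal(*samples)
    return float(res.statistic), float(res.pvalue)


def feature_discordance_tests(
    df: pd.DataFrame, alpha: float = 0.01
) -> pd.DataFrame:
    """Screen features for concordant-vs-discordant differences.

    ``df`` is tidy with columns [feature, stage, stratum, value] where
    stratum is "concordant" or "discordant".  One output row per
    (feature, stage) pair — nothing is silently dropped; pairs with an
    empty stratum are emitted with NaN p and skipped=True.  Direction is
    the sign of (discordant mean - concordant mean).
    """
    required = {"feature", "stage", "stratum", "value"}
    if not required.issubset(df.columns):
        raise ValueError(f"df must have columns {sorted(required)}")
    rows = []
    for (feat, stage), grp in df.groupby(["feature", "stage"], sort=True):
        c = grp.loc[grp["stratum"] == "concordant", "value"].dropna().to_numpy()
        d = grp.loc[grp["stratum"] == "discordant", "value"].dropna().to_numpy()
        row = {
            "feature": feat,
            "stage": stage,
            "n_concordant": len(c),
            "n_discordant": len(d),
            "mean_concordant": c.mean() if len(c) else np.nan,
            "mean_discordant": d.mean() if len(d) else np.nan,
        }
        if len(c) == 0 or len(d) == 0:
            row.update(p_mwu=np.nan, significant=False, skipped=True,
                       direction=0.0)
        else:
            if np.ptp(np.concatenate([c, d])) == 0:
                p = 1.0
            else:
                p = float(stats.mannwhitneyu(c, d, alternative="two-sided").pvalue)
            row.update(
                p_mwu=p,
                significant=p < alpha,
                skipped=False,
                direction=float(np.sign(row["mean_discordant"] - row["mean_concordant"])),
            )
        rows.append(row)
    return pd.DataFrame(rows)


def discordance_regression(
    X: pd.DataFrame,
    y: np.ndarray,
    seed: int = 0,
    epsilon: float = LOG_EPSILON,
    cv: int = 5,
) -> DiscordanceModel:
    """LASSO-penalized regression of log discordant proportion on
    segment-level features.

    y' = log(y + epsilon); features are standardized; the penalty is
    chosen by ``cv``-fold cross-validation (seeded) with the
    one-standard-error rule (largest penalty whose CV error is within
    one SE of the minimum — the conservative convention, which keeps
    spurious selections on pure-noise designs rare); an OLS refit on
    the selected support reports r-squared and the F statistic.
    """
    X = pd.DataFrame(X)
    y = np.asarray(y, dtype=float)
    if len(X) != len(y):
        raise ValueError("X and y length mismatch")
    if len(y) <= 10:
        raise ValueError("need more than 10 segments")
    if np.any((y < 0) | (y > 1)):
        raise ValueError("y must be proportions in [0, 1]")
    if np.ptp(y) == 0:
        raise ValueError("constant outcome: regression undefined")
    y_log = np.log(y + epsilon)
    Xs = StandardScaler().fit_transform(X.to_numpy(dtype=float))
    lasso = LassoCV(
        cv=KFold(n_splits=cv, shuffle=True, random_state=seed),
        random_state=seed,
        max_iter=50_000,
    ).fit(Xs, y_log)
    # one-standard-error rule on the CV curve
    mse_mean = lasso.mse_path_.mean(axis=1)
    mse_se = lasso.mse_path_.std(axis=1, ddof=1) / np.sqrt(lasso.mse_path_.shape[1])
    k_min = int(np.argmin(mse_mean))
    limit = mse_mean[k_min] + mse_se[k_min]
    ok = np.nonzero(mse_mean <= limit)[0]
    alpha_1se = float(lasso.alphas_[ok.min()])  # alphas_ is descending
    from sklearn.linear_model import Lasso

    fit = Lasso(alpha=alpha_1se, max_iter=50_000).fit(Xs, y_log)
    # treat numerically-tiny coefficients as zero
    tol = 1e-6 * max(1.0, float(np.max(np.abs(fit.coef_), initial=0.0)))
    support = np.abs(fit.coef_) > tol
    names = list(X.columns)
    selected = [n for n, s in zip(names, support) if s]
    if not selected:
        return DiscordanceModel([], {}, 0.0, np.nan, 1.0, alpha=alpha_1se)
    ols = sm.OLS(y_log, sm.add_constant(Xs[:, support])).fit()
    coefs = dict(zip(selected, ols.params[1:]))
    return DiscordanceModel(
        selected_features=selected,
        coefficients=coefs,
        r_squared=float(ols.rsquared),
        f_stat=float(ols.fvalue),
        f_p=float(ols.f_pvalue),
        alpha=alpha_1se,
    )


def dose_correlations(dose: np.ndarray, y: np.ndarray) -> dict[str, float]:
    """Pearson and Spearman correlation of a dose/severity variable with
    the discordant proportion.  An association is claimed only when both
    p-values are below 0.05."""
    dose = np.asarray(dose, dtype=float)
    y = np.asarray(y, dtype=float)
    ok = np.isfinite(dose) & np.isfinite(y)
    dose, y = dose[ok], y[ok]
    if len(dose) < 5:
        raise ValueError("need at least 5 paired observations")
    if np.ptp(dose) == 0 or np.ptp(y) == 0:
        return {
            "pearson_r": np.nan, "pearson_p": np.nan,
            "spearman_rho": np.nan, "spearman_p": np.nan,
            "associated": False,
        }
    pr = stats.pearsonr(dose, y)
    sr = stats.spearmanr(dose, y)
    return {
        "pearson_r": float(pr.statistic),
        "pearson_p": float(pr.pvalue),
        "spearman_rho": float(sr.statistic),
        "spearman_p": float(sr.pvalue),
        "associated": (pr.pvalue < 0.05) and (sr.pvalue < 0.05),
    }


def _stars(p: float) -> str:
    if not np.isfinite(p):
        return ""
    if p < 0.001:
        return "***"
    if p < 0.05:
        return "*"
    return ""


def breathing_cohort_compare(
    features: pd.DataFrame, cohort: pd.Series | np.ndarray
) -> pd.DataFrame:
    """Compare per-patient breathing features between two cohorts.

    ``features``: one row per patient, one column per feature (already
    averaged across that patient's nights).  ``cohort``: two-level
    labels aligned with the rows.  Each feature is routed through the
    normality gate: Gaussian in both cohorts -> Welch two-sample t-test;
    otherwise -> the MWU + Mood dual test.  Cohorts with n < 3 are
    skipped (flagged in the output).  Stars: * p<0.05, *** p<0.001.
    """
    cohort = pd.Series(np.asarray(cohort), index=features.index)
    levels = list(pd.unique(cohort))
    if len(levels) != 2:
        raise ValueError("cohort must have exactly two levels")
    a_lab, b_lab = levels
    rows = []
    for feat in features.columns:
        a = features.loc[cohort == a_lab, feat].dropna().to_numpy()
        b = features.loc[cohort == b_lab, feat].dropna().to_numpy()
        row = {
            "feature": feat,
            f"mean_{a_lab}": a.mean() if len(a) else np.nan,
            f"sd_{a_lab}": a.std(ddof=1) if len(a) > 1 else np.nan,
            f"median_{a_lab}": np.median(a) if len(a) else np.nan,
            f"iqr_{a_lab}": stats.iqr(a) if len(a) else np.nan,
            f"mean_{b_lab}": b.mean() if len(b) else np.nan,
            f"sd_{b_lab}": b.std(ddof=1) if len(b) > 1 else np.nan,
            f"median_{b_lab}": np.median(b) if len(b) else np.nan,
            f"iqr_{b_lab}": stats.iqr(b) if len(b) else np.nan,
        }
        if len(a) < 3 or len(b) < 3:
            row.update(test="skipped", p=np.nan, p_mood=np.nan,
                       significant=False, stars="")
            rows.append(row)
            continue
        try:
            non_gauss = normality_gate(a) or normality_gate(b)
        except ValueError:
            non_gauss = True  # too small for the gate: be conservative
        if not non_gauss:
            p = float(stats.ttest_ind(a, b, equal_var=False).pvalue)
            row.update(test="t-test", p=p, p_mood=np.nan,
                       significant=p < 0.05, stars=_stars(p))
        else:
            res = dual_test(a, b)
            p_show = max(res.p_mwu, res.p_mood)
            row.update(test="mwu+mood", p=res.p_mwu, p_mood=res.p_mood,
                       significant=res.significant,
                       stars=_stars(p_show) if res.significant else "")
        rows.append(row)
    return pd.DataFrame(rows)
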