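"""Predictive-model pipeline and method-agreement statistics.

The modelling chain mirrors common clinical-research practice: a
univariate screen keeps predictors associated with the outcome at
p < 0.2, a stepwise multivariate linear regression (p-to-enter 0.05,
p-to-remove 0.10, partial F/t tests) selects the independent predictors,
variance inflation factors flag collinearity (VIF > 10), and an ROC
analysis evaluates discrimination of abnormal LVEF at the 54% cutoff.

Agreement between two measurement methods is summarised by Bland-Altman
limits of agreement, Pearson correlation, Lin's concordance correlation
coefficient and the two-way random-effects absolute-agreement
single-measure ICC.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import stats as sps

__all__ = [
    "ModelResult",
    "AgreementReport",
    "univariate_screen",
    "stepwise_regression",
    "roc_analysis",
    "agreement_stats",
    "bonferroni",
]


@dataclass
class ModelResult:
    """Final multivariate model: coefficients, fit and collinearity."""

    retained_predictors: list[str]
    betas: dict[str, float]
    ci95: dict[str, tuple[float, float]]
    p_values: dict[str, float]
    r2: float
    adj_r2: float
    f_stat: float | None
    f_df: tuple[float, float] | None
    vifs: dict[str, float]
    n: int
    fitted_values: np.ndarray = field(repr=False, default=None)
    high_vif: list[str] = field(default_factory=list)


@dataclass
class AgreementReport:
    """Bland-Altman + correlation-based agreement between two methods."""

    mean_diff: float
    mean_diff_ci: tuple[float, float]
    loa_low: float
    loa_low_ci: tuple[float, float]
    loa_high: float
    loa_high_ci: tuple[float, float]
    pearson_r: float
    lin_ccc: float
    bias_correction_factor: float
    icc: float
    n: int


def _as_frame(table) -> pd.DataFrame:
    if isinstance(table, pd.DataFrame):
        return table
    return pd.DataFrame(table)


def univariate_screen(table, outcome: str, alpha_keep: float = 0.2):
    """Simple linear regression of the outcome on each predictor.

    Returns ``{name: (slope, p_value)}`` for predictors with
    p < ``alpha_keep`` (two-sided t-test on the slope).
    """
    df = _as_frame(table)
    if outcome not in df.columns:
        raise KeyError(f"outcome column {outcome!r} not in table")
    y = df[outcome].to_numpy(dtype=float)
    if len(y) < 3:
        raise ValueError("need n >= 3 per regression")
    if np.ptp(y) == 0:
        raise ValueError("constant outcome")
    kept: dict[str, tuple[float, float]] = {}
    for name in df.columns:
        if name == outcome:
            continue
        x = df[name].to_numpy(dtype=float)
        ok = np.isfinite(x) & np.isfinite(y)
        if ok.sum() < 3 or np.ptp(x[ok]) == 0:
            continue
        res = sps.linregress(x[ok], y[ok])
        if res.pvalue < alpha_keep:
            kept[name] = (float(res.slope), float(res.pvalue))
    return kept


def _check_collinearity(df: pd.DataFrame, candidates: list[str]) -> None:
    x = df[candidates].to_numpy(dtype=float)
    xc = x - x.mean(axis=0)
    norms = np.linalg.norm(xc, axis=0)
    for i in range(len(candidates)):
        for j in range(i + 1, len(candidates)):
            if norms[i] == 0 or norms[j] == 0:
                continue
            r = abs(float(xc[:, i] @ xc[:, j]) / (norms[i] * norms[j]))
            if r > 1 - 1e-10:
                raise ValueError(
                    "perfectly collinear candidates: "
                    f"{candidates[i]!r} and {candidates[j]!r}"
                )
    if np.linalg.matrix_rank(np.column_stack([np.ones(len(x)), x])) < len(candidates) + 1:
        raise ValueError(f"singular candidate matrix among {candidates}")


def _fit_ols(df: pd.DataFrame, outcome: str, predictors: list[str]):
    y = df[outcome].to_numpy(dtype=float)
    x = sm.add_constant(df[list(predictors)].to_numpy(dtype=float)) if predictors else np.ones((len(y), 1))
    return sm.OLS(y, x).fit()


def stepwise_regression(
    table,
    outcome: str,
    candidates: list[str],
    p_enter: float = 0.05,
    p_remove: float = 0.10,
) -> ModelResult:
    """Forward selection with backward elimination on partial F-tests.

    At each forward step the candidate with the smallest coefficient
    p-value is added if p < ``p_enter``; included predictors are then
    dropped (worst first) while any has p > ``p_remove``. VIFs come from
    auxiliary regressions, 1/(1 - R2_j); values above 10 are flagged.
    """
    df = _as_frame(table)
    candidates = list(candidates)
    n = len(df)
    if n <= len(candidates) + 1:
        raise ValueError("need n > number of candidates + 1")
    if candidates:
        _check_collinearity(df, candidates)

    included: list[str] = []
    while True:
        changed = False
        # forward step
        remaining = [c for c in candidates if c not in included]
        best_p, best_c = None, None
        for c in remaining:
            res = _fit_ols(df, outcome, included + [c])
            p = res.pvalues[-1]
            if best_p is None or p < best_p:
                best_p, best_c = p, c
        if best_c is not None and best_p < p_enter:
            included.append(best_c)
            changed = True
        # backward step
        while included:
            res = _fit_ols(df, outcome, included)
            pvals = res.pvalues[1:]
            worst = int(np.argmax(pvals))
            if pvals[worst] > p_remove:
                included.pop(worst)
                changed = True
            else:
                break
        if not changed:
            break

    res = _fit_ols(df, outcome, included)
    names = ["const"] + included
    betas = dict(zip(names, (float(b) for b in res.params)))
    ci = res.conf_int(alpha=0.05)
    ci95 = {nm: (float(lo), float(hi)) for nm, (lo, hi) in zip(names, ci)}
    p_values = dict(zip(names, (float(p) for p in res.pvalues)))

    vifs: dict[str, float] = {}
    for c in included:
        others = [o for o in included if o != c]
        if others:
            aux = _fit_ols(df, c, others)
            r2j = min(aux.rsquared, 1 - 1e-12)
        else:
            r2j = 0.0
        vifs[c] = float(1.0 / (1.0 - r2j))

    r2 = float(res.rsquared) if included else 0.0
    adj = float(res.rsquared_adj) if included else 0.0
    return ModelResult(
        retained_predictors=included,
        betas=betas,
        ci95=ci95,
        p_values=p_values,
        r2=r2,
        adj_r2=adj,
        f_stat=float(res.fvalue) if included else None,
        f_df=(float(res.df_model), float(res.df_resid)) if included else None,
        vifs=vifs,
        n=n,
        fitted_values=np.asarray(res.fittedvalues),
        high_vif=[c for c, v in vifs.items() if v > 10],
    )


def roc_analysis(scores, truth, cutoff: float = 54.0):
    """ROC of predicted LVEF against the abnormal-LVEF label (< cutoff).

    Lower predicted LVEF means more abnormal, so the decision score is
    the negated prediction. AUC uses the rank (Mann-Whitney) formulation
    with tie correction; the curve is (FPR, TPR) over all thresholds.
    Returns ``(auc, points)``.
    """
    scores = np.asarray(scores, dtype=float)
    truth = np.asarray(truth, dtype=float)
    if scores.shape != truth.shape:
        raise ValueError("scores and truth must have equal length")
    labels = truth < cutoff  # abnormal = positive class
    n_pos = int(labels.sum())
    n_neg = int((~labels).sum())
    if n_pos == 0 or n_neg == 0:
        raise ValueError("both LVEF classes must be present")
    decision = -scores  # higher = more abnormal
    ranks = sps.rankdata(decision)  # average ranks handle ties
    auc = (ranks[labels].sum() - n_pos * (n_pos + 1) / 2.0) / (n_pos * n_neg)

    # curve over all distinct thresholds, descending
    order = np.argsort(-decision, kind="mergesort")
    d_sorted, l_sorted = decision[order], labels[order]
    distinct = np.r_[np.nonzero(np.diff(d_sorted))[0], d_sorted.size - 1]
    tps = np.cumsum(l_sorted)[distinct]
    fps = np.cumsum(~l_sorted)[distinct]
    tpr = np.r_[0.0, tps / n_pos]
    fpr = np.r_[0.0, fps / n_neg]
    return float(auc), np.column_stack([fpr, tpr])


def agreement_stats(x, y) -> AgreementReport:
    """Bland-Altman, Pearson, Lin's CCC and ICC(2,1) for paired methods.

    Differences are d = x - y; limits of agreement are mean(d) +/-
    1.96*SD(d), with t-based 95% CIs (SE of a limit ~ SD*sqrt(3/n)).
    Lin's CCC = 2*cov(x,y) / (var x + var y + (mean x - mean y)^2) and
    factors as Pearson r times the bias-correction factor C_b.
    ICC is the two-way random-effects, absolute-agreement, single-measure
    coefficient.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape:
        raise ValueError("x and y must have equal length")
    n = len(x)
    if n < 3:
        raise ValueError("need n >= 3")
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        raise ValueError("zero variance in x or y")

    d = x - y
    md = float(d.mean())
    sd = float(d.std(ddof=1))
    tcrit = sps.t.ppf(0.975, n - 1)
    se_mean = sd / np.sqrt(n)
    se_loa = sd * np.sqrt(3.0 / n)
    loa_low = md - 1.96 * sd
    loa_high = md + 1.96 * sd

    r = float(sps.pearsonr(x, y).statistic)
    sx2, sy2 = x.var(ddof=1), y.var(ddof=1)
    sxy = float(np.cov(x, y, ddof=1)[0, 1])
    ccc = 2.0 * sxy / (sx2 + sy2 + (x.mean() - y.mean()) ** 2)
    cb = ccc / r if r != 0 else np.nan

    # ICC(2,1): two-way random, absolute agreement, single measure
    data = np.column_stack([x, y])
    k = 2
    grand = data.mean()
    row_means = data.mean(axis=1)
    col_means = data.mean(axis=0)
    msr = k * ((row_means - grand) ** 2).sum() / (n - 1)
    msc = n * ((col_means - grand) ** 2).sum() / (k - 1)
    resid = data - row_means[:, None] - col_means[None, :] + grand
    mse = (resid**2).sum() / ((n - 1) * (k - 1))
    icc = (msr - mse) / (msr + (k - 1) * mse + k * (msc - mse) / n)

    return AgreementReport(
        mean_diff=md,
        mean_diff_ci=(md - tcrit * se_mean, md + tcrit * se_mean),
        loa_low=loa_low,
        loa_low_ci=(loa_low - tcrit * se_loa, loa_low + tcrit * se_loa),
        loa_high=loa_high,
        loa_high_ci=(loa_high - tcrit * se_loa, loa_high + tcrit * se_loa),
        pearson_r=r,
        lin_ccc=float(ccc),
        bias_correction_factor=float(cb),
        icc=float(icc),
        n=n,
    )


def bonferroni(p, m: int):
    """Bonferroni adjustment: min(1, m*p), monotone in p."""
    if m < 1:
        raise ValueError("m must be >= 1")
    return np.minimum(1.0, m * np.asarray(p, dtype=float))
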