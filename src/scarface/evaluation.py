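"""Model and endpoint evaluation: confusion-matrix metrics with exact
binomial confidence intervals, Cohen's kappa, ROC/AUC, and survival
analysis (Kaplan–Meier, log-rank, Cox proportional hazards).

A note on rate orientation: published confusion matrices in this setting
tally responders in the TP cell but print sensitivity/specificity with
the *other* class as positive — i.e. sensitivity = tn/(tn+fp) and
specificity = tp/(tp+fn).  :func:`metric_report` exposes this through
``rates_from_tn`` rather than hiding it.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from lifelines import CoxPHFitter, KaplanMeierFitter
from lifelines.statistics import multivariate_logrank_test


@dataclass(frozen=True)
class ConfusionMatrix:
    tp: int
    tn: int
    fp: int
    fn: int
    positive_class: str = "responder"

    def __post_init__(self) -> None:
        if min(self.tp, self.tn, self.fp, self.fn) < 0:
            raise ValueError("confusion-matrix counts must be non-negative")
        if self.n == 0:
            raise ValueError("empty confusion matrix")

    @property
    def n(self) -> int:
        return self.tp + self.tn + self.fp + self.fn


@dataclass(frozen=True)
class MetricReport:
    accuracy: float
    accuracy_ci: tuple[float, float]
    sensitivity: float | None
    specificity: float | None
    kappa: float


def confusion_matrix(predicted, actual, positive_class: str) -> ConfusionMatrix:
    """Tally TP/TN/FP/FN with TP oriented to *positive_class*."""
    predicted, actual = list(predicted), list(actual)
    if len(predicted) != len(actual):
        raise ValueError("label vectors differ in length")
    seen = set(actual)
    unseen = [p for p in set(predicted) if p not in seen and len(seen) >= 2]
    if unseen:
        raise ValueError(f"predicted labels not among actual classes: {unseen}")
    tp = sum(1 for p, a in zip(predicted, actual) if a == positive_class and p == a)
    fn = sum(1 for p, a in zip(predicted, actual) if a == positive_class and p != a)
    tn = sum(1 for p, a in zip(predicted, actual) if a != positive_class and p == a)
    fp = sum(1 for p, a in zip(predicted, actual) if a != positive_class and p != a)
    return ConfusionMatrix(tp, tn, fp, fn, positive_class)


def clopper_pearson(successes: int, n: int, conf: float = 0.95) -> tuple[float, float]:
    """Exact binomial confidence interval via the beta-quantile formulation."""
    if n <= 0:
        raise ValueError("n must be positive")
    if not 0 <= successes <= n:
        raise ValueError("successes must lie in [0, n]")
    alpha = 1.0 - conf
    lo = 0.0 if successes == 0 else float(stats.beta.ppf(alpha / 2, successes, n - successes + 1))
    hi = 1.0 if successes == n else float(stats.beta.ppf(1 - alpha / 2, successes + 1, n - successes))
    return lo, hi


def cohen_kappa(cm: ConfusionMatrix) -> float:
    """Chance-corrected agreement, (po - pe) / (1 - pe), from the 2x2 table."""
    n = cm.n
    po = (cm.tp + cm.tn) / n
    pe = ((cm.tp + cm.fp) * (cm.tp + cm.fn) + (cm.fn + cm.tn) * (cm.fp + cm.tn)) / n**2
    if pe == 1.0:
        return 0.0 if po == 1.0 else -1.0
    return (po - pe) / (1.0 - pe)


def metric_report(
    cm: ConfusionMatrix, conf: float = 0.95, rates_from_tn: bool = True
) -> MetricReport:
    """Accuracy (with exact CI), sensitivity, specificity and kappa.

    With ``rates_from_tn`` (the published convention; see module
    docstring) sensitivity = tn/(tn+fp) and specificity = tp/(tp+fn);
    otherwise the textbook orientation applies.  A rate with an empty
    denominator is reported as None.
    """
    acc = (cm.tp + cm.tn) / cm.n
    ci = clopper_pearson(cm.tp + cm.tn, cm.n, conf)
    if rates_from_tn:
        sens = cm.tn / (cm.tn + cm.fp) if (cm.tn + cm.fp) else None
        spec = cm.tp / (cm.tp + cm.fn) if (cm.tp + cm.fn) else None
    else:
        sens = cm.tp / (cm.tp + cm.fn) if (cm.tp + cm.fn) else None
        spec = cm.tn / (cm.tn + cm.fp) if (cm.tn + cm.fp) else None
    return MetricReport(acc, ci, sens, spec, cohen_kappa(cm))


# ---------------------------------------------------------------------------
# ROC

def roc_auc(scores, actual, positive_class: str) -> tuple[pd.DataFrame, float]:
    """ROC curve and AUC.

    AUC is the Mann–Whitney rank statistic with midranks for ties:
    P(score_pos > score_neg) + 0.5 P(equal).
    """
    scores = np.asarray(scores, dtype=float)
    actual = np.asarray(list(actual))
    pos = actual == positive_class
    n1, n0 = int(pos.sum()), int((~pos).sum())
    if n1 == 0 or n0 == 0:
        raise ValueError("both classes required for ROC analysis")
    ranks = stats.rankdata(scores)
    auc = (ranks[pos].sum() - n1 * (n1 + 1) / 2) / (n1 * n0)
    order = np.argsort(-scores, kind="mergesort")
    tps = np.cumsum(pos[order])
    fps = np.cumsum(~pos[order])
    distinct = np.r_[np.flatnonzero(np.diff(scores[order])), len(scores) - 1]
    curve = pd.DataFrame(
        {
            "threshold": scores[order][distinct],
            "tpr": tps[distinct] / n1,
            "fpr": fps[distinct] / n0,
        }
    )
    curve = pd.concat(
        [pd.DataFrame({"threshold": [np.inf], "tpr": [0.0], "fpr": [0.0]}), curve],
        ignore_index=True,
    )
    return curve, float(auc)


# ---------------------------------------------------------------------------
# survival

@dataclass
class SurvivalResult:
    km_curves: dict[str, pd.DataFrame]  # per group: time / survival / at_risk
    logrank_chi2: float | None = None
    logrank_p: float | None = None
    cox: pd.DataFrame | None = None  # per covariate: hr, ci_low, ci_high, p


def km_logrank(times, events, groups) -> SurvivalResult:
    """Kaplan–Meier curves per group with an (unweighted) log-rank test."""
    df = pd.DataFrame({"time": times, "event": events, "group": list(groups)})
    if df.empty:
        raise ValueError("no observations")
    curves: dict[str, pd.DataFrame] = {}
    for g, sub in df.groupby("group", sort=True):
        if sub.empty:
            raise ValueError(f"empty group {g!r}")
        kmf = KaplanMeierFitter()
        kmf.fit(sub["time"], sub["event"])
        curves[str(g)] = pd.DataFrame(
            {
                "time": kmf.survival_function_.index.to_numpy(),
                "survival": kmf.survival_function_.iloc[:, 0].to_numpy(),
                "at_risk": kmf.event_table["at_risk"].reindex(
                    kmf.survival_function_.index, method="ffill"
                ).to_numpy(),
            }
        )
    chi2 = p = None
    if df["group"].nunique() >= 2:
        if (df.groupby("group")["event"].sum() > 0).sum() == 0:
            raise ValueError("log-rank test needs at least one event")
        res = multivariate_logrank_test(df["time"], df["group"], df["event"])
        chi2, p = float(res.test_statistic), float(res.p_value)
    return SurvivalResult(km_curves=curves, logrank_chi2=chi2, logrank_p=p)


def cox_fit(times, events, covariates: pd.DataFrame, multivariate: bool = True) -> pd.DataFrame:
    """Cox proportional-hazards estimates (Efron tie handling).

    Returns one row per covariate with the hazard ratio, Wald 95% CI and
    p-value.  With ``multivariate=False`` each covariate is fit in its
    own univariate model.  Constant or rank-deficient covariates raise.
    """
    covariates = covariates.astype(float)
    if covariates.std(axis=0).min() == 0:
        const = covariates.columns[covariates.std(axis=0) == 0].tolist()
        raise ValueError(f"constant covariates: {const}")
    X = covariates.to_numpy()
    if multivariate and np.linalg.matrix_rank(np.c_[X, np.ones(len(X))]) <= X.shape[1]:
        raise ValueError("rank-deficient covariate matrix (collinear columns)")
    if np.sum(events) == 0:
        raise ValueError("no events observed")

    def _one(cols: list[str]) -> pd.DataFrame:
        df = covariates[cols].copy()
        df["time"] = np.asarray(times, dtype=float)
        df["event"] = np.asarray(events, dtype=int)
        cph = CoxPHFitter()
        cph.fit(df, duration_col="time", event_col="event")
        s = cph.summary
        return pd.DataFrame(
            {
                "hr": s["exp(coef)"],
                "ci_low": s["exp(coef) lower 95%"],
                "ci_high": s["exp(coef) upper 95%"],
                "p": s["p"],
            }
        )

    if multivariate:
        return _one(list(covariates.columns))
    return pd.concat([_one([c]) for c in covariates.columns])
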