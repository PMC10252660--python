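"""Feature-selection battery and cohort splitting.

Five selectors feed the single-source models: ANOVA F ranking,
signal-to-noise ratio, univariate logistic significance, recursive
feature elimination, and the Boruta shadow-feature procedure.  Every
selector sees training samples only; validation ids are never passed in.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy import stats
from sklearn.ensemble import RandomForestClassifier
from sklearn.feature_selection import RFE, f_classif
from sklearn.svm import SVC

from .io import FeatureMatrix

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class FeatureSelectionResult:
    method: str
    selected: tuple[str, ...]
    scores: dict[str, float] = field(default_factory=dict)
    flagged: tuple[str, ...] = ()  # e.g. separation in logistic fits


@dataclass(frozen=True)
class SplitPlan:
    train_ids: tuple[str, ...]
    validation_ids: tuple[str, ...]
    ratio: float
    seed: int
    stratified: bool = True


def split_cohort(
    sample_ids: list[str],
    labels: dict[str, str],
    ratio: float = 0.7,
    seed: int = 0,
    stratified: bool = True,
) -> SplitPlan:
    """Stratified random train/validation split.

    The training size per class is ``floor(ratio * n_class)``; if the
    per-class floors fall short of ``floor(ratio * n)`` overall, the
    remainder goes to the training side of the classes with the largest
    fractional parts.  For 183 samples at ratio 0.7 this yields 128
    training and 55 validation samples.
    """
    n = len(sample_ids)
    if not 0.0 < ratio < 1.0:
        raise ValueError("ratio must be strictly between 0 and 1")
    y = [labels[s] for s in sample_ids]
    classes = sorted(set(y))
    if stratified and len(classes) < 2:
        raise ValueError("cannot stratify a single-class cohort")
    rng = np.random.default_rng(seed)
    target_train = int(np.floor(ratio * n))
    per_class = {c: [s for s, lab in zip(sample_ids, y) if lab == c] for c in classes}
    floors = {c: int(np.floor(ratio * len(per_class[c]))) for c in classes}
    remainder = target_train - sum(floors.values())
    fracs = sorted(
        classes, key=lambda c: (ratio * len(per_class[c])) % 1.0, reverse=True
    )
    for c in fracs[:max(remainder, 0)]:
        floors[c] += 1
    train: list[str] = []
    val: list[str] = []
    for c in classes:
        members = list(per_class[c])
        rng.shuffle(members)
        train.extend(members[: floors[c]])
        val.extend(members[floors[c]:])
    if not val or not train:
        raise ValueError("split produced an empty series; adjust ratio")
    train_set = set(train)
    return SplitPlan(
        train_ids=tuple(s for s in sample_ids if s in train_set),
        validation_ids=tuple(s for s in sample_ids if s not in train_set),
        ratio=ratio,
        seed=seed,
        stratified=stratified,
    )


# ---------------------------------------------------------------------------
# helpers

def _xy(X: FeatureMatrix, y: dict[str, str] | list[str]) -> tuple[np.ndarray, np.ndarray]:
    """Samples x features array plus a boolean label vector (positive =
    lexicographically last class, i.e. 'responder' vs 'non_responder')."""
    if isinstance(y, dict):
        y = [y[s] for s in X.sample_ids]
    classes = sorted(set(y))
    if len(classes) != 2:
        raise ValueError(f"need exactly two classes, got {classes}")
    yb = np.array([lab == classes[1] for lab in y], dtype=bool)
    return X.values.T, yb


def _top_k(scores: dict[str, float], k: int) -> tuple[str, ...]:
    """Top-k ids by descending score, ties broken by feature id."""
    ranked = sorted(scores.items(), key=lambda kv: (-kv[1], kv[0]))
    return tuple(fid for fid, _ in ranked[:k])


# ---------------------------------------------------------------------------
# selectors

def select_snr(X: FeatureMatrix, y, k: int) -> FeatureSelectionResult:
    """Signal-to-noise ratio (mean difference over summed class SDs),
    ranked by absolute value."""
    M, yb = _xy(X, y)
    if k > M.shape[1]:
        raise ValueError("k exceeds the number of features")
    mu1, mu0 = M[yb].mean(axis=0), M[~yb].mean(axis=0)
    sd1, sd0 = M[yb].std(axis=0, ddof=1), M[~yb].std(axis=0, ddof=1)
    denom = sd1 + sd0
    with np.errstate(divide="ignore", invalid="ignore"):
        snr = np.where(denom > 0, (mu1 - mu0) / denom, 0.0)
    if (denom == 0).any():
        logger.warning("%d features have zero pooled SD; scored 0", int((denom == 0).sum()))
    scores = dict(zip(X.feature_ids, np.abs(snr)))
    signed = dict(zip(X.feature_ids, snr))
    return FeatureSelectionResult("snr", _top_k(scores, k), signed)


def select_anova(X: FeatureMatrix, y, k: int) -> FeatureSelectionResult:
    """Top-k features by the one-way ANOVA F statistic."""
    M, yb = _xy(X, y)
    if k > M.shape[1]:
        raise ValueError("k exceeds the number of features")
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        F, _ = f_classif(M, yb)
    F = np.nan_to_num(F, nan=0.0, posinf=np.finfo(float).max)
    scores = dict(zip(X.feature_ids, F))
    return FeatureSelectionResult("anova", _top_k(scores, k), scores)


def select_logistic(X: FeatureMatrix, y, alpha: float = 0.05) -> FeatureSelectionResult:
    """Features whose single-feature logistic-regression coefficient is
    significant at *alpha* (Wald test, no multiplicity correction).

    Complete separation makes the Wald test degenerate; such features are
    flagged, treated as selected, and scored infinite.
    """
    import statsmodels.api as sm

    M, yb = _xy(X, y)
    selected: list[str] = []
    flagged: list[str] = []
    scores: dict[str, float] = {}
    for j, fid in enumerate(X.feature_ids):
        col = M[:, j]
        sd = col.std()
        if sd == 0:
            scores[fid] = 0.0
            continue
        z = (col - col.mean()) / sd
        design = sm.add_constant(z)
        try:
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                fit = sm.Logit(yb.astype(float), design).fit(disp=0, maxiter=100)
            p = float(fit.pvalues[1])
            if not np.isfinite(p) or abs(float(fit.params[1])) > 20:
                raise np.linalg.LinAlgError("separation")
            scores[fid] = -np.log10(max(p, 1e-300))
            if p < alpha:
                selected.append(fid)
        except Exception:
            flagged.append(fid)
            selected.append(fid)
            scores[fid] = float("inf")
    order = sorted(selected, key=lambda f: (-scores[f], f))
    return FeatureSelectionResult("logistic", tuple(order), scores, tuple(flagged))


def select_rfe(X: FeatureMatrix, y, k: int, estimator=None, step: float = 0.2) -> FeatureSelectionResult:
    """Recursive feature elimination down to *k* features."""
    M, yb = _xy(X, y)
    if k > M.shape[1]:
        raise ValueError("k exceeds the number of features")
    if k == M.shape[1]:
        return FeatureSelectionResult(
            "rfe", tuple(X.feature_ids), {f: 1.0 for f in X.feature_ids}
        )
    if estimator is None:
        estimator = SVC(kernel="linear", C=1.0)
    sd = M.std(axis=0)
    Z = (M - M.mean(axis=0)) / np.where(sd > 0, sd, 1.0)
    rfe = RFE(estimator, n_features_to_select=k, step=step)
    rfe.fit(Z, yb)
    ranks = dict(zip(X.feature_ids, rfe.ranking_.astype(float)))
    selected = tuple(sorted(
        (f for f, r in ranks.items() if r == 1.0), key=lambda f: f
    ))
    scores = {f: 1.0 / r for f, r in ranks.items()}
    return FeatureSelectionResult("rfe", selected, scores)


def select_boruta(
    X: FeatureMatrix,
    y,
    max_iter: int = 50,
    seed: int = 0,
    alpha: float = 0.01,
    n_estimators: int = 200,
) -> FeatureSelectionResult:
    """Boruta all-relevant selection via shadow features.

    Each iteration permutes every feature to build shadow copies, fits a
    random forest on the joint matrix, and scores a "hit" for features
    more important than the best shadow.  A two-sided binomial test at
    *alpha* against p=0.5 confirms or rejects features as iterations
    accumulate; features still tentative at ``max_iter`` are resolved by
    comparing their median importance to the median best-shadow
    importance.
    """
    if max_iter < 10:
        raise ValueError("max_iter must be at least 10")
    M, yb = _xy(X, y)
    rng = np.random.default_rng(seed)
    n_feat = M.shape[1]
    status = np.zeros(n_feat, dtype=int)  # 0 tentative, 1 confirmed, -1 rejected
    hits = np.zeros(n_feat, dtype=int)
    trials = 0
    imp_history: list[np.ndarray] = []
    shadow_max_history: list[float] = []
    for it in range(max_iter):
        active = status == 0
        if not active.any():
            break
        shadow = M.copy()
        for j in range(n_feat):
            shadow[:, j] = rng.permutation(shadow[:, j])
        joint = np.hstack([M, shadow])
        rf = RandomForestClassifier(
            n_estimators=n_estimators,
            max_depth=7,
            random_state=int(rng.integers(2**31 - 1)),
            n_jobs=1,
        )
        rf.fit(joint, yb)
        imp = rf.feature_importances_
        real_imp, shadow_imp = imp[:n_feat], imp[n_feat:]
        shadow_max = float(shadow_imp.max())
        imp_history.append(real_imp)
        shadow_max_history.append(shadow_max)
        hits[active] += (real_imp[active] > shadow_max).astype(int)
        trials += 1
        # Bonferroni-adjusted two-sided binomial test across attributes
        thr = alpha / (2 * n_feat)
        if trials >= 5:  # need a few trials before the binomial test has power
            for j in np.flatnonzero(status == 0):
                p_hi = stats.binomtest(int(hits[j]), trials, 0.5, alternative="greater").pvalue
                p_lo = stats.binomtest(int(hits[j]), trials, 0.5, alternative="less").pvalue
                if p_hi < thr:
                    status[j] = 1
                elif p_lo < thr:
                    status[j] = -1
    # resolve tentative by median-importance comparison
    med_shadow = float(np.median(shadow_max_history)) if shadow_max_history else 0.0
    med_imp = np.median(np.vstack(imp_history), axis=0) if imp_history else np.zeros(n_feat)
    for j in np.flatnonzero(status == 0):
        status[j] = 1 if med_imp[j] > med_shadow else -1
    scores = dict(zip(X.feature_ids, (hits / max(trials, 1)).astype(float)))
    selected = tuple(sorted(
        (f for f, s in zip(X.feature_ids, status) if s == 1),
        key=lambda f: (-scores[f], f),
    ))
    return FeatureSelectionResult("boruta", selected, scores)


SELECTORS = {
    "anova": select_anova,
    "snr": select_snr,
    "logistic": select_logistic,
    "rfe": select_rfe,
    "boruta": select_boruta,
}
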