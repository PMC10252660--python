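"""The stacked ensemble ("Scarface score") and its bootstrap benchmark.

The ensemble is a support vector machine over the union of the three
layers' selected features — by default 8 SNP coverage features, the 28
genomic-instability parameters and 7 expression features, 43 attributes
in all.  It consumes the raw selected features (not the single-source
models' predictions); a stacking-on-predictions mode exists behind a
flag for comparison.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .io import FeatureMatrix
from .models import FittedModel, fit_single_source, predict
from .selection import FeatureSelectionResult

LAYER_ORDER = ("snp", "gi", "expr")


@dataclass
class EnsembleBundle:
    feature_union: tuple[str, ...]
    model: FittedModel
    provenance: dict[str, FeatureSelectionResult] = field(default_factory=dict)


@dataclass(frozen=True)
class BootstrapReport:
    iterations: int
    accuracy_mean: float
    kappa_mean: float
    accuracy_ci: tuple[float, float]
    kappa_ci: tuple[float, float]
    accuracy_values: tuple[float, ...]
    kappa_values: tuple[float, ...]
    skipped_iterates: int
    seed: int


def assemble_feature_union(
    snp_sel: FeatureSelectionResult,
    gi_sel: FeatureSelectionResult,
    expr_sel: FeatureSelectionResult,
    matrices: dict[str, FeatureMatrix],
) -> FeatureMatrix:
    """Column-bind the selected features of the three layers.

    Feature ids are layer-prefixed ("snp:", "gi:", "expr:") in the fixed
    layer order, so the union is canonical regardless of input order.
    """
    selections = {"snp": snp_sel, "gi": gi_sel, "expr": expr_sel}
    empty = [layer for layer, sel in selections.items() if not sel.selected]
    if empty:
        raise ValueError(f"ensemble requires all three layers; empty selection for {empty}")
    sample_sets = {layer: tuple(matrices[layer].sample_ids) for layer in LAYER_ORDER}
    ref = sample_sets["snp"]
    mismatched = {
        layer: sorted(set(ids) ^ set(ref))
        for layer, ids in sample_sets.items()
        if set(ids) != set(ref)
    }
    if mismatched:
        raise ValueError(f"sample mismatch across layers: {mismatched}")
    blocks = []
    for layer in LAYER_ORDER:
        sub = matrices[layer].subset_features(list(selections[layer].selected))
        block = sub.data.loc[:, list(ref)].copy()
        block.index = [f"{layer}:{fid}" for fid in block.index]
        blocks.append(block)
    return FeatureMatrix(pd.concat(blocks, axis=0))


def fit_scarface(
    union_train: FeatureMatrix,
    y_train: dict[str, str] | list[str],
    seed: int = 0,
    provenance: dict[str, FeatureSelectionResult] | None = None,
) -> EnsembleBundle:
    """Fit the ensemble SVM on the assembled training feature union."""
    model = fit_single_source(union_train, y_train, "svm", seed=seed)
    return EnsembleBundle(
        feature_union=tuple(union_train.feature_ids),
        model=model,
        provenance=provenance or {},
    )


def scarface_score(bundle: EnsembleBundle, sample_features: FeatureMatrix):
    """Predicted label and continuous score (higher = predicted responder)
    for each sample carrying all 43 ensemble features."""
    return predict(bundle.model, sample_features)


def bootstrap_benchmark(
    bundle: EnsembleBundle,
    X_validation: FeatureMatrix,
    y_validation: dict[str, str] | list[str],
    B: int = 500,
    seed: int = 0,
) -> BootstrapReport:
    """Bootstrap the validation series to benchmark accuracy and kappa.

    Draws ``B`` resamples (with replacement, size = validation size) of
    the validation samples, scores the fixed ensemble's predictions on
    each, and reports means and 2.5/97.5 percentile intervals.  Resamples
    containing a single actual class leave kappa undefined; those
    iterates are skipped for kappa and counted.
    """
    from .evaluation import cohen_kappa, confusion_matrix

    if isinstance(y_validation, dict):
        y = np.array([y_validation[s] for s in X_validation.sample_ids])
    else:
        y = np.array(list(y_validation))
    if len(set(y)) < 2:
        raise ValueError("validation series must contain both classes")
    pred, _ = predict(bundle.model, X_validation)
    n = len(y)
    rng = np.random.default_rng(seed)
    acc_vals: list[float] = []
    kap_vals: list[float] = []
    skipped = 0
    positive = sorted(set(y))[-1]
    for _ in range(B):
        idx = rng.integers(0, n, size=n)
        yb, pb = y[idx], pred[idx]
        acc_vals.append(float(np.mean(yb == pb)))
        if len(set(yb)) < 2:
            skipped += 1
            continue
        cm = confusion_matrix(list(pb), list(yb), positive_class=positive)
        kap_vals.append(cohen_kappa(cm))
    acc = np.array(acc_vals)
    kap = np.array(kap_vals) if kap_vals else np.array([np.nan])
    return BootstrapReport(
        iterations=B,
        accuracy_mean=float(acc.mean()),
        kappa_mean=float(np.nanmean(kap)),
        accuracy_ci=(float(np.percentile(acc, 2.5)), float(np.percentile(acc, 97.5))),
        kappa_ci=(float(np.nanpercentile(kap, 2.5)), float(np.nanpercentile(kap, 97.5))),
        accuracy_values=tuple(acc_vals),
        kappa_values=tuple(kap_vals),
        skipped_iterates=skipped,
        seed=seed,
    )


def stack_predictions(
    models: dict[str, FittedModel], matrices: dict[str, FeatureMatrix]
) -> FeatureMatrix:
    """Alternative ensemble input: the three single-source models'
    continuous scores as a 3-feature matrix (stacking-on-predictions)."""
    ref = matrices[LAYER_ORDER[0]].sample_ids
    rows = {}
    for layer in LAYER_ORDER:
        _, scores = predict(models[layer], matrices[layer].subset_samples(ref))
        rows[f"{layer}:score"] = scores
    return FeatureMatrix(pd.DataFrame(rows, index=ref).T)
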