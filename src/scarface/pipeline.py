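"""End-to-end orchestration: cohort -> layers -> selection -> models ->
ensemble -> benchmark.

The three layers are built as in the source study design: the SNP
coverage matrix is near-zero-variance filtered; the genomic-instability
(GI) layer is the 28-parameter vector computed from each sample's
segment profile and is not subjected to feature selection (it is already
small); the expression matrix is median-normalized.  Selection and model
fitting see training samples only.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np

from .ensemble import (
    BootstrapReport,
    EnsembleBundle,
    assemble_feature_union,
    bootstrap_benchmark,
    fit_scarface,
)
from .io import CohortBundle, FeatureMatrix
from .layers import RESPONDER, filter_near_zero_variance, label_cohort, median_normalize
from .models import FittedModel, fit_single_source, predict
from .scars import ScarCatalogue, gi_matrix
from .selection import SELECTORS, FeatureSelectionResult, SplitPlan, split_cohort

logger = logging.getLogger(__name__)

LAYER_ALGORITHMS = {"snp": "svm", "gi": "svm", "expr": "neural_network"}
LAYER_K = {"snp": 8, "gi": None, "expr": 7}  # None: keep every feature


@dataclass
class PipelineResult:
    split: SplitPlan
    labels: dict[str, str]
    selections: dict[str, FeatureSelectionResult]
    models: dict[str, FittedModel]
    ensemble: EnsembleBundle
    layer_accuracy: dict[str, float]
    ensemble_accuracy: float
    bootstrap: BootstrapReport | None
    matrices: dict[str, FeatureMatrix] = field(default_factory=dict)


def build_layers(
    bundle: CohortBundle,
    catalogue: ScarCatalogue | None = None,
    scale: int | None = None,
    nzv_kwargs: dict | None = None,
) -> dict[str, FeatureMatrix]:
    """The three model-input matrices for every sample in the bundle."""
    from .scars import MB

    snp = filter_near_zero_variance(bundle.snp_matrix, **(nzv_kwargs or {}))
    gi = gi_matrix(
        bundle.profiles.values(), bundle.layout, catalogue, scale or MB
    )
    expr = median_normalize(bundle.expr_matrix)
    order = bundle.sample_ids
    return {
        "snp": snp.subset_samples(order),
        "gi": gi.subset_samples(order),
        "expr": expr.subset_samples(order),
    }


def run_pipeline(
    bundle: CohortBundle,
    seed: int = 0,
    ratio: float = 0.7,
    selector: str = "anova",
    layer_k: dict | None = None,
    bootstrap_B: int = 500,
    scale: int | None = None,
) -> PipelineResult:
    """Run the full analysis on one cohort bundle.

    Splits 70/30 (stratified), selects features per layer on the training
    series with the named selector, fits the per-layer models and the
    43-attribute ensemble SVM, and benchmarks the ensemble on the
    validation series (point accuracy plus a ``bootstrap_B``-iteration
    bootstrap of accuracy and kappa).
    """
    labels = label_cohort(bundle.clinical)
    layer_k = {**LAYER_K, **(layer_k or {})}
    matrices = build_layers(bundle, scale=scale)
    split = split_cohort(bundle.sample_ids, labels, ratio=ratio, seed=seed)
    train_ids, val_ids = list(split.train_ids), list(split.validation_ids)

    select = SELECTORS[selector]
    selections: dict[str, FeatureSelectionResult] = {}
    models: dict[str, FittedModel] = {}
    layer_accuracy: dict[str, float] = {}
    y_train = {s: labels[s] for s in train_ids}
    y_val = np.array([labels[s] for s in val_ids])
    for layer, X in matrices.items():
        X_train = X.subset_samples(train_ids)
        k = layer_k[layer]
        if k is None or k >= len(X.feature_ids):
            sel = FeatureSelectionResult(
                "all", tuple(X.feature_ids), {f: 0.0 for f in X.feature_ids}
            )
        else:
            kwargs = {"seed": seed} if selector == "boruta" else {}
            sel = select(X_train, y_train, k, **kwargs) if selector != "logistic" else select(X_train, y_train)
            if selector == "logistic" and k is not None:
                sel = FeatureSelectionResult(sel.method, sel.selected[:k], sel.scores, sel.flagged)
            if not sel.selected:
                logger.warning("%s selected nothing on layer %s; falling back to anova", selector, layer)
                sel = SELECTORS["anova"](X_train, y_train, k)
        selections[layer] = sel
        model = fit_single_source(
            X_train.subset_features(list(sel.selected)),
            y_train,
            LAYER_ALGORITHMS[layer],
            seed=seed,
        )
        models[layer] = model
        pred, _ = predict(model, X.subset_samples(val_ids))
        layer_accuracy[layer] = float(np.mean(pred == y_val))

    union_all = assemble_feature_union(
        selections["snp"], selections["gi"], selections["expr"], matrices
    )
    ens = fit_scarface(
        union_all.subset_samples(train_ids), y_train, seed=seed, provenance=selections
    )
    X_val_union = union_all.subset_samples(val_ids)
    pred, _ = predict(ens.model, X_val_union)
    ensemble_accuracy = float(np.mean(pred == y_val))
    boot = None
    if bootstrap_B and len(set(y_val)) == 2:
        boot = bootstrap_benchmark(
            ens, X_val_union, {s: labels[s] for s in val_ids}, B=bootstrap_B, seed=seed
        )
    return PipelineResult(
        split=split,
        labels=labels,
        selections=selections,
        models=models,
        ensemble=ens,
        layer_accuracy=layer_accuracy,
        ensemble_accuracy=ensemble_accuracy,
        bootstrap=boot,
        matrices=matrices,
    )
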