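#!/usr/bin/env python
"""Train the three single-source models and the 43-attribute ensemble.

Runs the full modeling pipeline (near-zero-variance filtering, median
normalization, GI parameter computation, feature selection, 70/30
stratified split, grid-tuned SVM / random forest / neural network, and
the ensemble SVM with its 500-iteration bootstrap benchmark) on the
cohort from 01_simulate_cohort.py.  Writes results/model_report.json.
"""

import argparse
import json
from pathlib import Path

from scarface.cli import _read_cohort
from scarface.pipeline import run_pipeline

ROOT = Path(__file__).resolve().parents[1]


def main() -> None:
    ap = argparse.ArgumentParser()
    ap.add_argument("--seed", type=int, default=1)
    ap.add_argument("--cohort", type=Path, default=ROOT / "scratch" / "cohort")
    ap.add_argument("--out", type=Path, default=ROOT / "results" / "model_report.json")
    args = ap.parse_args()

    bundle = _read_cohort(args.cohort)
    res = run_pipeline(bundle, seed=args.seed)
    report = {
        "n_train": len(res.split.train_ids),
        "n_validation": len(res.split.validation_ids),
        "layer_accuracy": res.layer_accuracy,
        "ensemble_accuracy": res.ensemble_accuracy,
        "selected_features": {
            layer: list(sel.selected) for layer, sel in res.selections.items()
        },
        "bootstrap": {
            "B": res.bootstrap.iterations,
            "accuracy_mean": res.bootstrap.accuracy_mean,
            "kappa_mean": res.bootstrap.kappa_mean,
            "accuracy_ci": list(res.bootstrap.accuracy_ci),
            "kappa_ci": list(res.bootstrap.kappa_ci),
            "skipped_iterates": res.bootstrap.skipped_iterates,
        },
        "seed": args.seed,
    }
    args.out.write_text(json.dumps(report, indent=2))
    print(f"model report -> {args.out}")
    for layer, acc in res.layer_accuracy.items():
        print(f"  {layer:5s} model validation accuracy: {acc:.4f}")
    print(f"  ensemble validation accuracy: {res.ensemble_accuracy:.4f}")
    print(f"  bootstrap (B={res.bootstrap.iterations}): accuracy "
          f"{res.bootstrap.accuracy_mean:.4f}, kappa {res.bootstrap.kappa_mean:.4f}")


if __name__ == "__main__":
    main()
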