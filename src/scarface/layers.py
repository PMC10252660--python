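"""Feature-layer construction: response labels, HRR/CCNE1 strata,
near-zero-variance filtering and median normalization.

The classifier's target is response to platinum-based chemotherapy:
responder means a platinum-free interval (PFI) of at least 12 months.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np

from .io import ClinicalRecord, FeatureMatrix

logger = logging.getLogger(__name__)

RESPONDER = "responder"
NON_RESPONDER = "non_responder"

#: Genes of the targeted DNA-damage-response panel annotated to the
#: homologous recombination repair pathway (config-overridable).
DEFAULT_HRR_GENES = frozenset(
    {
        "BRCA1", "BRCA2", "BARD1", "BRIP1", "CHEK1", "CHEK2", "FAM175A", "NBN",
        "PALB2", "ATM", "MRE11A", "RAD51B", "RAD51C", "RAD51D", "RAD54L",
        "FANCI", "FANCM", "FANCA", "ATR",
    }
)


@dataclass(frozen=True)
class ResponseLabel:
    sample_id: str
    label: str  # RESPONDER | NON_RESPONDER


@dataclass(frozen=True)
class StratumAssignment:
    sample_id: str
    hrr_status: str  # "HRRmut" | "HRRwt"
    three_way: str  # "HRRmut" | "HRRwt" | "CCNE1amp"


def label_response(
    record: ClinicalRecord, threshold_months: float = 12.0
) -> ResponseLabel:
    """Threshold the PFI at 12 months, inclusive on the responder side."""
    label = RESPONDER if record.pfi_months >= threshold_months else NON_RESPONDER
    return ResponseLabel(record.sample_id, label)


def label_cohort(
    records: list[ClinicalRecord], threshold_months: float = 12.0
) -> dict[str, str]:
    return {r.sample_id: label_response(r, threshold_months).label for r in records}


def classify_hrr(
    record: ClinicalRecord, hrr_gene_set: frozenset[str] = DEFAULT_HRR_GENES
) -> StratumAssignment:
    """HRRmut iff any mutated gene intersects the HRR set; in the three-way
    grouping CCNE1 amplification takes precedence as its own subgroup."""
    if not hrr_gene_set:
        raise ValueError("hrr_gene_set must be non-empty")
    hrr = "HRRmut" if record.hrr_mutations & hrr_gene_set else "HRRwt"
    three_way = "CCNE1amp" if record.ccne1_amplified else hrr
    return StratumAssignment(record.sample_id, hrr, three_way)


def filter_near_zero_variance(
    matrix: FeatureMatrix,
    freq_cut: float = 95.0 / 5.0,
    unique_cut: float = 0.1,
    min_total: float | None = None,
) -> FeatureMatrix:
    """Drop uninformative count features before modeling.

    A feature is removed when its total count across samples is below
    ``min_total`` (default: 10x the sample count), OR when the ratio of
    its most frequent to second most frequent value is at least
    ``freq_cut`` and its fraction of distinct values is at most
    ``unique_cut`` (the near-zero-variance rule).  Surviving features
    keep their original order.
    """
    X = matrix.values
    n_samples = X.shape[1]
    if min_total is None:
        min_total = 10.0 * n_samples
    keep = []
    for i, fid in enumerate(matrix.feature_ids):
        row = X[i]
        if row.sum() < min_total:
            continue
        _, counts = np.unique(row, return_counts=True)
        if counts.size == 1:
            continue  # constant: zero variance
        top2 = np.sort(counts)[::-1][:2]
        freq_ratio = top2[0] / top2[1]
        unique_frac = counts.size / n_samples
        if freq_ratio >= freq_cut and unique_frac <= unique_cut:
            continue
        keep.append(fid)
    if not keep:
        raise ValueError(
            "near-zero-variance filter removed every feature; relax "
            "freq_cut/unique_cut/min_total"
        )
    logger.info("NZV filter: %d of %d features retained", len(keep), X.shape[0])
    return matrix.subset_features(keep)


def median_normalize(matrix: FeatureMatrix) -> FeatureMatrix:
    """Scale each sample so its median equals the grand median of the
    per-sample medians (keeps counts on an interpretable scale).

    Idempotent, and invariant to per-sample positive rescaling.
    """
    X = matrix.values
    medians = np.median(X, axis=0)
    zero = [s for s, m in zip(matrix.sample_ids, medians) if m <= 0]
    if zero:
        raise ValueError(f"zero-median samples cannot be median-normalized: {zero[:5]}")
    target = np.median(medians)
    scaled = X * (target / medians)[None, :]
    out = matrix.data.copy()
    out.loc[:, :] = scaled
    return FeatureMatrix(out)
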