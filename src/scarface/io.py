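"""Readers and writers for the pipeline's tabular inputs.

Formats (all plain text):

* genome layout TSV — columns ``chrom``, ``length``, ``cen_start``, ``cen_end``
* segments TSV (SEG dialect) — ``sample``, ``chrom``, ``start``, ``end``,
  ``total_cn``, ``minor_cn``; 1-based closed coordinates
* feature matrix TSV — first column ``feature_id``, one column per sample
* clinical CSV — one row per sample, see :class:`ClinicalRecord`
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .genome import (
    Chromosome,
    FormatError,
    GenomeLayout,
    Segment,
    SegmentProfile,
    normalize_minor_allele,
)

logger = logging.getLogger(__name__)

STAGE_GROUPS = ("localized", "locally_advanced", "metastatic")


# ---------------------------------------------------------------------------
# genome layout

def read_genome_layout(path: str | Path) -> GenomeLayout:
    df = pd.read_csv(path, sep="\t", dtype={"chrom": str})
    for col in ("chrom", "length", "cen_start", "cen_end"):
        if col not in df.columns:
            raise FormatError(f"{path}: missing column {col!r}")
    chroms = []
    for i, row in df.iterrows():
        try:
            chroms.append(
                Chromosome(
                    str(row["chrom"]),
                    int(row["length"]),
                    int(row["cen_start"]),
                    int(row["cen_end"]),
                )
            )
        except (ValueError, TypeError, FormatError) as exc:
            raise FormatError(f"{path}: line {i + 2}: {exc}") from exc
    return GenomeLayout(tuple(chroms))


def write_genome_layout(layout: GenomeLayout, path: str | Path) -> None:
    pd.DataFrame(
        [(c.name, c.length, c.cen_start, c.cen_end) for c in layout],
        columns=["chrom", "length", "cen_start", "cen_end"],
    ).to_csv(path, sep="\t", index=False)


def grch38_layout() -> GenomeLayout:
    """A GRCh38-scaled autosome layout shipped with the package (for realism;
    never required by tests)."""
    return read_genome_layout(Path(__file__).parent / "data" / "grch38_autosomes.tsv")


# ---------------------------------------------------------------------------
# segments

def read_segments(path: str | Path, layout: GenomeLayout) -> list[SegmentProfile]:
    df = pd.read_csv(path, sep="\t", dtype={"sample": str, "chrom": str})
    required = ("sample", "chrom", "start", "end", "total_cn", "minor_cn")
    for col in required:
        if col not in df.columns:
            raise FormatError(f"{path}: missing column {col!r}")
    profiles: dict[str, SegmentProfile] = {}
    for i, row in df.iterrows():
        try:
            seg = normalize_minor_allele(
                str(row["chrom"]), int(row["start"]), int(row["end"]),
                int(row["total_cn"]), int(row["minor_cn"]),
            )
        except (ValueError, TypeError, FormatError) as exc:
            raise FormatError(f"{path}: line {i + 2}: {exc}") from exc
        sid = str(row["sample"])
        profiles.setdefault(sid, SegmentProfile(sid)).segments.append(seg)
    for prof in profiles.values():
        prof.validate(layout)
    return list(profiles.values())


def write_segments(profiles: list[SegmentProfile], path: str | Path) -> None:
    rows = [
        (p.sample_id, s.chrom, s.start, s.end, s.total_cn, s.minor_cn)
        for p in profiles
        for s in p.segments
    ]
    pd.DataFrame(
        rows, columns=["sample", "chrom", "start", "end", "total_cn", "minor_cn"]
    ).to_csv(path, sep="\t", index=False)


# ---------------------------------------------------------------------------
# feature matrices

@dataclass
class FeatureMatrix:
    """A features x samples numeric grid with unique, ordered labels."""

    data: pd.DataFrame  # index = feature ids, columns = sample ids

    def __post_init__(self) -> None:
        if self.data.index.duplicated().any():
            raise FormatError("duplicate feature ids")
        if self.data.columns.duplicated().any():
            raise FormatError("duplicate sample ids")
        if not np.isfinite(self.data.to_numpy(dtype=float)).all():
            raise FormatError("non-finite values in feature matrix")

    @property
    def feature_ids(self) -> list[str]:
        return list(self.data.index)

    @property
    def sample_ids(self) -> list[str]:
        return list(self.data.columns)

    @property
    def values(self) -> np.ndarray:
        return self.data.to_numpy(dtype=float)

    def subset_samples(self, sample_ids: list[str]) -> "FeatureMatrix":
        return FeatureMatrix(self.data.loc[:, sample_ids].copy())

    def subset_features(self, feature_ids: list[str]) -> "FeatureMatrix":
        missing = [f for f in feature_ids if f not in self.data.index]
        if missing:
            raise KeyError(f"features not in matrix: {missing[:5]}")
        return FeatureMatrix(self.data.loc[feature_ids, :].copy())


def read_matrix(path: str | Path) -> FeatureMatrix:
    df = pd.read_csv(path, sep="\t", index_col=0)
    df.index = df.index.astype(str)
    df.columns = df.columns.astype(str)
    try:
        return FeatureMatrix(df.astype(float))
    except ValueError as exc:
        raise FormatError(f"{path}: {exc}") from exc


def write_matrix(matrix: FeatureMatrix, path: str | Path) -> None:
    df = matrix.data.copy()
    df.index.name = "feature_id"
    df.to_csv(path, sep="\t")


# ---------------------------------------------------------------------------
# clinical records

@dataclass
class ClinicalRecord:
    """Per-sample clinical endpoints and molecular flags.

    Times are in months.  ``pfi_months`` is the platinum-free interval
    (end of platinum chemotherapy to relapse); ``parpi_pfs_months`` is
    progression-free survival on PARP-inhibitor therapy (missing when the
    patient never received a PARPi); ``os_months`` is overall survival.
    """

    sample_id: str
    pfi_months: float
    relapse_event: int
    os_months: float
    os_event: int
    stage_group: str
    parpi_pfs_months: float | None = None
    parpi_event: int | None = None
    hrr_mutations: frozenset[str] = field(default_factory=frozenset)
    ccne1_amplified: int = 0

    def __post_init__(self) -> None:
        if self.pfi_months < 0 or self.os_months < 0:
            raise FormatError(f"sample {self.sample_id}: negative survival time")
        if self.parpi_pfs_months is not None and self.parpi_pfs_months < 0:
            raise FormatError(f"sample {self.sample_id}: negative PARPi PFS")
        for ev in (self.relapse_event, self.os_event):
            if ev not in (0, 1):
                raise FormatError(f"sample {self.sample_id}: non-binary event {ev!r}")
        if self.parpi_event is not None and self.parpi_event not in (0, 1):
            raise FormatError(f"sample {self.sample_id}: non-binary PARPi event")
        if self.stage_group not in STAGE_GROUPS:
            raise FormatError(
                f"sample {self.sample_id}: stage_group {self.stage_group!r} "
                f"not in {STAGE_GROUPS}"
            )


def read_clinical(path: str | Path) -> list[ClinicalRecord]:
    df = pd.read_csv(path, dtype={"sample_id": str})
    if df["sample_id"].duplicated().any():
        dups = df.loc[df["sample_id"].duplicated(), "sample_id"].tolist()
        raise FormatError(f"{path}: duplicate sample ids {dups[:5]}")
    records = []
    for i, row in df.iterrows():
        muts = row.get("hrr_mutations", "")
        muts = frozenset() if pd.isna(muts) or muts == "" else frozenset(str(muts).split(";"))
        parpi_t = row.get("parpi_pfs_months", np.nan)
        parpi_e = row.get("parpi_event", np.nan)
        try:
            records.append(
                ClinicalRecord(
                    sample_id=str(row["sample_id"]),
                    pfi_months=float(row["pfi_months"]),
                    relapse_event=int(row["relapse_event"]),
                    os_months=float(row["os_months"]),
                    os_event=int(row["os_event"]),
                    stage_group=str(row["stage_group"]),
                    parpi_pfs_months=None if pd.isna(parpi_t) else float(parpi_t),
                    parpi_event=None if pd.isna(parpi_e) else int(parpi_e),
                    hrr_mutations=muts,
                    ccne1_amplified=int(row.get("ccne1_amplified", 0)),
                )
            )
        except (ValueError, TypeError, KeyError, FormatError) as exc:
            raise FormatError(f"{path}: line {i + 2}: {exc}") from exc
    return records


def write_clinical(records: list[ClinicalRecord], path: str | Path) -> None:
    rows = []
    for r in records:
        rows.append(
            {
                "sample_id": r.sample_id,
                "pfi_months": r.pfi_months,
                "relapse_event": r.relapse_event,
                "os_months": r.os_months,
                "os_event": r.os_event,
                "stage_group": r.stage_group,
                "parpi_pfs_months": "" if r.parpi_pfs_months is None else r.parpi_pfs_months,
                "parpi_event": "" if r.parpi_event is None else r.parpi_event,
                "hrr_mutations": ";".join(sorted(r.hrr_mutations)),
                "ccne1_amplified": r.ccne1_amplified,
            }
        )
    pd.DataFrame(rows).to_csv(path, index=False)


# ---------------------------------------------------------------------------
# cohort bundle

@dataclass
class CohortBundle:
    """Everything the pipeline consumes for one cohort.

    Sample id sets may disagree between components (as in real multi-assay
    cohorts); :meth:`harmonize` drops to the intersection with a logged
    report rather than erroring.
    """

    layout: GenomeLayout
    profiles: dict[str, SegmentProfile]
    snp_matrix: FeatureMatrix
    expr_matrix: FeatureMatrix
    clinical: list[ClinicalRecord]
    metadata: dict = field(default_factory=dict)  # simulation ground truth; never consumed by the pipeline

    @property
    def sample_ids(self) -> list[str]:
        return [r.sample_id for r in self.clinical]

    def harmonize(self) -> "CohortBundle":
        sets = {
            "profiles": set(self.profiles),
            "snp": set(self.snp_matrix.sample_ids),
            "expr": set(self.expr_matrix.sample_ids),
            "clinical": {r.sample_id for r in self.clinical},
        }
        common = set.intersection(*sets.values())
        dropped = {k: sorted(v - common) for k, v in sets.items() if v - common}
        if dropped:
            logger.warning("dropping samples missing from some components: %s", dropped)
        order = [r.sample_id for r in self.clinical if r.sample_id in common]
        return CohortBundle(
            layout=self.layout,
            profiles={s: self.profiles[s] for s in order},
            snp_matrix=self.snp_matrix.subset_samples(order),
            expr_matrix=self.expr_matrix.subset_samples(order),
            clinical=[r for r in self.clinical if r.sample_id in common],
            metadata=self.metadata,
        )
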