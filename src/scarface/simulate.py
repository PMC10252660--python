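"""Synthetic HGSOC cohort generator.

The generator emulates the statistical structure the analysis pipeline
assumes, tied together by a latent per-sample HRD state:

* **segment profiles** — per chromosome, breakpoints from a Poisson
  process whose rate depends on the HRD state, allele states drawn per
  segment with a class-specific LOH probability, so scar burden scales
  with HRD;
* **coverage / expression matrices** — negative-binomial counts with a
  small set of class-informative features (log-scale mean shift between
  HRD states) among exchangeable noise;
* **survival outcomes** — exponential platinum-free intervals (PFI) with
  class-specific medians, so HRD samples are predominantly responders
  (PFI >= 12 months); overall survival and PARP-inhibitor PFS are
  generated analogously.

Censoring times for PFI start at 12 months (a minimum-follow-up
assumption) so the responder label stays observable under censoring.
All randomness flows from the single integer seed in the config.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .genome import GenomeLayout, Segment, SegmentProfile, merge_adjacent_equal, mini_genome
from .io import ClinicalRecord, CohortBundle, FeatureMatrix
from .scars import MB

logger = logging.getLogger(__name__)

LN2 = math.log(2.0)

HRR_GENE_WEIGHTS = {"BRCA1": 0.40, "BRCA2": 0.35, "RAD51C": 0.07, "PALB2": 0.06,
                    "BRIP1": 0.06, "ATM": 0.06}


@dataclass(frozen=True)
class SimulationConfig:
    """Study conditions for a synthetic cohort.

    Breakpoint rates are expected breakpoints per 100 Mb; effects are
    log2-scale mean shifts between HRD states; medians are months.
    ``scale`` is bp per Mb and rescales rate/threshold units together
    with a rescaled genome layout.
    """

    n_samples: int = 183
    hrd_fraction: float = 0.5
    layout: GenomeLayout = field(default_factory=mini_genome)
    scale: int = MB
    breakpoint_rate_hrd: float = 8.0
    breakpoint_rate_stable: float = 2.0
    loh_prob_hrd: float = 0.40
    loh_prob_stable: float = 0.05
    n_snps: int = 1000
    n_informative_snps: int = 8
    snp_effect: float = 1.5
    n_genes: int = 600
    n_informative_genes: int = 7
    expr_log2fc: float = 1.5
    dispersion: float = 0.3
    median_pfi_responder: float = 72.0
    median_pfi_nonresponder: float = 4.0
    censor_rate: float = 0.15
    seed: int = 0

    def __post_init__(self) -> None:
        for name in ("hrd_fraction", "censor_rate"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must be in [0, 1], got {v}")
        for name in ("breakpoint_rate_hrd", "breakpoint_rate_stable",
                     "median_pfi_responder", "median_pfi_nonresponder"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be non-negative")
        if self.n_informative_snps > self.n_snps:
            raise ValueError("n_informative_snps exceeds n_snps")
        if self.n_informative_genes > self.n_genes:
            raise ValueError("n_informative_genes exceeds n_genes")

    def null(self) -> "SimulationConfig":
        """The no-signal counterpart: identical classes, zero effects,
        equal PFI medians at the 12-month threshold (balanced labels)."""
        return replace(
            self,
            breakpoint_rate_hrd=self.breakpoint_rate_stable,
            loh_prob_hrd=self.loh_prob_stable,
            snp_effect=0.0,
            expr_log2fc=0.0,
            median_pfi_responder=12.0,
            median_pfi_nonresponder=12.0,
        )


# ---------------------------------------------------------------------------
# segment profiles

_TOTALS_LOH = ([1, 2], [0.7, 0.3])
_TOTALS_OTHER = ([2, 3, 4], [0.7, 0.2, 0.1])


def simulate_profile(
    hrd: bool,
    layout: GenomeLayout,
    rng: np.random.Generator,
    config: SimulationConfig | None = None,
    sample_id: str = "sim",
) -> SegmentProfile:
    """One sample's segment profile under the class-specific scar regime."""
    cfg = config or SimulationConfig(layout=layout)
    rate = cfg.breakpoint_rate_hrd if hrd else cfg.breakpoint_rate_stable
    loh_prob = cfg.loh_prob_hrd if hrd else cfg.loh_prob_stable
    segments: list[Segment] = []
    for chrom in layout:
        lam = rate * chrom.length / (100 * cfg.scale)
        k = int(rng.poisson(lam))
        k = min(k, chrom.length - 1)
        if k > 0:
            # duplicate draws are vanishingly rare at genome scale; np.unique
            # silently drops them rather than resampling
            cuts = np.unique(rng.integers(1, chrom.length, size=k))
        else:
            cuts = np.array([], dtype=int)
        bounds = [1, *[int(c) + 1 for c in cuts], chrom.length + 1]
        chrom_segs = []
        for lo, hi in zip(bounds, bounds[1:]):
            if rng.random() < loh_prob:
                total = int(rng.choice(_TOTALS_LOH[0], p=_TOTALS_LOH[1]))
                minor = 0
            else:
                total = int(rng.choice(_TOTALS_OTHER[0], p=_TOTALS_OTHER[1]))
                minor = 1 if total < 4 else int(rng.choice([1, 2]))
            chrom_segs.append(Segment(chrom.name, lo, hi - 1, total, minor))
        segments.extend(merge_adjacent_equal(chrom_segs))
    return SegmentProfile(sample_id, segments).validate(layout)


# ---------------------------------------------------------------------------
# count matrices

def simulate_matrix(
    labels: np.ndarray,
    n_features: int,
    n_informative: int,
    effect: float,
    rng: np.random.Generator,
    sample_ids: list[str] | None = None,
    prefix: str = "f",
    dispersion: float = 0.3,
    base_mean: float = 100.0,
) -> tuple[FeatureMatrix, list[str]]:
    """Negative-binomial count matrix with *n_informative* class-informative
    features among exchangeable noise.

    Informative features shift their class-1 mean by ``effect`` on the
    log2 scale, alternating direction.  Their ids carry a trailing ``i``
    (ground-truth marker for tests; the pipeline never parses ids).
    Returns the matrix and the informative ids.
    """
    if effect < 0:
        raise ValueError("effect must be non-negative")
    labels = np.asarray(labels, dtype=bool)
    n = labels.size
    if sample_ids is None:
        sample_ids = [f"S{i:04d}" for i in range(n)]
    info_idx = np.sort(rng.choice(n_features, size=n_informative, replace=False))
    info_set = set(int(i) for i in info_idx)
    base = rng.lognormal(mean=math.log(base_mean), sigma=0.7, size=n_features)
    mu = np.tile(base[:, None], (1, n))
    for rank, j in enumerate(info_idx):
        sign = 1.0 if rank % 2 == 0 else -1.0
        mu[j, labels] = base[j] * 2.0 ** (sign * effect)
    # gamma-Poisson mixture: var = mu + dispersion * mu^2
    shape = 1.0 / dispersion
    lam = rng.gamma(shape, mu * dispersion)
    counts = rng.poisson(lam).astype(float)
    ids = [
        f"{prefix}{j:05d}i" if j in info_set else f"{prefix}{j:05d}"
        for j in range(n_features)
    ]
    fm = FeatureMatrix(pd.DataFrame(counts, index=ids, columns=sample_ids))
    return fm, [ids[j] for j in info_idx]


# ---------------------------------------------------------------------------
# survival outcomes

def _exp_months(rng: np.random.Generator, median: float) -> float:
    return float(rng.exponential(median / LN2)) if median > 0 else 0.0


def simulate_outcomes(
    hrd: np.ndarray,
    config: SimulationConfig,
    rng: np.random.Generator,
    sample_ids: list[str] | None = None,
) -> list[ClinicalRecord]:
    """Clinical endpoints for each sample given its latent HRD state."""
    hrd = np.asarray(hrd, dtype=bool)
    n = hrd.size
    if sample_ids is None:
        sample_ids = [f"S{i:04d}" for i in range(n)]
    records = []
    for i in range(n):
        m_pfi = config.median_pfi_responder if hrd[i] else config.median_pfi_nonresponder
        t = _exp_months(rng, m_pfi)
        if rng.random() < config.censor_rate:
            c = 12.0 + _exp_months(rng, 24.0)
            pfi, relapse = min(t, c), int(t <= c)
        else:
            pfi, relapse = t, 1
        os_true = t + _exp_months(rng, 18.0)
        follow = rng.uniform(24.0, 120.0)
        os_m, os_e = min(os_true, follow), int(os_true <= follow)
        if rng.random() < 0.31:  # received PARPi
            m_pfs = 20.0 if hrd[i] else 8.0
            pt = _exp_months(rng, m_pfs)
            if rng.random() < config.censor_rate:
                pc = 1.0 + _exp_months(rng, 12.0)
                parpi_t, parpi_e = min(pt, pc), int(pt <= pc)
            else:
                parpi_t, parpi_e = pt, 1
        else:
            parpi_t, parpi_e = None, None
        stage = rng.choice(
            ["localized", "locally_advanced", "metastatic"], p=[0.179, 0.632, 0.189]
        )
        if rng.random() < (0.55 if hrd[i] else 0.17):
            genes = list(HRR_GENE_WEIGHTS)
            probs = np.array(list(HRR_GENE_WEIGHTS.values()))
            muts = frozenset([str(rng.choice(genes, p=probs / probs.sum()))])
        else:
            muts = frozenset()
        ccne1 = int(rng.random() < (0.03 if hrd[i] else 0.20))
        records.append(
            ClinicalRecord(
                sample_id=sample_ids[i],
                pfi_months=pfi,
                relapse_event=relapse,
                os_months=os_m,
                os_event=os_e,
                stage_group=str(stage),
                parpi_pfs_months=parpi_t,
                parpi_event=parpi_e,
                hrr_mutations=muts,
                ccne1_amplified=ccne1,
            )
        )
    return records


# ---------------------------------------------------------------------------
# whole cohorts

def simulate_cohort(config: SimulationConfig) -> CohortBundle:
    """A full cohort bundle; bit-identical under an identical config."""
    rng = np.random.default_rng(config.seed)
    n = config.n_samples
    sample_ids = [f"S{i:04d}" for i in range(n)]
    hrd = rng.random(n) < config.hrd_fraction
    profiles = {
        sid: simulate_profile(bool(hrd[i]), config.layout, rng, config, sid)
        for i, sid in enumerate(sample_ids)
    }
    snp_matrix, snp_info = simulate_matrix(
        hrd, config.n_snps, config.n_informative_snps, config.snp_effect,
        rng, sample_ids, prefix="snp", dispersion=config.dispersion,
    )
    expr_matrix, expr_info = simulate_matrix(
        hrd, config.n_genes, config.n_informative_genes, config.expr_log2fc,
        rng, sample_ids, prefix="gene", dispersion=config.dispersion,
    )
    clinical = simulate_outcomes(hrd, config, rng, sample_ids)
    metadata = {
        "hrd": {sid: bool(hrd[i]) for i, sid in enumerate(sample_ids)},
        "informative_snps": snp_info,
        "informative_genes": expr_info,
        "seed": config.seed,
    }
    return CohortBundle(
        layout=config.layout,
        profiles=profiles,
        snp_matrix=snp_matrix,
        expr_matrix=expr_matrix,
        clinical=clinical,
        metadata=metadata,
    )


def write_cohort(bundle: CohortBundle, out_dir) -> None:
    """Write the four pipeline input files plus the ground-truth sidecar."""
    from pathlib import Path

    import yaml

    from . import io as _io

    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    _io.write_genome_layout(bundle.layout, out / "layout.tsv")
    _io.write_segments(list(bundle.profiles.values()), out / "segments.tsv")
    _io.write_matrix(bundle.snp_matrix, out / "snp_matrix.tsv")
    _io.write_matrix(bundle.expr_matrix, out / "expr_matrix.tsv")
    _io.write_clinical(bundle.clinical, out / "clinical.csv")
    with open(out / "metadata.yaml", "w") as fh:
        yaml.safe_dump(bundle.metadata, fh)
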