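"""Partitioning statistics: I_Lo, I_Ld, log FC, SPI, attachment, and
replicate aggregation; ionic-strength utilities.

The two headline per-vesicle metrics are

    log FC = log2(I_Lo / I_Ld)
    SPI    = I_Lo / (I_Lo + I_Ld) x 100  [percent]

where I_Lo and I_Ld are the background-subtracted mean DNA intensities over
the liquid-ordered and liquid-disordered membrane arcs of one vesicle.
log FC > 0 (SPI > 50%) means preferential partitioning into the Lo phase;
log FC = 0 (SPI = 50%) means no phase preference.  Aggregation is two-stage:
per-GUV values are averaged within each replicate, then the condition mean
and sample standard deviation are taken across replicate means.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np

from typing import TYPE_CHECKING

from .config import RunConfig
from .labels import LD, LO

if TYPE_CHECKING:  # avoid an import cycle; these are type hints only
    from .profiles import AngularProfile
    from .segmentation import PhaseLabeling

__all__ = [
    "PartitionRecord",
    "ConditionSummary",
    "IonSpecies",
    "log_fold_change",
    "selective_partitioning_index",
    "compute_partition_record",
    "normalize_attachment",
    "aggregate_condition",
    "select_heatmap_sample",
    "ionic_strength",
    "equivalent_concentration",
]


@dataclass
class PartitionRecord:
    """Per-GUV partitioning result.

    ``log_fc`` and ``spi`` are NaN when the vesicle fails QC (non-coexistent
    phases, or a non-positive background-subtracted phase mean).
    """

    guv_id: str
    condition_id: str
    replicate_id: str
    i_lo: float
    i_ld: float
    log_fc: float
    spi: float
    whole_vesicle_intensity: float
    n_lo_bins: int
    n_ld_bins: int
    qc_pass: bool


@dataclass
class ConditionSummary:
    """Condition-level aggregate over replicates (two-stage mean +/- SD)."""

    condition_id: str
    per_replicate_mean_log_fc: list[float]
    per_replicate_mean_spi: list[float]
    per_replicate_n_guvs: list[int]
    mean_log_fc: float
    sd_log_fc: float
    mean_spi: float
    sd_spi: float
    n_replicates: int
    n_guvs_total: int
    replicate_ok: bool


@dataclass(frozen=True)
class IonSpecies:
    """An ionic species with charge number ``z`` and concentration in mM."""

    name: str
    z: int
    c_mM: float

    def __post_init__(self) -> None:
        if self.z == 0:
            raise ValueError("ion charge must be nonzero")
        if self.c_mM < 0:
            raise ValueError("concentration must be >= 0")


def log_fold_change(i_lo: float, i_ld: float) -> float:
    """log2 fold change of DNA intensity between Lo and Ld arcs."""
    if i_lo <= 0 or i_ld <= 0:
        return math.nan
    return math.log2(i_lo / i_ld)


def selective_partitioning_index(i_lo: float, i_ld: float) -> float:
    """Selective Partitioning Index: the Lo share of total per-phase DNA
    intensity, in percent.  50% means no preference."""
    if i_lo <= 0 or i_ld <= 0:
        return math.nan
    return 100.0 * i_lo / (i_lo + i_ld)


def compute_partition_record(
    profile: "AngularProfile",
    labeling: "PhaseLabeling",
    condition_id: str = "",
    replicate_id: str = "",
) -> PartitionRecord:
    """Background-subtract per-bin DNA means and reduce them to I_Lo, I_Ld,
    log FC, SPI and the whole-vesicle attachment intensity.

    Phase intensities are bin-averaged (mean of per-bin means over each
    phase's bins), equalising angular weighting when bins hold unequal
    pixel counts.  A record always comes back; ``qc_pass`` is False (and
    the ratio metrics NaN) when the labeling is non-coexistent or either
    subtracted phase mean is non-positive.
    """
    if labeling.guv_id != profile.guv_id:
        raise ValueError("profile and labeling refer to different GUVs")
    dna = profile.dna_mean - profile.dna_bg
    lo_mask = labeling.bin_label == LO
    ld_mask = labeling.bin_label == LD
    n_lo = int(lo_mask.sum())
    n_ld = int(ld_mask.sum())
    i_lo = float(dna[lo_mask].mean()) if n_lo else math.nan
    i_ld = float(dna[ld_mask].mean()) if n_ld else math.nan
    valid = profile.valid_bin
    whole = float(dna[valid].mean()) if valid.any() else math.nan

    qc = bool(
        labeling.coexistent
        and n_lo > 0
        and n_ld > 0
        and i_lo > 0
        and i_ld > 0
    )
    if qc:
        lfc = log_fold_change(i_lo, i_ld)
        spi = selective_partitioning_index(i_lo, i_ld)
    else:
        lfc = math.nan
        spi = math.nan
    return PartitionRecord(
        guv_id=profile.guv_id,
        condition_id=condition_id,
        replicate_id=replicate_id,
        i_lo=i_lo,
        i_ld=i_ld,
        log_fc=lfc,
        spi=spi,
        whole_vesicle_intensity=whole,
        n_lo_bins=n_lo,
        n_ld_bins=n_ld,
        qc_pass=qc,
    )


def normalize_attachment(
    records: Sequence[PartitionRecord], reference_condition: str
) -> dict[str, float]:
    """Mean whole-vesicle DNA intensity per condition, normalized to the
    reference condition (which maps to exactly 1.0).

    Only ``qc_pass`` records contribute.
    """
    by_condition: dict[str, list[float]] = {}
    for r in records:
        if r.qc_pass:
            by_condition.setdefault(r.condition_id, []).append(
                r.whole_vesicle_intensity
            )
    if reference_condition not in by_condition:
        raise ValueError(
            f"reference condition {reference_condition!r} has no qc_pass records"
        )
    ref_mean = float(np.mean(by_condition[reference_condition]))
    if ref_mean == 0:
        raise ValueError("reference condition has zero mean attachment")
    out = {
        cond: float(np.mean(vals)) / ref_mean for cond, vals in by_condition.items()
    }
    out[reference_condition] = 1.0
    return out


def aggregate_condition(
    records: Sequence[PartitionRecord], config: RunConfig
) -> ConditionSummary:
    """Two-stage aggregation: GUV -> replicate mean -> condition mean and
    sample SD (ddof=1) across replicate means.

    All records must share one condition; only ``qc_pass`` records enter.
    SD fields are NaN with fewer than two replicates.  ``replicate_ok`` is
    False if any replicate holds fewer than ``config.min_guvs_per_replicate``
    qc_pass GUVs.
    """
    conditions = {r.condition_id for r in records}
    if len(conditions) > 1:
        raise ValueError(f"records span multiple conditions: {sorted(conditions)}")
    passing = [r for r in records if r.qc_pass]
    if not passing:
        raise ValueError("no qc_pass records to aggregate")
    condition_id = passing[0].condition_id

    by_rep: dict[str, list[PartitionRecord]] = {}
    for r in passing:
        by_rep.setdefault(r.replicate_id, []).append(r)
    rep_ids = sorted(by_rep)
    rep_lfc = [float(np.mean([r.log_fc for r in by_rep[k]])) for k in rep_ids]
    rep_spi = [float(np.mean([r.spi for r in by_rep[k]])) for k in rep_ids]
    rep_n = [len(by_rep[k]) for k in rep_ids]
    n_reps = len(rep_ids)

    sd_lfc = float(np.std(rep_lfc, ddof=1)) if n_reps >= 2 else math.nan
    sd_spi = float(np.std(rep_spi, ddof=1)) if n_reps >= 2 else math.nan
    return ConditionSummary(
        condition_id=condition_id,
        per_replicate_mean_log_fc=rep_lfc,
        per_replicate_mean_spi=rep_spi,
        per_replicate_n_guvs=rep_n,
        mean_log_fc=float(np.mean(rep_lfc)),
        sd_log_fc=sd_lfc,
        mean_spi=float(np.mean(rep_spi)),
        sd_spi=sd_spi,
        n_replicates=n_reps,
        n_guvs_total=len(passing),
        replicate_ok=all(n >= config.min_guvs_per_replicate for n in rep_n),
    )


def select_heatmap_sample(
    records: Sequence[PartitionRecord], n: int, seed: int
) -> list[PartitionRecord]:
    """Uniform random sample of min(n, available) qc_pass records without
    replacement; deterministic for a fixed seed."""
    if n < 1:
        raise ValueError("n must be >= 1")
    passing = [r for r in records if r.qc_pass]
    k = min(n, len(passing))
    if k == 0:
        return []
    rng = np.random.default_rng(seed)
    idx = rng.choice(len(passing), size=k, replace=False)
    return [passing[i] for i in idx]


def ionic_strength(ions: Iterable[IonSpecies]) -> float:
    """Ionic strength I = 1/2 sum_i c_i z_i^2, in mM."""
    return 0.5 * sum(ion.c_mM * ion.z**2 for ion in ions)


def equivalent_concentration(z: int, target_I_mM: float) -> float:
    """Concentration of a single species of charge ``z`` whose ionic
    strength equals ``target_I_mM``: c = 2 I / z^2."""
    if z == 0:
        raise ValueError("charge must be nonzero")
    if target_I_mM < 0:
        raise ValueError("target ionic strength must be >= 0")
    return 2.0 * target_I_mM / z**2
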