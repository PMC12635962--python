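"""Run configuration for the GUV partitioning pipeline.

All tunable parameters of the pipeline live in :class:`RunConfig` so that a
run is fully determined by (images, config, seed).  Channel roles are always
taken from the config, never inferred from image metadata.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping

import yaml

#: Pixel edge length of the study's confocal acquisitions, in micrometres.
DEFAULT_PIXEL_SIZE_UM = 0.37879


@dataclass
class RunConfig:
    """Parameters controlling detection, profiling, segmentation and
    aggregation.

    Parameters
    ----------
    channel_map
        Mapping from file channel index to role, e.g. ``{0: "marker",
        1: "dna"}``.  ``marker`` is the Ld-phase lipid label (Liss Rhod-PE
        in the study), ``dna`` the DNA label (Cy5).
    pixel_size_um
        Pixel edge length in micrometres; converts the radius search range
        to pixels.
    radius_min_um, radius_max_um
        Vesicle radius search range in micrometres.  The default 5-50 um
        spans typical GUV equatorial sections while excluding debris.
    score_threshold
        Minimum ring-coherence score in [0, 1] for a detection to be
        accepted (fraction of the circumference whose radial intensity
        centroid lies on the fitted circle; noise-edge circles stay below
        ~0.4, true membranes above ~0.85).
    overlap_factor
        Two rings are flagged ``overlapping`` when their center distance is
        below ``overlap_factor * (r1 + r2)``.
    annulus_halfwidth_px
        Half-width of the membrane annulus sampled around each ring, in
        pixels (default 3 px ~ 1.1 um at the default pixel size).
    n_bins
        Number of equal angular sectors per vesicle (default 180, i.e. 2
        degree bins).
    threshold_method
        Marker threshold rule for Lo/Ld labeling; only ``"otsu"`` (exact
        two-class variance maximization, per-GUV) is implemented.
    min_run_bins
        Same-label runs shorter than this are absorbed into their flanking
        arc (speckle suppression).
    boundary_guard_bins
        Bins within this distance of a Lo/Ld transition are excluded from
        phase means (PSF mixes phases at domain boundaries).
    min_arc_fraction
        Each phase must occupy at least this fraction of the valid arc for
        the vesicle to count as phase-coexistent.
    min_bimodality
        Minimum between-class variance fraction (eta^2 in [0, 1]) of the
        marker split for a profile to count as two-phase.  Unimodal noise
        tops out near 2/pi ~ 0.64 for Gaussian data, well-separated phase
        arcs approach 1; profiles below the floor are labeled single-phase.
    min_guvs_per_replicate
        Replicate-level QC threshold (the study used >= 20 GUVs per
        replicate).
    heatmap_sample_size
        Number of GUVs drawn for the per-GUV heatmap (the study shows 50).
    seed
        Seed for the heatmap subsampling.
    detect_smooth_sigma
        Gaussian sigma (px) applied to the summed-channel image before edge
        extraction.
    """

    channel_map: Mapping[int, str] = field(
        default_factory=lambda: {0: "marker", 1: "dna"}
    )
    pixel_size_um: float = DEFAULT_PIXEL_SIZE_UM
    radius_min_um: float = 5.0
    radius_max_um: float = 50.0
    score_threshold: float = 0.6
    overlap_factor: float = 1.0
    annulus_halfwidth_px: float = 3.0
    n_bins: int = 180
    threshold_method: str = "otsu"
    min_run_bins: int = 5
    boundary_guard_bins: int = 1
    min_arc_fraction: float = 0.1
    min_bimodality: float = 0.75
    min_guvs_per_replicate: int = 20
    heatmap_sample_size: int = 50
    seed: int = 0
    detect_smooth_sigma: float = 2.0

    def __post_init__(self) -> None:
        roles = set(self.channel_map.values())
        if not {"marker", "dna"} <= roles:
            raise ValueError(
                "channel_map must assign both 'marker' and 'dna' roles"
            )
        if not (0 < self.radius_min_um < self.radius_max_um):
            raise ValueError("radius range must satisfy 0 < min < max")
        if self.n_bins < 36:
            raise ValueError("n_bins must be >= 36")
        if self.heatmap_sample_size < 1:
            raise ValueError("heatmap_sample_size must be >= 1")
        if self.annulus_halfwidth_px <= 0:
            raise ValueError("annulus_halfwidth_px must be > 0")
        if not 0.0 <= self.min_arc_fraction <= 0.5:
            raise ValueError("min_arc_fraction must be in [0, 0.5]")
        if self.pixel_size_um <= 0:
            raise ValueError("pixel_size_um must be > 0")

    @property
    def radius_min_px(self) -> float:
        return self.radius_min_um / self.pixel_size_um

    @property
    def radius_max_px(self) -> float:
        return self.radius_max_um / self.pixel_size_um

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d["channel_map"] = {int(k): str(v) for k, v in self.channel_map.items()}
        return d

    @classmethod
    def from_dict(cls, d: Mapping) -> "RunConfig":
        d = dict(d)
        if "channel_map" in d:
            d["channel_map"] = {int(k): str(v) for k, v in d["channel_map"].items()}
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(d) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        return cls(**d)

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        if not isinstance(data, dict):
            raise ValueError(f"config file {path} must contain a mapping")
        return cls.from_dict(data)

    def to_yaml(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(self.to_dict(), fh, sort_keys=True)
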