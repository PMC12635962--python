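"""Synthetic two-channel PS-GUV scenes with known ground truth.

Each vesicle is rendered as a circular membrane band with a Gaussian radial
profile.  Arcs of the ring belong to either the liquid-disordered (LD,
marker-bright) or liquid-ordered (LO, marker-dark) phase; the DNA channel's
amplitude ratio between LO and LD arcs, ``rho``, is the ground-truth
partition ratio, so the true per-vesicle metrics are

    log FC = log2(rho),    SPI = 100 * rho / (1 + rho).

Intensities are simulated in photon-count-like units so Poisson shot noise
is physically meaningful; optional Gaussian read noise and a constant
background offset complete the noise model.  All randomness flows from a
single seed through ``numpy.random.SeedSequence`` spawning, so each scene
of a suite is independently reproducible.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import ndimage

from .config import RunConfig
from .io import ConfocalScene
from .labels import LD, LO

__all__ = [
    "SyntheticGUVSpec",
    "SceneNoiseModel",
    "render_scene",
    "benchmark_suite",
    "BenchmarkCase",
    "amplitude_for_snr",
    "TRUTH_COLUMNS",
]

#: Default marker amplitude of the LO phase relative to LD: the unlabeled
#: phase is not exactly zero in real images (bleed-through floor).
LO_MARKER_FLOOR = 0.05


@dataclass
class SyntheticGUVSpec:
    """Ground-truth parameters of one simulated vesicle.

    ``arcs`` is an ordered list of ``(start_rad, end_rad, phase)`` tiling
    [0, 2*pi) without overlap.  ``marker_intensity`` and ``dna_intensity``
    map phase -> mean amplitude in counts.
    """

    center_xy: tuple[float, float]
    radius_px: float
    membrane_sigma_px: float
    arcs: list[tuple[float, float, str]]
    marker_intensity: dict[str, float]
    dna_intensity: dict[str, float]
    guv_id: str = ""

    def __post_init__(self) -> None:
        if self.radius_px <= 0 or self.membrane_sigma_px <= 0:
            raise ValueError("radius and membrane sigma must be > 0")
        pos = 0.0
        for start, end, phase in self.arcs:
            if phase not in (LO, LD):
                raise ValueError(f"unknown phase {phase!r}")
            if not math.isclose(start, pos, abs_tol=1e-9) or end <= start:
                raise ValueError("arcs must tile [0, 2*pi) in order without overlap")
            pos = end
        if not math.isclose(pos, 2.0 * math.pi, abs_tol=1e-9):
            raise ValueError("arcs must cover the full circle")
        for amp_map in (self.marker_intensity, self.dna_intensity):
            if any(v < 0 for v in amp_map.values()):
                raise ValueError("amplitudes must be >= 0")

    @property
    def rho(self) -> float:
        """Ground-truth DNA partition ratio LO/LD."""
        return self.dna_intensity[LO] / self.dna_intensity[LD]

    @property
    def true_log_fc(self) -> float:
        return math.log2(self.rho)

    @property
    def true_spi(self) -> float:
        return 100.0 * self.rho / (1.0 + self.rho)

    @property
    def ld_arc_fraction(self) -> float:
        return sum(e - s for s, e, p in self.arcs if p == LD) / (2.0 * math.pi)


@dataclass
class SceneNoiseModel:
    """Photometric noise model applied after rendering the expected image."""

    background: tuple[float, float] = (10.0, 10.0)  # (marker, dna) counts
    psf_sigma_px: float = 1.0
    shot_noise: bool = True
    read_noise_sd: float = 1.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.psf_sigma_px < 0 or self.read_noise_sd < 0:
            raise ValueError("psf_sigma_px and read_noise_sd must be >= 0")


#: Columns of the ground-truth table emitted by :func:`render_scene`.
TRUTH_COLUMNS = [
    "guv_id",
    "center_x",
    "center_y",
    "radius_px",
    "membrane_sigma_px",
    "ld_arc_fraction",
    "arcs",
    "rho",
    "true_log_fc",
    "true_spi",
    "coexistent",
    "edge_clipped",
]


def amplitude_for_snr(snr: float, background: float, read_noise_sd: float = 0.0) -> float:
    """Membrane amplitude A (counts) so that A / sigma_noise(peak) = snr
    under Poisson statistics: sigma^2 = A + background + read_sd^2."""
    if snr <= 0:
        raise ValueError("snr must be > 0")
    b = background + read_noise_sd**2
    # solve A^2 = snr^2 (A + b)
    return 0.5 * (snr**2 + snr * math.sqrt(snr**2 + 4.0 * b))


def _phase_of_angle(theta: np.ndarray, arcs: Sequence[tuple[float, float, str]]) -> np.ndarray:
    """Phase amplitude selector: 1.0 where the angle falls in an LD arc."""
    is_ld = np.zeros(theta.shape, dtype=bool)
    for start, end, phase in arcs:
        if phase == LD:
            is_ld |= (theta >= start) & (theta < end)
    return is_ld


def render_scene(
    specs: Sequence[SyntheticGUVSpec],
    noise: SceneNoiseModel,
    shape: tuple[int, int] = (256, 256),
    scene_id: str = "synthetic",
    condition_id: str = "",
    replicate_id: str = "",
) -> tuple[ConfocalScene, pd.DataFrame]:
    """Render vesicles into a two-channel scene and return it with the
    ground-truth table.

    Each channel is background + sum of Gaussian radial bands (amplitude
    set by the local arc's phase), convolved with the PSF, then shot and
    read noise are applied.
    """
    h, w = shape
    marker = np.full(shape, float(noise.background[0]))
    dna = np.full(shape, float(noise.background[1]))
    yy, xx = np.mgrid[0:h, 0:w].astype(float)

    rows = []
    for k, spec in enumerate(specs):
        cx, cy = spec.center_xy
        r = np.hypot(xx - cx, yy - cy)
        band = np.exp(-0.5 * ((r - spec.radius_px) / spec.membrane_sigma_px) ** 2)
        theta = np.mod(np.arctan2(yy - cy, xx - cx), 2.0 * math.pi)
        is_ld = _phase_of_angle(theta, spec.arcs)
        for img, amp in ((marker, spec.marker_intensity), (dna, spec.dna_intensity)):
            img += band * np.where(is_ld, amp[LD], amp[LO])
        guv_id = spec.guv_id or f"{scene_id}-truth{k:03d}"
        pad = spec.radius_px + 3 * spec.membrane_sigma_px
        rows.append(
            {
                "guv_id": guv_id,
                "center_x": cx,
                "center_y": cy,
                "radius_px": spec.radius_px,
                "membrane_sigma_px": spec.membrane_sigma_px,
                "ld_arc_fraction": spec.ld_arc_fraction,
                "arcs": ";".join(f"{s:.6f}:{e:.6f}:{p}" for s, e, p in spec.arcs),
                "rho": spec.rho,
                "true_log_fc": spec.true_log_fc,
                "true_spi": spec.true_spi,
                "coexistent": 0.0 < spec.ld_arc_fraction < 1.0,
                "edge_clipped": (
                    cx - pad < 0 or cy - pad < 0 or cx + pad > w - 1 or cy + pad > h - 1
                ),
            }
        )

    if noise.psf_sigma_px > 0:
        marker = ndimage.gaussian_filter(marker, noise.psf_sigma_px)
        dna = ndimage.gaussian_filter(dna, noise.psf_sigma_px)

    rng = np.random.default_rng(noise.seed)
    if noise.shot_noise:
        marker = rng.poisson(np.clip(marker, 0, None)).astype(float)
        dna = rng.poisson(np.clip(dna, 0, None)).astype(float)
    if noise.read_noise_sd > 0:
        marker = marker + rng.normal(0.0, noise.read_noise_sd, shape)
        dna = dna + rng.normal(0.0, noise.read_noise_sd, shape)
    marker = np.clip(marker, 0, None)
    dna = np.clip(dna, 0, None)

    scene = ConfocalScene(
        marker_channel=marker,
        dna_channel=dna,
        pixel_size_um=0.37879,
        scene_id=scene_id,
        condition_id=condition_id,
        replicate_id=replicate_id,
    )
    return scene, pd.DataFrame(rows, columns=TRUTH_COLUMNS)


def two_phase_arcs(ld_fraction: float, start: float = 0.0) -> list[tuple[float, float, str]]:
    """One LD arc of the given fraction starting at ``start``, LO elsewhere.

    ``ld_fraction`` of 0 or 1 yields a single-phase vesicle.
    """
    tau = 2.0 * math.pi
    if not 0.0 <= ld_fraction <= 1.0:
        raise ValueError("ld_fraction must be in [0, 1]")
    if ld_fraction == 0.0:
        return [(0.0, tau, LO)]
    if ld_fraction == 1.0:
        return [(0.0, tau, LD)]
    if start == 0.0:
        return [(0.0, ld_fraction * tau, LD), (ld_fraction * tau, tau, LO)]
    end = start + ld_fraction * tau
    if end < tau:
        return [(0.0, start, LO), (start, end, LD), (end, tau, LO)]
    return [(0.0, end - tau, LD), (end - tau, start, LO), (start, tau, LD)]


def make_spec(
    center_xy: tuple[float, float],
    radius_px: float,
    rho: float,
    ld_fraction: float = 0.5,
    ld_marker_amp: float = 150.0,
    ld_dna_amp: float = 120.0,
    membrane_sigma_px: float = 1.5,
    arc_start: float = 0.0,
    guv_id: str = "",
) -> SyntheticGUVSpec:
    """Convenience constructor for a two-arc vesicle with partition ratio
    ``rho``; the LO marker amplitude is the bleed-through floor."""
    return SyntheticGUVSpec(
        center_xy=center_xy,
        radius_px=radius_px,
        membrane_sigma_px=membrane_sigma_px,
        arcs=two_phase_arcs(ld_fraction, arc_start),
        marker_intensity={LD: ld_marker_amp, LO: ld_marker_amp * LO_MARKER_FLOOR},
        dna_intensity={LD: ld_dna_amp, LO: ld_dna_amp * rho},
        guv_id=guv_id,
    )


@dataclass
class BenchmarkCase:
    """One benchmark scene with its ground truth and generation tags."""

    name: str
    scene: ConfocalScene
    truth: pd.DataFrame
    specs: list[SyntheticGUVSpec]
    noise: SceneNoiseModel
    rho: float
    ld_fraction: float
    snr: float | None  # None for noiseless cases
    tags: set = field(default_factory=set)


def _case_seed(root: np.random.SeedSequence, index: int) -> int:
    """Stable per-case seed below 2^31 from the suite's root sequence."""
    return int(np.random.SeedSequence((root.entropy, index)).generate_state(1)[0] % (2**31))


def benchmark_suite(seed: int = 0) -> list[BenchmarkCase]:
    """Deterministic benchmark suite spanning the pipeline's regimes.

    Covers rho in {1/4, 1/2, 1, 2, 4} x LD arc fraction in
    {0.25, 0.5, 0.75} x SNR in {3, 5, 10} (one noisy vesicle per scene at
    randomized sub-pixel geometry), noiseless exactness cases (integer
    centers, quarter-aligned arcs, no PSF), an edge-clipped vesicle, a
    touching pair, and single-phase controls that downstream QC must
    reject.  Same seed -> bit-identical scenes.
    """
    root = np.random.SeedSequence(seed)
    cases: list[BenchmarkCase] = []
    index = 0
    rhos = [0.25, 0.5, 1.0, 2.0, 4.0]
    shape = (160, 160)
    background = 10.0

    # noiseless exactness cases: half-integer center (every 90-degree
    # rotation of the pixel grid about it is exact, and no pixel sits on a
    # bin or axis boundary) with arc transitions on the diagonals, so the
    # radial sampling factors cancel exactly between the two phases
    for rho in rhos:
        scene_id = f"noiseless-rho{rho:g}"
        spec = make_spec((80.5, 80.5), 22.0, rho, ld_fraction=0.5,
                         arc_start=math.pi / 4, guv_id="")
        noise = SceneNoiseModel(
            background=(background, background),
            psf_sigma_px=0.0,
            shot_noise=False,
            read_noise_sd=0.0,
            seed=_case_seed(root, index),
        )
        scene, truth = render_scene([spec], noise, shape, scene_id=scene_id)
        cases.append(
            BenchmarkCase(scene_id, scene, truth, [spec], noise, rho, 0.5, None,
                          tags={"noiseless"})
        )
        index += 1

    # noisy grid: randomized sub-pixel geometry per case
    for rho in rhos:
        for ld_frac in (0.25, 0.5, 0.75):
            for snr in (3.0, 5.0, 10.0):
                case_seed = _case_seed(root, index)
                rng = np.random.default_rng(case_seed)
                radius = float(rng.uniform(16.0, 26.0))
                cx = float(rng.uniform(70.0, 90.0))
                cy = float(rng.uniform(70.0, 90.0))
                amp = amplitude_for_snr(snr, background, read_noise_sd=1.0)
                spec = make_spec(
                    (cx, cy), radius, rho, ld_fraction=ld_frac,
                    ld_marker_amp=amp, ld_dna_amp=amp,
                    arc_start=float(rng.uniform(0.0, 2.0 * math.pi)),
                )
                noise = SceneNoiseModel(
                    background=(background, background),
                    psf_sigma_px=1.0,
                    shot_noise=True,
                    read_noise_sd=1.0,
                    seed=case_seed,
                )
                scene_id = f"noisy-rho{rho:g}-ld{ld_frac:g}-snr{snr:g}"
                scene, truth = render_scene([spec], noise, shape, scene_id=scene_id)
                cases.append(
                    BenchmarkCase(scene_id, scene, truth, [spec], noise,
                                  rho, ld_frac, snr, tags={"noisy"})
                )
                index += 1

    # edge-clipped vesicle
    spec = make_spec((10.0, 80.0), 20.0, 2.0, ld_fraction=0.5)
    noise = SceneNoiseModel(background=(background, background), psf_sigma_px=1.0,
                            shot_noise=True, read_noise_sd=1.0,
                            seed=_case_seed(root, index))
    scene, truth = render_scene([spec], noise, shape, scene_id="edge-clipped")
    cases.append(BenchmarkCase("edge-clipped", scene, truth, [spec], noise,
                               2.0, 0.5, 10.0, tags={"edge"}))
    index += 1

    # touching pair (centers closer than r1 + r2 after annulus padding)
    specs = [
        make_spec((52.0, 80.0), 20.0, 2.0, ld_fraction=0.5, guv_id=""),
        make_spec((95.0, 80.0), 20.0, 0.5, ld_fraction=0.5, arc_start=math.pi / 2),
    ]
    noise = SceneNoiseModel(background=(background, background), psf_sigma_px=1.0,
                            shot_noise=True, read_noise_sd=1.0,
                            seed=_case_seed(root, index))
    scene, truth = render_scene(specs, noise, shape, scene_id="touching-pair")
    cases.append(BenchmarkCase("touching-pair", scene, truth, specs, noise,
                               2.0, 0.5, 10.0, tags={"touching"}))
    index += 1

    # single-phase controls: all-LD and all-LO vesicles, no phase coexistence
    for ld_frac, name in ((1.0, "control-all-ld"), (0.0, "control-all-lo")):
        spec = SyntheticGUVSpec(
            center_xy=(80.0, 80.0),
            radius_px=20.0,
            membrane_sigma_px=1.5,
            arcs=two_phase_arcs(ld_frac),
            marker_intensity={LD: 150.0, LO: 150.0 * LO_MARKER_FLOOR},
            dna_intensity={LD: 120.0, LO: 120.0},
        )
        noise = SceneNoiseModel(background=(background, background), psf_sigma_px=1.0,
                                shot_noise=True, read_noise_sd=1.0,
                                seed=_case_seed(root, index))
        scene, truth = render_scene([spec], noise, shape, scene_id=name)
        cases.append(BenchmarkCase(name, scene, truth, [spec], noise,
                                   1.0, ld_frac, 10.0, tags={"control"}))
        index += 1

    return cases


def suite_config(n_bins: int = 180) -> RunConfig:
    """Run configuration matched to the suite's geometry (radii 14-28 px
    at the confocal pixel size)."""
    px = 0.37879
    return RunConfig(
        pixel_size_um=px,
        radius_min_um=13.0 * px,
        radius_max_um=30.0 * px,
        n_bins=n_bins,
    )
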