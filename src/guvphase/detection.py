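"""Ring-like GUV detection via a circular Hough transform.

Detection runs on the smoothed sum of both channels so that Lo arcs, which
are dark in the lipid-marker channel, still contribute through the DNA
channel when DNA is bound (and vice versa).  The procedure is fully
deterministic: Canny edges -> circular Hough accumulation over the
configured radius range -> non-concentric peak selection -> sub-pixel
refinement of center and radius from annular intensity.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage
from skimage.feature import canny
from skimage.transform import hough_circle, hough_circle_peaks

from .config import RunConfig
from .io import ConfocalScene

__all__ = ["GUVRing", "detect_vesicles", "filter_rings"]

EDGE_CLIPPED = "edge_clipped"
OVERLAPPING = "overlapping"
LOW_SCORE = "low_score"

#: Accumulator floor for shortlisting Hough candidates.  Deliberately
#: permissive: noise edges reach ~0.5 of a small circumference, so the
#: accumulator cannot separate rings from noise on its own; the coherence
#: score computed during refinement does.
HOUGH_SHORTLIST_FLOOR = 0.25


@dataclass
class GUVRing:
    """A detected vesicle cross-section.

    ``center_xy`` is sub-pixel, 0-based, (x=column, y=row).
    ``detection_score`` is the ring-coherence score in [0, 1]: the fraction
    of the circumference whose radial intensity centroid lies on the
    fitted circle.
    """

    center_xy: tuple[float, float]
    radius_px: float
    annulus_halfwidth_px: float
    detection_score: float
    guv_id: str = ""
    flags: set = field(default_factory=set)

    def __post_init__(self) -> None:
        if not (0 < self.annulus_halfwidth_px <= self.radius_px):
            raise ValueError("require radius_px >= annulus_halfwidth_px > 0")
        if not 0.0 <= self.detection_score <= 1.0:
            raise ValueError("detection_score must be in [0, 1]")


def _annular_gradient_score(grad_mag: np.ndarray, cx: float, cy: float,
                            radius: float, halfwidth: float) -> float:
    """Mean gradient magnitude in the annulus |r - radius| <= halfwidth."""
    h, w = grad_mag.shape
    y0 = max(int(cy - radius - halfwidth) - 1, 0)
    y1 = min(int(cy + radius + halfwidth) + 2, h)
    x0 = max(int(cx - radius - halfwidth) - 1, 0)
    x1 = min(int(cx + radius + halfwidth) + 2, w)
    yy, xx = np.mgrid[y0:y1, x0:x1]
    r = np.hypot(xx - cx, yy - cy)
    mask = np.abs(r - radius) <= halfwidth
    if not mask.any():
        return 0.0
    return float(grad_mag[y0:y1, x0:x1][mask].mean())


def _refine_ring(image: np.ndarray, cx: float, cy: float, radius: float,
                 halfwidth: float, background: float,
                 n_angles: int = 360, iterations: int = 6,
                 coherence_tol_px: float = 1.5,
                 peak_mass_min: float = 0.7) -> tuple[float, float, float, float]:
    """Sub-pixel refinement by an active-ring fit, returning a coherence
    score in [0, 1].

    At each iteration the image is sampled on a polar grid around the
    current circle; each ray's annular-intensity centroid gives the local
    membrane radius, and the displacements are fitted to the first-order
    circle model rc(theta) = r + dx cos(theta) + dy sin(theta).  Rays
    without membrane signal (dark Lo arcs, out-of-frame sectors) carry no
    weight, so a ring that is bright over only part of its circumference
    still refines correctly.

    The coherence score is the fraction of contributing rays that carry a
    well-formed membrane band on the fitted circle: the ray's radial
    centroid lands within ``coherence_tol_px`` of the model radius AND at
    least ``peak_mass_min`` of the ray's intensity mass lies within the
    annulus half-width of it.  A flat (noise-only) radial profile centers
    its mass anywhere in the sampling band and spreads it evenly (mass
    fraction ~ halfwidth/band ~ 0.5), so circle candidates hallucinated
    from noise edges score low, which makes this a far sharper
    accept/reject statistic than the raw accumulator value.
    """
    band = halfwidth + 3.0
    thetas = np.linspace(0.0, 2.0 * math.pi, n_angles, endpoint=False)
    cos_t, sin_t = np.cos(thetas), np.sin(thetas)
    coherence = 0.0
    for _ in range(iterations):
        r_lo = max(radius - band, 1.0)
        rs = np.linspace(r_lo, radius + band, int(round((radius + band - r_lo) * 2)) + 1)
        xs = cx + np.outer(cos_t, rs)
        ys = cy + np.outer(sin_t, rs)
        vals = ndimage.map_coordinates(
            image, [ys.ravel(), xs.ravel()], order=1, mode="constant", cval=0.0
        ).reshape(n_angles, len(rs))
        vals = np.clip(vals - background, 0.0, None)
        weight = vals.sum(axis=1)
        if weight.max() <= 0:
            break
        # every ray of an in-frame ring crosses the membrane, so the floor
        # only needs to reject out-of-frame / fully masked sectors
        ok = weight > 0.05 * weight.max()
        if ok.sum() < 8:
            break
        rc = (vals @ rs) / np.maximum(weight, 1e-12)
        design = np.column_stack([np.ones(int(ok.sum())), cos_t[ok], sin_t[ok]])
        (r_new, dx, dy), *_ = np.linalg.lstsq(design, rc[ok], rcond=None)
        model = r_new + dx * cos_t[ok] + dy * sin_t[ok]
        resid = rc[ok] - model
        within = np.abs(rs[None, :] - model[:, None]) <= halfwidth
        peak_mass = (vals[ok] * within).sum(axis=1) / np.maximum(weight[ok], 1e-12)
        coherent = (np.abs(resid) <= coherence_tol_px) & (peak_mass >= peak_mass_min)
        # intensity-weighted so that dim (Lo) arcs neither carry nor sink
        # the score; a noise circle spreads weight over incoherent rays
        coherence = float(np.sum(weight[ok] * coherent) / np.sum(weight[ok]))
        cx += float(np.clip(dx, -2.0, 2.0))
        cy += float(np.clip(dy, -2.0, 2.0))
        radius = float(np.clip(r_new, radius - 3.0, radius + 3.0))
        if abs(dx) < 1e-4 and abs(dy) < 1e-4:
            break
    return cx, cy, radius, coherence


def detect_vesicles(scene: ConfocalScene, config: RunConfig) -> list[GUVRing]:
    """Detect ring-like vesicle cross-sections in a scene.

    Returns rings sorted by descending detection score.  Rings whose
    annulus extends beyond the image are flagged ``edge_clipped``; ring
    pairs with center distance below ``overlap_factor * (r1 + r2)`` are
    flagged ``overlapping``.  An empty list is a valid result.
    """
    combined = scene.marker_channel.astype(float) + scene.dna_channel.astype(float)
    if combined.size == 0:
        raise ValueError("scene has empty channels")
    smoothed = ndimage.gaussian_filter(combined, config.detect_smooth_sigma)
    # refinement and scoring use a lightly smoothed image so the membrane
    # band stays narrow relative to the annulus half-width
    refine_img = ndimage.gaussian_filter(combined, 1.0)

    span = np.ptp(smoothed)
    if span == 0:
        return []
    norm = (smoothed - smoothed.min()) / span
    edges = canny(norm, sigma=1.0)
    if not edges.any():
        return []

    r_lo = max(int(math.floor(config.radius_min_px)), 3)
    r_hi = max(int(math.ceil(config.radius_max_px)), r_lo + 1)
    # radii beyond half the image diagonal cannot form a meaningful ring
    r_cap = int(math.hypot(*combined.shape))
    radii = np.arange(r_lo, min(r_hi, r_cap) + 1)
    accum = hough_circle(edges, radii)
    max_peaks = max(64, combined.size // (r_lo * r_lo))
    # the accumulator only shortlists candidates; acceptance is decided by
    # the ring-coherence score computed during refinement
    scores, cxs, cys, rads = hough_circle_peaks(
        accum,
        radii,
        min_xdistance=r_lo,
        min_ydistance=r_lo,
        threshold=HOUGH_SHORTLIST_FLOOR,
        total_num_peaks=max_peaks,
        normalize=False,
    )
    if len(scores) == 0:
        return []

    grad_y, grad_x = np.gradient(smoothed)
    grad_mag = np.hypot(grad_x, grad_y)
    # rings occupy a small area fraction, so the median of the smoothed
    # image is a pedestal-free background estimate for ray profiles
    background = float(np.median(refine_img))

    # group candidates by center proximity; keep, per group, the radius with
    # the highest mean annular gradient (selects the membrane, not the halo)
    order = np.argsort(-scores)
    kept: list[tuple[float, float, float, float]] = []  # cx, cy, r, score
    for i in order:
        cx, cy, r, s = float(cxs[i]), float(cys[i]), float(rads[i]), float(scores[i])
        matched = False
        for j, (kx, ky, kr, ks) in enumerate(kept):
            if math.hypot(cx - kx, cy - ky) < max(kr, r) * 0.75:
                matched = True
                cand = _annular_gradient_score(grad_mag, cx, cy, r, config.annulus_halfwidth_px)
                incumbent = _annular_gradient_score(grad_mag, kx, ky, kr, config.annulus_halfwidth_px)
                if cand > incumbent:
                    kept[j] = (cx, cy, r, max(s, ks))
                break
        if not matched:
            kept.append((cx, cy, r, s))

    h, w = combined.shape
    refined: list[tuple[float, float, float, float]] = []
    for cx, cy, r, s in kept:
        cx, cy, r, coherence = _refine_ring(
            refine_img, cx, cy, r, config.annulus_halfwidth_px, background
        )
        if not (0 <= cx < w and 0 <= cy < h):
            continue
        if coherence < config.score_threshold:
            continue
        # distinct Hough candidates can converge onto one membrane
        duplicate = False
        for j, (kx, ky, kr, ks) in enumerate(refined):
            if math.hypot(cx - kx, cy - ky) < 0.5 * min(r, kr):
                duplicate = True
                if coherence > ks:
                    refined[j] = (cx, cy, r, coherence)
                break
        if not duplicate:
            refined.append((cx, cy, r, coherence))

    rings: list[GUVRing] = []
    for cx, cy, r, score in refined:
        flags: set = set()
        pad = r + config.annulus_halfwidth_px
        if cx - pad < 0 or cy - pad < 0 or cx + pad > w - 1 or cy + pad > h - 1:
            flags.add(EDGE_CLIPPED)
        rings.append(
            GUVRing(
                center_xy=(cx, cy),
                radius_px=r,
                annulus_halfwidth_px=config.annulus_halfwidth_px,
                detection_score=float(np.clip(score, 0.0, 1.0)),
                flags=flags,
            )
        )

    for i, a in enumerate(rings):
        for b in rings[i + 1:]:
            d = math.hypot(a.center_xy[0] - b.center_xy[0],
                           a.center_xy[1] - b.center_xy[1])
            if d < (a.radius_px + b.radius_px) * config.overlap_factor:
                a.flags.add(OVERLAPPING)
                b.flags.add(OVERLAPPING)

    rings.sort(key=lambda r: -r.detection_score)
    for k, ring in enumerate(rings):
        ring.guv_id = f"{scene.scene_id}-g{k:03d}" if scene.scene_id else f"g{k:03d}"
    return rings


def filter_rings(rings: list[GUVRing], config: RunConfig) -> list[GUVRing]:
    """Drop edge-clipped and low-score rings; overlapping rings are kept
    (their shared arcs are masked downstream).  Score ordering preserved."""
    return [
        r for r in rings
        if EDGE_CLIPPED not in r.flags
        and LOW_SCORE not in r.flags
        and r.detection_score >= config.score_threshold
    ]
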