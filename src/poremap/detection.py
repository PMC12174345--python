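"""Pore localization in topography images by template cross-correlation.

Detection mirrors the multi-stringency confidence-set procedure used on
AFM micrographs: a normalized (Pearson) cross-correlation map against an
inverted-pore template, greedy non-maximum suppression, sub-pixel
centroid refinement, and a confidence tier per detection given by the
most stringent of three correlation thresholds it passes.  Tier sets are
nested by construction (tier 1 ⊆ tier 2 ⊆ tier 3).

Correlation uses wrap (periodic) boundary handling, which makes the
detector exactly equivariant under integer cyclic shifts of the image.
"""

from __future__ import annotations

import math

import numpy as np
from scipy import ndimage

from .particles import ParticleSet
from .synthetic import PORE_DIAMETER_NM
from .topography import TopographyImage

__all__ = [
    "build_pore_template",
    "detect_pores",
    "correlation_map",
    "extract_profile",
    "full_width_at_half_depth",
    "DEFAULT_THRESHOLDS",
]

#: default correlation cutoffs, most to least stringent
DEFAULT_THRESHOLDS = (0.8, 0.6, 0.45)


def build_pore_template(
    pore_diameter: float = PORE_DIAMETER_NM, pixel_size: float = 0.5
) -> TopographyImage:
    """Zero-mean template of an inverted radially symmetric pore.

    The depression is Gaussian with FWHM = ``pore_diameter``; the template
    spans one diameter of margin around the pore and has exactly zero mean
    so that flat background correlates to zero.
    """
    if pixel_size > pore_diameter / 4:
        raise ValueError(
            f"pixel_size {pixel_size} nm too coarse to resolve a "
            f"{pore_diameter} nm pore (need <= diameter/4)"
        )
    half = int(math.ceil(pore_diameter / pixel_size))
    ax = np.arange(-half, half + 1) * pixel_size
    d2 = ax[:, None] ** 2 + ax[None, :] ** 2
    sigma = pore_diameter / (2 * math.sqrt(2 * math.log(2)))
    t = -np.exp(-d2 / (2 * sigma * sigma))
    t -= t.mean()
    return TopographyImage(t, pixel_size, {"kind": "pore_template"})


def correlation_map(image: TopographyImage, template: TopographyImage) -> np.ndarray:
    """Pearson normalized cross-correlation of ``template`` over ``image``.

    Local image mean and variance are computed over the template footprint
    with wrap boundary handling; output values lie in [-1, 1].
    """
    img = image.heights
    t = template.heights
    if t.shape[0] > img.shape[0] or t.shape[1] > img.shape[1]:
        raise ValueError("template larger than image")
    t0 = t - t.mean()
    t_norm = math.sqrt(np.sum(t0 * t0))
    npix = t.size
    # numerator: correlation with the zero-mean template (local image mean
    # drops out exactly because sum(t0) == 0)
    num = ndimage.correlate(img, t0, mode="wrap")
    local_mean = ndimage.uniform_filter(img, size=t.shape, mode="wrap")
    local_sq = ndimage.uniform_filter(img * img, size=t.shape, mode="wrap")
    local_var = np.maximum(local_sq - local_mean**2, 0.0)
    denom = t_norm * np.sqrt(npix * local_var)
    with np.errstate(invalid="ignore", divide="ignore"):
        corr = np.where(denom > 1e-12 * max(t_norm, 1.0), num / denom, 0.0)
    return np.clip(corr, -1.0, 1.0)


def detect_pores(
    image: TopographyImage,
    template: TopographyImage | None = None,
    thresholds: tuple[float, float, float] = DEFAULT_THRESHOLDS,
    min_separation: float = 4.0,
) -> ParticleSet:
    """Localize pore centers with three stringency tiers.

    ``thresholds`` are correlation cutoffs, strictly decreasing from most
    to least stringent; ``min_separation`` (nm) is the greedy non-maximum
    suppression radius.  Returns particles with ``tier`` = the most
    stringent threshold passed (1 = highest confidence); use
    :meth:`ParticleSet.at_tier` to take a confidence set.
    """
    t1, t2, t3 = thresholds
    if not (t1 > t2 > t3):
        raise ValueError("thresholds must be strictly decreasing (t1 > t2 > t3)")
    if min_separation <= 0:
        raise ValueError("min_separation must be positive")
    if template is None:
        template = build_pore_template(pixel_size=image.pixel_size)
    if not math.isclose(template.pixel_size, image.pixel_size, rel_tol=1e-6):
        raise ValueError("template and image pixel sizes differ")
    if image.heights.size == 0:
        return ParticleSet(np.empty((0, 2)), np.empty(0, int))

    corr = correlation_map(image, template)
    # local maxima above the loosest threshold
    maxf = ndimage.maximum_filter(corr, size=3, mode="wrap")
    cand = np.argwhere((corr >= t3) & (corr >= maxf - 1e-12))
    if len(cand) == 0:
        return ParticleSet(
            np.empty((0, 2)), np.empty(0, int),
            condition=str(image.metadata.get("condition", "")),
        )
    scores = corr[cand[:, 0], cand[:, 1]]
    # greedy NMS: best score first; ties broken lexicographically by (row, col)
    order = np.lexsort((cand[:, 1], cand[:, 0], -scores))
    cand = cand[order]
    scores = scores[order]
    min_sep_px = min_separation / image.pixel_size
    kept: list[int] = []
    kept_rc = np.empty((0, 2))
    for i, rc in enumerate(cand):
        if kept and np.min(np.sum((kept_rc - rc) ** 2, axis=1)) < min_sep_px**2:
            continue
        kept.append(i)
        kept_rc = cand[kept].astype(float)

    rows, cols, tiers = [], [], []
    nr, nc = corr.shape
    for i in kept:
        r, c = cand[i]
        # sub-pixel centroid over the 3x3 correlation neighbourhood
        rr = (np.arange(r - 1, r + 2)) % nr
        cc = (np.arange(c - 1, c + 2)) % nc
        w = corr[np.ix_(rr, cc)].copy()
        w -= w.min()
        if w.sum() > 0:
            dr = float(np.sum(w * np.arange(-1, 2)[:, None]) / w.sum())
            dc = float(np.sum(w * np.arange(-1, 2)[None, :]) / w.sum())
        else:
            dr = dc = 0.0
        rows.append(r + dr)
        cols.append(c + dc)
        s = scores[i]
        tiers.append(1 if s >= t1 else (2 if s >= t2 else 3))

    xy = image.pixel_to_world(np.column_stack([rows, cols]))
    return ParticleSet(
        xy, np.asarray(tiers, int),
        condition=str(image.metadata.get("condition", "")),
    )


def extract_profile(
    image: TopographyImage, a: tuple[float, float], b: tuple[float, float],
    n_samples: int | None = None,
) -> tuple[np.ndarray, np.ndarray]:
    """Bilinearly interpolated height profile along the segment a -> b.

    Returns ``(s, h)`` with arc-length coordinates ``s`` (nm, from ``a``)
    and heights ``h`` (nm).  Endpoints must lie inside the image.
    """
    w, h_nm = image.extent
    for p in (a, b):
        if not (0 <= p[0] <= w and 0 <= p[1] <= h_nm):
            raise ValueError(f"profile endpoint {p} outside image extent {(w, h_nm)}")
    a = np.asarray(a, float)
    b = np.asarray(b, float)
    length = float(np.hypot(*(b - a)))
    if n_samples is None:
        n_samples = max(2, int(round(length / image.pixel_size)) * 4 + 1)
    s = np.linspace(0.0, length, n_samples)
    xy = a[None, :] + (b - a)[None, :] * (s / max(length, 1e-12))[:, None]
    rc = image.world_to_pixel(xy)
    heights = ndimage.map_coordinates(
        image.heights, [rc[:, 0], rc[:, 1]], order=1, mode="nearest"
    )
    return s, heights


def full_width_at_half_depth(s: np.ndarray, h: np.ndarray) -> float:
    """Full width at half depth of the central depression of a profile.

    Baseline is the median of the outer 20% of samples at each end; depth
    is baseline minus the profile minimum; crossings of the half-depth
    level on either side of the minimum are located by linear
    interpolation.  Raises if the profile has no depression.
    """
    s = np.asarray(s, float)
    h = np.asarray(h, float)
    k = max(1, len(h) // 5)
    baseline = float(np.median(np.concatenate([h[:k], h[-k:]])))
    imin = int(np.argmin(h))
    depth = baseline - h[imin]
    if depth <= 0:
        raise ValueError("profile has no central depression")
    level = baseline - depth / 2

    def cross(idx_range, reverse):
        rng = reversed(idx_range) if reverse else idx_range
        prev = imin
        for i in rng:
            if h[i] >= level:
                # interpolate between i and prev
                if h[i] == h[prev]:
                    return s[i]
                f = (level - h[prev]) / (h[i] - h[prev])
                return s[prev] + f * (s[i] - s[prev])
            prev = i
        raise ValueError("half-depth level not crossed within profile")

    left = cross(range(imin - 1, -1, -1), False)
    right = cross(range(imin + 1, len(h)), False)
    return float(abs(right - left))
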