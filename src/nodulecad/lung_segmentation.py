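"""Lung volume segmentation in four sub-steps.

1. initial extraction of the low-attenuation (air) region by Otsu's method,
   with border-connected background removed;
2. removal of the trachea / main bronchi by seeded 3D region growing with a
   volume-jump leak guard;
3. separation of anteriorly fused lungs along the junction line found by
   gray-integral projection;
4. boundary repair by a rolling ball of radius 15 mm along each per-slice
   lung contour, recovering juxta-pleural indentations.

The rolling-ball contract — fill an indentation wherever a disc of the given
radius touches the contour at more than one point — is implemented as 2D
morphological closing per slice with a radius-r disc, which is its set-
theoretic equivalent for contour indentations.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, replace

import numpy as np
from scipy import ndimage
from skimage.morphology import disk

from nodulecad.volume_io import CTVolume

logger = logging.getLogger(__name__)

_STRUCT26 = np.ones((3, 3, 3), bool)


class SegmentationError(RuntimeError):
    """Raised when a segmentation sub-step produces an empty/implausible result."""


@dataclass
class LungMask:
    """Labeled lung fields: 0 background, 1 right lung, 2 left lung."""

    labels: np.ndarray
    spacing: tuple[float, float, float]
    right_label: int = 1
    left_label: int = 2
    junction_separated: bool = False

    @property
    def mask(self) -> np.ndarray:
        return self.labels > 0


def otsu_threshold(values: np.ndarray, nbins: int = 256) -> float:
    """Threshold maximizing between-class variance over an *nbins* histogram.

    Returns the upper edge of the background class (a value strictly between
    the two modes for well-separated bimodal input).
    """
    values = np.asarray(values).ravel()
    values = values[np.isfinite(values)]
    if values.size == 0 or np.ptp(values) == 0:
        raise ValueError("Otsu threshold undefined for constant input")
    hist, edges = np.histogram(values, bins=nbins)
    p = hist.astype(float) / hist.sum()
    centers = (edges[:-1] + edges[1:]) / 2.0
    w0 = np.cumsum(p)
    w1 = 1.0 - w0
    mu = np.cumsum(p * centers)
    mu_t = mu[-1]
    with np.errstate(divide="ignore", invalid="ignore"):
        var_between = (mu_t * w0 - mu) ** 2 / (w0 * w1)
    var_between[~np.isfinite(var_between)] = -1.0
    k = int(np.argmax(var_between[:-1]))  # split after bin k
    return float(edges[k + 1])


def extract_initial_lung(vol: CTVolume, min_component_mm3: float = 500.0) -> np.ndarray:
    """Candidate lung + airway region: below-Otsu voxels interior to the body.

    Background air connected to the lateral (y/x) borders of the volume is
    removed; components smaller than *min_component_mm3* are dropped.
    """
    if not vol.normalized:
        raise ValueError("expected a window-normalized volume")
    t = otsu_threshold(vol.data)
    low = vol.data < t

    labels, n = ndimage.label(low, structure=_STRUCT26)
    if n == 0:
        raise SegmentationError("no low-attenuation region found (all-tissue volume?)")
    border_labels = set()
    for sl in (np.s_[:, 0, :], np.s_[:, -1, :], np.s_[:, :, 0], np.s_[:, :, -1]):
        border_labels.update(np.unique(labels[sl]))
    border_labels.discard(0)
    keep = np.ones(n + 1, bool)
    keep[0] = False
    for b in border_labels:
        keep[b] = False
    region = keep[labels]

    if not region.any():
        raise SegmentationError(
            "initial lung extraction is empty; Otsu threshold "
            f"{t:.3f} separated nothing from the border-connected background")
    # drop specks
    labels, n = ndimage.label(region, structure=_STRUCT26)
    sizes = ndimage.sum_labels(np.ones_like(labels), labels, index=np.arange(1, n + 1))
    min_vox = min_component_mm3 / vol.voxel_volume
    good = np.concatenate([[False], sizes >= min_vox])
    region = good[labels]
    if not region.any():
        raise SegmentationError("no lung-sized low-attenuation component found")
    return region


def _find_tracheal_seed(region: np.ndarray, spacing) -> tuple[int, int, int] | None:
    """Most superior dark, near-midline, roughly circular cross-section."""
    nz, ny, nx = region.shape
    midx = nx / 2.0
    voxel_area = spacing[1] * spacing[2]
    top = range(nz - 1, max(nz - max(2, nz // 10) - 1, -1), -1)
    for z in top:
        sl = region[z]
        if not sl.any():
            continue
        lab, n = ndimage.label(sl)
        for i in range(1, n + 1):
            comp = lab == i
            area = comp.sum() * voxel_area
            if not (20.0 <= area <= 300.0):
                continue
            ys, xs = np.nonzero(comp)
            cx = xs.mean()
            if abs(cx - midx) * spacing[2] > 30.0:
                continue
            # circularity: 4*pi*area / perimeter^2 (perimeter by boundary count)
            er = ndimage.binary_erosion(comp)
            perim = (comp & ~er).sum() * spacing[2]
            circ = 4 * np.pi * comp.sum() * voxel_area / max(perim, 1e-9) ** 2
            if circ < 0.7:
                continue
            return (z, int(round(ys.mean())), int(round(cx)))
    return None


def remove_airways(vol: CTVolume, region: np.ndarray, leak_factor: float = 1.5,
                   seed: tuple[int, int, int] | None = None,
                   guard_min_volume: int = 200) -> np.ndarray:
    """Remove trachea/main bronchi by 3D region growing from a tracheal seed.

    Growth proceeds by iterative 26-connected dilation restricted to *region*
    and aborts when the grown volume jumps by more than *leak_factor* between
    iterations (leak into the lung fields).  The guard arms only once the
    grown set exceeds *guard_min_volume* voxels, because the early spherical
    growth phase of any tube shows large volume ratios.  Without a usable
    seed the region is returned unchanged with a logged warning.
    """
    if seed is None:
        seed = _find_tracheal_seed(region, vol.spacing)
    if seed is None or not region[tuple(seed)]:
        logger.warning("no tracheal seed found; airway removal skipped")
        return region

    grown = np.zeros_like(region)
    grown[tuple(seed)] = True
    vol_prev = 1
    for _ in range(max(region.shape) * 2):
        nxt = ndimage.binary_dilation(grown, structure=_STRUCT26) & region
        vol_next = int(nxt.sum())
        if vol_next == vol_prev:
            grown = nxt
            break
        if vol_prev > guard_min_volume and vol_next > leak_factor * vol_prev:
            logger.warning("airway region growing leak guard triggered "
                           "(%d -> %d voxels); growth stopped", vol_prev, vol_next)
            break
        grown = nxt
        vol_prev = vol_next
    return region & ~grown


def separate_fused_lungs(region: np.ndarray,
                         spacing: tuple[float, float, float] = (1.0, 1.0, 1.0),
                         band_fraction: float = 0.25) -> LungMask:
    """Separate anteriorly fused lungs and label left/right.

    Per slice where the two lungs form one 26-connected 2D component spanning
    the midline, the column-wise integral projection of the binary region is
    computed over a central band (default the central 25 % of the x-extent)
    and the region is cut along the minimum-projection column; the cut path
    is smoothed across slices with a running median of 5.
    """
    region = region.astype(bool)
    nz, ny, nx = region.shape
    xs_any = np.nonzero(region.any(axis=(0, 1)))[0]
    if xs_any.size == 0:
        return LungMask(labels=np.zeros(region.shape, np.int32), spacing=spacing)
    x_lo, x_hi = xs_any[0], xs_any[-1]
    mid = (x_lo + x_hi) / 2.0
    half_band = max(1, int(round((x_hi - x_lo + 1) * band_fraction / 2)))
    b0, b1 = int(mid) - half_band, int(mid) + half_band + 1

    fused = np.full(nz, -1, int)
    for z in range(nz):
        sl = region[z]
        if not sl.any():
            continue
        lab, n = ndimage.label(sl, structure=np.ones((3, 3), bool))
        for i in range(1, n + 1):
            comp = lab == i
            xs = np.nonzero(comp.any(axis=0))[0]
            if xs[0] >= mid - 2 or xs[-1] <= mid + 2:
                continue
            proj = comp[:, b0:b1].sum(axis=0)
            heights = comp.sum(axis=0)
            typical = np.median(heights[heights > 0])
            # a true junction is a thin bridge; a single wide lung is not
            if proj.min() < 0.5 * typical:
                fused[z] = b0 + int(np.argmin(proj))
            break

    cut = region.copy()
    any_cut = False
    fz = np.nonzero(fused >= 0)[0]
    if fz.size:
        # median-of-5 smoothing of the cut path across slices
        path = fused.astype(float)
        path[fused < 0] = np.nan
        sm = fused.copy()
        for z in fz:
            window = path[max(0, z - 2): z + 3]
            sm[z] = int(np.nanmedian(window))
        for z in fz:
            cut[z, :, sm[z]] = False
            any_cut = True

    labels3, n = ndimage.label(cut, structure=_STRUCT26)
    if n == 0:
        return LungMask(labels=np.zeros(region.shape, np.int32), spacing=spacing)
    sizes = ndimage.sum_labels(np.ones_like(labels3), labels3, index=np.arange(1, n + 1))
    order = np.argsort(sizes)[::-1] + 1
    out = np.zeros(region.shape, np.int32)
    if n == 1:
        out[labels3 == order[0]] = 1
        return LungMask(labels=out, spacing=spacing, junction_separated=any_cut)
    a, b = order[0], order[1]
    cx_a = ndimage.center_of_mass(labels3 == a)[2]
    cx_b = ndimage.center_of_mass(labels3 == b)[2]
    right, left = (a, b) if cx_a < cx_b else (b, a)  # right lung at low x
    out[labels3 == right] = 1
    out[labels3 == left] = 2
    return LungMask(labels=out, spacing=spacing, junction_separated=any_cut)


def repair_boundary(mask: LungMask, radius_mm: float = 15.0,
                    fill_holes: bool = True) -> LungMask:
    """Fill contour indentations with a rolling ball of *radius_mm*.

    Per slice and per lung, morphological closing with a radius-r disc; the
    result contains the input (monotone growth) and is idempotent.  Interior
    holes left by bright vessels are also filled per slice.
    """
    if radius_mm <= 0:
        raise ValueError("rolling-ball radius must be positive")
    r_vox = max(1, int(round(radius_mm / mask.spacing[1])))
    selem = disk(r_vox)
    pad = r_vox + 1
    out = np.zeros_like(mask.labels)
    for lab in (mask.right_label, mask.left_label):
        m = mask.labels == lab
        if not m.any():
            continue
        closed = np.zeros_like(m)
        for z in range(m.shape[0]):
            sl = m[z]
            if not sl.any():
                continue
            padded = np.pad(sl, pad)
            c = ndimage.binary_closing(padded, structure=selem)
            c = c[pad:-pad, pad:-pad]
            if fill_holes:
                c = ndimage.binary_fill_holes(c)
            closed[z] = c
        out[closed & (out == 0)] = lab
    # never lose original voxels
    keep = (mask.labels > 0) & (out == 0)
    out[keep] = mask.labels[keep]
    return replace(mask, labels=out)


def segment_lungs(vol: CTVolume, rolling_ball_radius_mm: float = 15.0,
                  leak_factor: float = 1.5) -> LungMask:
    """Full four-step lung segmentation of a normalized, isotropic volume."""
    region = extract_initial_lung(vol)
    logger.info("initial lung region: %d voxels", int(region.sum()))
    region = remove_airways(vol, region, leak_factor=leak_factor)
    lungs = separate_fused_lungs(region, spacing=vol.spacing)
    lungs = repair_boundary(lungs, radius_mm=rolling_ball_radius_mm)
    logger.info("final lung mask: %d voxels", int(lungs.mask.sum()))
    return lungs
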