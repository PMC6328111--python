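"""Candidate grouping and extraction.

High-attenuation structures inside the segmented lungs (multilevel-Otsu upper
class) are 26-connectivity labeled and split, per lung, into the *vessel
tree* group — the largest connected component, which also carries any nodule
attached to it — and the *non-vessel tree* group (everything else: isolated
and juxta-pleural nodules, tiny peripheral vessels, noise).

Candidates are then extracted from dot-enhanced maps with group-specific
binarization thresholds (15/256 for the vessel-tree group, 10/256 for the
non-vessel group, on the normalized filter-output scale), followed by
constrained region growing: because dot-enhanced candidates appear slightly
smaller than the underlying object, each seed grows up to 5 mm of geodesic
distance *within* its group mask, which reclaims the full nodule without
flooding along the vessel tree.
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import combinations

import numpy as np
from scipy import ndimage
from skimage.graph import MCP_Geometric
from skimage.segmentation import watershed

from nodulecad.volume_io import CTVolume
from nodulecad.lung_segmentation import LungMask
from nodulecad.dot_enhancement import multiscale_dot_filter, DEFAULT_SCALES

_STRUCT26 = np.ones((3, 3, 3), bool)

#: binarization thresholds on the normalized dot-response scale
T_VESSEL_GROUP = 15.0 / 256.0
T_NONVESSEL_GROUP = 10.0 / 256.0

#: candidates smaller than a 2 mm sphere are discarded in the non-vessel group
MIN_NONVESSEL_VOLUME_MM3 = 4.19

GROWTH_LIMIT_MM = 5.0


@dataclass
class Candidate:
    """One labeled 3D connected component proposed as a nodule."""

    id: int
    voxels: np.ndarray  # (N, 3) int indices (z, y, x)
    group: str  # "vessel_tree" | "non_vessel_tree"
    volume_mm3: float
    centroid_mm: tuple[float, float, float]
    shape: tuple[int, int, int]
    spacing: tuple[float, float, float]

    def mask(self) -> np.ndarray:
        m = np.zeros(self.shape, bool)
        m[tuple(self.voxels.T)] = True
        return m


def candidates_from_mask(mask: np.ndarray, group: str,
                         spacing=(1.0, 1.0, 1.0)) -> list[Candidate]:
    """Label a binary volume (26-connectivity) into Candidate objects."""
    labeled, n = ndimage.label(mask, structure=_STRUCT26)
    voxel_volume = float(np.prod(spacing))
    out = []
    for i in range(1, n + 1):
        vox = np.argwhere(labeled == i)
        centroid = tuple(float(v) for v in vox.mean(axis=0) * np.asarray(spacing))
        out.append(Candidate(id=i, voxels=vox, group=group,
                             volume_mm3=len(vox) * voxel_volume,
                             centroid_mm=centroid, shape=mask.shape,
                             spacing=tuple(spacing)))
    return out


def candidates_to_table(candidates: list[Candidate]):
    import pandas as pd

    rows = [{"id": c.id, "group": c.group, "cz": c.centroid_mm[0],
             "cy": c.centroid_mm[1], "cx": c.centroid_mm[2],
             "volume_mm3": c.volume_mm3} for c in candidates]
    return pd.DataFrame(rows, columns=["id", "group", "cz", "cy", "cx", "volume_mm3"])


# ------------------------------------------------------------ thresholds


def multilevel_otsu(values: np.ndarray, classes: int = 3, nbins: int = 256) -> list[float]:
    """Multilevel Otsu thresholds over an *nbins* histogram (exhaustive search).

    Returns ``classes - 1`` ascending thresholds maximizing the between-class
    variance; the highest threshold separates the high-attenuation
    (vessel + nodule) class.  ``classes=2`` reduces to ordinary Otsu.
    """
    if classes < 2:
        raise ValueError("classes must be >= 2")
    values = np.asarray(values).ravel()
    values = values[np.isfinite(values)]
    if values.size == 0 or len(np.unique(values)) < classes:
        raise ValueError(f"need at least {classes} distinct values")
    hist, edges = np.histogram(values, bins=nbins)
    p = hist.astype(float) / hist.sum()
    centers = (edges[:-1] + edges[1:]) / 2.0
    cw = np.concatenate([[0.0], np.cumsum(p)])
    cm = np.concatenate([[0.0], np.cumsum(p * centers)])

    def class_stat(a, b):  # bins a..b-1
        w = cw[b] - cw[a]
        if w <= 0:
            return 0.0
        mu = (cm[b] - cm[a]) / w
        return w * mu * mu

    best, best_cuts = -1.0, None
    for cuts in combinations(range(1, nbins), classes - 1):
        bounds = (0,) + cuts + (nbins,)
        stat = sum(class_stat(bounds[i], bounds[i + 1]) for i in range(classes))
        if stat > best:
            best, best_cuts = stat, cuts
    return [float(edges[c]) for c in best_cuts]


def high_attenuation_mask(vol: CTVolume, lungs: LungMask, classes: int = 3) -> np.ndarray:
    """Vessel + nodule mask: lung-interior voxels above the top Otsu threshold."""
    inside = lungs.mask
    thresholds = multilevel_otsu(vol.data[inside], classes=classes)
    return inside & (vol.data >= thresholds[-1])


# ------------------------------------------------------------ labeling & groups


def label_components_26(mask: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """26-connectivity component labeling; returns (labels, sizes[1..n])."""
    labeled, n = ndimage.label(mask, structure=_STRUCT26)
    if n == 0:
        return labeled, np.zeros(0, int)
    sizes = ndimage.sum_labels(np.ones_like(labeled), labeled,
                               index=np.arange(1, n + 1)).astype(int)
    return labeled, sizes


def split_groups(labeled: np.ndarray, lungs: LungMask) -> tuple[np.ndarray, np.ndarray]:
    """Split labeled structures into (vessel_tree_mask, non_vessel_mask).

    Per lung, the largest component by voxel count becomes the vessel tree
    (ties broken by lowest label id); all other components go to the
    non-vessel group.  Components are assigned to the lung they overlap most.
    """
    import logging

    n = int(labeled.max())
    vessel = np.zeros(labeled.shape, bool)
    nonvessel = np.zeros(labeled.shape, bool)
    if n == 0:
        logging.getLogger(__name__).warning("no structures inside the lungs")
        return vessel, nonvessel
    idx = np.arange(1, n + 1)
    sizes = ndimage.sum_labels(np.ones_like(labeled), labeled, index=idx)
    overlap = {}
    for lung_label in (lungs.right_label, lungs.left_label):
        overlap[lung_label] = ndimage.sum_labels((lungs.labels == lung_label).astype(float),
                                                 labeled, index=idx)
    assigned = np.where(overlap[lungs.right_label] >= overlap[lungs.left_label],
                        lungs.right_label, lungs.left_label)
    for lung_label in (lungs.right_label, lungs.left_label):
        members = idx[(assigned == lung_label) & (sizes > 0)]
        if members.size == 0:
            logging.getLogger(__name__).warning("lung %d has no structures", lung_label)
            continue
        member_sizes = sizes[members - 1]
        largest = members[int(np.argmax(member_sizes))]  # argmax -> lowest id on ties
        vessel |= labeled == largest
        for m in members:
            if m != largest:
                nonvessel |= labeled == m
    return vessel, nonvessel


# ------------------------------------------------------------ extraction


def binarize_enhanced(enhanced: CTVolume, T: float) -> np.ndarray:
    """Threshold a normalized dot-response map at fraction *T*."""
    return enhanced.data >= T


def constrained_region_growing(seed_mask: np.ndarray, reference_mask: np.ndarray,
                               limit_mm: float = GROWTH_LIMIT_MM,
                               spacing=(1.0, 1.0, 1.0)) -> np.ndarray:
    """Grow seeds into *reference_mask* up to *limit_mm* of geodesic distance.

    Distance is measured within the reference mask (26-connected moves with
    Euclidean step lengths), so growth cannot jump across background; with
    ``limit_mm=0`` the result is ``seed_mask & reference_mask``.
    """
    if limit_mm < 0:
        raise ValueError("growth limit must be >= 0")
    seeds = seed_mask & reference_mask
    if not seeds.any():
        return np.zeros_like(reference_mask)
    if limit_mm == 0:
        return seeds
    costs = np.where(reference_mask, 1.0, np.inf)
    mcp = MCP_Geometric(costs, sampling=spacing)
    dist, _ = mcp.find_costs(np.argwhere(seeds))
    return reference_mask & (dist <= limit_mm)


def grow_candidates(seed_mask: np.ndarray, reference_mask: np.ndarray, group: str,
                    limit_mm: float = GROWTH_LIMIT_MM,
                    spacing=(1.0, 1.0, 1.0)) -> list[Candidate]:
    """Grow each 26-connected seed object separately into Candidates.

    All seeds share one geodesic distance map; grown voxels reachable from
    several seed objects are assigned to the nearest one (watershed on the
    distance map), so a nodule seed next to a bifurcation seed keeps its own
    identity instead of merging into one oversized candidate.
    """
    seeds = seed_mask & reference_mask
    if not seeds.any():
        return []
    seed_labels, _ = ndimage.label(seeds, structure=_STRUCT26)
    if limit_mm == 0:
        grown = seeds
        dist = np.where(seeds, 0.0, np.inf)
    else:
        costs = np.where(reference_mask, 1.0, np.inf)
        mcp = MCP_Geometric(costs, sampling=spacing)
        dist, _ = mcp.find_costs(np.argwhere(seeds))
        grown = reference_mask & (dist <= limit_mm)
    assigned = watershed(dist, markers=seed_labels, mask=grown)
    voxel_volume = float(np.prod(spacing))
    out = []
    for i in range(1, int(seed_labels.max()) + 1):
        vox = np.argwhere(assigned == i)
        if len(vox) == 0:
            continue
        centroid = tuple(float(v) for v in vox.mean(axis=0) * np.asarray(spacing))
        out.append(Candidate(id=len(out) + 1, voxels=vox, group=group,
                             volume_mm3=len(vox) * voxel_volume,
                             centroid_mm=centroid, shape=seed_mask.shape,
                             spacing=tuple(spacing)))
    return out


def extract_vessel_group_candidates(vol: CTVolume, vessel_mask: np.ndarray,
                                    scales=DEFAULT_SCALES, T: float = T_VESSEL_GROUP,
                                    growth_limit_mm: float = GROWTH_LIMIT_MM,
                                    ) -> list[Candidate]:
    """Dot-filter the vessel-tree region and cut candidates away from the tree.

    Small objects are deliberately *not* removed here — subtle nodules in the
    vessel-tree group would go with them; vessel-bifurcation false positives
    survive to be removed by the downstream classifier.
    """
    masked = _masked_volume(vol, vessel_mask)
    roi = ndimage.binary_dilation(vessel_mask, iterations=2)
    enhanced = multiscale_dot_filter(masked, scales=scales, mask=roi)
    seeds = binarize_enhanced(enhanced, T) & vessel_mask
    return grow_candidates(seeds, vessel_mask, "vessel_tree", growth_limit_mm, vol.spacing)


def extract_nonvessel_group_candidates(vol: CTVolume, non_vessel_mask: np.ndarray,
                                       scales=DEFAULT_SCALES, T: float = T_NONVESSEL_GROUP,
                                       min_volume_mm3: float = MIN_NONVESSEL_VOLUME_MM3,
                                       growth_limit_mm: float = GROWTH_LIMIT_MM,
                                       ) -> list[Candidate]:
    """Extract non-vessel-group candidates (mask already rule-filtered).

    Dot filter -> binarize at 10/256 -> drop objects below 4.19 mm^3 (2 mm
    diameter) -> constrained growth.  Tiny-vessel bifurcations respond much
    more weakly than vessel-tree ones and fall below the threshold.
    """
    masked = _masked_volume(vol, non_vessel_mask)
    roi = ndimage.binary_dilation(non_vessel_mask, iterations=2)
    enhanced = multiscale_dot_filter(masked, scales=scales, mask=roi)
    seeds = binarize_enhanced(enhanced, T) & non_vessel_mask
    labeled, sizes = label_components_26(seeds)
    voxel_volume = float(np.prod(vol.spacing))
    keep = np.concatenate([[False], sizes * voxel_volume >= min_volume_mm3])
    seeds = keep[labeled]
    return grow_candidates(seeds, non_vessel_mask, "non_vessel_tree",
                           growth_limit_mm, vol.spacing)


def _masked_volume(vol: CTVolume, mask: np.ndarray) -> CTVolume:
    from dataclasses import replace

    return replace(vol, data=np.where(mask, vol.data, 0.0))
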