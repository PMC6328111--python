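"""Rule-based removal of obvious non-vessel-group false positives.

Four deliberately lax rules: a candidate is kept iff

* 14.14 mm^3 <= volume <= 14.14 cm^3 (the volumes of 2 mm- and 30 mm-diameter
  spheres bracket the clinically relevant 3-30 mm size class with margin),
* elongation factor <= 6 (per-slice bounding-ellipse axis ratio),
* 2D compactness >= 0.3 (per-slice area / bounding-box area),
* sphericity >= 0.3 (overlap with the volume-equivalent sphere).

Boundary values survive: elimination requires a strict violation.  The lax
cut-offs protect juxta-vascular nodules attached to tiny vessels, whose
composite shapes score worse than clean spheres.

Per-candidate aggregation over transverse sections is worst-case (maximum
elongation, minimum compactness) by default; ``aggregate="largest_slice"``
evaluates only the candidate's largest-area section instead.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from nodulecad.candidate_extraction import Candidate

VOLUME_MIN_MM3 = 14.14
VOLUME_MAX_MM3 = 14.14e3  # 14.14 cm^3
ELONGATION_MAX = 6.0
COMPACTNESS_MIN = 0.3
SPHERICITY_MIN = 0.3


def _slices(candidate: Candidate):
    vox = candidate.voxels
    for z in np.unique(vox[:, 0]):
        yield vox[vox[:, 0] == z, 1:]


def _slice_elongation(yx: np.ndarray) -> float:
    """Axis ratio of the second-moment (covariance) ellipse of in-slice voxels.

    A uniform 1-voxel-wide square contributes 1/12 to each coordinate
    variance, so thin bars and single voxels stay finite.
    """
    if len(yx) == 1:
        return 1.0
    cov = np.cov(yx.astype(float), rowvar=False, bias=True) + np.eye(2) / 12.0
    ev = np.linalg.eigvalsh(cov)
    return float(np.sqrt(ev[1] / ev[0]))


def elongation_factor(candidate: Candidate, aggregate: str = "worst") -> float:
    """Major/minor axis ratio of the bounding ellipse, per transverse section.

    ``aggregate="worst"`` (default) returns the maximum ratio over the
    candidate's sections; ``"largest_slice"`` the ratio on its largest section.
    """
    ratios, areas = [], []
    for yx in _slices(candidate):
        ratios.append(_slice_elongation(yx))
        areas.append(len(yx))
    if not ratios:
        raise ValueError("empty candidate")
    if aggregate == "largest_slice":
        return ratios[int(np.argmax(areas))]
    return float(max(ratios))


def compactness2d(candidate: Candidate, aggregate: str = "worst") -> float:
    """In-slice area over axis-aligned bounding-box area, in (0, 1]."""
    vals, areas = [], []
    for yx in _slices(candidate):
        h = yx[:, 0].max() - yx[:, 0].min() + 1
        w = yx[:, 1].max() - yx[:, 1].min() + 1
        vals.append(len(yx) / (h * w))
        areas.append(len(yx))
    if not vals:
        raise ValueError("empty candidate")
    if aggregate == "largest_slice":
        return vals[int(np.argmax(areas))]
    return float(min(vals))


def sphericity(candidate: Candidate) -> float:
    """Fraction of the candidate inside its volume-equivalent sphere.

    The sphere is centered at the candidate's (unweighted) center of mass and
    has the candidate's voxel volume; returns |S ∩ C| / |S| in [0, 1].
    """
    vox = candidate.voxels.astype(float)
    if len(vox) == 0:
        raise ValueError("empty candidate")
    center = vox.mean(axis=0)
    # radius of the equal-volume sphere, in voxels (isotropic assumption)
    r = (3.0 * len(vox) / (4.0 * np.pi)) ** (1.0 / 3.0)
    inside = np.sum(np.sum((vox - center) ** 2, axis=1) <= r * r)
    return float(inside) / len(vox)


def apply_rules(candidates: list[Candidate], *, aggregate: str = "worst",
                volume_min: float = VOLUME_MIN_MM3, volume_max: float = VOLUME_MAX_MM3,
                elongation_max: float = ELONGATION_MAX,
                compactness_min: float = COMPACTNESS_MIN,
                sphericity_min: float = SPHERICITY_MIN,
                ) -> tuple[list[Candidate], pd.DataFrame]:
    """Apply all four rules; returns (survivors, report).

    The report has one row per candidate with the measured values, per-rule
    pass flags, and the overall verdict (pass iff all four rules pass).
    """
    rows, survivors = [], []
    for c in candidates:
        elo = elongation_factor(c, aggregate=aggregate)
        comp = compactness2d(c, aggregate=aggregate)
        sph = sphericity(c)
        ok_vol = volume_min <= c.volume_mm3 <= volume_max
        ok_elo = elo <= elongation_max
        ok_comp = comp >= compactness_min
        ok_sph = sph >= sphericity_min
        verdict = ok_vol and ok_elo and ok_comp and ok_sph
        rows.append({"id": c.id, "volume_mm3": c.volume_mm3, "elongation": elo,
                     "compactness": comp, "sphericity": sph,
                     "pass_volume": ok_vol, "pass_elongation": ok_elo,
                     "pass_compactness": ok_comp, "pass_sphericity": ok_sph,
                     "verdict": verdict})
        if verdict:
            survivors.append(c)
    report = pd.DataFrame(rows, columns=["id", "volume_mm3", "elongation", "compactness",
                                         "sphericity", "pass_volume", "pass_elongation",
                                         "pass_compactness", "pass_sphericity", "verdict"])
    return survivors, report
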