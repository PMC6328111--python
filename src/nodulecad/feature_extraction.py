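"""Gray-level, gradient and shape features for vessel-group candidates.

The feature pool has 27 named descriptors in a fixed canonical order:

* 4 gray-level statistics of the candidate's normalized intensities;
* 7 surface-gradient features — gradient magnitudes from 3x3x3 isotropic
  (Sobel-type) kernels evaluated at 26-connectivity surface voxels: max, min,
  mean, sample std, skewness, kurtosis, and the small-value ratio (fraction
  of magnitudes below 0.2x the candidate's maximum).  Nodules are radially
  near-symmetric, so their surface-gradient distribution is tight and
  symmetric; vessel bifurcations are strongly skewed;
* 10 shell-gradient features on a shell (dilation by 2 voxels minus erosion
  by 1) around the candidate: five field-strength statistics and five
  orientation scores (cosine between the gradient and the inward radial
  direction; radial for blobs, mixed for bifurcations);
* 6 shape features — 3D compactness, irregularity, sphericity, and the three
  inertia-tensor descriptors elongation (e1/e2), flatness (e2/e3) and
  non-compactness (trace / V^(5/3), size-invariant for uniform bodies).

All features are invariant under whole-voxel translation; the eigenvalue
ratios are additionally invariant under intensity scaling.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import ndimage

from nodulecad.volume_io import CTVolume
from nodulecad.candidate_extraction import Candidate
from nodulecad.rule_filter import sphericity as _rule_sphericity

_STRUCT26 = np.ones((3, 3, 3), bool)
_STRUCT6 = ndimage.generate_binary_structure(3, 1)

#: eigenvalue ratios are capped here — degenerate (near-planar or near-linear)
#: candidates otherwise produce astronomically large ratios that destroy
#: feature standardization downstream; anything above the cap is equally
#: "completely degenerate" for classification purposes
FLATNESS_CAP = 1e3
SVR_CUTOFF = 0.2  # "small" surface gradient = below this fraction of the max

FEATURE_NAMES = (
    "gray_level_max", "gray_level_min", "gray_level_mean", "gray_level_std",
    "SurG_max", "SurG_min", "SurG_mean", "SurG_std", "SurG_skewness",
    "SurG_kurtosis", "SurG_svr",
    "ShellGM_av", "ShellGM_std", "ShellGM_cv", "ShellGM_max", "ShellGM_min",
    "ShellGD_max", "ShellGD_min", "ShellGD_med", "ShellGD_min_max_sq",
    "ShellGD_med_max_sq",
    "compactness3D", "irregularity", "sphericity",
    "elongation_shape", "flatness_shape", "non_compactness",
)

#: the discriminating subset retained by random-subset feature selection
SELECTED_FEATURES = (
    "gray_level_max", "gray_level_min", "gray_level_mean", "gray_level_std",
    "SurG_max", "SurG_std", "SurG_skewness", "SurG_svr",
    "ShellGM_av", "ShellGM_cv", "ShellGM_min", "ShellGD_min_max_sq",
    "sphericity", "irregularity", "compactness3D", "flatness_shape",
)


@dataclass
class InertiaTensor:
    """Mass-weighted moment-of-inertia tensor of a candidate.

    Mass of voxel k is its normalized CT intensity times the voxel volume
    (numerically the intensity itself at 1 mm isotropy).  Eigenvalues are
    sorted descending, e1 >= e2 >= e3 >= 0.
    """

    matrix: np.ndarray  # 3x3 symmetric
    eigenvalues: np.ndarray  # (3,) descending


def _bbox(candidate: Candidate, margin: int):
    lo = candidate.voxels.min(axis=0) - margin
    hi = candidate.voxels.max(axis=0) + margin + 1
    lo = np.maximum(lo, 0)
    hi = np.minimum(hi, candidate.shape)
    return tuple(slice(lo[i], hi[i]) for i in range(3)), lo


def gray_features(candidate: Candidate, vol: CTVolume) -> dict[str, float]:
    if len(candidate.voxels) == 0:
        raise ValueError("empty candidate")
    vals = vol.data[tuple(candidate.voxels.T)]
    return {
        "gray_level_max": float(vals.max()),
        "gray_level_min": float(vals.min()),
        "gray_level_mean": float(vals.mean()),
        "gray_level_std": float(vals.std()),  # population std
    }


def surface_voxels(candidate: Candidate) -> np.ndarray:
    """(N, 3) indices of candidate voxels with >= 1 background 26-neighbor."""
    box, lo = _bbox(candidate, 1)
    m = np.zeros(tuple(s.stop - s.start for s in box), bool)
    m[tuple((candidate.voxels - lo).T)] = True
    interior = ndimage.binary_erosion(m, structure=_STRUCT26, border_value=0)
    surf = np.argwhere(m & ~interior) + lo
    return surf


def _isotropic_gradient_kernels() -> list[np.ndarray]:
    """3x3x3 Sobel-type kernels: [1,2,1]x[1,2,1] smoothing, [-1,0,1]/2 derivative."""
    smooth = np.array([1.0, 2.0, 1.0]) / 4.0
    deriv = np.array([-1.0, 0.0, 1.0]) / 2.0
    kernels = []
    for axis in range(3):
        parts = [smooth, smooth, smooth]
        parts[axis] = deriv
        k = np.einsum("i,j,k->ijk", parts[0], parts[1], parts[2])
        kernels.append(k)
    return kernels


def surface_gradient_features(candidate: Candidate, vol: CTVolume,
                              skewness_as_printed: bool = False) -> dict[str, float]:
    """Seven statistics of the gradient magnitude at surface voxels.

    ``skewness_as_printed=True`` uses m3/m2^3 instead of the standard
    m3/m2^(3/2) (a compatibility variant; the standard form is the default).
    Degenerate all-equal magnitudes give skewness = kurtosis = 0.
    """
    surf = surface_voxels(candidate)
    if len(surf) < 2:
        raise ValueError("need >= 2 surface voxels for gradient statistics")
    box, lo = _bbox(candidate, 2)
    sub = vol.data[box]
    mags_sq = np.zeros(sub.shape)
    for k in _isotropic_gradient_kernels():
        g = ndimage.correlate(sub, k, mode="nearest")
        mags_sq += g * g
    mags = np.sqrt(mags_sq)[tuple((surf - lo).T)]
    n = len(mags)
    mean = float(mags.mean())
    std = float(mags.std(ddof=1))
    m2 = float(((mags - mean) ** 2).mean())
    m3 = float(((mags - mean) ** 3).mean())
    m4 = float(((mags - mean) ** 4).mean())
    if m2 <= 1e-30:
        skew = kurt = 0.0
    else:
        skew = m3 / (m2 ** 3 if skewness_as_printed else m2 ** 1.5)
        kurt = m4 / m2 ** 2
    svr = float(np.mean(mags < SVR_CUTOFF * mags.max())) if mags.max() > 0 else 0.0
    return {
        "SurG_max": float(mags.max()), "SurG_min": float(mags.min()),
        "SurG_mean": mean, "SurG_std": std, "SurG_skewness": float(skew),
        "SurG_kurtosis": float(kurt), "SurG_svr": svr,
    }


def shell_gradient_features(candidate: Candidate, vol: CTVolume) -> dict[str, float]:
    """Shell-based gradient field strength and orientation features.

    The shell is (candidate dilated by 2 voxels) minus (candidate eroded by
    1).  Strength = central-difference gradient magnitude; orientation score
    = cosine between the gradient and the inward radial direction toward the
    candidate centroid (+1 for a perfectly radial bright blob).  The squared
    ratios use max |score| in the denominator, so they lie in [0, 1].
    """
    box, lo = _bbox(candidate, 3)
    m = np.zeros(tuple(s.stop - s.start for s in box), bool)
    m[tuple((candidate.voxels - lo).T)] = True
    dil = ndimage.binary_dilation(m, structure=_STRUCT6, iterations=2)
    ero = ndimage.binary_erosion(m, structure=_STRUCT6, border_value=0)
    shell = dil & ~ero
    sub = vol.data[box]
    gz, gy, gx = np.gradient(sub, *vol.spacing)
    pts = np.argwhere(shell)
    g = np.stack([gz[shell], gy[shell], gx[shell]], axis=1)
    mags = np.linalg.norm(g, axis=1)

    centroid = candidate.voxels.mean(axis=0) - lo
    radial = centroid[None, :] - pts  # inward
    rn = np.linalg.norm(radial, axis=1)
    valid = (rn > 1e-9) & (mags > 1e-12)
    scores = np.zeros(len(pts))
    scores[valid] = np.einsum("ij,ij->i", g[valid], radial[valid]) / (mags[valid] * rn[valid])

    av = float(mags.mean())
    std = float(mags.std())
    cv = std / av if av > 0 else 0.0
    smax, smin, smed = float(scores.max()), float(scores.min()), float(np.median(scores))
    denom = float(np.max(np.abs(scores)))
    if denom > 0:
        min_max_sq = (smin / denom) ** 2
        med_max_sq = (smed / denom) ** 2
    else:
        min_max_sq = med_max_sq = 0.0
    return {
        "ShellGM_av": av, "ShellGM_std": std, "ShellGM_cv": float(cv),
        "ShellGM_max": float(mags.max()), "ShellGM_min": float(mags.min()),
        "ShellGD_max": smax, "ShellGD_min": smin, "ShellGD_med": smed,
        "ShellGD_min_max_sq": float(min_max_sq), "ShellGD_med_max_sq": float(med_max_sq),
    }


def inertia_tensor(candidate: Candidate, vol: CTVolume) -> InertiaTensor:
    """Mass-weighted inertia tensor (mass = normalized intensity, 1 mm voxels)."""
    pos = candidate.voxels.astype(float) * np.asarray(vol.spacing)
    mass = vol.data[tuple(candidate.voxels.T)].astype(float)
    total = mass.sum()
    if total <= 0:
        raise ValueError("candidate has zero total mass")
    centroid = (mass[:, None] * pos).sum(axis=0) / total
    d = pos - centroid
    z, y, x = d[:, 0], d[:, 1], d[:, 2]
    Ixx = np.sum(mass * (y * y + z * z))
    Iyy = np.sum(mass * (x * x + z * z))
    Izz = np.sum(mass * (x * x + y * y))
    Ixy = -np.sum(mass * x * y)
    Ixz = -np.sum(mass * x * z)
    Iyz = -np.sum(mass * y * z)
    M = np.array([[Ixx, Ixy, Ixz], [Ixy, Iyy, Iyz], [Ixz, Iyz, Izz]])
    ev = np.linalg.eigvalsh(M)[::-1]
    return InertiaTensor(matrix=M, eigenvalues=ev)


def _surface_area_mm2(candidate: Candidate, spacing) -> float:
    """Exposed-face counting (6-connectivity) surface area."""
    box, lo = _bbox(candidate, 1)
    m = np.zeros(tuple(s.stop - s.start for s in box), bool)
    m[tuple((candidate.voxels - lo).T)] = True
    faces = 0
    for axis in range(3):
        padded = np.pad(m, [(1, 1) if a == axis else (0, 0) for a in range(3)])
        diff = np.diff(padded.astype(np.int8), axis=axis)
        faces += int(np.abs(diff).sum())
    # isotropic assumption: every face has the same area
    face_area = float(np.prod(spacing)) / spacing[0]
    return faces * face_area


def shape_features(candidate: Candidate, vol: CTVolume) -> dict[str, float]:
    it = inertia_tensor(candidate, vol)
    e1, e2, e3 = (float(v) for v in it.eigenvalues)
    elongation = min(e1 / e2, FLATNESS_CAP) if e2 > 0 else FLATNESS_CAP
    flatness = min(e2 / e3, FLATNESS_CAP) if e3 > 0 else FLATNESS_CAP
    V = candidate.volume_mm3
    non_compactness = (e1 + e2 + e3) / V ** (5.0 / 3.0)
    lo = candidate.voxels.min(axis=0)
    hi = candidate.voxels.max(axis=0) + 1
    bbox_vol = float(np.prod((hi - lo) * np.asarray(vol.spacing)))
    compactness3d = V / bbox_vol
    area = _surface_area_mm2(candidate, vol.spacing)
    r_eq = (3.0 * V / (4.0 * np.pi)) ** (1.0 / 3.0)
    sphere_area = 4.0 * np.pi * r_eq ** 2
    irregularity = 1.0 - sphere_area / area if area > 0 else 0.0
    return {
        "compactness3D": float(compactness3d),
        "irregularity": float(irregularity),
        "sphericity": _rule_sphericity(candidate),
        "elongation_shape": float(elongation),
        "flatness_shape": float(flatness),
        "non_compactness": float(non_compactness),
    }


def feature_vector(candidate: Candidate, vol: CTVolume) -> dict[str, float]:
    """The full 27-feature vector, in canonical :data:`FEATURE_NAMES` order."""
    fv = {}
    fv.update(gray_features(candidate, vol))
    fv.update(surface_gradient_features(candidate, vol))
    fv.update(shell_gradient_features(candidate, vol))
    fv.update(shape_features(candidate, vol))
    return {name: fv[name] for name in FEATURE_NAMES}


def select_features(fv: dict[str, float]) -> dict[str, float]:
    """The 16-feature discriminating subset, in canonical order."""
    return {name: fv[name] for name in SELECTED_FEATURES}


def feature_matrix(candidates, vol: CTVolume, names=FEATURE_NAMES):
    """Feature table (one row per candidate id) as a pandas DataFrame."""
    import pandas as pd

    rows = []
    for c in candidates:
        fv = feature_vector(c, vol)
        rows.append({"id": c.id, **{n: fv[n] for n in names}})
    return pd.DataFrame(rows, columns=["id", *names])
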