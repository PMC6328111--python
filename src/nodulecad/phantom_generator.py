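"""Synthetic thorax phantoms with known ground truth.

A phantom emulates the object classes a chest-CT nodule detector must deal
with: air-filled lung fields inside a soft-tissue thorax, a trachea stub, a
recursively branching high-attenuation vessel tree with Y-bifurcations (the
dominant false-positive source), tiny disconnected peripheral vessels at low
contrast, and implanted nodules of four placements — isolated, juxta-pleural
(touching the lung border), juxta-vascular attached to the main tree, and
juxta-vascular attached to a tiny vessel.

Intensities are generated directly in the normalized 0-1 lung-window domain
(air ~0.05, parenchyma ~0.15, tiny vessels ~0.40, vessels/nodules ~0.65,
chest wall ~0.90) so phantoms plug in right after window normalization; an
HU-domain export is available through :func:`nodulecad.volume_io.denormalize`.
Solid structures are hard shapes smoothed by a sub-voxel Gaussian
(0.5 voxels by default), approximating partial-volume blur while keeping
thin terminal vessel branches connected in the attenuation image, as they
are in real thin-slice CT.  All randomness comes from one seeded generator,
so a spec + seed pair is bit-reproducible.

The module also provides a labeled Gaussian feature-set generator used to
test feature selection and the imbalance-aware classifier in isolation.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage

from nodulecad.volume_io import CTVolume

# normalized-intensity palette
AIR = 0.05
PARENCHYMA = 0.15
TINY_VESSEL = 0.40
VESSEL = 0.65
WALL = 0.90

NODULE_TYPES = ("isolated", "juxta_pleural", "juxta_vascular_tree", "juxta_vascular_tiny")


class SpecError(ValueError):
    """Raised when a phantom spec is internally inconsistent."""


@dataclass
class NoduleSpec:
    """One nodule to implant.

    ``center`` is a physical (z, y, x) position in mm, or ``None`` to let the
    generator place the nodule automatically according to its ``type``
    (e.g. on a vessel branch for ``juxta_vascular_tree``).
    ``contrast`` is the intensity step above lung parenchyma, in normalized
    units.
    """

    type: str = "isolated"
    center: tuple[float, float, float] | None = None
    diameter_mm: float = 8.0
    contrast: float = 0.5

    def __post_init__(self) -> None:
        if self.type not in NODULE_TYPES:
            raise SpecError(f"unknown nodule type {self.type!r}; expected one of {NODULE_TYPES}")
        if not (3.0 <= self.diameter_mm <= 30.0):
            raise SpecError(f"nodule diameter must be in [3, 30] mm, got {self.diameter_mm}")


@dataclass
class PhantomSpec:
    shape: tuple[int, int, int] = (88, 120, 120)
    spacing: tuple[float, float, float] = (1.0, 1.0, 1.0)
    nodules: list[NoduleSpec] = field(default_factory=list)
    vessel_root_radius_mm: float = 3.0
    vessel_levels: int = 5
    vessel_root_length_mm: float = 16.0
    bifurcation_angle_deg: tuple[float, float] = (25.0, 50.0)
    tiny_vessel_count: int = 3
    noise_sd: float = 0.015
    blur_sigma_vox: float = 0.5
    seed: int = 0

    def __post_init__(self) -> None:
        if self.noise_sd < 0:
            raise SpecError("noise_sd must be >= 0")
        if self.vessel_levels < 1:
            raise SpecError("vessel_levels must be >= 1")


@dataclass
class PhantomTruth:
    """Ground truth emitted with each phantom.

    ``objects`` is a list of ``(type, center_mm, diameter_mm)``;
    ``lung_mask`` the true lung fields; ``vessel_mask`` the rasterized main
    trees; ``tiny_vessel_mask`` the disconnected peripheral tubes.
    """

    objects: list[tuple[str, tuple[float, float, float], float]]
    lung_mask: np.ndarray
    vessel_mask: np.ndarray
    tiny_vessel_mask: np.ndarray

    def to_table(self):
        import pandas as pd

        rows = [{"type": t, "cz": c[0], "cy": c[1], "cx": c[2], "diameter_mm": d}
                for t, c, d in self.objects]
        return pd.DataFrame(rows, columns=["type", "cz", "cy", "cx", "diameter_mm"])


# ---------------------------------------------------------------- geometry


def _ellipsoid_mask(shape, center, semi):
    zz, yy, xx = np.ogrid[: shape[0], : shape[1], : shape[2]]
    return ((zz - center[0]) / semi[0]) ** 2 + ((yy - center[1]) / semi[1]) ** 2 + (
        (xx - center[2]) / semi[2]
    ) ** 2 <= 1.0


def _paint_capsule(arr, p0, p1, radius, value):
    """Max-composite a capsule (tube with round caps) into *arr* (voxel coords)."""
    p0 = np.asarray(p0, float)
    p1 = np.asarray(p1, float)
    lo = np.floor(np.minimum(p0, p1) - radius - 1).astype(int)
    hi = np.ceil(np.maximum(p0, p1) + radius + 1).astype(int) + 1
    lo = np.maximum(lo, 0)
    hi = np.minimum(hi, arr.shape)
    if np.any(lo >= hi):
        return
    zz, yy, xx = np.meshgrid(*(np.arange(lo[i], hi[i]) for i in range(3)), indexing="ij")
    pts = np.stack([zz, yy, xx], axis=-1).astype(float)
    d = p1 - p0
    L2 = float(d @ d)
    if L2 < 1e-12:
        dist = np.linalg.norm(pts - p0, axis=-1)
    else:
        t = np.clip(((pts - p0) @ d) / L2, 0.0, 1.0)
        proj = p0 + t[..., None] * d
        dist = np.linalg.norm(pts - proj, axis=-1)
    sub = arr[lo[0]:hi[0], lo[1]:hi[1], lo[2]:hi[2]]
    np.maximum(sub, np.where(dist <= radius, value, 0.0), out=sub)


def _paint_ball(arr, center, radius, value):
    """Max-composite a ball with a 1-voxel antialiased edge centered at *radius*.

    The linear edge ramp puts the half-intensity isosurface exactly at the
    nominal radius, so implanted nodules voxelize to the analytic sphere
    volume instead of the ~5 %-inflated hard rasterization.
    """
    center = np.asarray(center, float)
    lo = np.maximum(np.floor(center - radius - 2).astype(int), 0)
    hi = np.minimum(np.ceil(center + radius + 2).astype(int) + 1, arr.shape)
    if np.any(lo >= hi):
        return
    zz, yy, xx = np.meshgrid(*(np.arange(lo[i], hi[i]) for i in range(3)), indexing="ij")
    dist = np.sqrt((zz - center[0]) ** 2 + (yy - center[1]) ** 2 + (xx - center[2]) ** 2)
    w = np.clip(radius + 0.5 - dist, 0.0, 1.0)
    sub = arr[lo[0]:hi[0], lo[1]:hi[1], lo[2]:hi[2]]
    np.maximum(sub, value * w, out=sub)


def _rotate_about(v, axis, angle):
    axis = axis / np.linalg.norm(axis)
    c, s = np.cos(angle), np.sin(angle)
    return v * c + np.cross(axis, v) * s + axis * (axis @ v) * (1 - c)


def _ellipsoid_rho(p, center, semi):
    return float(np.sqrt(np.sum(((np.asarray(p) - center) / semi) ** 2)))


# ---------------------------------------------------------------- vessel tree


def _grow_tree(rng, start, direction, length, radius, levels, lung_center, lung_semi,
               angle_range):
    """Recursive Y-bifurcating tube tree, kept inside the lung ellipsoid.

    Returns a list of (p0, p1, radius, level) segments in voxel coordinates.
    Consecutive segments share endpoints, so the rasterized tree is one
    26-connected component.
    """
    segments = []

    def step(p0, direction, length, radius, level):
        direction = direction / np.linalg.norm(direction)
        p1 = p0 + direction * length
        # steer back toward the lung center if the endpoint would leave the lung
        for _ in range(8):
            if _ellipsoid_rho(p1, lung_center, lung_semi) <= 0.92:
                break
            inward = lung_center - p0
            inward = inward / (np.linalg.norm(inward) + 1e-9)
            direction = direction * 0.6 + inward * 0.4
            direction /= np.linalg.norm(direction)
            p1 = p0 + direction * length
        else:
            p1 = p0 + direction * length * 0.4
        segments.append((p0.copy(), p1.copy(), radius, level))
        if level + 1 >= levels:
            return
        axis = rng.normal(size=3)
        axis -= (axis @ direction) * direction
        if np.linalg.norm(axis) < 1e-6:
            axis = np.array([1.0, 0.0, 0.0])
        half = np.deg2rad(rng.uniform(*angle_range))
        for sign in (+1.0, -1.0):
            child_dir = _rotate_about(direction, axis, sign * half)
            # taper ~ Murray's law (2^-1/3 per generation), floored so terminal
            # branches stay resolvable after partial-volume blur
            step(p1, child_dir, length * 0.78, max(radius * 0.79, 1.2), level + 1)

    step(np.asarray(start, float), np.asarray(direction, float), length, radius, 0)
    return segments


# ---------------------------------------------------------------- generator


def generate_phantom(spec: PhantomSpec) -> tuple[CTVolume, PhantomTruth]:
    """Render a phantom volume and its ground-truth record.

    Raises :class:`SpecError` if an explicitly positioned nodule falls
    outside the lung fields.
    """
    rng = np.random.default_rng(spec.seed)
    shape = tuple(spec.shape)
    sp = np.asarray(spec.spacing, float)
    nz, ny, nx = shape

    body_center = np.array([nz / 2, ny / 2, nx / 2])
    body_semi = np.array([nz / 2, ny * 0.43, nx * 0.48])
    body = _ellipsoid_mask(shape, body_center, body_semi)

    lung_semi = np.array([nz * 0.36, ny * 0.28, nx * 0.17])
    lung_centers = [
        body_center + np.array([0.0, 0.0, -nx * 0.22]),  # right lung (low x)
        body_center + np.array([0.0, 0.0, +nx * 0.22]),  # left lung
    ]
    lungs = np.zeros(shape, bool)
    for c in lung_centers:
        lungs |= _ellipsoid_mask(shape, c, lung_semi)

    base = np.full(shape, AIR)
    base[body] = WALL
    base[lungs] = PARENCHYMA

    # trachea: an enclosed air tube above the lungs, near the midline
    z_top = body_center[0] + body_semi[0]
    trach = np.zeros(shape)
    t0 = np.array([min(z_top - 5.0, nz - 2.0), ny / 2, nx / 2])
    t1 = np.array([body_center[0] + lung_semi[0] * 0.55, ny / 2, nx / 2])
    _paint_capsule(trach, t0, t1, 3.5, 1.0)
    base[trach > 0] = AIR

    # main vessel trees, one per lung
    struct = np.zeros(shape)
    all_segments = []
    for c in lung_centers:
        lateral = np.sign(c[2] - body_center[2]) or 1.0
        hilum = c + np.array([0.0, 0.0, -lateral * lung_semi[2] * 0.85])
        direction = np.array([0.15, 0.1, lateral])
        segs = _grow_tree(rng, hilum, direction, spec.vessel_root_length_mm / sp[2],
                          spec.vessel_root_radius_mm / sp[2], spec.vessel_levels,
                          c, lung_semi, spec.bifurcation_angle_deg)
        all_segments.append(segs)
        for p0, p1, r, _lvl in segs:
            _paint_capsule(struct, p0, p1, r, VESSEL)
    vessel_mask = struct > 0

    # tiny disconnected peripheral vessels with a small Y at the end
    tiny = np.zeros(shape)
    tree_clearance = ndimage.binary_dilation(vessel_mask, iterations=3)
    tiny_ends = []
    for k in range(spec.tiny_vessel_count):
        lung_idx = int(k % 2)
        c = lung_centers[lung_idx]
        for _attempt in range(40):
            u = rng.normal(size=3)
            u /= np.linalg.norm(u)
            rho = rng.uniform(0.55, 0.80)
            p0 = c + u * rho * lung_semi
            d = rng.normal(size=3)
            d /= np.linalg.norm(d)
            p1 = p0 + d * 8.0
            if _ellipsoid_rho(p1, c, lung_semi) > 0.9:
                continue
            box = tuple(slice(max(0, int(min(p0[i], p1[i])) - 4),
                              min(shape[i], int(max(p0[i], p1[i])) + 5)) for i in range(3))
            if tree_clearance[box].any():
                continue
            _paint_capsule(tiny, p0, p1, 1.1, TINY_VESSEL)
            axis = rng.normal(size=3)
            axis -= (axis @ d) * d
            axis /= np.linalg.norm(axis) + 1e-9
            for sign in (+1.0, -1.0):
                bd = _rotate_about(d, axis, sign * np.deg2rad(40.0))
                _paint_capsule(tiny, p1, p1 + bd * 4.0, 0.9, TINY_VESSEL)
            tiny_ends.append(p1)
            break
    tiny_mask = tiny > 0
    np.maximum(struct, tiny, out=struct)

    # nodules
    truth_objects = []
    for nod in spec.nodules:
        center_vox = _place_nodule(nod, rng, lung_centers, lung_semi, all_segments,
                                   tiny_ends, sp, lungs)
        radius_vox = nod.diameter_mm / 2.0 / sp[2]
        _paint_ball(struct, center_vox, radius_vox, PARENCHYMA + nod.contrast)
        center_mm = tuple(float(v) for v in center_vox * sp)
        truth_objects.append((nod.type, center_mm, float(nod.diameter_mm)))

    # partial-volume blur of the solid structures, then composite
    blurred = ndimage.gaussian_filter(struct, sigma=spec.blur_sigma_vox)
    out = np.maximum(base, blurred)

    if spec.noise_sd > 0:
        out = out + rng.normal(0.0, spec.noise_sd, size=shape)
    out = np.clip(out, 0.0, 1.0)

    vol = CTVolume(data=out, spacing=tuple(sp), normalized=True,
                   meta={"phantom_seed": spec.seed})
    truth = PhantomTruth(objects=truth_objects, lung_mask=lungs,
                         vessel_mask=vessel_mask, tiny_vessel_mask=tiny_mask)
    return vol, truth


def _place_nodule(nod, rng, lung_centers, lung_semi, all_segments, tiny_ends, sp, lungs):
    if nod.center is not None:
        center_vox = np.asarray(nod.center, float) / sp
        idx = tuple(np.round(center_vox).astype(int))
        if not (all(0 <= idx[i] < lungs.shape[i] for i in range(3)) and lungs[idx]):
            raise SpecError(f"nodule center {nod.center} mm lies outside the lung fields")
        return center_vox

    radius_vox = nod.diameter_mm / 2.0 / sp[2]
    if nod.type == "juxta_vascular_tree":
        segs = all_segments[int(rng.integers(len(all_segments)))]
        thick = [s for s in segs if s[3] <= 2] or segs
        p0, p1, _r, _lvl = thick[int(rng.integers(len(thick)))]
        t = rng.uniform(0.3, 0.8)
        return p0 + t * (p1 - p0)
    if nod.type == "juxta_vascular_tiny":
        if tiny_ends:
            return np.asarray(tiny_ends[int(rng.integers(len(tiny_ends)))], float)
        # fall through to isolated placement when no tiny vessels exist
    lung_idx = int(rng.integers(2))
    c = lung_centers[lung_idx]
    if nod.type == "juxta_pleural":
        for _ in range(50):
            u = rng.normal(size=3)
            u /= np.linalg.norm(u)
            r_u = 1.0 / np.sqrt(np.sum((u / lung_semi) ** 2))
            rho = 1.0 - 0.5 * radius_vox / r_u
            p = c + u * rho * lung_semi
            idx = tuple(np.round(p).astype(int))
            if all(2 <= idx[i] < lungs.shape[i] - 2 for i in range(3)) and lungs[idx]:
                return p
        raise SpecError("failed to place juxta-pleural nodule")
    # isolated (or fallback): clear of the lung border
    for _ in range(50):
        u = rng.normal(size=3)
        u /= np.linalg.norm(u)
        rho = rng.uniform(0.15, 0.55)
        p = c + u * rho * lung_semi
        if _ellipsoid_rho(p, c, lung_semi) + (radius_vox + 3) / np.min(lung_semi) < 0.95:
            return p
    raise SpecError("failed to place isolated nodule")


def random_phantom_spec(seed: int, *, n_isolated: int = 1, n_juxta_pleural: int = 1,
                        n_juxta_vascular_tree: int = 1, n_juxta_vascular_tiny: int = 1,
                        diameter_range: tuple[float, float] = (6.0, 12.0),
                        contrast: float = 0.5, **kwargs) -> PhantomSpec:
    """A randomized study phantom: auto-placed nodules of the four types."""
    rng = np.random.default_rng(seed)
    nodules = []
    for typ, n in (("isolated", n_isolated), ("juxta_pleural", n_juxta_pleural),
                   ("juxta_vascular_tree", n_juxta_vascular_tree),
                   ("juxta_vascular_tiny", n_juxta_vascular_tiny)):
        for _ in range(n):
            d = float(rng.uniform(*diameter_range))
            nodules.append(NoduleSpec(type=typ, center=None, diameter_mm=d, contrast=contrast))
    return PhantomSpec(nodules=nodules, seed=seed, **kwargs)


# ---------------------------------------------------------------- feature fixture


def generate_candidate_features(n_pos: int, n_neg: int, separation: float, seed: int,
                                n_informative: int = 5, n_noise: int = 15,
                                ) -> tuple[np.ndarray, np.ndarray]:
    """Two unit-variance Gaussian classes in ``n_informative + n_noise`` dims.

    The class means differ by *separation* in Euclidean norm, spread evenly
    over the first ``n_informative`` dimensions; the remaining dimensions are
    pure noise.  Used to test feature selection and the weighted SVM without
    any imaging.  Returns ``(X, y)`` with labels 1 (positive) / 0 (negative);
    rows are positives first.
    """
    if n_pos < 1 or n_neg < 1:
        raise ValueError("need at least one sample per class")
    if separation < 0:
        raise ValueError("separation must be >= 0")
    rng = np.random.default_rng(seed)
    p = n_informative + n_noise
    shift = np.zeros(p)
    if n_informative > 0:
        shift[:n_informative] = separation / np.sqrt(n_informative)
    X_pos = rng.normal(size=(n_pos, p)) + shift
    X_neg = rng.normal(size=(n_neg, p))
    X = np.vstack([X_pos, X_neg])
    y = np.concatenate([np.ones(n_pos, int), np.zeros(n_neg, int)])
    return X, y
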