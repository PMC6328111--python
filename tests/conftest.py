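import numpy as np
import pytest

from nodulecad.volume_io import CTVolume
from nodulecad.phantom_generator import random_phantom_spec, generate_phantom
from nodulecad.candidate_extraction import Candidate


@pytest.fixture(scope="session")
def phantom():
    """One randomized study phantom (all four nodule types) and its truth."""
    return generate_phantom(random_phantom_spec(1))


@pytest.fixture(scope="session")
def segmented(phantom):
    from nodulecad.lung_segmentation import segment_lungs

    vol, truth = phantom
    return segment_lungs(vol)


def make_candidate(mask, spacing=(1.0, 1.0, 1.0), group="non_vessel_tree", cid=1):
    vox = np.argwhere(mask)
    return Candidate(id=cid, voxels=vox, group=group,
                     volume_mm3=len(vox) * float(np.prod(spacing)),
                     centroid_mm=tuple(vox.mean(axis=0) * np.asarray(spacing)),
                     shape=mask.shape, spacing=tuple(spacing))


def ball_mask(shape, center, radius):
    grids = np.ogrid[tuple(slice(0, s) for s in shape)]
    r2 = sum((g - c) ** 2 for g, c in zip(grids, center))
    return r2 <= radius ** 2


def make_volume(data, **kw):
    return CTVolume(np.asarray(data, float), **kw)
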