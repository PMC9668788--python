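import numpy as np
import pytest

from psmapet import BinaryMask, LabelledMask, PhantomConfig, VolumeGrid

STUDY_SPACING = (4.07, 4.07, 2.0)


def make_grid(values, spacing=(1.0, 1.0, 1.0), origin=(0.0, 0.0, 0.0)) -> VolumeGrid:
    return VolumeGrid(np.asarray(values, dtype=float), spacing, origin)


def make_binary(membership, spacing=(1.0, 1.0, 1.0)) -> BinaryMask:
    membership = np.asarray(membership, dtype=bool)
    return BinaryMask(make_grid(np.zeros(membership.shape), spacing), membership)


def make_labelled(labels, sites=None, spacing=(1.0, 1.0, 1.0)) -> LabelledMask:
    labels = np.asarray(labels)
    grid = make_grid(np.zeros(labels.shape), spacing)
    if sites is None:
        sites = {int(v): "distant_nodal" for v in np.unique(labels) if v}
    return LabelledMask(grid, labels, sites)


@pytest.fixture(scope="session")
def small_phantom_config() -> PhantomConfig:
    """Reduced-grid phantom (same spacing/uptake model) for fast cohort tests."""
    return PhantomConfig(shape=(48, 48, 96))


@pytest.fixture(scope="session")
def tiny_phantom_config() -> PhantomConfig:
    return PhantomConfig(shape=(40, 40, 64), lesion_radius_mm=(4.0, 12.0))
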