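"""Shared fixtures: synthetic slices/stacks generated once per session."""

import numpy as np
import pytest

from trabmri import TrabecularParams, generate_slice
from trabmri.segment import BinaryTrabecularMap, EndostealMask


@pytest.fixture(scope="session")
def default_params():
    return TrabecularParams(seed=1)


@pytest.fixture(scope="session")
def default_slice(default_params):
    """(grey, truth) for the default acquisition emulation."""
    return generate_slice(default_params)


@pytest.fixture(scope="session")
def clean_params():
    """Noise- and blur-free acquisition: binarization is exactly separable."""
    return TrabecularParams(seed=2, noise_sd=0.0, psf_fwhm=0.0)


@pytest.fixture(scope="session")
def clean_slice(clean_params):
    return generate_slice(clean_params)


def make_binary(bone: np.ndarray, voxel: float = 0.195,
                mask: np.ndarray | None = None) -> BinaryTrabecularMap:
    """Wrap a raw boolean bone map as a BinaryTrabecularMap for tests."""
    bone = np.asarray(bone, dtype=bool)
    if mask is None:
        mask = np.ones_like(bone)
    m = EndostealMask(mask=np.asarray(mask, bool), voxel_inplane=voxel)
    return BinaryTrabecularMap(bone=bone & m.mask, mask=m, threshold=0.5)
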