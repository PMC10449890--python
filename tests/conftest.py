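"""Shared fixtures: spectral calibration, source, and a segmented phantom
stack reused across segmentation/rendering tests (session-scoped because
rendering and segmenting the stack is the expensive part)."""

import numpy as np
import pytest

from limbusoct.phantom import (
    DEFAULT_WAVELENGTH_RANGE,
    LimbusPhantom,
    SourceSpectrumModel,
    build_source_spectrum,
    render_bscan_stack,
)
from limbusoct.recon import BackgroundSpectrum, KMap
from limbusoct.segment import propagate_stack, segment_first_frame

N_PIXELS = 2048


@pytest.fixture(scope="session")
def wavelength_grid():
    return np.linspace(*DEFAULT_WAVELENGTH_RANGE, N_PIXELS)


@pytest.fixture(scope="session")
def source_spectrum(wavelength_grid):
    return build_source_spectrum(SourceSpectrumModel(), wavelength_grid)


@pytest.fixture(scope="session")
def background(source_spectrum):
    return BackgroundSpectrum(source_spectrum)


@pytest.fixture(scope="session")
def kmap(wavelength_grid):
    return KMap(wavelength_grid)


@pytest.fixture(scope="session")
def uniform_k_grid():
    """Debug wavelength grid whose samples are uniform in k."""
    k = np.linspace(2 * np.pi / DEFAULT_WAVELENGTH_RANGE[1],
                    2 * np.pi / DEFAULT_WAVELENGTH_RANGE[0], N_PIXELS)
    return (2 * np.pi / k)[::-1]


@pytest.fixture(scope="session")
def phantom16():
    return LimbusPhantom(n_frames=16)


@pytest.fixture(scope="session")
def phantom_stack(phantom16):
    """16-frame rendered phantom stack with its ground truth."""
    return render_bscan_stack(phantom16, seed=1)


@pytest.fixture(scope="session")
def stack_boundaries(phantom_stack):
    """Propagated surface boundaries for the session phantom stack."""
    stack, gt = phantom_stack
    cols = np.linspace(0, stack.shape[2] - 1, 5).round().astype(int)
    seeds = np.column_stack([cols, gt.surface_rows[0][cols]]).astype(float)
    first = segment_first_frame(stack[0], seeds)
    return propagate_stack(stack, first)
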