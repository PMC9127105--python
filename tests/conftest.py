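import numpy as np
import pytest

from fsesim.acquisition import SequenceParams
from fsesim.anatomy import (LABEL_ID, LabelVolume, RelaxationProperties,
                            TissueClass, generate_synthetic_phantom)


@pytest.fixture(scope="session")
def small_phantom() -> LabelVolume:
    """Brain-like phantom on a coarse 32x32x20 grid (fast pipeline runs)."""
    return generate_synthetic_phantom(size_mm=(64.0, 64.0, 40.0), spacing=2.0, seed=1)


@pytest.fixture(scope="session")
def slab_phantom() -> LabelVolume:
    """Two adjacent tissue slabs (GM | WM) with sharp interior plateaus.

    Symmetric in-plane, so every slice mask has the same centroid: the
    static motion index is exactly zero and region means are easy to read.
    """
    lab = np.zeros((64, 64, 20), np.int32)
    lab[8:56, 8:32, 2:18] = LABEL_ID["Cortical plate"]       # gray matter
    lab[8:56, 32:56, 2:18] = LABEL_ID["Intermediate zone"]   # white matter
    return LabelVolume(lab, spacing=(2.0, 2.0, 2.0))


@pytest.fixture(scope="session")
def toy_props() -> RelaxationProperties:
    """User-supplied toy relaxation values (tests never rely on defaults)."""
    return RelaxationProperties(
        field_strength_T=1.5,
        t1_ms={TissueClass.GRAY_MATTER: 2000.0,
               TissueClass.WHITE_MATTER: 3000.0,
               TissueClass.CSF: 4000.0},
        t2_ms={TissueClass.GRAY_MATTER: 100.0,
               TissueClass.WHITE_MATTER: 200.0,
               TissueClass.CSF: 1000.0},
    )


def make_toy_seq(**overrides) -> SequenceParams:
    """Small, fast sequence with full-Fourier sampling by default."""
    params = dict(
        name="toy", effective_te_ms=80.0, echo_spacing_ms=5.0,
        echo_train_length=64, tr_ms=1000.0, n_slices=8,
        slice_thickness_mm=3.0, slice_gap_mm=0.0,
        fov_mm=160.0, base_resolution=64,
        phase_resolution=1.0, phase_oversampling=0.0,
        noise_sd=0.0,
    )
    params.update(overrides)
    return SequenceParams(**params)


@pytest.fixture
def toy_seq() -> SequenceParams:
    return make_toy_seq()
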