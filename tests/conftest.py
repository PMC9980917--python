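import numpy as np
import pytest
from hypothesis import settings

from stromascope.quantify import quantify_core
from stromascope.register import register_rounds
from stromascope.segment import SegmentationParams, segment_core
from stromascope.synthcore import CoreSpec, generate_core

settings.register_profile("ci", deadline=None, derandomize=True, max_examples=30)
settings.load_profile("ci")

SIZE = 256


@pytest.fixture(scope="session")
def params_small():
    return SegmentationParams.for_image_size(SIZE)


@pytest.fixture(scope="session")
def mri_pos_core():
    """One MRI-positive core at 256 px with a known inter-round shift."""
    spec = CoreSpec.for_class("mri_pos", seed=3, size=SIZE, round2_shift=(5.0, -3.0))
    r1, r2, truth = generate_core(spec)
    return spec, r1, r2, truth


@pytest.fixture(scope="session")
def segmented_core(mri_pos_core, params_small):
    """Registered + segmented + quantified version of the shared core."""
    spec, r1, r2, truth = mri_pos_core
    aligned, reg = register_rounds(r1, r2)
    masks, low = segment_core(r1, aligned, params_small)
    quant = quantify_core(
        masks, pixel_size_um=spec.pixel_size_um, core_id=spec.core_id,
        lesion_class=spec.lesion_class, registration_ok=reg.ok,
    )
    return masks, quant, reg, low


def segment_one(lesion_class: str, seed: int, size: int = SIZE,
                shift=(5.0, -3.0), **overrides):
    """Helper: full generate/register/segment/quantify round trip."""
    spec = CoreSpec.for_class(lesion_class, seed=seed, size=size,
                              round2_shift=shift, **overrides)
    r1, r2, truth = generate_core(spec)
    aligned, reg = register_rounds(r1, r2)
    params = SegmentationParams.for_image_size(size)
    masks, low = segment_core(r1, aligned, params)
    quant = quantify_core(
        masks, pixel_size_um=spec.pixel_size_um, core_id=spec.core_id,
        lesion_class=spec.lesion_class, registration_ok=reg.ok,
    )
    return spec, truth, masks, quant, reg
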