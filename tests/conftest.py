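import numpy as np
import pytest

from renalmorph import (
    BinarySectionImage,
    CohortSpec,
    KidneyShapeParams,
    make_kidney_mask,
)

# fairly coarse grid: fast, and all tolerances are stated in pixel units
PIXEL_SIZE = 0.05


@pytest.fixture(scope="session")
def ellipse_image() -> BinarySectionImage:
    """Rasterized ideal ellipse, a=12 mm, b=7 mm, no notch, no noise."""
    return make_kidney_mask(
        KidneyShapeParams(a=12, b=7, notch_depth=0, pixel_size=PIXEL_SIZE)
    )


@pytest.fixture(scope="session")
def notched_image() -> BinarySectionImage:
    """Notched ellipse: a=12, b=7, pelvic notch 2 mm deep at the midline."""
    return make_kidney_mask(
        KidneyShapeParams(a=12, b=7, notch_depth=2, notch_width=1.5, pixel_size=PIXEL_SIZE)
    )


@pytest.fixture(scope="session")
def noise_free_spec() -> CohortSpec:
    return CohortSpec(seed=11, collagen_noise_sd=0.0)


def rect_image(h: int = 30, w: int = 70, ps: float = 0.1) -> BinarySectionImage:
    mask = np.zeros((h + 10, w + 10), dtype=bool)
    mask[5 : 5 + h, 5 : 5 + w] = True
    return BinarySectionImage(mask=mask, pixel_size=ps)
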