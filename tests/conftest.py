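import numpy as np
import pandas as pd
import pytest

from ifcgate.features import EventImage, Mask
from ifcgate.synthetic_data import MixtureSpec, ShapeSpec


@pytest.fixture
def tiny_table() -> pd.DataFrame:
    return pd.DataFrame(
        {
            "event_id": [0, 1, 2],
            "rsg_intensity": [1500.0, 4.0, 900.0],
            "pi_intensity": [5.0, 2000.0, 310.0],
        }
    )


@pytest.fixture
def shape_spec() -> ShapeSpec:
    return ShapeSpec()


@pytest.fixture
def balanced_spec() -> MixtureSpec:
    return MixtureSpec()  # four subpopulations at 0.25 each


def disk_image(radius: int = 10, size: int = 48, high: float = 200.0) -> EventImage:
    """Bright disk on dark background, single channel ``x``."""
    rr, cc = np.mgrid[0:size, 0:size]
    disk = (rr - size / 2) ** 2 + (cc - size / 2) ** 2 <= radius**2
    img = np.where(disk, high, 10.0)
    return EventImage(channels={"x": img}, pixel_size_um=1.0)


def full_mask(shape: tuple[int, int]) -> Mask:
    return Mask(np.ones(shape, dtype=bool))
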