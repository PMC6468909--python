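import numpy as np
import pytest

from pross.config import ThresholdConfig
from pross.intervals import IntervalSet
from pross.records_io import FeatureAnnotation, FeatureType


@pytest.fixture
def config() -> ThresholdConfig:
    return ThresholdConfig()


@pytest.fixture
def rng() -> np.random.Generator:
    return np.random.default_rng(20240521)


def make_feature(
    fid: str = "F001",
    ftype: FeatureType = FeatureType.region_of_interest,
    description: str = "Interaction with X",
    spans=((10, 20),),
) -> FeatureAnnotation:
    return FeatureAnnotation(fid, ftype, description, IntervalSet(spans))


def random_intervals(rng: np.random.Generator, length: int, max_n: int = 5):
    """Random (possibly overlapping) interval list within 1..length."""
    n = int(rng.integers(0, max_n + 1))
    out = []
    for _ in range(n):
        start = int(rng.integers(1, length + 1))
        end = int(rng.integers(start, min(length, start + int(rng.integers(1, 30))) + 1))
        out.append((start, end))
    return out
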