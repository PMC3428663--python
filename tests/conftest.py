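import numpy as np
import pytest

from doee import PixelGeometry, RaterMaskPair
from doee.region_partition import ConnectedRegion


@pytest.fixture
def unit_geom():
    return PixelGeometry(1.0, 1.0)


def make_pair(r1, r2, geom=None, scan_id="test"):
    """Build a RaterMaskPair from array-likes (2D accepted)."""
    geom = geom or PixelGeometry(1.0, 1.0)
    return RaterMaskPair(np.asarray(r1, bool), np.asarray(r2, bool), geom, scan_id)


def random_pair(rng, shape=(24, 24), density=0.2, scan_id="rand"):
    """Random blobby mask pair: thresholded smoothed noise, correlated raters."""
    from scipy.ndimage import gaussian_filter

    base = gaussian_filter(rng.normal(size=shape), 2.0)
    thr = np.quantile(base, 1 - density)
    r1 = base > thr
    r2 = gaussian_filter(base + 0.3 * rng.normal(size=shape), 2.0) > thr
    return make_pair(r1, r2, scan_id=scan_id)


def region(label, area_r1, area_r2, area_intersection, scan_id="s", sl=0):
    """ConnectedRegion from per-rater areas via inclusion-exclusion."""
    return ConnectedRegion(
        scan_id=scan_id,
        slice_index=sl,
        label=label,
        area_union=area_r1 + area_r2 - area_intersection,
        area_r1=area_r1,
        area_r2=area_r2,
        area_intersection=area_intersection,
    )


@pytest.fixture
def worked_example_regions():
    """Region records for the worked example: eight lesion pairs,
    matched pairs nested (intersection = smaller area), two single-rater."""
    pairs = [
        (106.7, 131.8),
        (58.0, 58.0),
        (32.1, 32.1),
        (27.7, 27.7),
        (174.7, 224.0),
        (507.9, 574.6),
    ]
    regions = [region("CR12", a, b, min(a, b)) for a, b in pairs]
    regions.append(region("CR1", 10.6, 0.0, 0.0))
    regions.append(region("CR1", 28.9, 0.0, 0.0))
    return regions
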