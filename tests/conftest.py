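import numpy as np
import pytest
from scipy.spatial import cKDTree

from retinaquant.cellmap import CellMap
from retinaquant.geometry import RetinaGeometry


@pytest.fixture(scope="session")
def geom():
    return RetinaGeometry()


def uniform_disc_cells(n, radius_mm=2.2, seed=0, **kw):
    """Exactly-n uniform points on the disc (not Poisson) for oracle tests."""
    rng = np.random.default_rng(seed)
    r = radius_mm * np.sqrt(rng.random(n))
    t = 2 * np.pi * rng.random(n)
    return CellMap(x=r * np.cos(t), y=r * np.sin(t), **kw)


def match_detections(detected_xy, truth_xy, radius):
    """Greedy one-to-one nearest matching; returns number of true positives."""
    if len(detected_xy) == 0 or len(truth_xy) == 0:
        return 0
    tree = cKDTree(truth_xy)
    d, idx = tree.query(detected_xy, k=1, distance_upper_bound=radius)
    matched = set()
    tp = 0
    for dist, i in sorted(zip(d, idx)):
        if np.isfinite(dist) and i not in matched:
            matched.add(i)
            tp += 1
    return tp
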