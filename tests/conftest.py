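import numpy as np
import pytest

from vfprog.deviations import P_NONE, VFTest, synthetic_normative_model
from vfprog.deviations import VFSeries
from vfprog.grid import build_grid
from vfprog.synth import SyntheticCohortConfig, simulate_cohort


@pytest.fixture(scope="session")
def grid_od():
    return build_grid("OD")


@pytest.fixture(scope="session")
def grid_os():
    return build_grid("OS")


@pytest.fixture(scope="session")
def norm():
    return synthetic_normative_model()


@pytest.fixture(scope="session")
def small_cohort(norm):
    # enriched progression fraction so detection paths (including the
    # stricter criterion) are exercised at this small scale
    cfg = SyntheticCohortConfig(n_subjects=50, seed=20250925,
                                progression_fraction=0.35)
    return simulate_cohort(cfg, norm=norm)


def xy_index(grid):
    """(x, y) -> location index lookup for a grid."""
    return {(p.x, p.y): p.index for p in grid.locations}


def levels_from(entries, grid=None, default=P_NONE):
    """Build a 52-vector of probability levels from {(x, y): level} or
    {index: level} entries."""
    lv = np.full(52, default)
    lookup = xy_index(grid) if grid is not None else None
    for key, p in entries.items():
        idx = lookup[key] if isinstance(key, tuple) else key
        lv[idx] = p
    return lv


def series_from_levels(level_maps, days=None, reliable=None,
                       test_type="SAP", eye_id="E1", subject_id="S1"):
    """A VFSeries of stub exams carrying only probability levels."""
    n = len(level_maps)
    days = list(range(0, 300 * n, 300)) if days is None else days
    reliable = [True] * n if reliable is None else reliable
    tests = []
    for lv, day, rel in zip(level_maps, days, reliable):
        t = VFTest(
            subject_id=subject_id, eye_id=eye_id, eye_side="OD", day=day,
            test_type=test_type, sens=np.zeros(52),
            fl=0.0 if rel else 0.5, fp=0.0, fn=0.0,
        )
        t.levels = np.asarray(lv, dtype=float)
        t.psd = 0.0
        tests.append(t)
    return VFSeries(subject_id=subject_id, eye_id=eye_id, eye_side="OD",
                    test_type=test_type, tests=tests)
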