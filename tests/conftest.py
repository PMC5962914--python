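"""Shared fixtures: small analytic phantoms and fast cohort parameters."""

import numpy as np
import pytest
from hypothesis import settings

from svdnet.cohortsim import CohortParams, MeasureParams

settings.register_profile("deterministic", derandomize=True, deadline=None)
settings.load_profile("deterministic")
from svdnet.phantom import StraightCenterline, TractSpec, make_tensor_phantom

# tube geometry chosen so that no voxel center outside the nominal tube ends
# falls inside the end-cap spheres: the axial gap from each tube end to the
# first outside voxel center (1.35 mm) exceeds sqrt(r^2 - 1.77^2) for r = 2.2
TUBE_START_X = 10.1
TUBE_END_X = 69.9
TUBE_RADIUS = 2.2
TUBE_AXIS_Y = 15.0
TUBE_AXIS_Z = 15.0
TUBE_EIGS = (1.7e-3, 0.2e-3)
BACKGROUND_D = 0.8e-3


def make_straight_tube(start_x=TUBE_START_X, end_x=TUBE_END_X,
                       radius=TUBE_RADIUS, shape=(32, 12, 12)):
    cl = StraightCenterline([start_x, TUBE_AXIS_Y, TUBE_AXIS_Z],
                            [end_x, TUBE_AXIS_Y, TUBE_AXIS_Z])
    tract = TractSpec(cl, radius, *TUBE_EIGS, endpoint_region_ids=(1, 2))
    return make_tensor_phantom([tract], shape=shape, voxel_size_mm=2.5,
                               background_diffusivity=BACKGROUND_D)


@pytest.fixture(scope="session")
def straight_tube():
    return make_straight_tube()


@pytest.fixture(scope="session")
def tube_volume(straight_tube):
    return straight_tube[0]


@pytest.fixture(scope="session")
def tube_parcellation(straight_tube):
    return straight_tube[1]


def fast_cohort_params(**overrides) -> CohortParams:
    """Cohort params restricted to the two driver measures (fast to simulate)."""
    measures = {
        "global_efficiency": MeasureParams(7.94, 2.30, -0.1764, 0.09, 0.1,
                                           intercept_slope_corr=0.3),
        "global_cognition": MeasureParams(0.0, 0.7, -0.027, 0.035, 0.1,
                                          intercept_slope_corr=0.2,
                                          efficiency_slope_corr=0.55),
    }
    kwargs = dict(measures=measures)
    kwargs.update(overrides)
    return CohortParams(**kwargs)


def noise_free_params(**overrides) -> CohortParams:
    measures = {
        "global_efficiency": MeasureParams(7.94, 2.30, -0.18, 0.1, 0.0),
        "global_cognition": MeasureParams(0.0, 0.7, -0.027, 0.02, 0.0,
                                          efficiency_slope_corr=0.5),
    }
    kwargs = dict(measures=measures, dropout_hazard_per_year=0.0)
    kwargs.update(overrides)
    return CohortParams(**kwargs)


# ---------------------------------------------------------------------------
# independent oracles (used by several test modules)
# ---------------------------------------------------------------------------

def fa_direct(eigenvalues) -> float:
    """FA from eigenvalues by the direct formula (independent of the package)."""
    lam = np.asarray(eigenvalues, dtype=float)
    lbar = lam.mean()
    return float(np.sqrt(1.5) * np.sqrt(((lam - lbar) ** 2).sum())
                 / np.sqrt((lam ** 2).sum()))


def floyd_warshall_efficiency(weights: np.ndarray) -> float:
    """Brute-force weighted global efficiency (triple-loop Floyd-Warshall)."""
    w = np.asarray(weights, dtype=float)
    n = w.shape[0]
    d = np.full((n, n), np.inf)
    np.fill_diagonal(d, 0.0)
    for i in range(n):
        for j in range(n):
            if i != j and w[i, j] > 0:
                d[i, j] = 1.0 / w[i, j]
    for k in range(n):
        for i in range(n):
            for j in range(n):
                if d[i, k] + d[k, j] < d[i, j]:
                    d[i, j] = d[i, k] + d[k, j]
    total = 0.0
    for i in range(n):
        for j in range(n):
            if i != j and np.isfinite(d[i, j]):
                total += 1.0 / d[i, j]
    return total / (n * (n - 1))


def floyd_warshall_local_efficiency_mean(weights: np.ndarray) -> float:
    w = np.asarray(weights, dtype=float)
    n = w.shape[0]
    vals = []
    for i in range(n):
        nb = [j for j in range(n) if w[i, j] > 0]
        if len(nb) < 2:
            vals.append(0.0)
        else:
            vals.append(floyd_warshall_efficiency(w[np.ix_(nb, nb)]))
    return float(np.mean(vals))
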