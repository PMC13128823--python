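import numpy as np
import pandas as pd
import pytest

import gridocc as g


def toy_frames():
    """Three grids, nested subunits, a removal-consistent survey table."""
    grids = pd.DataFrame(
        {
            "grid_id": ["G1", "G2", "G3"],
            "state": ["IL", "MN", "WI"],
            "n_occupied_neighbors": [2, 5, 7],
            "developed_prop": [0.10, 0.35, 0.60],
        }
    )
    subunits = pd.DataFrame(
        {
            "subunit_id": ["G1-a", "G1-b", "G2-a", "G3-a"],
            "grid_id": ["G1", "G1", "G2", "G3"],
            "kind": ["patch", "roadside", "patch", "patch"],
            "developed_prop_500m": [0.05, 0.40, 0.25, 0.80],
        }
    )
    surveys = pd.DataFrame(
        [
            # G1: detection at visit 1 (k=2) -> visits 2-3 censored
            ("G1", "G1-a", 1, 1, 190, 0, True),
            ("G1", "G1-a", 2, 1, 190, 1, True),
            ("G1", "G1-b", 1, 1, 191, 0, True),
            ("G1", "G1-b", 2, 1, 191, 0, True),
            # G2: no detections, full six surveys
            *[("G2", "G2-a", k, (k + 1) // 2, 195 + 12 * ((k - 1) // 2), 0, True)
              for k in range(1, 7)],
            # G3: detection at visit 2
            ("G3", "G3-a", 1, 1, 200, 0, True),
            ("G3", "G3-a", 2, 1, 200, 0, True),
            ("G3", "G3-a", 3, 2, 213, 1, True),
            ("G3", "G3-a", 4, 2, 213, 0, True),
        ],
        columns=[
            "grid_id", "subunit_id", "k", "visit",
            "day_of_year", "detection", "conducted",
        ],
    )
    return grids, subunits, surveys


@pytest.fixture
def toy_dataset():
    grids, subunits, surveys = toy_frames()
    return g.Dataset.from_frames(grids, subunits, surveys)


@pytest.fixture(scope="session")
def sim_small():
    """30-grid simulated study with the default generating coefficients."""
    design = g.SimDesign(n_grids={"IL": 10, "MN": 10, "WI": 10})
    return g.simulate_study(design, seed=11)


@pytest.fixture(scope="session")
def fitted_small(sim_small):
    """Quick reduced-length fit reused by posterior property tests."""
    dataset, _ = sim_small
    config = g.FitConfig(n_iter=2_000, n_burnin=500, n_retained=4_500, seed=7)
    return g.fit(dataset, config)


def enumerate_grid_loglik(y, subunit_index, psi_i, theta_j, p_k):
    """Brute-force oracle: sum the joint probability over all latent (z, a).

    Independent of the analytic marginalization: enumerates z in {0,1} and
    every a-configuration over the subunits, multiplying plain Bernoulli
    probabilities.
    """
    y = np.asarray(y, float)
    sub = np.asarray(subunit_index, int)
    theta_j = np.atleast_1d(np.asarray(theta_j, float))
    p_k = np.broadcast_to(np.asarray(p_k, float), y.shape)
    J = len(theta_j)
    total = 0.0
    for z in (0, 1):
        pz = psi_i if z == 1 else 1.0 - psi_i
        for mask in range(2**J):
            a = [(mask >> j) & 1 for j in range(J)]
            pa = 1.0
            for j in range(J):
                cond = theta_j[j] if z == 1 else 0.0
                pa *= cond if a[j] == 1 else 1.0 - cond
            py = 1.0
            for i in range(len(y)):
                prob1 = p_k[i] if a[sub[i]] == 1 else 0.0
                py *= prob1 if y[i] == 1 else 1.0 - prob1
            total += pz * pa * py
    return np.log(total) if total > 0 else -np.inf


def random_instance(rng, max_sub=3, max_surv=3):
    """Random small likelihood instance for the enumeration oracle."""
    J = rng.integers(1, max_sub + 1)
    counts = rng.integers(0, max_surv + 1, size=J)
    sub_idx = np.repeat(np.arange(J), counts)
    K = len(sub_idx)
    psi_i = rng.uniform(0.02, 0.98)
    theta_j = rng.uniform(0.02, 0.98, size=J)
    p_k = rng.uniform(0.02, 0.98, size=K)
    y = (rng.random(K) < 0.4).astype(float)
    return y, sub_idx, psi_i, theta_j, p_k
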