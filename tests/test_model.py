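import numpy as np
import pytest
from scipy.special import expit, logit

import gridocc as g
from gridocc.data import ValidationError
from gridocc.model import (
    build_design,
    grid_marginal_loglik,
    loglik_from_vector,
    p,
    psi,
    reexpress_params,
    theta,
)

from conftest import enumerate_grid_loglik, random_instance


def make_params(**kw):
    defaults = dict(
        state_levels=("IL", "MN", "WI"),
        psi_state_intercepts=np.zeros(3),
    )
    defaults.update(kw)
    return g.ModelParams(**defaults)


class TestProbabilityFunctions:
    def test_all_zero_coefficients_give_half(self):
        params = make_params()
        assert psi(params, "IL") == pytest.approx(0.5)
        assert theta(params) == pytest.approx(0.5)
        assert p(params, first_visit=0) == pytest.approx(0.5)

    def test_theta_intercept_back_transform(self):
        params = make_params(theta_intercept=float(logit(0.58)))
        assert theta(params, developed_500m_std=0.7) == pytest.approx(0.58)

    def test_psi_monotone_in_neighbors(self):
        lo = psi(make_params(beta_neighbors=0.3), "WI", neighbors_std=1.0)
        hi = psi(make_params(beta_neighbors=0.9), "WI", neighbors_std=1.0)
        assert hi > lo

    @pytest.mark.parametrize(
        "psi_v, theta_v, expected",
        [(1.0, 0.58, 0.58), (0.0, 0.58, 0.0), (0.75, 0.58, 0.435)],
    )
    def test_small_scale_occupancy(self, psi_v, theta_v, expected):
        params = make_params(
            psi_state_intercepts=np.full(3, 25.0 if psi_v == 1.0 else (-25.0 if psi_v == 0.0 else float(logit(psi_v)))),
            theta_intercept=float(logit(theta_v)),
        )
        got = g.small_scale_occupancy(params, "MN")
        assert got == pytest.approx(expected, abs=1e-6)


class TestBuildDesign:
    def test_first_visit_indicator(self, toy_dataset):
        dm = build_design(toy_dataset)
        k = toy_dataset.surveys["k"].to_numpy()
        np.testing.assert_array_equal(dm.X_p[:, 1], (k <= 2).astype(float))

    def test_doy_standardized_and_squared(self, toy_dataset):
        dm = build_design(toy_dataset)
        doy = toy_dataset.surveys["day_of_year"].to_numpy(float)
        st = dm.standardizers["day_of_year"]
        z = st.transform(doy)
        np.testing.assert_allclose(dm.X_p[:, 2], z, atol=1e-12)
        np.testing.assert_allclose(dm.X_p[:, 3], z**2, atol=1e-12)
        # a survey exactly at the sample-mean day gets standardized doy 0
        assert st.transform(st.mean) == pytest.approx(0.0)

    def test_state_onehots_and_standardization(self, toy_dataset):
        dm = build_design(toy_dataset)
        assert dm.X_psi.shape == (3, 5)
        np.testing.assert_array_equal(dm.X_psi[:, :3], np.eye(3))
        assert abs(dm.X_psi[:, 3].mean()) < 1e-10
        assert dm.X_psi[:, 3].std(ddof=1) == pytest.approx(1.0)

    def test_deterministic(self, toy_dataset):
        a = build_design(toy_dataset)
        b = build_design(toy_dataset.copy())
        np.testing.assert_array_equal(a.X_p, b.X_p)
        np.testing.assert_array_equal(a.X_psi, b.X_psi)

    def test_constant_covariate_error(self, toy_dataset):
        ds = toy_dataset.copy()
        ds.grids["n_occupied_neighbors"] = 4
        with pytest.raises(ValidationError, match="constant"):
            build_design(ds)


class TestGridMarginalLoglik:
    def test_certain_detection(self):
        ll = grid_marginal_loglik([1], [0], 1.0, [1.0], [1.0])
        assert ll == pytest.approx(0.0)

    def test_certain_miss_traces_to_psi(self):
        # with theta=p=1 only z=0 can explain a miss
        ll = grid_marginal_loglik([0], [0], 0.5, [1.0], [1.0])
        assert ll == pytest.approx(np.log(0.5))

    def test_empty_history_is_zero(self):
        assert grid_marginal_loglik([], [], 0.37, [], []) == pytest.approx(0.0)

    def test_unsurveyed_subunit_contributes_factor_one(self):
        base = grid_marginal_loglik([1, 0], [0, 0], 0.6, [0.5], [0.4, 0.4])
        extra = grid_marginal_loglik(
            [1, 0], [0, 0], 0.6, [0.5, 0.7], [0.4, 0.4], n_subunits=2
        )
        assert extra == pytest.approx(base, abs=1e-12)

    def test_detection_zeroes_unoccupied_branch(self):
        # a detection forbids z=0: likelihood = psi * (conditional part)
        ll_det = grid_marginal_loglik([1], [0], 0.01, [0.9], [0.8])
        assert ll_det == pytest.approx(np.log(0.01 * 0.9 * 0.8))

    def test_matches_enumeration_oracle(self):
        rng = np.random.default_rng(202)
        for _ in range(300):
            inst = random_instance(rng)
            got = grid_marginal_loglik(*inst)
            want = enumerate_grid_loglik(*inst)
            assert got == pytest.approx(want, abs=1e-10)

    def test_invalid_detection_value(self):
        with pytest.raises(ValidationError):
            grid_marginal_loglik([2], [0], 0.5, [0.5], [0.5])


class TestTotalLoglik:
    def test_additive_over_grids(self, sim_small):
        dataset, truth = sim_small
        dm = build_design(dataset)
        params = truth.params
        vec_total = loglik_from_vector(dm, params.to_vector())

        # independent route: per-grid marginal with explicit probabilities
        from gridocc.model import p_probs, psi_probs, theta_probs

        psi_i = psi_probs(dm, params)
        theta_j = theta_probs(dm, params)
        p_k = p_probs(dm, params)
        total = 0.0
        for i in range(dm.n_grids):
            subs = np.flatnonzero(dm.sub_grid == i)
            mask = np.isin(dm.surv_sub, subs)
            remap = {s: j for j, s in enumerate(subs)}
            sub_idx = np.array([remap[s] for s in dm.surv_sub[mask]], dtype=int)
            total += grid_marginal_loglik(
                dm.y[mask], sub_idx, psi_i[i], theta_j[subs], p_k[mask]
            )
        assert vec_total == pytest.approx(total, abs=1e-8)

    def test_invariant_to_row_order(self, sim_small):
        dataset, truth = sim_small
        dm = build_design(dataset)
        base = g.total_loglik(dm, truth.params)

        shuffled = dataset.copy()
        rng = np.random.default_rng(3)
        shuffled.surveys = shuffled.surveys.sample(
            frac=1.0, random_state=5
        ).reset_index(drop=True)
        order = rng.permutation(len(shuffled.subunits))
        shuffled.subunits = shuffled.subunits.iloc[order].reset_index(drop=True)
        dm2 = build_design(shuffled)
        assert g.total_loglik(dm2, truth.params) == pytest.approx(base, abs=1e-8)

    def test_truth_dominates_perturbed_params(self):
        # expected log-likelihood is maximized at the generating parameters
        rng = np.random.default_rng(9)
        design = g.SimDesign(n_grids={"IL": 17, "MN": 17, "WI": 16})
        diffs = []
        for rep in range(8):
            ds, truth = g.simulate_study(design, seed=500 + rep)
            dm = build_design(ds)
            true_vec = reexpress_params(
                truth.params, truth.standardizers, dm.standardizers
            ).to_vector()
            pert = true_vec + rng.normal(0, 0.7, size=true_vec.shape)
            diffs.append(
                loglik_from_vector(dm, true_vec) - loglik_from_vector(dm, pert)
            )
        assert np.mean(diffs) > 0

    def test_finite_at_extreme_parameters(self, sim_small):
        dataset, _ = sim_small
        dm = build_design(dataset)
        vec = np.full(len(dm.param_names()), 30.0)
        assert np.isfinite(loglik_from_vector(dm, vec))
        assert np.isfinite(loglik_from_vector(dm, -vec))


class TestReexpression:
    def test_probabilities_invariant(self, sim_small):
        """Coefficients re-expressed to a new standardization scale give the
        same probabilities on the same raw covariates."""
        dataset, truth = sim_small
        dm = build_design(dataset)
        mapped = reexpress_params(truth.params, truth.standardizers, dm.standardizers)

        doy_raw = dataset.surveys["day_of_year"].to_numpy(float)
        z_from = truth.standardizers["day_of_year"].transform(doy_raw)
        z_to = dm.standardizers["day_of_year"].transform(doy_raw)
        p_from = p(truth.params, first_visit=1, doy_std=z_from)
        p_to = p(mapped, first_visit=1, doy_std=z_to)
        np.testing.assert_allclose(p_from, p_to, atol=1e-12)

        nb_raw = dataset.grids["n_occupied_neighbors"].to_numpy(float)
        psi_from = psi(
            truth.params, "MN",
            neighbors_std=truth.standardizers["neighbors"].transform(nb_raw),
        )
        psi_to = psi(
            mapped, "MN",
            neighbors_std=dm.standardizers["neighbors"].transform(nb_raw),
        )
        np.testing.assert_allclose(psi_from, psi_to, atol=1e-12)


class TestParamsSerialization:
    def test_dict_roundtrip(self):
        params = g.default_params()
        back = g.ModelParams.from_dict(params.to_dict())
        np.testing.assert_allclose(back.to_vector(), params.to_vector())
        assert back.state_levels == params.state_levels

    def test_vector_roundtrip_and_dim_check(self):
        params = g.default_params()
        back = g.ModelParams.from_vector(params.to_vector(), params.state_levels)
        assert back.to_dict() == params.to_dict()
        with pytest.raises(ValidationError):
            g.ModelParams.from_vector(np.zeros(5), ("IL", "MN", "WI"))
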