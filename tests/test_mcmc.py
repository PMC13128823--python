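import numpy as np
import pytest
from scipy.optimize import minimize
from scipy.special import expit, logit

import gridocc as g
from gridocc.data import ValidationError
from gridocc.mcmc import (
    PosteriorSamples,
    gelman_rubin,
    mean_subunit_occupancy,
    predict_p,
    predict_psi,
    psi_ratio,
    state_occupancy,
)
from gridocc.model import build_design, loglik_from_vector


def certain_detection_params(levels=("IL", "MN", "WI")):
    return g.ModelParams(
        state_levels=levels,
        psi_state_intercepts=np.zeros(len(levels)),
        theta_intercept=20.0,
        p_intercept=20.0,
    )


def synthetic_samples(sim_small, draws_by_name):
    """PosteriorSamples with hand-made coefficient draws (1 chain)."""
    dataset, _ = sim_small
    dm = build_design(dataset)
    names = dm.param_names()
    n = len(next(iter(draws_by_name.values())))
    params = np.zeros((1, n, len(names)))
    for name, vals in draws_by_name.items():
        params[0, :, names.index(name)] = vals
    z = np.ones((1, n, dm.n_grids), dtype=np.int8)
    return PosteriorSamples(
        params=params,
        param_names=names,
        z=z,
        design=dm,
        config=g.FitConfig(n_iter=n + 1, n_burnin=1, n_retained=n, n_chains=1),
        accept_rates=np.zeros(len(names)),
    )


class TestGelmanRubin:
    def test_identical_chains_classic_is_one(self):
        rng = np.random.default_rng(0)
        chain = rng.standard_normal(5_000)
        x = np.tile(chain, (3, 1))
        r = gelman_rubin({"b": x}, split=False)["b"]
        assert r == pytest.approx(1.0, abs=1e-3)

    def test_iid_chains_near_one(self):
        rng = np.random.default_rng(1)
        x = rng.standard_normal((3, 5_000))
        assert gelman_rubin({"b": x})["b"] < 1.01

    def test_shifted_chain_flagged(self):
        rng = np.random.default_rng(2)
        x = rng.standard_normal((3, 5_000))
        x[0] += 5.0
        assert gelman_rubin({"b": x})["b"] > 1.1

    def test_matches_arviz_split_rhat(self):
        az = pytest.importorskip("arviz")
        rng = np.random.default_rng(3)
        x = np.cumsum(rng.standard_normal((4, 400)), axis=1) * 0.05
        ours = gelman_rubin({"b": x})["b"]
        theirs = float(az.rhat(x, method="split"))
        assert ours == pytest.approx(theirs, rel=1e-6)


class TestFitStructure:
    def test_all_detected_gives_degenerate_count(self):
        design = g.SimDesign(n_grids={"IL": 5, "MN": 5, "WI": 5})
        params = certain_detection_params()
        # psi intercepts at +20: every grid occupied and detected
        params.psi_state_intercepts = np.full(3, 20.0)
        ds, _ = g.simulate_study(design, params, seed=2)
        assert g.design_summary(ds)["n_detected_grids"] == 15
        samples = g.fit(ds, g.FitConfig(n_iter=600, n_burnin=200, n_retained=1200, seed=4))
        counts = samples.occupied_count_draws()
        assert (counts == 15).all()

    def test_forced_latent_states(self, sim_small, fitted_small):
        dataset, _ = sim_small
        dm = fitted_small.design
        det_grid = dm.det_grid
        z = fitted_small.z.reshape(-1, dm.n_grids)
        assert (z[:, det_grid] == 1).all()

    def test_derived_count_bounds(self, sim_small, fitted_small):
        dataset, _ = sim_small
        n_det = g.design_summary(dataset)["n_detected_grids"]
        counts = fitted_small.occupied_count_draws()
        assert counts.min() >= n_det
        assert counts.max() <= dataset.n_grids
        occ = g.derived_occupied_count(fitted_small)
        assert occ["lo95"] >= n_det

    def test_seed_determinism(self, sim_small):
        dataset, _ = sim_small
        cfg = g.FitConfig(n_iter=400, n_burnin=100, n_retained=900, seed=9)
        s1 = g.fit(dataset, cfg)
        s2 = g.fit(dataset, cfg)
        np.testing.assert_array_equal(s1.params, s2.params)
        np.testing.assert_array_equal(s1.z, s2.z)
        s3 = g.fit(dataset, g.FitConfig(n_iter=400, n_burnin=100, n_retained=900, seed=10))
        assert not np.array_equal(s1.params, s3.params)

    def test_config_validation(self):
        with pytest.raises(ValidationError):
            g.FitConfig(n_iter=100, n_burnin=200)
        with pytest.raises(ValidationError):
            g.FitConfig(n_iter=1_000, n_burnin=500, n_retained=10_000)

    def test_thinning_matches_regime(self):
        cfg = g.FitConfig()
        assert cfg.thin == 12  # floor(3 * 20000 / 5000)

    def test_summary_table(self, fitted_small):
        summ = fitted_small.summary()
        assert set(summ.columns) == {
            "parameter", "mean", "sd", "q2.5", "q50", "q97.5", "rhat",
        }
        assert "n_occupied" in set(summ["parameter"])
        assert (summ["q2.5"] <= summ["q97.5"]).all()


class TestMLECrossCheck:
    def test_posterior_mean_occupancy_matches_mle(self):
        """On a large simulated study the posterior mean of the average psi /
        theta / p agrees with a direct numerical maximization of the
        marginal likelihood."""
        design = g.SimDesign(n_grids={"IL": 100, "MN": 100, "WI": 100})
        ds, truth = g.simulate_study(design, seed=31)
        dm = build_design(ds)

        obj = lambda v: -loglik_from_vector(dm, v)
        x0 = np.zeros(len(dm.param_names()))
        res = minimize(obj, x0, method="Nelder-Mead",
                       options={"maxiter": 20_000, "xatol": 1e-6, "fatol": 1e-8})
        assert res.fun < obj(x0)
        mle = res.x

        samples = g.fit(dm, g.FitConfig(n_iter=3_000, n_burnin=1_000,
                                        n_retained=6_000, seed=6))
        flat = samples.flat_params()
        S = 3

        def mean_psi(vec):
            return float(expit(dm.X_psi @ vec[: S + 2]).mean())

        def mean_theta(vec):
            return float(expit(dm.X_theta @ vec[S + 2 : S + 4]).mean())

        post_psi = np.mean([mean_psi(v) for v in flat[::10]])
        post_theta = np.mean([mean_theta(v) for v in flat[::10]])
        assert post_psi == pytest.approx(mean_psi(mle), abs=0.04)
        assert post_theta == pytest.approx(mean_theta(mle), abs=0.06)


class TestDerivedQuantities:
    def test_predict_p_flat_without_doy_effects(self, sim_small):
        samples = synthetic_samples(
            sim_small, {"p_int": np.full(50, logit(0.4))}
        )
        curves = predict_p(samples, [180, 200, 240], first_visit=False)
        np.testing.assert_allclose(curves, 0.4, atol=1e-12)

    def test_detection_peak_at_vertex(self, sim_small):
        b1, b2 = 0.6, -0.4
        samples = synthetic_samples(
            sim_small,
            {"beta_doy": np.full(10, b1), "beta_doy2": np.full(10, b2)},
        )
        st = samples.design.standardizers["day_of_year"]
        peak_doy = st.mean - b1 / (2 * b2) * st.sd
        grid = np.linspace(st.mean - 2 * st.sd, st.mean + 2 * st.sd, 401)
        curve = predict_p(samples, grid).mean(axis=0)
        assert grid[np.argmax(curve)] == pytest.approx(peak_doy, abs=0.5)

    def test_first_visit_dominates_iff_positive_effect(self, sim_small):
        samples = synthetic_samples(
            sim_small, {"beta_first_visit": np.full(10, 0.9),
                        "beta_doy": np.full(10, 0.3)}
        )
        doy = np.linspace(180, 250, 30)
        first = predict_p(samples, doy, first_visit=True)
        later = predict_p(samples, doy, first_visit=False)
        assert (first >= later).all()

    def test_predict_psi_at_standardized_zero(self, sim_small):
        ints = np.linspace(-1, 1, 30)
        samples = synthetic_samples(sim_small, {"psi_int[MN]": ints})
        st = samples.design.standardizers
        prof = {
            "state": "MN",
            "n_occupied_neighbors": st["neighbors"].mean,
            "developed_prop": st["developed_prop"].mean,
        }
        draws = predict_psi(samples, prof)[:, 0]
        np.testing.assert_allclose(draws, expit(ints), atol=1e-12)

    def test_psi_monotone_when_slope_positive(self, sim_small):
        samples = synthetic_samples(
            sim_small, {"beta_neighbors": np.full(20, 0.8)}
        )
        prof = [{"state": "IL", "n_occupied_neighbors": n} for n in range(9)]
        draws = predict_psi(samples, prof)
        assert (np.diff(draws, axis=1) > 0).all()

    def test_psi_ratio_both_definitions(self, fitted_small):
        out = psi_ratio(fitted_small, 6, 4)
        assert out["ratio_lo95"] <= out["median_ratio"] <= out["ratio_hi95"]
        assert out["mean_ratio"] > 0 and out["ratio_of_means"] > 0

    def test_state_and_subunit_summaries(self, fitted_small):
        so = state_occupancy(fitted_small)
        assert list(so["state"]) == list(fitted_small.design.state_levels)
        assert ((so["mean"] >= so["lo95"]) & (so["mean"] <= so["hi95"])).all()
        th = mean_subunit_occupancy(fitted_small)
        assert 0 < th["lo95"] <= th["mean"] <= th["hi95"] < 1


class TestOccupiedCountCoverage:
    def test_credible_interval_covers_true_count(self):
        """95% CI for sum(z) covers the realized occupied-grid count at close
        to nominal rate across replicates (scaled-down simulation)."""
        design = g.SimDesign(n_grids={"IL": 15, "MN": 15, "WI": 15})
        hits = 0
        n_rep = 25
        for rep in range(n_rep):
            ds, truth = g.simulate_study(design, seed=4_000 + rep)
            s = g.fit(ds, g.FitConfig(n_iter=1_500, n_burnin=500,
                                      n_retained=3_000, seed=rep))
            occ = g.derived_occupied_count(s)
            if occ["lo95"] <= truth.z.sum() <= occ["hi95"]:
                hits += 1
        assert hits >= int(0.8 * n_rep)
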