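"""Bayesian fitting of the multi-scale occupancy model.

The sampler is a data-augmented Gibbs/Metropolis scheme:

1. latent states are drawn from closed-form full conditionals — grid states
   z_i with the subunit layer collapsed, then subunit states a_ij given z_i;
   both are fixed to 1 wherever a detection forces them;
2. the three coefficient blocks (psi, theta, p), which are conditionally
   independent Bernoulli regressions given (z, a), are updated by a
   componentwise random-walk Metropolis sweep followed by a joint
   adaptive-covariance Metropolis step per block (the joint step handles the
   strong intercept/slope correlations), with independent
   Normal(0, prior_sd) priors on every intercept and slope.

Proposal scales and covariances adapt (target acceptance 0.44 componentwise,
0.25 joint) during burn-in only, frozen afterwards to preserve detailed
balance.  Post burn-in draws are
thinned with stride m = floor(n_chains * (n_iter - n_burnin) / n_retained).

Convergence is assessed with the Gelman-Rubin statistic (split form by
default); derived quantities — the number of occupied grids sum(z), state-
level occupancy, occupancy-vs-neighbors curves, seasonal detection curves —
are computed per retained draw.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.special import expit, log_expit

from .data import Dataset, Standardizer, ValidationError
from .model import DesignMatrices, ModelParams, build_design

__all__ = [
    "FitConfig",
    "PosteriorSamples",
    "smoke_config",
    "full_config",
    "fit",
    "gelman_rubin",
    "derived_occupied_count",
    "predict_psi",
    "psi_ratio",
    "predict_p",
]

logger = logging.getLogger("gridocc")


@dataclass
class FitConfig:
    """MCMC settings.  Defaults follow the full analysis regime: 3 chains of
    25,000 iterations, 5,000 burn-in, thinned to 5,000 retained draws, and an
    R-hat flag at 1.1.

    The prior is independent Normal(0, prior_sd) on every intercept and
    slope.  The default sd of 2.25 is weakly informative on the logit scale
    (its implied prior on each probability is near-uniform); much larger
    values (e.g. 10) are bathtub-shaped on the probability scale and bias
    weakly identified intercepts outward under removal censoring."""

    n_chains: int = 3
    n_iter: int = 25_000
    n_burnin: int = 5_000
    n_retained: int = 5_000
    prior_sd: float = 2.25
    seed: int | None = None
    rhat_threshold: float = 1.1

    def __post_init__(self) -> None:
        if self.n_burnin >= self.n_iter:
            raise ValidationError("n_burnin must be < n_iter")
        if self.n_retained > self.n_chains * (self.n_iter - self.n_burnin):
            raise ValidationError("n_retained exceeds available post-burn-in draws")
        if self.prior_sd <= 0:
            raise ValidationError("prior_sd must be positive")

    @property
    def thin(self) -> int:
        return max(
            1,
            int(self.n_chains * (self.n_iter - self.n_burnin) // self.n_retained),
        )


def smoke_config(seed: int | None = None, **kw) -> FitConfig:
    """Reduced regime for pipelines and tests: 3 x 4,000, burn-in 1,000.

    Short enough for seconds-scale fits, long enough for the adaptive
    proposals to settle on this model's correlated, heavy-tailed blocks.
    """
    kw.setdefault("n_iter", 4_000)
    kw.setdefault("n_burnin", 1_000)
    kw.setdefault("n_retained", 9_000)
    return FitConfig(seed=seed, **kw)


def full_config(seed: int | None = None, **kw) -> FitConfig:
    """The full regime (3 x 25,000 / 5,000 burn-in / 5,000 retained)."""
    return FitConfig(seed=seed, **kw)


# ---------------------------------------------------------------------------
# Posterior container
# ---------------------------------------------------------------------------


@dataclass
class PosteriorSamples:
    """Retained draws: coefficients (chain, draw, param) and latent z."""

    params: np.ndarray          # (C, D, P)
    param_names: list[str]
    z: np.ndarray               # (C, D, G) int8
    design: DesignMatrices
    config: FitConfig
    accept_rates: np.ndarray    # (P,) mean post-burn-in acceptance per param
    seed: int | None = None

    @property
    def n_chains(self) -> int:
        return self.params.shape[0]

    @property
    def n_draws(self) -> int:
        return self.params.shape[1]

    def flat(self, name: str) -> np.ndarray:
        """All retained draws of one coefficient, chains concatenated."""
        j = self.param_names.index(name)
        return self.params[:, :, j].reshape(-1)

    def flat_params(self) -> np.ndarray:
        return self.params.reshape(-1, self.params.shape[2])

    def occupied_count_draws(self) -> np.ndarray:
        """Per-draw derived parameter sum_i z_i."""
        return self.z.sum(axis=2).reshape(-1)

    def summary(self) -> pd.DataFrame:
        """Posterior table: mean, sd, 2.5/50/97.5% quantiles and R-hat."""
        rhat = gelman_rubin(self)
        rows = []
        for j, name in enumerate(self.param_names):
            d = self.params[:, :, j].reshape(-1)
            rows.append(
                {
                    "parameter": name,
                    "mean": d.mean(),
                    "sd": d.std(ddof=1),
                    "q2.5": np.quantile(d, 0.025),
                    "q50": np.quantile(d, 0.5),
                    "q97.5": np.quantile(d, 0.975),
                    "rhat": rhat[name],
                }
            )
        nz = self.z.sum(axis=2)
        d = nz.reshape(-1).astype(float)
        rows.append(
            {
                "parameter": "n_occupied",
                "mean": d.mean(),
                "sd": d.std(ddof=1),
                "q2.5": np.quantile(d, 0.025),
                "q50": np.quantile(d, 0.5),
                "q97.5": np.quantile(d, 0.975),
                "rhat": _split_rhat(nz.astype(float)),
            }
        )
        return pd.DataFrame(rows)

    def to_long_dataframe(self) -> pd.DataFrame:
        """Long format (chain, draw, parameter, value) incl. derived sum(z)."""
        C, D, P = self.params.shape
        chains = np.repeat(np.arange(C), D)
        draws = np.tile(np.arange(D), C)
        frames = []
        for j, name in enumerate(self.param_names):
            frames.append(
                pd.DataFrame(
                    {
                        "chain": chains,
                        "draw": draws,
                        "parameter": name,
                        "value": self.params[:, :, j].reshape(-1),
                    }
                )
            )
        frames.append(
            pd.DataFrame(
                {
                    "chain": chains,
                    "draw": draws,
                    "parameter": "n_occupied",
                    "value": self.z.sum(axis=2).reshape(-1).astype(float),
                }
            )
        )
        return pd.concat(frames, ignore_index=True)

    def to_model_params(self, draw_vector: np.ndarray) -> ModelParams:
        return ModelParams.from_vector(draw_vector, self.design.state_levels)


# ---------------------------------------------------------------------------
# Sampler
# ---------------------------------------------------------------------------


def fit(
    data: Dataset | DesignMatrices,
    config: FitConfig | None = None,
    seed: int | None = None,
) -> PosteriorSamples:
    """Run the data-augmented MCMC and return retained draws.

    ``data`` may be a validated :class:`Dataset` (design matrices are built
    internally) or prebuilt :class:`DesignMatrices`.  ``seed`` overrides
    ``config.seed``; identical seed and config give identical draws.
    """
    config = config or FitConfig()
    if seed is None:
        seed = config.seed
    dm = data if isinstance(data, DesignMatrices) else build_design(data)

    root = np.random.SeedSequence(seed)
    chain_seeds = root.spawn(config.n_chains)
    P = dm.X_psi.shape[1] + dm.X_theta.shape[1] + dm.X_p.shape[1]
    names = dm.param_names()

    thin = config.thin
    keep = (config.n_iter - config.n_burnin) // thin
    all_params = np.empty((config.n_chains, keep, P))
    all_z = np.empty((config.n_chains, keep, dm.n_grids), dtype=np.int8)
    acc = np.zeros(P)

    for c, ss in enumerate(chain_seeds):
        rng = np.random.default_rng(ss)
        draws, zdraws, acc_c = _run_chain(dm, config, rng)
        all_params[c] = draws[:keep]
        all_z[c] = zdraws[:keep]
        acc += acc_c / config.n_chains

    post = PosteriorSamples(
        params=all_params,
        param_names=names,
        z=all_z,
        design=dm,
        config=config,
        accept_rates=acc,
        seed=seed,
    )

    means = post.flat_params().mean(axis=0)
    drifted = [n for n, m in zip(names, means) if abs(m) > 15.0]
    if drifted:
        warnings.warn(
            f"possible separation: coefficients beyond +/-15 on the logit "
            f"scale: {drifted}",
            RuntimeWarning,
            stacklevel=2,
        )
    rhat = gelman_rubin(post)
    bad = {k: v for k, v in rhat.items() if v >= config.rhat_threshold}
    if bad:
        warnings.warn(
            f"Gelman-Rubin statistic >= {config.rhat_threshold} for {bad}; "
            "increase n_iter",
            RuntimeWarning,
            stacklevel=2,
        )
    return post


def _run_chain(dm: DesignMatrices, config: FitConfig, rng: np.random.Generator):
    G, J, K = dm.n_grids, dm.n_subunits, dm.n_surveys
    S = len(dm.state_levels)
    X_psi, X_theta, X_p = dm.X_psi, dm.X_theta, dm.X_p
    y = dm.y.astype(float)
    sign_y = 2.0 * y - 1.0
    sub_grid, surv_sub = dm.sub_grid, dm.surv_sub
    det_sub = dm.det_sub
    det_grid = dm.det_grid
    free_grid = ~det_grid

    blocks = [
        ("psi", X_psi, slice(0, S + 2)),
        ("theta", X_theta, slice(S + 2, S + 4)),
        ("p", X_p, slice(S + 4, S + 8)),
    ]
    P = S + 8
    beta = 0.3 * rng.standard_normal(P)
    etas = {name: X @ beta[sl] for name, X, sl in blocks}
    scales = np.full(P, 0.5)
    prior_var = config.prior_sd**2

    # Per-block adaptive-covariance state (Welford accumulators over burn-in)
    adapt = {
        name: {
            "n": 0,
            "mean": np.zeros(sl.stop - sl.start),
            "M2": np.zeros((sl.stop - sl.start, sl.stop - sl.start)),
            "chol": np.eye(sl.stop - sl.start) * 0.1,
            "log_s": 0.0,
            "acc": 0,
            "prop": 0,
        }
        for name, _, sl in blocks
    }

    z = np.ones(G, dtype=np.int8)
    a = np.ones(J, dtype=np.int8)

    thin = config.thin
    keep = (config.n_iter - config.n_burnin) // thin
    out_params = np.empty((keep, P))
    out_z = np.empty((keep, G), dtype=np.int8)
    n_acc = np.zeros(P)
    n_prop = np.zeros(P)
    kept = 0

    for it in range(config.n_iter):
        # ---- latent states ------------------------------------------------
        log_q = np.bincount(surv_sub, weights=log_expit(-etas["p"]), minlength=J)
        theta_j = expit(etas["theta"])
        psi_i = expit(etas["psi"])

        # z for detection-free grids, with the subunit layer collapsed:
        # P(z=1 | ...) ∝ psi * prod_j (theta_j q_j + 1 - theta_j)
        m_j = theta_j * np.exp(log_q) + (1.0 - theta_j)  # valid where no det
        log_m = np.log(m_j)
        sum_log_m = np.bincount(sub_grid, weights=log_m, minlength=G)
        w1 = psi_i * np.exp(np.minimum(sum_log_m, 0.0))
        pz = w1 / (w1 + (1.0 - psi_i))
        z = np.where(det_grid, 1, (rng.random(G) < pz)).astype(np.int8)

        # a | z: forced 1 where the subunit has a detection
        pa = theta_j * np.exp(log_q) / m_j
        draw_a = (rng.random(J) < pa).astype(np.int8) * z[sub_grid]
        a = np.where(det_sub, 1, draw_a).astype(np.int8)

        # ---- coefficient blocks -------------------------------------------
        responses = {
            "psi": (z.astype(float), None),
            "theta": (a.astype(float), z[sub_grid].astype(float)),
            "p": (y, a[surv_sub].astype(float)),
        }
        adapting = it < config.n_burnin
        for name, X, sl in blocks:
            resp, mask = responses[name]
            sgn = 2.0 * resp - 1.0
            eta = etas[name]
            if mask is None:
                ll_cur = float(log_expit(sgn * eta).sum())
            else:
                ll_cur = float(mask @ log_expit(sgn * eta))
            for j_local in range(X.shape[1]):
                pj = sl.start + j_local
                n_prop[pj] += 1
                step = scales[pj] * rng.standard_normal()
                eta_new = eta + X[:, j_local] * step
                if mask is None:
                    ll_new = float(log_expit(sgn * eta_new).sum())
                else:
                    ll_new = float(mask @ log_expit(sgn * eta_new))
                b_new = beta[pj] + step
                log_r = (
                    ll_new
                    - ll_cur
                    + 0.5 * (beta[pj] ** 2 - b_new**2) / prior_var
                )
                accepted = np.log(rng.random()) < log_r
                if accepted:
                    beta[pj] = b_new
                    eta = eta_new
                    ll_cur = ll_new
                    n_acc[pj] += 1
                if adapting:
                    gamma = (it + 1) ** -0.6
                    scales[pj] *= np.exp(gamma * ((1.0 if accepted else 0.0) - 0.44))
                    scales[pj] = min(max(scales[pj], 1e-3), 10.0)

            # joint adaptive-covariance step for the whole block
            st = adapt[name]
            d = sl.stop - sl.start
            st["prop"] += 1
            step_vec = (
                np.exp(st["log_s"])
                * (2.38 / np.sqrt(d))
                * (st["chol"] @ rng.standard_normal(d))
            )
            eta_new = eta + X @ step_vec
            if mask is None:
                ll_new = float(log_expit(sgn * eta_new).sum())
            else:
                ll_new = float(mask @ log_expit(sgn * eta_new))
            b_cur = beta[sl]
            b_new = b_cur + step_vec
            log_r = (
                ll_new
                - ll_cur
                + 0.5 * float(b_cur @ b_cur - b_new @ b_new) / prior_var
            )
            accepted = np.log(rng.random()) < log_r
            if accepted:
                beta[sl] = b_new
                eta = eta_new
                ll_cur = ll_new
                st["acc"] += 1
            if adapting:
                gamma = (it + 1) ** -0.6
                st["log_s"] += gamma * ((1.0 if accepted else 0.0) - 0.25)
                st["log_s"] = min(max(st["log_s"], -8.0), 4.0)
                # Welford update of the block covariance from the current state
                st["n"] += 1
                delta = beta[sl] - st["mean"]
                st["mean"] += delta / st["n"]
                st["M2"] += np.outer(delta, beta[sl] - st["mean"])
                if st["n"] > 50 and it % 25 == 0:
                    cov = st["M2"] / (st["n"] - 1) + 1e-6 * np.eye(d)
                    try:
                        st["chol"] = np.linalg.cholesky(cov)
                    except np.linalg.LinAlgError:
                        pass
            etas[name] = eta

        if not np.isfinite(beta).all():
            raise RuntimeError(
                f"non-finite coefficient state at iteration {it}: {beta}"
            )

        if it >= config.n_burnin and (it - config.n_burnin) % thin == thin - 1:
            if kept < keep:
                out_params[kept] = beta
                out_z[kept] = z
                kept += 1
        if (it + 1) % 1000 == 0:
            with np.errstate(invalid="ignore"):
                rates = np.where(n_prop > 0, n_acc / n_prop, np.nan)
            logger.debug(
                "iter %d: mean acceptance %.3f", it + 1, np.nanmean(rates)
            )

    with np.errstate(invalid="ignore"):
        acc_rates = np.where(n_prop > 0, n_acc / n_prop, np.nan)
    return out_params[:kept], out_z[:kept], acc_rates


# ---------------------------------------------------------------------------
# Convergence diagnostics
# ---------------------------------------------------------------------------


def _classic_rhat(x: np.ndarray) -> float:
    """Gelman-Rubin potential scale reduction on a (chains, draws) array."""
    m, n = x.shape
    means = x.mean(axis=1)
    W = x.var(axis=1, ddof=1).mean()
    B = n * means.var(ddof=1)
    if W == 0.0:
        return 1.0 if B == 0.0 else np.inf
    var_hat = (n - 1) / n * W + B / n
    return float(np.sqrt(var_hat / W))


def _split_rhat(x: np.ndarray) -> float:
    m, n = x.shape
    half = n // 2
    if half < 2:
        return np.nan
    split = x[:, : 2 * half].reshape(2 * m, half)
    return _classic_rhat(split)


def gelman_rubin(samples, split: bool = True) -> dict[str, float]:
    """Per-parameter Gelman-Rubin statistic.

    ``samples`` is a :class:`PosteriorSamples` or a mapping of parameter
    name -> (chains, draws) array.  The split form (each chain halved)
    additionally detects within-chain trends; the classic form is available
    with ``split=False``.
    """
    stat = _split_rhat if split else _classic_rhat
    if isinstance(samples, PosteriorSamples):
        if samples.n_chains < 2 and split is False:
            raise ValidationError("Gelman-Rubin requires at least 2 chains")
        return {
            name: stat(samples.params[:, :, j])
            for j, name in enumerate(samples.param_names)
        }
    return {name: stat(np.asarray(arr, float)) for name, arr in samples.items()}


# ---------------------------------------------------------------------------
# Derived posterior quantities
# ---------------------------------------------------------------------------


def derived_occupied_count(samples: PosteriorSamples) -> dict[str, float]:
    """Posterior summary of the derived occupied-grid count sum_i z_i."""
    d = samples.occupied_count_draws().astype(float)
    return {
        "mean": float(d.mean()),
        "median": float(np.median(d)),
        "lo95": float(np.quantile(d, 0.025)),
        "hi95": float(np.quantile(d, 0.975)),
    }


def _profile_frame(profiles) -> pd.DataFrame:
    if isinstance(profiles, pd.DataFrame):
        return profiles
    if isinstance(profiles, dict):
        profiles = [profiles]
    return pd.DataFrame(list(profiles))


def predict_psi(samples: PosteriorSamples, profiles) -> np.ndarray:
    """Posterior draws of psi at covariate profiles on the natural scale.

    ``profiles``: DataFrame / list of dicts with keys ``state`` (optional —
    omitted or NaN averages the state intercepts equally per draw),
    ``n_occupied_neighbors`` and ``developed_prop`` (optional; default =
    sample mean, i.e. standardized zero).  Returns (n_draws, n_profiles).
    """
    prof = _profile_frame(profiles)
    st = samples.design.standardizers
    S = len(samples.design.state_levels)
    flat = samples.flat_params()
    ints = flat[:, :S]
    b_nb = flat[:, S]
    b_dev = flat[:, S + 1]

    out = np.empty((flat.shape[0], len(prof)))
    for c, (_, row) in enumerate(prof.iterrows()):
        z_nb = (
            st["neighbors"].transform(row["n_occupied_neighbors"])
            if "n_occupied_neighbors" in row and pd.notna(row.get("n_occupied_neighbors"))
            else 0.0
        )
        z_dev = (
            st["developed_prop"].transform(row["developed_prop"])
            if "developed_prop" in row and pd.notna(row.get("developed_prop"))
            else 0.0
        )
        state = row.get("state")
        slope = b_nb * z_nb + b_dev * z_dev
        if state is None or (isinstance(state, float) and np.isnan(state)):
            out[:, c] = expit(ints + slope[:, None]).mean(axis=1)
        else:
            j = samples.design.state_levels.index(state)
            out[:, c] = expit(ints[:, j] + slope)
    return out


def psi_ratio(
    samples: PosteriorSamples,
    neighbors_num: float = 6,
    neighbors_den: float = 4,
    state: str | None = None,
    developed_prop: float | None = None,
) -> dict[str, float]:
    """Ratio of occupancy at two occupied-neighbor counts.

    Computed two ways (the per-draw ratio summarized, and the ratio of
    posterior means), since the two are not interchangeable for a nonlinear
    functional.
    """
    prof = [
        {"state": state, "n_occupied_neighbors": neighbors_num,
         "developed_prop": developed_prop},
        {"state": state, "n_occupied_neighbors": neighbors_den,
         "developed_prop": developed_prop},
    ]
    draws = predict_psi(samples, prof)
    ratio = draws[:, 0] / draws[:, 1]
    return {
        "mean_ratio": float(ratio.mean()),
        "median_ratio": float(np.median(ratio)),
        "ratio_lo95": float(np.quantile(ratio, 0.025)),
        "ratio_hi95": float(np.quantile(ratio, 0.975)),
        "ratio_of_means": float(draws[:, 0].mean() / draws[:, 1].mean()),
    }


def predict_p(
    samples: PosteriorSamples,
    day_of_year,
    first_visit: bool = True,
) -> np.ndarray:
    """Posterior draws of detection probability over a day-of-year grid.

    Returns (n_draws, len(day_of_year)); the seasonal shape is quadratic on
    the logit scale by construction.
    """
    doy = np.atleast_1d(np.asarray(day_of_year, float))
    st = samples.design.standardizers["day_of_year"]
    zd = st.transform(doy)
    S = len(samples.design.state_levels)
    flat = samples.flat_params()
    b0 = flat[:, S + 4]
    b_fv = flat[:, S + 5]
    b1 = flat[:, S + 6]
    b2 = flat[:, S + 7]
    eta = (
        b0[:, None]
        + (b_fv[:, None] if first_visit else 0.0)
        + b1[:, None] * zd[None, :]
        + b2[:, None] * zd[None, :] ** 2
    )
    return expit(eta)


def state_occupancy(samples: PosteriorSamples) -> pd.DataFrame:
    """Posterior state-level occupancy at sample-mean covariates."""
    rows = []
    for s in samples.design.state_levels:
        draws = predict_psi(samples, {"state": s})[:, 0]
        rows.append(
            {
                "state": s,
                "mean": draws.mean(),
                "lo95": np.quantile(draws, 0.025),
                "hi95": np.quantile(draws, 0.975),
            }
        )
    return pd.DataFrame(rows)


def mean_subunit_occupancy(samples: PosteriorSamples) -> dict[str, float]:
    """Posterior of the dataset-average conditional subunit-use probability."""
    S = len(samples.design.state_levels)
    flat = samples.flat_params()
    eta = flat[:, S + 2 : S + 4] @ samples.design.X_theta.T
    draws = expit(eta).mean(axis=1)
    return {
        "mean": float(draws.mean()),
        "lo95": float(np.quantile(draws, 0.025)),
        "hi95": float(np.quantile(draws, 0.975)),
    }
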