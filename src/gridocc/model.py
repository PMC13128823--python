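"""Multi-scale occupancy likelihood with logit-linear covariate submodels.

The hierarchy has three Bernoulli levels:

* grid occupancy            z_i   ~ Bernoulli(psi_i)
* subunit use | occupied    a_ij  ~ Bernoulli(z_i * theta_ij)
* detection | used          y_ijk ~ Bernoulli(a_ij * p_ijk)

with logit-linear predictors

* logit(psi_i)   = psi_int[state_i] + b_nb * neighbors_i + b_dev * developed_i
* logit(theta_ij) = theta_int + b_dev500 * developed_500m_ij
* logit(p_ijk)   = p_int + b_first * first_visit_ijk + b_doy * doy_ijk
                   + b_doy2 * doy_ijk^2

All covariates are standardized to mean 0, variance 1 over their unit set;
the day-of-year quadratic term is the square of the standardized day.  State
enters through one intercept per level (means parameterization), so state-
level occupancy estimates need no reference-category algebra.

:func:`grid_marginal_loglik` marginalizes the latent (z, a) pair exactly: the
per-subunit mixture theta*D + (1-theta)*[no detection] collapses the a_ij sum
and the outer psi mixture collapses z, so ragged removal-censored histories
need no special handling beyond omitting unconducted surveys (the censoring
mechanism depends only on observed detections and is ignorable).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.special import expit, log_expit, logit

from .data import Dataset, Standardizer, ValidationError, standardize

__all__ = [
    "ModelParams",
    "DesignMatrices",
    "build_design",
    "psi",
    "theta",
    "p",
    "small_scale_occupancy",
    "psi_probs",
    "theta_probs",
    "p_probs",
    "grid_marginal_loglik",
    "total_loglik",
    "loglik_from_vector",
    "reexpress_params",
    "LOGLIK_FLOOR",
]

#: Per-grid log-likelihood floor (log of the smallest normal double); keeps
#: total_loglik finite even when a caller passes degenerate probabilities.
LOGLIK_FLOOR = float(np.log(np.finfo(float).tiny))


# ---------------------------------------------------------------------------
# Parameters
# ---------------------------------------------------------------------------


@dataclass
class ModelParams:
    """Named coefficients on the logit scale for the three submodels."""

    state_levels: tuple[str, ...]
    psi_state_intercepts: np.ndarray
    beta_neighbors: float = 0.0
    beta_dev_grid: float = 0.0
    theta_intercept: float = 0.0
    beta_dev_subunit: float = 0.0
    p_intercept: float = 0.0
    beta_first_visit: float = 0.0
    beta_doy: float = 0.0
    beta_doy2: float = 0.0

    def __post_init__(self) -> None:
        self.state_levels = tuple(self.state_levels)
        self.psi_state_intercepts = np.asarray(
            self.psi_state_intercepts, dtype=float
        )
        if self.psi_state_intercepts.shape != (len(self.state_levels),):
            raise ValidationError(
                "psi_state_intercepts must have one entry per state level"
            )
        vec = self.to_vector()
        if not np.all(np.isfinite(vec)):
            raise ValidationError("all coefficients must be finite")

    @property
    def n_states(self) -> int:
        return len(self.state_levels)

    def names(self) -> list[str]:
        return (
            [f"psi_int[{s}]" for s in self.state_levels]
            + [
                "beta_neighbors",
                "beta_dev_grid",
                "theta_int",
                "beta_dev_subunit",
                "p_int",
                "beta_first_visit",
                "beta_doy",
                "beta_doy2",
            ]
        )

    def to_vector(self) -> np.ndarray:
        return np.concatenate(
            [
                self.psi_state_intercepts,
                [
                    self.beta_neighbors,
                    self.beta_dev_grid,
                    self.theta_intercept,
                    self.beta_dev_subunit,
                    self.p_intercept,
                    self.beta_first_visit,
                    self.beta_doy,
                    self.beta_doy2,
                ],
            ]
        )

    @classmethod
    def from_vector(cls, vec, state_levels) -> "ModelParams":
        vec = np.asarray(vec, dtype=float)
        s = len(state_levels)
        if vec.shape != (s + 8,):
            raise ValidationError(
                f"parameter vector must have length {s + 8}, got {vec.shape}"
            )
        return cls(
            state_levels=tuple(state_levels),
            psi_state_intercepts=vec[:s].copy(),
            beta_neighbors=float(vec[s]),
            beta_dev_grid=float(vec[s + 1]),
            theta_intercept=float(vec[s + 2]),
            beta_dev_subunit=float(vec[s + 3]),
            p_intercept=float(vec[s + 4]),
            beta_first_visit=float(vec[s + 5]),
            beta_doy=float(vec[s + 6]),
            beta_doy2=float(vec[s + 7]),
        )

    def to_dict(self) -> dict[str, float]:
        return dict(zip(self.names(), map(float, self.to_vector())))

    @classmethod
    def from_dict(cls, d: dict) -> "ModelParams":
        levels = tuple(
            k[len("psi_int["):-1] for k in d if k.startswith("psi_int[")
        )
        if not levels:
            raise ValidationError("no psi_int[<state>] entries found")
        vec = [d[f"psi_int[{s}]"] for s in levels] + [
            d["beta_neighbors"],
            d["beta_dev_grid"],
            d["theta_int"],
            d["beta_dev_subunit"],
            d["p_int"],
            d["beta_first_visit"],
            d["beta_doy"],
            d["beta_doy2"],
        ]
        return cls.from_vector(np.asarray(vec, float), levels)

    # Block views used by the sampler -------------------------------------

    def psi_block(self) -> np.ndarray:
        return np.concatenate(
            [self.psi_state_intercepts, [self.beta_neighbors, self.beta_dev_grid]]
        )

    def theta_block(self) -> np.ndarray:
        return np.array([self.theta_intercept, self.beta_dev_subunit])

    def p_block(self) -> np.ndarray:
        return np.array(
            [self.p_intercept, self.beta_first_visit, self.beta_doy, self.beta_doy2]
        )


# ---------------------------------------------------------------------------
# Design matrices
# ---------------------------------------------------------------------------


@dataclass
class DesignMatrices:
    """Covariate matrices and index maps derived from a :class:`Dataset`.

    Rows of ``X_p`` correspond to conducted surveys only.  ``sub_grid`` maps
    each subunit row to its grid row; ``surv_sub`` maps each survey row to its
    subunit row.
    """

    state_levels: tuple[str, ...]
    grid_ids: np.ndarray
    subunit_ids: np.ndarray
    X_psi: np.ndarray      # (G, S + 2): state one-hots, z(neighbors), z(dev)
    X_theta: np.ndarray    # (J, 2): 1, z(dev500)
    X_p: np.ndarray        # (K, 4): 1, first_visit, z(doy), z(doy)^2
    sub_grid: np.ndarray   # (J,) int
    surv_sub: np.ndarray   # (K,) int
    y: np.ndarray          # (K,) int8 detections
    standardizers: dict[str, Standardizer] = field(default_factory=dict)

    @property
    def n_grids(self) -> int:
        return self.X_psi.shape[0]

    @property
    def n_subunits(self) -> int:
        return self.X_theta.shape[0]

    @property
    def n_surveys(self) -> int:
        return self.X_p.shape[0]

    @property
    def det_sub(self) -> np.ndarray:
        """Boolean: subunit has at least one detection."""
        return np.bincount(self.surv_sub, weights=self.y, minlength=self.n_subunits) > 0

    @property
    def det_grid(self) -> np.ndarray:
        """Boolean: grid has at least one detection."""
        return (
            np.bincount(
                self.sub_grid,
                weights=self.det_sub.astype(float),
                minlength=self.n_grids,
            )
            > 0
        )

    def param_names(self) -> list[str]:
        return ModelParams(
            self.state_levels, np.zeros(len(self.state_levels))
        ).names()


def build_design(
    dataset: Dataset,
    standardizers: dict[str, Standardizer] | None = None,
) -> DesignMatrices:
    """Build standardized design matrices from a validated dataset.

    The first-visit indicator is 1 for surveys k in {1, 2}.  Neighbors and
    both developed-land covariates are standardized over their unit sets;
    day of year over the conducted surveys.  Pass ``standardizers`` to reuse
    externally fitted standardizers (e.g. when predicting onto new units).
    """
    g, s, y = dataset.grids, dataset.subunits, dataset.surveys
    levels = dataset.state_levels

    def _std(name, values):
        if standardizers is not None and name in standardizers:
            st = standardizers[name]
            return st.transform(values), st
        return standardize(values)

    z_nb, st_nb = _std("neighbors", g["n_occupied_neighbors"].to_numpy(float))
    z_dev, st_dev = _std("developed_prop", g["developed_prop"].to_numpy())
    z_dev500, st_dev500 = _std(
        "developed_prop_500m", s["developed_prop_500m"].to_numpy()
    )
    z_doy, st_doy = _std("day_of_year", y["day_of_year"].to_numpy(float))

    state_onehot = np.zeros((len(g), len(levels)))
    state_idx = {lvl: i for i, lvl in enumerate(levels)}
    for r, st_label in enumerate(g["state"]):
        state_onehot[r, state_idx[st_label]] = 1.0
    X_psi = np.column_stack([state_onehot, z_nb, z_dev])

    X_theta = np.column_stack([np.ones(len(s)), z_dev500])

    first_visit = (y["k"] <= 2).to_numpy(float)
    X_p = np.column_stack([np.ones(len(y)), first_visit, z_doy, z_doy**2])

    grid_pos = {gid: i for i, gid in enumerate(g["grid_id"])}
    sub_pos = {sid: j for j, sid in enumerate(s["subunit_id"])}
    sub_grid = np.array([grid_pos[gid] for gid in s["grid_id"]], dtype=np.int64)
    surv_sub = np.array([sub_pos[sid] for sid in y["subunit_id"]], dtype=np.int64)

    return DesignMatrices(
        state_levels=levels,
        grid_ids=g["grid_id"].to_numpy(),
        subunit_ids=s["subunit_id"].to_numpy(),
        X_psi=X_psi,
        X_theta=X_theta,
        X_p=X_p,
        sub_grid=sub_grid,
        surv_sub=surv_sub,
        y=y["detection"].to_numpy(np.int8),
        standardizers={
            "neighbors": st_nb,
            "developed_prop": st_dev,
            "developed_prop_500m": st_dev500,
            "day_of_year": st_doy,
        },
    )


# ---------------------------------------------------------------------------
# Probability functions
# ---------------------------------------------------------------------------


def psi(params: ModelParams, state: str, neighbors_std=0.0, developed_std=0.0):
    """Grid occupancy probability at standardized covariate values."""
    i = params.state_levels.index(state)
    eta = (
        params.psi_state_intercepts[i]
        + params.beta_neighbors * np.asarray(neighbors_std, float)
        + params.beta_dev_grid * np.asarray(developed_std, float)
    )
    return expit(eta)


def theta(params: ModelParams, developed_500m_std=0.0):
    """Conditional subunit-use probability given the grid is occupied."""
    eta = params.theta_intercept + params.beta_dev_subunit * np.asarray(
        developed_500m_std, float
    )
    return expit(eta)


def p(params: ModelParams, first_visit, doy_std=0.0):
    """Per-survey detection probability given the subunit is used."""
    fv = np.asarray(first_visit, float)
    d = np.asarray(doy_std, float)
    eta = (
        params.p_intercept
        + params.beta_first_visit * fv
        + params.beta_doy * d
        + params.beta_doy2 * d**2
    )
    return expit(eta)


def small_scale_occupancy(
    params: ModelParams,
    state: str,
    neighbors_std=0.0,
    developed_std=0.0,
    developed_500m_std=0.0,
):
    """Unconditional subunit-use probability psi * theta."""
    return psi(params, state, neighbors_std, developed_std) * theta(
        params, developed_500m_std
    )


def psi_probs(dm: DesignMatrices, params: ModelParams) -> np.ndarray:
    return expit(dm.X_psi @ params.psi_block())


def theta_probs(dm: DesignMatrices, params: ModelParams) -> np.ndarray:
    return expit(dm.X_theta @ params.theta_block())


def p_probs(dm: DesignMatrices, params: ModelParams) -> np.ndarray:
    return expit(dm.X_p @ params.p_block())


# ---------------------------------------------------------------------------
# Marginal likelihood
# ---------------------------------------------------------------------------


def grid_marginal_loglik(
    y,
    subunit_index,
    psi_i: float,
    theta_j,
    p_k,
    n_subunits: int | None = None,
) -> float:
    """Exact log-likelihood of one grid's detection history.

    Marginalizes the latent grid state z and per-subunit states a:

    L = psi * prod_j [ theta_j * prod_k p^y (1-p)^(1-y) + (1-theta_j) * 1{no
    detection in j} ] + (1 - psi) * 1{no detection anywhere}

    Parameters
    ----------
    y : array of 0/1
        Detections for the grid's conducted surveys.
    subunit_index : int array
        Subunit row (0..J-1) of each survey.  Subunits with no conducted
        surveys contribute a factor of 1.
    psi_i, theta_j, p_k
        Probabilities: scalar, per-subunit vector (length J), per-survey
        vector aligned with ``y``.

    Probabilities may touch 0/1 exactly; the result is floored at
    :data:`LOGLIK_FLOOR` instead of returning -inf.
    """
    y = np.asarray(y, dtype=float)
    if y.size and not np.isin(y, (0.0, 1.0)).all():
        raise ValidationError("detections must be 0 or 1 (conducted surveys only)")
    sub = np.asarray(subunit_index, dtype=np.int64)
    theta_j = np.atleast_1d(np.asarray(theta_j, dtype=float))
    p_k = np.broadcast_to(np.asarray(p_k, dtype=float), y.shape)
    J = int(n_subunits) if n_subunits is not None else len(theta_j)

    with np.errstate(divide="ignore"):
        log_p = np.log(p_k)
        log_q = np.log1p(-p_k)
        log_det_terms = np.where(y == 1.0, log_p, log_q)
        log_D = np.bincount(sub, weights=log_det_terms, minlength=J)
        any_det_sub = np.bincount(sub, weights=y, minlength=J) > 0

        log_theta = np.log(theta_j)
        log_1mtheta = np.log1p(-theta_j)
        # per-subunit mixture over a_ij
        branch_a1 = log_theta + log_D
        branch_a0 = np.where(any_det_sub, -np.inf, log_1mtheta)
        log_m = np.logaddexp(branch_a1, branch_a0)

        z1 = np.log(psi_i) + log_m.sum()
        z0 = -np.inf if any_det_sub.any() else np.log1p(-psi_i)
    ll = float(np.logaddexp(z1, z0))
    return max(ll, LOGLIK_FLOOR)


def total_loglik(dm: DesignMatrices, params: ModelParams) -> float:
    """Sum of per-grid marginal log-likelihoods (grids independent)."""
    return loglik_from_vector(dm, params.to_vector())


def loglik_from_vector(dm: DesignMatrices, vec) -> float:
    """Vectorized marginal log-likelihood from a flat coefficient vector.

    Fast path used by the MCMC cross-checks and optimizers; identical in
    value to summing :func:`grid_marginal_loglik` over grids.
    """
    vec = np.asarray(vec, dtype=float)
    s = len(dm.state_levels)
    b_psi, b_theta, b_p = vec[: s + 2], vec[s + 2 : s + 4], vec[s + 4 :]

    eta_p = dm.X_p @ b_p
    sign = 2.0 * dm.y - 1.0
    log_py = log_expit(sign * eta_p)  # log p if y=1, log(1-p) if y=0
    log_D = np.bincount(dm.surv_sub, weights=log_py, minlength=dm.n_subunits)

    eta_t = dm.X_theta @ b_theta
    det_sub = dm.det_sub
    branch_a1 = log_expit(eta_t) + log_D
    branch_a0 = np.where(det_sub, -np.inf, log_expit(-eta_t))
    log_m = np.logaddexp(branch_a1, branch_a0)

    eta_psi = dm.X_psi @ b_psi
    sum_log_m = np.bincount(dm.sub_grid, weights=log_m, minlength=dm.n_grids)
    z1 = log_expit(eta_psi) + sum_log_m
    z0 = np.where(dm.det_grid, -np.inf, log_expit(-eta_psi))
    ll = np.maximum(np.logaddexp(z1, z0), LOGLIK_FLOOR)
    return float(ll.sum())


# ---------------------------------------------------------------------------
# Reparameterization between standardization scales
# ---------------------------------------------------------------------------


def reexpress_params(
    params: ModelParams,
    std_from: dict[str, Standardizer],
    std_to: dict[str, Standardizer],
) -> ModelParams:
    """Map coefficients from one covariate standardization to another.

    The logit-linear predictors are invariant under affine changes of the
    covariate scale once the coefficients are adjusted; for a covariate with
    x_from = c + r * x_to (c = (mu_to - mu_from)/sd_from, r = sd_to/sd_from)
    a linear term b*x_from becomes intercept += b*c, slope = b*r, and the
    day-of-year quadratic b1*x + b2*x^2 becomes

        intercept += b1*c + b2*c^2,  slope = r*(b1 + 2*b2*c),  quad = b2*r^2.

    Needed when comparing simulation-truth coefficients (standardized over
    the full planned schedule) with coefficients fit to removal-censored
    data (standardized over conducted surveys only).
    """

    def _cr(name):
        f, t = std_from[name], std_to[name]
        return (t.mean - f.mean) / f.sd, t.sd / f.sd

    out = ModelParams.from_vector(params.to_vector(), params.state_levels)

    c, r = _cr("neighbors")
    out.psi_state_intercepts = out.psi_state_intercepts + params.beta_neighbors * c
    out.beta_neighbors = params.beta_neighbors * r
    c, r = _cr("developed_prop")
    out.psi_state_intercepts = out.psi_state_intercepts + params.beta_dev_grid * c
    out.beta_dev_grid = params.beta_dev_grid * r

    c, r = _cr("developed_prop_500m")
    out.theta_intercept = params.theta_intercept + params.beta_dev_subunit * c
    out.beta_dev_subunit = params.beta_dev_subunit * r

    c, r = _cr("day_of_year")
    b1, b2 = params.beta_doy, params.beta_doy2
    out.p_intercept = params.p_intercept + b1 * c + b2 * c**2
    out.beta_doy = r * (b1 + 2.0 * b2 * c)
    out.beta_doy2 = b2 * r**2
    return out


def logit_scale(prob: float) -> float:
    """Convenience: probability -> logit (used when specifying intercepts)."""
    return float(logit(prob))
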