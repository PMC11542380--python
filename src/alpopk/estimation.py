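"""Nonlinear mixed-effects estimation by stochastic approximation EM (SAEM).

The statistical model for subject *i*, observation *j*:

    y_ij = f(t_ij; theta_i) + (a + b * f) * eps_ij,     eps_ij ~ N(0, 1)

where ``f`` is the closed-form one-compartment zero-order-absorption model and
``theta_i = (tk0_i, v_i, cl_i)`` arises from diagonal random effects on a
transformed scale ``phi``: log scale for lognormal-kind parameters, natural
scale for normal-kind ones, ``phi_i ~ N(mu, diag(omega^2))``.

SAEM alternates a Metropolis random-walk E-step on each subject's ``phi_i``
(targeting its conditional posterior) with stochastic-approximation updates
of the sufficient statistics and exact M-step updates of ``mu``/``omega``;
the residual-error pair ``(a, b)`` is updated by minimising the approximated
conditional deviance.  The default schedule is 300 exploratory iterations
(step size 1) followed by 200 smoothing iterations (step size 1/k).

The marginal likelihood (OFV = -2 log L) is computed by importance sampling
around each subject's conditional mode; a Laplace approximation of the same
quantity drives the optional Fisher-information standard errors.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy.optimize import least_squares, minimize
from scipy.special import logsumexp

from .pk import _single_dose
from .population import (
    ParameterDistribution,
    PopulationModel,
    residual_sd,
    sample_param_arrays,
)
from .trial import Dataset

__all__ = [
    "SaemSettings",
    "FitResult",
    "DEFAULT_KINDS",
    "KIND_PRESETS",
    "saem_fit",
    "loglikelihood",
    "information_criteria",
    "covariate_screen",
    "gof",
    "vpc",
]

PARAM_NAMES = ("tk0", "v", "cl")

#: transformed-scale convention per occasion (see population module docstring)
KIND_PRESETS: dict[str, dict[str, str]] = {
    "day1": {"tk0": "lognormal", "v": "normal", "cl": "lognormal"},
    "day14": {"tk0": "lognormal", "v": "normal", "cl": "lognormal"},
    "day28": {"tk0": "lognormal", "v": "lognormal", "cl": "lognormal"},
}
DEFAULT_KINDS = KIND_PRESETS["day1"]

_LOG_2PI = math.log(2.0 * math.pi)
_G_FLOOR = 1e-6  # floor on the residual SD inside likelihoods

_COVARIATE_COLUMNS = {"sex": "SEX", "age": "AGE", "weight": "WT", "height": "HT"}


@dataclass(frozen=True)
class SaemSettings:
    """SAEM schedule and Monte-Carlo sizes.

    ``n_exploratory`` iterations use step size 1 (forgetting), then
    ``n_smoothing`` iterations use step size ``1/k`` (averaging);
    ``mcmc_steps`` Metropolis sweeps over the three ``phi`` components are
    run per subject per iteration, with proposal SDs adapted toward a
    30-50 % acceptance rate during the exploratory phase.
    """

    n_exploratory: int = 300
    n_smoothing: int = 200
    mcmc_steps: int = 2
    ll_mc_size: int = 2000
    seed: int = 1234
    initial: Mapping[str, float] | None = None
    omega_floor: float = 1e-6

    def __post_init__(self) -> None:
        for name in ("n_exploratory", "n_smoothing", "mcmc_steps", "ll_mc_size"):
            if getattr(self, name) < 1:
                raise ValueError(f"{name} must be >= 1")


@dataclass
class FitResult:
    """SAEM estimates with uncertainty, likelihood and diagnostics inputs."""

    population: PopulationModel
    kinds: dict[str, str]
    subject_ids: np.ndarray
    eta_modes: np.ndarray  # (n_subjects, 3), transformed scale
    ofv: float | None
    ofv_mc_se: float | None
    aic: float | None
    bic: float | None
    bicc: float | None
    n_subjects: int
    n_obs: int
    converged: bool
    trajectory: dict[str, np.ndarray]
    occasion: str | None = None
    covariate: tuple[str, str] | None = None  # (parameter, covariate)
    beta: float | None = None
    se: dict[str, float] | None = None
    rse: dict[str, float] | None = None

    @property
    def n_params(self) -> int:
        return 8 + (1 if self.covariate is not None else 0)

    def estimates(self) -> dict[str, float]:
        pop = self.population
        out = {
            "tk0": pop.tk0.typical, "v": pop.v.typical, "cl": pop.cl.typical,
            "omega_tk0": pop.tk0.omega, "omega_v": pop.v.omega,
            "omega_cl": pop.cl.omega, "a": pop.err_a, "b": pop.err_b,
        }
        if self.covariate is not None:
            out["beta"] = self.beta
        return out

    def to_dict(self, with_trajectory: bool = False) -> dict:
        d = {
            "population": self.population.to_dict(),
            "kinds": self.kinds,
            "occasion": self.occasion,
            "estimates": self.estimates(),
            "ofv": self.ofv, "ofv_mc_se": self.ofv_mc_se,
            "aic": self.aic, "bic": self.bic, "bicc": self.bicc,
            "n_subjects": self.n_subjects, "n_obs": self.n_obs,
            "converged": bool(self.converged),
            "covariate": list(self.covariate) if self.covariate else None,
            "beta": self.beta,
            "se": self.se, "rse": self.rse,
            "subject_ids": [int(s) for s in self.subject_ids],
            "eta_modes": self.eta_modes.tolist(),
        }
        if with_trajectory:
            d["trajectory"] = {k: v.tolist() for k, v in self.trajectory.items()}
        return d


# ---------------------------------------------------------------------------
# internal problem representation
# ---------------------------------------------------------------------------


class _Problem:
    """Rectangularised view of one occasion's data: per-subject dose, a
    (n, m) time matrix, a (n, m) observation matrix and a validity mask."""

    def __init__(self, data: Dataset, occasion: str | None, kinds: Mapping[str, str]):
        occs = data.occasions
        if occasion is None:
            if len(occs) != 1:
                raise ValueError(f"dataset has occasions {occs}; specify one")
            occasion = occs[0]
        elif occasion not in occs:
            raise ValueError(f"occasion {occasion!r} not in dataset (has {occs})")
        self.occasion = occasion
        self.kinds = dict(kinds)
        self.log_scale = np.array([self.kinds[p] == "lognormal" for p in PARAM_NAMES])

        obs = data.observations(occasion)
        doses = data.doses(occasion)
        ids = obs["ID"].unique()
        if len(ids) < 2:
            raise ValueError("estimation requires >= 2 subjects")
        self.subject_ids = ids
        self.n = len(ids)
        t_list, y_list, d_list = [], [], []
        for sid in ids:
            o = obs[obs["ID"] == sid]
            if len(o) < 4:
                raise ValueError(f"subject {sid}: needs >= 4 observations, has {len(o)}")
            drows = doses[doses["ID"] == sid]
            if len(drows) != 1:
                raise ValueError(
                    f"subject {sid} occasion {occasion}: expected exactly one dose "
                    f"event, found {len(drows)}"
                )
            t_list.append(o["TIME"].to_numpy(float))
            y_list.append(o["DV"].to_numpy(float))
            d_list.append(float(drows["AMT"].iloc[0]))
        m = max(len(t) for t in t_list)
        self.T = np.zeros((self.n, m))
        self.Y = np.zeros((self.n, m))
        self.mask = np.zeros((self.n, m), dtype=bool)
        for i, (t, y) in enumerate(zip(t_list, y_list)):
            self.T[i, : len(t)] = t
            self.Y[i, : len(y)] = y
            self.mask[i, : len(t)] = True
        self.D = np.asarray(d_list)
        self.n_obs = int(self.mask.sum())
        self.cov_df = data.covariates().set_index("ID").loc[ids]

    # -- transforms ------------------------------------------------------
    def to_phi(self, params: np.ndarray) -> np.ndarray:
        return np.where(self.log_scale, np.log(params), params)

    def to_params(self, phi: np.ndarray) -> np.ndarray:
        return np.where(self.log_scale, np.exp(phi), phi)

    def covariate_vector(self, name: str) -> np.ndarray:
        col = _COVARIATE_COLUMNS[name]
        x = self.cov_df[col].to_numpy(float)
        if name == "sex":
            return x
        if np.any(x <= 0):
            raise ValueError(f"covariate {name} must be positive")
        return np.log(x / np.median(x))

    # -- likelihood pieces ----------------------------------------------
    def predict(self, params: np.ndarray) -> np.ndarray:
        """(n, m) predicted concentrations for (n, 3) natural parameters."""
        tk0, v, cl = params[:, 0:1], params[:, 1:2], params[:, 2:3]
        return _single_dose(tk0, cl / v, cl, self.D[:, None], self.T)

    def obs_loglik(self, params: np.ndarray, a: float, b: float) -> np.ndarray:
        """Per-subject observation log-likelihood (length n)."""
        f = self.predict(params)
        g = np.maximum(a + b * f, _G_FLOOR)
        ll = -0.5 * (((self.Y - f) / g) ** 2 + _LOG_2PI) - np.log(g)
        return np.where(self.mask, ll, 0.0).sum(axis=1)

    def prior_loglik(self, phi: np.ndarray, mu_i: np.ndarray, omega: np.ndarray) -> np.ndarray:
        om = np.maximum(omega, _G_FLOOR)
        z = (phi - mu_i) / om
        return (-0.5 * (z**2 + _LOG_2PI) - np.log(om)).sum(axis=1)

    def valid_phi(self, phi: np.ndarray) -> np.ndarray:
        """Normal-kind parameters must stay strictly positive."""
        params = self.to_params(phi)
        return np.all(params > 0, axis=1)


def _initial_values(prob: _Problem, settings: SaemSettings) -> tuple[np.ndarray, np.ndarray, float, float]:
    """Naive pooled nonlinear least squares for typicals + heuristic spreads."""
    init = dict(settings.initial or {})
    t = prob.T[prob.mask]
    y = prob.Y[prob.mask]
    d = np.broadcast_to(prob.D[:, None], prob.T.shape)[prob.mask]

    if all(k in init for k in PARAM_NAMES):
        typ = np.array([init[k] for k in PARAM_NAMES], float)
    else:
        def resid(theta):
            tk0, v, cl = theta
            return _single_dose(tk0, cl / v, cl, d, t) - y

        try:
            sol = least_squares(
                resid, x0=np.array([1.0, 30.0, 15.0]),
                bounds=([0.05, 1.0, 0.5], [8.0, 500.0, 200.0]),
            )
            typ = sol.x
        except Exception:  # pragma: no cover - defensive fallback
            typ = np.array([1.0, 30.0, 15.0])

    omega = np.array(
        [
            init.get(f"omega_{p}", 0.3 if prob.kinds[p] == "lognormal" else 0.3 * typ[j])
            for j, p in enumerate(PARAM_NAMES)
        ]
    )
    a = float(init.get("a", max(0.1 * float(np.mean(y)), 1e-3)))
    b = float(init.get("b", 0.2))
    return typ, omega, a, b


def _update_error(F, R, mask, log_ab):
    """Minimise the approximated conditional deviance in (log a, log b)."""
    Fm, Rm = F[mask], R[mask]

    def q(x):
        a, b = np.exp(np.clip(x, -30.0, 10.0))
        g = np.maximum(a + b * Fm, _G_FLOOR)
        return float(np.sum(2.0 * np.log(g) + Rm / g**2))

    sol = minimize(q, log_ab, method="Nelder-Mead",
                   options={"maxiter": 40, "xatol": 1e-4, "fatol": 1e-6})
    return np.clip(sol.x, -30.0, 10.0)


def saem_fit(
    data: Dataset,
    occasion: str | None = None,
    kinds: Mapping[str, str] | None = None,
    settings: SaemSettings | None = None,
    covariate: tuple[str, str] | None = None,
    compute_ll: bool = True,
    compute_se: bool = False,
) -> FitResult:
    """Fit the population model to one occasion of a dataset by SAEM.

    Parameters
    ----------
    covariate : (parameter, covariate) pair, optional
        Extends the model with one covariate effect on one parameter's
        transformed-scale mean: ``phi_ik ~ N(mu_k + beta * x_i, omega_k^2)``
        with ``x`` the 0/1 sex indicator or the log-ratio of a continuous
        covariate to its median (a power model on the natural scale).
    """
    settings = settings or SaemSettings()
    prob = _Problem(data, occasion, kinds or KIND_PRESETS.get(
        occasion or (data.occasions[0] if len(data.occasions) == 1 else ""), DEFAULT_KINDS
    ))
    rng = np.random.default_rng(settings.seed)

    x = None
    cov_param_idx = None
    if covariate is not None:
        param, covname = covariate
        if param not in PARAM_NAMES:
            raise ValueError(f"unknown parameter {param!r}")
        cov_param_idx = PARAM_NAMES.index(param)
        x = prob.covariate_vector(covname)
        if np.ptp(x) == 0:
            raise ValueError(f"covariate {covname!r} is constant")

    typ, omega, a, b = _initial_values(prob, settings)
    mu = prob.to_phi(typ[None, :])[0]
    beta = 0.0

    phi = np.tile(mu, (prob.n, 1))
    # proposal SDs live on the phi scale (log units for lognormal kinds,
    # natural units for normal kinds); start at the omega initials
    prop_sd = np.where(prob.log_scale, np.maximum(omega, 0.05),
                       np.maximum(omega, 0.05 * typ)).astype(float)

    H1 = phi.copy()
    H2 = phi**2
    F = prob.predict(prob.to_params(phi))
    R = (prob.Y - F) ** 2
    log_ab = np.log([a, b])

    n_iter = settings.n_exploratory + settings.n_smoothing
    traj = {k: np.empty(n_iter) for k in
            ("tk0", "v", "cl", "omega_tk0", "omega_v", "omega_cl", "a", "b", "beta")}

    def mu_matrix():
        m = np.tile(mu, (prob.n, 1))
        if x is not None:
            m[:, cov_param_idx] += beta * x
        return m

    cur_obs_ll = prob.obs_loglik(prob.to_params(phi), a, b)

    for it in range(n_iter):
        gamma = 1.0 if it < settings.n_exploratory else 1.0 / (it - settings.n_exploratory + 1)
        mu_i = mu_matrix()
        # --- E-step ------------------------------------------------------
        # sweep 1: independence proposals from the current prior (keeps the
        # chain alive even when a random-walk scale has shrunk)
        for k in range(3):
            cand = phi.copy()
            cand[:, k] = mu_i[:, k] + max(omega[k], _G_FLOOR) * rng.standard_normal(prob.n)
            ok = prob.valid_phi(cand)
            cand_obs_ll = np.where(
                ok, prob.obs_loglik(prob.to_params(np.where(ok[:, None], cand, phi)), a, b),
                -np.inf,
            )
            accept = np.log(rng.random(prob.n)) < cand_obs_ll - cur_obs_ll
            phi[accept] = cand[accept]
            cur_obs_ll = np.where(accept, cand_obs_ll, cur_obs_ll)
        # remaining sweeps: componentwise Metropolis random walk
        for _ in range(settings.mcmc_steps):
            for k in range(3):
                cand = phi.copy()
                cand[:, k] += prop_sd[k] * rng.standard_normal(prob.n)
                ok = prob.valid_phi(cand)
                cand_obs_ll = np.where(
                    ok, prob.obs_loglik(prob.to_params(np.where(ok[:, None], cand, phi)), a, b),
                    -np.inf,
                )
                cur_prior = prob.prior_loglik(phi, mu_i, omega)
                cand_prior = prob.prior_loglik(cand, mu_i, omega)
                log_alpha = cand_obs_ll + cand_prior - cur_obs_ll - cur_prior
                accept = np.log(rng.random(prob.n)) < log_alpha
                phi[accept] = cand[accept]
                cur_obs_ll = np.where(accept, cand_obs_ll, cur_obs_ll)
                if it < settings.n_exploratory:
                    rate = float(accept.mean())
                    if rate > 0.5:
                        prop_sd[k] *= 1.15
                    elif rate < 0.3:
                        prop_sd[k] /= 1.15
        # --- stochastic approximation of sufficient statistics ----------
        params_now = prob.to_params(phi)
        f_now = prob.predict(params_now)
        H1 += gamma * (phi - H1)
        H2 += gamma * (phi**2 - H2)
        F += gamma * (f_now - F)
        R += gamma * ((prob.Y - f_now) ** 2 - R)
        # --- M-step ------------------------------------------------------
        if x is None:
            mu = H1.mean(axis=0)
            omega2 = H2.mean(axis=0) - mu**2
        else:
            mu = H1.mean(axis=0)
            omega2 = H2.mean(axis=0) - mu**2
            X = np.column_stack([np.ones(prob.n), x])
            coef, *_ = np.linalg.lstsq(X, H1[:, cov_param_idx], rcond=None)
            mu[cov_param_idx], beta = coef
            pred = X @ coef
            omega2[cov_param_idx] = float(
                np.mean(H2[:, cov_param_idx] - 2.0 * pred * H1[:, cov_param_idx] + pred**2)
            )
        if it < settings.n_exploratory:
            # simulated-annealing guard: omegas may shrink at most 5% per
            # exploratory iteration, preventing premature collapse
            omega2 = np.maximum(omega2, (0.95 * omega) ** 2)
        omega = np.sqrt(np.maximum(omega2, settings.omega_floor**2))
        log_ab = _update_error(F, R, prob.mask, log_ab)
        a, b = np.exp(log_ab)
        cur_obs_ll = prob.obs_loglik(prob.to_params(phi), a, b)

        typ_now = prob.to_params(mu[None, :])[0]
        for j, p in enumerate(PARAM_NAMES):
            traj[p][it] = typ_now[j]
            traj[f"omega_{p}"][it] = omega[j]
        traj["a"][it], traj["b"][it], traj["beta"][it] = a, b, beta

    if np.any(omega <= settings.omega_floor * (1 + 1e-9)):
        warnings.warn("one or more omegas hit the floor (degenerate random effect)",
                      UserWarning, stacklevel=2)

    # convergence: trailing relative dispersion of the smoothing trajectory
    tail = slice(max(0, n_iter - min(50, settings.n_smoothing)), n_iter)
    converged = True
    for k, series in traj.items():
        if k == "beta" and x is None:
            continue
        s = series[tail]
        scale = max(abs(float(np.mean(s))), 1e-6)
        if float(np.std(s)) / scale > 0.05:
            converged = False
    if not converged:
        warnings.warn("SAEM trajectory still moving over the final iterations; "
                      "returning the (possibly unconverged) last estimates",
                      UserWarning, stacklevel=2)

    typ_final = prob.to_params(mu[None, :])[0]
    pop = PopulationModel(
        tk0=ParameterDistribution(typ_final[0], float(omega[0]), prob.kinds["tk0"]),
        v=ParameterDistribution(typ_final[1], float(omega[1]), prob.kinds["v"]),
        cl=ParameterDistribution(typ_final[2], float(omega[2]), prob.kinds["cl"]),
        err_a=float(a), err_b=float(b), label=prob.occasion,
    )

    mu_i = mu_matrix()
    phi_modes = _conditional_modes(prob, mu_i, omega, a, b, start=phi)
    eta_modes = phi_modes - mu_i

    fit = FitResult(
        population=pop, kinds=dict(prob.kinds), subject_ids=prob.subject_ids,
        eta_modes=eta_modes, ofv=None, ofv_mc_se=None, aic=None, bic=None,
        bicc=None, n_subjects=prob.n, n_obs=prob.n_obs, converged=converged,
        trajectory=traj, occasion=prob.occasion,
        covariate=covariate, beta=(float(beta) if x is not None else None),
    )
    if compute_ll:
        ofv, mc_se = loglikelihood(fit, data, mc_size=settings.ll_mc_size,
                                   seed=int(rng.integers(2**31 - 1)))
        fit.ofv, fit.ofv_mc_se = ofv, mc_se
        ic = information_criteria(ofv, fit.n_params, prob.n, prob.n_obs)
        fit.aic, fit.bic, fit.bicc = ic["AIC"], ic["BIC"], ic["BICc"]
    if compute_se:
        fit.se, fit.rse = _fisher_se(fit, prob)
    return fit


def _conditional_modes(prob, mu_i, omega, a, b, start=None):
    """Per-subject MAP of phi given the population parameters."""
    modes = np.empty((prob.n, 3))
    start = start if start is not None else mu_i
    for i in range(prob.n):
        sub = _SubjectView(prob, i)

        def nlp(phi_i):
            if not sub.valid(phi_i):
                return 1e12
            return -(sub.obs_loglik(phi_i, a, b) + sub.prior_loglik(phi_i, mu_i[i], omega))

        sol = minimize(nlp, start[i], method="Nelder-Mead",
                       options={"xatol": 1e-6, "fatol": 1e-9, "maxiter": 400})
        modes[i] = sol.x
    return modes


class _SubjectView:
    """Scalar-subject view of a :class:`_Problem` (for mode finding / IS)."""

    def __init__(self, prob: _Problem, i: int):
        self.prob = prob
        self.t = prob.T[i][prob.mask[i]]
        self.y = prob.Y[i][prob.mask[i]]
        self.d = prob.D[i]
        self.log_scale = prob.log_scale

    def valid(self, phi) -> bool:
        params = np.where(self.log_scale, np.exp(phi), phi)
        return bool(np.all(params > 0) and np.all(np.isfinite(params)))

    def params(self, phi: np.ndarray) -> np.ndarray:
        """phi (..., 3) -> natural params (..., 3)."""
        return np.where(self.log_scale, np.exp(phi), phi)

    def obs_loglik(self, phi, a, b):
        p = np.atleast_2d(self.params(np.asarray(phi, float)))
        tk0, v, cl = p[:, 0:1], p[:, 1:2], p[:, 2:3]
        f = _single_dose(tk0, cl / v, cl, self.d, self.t[None, :])
        g = np.maximum(a + b * f, _G_FLOOR)
        ll = (-0.5 * (((self.y[None, :] - f) / g) ** 2 + _LOG_2PI) - np.log(g)).sum(axis=1)
        return ll if np.asarray(phi).ndim > 1 else float(ll[0])

    def prior_loglik(self, phi, mu_i, omega):
        om = np.maximum(omega, _G_FLOOR)
        z = (np.asarray(phi, float) - mu_i) / om
        ll = (-0.5 * (z**2 + _LOG_2PI) - np.log(om)).sum(axis=-1)
        return ll


def _numeric_hessian(fun, x0, step=1e-4):
    n = len(x0)
    H = np.empty((n, n))
    h = step * np.maximum(np.abs(x0), 1.0)
    f0 = fun(x0)
    for i in range(n):
        for j in range(i, n):
            ei = np.zeros(n); ei[i] = h[i]
            ej = np.zeros(n); ej[j] = h[j]
            if i == j:
                H[i, i] = (fun(x0 + ei) - 2 * f0 + fun(x0 - ei)) / h[i] ** 2
            else:
                H[i, j] = H[j, i] = (
                    fun(x0 + ei + ej) - fun(x0 + ei - ej)
                    - fun(x0 - ei + ej) + fun(x0 - ei - ej)
                ) / (4 * h[i] * h[j])
    return H


def loglikelihood(
    fit: FitResult, data: Dataset, mc_size: int = 10000, seed: int = 0
) -> tuple[float, float]:
    """OFV (-2 log marginal likelihood) by importance sampling.

    A Gaussian proposal is centred on each subject's conditional mode with
    covariance from the numerical Hessian there.  Returns ``(ofv, mc_se)``
    where ``mc_se`` is the delta-method Monte-Carlo standard error of the OFV.
    """
    if mc_size < 100:
        raise ValueError("mc_size must be >= 100")
    prob = _Problem(data, fit.occasion, fit.kinds)
    pop = fit.population
    omega = np.array([pop.tk0.omega, pop.v.omega, pop.cl.omega])
    typ = np.array([pop.tk0.typical, pop.v.typical, pop.cl.typical])
    mu = prob.to_phi(typ[None, :])[0]
    mu_i = np.tile(mu, (prob.n, 1))
    if fit.covariate is not None:
        pidx = PARAM_NAMES.index(fit.covariate[0])
        mu_i[:, pidx] += fit.beta * prob.covariate_vector(fit.covariate[1])
    a, b = pop.err_a, pop.err_b

    start = fit.eta_modes + mu_i if fit.eta_modes.shape == (prob.n, 3) else mu_i
    modes = _conditional_modes(prob, mu_i, omega, a, b, start=start)

    rng = np.random.default_rng(seed)
    ll_total = 0.0
    var_total = 0.0
    for i in range(prob.n):
        sub = _SubjectView(prob, i)

        def nlp(phi_i, _sub=sub, _mu=mu_i[i]):
            if not _sub.valid(phi_i):
                return 1e12
            return -(_sub.obs_loglik(phi_i, a, b) + _sub.prior_loglik(phi_i, _mu, omega))

        H = _numeric_hessian(nlp, modes[i])
        evals, evecs = np.linalg.eigh(0.5 * (H + H.T))
        evals = np.clip(evals, 1e-8, None)
        cov = (evecs / evals) @ evecs.T  # inverse with clipped spectrum
        L = np.linalg.cholesky(cov + 1e-12 * np.eye(3))
        z = rng.standard_normal((mc_size, 3))
        draws = modes[i] + z @ L.T
        logdet = 2.0 * np.sum(np.log(np.diag(L)))
        logq = -0.5 * (z**2).sum(axis=1) - 1.5 * _LOG_2PI - 0.5 * logdet
        valid = np.all(sub.params(draws) > 0, axis=1)
        logjoint = np.full(mc_size, -np.inf)
        if valid.any():
            lj = sub.obs_loglik(draws[valid], a, b) + sub.prior_loglik(
                draws[valid], mu_i[i], omega
            )
            logjoint[valid] = lj
        logw = logjoint - logq
        li = logsumexp(logw) - math.log(mc_size)
        w = np.exp(logw - logw.max())
        mean_w = float(np.mean(w))
        var_li = float(np.var(w)) / (mc_size * mean_w**2)
        ll_total += li
        var_total += var_li
    ofv = -2.0 * ll_total
    return float(ofv), float(2.0 * math.sqrt(var_total))


def laplace_ofv(fit_or_pop, data: Dataset, occasion=None, kinds=None,
                covariate=None, beta=0.0) -> float:
    """Laplace-approximated OFV (deterministic; used for standard errors,
    covariate screening and as an analytic cross-check in the vanishing-omega
    limit)."""
    if isinstance(fit_or_pop, FitResult):
        pop = fit_or_pop.population
        occasion = occasion or fit_or_pop.occasion
        kinds = kinds or fit_or_pop.kinds
        covariate = covariate or fit_or_pop.covariate
        beta = fit_or_pop.beta if fit_or_pop.beta is not None else 0.0
    else:
        pop = fit_or_pop
        kinds = kinds or DEFAULT_KINDS
    prob = _Problem(data, occasion, kinds)
    return _laplace_ofv_arrays(prob, pop, covariate, beta)


def _laplace_ofv_arrays(prob, pop, covariate=None, beta=0.0, shift=None,
                        mode_cache=None):
    """Laplace OFV for population ``pop`` on ``prob``.

    ``shift`` is an optional (n, 3) addition to the per-subject prior means
    (covariate effects); ``mode_cache`` (an (n, 3) array) warm-starts and is
    updated with the per-subject conditional modes, which makes repeated
    evaluations along a profile cheap.
    """
    omega = np.array([pop.tk0.omega, pop.v.omega, pop.cl.omega])
    typ = np.array([pop.tk0.typical, pop.v.typical, pop.cl.typical])
    mu = prob.to_phi(typ[None, :])[0]
    mu_i = np.tile(mu, (prob.n, 1))
    if covariate is not None:
        pidx = PARAM_NAMES.index(covariate[0])
        mu_i[:, pidx] += beta * prob.covariate_vector(covariate[1])
    if shift is not None:
        mu_i = mu_i + shift
    a, b = pop.err_a, pop.err_b
    start = mode_cache if mode_cache is not None else mu_i
    modes = _conditional_modes(prob, mu_i, omega, a, b, start=start)
    if mode_cache is not None:
        mode_cache[:] = modes
    total = 0.0
    for i in range(prob.n):
        sub = _SubjectView(prob, i)

        def nlp(phi_i, _sub=sub, _mu=mu_i[i]):
            if not _sub.valid(phi_i):
                return 1e12
            return -(_sub.obs_loglik(phi_i, a, b) + _sub.prior_loglik(phi_i, _mu, omega))

        H = _numeric_hessian(nlp, modes[i])
        sign, logdet = np.linalg.slogdet(0.5 * (H + H.T))
        if sign <= 0:  # fall back to clipped spectrum
            evals = np.clip(np.linalg.eigvalsh(0.5 * (H + H.T)), 1e-8, None)
            logdet = float(np.sum(np.log(evals)))
        total += -nlp(modes[i]) + 1.5 * _LOG_2PI - 0.5 * logdet
    return float(-2.0 * total)


def _fisher_se(fit: FitResult, prob: _Problem):
    """SEs from the numerical Hessian of the Laplace OFV at the estimates."""
    pop = fit.population
    names = ["tk0", "v", "cl", "omega_tk0", "omega_v", "omega_cl", "a", "b"]
    x0 = np.array([pop.tk0.typical, pop.v.typical, pop.cl.typical,
                   pop.tk0.omega, pop.v.omega, pop.cl.omega,
                   pop.err_a, pop.err_b])

    def ofv_at(x):
        p = PopulationModel(
            tk0=ParameterDistribution(max(x[0], 1e-9), max(x[3], 0.0), pop.tk0.kind),
            v=ParameterDistribution(max(x[1], 1e-9), max(x[4], 0.0), pop.v.kind),
            cl=ParameterDistribution(max(x[2], 1e-9), max(x[5], 0.0), pop.cl.kind),
            err_a=max(x[6], 0.0), err_b=max(x[7], 0.0), label=pop.label,
        )
        return _laplace_ofv_arrays(prob, p, fit.covariate, fit.beta or 0.0)

    H = _numeric_hessian(ofv_at, x0, step=5e-3)
    try:
        cov = 2.0 * np.linalg.pinv(0.5 * (H + H.T))
        se_vals = np.sqrt(np.clip(np.diag(cov), 0.0, None))
    except np.linalg.LinAlgError:  # pragma: no cover
        se_vals = np.full(len(x0), np.nan)
    se = {n: float(s) for n, s in zip(names, se_vals)}
    rse = {n: float(100.0 * s / abs(v)) if v != 0 else float("nan")
           for (n, s), v in zip(se.items(), x0)}
    return se, rse


def information_criteria(
    ofv: float, n_params: int, n_subjects: int, n_obs: int,
    n_random_linked: int | None = None,
) -> dict[str, float]:
    """AIC/BIC/BICc from an OFV.

    ``BICc`` uses the hybrid penalty: parameters tied to random effects
    (typicals + omegas; default ``n_params - 2``, i.e. all but the two
    residual-error coefficients) are penalised by ``ln(n_subjects)``, the
    rest by ``ln(n_obs)``.
    """
    if n_subjects < 1 or n_obs < 1:
        raise ValueError("counts must be >= 1")
    if n_params < 0:
        raise ValueError("n_params must be >= 0")
    k_r = max(n_params - 2, 0) if n_random_linked is None else n_random_linked
    if k_r > n_params:
        raise ValueError("n_random_linked cannot exceed n_params")
    k_f = n_params - k_r
    return {
        "AIC": ofv + 2.0 * n_params,
        "BIC": ofv + n_params * math.log(n_subjects),
        "BICc": ofv + k_r * math.log(n_subjects) + k_f * math.log(n_obs),
    }


def covariate_screen(
    fit: FitResult,
    data: Dataset,
    candidates: Sequence[str] = ("sex", "age", "weight", "height"),
    alpha: float = 0.05,
    familywise: bool = True,
) -> pd.DataFrame:
    """Forward-addition screen of covariate effects on tk0/v/cl.

    Each (covariate, parameter) pair extends the fitted model with one
    coefficient ``beta`` on the parameter's transformed-scale mean (a power
    model on continuous covariates via the centred log-ratio to the median,
    a fractional shift on sex); ``beta`` is profiled by maximising the
    deterministic Laplace marginal likelihood with the base parameters held
    fixed, so the OFV change isolates the covariate term.

    A pair "improves" the model when its OFV drop beats the 1-df chi-square
    critical value at level ``alpha`` — Bonferroni-divided across the tested
    pairs when ``familywise`` is true (the default), so that declaring *any*
    covariate influential has familywise level ``alpha`` — and ``dBIC < 0``.
    ``familywise=False`` applies the per-test threshold (-3.84 at
    alpha = 0.05) instead.
    """
    prob = _Problem(data, fit.occasion, fit.kinds)
    mode_cache = np.tile(
        prob.to_phi(np.array([[fit.population.tk0.typical,
                               fit.population.v.typical,
                               fit.population.cl.typical]]))[0],
        (prob.n, 1),
    ) + fit.eta_modes
    log_n = math.log(fit.n_subjects)
    for cov in candidates:
        if cov not in _COVARIATE_COLUMNS:
            raise ValueError(f"unknown covariate {cov!r}")
    n_tests = sum(
        3 for cov in candidates
        if np.ptp(prob.cov_df[_COVARIATE_COLUMNS[cov]].to_numpy(float)) > 0
    )
    from scipy.stats import chi2 as _chi2
    level = alpha / max(n_tests, 1) if familywise else alpha
    threshold = -float(_chi2.isf(level, 1))

    rows = []
    for cov in candidates:
        if cov not in _COVARIATE_COLUMNS:
            raise ValueError(f"unknown covariate {cov!r}")
        col = _COVARIATE_COLUMNS[cov]
        vals = prob.cov_df[col].to_numpy(float)
        if np.ptp(vals) == 0:
            for param in PARAM_NAMES:
                rows.append({"covariate": cov, "parameter": param, "beta": np.nan,
                             "dofv": np.nan, "dbic": np.nan, "improves": False,
                             "note": "constant covariate; skipped"})
            continue
        x = prob.covariate_vector(cov)
        x = x - x.mean()  # centred: the coefficient is orthogonal to the mean
        for pidx, param in enumerate(PARAM_NAMES):
            # bound the coefficient so the largest per-subject shift stays
            # physiological: 1.5 log units for lognormal kinds, 60% of the
            # typical value for normal kinds (prior means must stay positive)
            typical = fit.population.distributions()[pidx].typical
            max_shift = 1.5 if prob.log_scale[pidx] else 0.6 * typical
            scale = max_shift / float(np.max(np.abs(x)))
            cache = mode_cache.copy()

            def profile(beta_val, _pidx=pidx, _x=x, _cache=cache):
                shift = np.zeros((prob.n, 3))
                shift[:, _pidx] = beta_val * _x
                return _laplace_ofv_arrays(prob, fit.population, shift=shift,
                                           mode_cache=_cache)

            # near-quadratic profile: estimate slope/curvature from a
            # 3-point stencil, jump to the vertex, then re-evaluate the
            # null point with the same (equally refined) mode cache so the
            # difference isolates the covariate term
            h = 0.2 * scale
            f_minus, f_plus = profile(-h), profile(h)
            f_zero = profile(0.0)
            grad = (f_plus - f_minus) / (2 * h)
            curv = (f_plus - 2 * f_zero + f_minus) / h**2
            if curv > 0:
                beta_hat = float(np.clip(-grad / curv, -scale, scale))
            else:  # non-convex stencil: fall back to the better side
                beta_hat = -scale if f_minus < f_plus else scale
            f_hat = profile(beta_hat)
            f_zero = profile(0.0)  # final null evaluation, refined cache
            if f_zero <= f_hat:
                beta_hat, f_hat = 0.0, f_zero
            dofv = min(f_hat - f_zero, 0.0)
            dbic = dofv + log_n
            rows.append({
                "covariate": cov, "parameter": param, "beta": beta_hat,
                "dofv": dofv, "dbic": dbic,
                "improves": bool(dofv < threshold and dbic < 0), "note": "",
            })
    return pd.DataFrame(rows, columns=["covariate", "parameter", "beta",
                                       "dofv", "dbic", "improves", "note"])


def gof(fit: FitResult, data: Dataset) -> pd.DataFrame:
    """Goodness-of-fit table: observed vs population/individual predictions
    and weighted residuals.

    ``IWRES = (y - f_ind) / (a + b * f_ind)`` with individual predictions at
    the conditional modes; population residuals (PWRES here) use the
    typical-parameter predictions in the same way.
    """
    prob = _Problem(data, fit.occasion, fit.kinds)
    pop = fit.population
    typ = np.array([pop.tk0.typical, pop.v.typical, pop.cl.typical])
    mu = prob.to_phi(typ[None, :])[0]
    mu_i = np.tile(mu, (prob.n, 1))
    if fit.covariate is not None:
        pidx = PARAM_NAMES.index(fit.covariate[0])
        mu_i[:, pidx] += (fit.beta or 0.0) * prob.covariate_vector(fit.covariate[1])
    phi_ind = mu_i + fit.eta_modes
    f_ind = prob.predict(prob.to_params(phi_ind))
    f_pop = prob.predict(np.tile(typ, (prob.n, 1)))
    a, b = pop.err_a, pop.err_b
    g_ind = np.maximum(a + b * f_ind, _G_FLOOR)
    g_pop = np.maximum(a + b * f_pop, _G_FLOOR)
    rows = []
    for i, sid in enumerate(prob.subject_ids):
        sel = prob.mask[i]
        rows.append(pd.DataFrame({
            "ID": sid,
            "TIME": prob.T[i][sel],
            "DV": prob.Y[i][sel],
            "PRED_POP": f_pop[i][sel],
            "PRED_IND": f_ind[i][sel],
            "IWRES": ((prob.Y[i] - f_ind[i]) / g_ind[i])[sel],
            "PWRES": ((prob.Y[i] - f_pop[i]) / g_pop[i])[sel],
        }))
    return pd.concat(rows, ignore_index=True)


def vpc(
    fit: FitResult,
    data: Dataset,
    n_replicates: int = 200,
    percentiles: tuple[float, ...] = (5.0, 50.0, 95.0),
    seed: int = 0,
    band: tuple[float, float] = (2.5, 97.5),
) -> pd.DataFrame:
    """Visual-predictive-check table.

    Simulates ``n_replicates`` datasets at the observed design from the
    fitted model, computes each requested percentile per observation-time
    bin per replicate, and reports the across-replicate band of every
    percentile next to the observed percentile and a coverage flag.
    """
    if n_replicates < 100:
        raise ValueError("n_replicates must be >= 100")
    prob = _Problem(data, fit.occasion, fit.kinds)
    rng = np.random.default_rng(seed)
    pop = fit.population
    times = np.unique(prob.T[prob.mask])
    obs_by_bin = [prob.Y[prob.mask & (prob.T == t)] for t in times]

    sim_pct = np.empty((n_replicates, len(times), len(percentiles)))
    for r in range(n_replicates):
        _, params = sample_param_arrays(pop, prob.n, rng)
        f = prob.predict(params)
        y = f + residual_sd(pop, f) * rng.standard_normal(f.shape)
        y = np.maximum(y, 0.0)
        for ti, t in enumerate(times):
            sel = prob.mask & (prob.T == t)
            sim_pct[r, ti] = np.percentile(y[sel], percentiles)

    rows = []
    for ti, t in enumerate(times):
        for pi, pct in enumerate(percentiles):
            lo, mid, hi = np.percentile(sim_pct[:, ti, pi], [band[0], 50.0, band[1]])
            observed = float(np.percentile(obs_by_bin[ti], pct))
            rows.append({
                "time": float(t), "percentile": pct, "observed": observed,
                "sim_lo": float(lo), "sim_median": float(mid), "sim_hi": float(hi),
                "within_band": bool(lo <= observed <= hi),
            })
    return pd.DataFrame(rows)
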