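"""Mixed-effects multinomial logistic model for one stratum.

For a death certificate *i* in a stratum with targets u = 1..U the linear
predictor of target u is

    theta_i[1] = 0                                    (reference category)
    theta_i[u] = alpha[u] + beta[u] * year_i + sum_j gamma[u][j] * M_ij
                 + pi_state[u][s_i] + pi_place[u][p_i] + pi_race[u][r_i]

and the observed target follows Categorical(softmax(theta_i)).  The first
target in canonical cause order is the reference category, so all other
coefficients are log relative-risk ratios (RRRs) against it.  alpha, beta
and gamma are fixed effects with weakly informative Normal(0, 2.5) priors;
the state / place-of-death / race effects are random effects with a shared
scale per factor, sigma_f ~ HalfNormal(1).

Two inference engines share one log-posterior implementation:

* :func:`fit_map` — L-BFGS maximum a posteriori with the random-effect
  scales held fixed (the joint posterior is unbounded as sigma -> 0, the
  usual hierarchical funnel, so scales are not optimized);
* :func:`fit_mcmc` — the in-package No-U-Turn sampler over a non-centred
  parameterization with hierarchical (estimated) scales.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from scipy.optimize import minimize
from scipy.special import logsumexp

from .causes import CauseList, DEFAULT_CAUSE_LIST
from .strata import StratumDataset

FACTORS = ("state", "place", "race")

_HALF_LOG_2PI = 0.5 * np.log(2.0 * np.pi)


@dataclass
class PriorConfig:
    """Prior scales; defaults are weakly informative stand-ins."""

    fixed_scale: float = 2.5       # Normal(0, fixed_scale) on alpha, beta, gamma
    sigma_scale: float = 1.0       # HalfNormal(sigma_scale) on each sigma_f
    map_sigma: dict[str, float] = field(
        default_factory=lambda: {f: 1.0 for f in FACTORS}
    )                              # fixed sigma_f used by the MAP engine

    def __post_init__(self) -> None:
        if self.fixed_scale <= 0 or self.sigma_scale <= 0:
            raise ValueError("prior scales must be positive")
        if any(v <= 0 for v in self.map_sigma.values()):
            raise ValueError("map_sigma values must be positive")


@dataclass
class ModelParameters:
    """Parameters with one column per target; column 0 (reference) is zero."""

    alpha: np.ndarray           # (U,)
    beta: np.ndarray            # (U,)
    gamma: np.ndarray           # (U, J)
    pi_state: np.ndarray        # (U, S)
    pi_place: np.ndarray        # (U, P)
    pi_race: np.ndarray         # (U, R)
    sigma: dict[str, float]     # shared random-effect scale per factor

    def __post_init__(self) -> None:
        for arr in (self.alpha, self.beta, self.gamma,
                    self.pi_state, self.pi_place, self.pi_race):
            if not np.allclose(np.asarray(arr)[0], 0.0):
                raise ValueError("reference-category (first) parameters must be zero")
        if any(v <= 0 for v in self.sigma.values()):
            raise ValueError("sigma must be positive")

    @property
    def n_targets(self) -> int:
        return len(self.alpha)

    @classmethod
    def zeros(cls, U: int, J: int, S: int, P: int, R: int,
              sigma: dict[str, float] | None = None) -> "ModelParameters":
        return cls(
            alpha=np.zeros(U), beta=np.zeros(U), gamma=np.zeros((U, J)),
            pi_state=np.zeros((U, S)), pi_place=np.zeros((U, P)),
            pi_race=np.zeros((U, R)),
            sigma=dict(sigma) if sigma else {f: 1.0 for f in FACTORS},
        )


@dataclass
class FitResult:
    mode: str                              # "MAP" or "MCMC"
    stratum_key: str
    targets: tuple[str, ...]
    params: ModelParameters                # point estimate (posterior mean for MCMC)
    seed: int
    diagnostics: dict = field(default_factory=dict)
    draws: list[ModelParameters] | None = None   # flattened across chains (MCMC)

    def save(self, path: str | Path) -> None:
        payload = {
            "mode": self.mode,
            "stratum_key": self.stratum_key,
            "targets": list(self.targets),
            "seed": self.seed,
            "diagnostics": self.diagnostics,
            "params": {
                "alpha": self.params.alpha.tolist(),
                "beta": self.params.beta.tolist(),
                "gamma": self.params.gamma.tolist(),
                "pi_state": self.params.pi_state.tolist(),
                "pi_place": self.params.pi_place.tolist(),
                "pi_race": self.params.pi_race.tolist(),
                "sigma": self.params.sigma,
            },
        }
        Path(path).write_text(json.dumps(payload, indent=1), encoding="utf-8")


def linear_predictor(
    params: ModelParameters,
    year: np.ndarray,
    M: np.ndarray,
    state_idx: np.ndarray,
    place_idx: np.ndarray,
    race_idx: np.ndarray,
) -> np.ndarray:
    """theta matrix (n, U); first column exactly 0.

    Factor indices beyond the fitted level sets (unseen levels at prediction
    time) contribute 0, the population mean of the random effect.
    """
    year = np.asarray(year, dtype=float)
    M = np.asarray(M, dtype=float)
    if M.shape[1] != params.gamma.shape[1]:
        raise ValueError(
            f"M has {M.shape[1]} causes, gamma expects {params.gamma.shape[1]}"
        )
    theta = (
        params.alpha[None, :]
        + np.outer(year, params.beta)
        + M @ params.gamma.T
    )

    def _re(pi: np.ndarray, idx: np.ndarray) -> np.ndarray:
        idx = np.asarray(idx)
        seen = idx < pi.shape[1]
        out = np.zeros((len(idx), pi.shape[0]))
        out[seen] = pi[:, idx[seen]].T
        return out

    theta += _re(params.pi_state, state_idx)
    theta += _re(params.pi_place, place_idx)
    theta += _re(params.pi_race, race_idx)
    theta[:, 0] = 0.0
    return theta


def class_probabilities(theta: np.ndarray) -> np.ndarray:
    """Numerically stable softmax along the last axis."""
    theta = np.asarray(theta, dtype=float)
    if not np.all(np.isfinite(theta)):
        raise ValueError("non-finite linear predictor")
    shifted = theta - theta.max(axis=-1, keepdims=True)
    e = np.exp(shifted)
    return e / e.sum(axis=-1, keepdims=True)


def _training_features(ds: StratumDataset):
    return ds.year, ds.M, ds.state_idx, ds.place_idx, ds.race_idx


def log_likelihood(params: ModelParameters, ds: StratumDataset) -> float:
    """Sum of categorical log-probabilities over the training set."""
    if ds.n_train == 0:
        raise ValueError("empty training set")
    if ds.y.max() >= params.n_targets:
        raise ValueError("outcome index out of range for parameter dimension")
    theta = linear_predictor(params, *_training_features(ds))
    lse = logsumexp(theta, axis=1)
    return float(np.sum(theta[np.arange(ds.n_train), ds.y] - lse))


def _normal_logpdf(x: np.ndarray, scale: float) -> float:
    x = np.asarray(x, dtype=float)
    return float(np.sum(-0.5 * (x / scale) ** 2 - np.log(scale) - _HALF_LOG_2PI))


def _halfnormal_logpdf(x: float, scale: float) -> float:
    if x <= 0:
        raise ValueError("HalfNormal support is positive")
    return float(np.log(2.0) - 0.5 * (x / scale) ** 2 - np.log(scale) - _HALF_LOG_2PI)


def log_prior(params: ModelParameters, prior: PriorConfig) -> float:
    """Joint log prior over the free (non-reference) parameters.

    alpha, beta, gamma ~ Normal(0, fixed_scale); pi_f ~ Normal(0, sigma_f);
    sigma_f ~ HalfNormal(sigma_scale).
    """
    lp = _normal_logpdf(params.alpha[1:], prior.fixed_scale)
    lp += _normal_logpdf(params.beta[1:], prior.fixed_scale)
    lp += _normal_logpdf(params.gamma[1:], prior.fixed_scale)
    for factor, pi in (("state", params.pi_state),
                       ("place", params.pi_place),
                       ("race", params.pi_race)):
        sig = params.sigma[factor]
        lp += _normal_logpdf(pi[1:], sig)
        lp += _halfnormal_logpdf(sig, prior.sigma_scale)
    return lp


# ---------------------------------------------------------------------------
# Shared log-posterior machinery (flat free-parameter vector, one column per
# non-reference target)
# ---------------------------------------------------------------------------


class _Posterior:
    """Log posterior and gradient over the free parameters of one stratum."""

    def __init__(self, ds: StratumDataset, prior: PriorConfig):
        if ds.n_targets < 2:
            raise ValueError("need at least 2 targets to fit")
        if ds.n_train == 0:
            raise ValueError("empty training set")
        self.ds = ds
        self.prior = prior
        self.U = ds.n_targets
        self.K = self.U - 1
        self.J = ds.M.shape[1]
        self.S = len(ds.state_levels)
        self.P = len(ds.place_levels)
        self.R = len(ds.race_levels)
        self.X = np.column_stack(
            [np.ones(ds.n_train), ds.year, ds.M.astype(float)]
        )  # (n, 2+J)
        self.Y = np.zeros((ds.n_train, self.U))
        self.Y[np.arange(ds.n_train), ds.y] = 1.0
        # slices into the flat vector [alpha beta gamma pi_s pi_p pi_r]
        sizes = [self.K, self.K, self.K * self.J,
                 self.K * self.S, self.K * self.P, self.K * self.R]
        bounds = np.cumsum([0] + sizes)
        self.slices = {
            name: slice(bounds[i], bounds[i + 1])
            for i, name in enumerate(("alpha", "beta", "gamma", "state", "place", "race"))
        }
        self.dim = bounds[-1]

    def unpack(self, v: np.ndarray, sigma: dict[str, float]) -> ModelParameters:
        K, J, S, P, R = self.K, self.J, self.S, self.P, self.R
        get = lambda name, shape: v[self.slices[name]].reshape(shape)
        pad = lambda a: np.vstack([np.zeros((1,) + a.shape[1:]), a])
        return ModelParameters(
            alpha=np.concatenate([[0.0], get("alpha", (K,))]),
            beta=np.concatenate([[0.0], get("beta", (K,))]),
            gamma=pad(get("gamma", (K, J))),
            pi_state=pad(get("state", (K, S))),
            pi_place=pad(get("place", (K, P))),
            pi_race=pad(get("race", (K, R))),
            sigma=dict(sigma),
        )

    def pack(self, params: ModelParameters) -> np.ndarray:
        return np.concatenate(
            [params.alpha[1:], params.beta[1:], params.gamma[1:].ravel(),
             params.pi_state[1:].ravel(), params.pi_place[1:].ravel(),
             params.pi_race[1:].ravel()]
        )

    def loglik_and_grad(self, v: np.ndarray):
        """Categorical log-likelihood and gradient w.r.t. the flat vector."""
        ds, K = self.ds, self.K
        B = np.empty((self.X.shape[1], K))
        B[0] = v[self.slices["alpha"]]
        B[1] = v[self.slices["beta"]]
        B[2:] = v[self.slices["gamma"]].reshape(K, self.J).T
        theta_free = self.X @ B
        for name, idx, n_lvl in (
            ("state", ds.state_idx, self.S),
            ("place", ds.place_idx, self.P),
            ("race", ds.race_idx, self.R),
        ):
            pi = v[self.slices[name]].reshape(K, n_lvl)
            theta_free += pi[:, idx].T
        theta = np.column_stack([np.zeros(ds.n_train), theta_free])
        lse = logsumexp(theta, axis=1)
        ll = float(np.sum(theta[np.arange(ds.n_train), ds.y] - lse))
        P_mat = np.exp(theta - lse[:, None])
        resid = (self.Y - P_mat)[:, 1:]  # (n, K)
        grad = np.empty_like(v)
        gB = self.X.T @ resid            # (2+J, K)
        grad[self.slices["alpha"]] = gB[0]
        grad[self.slices["beta"]] = gB[1]
        grad[self.slices["gamma"]] = gB[2:].T.ravel()
        for name, idx, n_lvl in (
            ("state", ds.state_idx, self.S),
            ("place", ds.place_idx, self.P),
            ("race", ds.race_idx, self.R),
        ):
            acc = np.zeros((n_lvl, K))
            np.add.at(acc, idx, resid)
            grad[self.slices[name]] = acc.T.ravel()
        return ll, grad

    def map_logpost_and_grad(self, v: np.ndarray):
        """Log posterior with sigma fixed at prior.map_sigma (constants dropped)."""
        ll, grad = self.loglik_and_grad(v)
        fs2 = self.prior.fixed_scale**2
        for name in ("alpha", "beta", "gamma"):
            s = self.slices[name]
            ll -= 0.5 * np.sum(v[s] ** 2) / fs2
            grad[s] -= v[s] / fs2
        for name in FACTORS:
            s = self.slices[name]
            sg2 = self.prior.map_sigma[name] ** 2
            ll -= 0.5 * np.sum(v[s] ** 2) / sg2
            grad[s] -= v[s] / sg2
        return ll, grad

    # -- non-centred parameterization for MCMC: v = [fixed..., z..., log_sigma(3)]

    def mcmc_dim(self) -> int:
        return self.dim + 3

    def mcmc_logpost_and_grad(self, w: np.ndarray):
        v = w[: self.dim].copy()
        log_sig = w[self.dim:]
        sig = np.exp(log_sig)
        z = {name: w[self.slices[name]] for name in FACTORS}
        for i, name in enumerate(FACTORS):
            v[self.slices[name]] = sig[i] * z[name]
        ll, grad_v = self.loglik_and_grad(v)
        grad = np.empty_like(w)
        grad[: self.dim] = grad_v
        fs2 = self.prior.fixed_scale**2
        for name in ("alpha", "beta", "gamma"):
            s = self.slices[name]
            ll -= 0.5 * np.sum(w[s] ** 2) / fs2
            grad[s] -= w[s] / fs2
        for i, name in enumerate(FACTORS):
            s = self.slices[name]
            # chain rule: d/dz = sigma * dLL/dpi ; d/dlog_sigma = sum(dLL/dpi * pi)
            grad[self.dim + i] = np.sum(grad_v[s] * sig[i] * z[name])
            grad[s] = sig[i] * grad_v[s] - z[name]
            ll -= 0.5 * np.sum(z[name] ** 2)
        # HalfNormal(sigma_scale) on sigma, with log-transform Jacobian
        ss2 = self.prior.sigma_scale**2
        ll += float(np.sum(-0.5 * sig**2 / ss2 + log_sig))
        grad[self.dim:] += -(sig**2) / ss2 + 1.0
        return ll, grad

    def mcmc_prior_inv_mass(self) -> np.ndarray:
        """Prior marginal variances as the initial diagonal (inverse) mass."""
        m = np.ones(self.mcmc_dim())
        for name in ("alpha", "beta", "gamma"):
            m[self.slices[name]] = self.prior.fixed_scale**2
        return m

    def mcmc_unpack(self, w: np.ndarray) -> ModelParameters:
        v = w[: self.dim].copy()
        sig = np.exp(w[self.dim:])
        for i, name in enumerate(FACTORS):
            v[self.slices[name]] = sig[i] * w[self.slices[name]]
        return self.unpack(v, dict(zip(FACTORS, sig)))


def fit_map(
    ds: StratumDataset,
    prior: PriorConfig | None = None,
    seed: int = 0,
    gtol: float = 1e-6,
    maxiter: int = 2000,
) -> FitResult:
    """Maximum a posteriori fit by L-BFGS with analytic gradients.

    Deterministic: initialization is the zero vector.  Raises on
    non-convergence with the optimizer's diagnostics.
    """
    prior = prior or PriorConfig()
    if not ds.fittable:
        raise ValueError(f"stratum {ds.stratum.key} unfittable: {ds.unfittable_reason}")
    post = _Posterior(ds, prior)

    def objective(v):
        lp, g = post.map_logpost_and_grad(v)
        return -lp, -g

    res = minimize(
        objective, np.zeros(post.dim), jac=True, method="L-BFGS-B",
        options={"maxiter": maxiter, "gtol": gtol, "ftol": 1e-12},
    )
    grad_norm = float(np.max(np.abs(res.jac)))
    if not res.success and grad_norm > 1e-3:
        raise RuntimeError(
            f"MAP optimization failed for {ds.stratum.key}: {res.message} "
            f"(|grad|_inf={grad_norm:.2e})"
        )
    params = post.unpack(res.x, prior.map_sigma)
    return FitResult(
        mode="MAP",
        stratum_key=ds.stratum.key,
        targets=ds.targets,
        params=params,
        seed=seed,
        diagnostics={
            "grad_norm": grad_norm,
            "n_iter": int(res.nit),
            "logpost": -float(res.fun),
            "converged": bool(res.success or grad_norm <= 1e-3),
        },
    )


def fit_mcmc(
    ds: StratumDataset,
    prior: PriorConfig | None = None,
    chains: int = 2,
    warmup: int = 500,
    samples: int = 500,
    seed: int = 0,
    target_accept: float = 0.9,
) -> FitResult:
    """Full-Bayes fit with the in-package No-U-Turn sampler.

    Runs ``chains`` independent chains (seeded from ``seed``), computes
    split-R-hat and bulk ESS with arviz on every free parameter, counts
    divergences, and summarizes the posterior by its mean.  A warning flag is
    set in the diagnostics when any R-hat exceeds 1.01.
    """
    import arviz as az

    from ._nuts import nuts_sample

    prior = prior or PriorConfig()
    if chains < 2:
        raise ValueError("at least 2 chains are required for split-R-hat")
    if not ds.fittable:
        raise ValueError(f"stratum {ds.stratum.key} unfittable: {ds.unfittable_reason}")
    post = _Posterior(ds, prior)

    seeds = np.random.SeedSequence(seed).generate_state(chains) % (2**31)
    chain_draws = []
    divergences = 0
    stats_list = []
    for c in range(chains):
        rng = np.random.default_rng(int(seeds[c]))
        q0 = 0.1 * rng.standard_normal(post.mcmc_dim())
        draws, stats = nuts_sample(
            post.mcmc_logpost_and_grad, q0, warmup, samples,
            seed=int(seeds[c]), target_accept=target_accept,
            init_inv_mass=post.mcmc_prior_inv_mass(),
        )
        chain_draws.append(draws)
        divergences += stats.divergences
        stats_list.append(stats)
    arr = np.stack(chain_draws)  # (chains, samples, dim)

    idata = az.from_dict(posterior={"w": arr})
    rhat = az.rhat(idata, method="split")["w"].values
    rank_rhat = az.rhat(idata, method="rank")["w"].values
    ess = az.ess(idata)["w"].values
    max_rhat = float(np.nanmax(rhat))
    min_ess = float(np.nanmin(ess))

    flat = arr.reshape(-1, arr.shape[-1])
    draw_params = [post.mcmc_unpack(w) for w in flat]
    # posterior-mean parameters on the natural scale
    mean_params = ModelParameters(
        alpha=np.mean([p.alpha for p in draw_params], axis=0),
        beta=np.mean([p.beta for p in draw_params], axis=0),
        gamma=np.mean([p.gamma for p in draw_params], axis=0),
        pi_state=np.mean([p.pi_state for p in draw_params], axis=0),
        pi_place=np.mean([p.pi_place for p in draw_params], axis=0),
        pi_race=np.mean([p.pi_race for p in draw_params], axis=0),
        sigma={
            f: float(np.mean([p.sigma[f] for p in draw_params])) for f in FACTORS
        },
    )
    return FitResult(
        mode="MCMC",
        stratum_key=ds.stratum.key,
        targets=ds.targets,
        params=mean_params,
        seed=seed,
        diagnostics={
            "max_rhat": max_rhat,
            "max_rank_rhat": float(np.nanmax(rank_rhat)),
            "min_ess": min_ess,
            "divergences": int(divergences),
            "rhat_warning": bool(max_rhat > 1.01),
            "step_sizes": [s.step_size for s in stats_list],
            "mean_accept": [s.mean_accept for s in stats_list],
        },
        draws=draw_params,
    )


# ---------------------------------------------------------------------------
# RRR extraction
# ---------------------------------------------------------------------------


def rrr_table(fit: FitResult, cause_list: CauseList = DEFAULT_CAUSE_LIST) -> pd.DataFrame:
    """exp(gamma) as a table: rows = contributing causes, columns = targets.

    The reference target's column is identically 1.  Raw (unclipped) values;
    use :func:`format_rrr_table` for the display convention.
    """
    rrr = np.exp(fit.params.gamma.T)  # (J, U)
    rrr[:, 0] = 1.0
    return pd.DataFrame(
        rrr,
        index=[cause_list.label(c) for c in cause_list.causes],
        columns=[cause_list.label(t) for t in fit.targets],
    )


def format_rrr_table(table: pd.DataFrame, low: float = 0.1, high: float = 10.0) -> pd.DataFrame:
    """Render RRRs in display convention: "1.23x", extremes as "<=0.1x" / ">=10x"."""

    def fmt(v: float) -> str:
        if v <= low:
            return "≤0.1x"
        if v >= high:
            return "≥10x"
        return f"{v:.2f}x"

    return table.map(fmt)
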