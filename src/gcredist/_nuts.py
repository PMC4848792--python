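"""No-U-Turn sampler with dual-averaging step size and adaptive mass matrix.

A self-contained gradient-based sampler for the stratum log-posteriors:
standard NUTS (doubling trajectories, slice-sampling acceptance, U-turn
termination in velocity space) with

* dual-averaging step-size adaptation toward a target acceptance statistic,
* mass-matrix estimation from middle warmup windows — diagonal first, then
  a shrinkage-regularized dense matrix in the final window, which captures
  the posterior correlations (softmax coupling across targets, scale/effect
  coupling in the hierarchical terms) that a diagonal metric cannot,
* divergence detection at an energy-error threshold of 1000.

The interface is a single function taking ``logp_and_grad(q) -> (logp, grad)``.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.linalg import cholesky, solve_triangular

ENERGY_ERROR_THRESHOLD = 1000.0


@dataclass
class SampleStats:
    step_size: float
    divergences: int
    mean_accept: float
    max_depth_hits: int


class _Metric:
    """Euclidean metric; ``cov`` is the inverse mass matrix (posterior cov)."""

    def __init__(self, diag: np.ndarray | None = None, dense: np.ndarray | None = None):
        if dense is not None:
            self.dense = dense
            self.chol = cholesky(dense, lower=True)  # cov = L L^T
            self.diag = None
        else:
            self.diag = np.asarray(diag, dtype=float)
            self.sqrt_diag = np.sqrt(self.diag)
            self.dense = None

    def velocity(self, r: np.ndarray) -> np.ndarray:
        """dq/dt = M^{-1} r."""
        if self.dense is not None:
            return self.dense @ r
        return self.diag * r

    def sample_momentum(self, rng: np.random.Generator, dim: int) -> np.ndarray:
        """r ~ N(0, M); with cov = L L^T, r = L^{-T} xi has cov (L L^T)^{-1}."""
        xi = rng.standard_normal(dim)
        if self.dense is not None:
            return solve_triangular(self.chol, xi, lower=True, trans="T")
        return xi / self.sqrt_diag

    def kinetic(self, r: np.ndarray) -> float:
        return 0.5 * float(np.dot(r, self.velocity(r)))


def _leapfrog(logp_and_grad, q, r, grad, eps, metric):
    r1 = r + 0.5 * eps * grad
    q1 = q + eps * metric.velocity(r1)
    logp1, grad1 = logp_and_grad(q1)
    r1 = r1 + 0.5 * eps * grad1
    return q1, r1, logp1, grad1


def _find_reasonable_step_size(logp_and_grad, q, rng, metric):
    eps = 1.0
    logp, grad = logp_and_grad(q)
    r = metric.sample_momentum(rng, q.size)
    h0 = logp - metric.kinetic(r)

    def h_after(eps):
        _, r1, logp1, _ = _leapfrog(logp_and_grad, q, r, grad, eps, metric)
        h = logp1 - metric.kinetic(r1)
        return h if np.isfinite(h) else -np.inf

    direction = 1.0 if (h_after(eps) - h0) > np.log(0.5) else -1.0
    for _ in range(100):
        eps *= 2.0**direction
        if direction * (h_after(eps) - h0) <= direction * np.log(0.5):
            break
    return eps


class _Tree:
    """One NUTS transition with multinomial (progressive) sampling.

    Leaves carry log weight h - h0; a subtree's proposal is drawn with
    probability proportional to its summed weight.  Recursion depth equals
    tree depth (<= max_depth).
    """

    def __init__(self, logp_and_grad, eps, metric, h0, rng):
        self.f = logp_and_grad
        self.eps = eps
        self.metric = metric
        self.h0 = h0
        self.rng = rng
        self.divergent = False
        self.sum_accept = 0.0
        self.n_leapfrog = 0

    def build(self, q, r, grad, v, depth):
        """Returns (qm, rm, gm, qp, rp, gp, proposal, log_sum_weight, rho, keep_going)."""
        if depth == 0:
            q1, r1, logp1, grad1 = _leapfrog(self.f, q, r, grad, v * self.eps, self.metric)
            h = logp1 - self.metric.kinetic(r1)
            if not np.isfinite(h):
                h = -np.inf
            if self.h0 - h > ENERGY_ERROR_THRESHOLD:
                self.divergent = True
            self.sum_accept += min(1.0, np.exp(h - self.h0))
            self.n_leapfrog += 1
            return q1, r1, grad1, q1, r1, grad1, q1, h - self.h0, r1.copy(), not self.divergent

        qm, rm, gm, qp, rp, gp, qs, lw1, rho1, going = self.build(q, r, grad, v, depth - 1)
        if going:
            if v < 0:
                qm, rm, gm, _, _, _, qs2, lw2, rho2, going2 = self.build(qm, rm, gm, v, depth - 1)
            else:
                _, _, _, qp, rp, gp, qs2, lw2, rho2, going2 = self.build(qp, rp, gp, v, depth - 1)
            lw_tot = np.logaddexp(lw1, lw2)
            if going2 and np.log(self.rng.random()) < lw2 - lw_tot:
                qs = qs2
            lw1 = lw_tot
            rho1 = rho1 + rho2
            going = going2 and self.no_uturn(rho1, rm, rp)
        return qm, rm, gm, qp, rp, gp, qs, lw1, rho1, going

    def no_uturn(self, rho, rm, rp):
        """Momentum-sum U-turn criterion: stop when the trajectory's net
        displacement opposes either end's momentum."""
        return (
            np.dot(rho, self.metric.velocity(rm)) >= 0
            and np.dot(rho, self.metric.velocity(rp)) >= 0
        )


def _shrunk_cov(window: np.ndarray, prior_diag: np.ndarray) -> np.ndarray:
    """Sample covariance shrunk toward its own diagonal plus a prior floor."""
    n_w = len(window)
    cov = np.cov(window, rowvar=False)
    w = n_w / (n_w + 5.0)
    shrunk = w * cov + (1 - w) * np.diag(np.maximum(np.diag(cov), 1e-3 * prior_diag))
    # relative jitter keeps the Cholesky factorization well-posed
    shrunk[np.diag_indices_from(shrunk)] *= 1.0 + 1e-8
    shrunk[np.diag_indices_from(shrunk)] += 1e-10
    return shrunk


def nuts_sample(
    logp_and_grad,
    q0: np.ndarray,
    n_warmup: int,
    n_samples: int,
    seed: int,
    max_depth: int = 10,
    target_accept: float = 0.8,
    init_inv_mass: np.ndarray | None = None,
    dense_mass: bool = False,
):
    """Run one NUTS chain; returns (samples, SampleStats).

    Warmup: the first 15% adapts step size only; positions collected in
    (15%, 45%] refresh a diagonal metric, positions in (45%, 80%] estimate
    the dense metric; the final 20% re-adapts the step size under the final
    metric.  ``init_inv_mass`` seeds the diagonal metric (e.g. prior
    variances).
    """
    rng = np.random.default_rng(seed)
    q = np.array(q0, dtype=float)
    dim = q.size
    prior_diag = (
        np.ones(dim) if init_inv_mass is None else np.asarray(init_inv_mass, dtype=float)
    )
    metric = _Metric(diag=prior_diag)

    eps = _find_reasonable_step_size(logp_and_grad, q, rng, metric)
    mu = np.log(10.0 * eps)
    log_eps_bar, h_bar, t0, gamma, kappa = 0.0, 0.0, 10.0, 0.05, 0.75
    adapt_iter = 0

    # expanding-window schedule: init buffer adapts step size only, then
    # doubling covariance windows, then a terminal step-size buffer
    init_buffer = min(75, max(int(0.15 * n_warmup), 1))
    term_buffer = min(50, max(int(0.10 * n_warmup), 1))
    mass_updates: list[int] = []
    w_start, w_size = init_buffer, 25
    while w_start + w_size < n_warmup - term_buffer:
        if w_start + 3 * w_size >= n_warmup - term_buffer:
            w_size = (n_warmup - term_buffer) - w_start  # extend the last window
        mass_updates.append(w_start + w_size)
        w_start += w_size
        w_size *= 2
    stage_a_end = init_buffer
    stage_b_end = mass_updates[-1] if mass_updates else n_warmup
    window: list[np.ndarray] = []

    samples = np.empty((n_samples, dim))
    divergences = 0
    accept_sum = 0.0
    max_depth_hits = 0
    logp, grad = logp_and_grad(q)

    for m in range(n_warmup + n_samples):
        warming = m < n_warmup
        r0 = metric.sample_momentum(rng, dim)
        h0 = logp - metric.kinetic(r0)

        tree = _Tree(logp_and_grad, eps, metric, h0, rng)
        qm, rm, gm = q.copy(), r0.copy(), grad.copy()
        qp, rp, gp = q.copy(), r0.copy(), grad.copy()
        q_next = q
        rho_total = r0.copy()
        log_sum_w, going, depth = 0.0, True, 0
        while going:
            v = 1 if rng.random() < 0.5 else -1
            if v < 0:
                qm, rm, gm, _, _, _, qs, lw2, rho2, going2 = tree.build(qm, rm, gm, v, depth)
            else:
                _, _, _, qp, rp, gp, qs, lw2, rho2, going2 = tree.build(qp, rp, gp, v, depth)
            if going2:
                # biased progressive sampling favours the fresh subtree
                if lw2 > log_sum_w or np.log(rng.random()) < lw2 - log_sum_w:
                    q_next = qs
                log_sum_w = np.logaddexp(log_sum_w, lw2)
                rho_total += rho2
            going = going2 and tree.no_uturn(rho_total, rm, rp)
            depth += 1
            if depth >= max_depth:
                if not warming:
                    max_depth_hits += 1
                break
        if q_next is not q:
            q = q_next
            logp, grad = logp_and_grad(q)

        accept_stat = tree.sum_accept / max(tree.n_leapfrog, 1)
        if tree.divergent and not warming:
            divergences += 1

        if warming:
            adapt_iter += 1
            frac = 1.0 / (adapt_iter + t0)
            h_bar = (1 - frac) * h_bar + frac * (target_accept - accept_stat)
            log_eps = mu - np.sqrt(adapt_iter) / gamma * h_bar
            eta = adapt_iter**-kappa
            log_eps_bar = eta * log_eps + (1 - eta) * log_eps_bar
            eps = float(np.exp(log_eps))
            if stage_a_end <= m < stage_b_end:
                window.append(q.copy())
            if (m + 1) in mass_updates and len(window) >= 10:
                arr = np.stack(window)
                final_window = (m + 1) == stage_b_end
                if dense_mass and final_window and len(window) > 3:
                    metric = _Metric(dense=_shrunk_cov(arr, prior_diag))
                else:
                    var = np.var(arr, axis=0)
                    n_w = len(window)
                    var = n_w / (n_w + 5.0) * var + 1e-3 * (5.0 / (n_w + 5.0)) * prior_diag
                    metric = _Metric(diag=np.maximum(var, 1e-10))
                window = []
                # restart step-size adaptation under the new metric
                eps = _find_reasonable_step_size(logp_and_grad, q, rng, metric)
                mu = np.log(10.0 * eps)
                log_eps_bar, h_bar, adapt_iter = 0.0, 0.0, 0
            if m == n_warmup - 1:
                eps = float(np.exp(log_eps_bar)) if adapt_iter else eps
        else:
            samples[m - n_warmup] = q
            accept_sum += accept_stat

    stats = SampleStats(
        step_size=eps,
        divergences=divergences,
        mean_accept=accept_sum / max(n_samples, 1),
        max_depth_hits=max_depth_hits,
    )
    return samples, stats
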