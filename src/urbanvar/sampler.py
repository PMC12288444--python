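"""A self-contained No-U-Turn sampler (NUTS) with dual-averaging step-size
adaptation and a warmup-estimated mass matrix (diagonal early, dense once
enough warmup draws have accumulated).

The target is supplied as ``logp_grad(theta) -> (logp, grad)`` on an
unconstrained parameter vector. The implementation follows the classic
slice-variable tree-doubling construction with a configurable maximum tree
depth, and adapts the step size towards a target acceptance statistic. A
dense metric matters here: hierarchical location-scale models put strong
ridge-like correlations between group-level fixed effects and the group
random intercepts, which a diagonal metric cannot absorb.

Chains are run sequentially; a chain's randomness comes from a single
``numpy.random.Generator`` seeded from the run seed, so identical seeds give
identical draws.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass
from typing import Callable

import numpy as np

logger = logging.getLogger("urbanvar")

__all__ = ["nuts_sample", "NUTSStats"]

_DELTA_MAX = 1000.0  # divergence threshold on the joint log density


@dataclass
class NUTSStats:
    step_size: np.ndarray  # per chain, adapted value
    n_divergent: np.ndarray  # per chain, post-warmup divergences
    mean_accept: np.ndarray  # per chain
    max_treedepth_hits: np.ndarray


class _Metric:
    """Mass matrix M: kinetic energy 0.5 p' M^-1 p.

    Diagonal form stores inv_diag = M^-1; dense form stores the Cholesky
    factor L of the (regularised) posterior covariance estimate Sigma with
    M^-1 = Sigma = L L'.
    """

    def __init__(self, dim: int):
        self.dim = dim
        self.inv_diag: np.ndarray | None = np.ones(dim)
        self.chol: np.ndarray | None = None  # L with Sigma = L L'

    def vel(self, p: np.ndarray) -> np.ndarray:
        """M^-1 p (the velocity)."""
        if self.chol is None:
            return self.inv_diag * p
        return self.chol @ (self.chol.T @ p)

    def kinetic(self, p: np.ndarray) -> float:
        if self.chol is None:
            return 0.5 * float(np.dot(p, self.inv_diag * p))
        u = self.chol.T @ p
        return 0.5 * float(u @ u)

    def sample_p(self, rng: np.random.Generator) -> np.ndarray:
        """p ~ N(0, M)."""
        z = rng.standard_normal(self.dim)
        if self.chol is None:
            return z / np.sqrt(self.inv_diag)
        # cov(p) = L'^-1 L^-1 = Sigma^-1
        from scipy.linalg import solve_triangular

        return solve_triangular(self.chol.T, z, lower=False)

    def update_diag(self, var: np.ndarray, n: int) -> None:
        shrunk = (n / (n + 5.0)) * var + (5.0 / (n + 5.0)) * 1e-3
        self.inv_diag = np.maximum(shrunk, 1e-10)
        self.chol = None

    def update_dense(self, cov: np.ndarray, n: int) -> None:
        w = n / (n + 5.0)
        sigma = w * cov + (1.0 - w) * 1e-3 * np.eye(self.dim)
        sigma[np.diag_indices_from(sigma)] += 1e-10
        try:
            self.chol = np.linalg.cholesky(sigma)
            self.inv_diag = None
        except np.linalg.LinAlgError:  # fall back to the diagonal
            self.update_diag(np.diag(cov), n)


def _leapfrog(logp_grad, theta, p, grad, eps, metric: _Metric):
    p = p + 0.5 * eps * grad
    theta = theta + eps * metric.vel(p)
    logp, grad = logp_grad(theta)
    p = p + 0.5 * eps * grad
    return theta, p, logp, grad


def _joint(logp, p, metric: _Metric):
    return logp - metric.kinetic(p) if np.isfinite(logp) else -np.inf


class _Tree:
    __slots__ = (
        "theta_minus", "p_minus", "grad_minus",
        "theta_plus", "p_plus", "grad_plus",
        "theta_prop", "logp_prop", "grad_prop",
        "n_valid", "keep_going", "sum_accept", "n_accept", "divergent",
    )


def _build_tree(logp_grad, theta, p, grad, log_u, direction, depth, eps, joint0, metric, rng):
    """Recursively double the trajectory; returns a _Tree."""
    t = _Tree()
    if depth == 0:
        theta1, p1, logp1, grad1 = _leapfrog(logp_grad, theta, p, grad, direction * eps, metric)
        joint = _joint(logp1, p1, metric)
        t.n_valid = int(log_u <= joint)
        t.divergent = bool(log_u - _DELTA_MAX > joint)
        t.keep_going = not t.divergent
        t.theta_minus = t.theta_plus = t.theta_prop = theta1
        t.p_minus = t.p_plus = p1
        t.grad_minus = t.grad_plus = t.grad_prop = grad1
        t.logp_prop = logp1
        t.sum_accept = min(1.0, math.exp(min(0.0, joint - joint0)))
        t.n_accept = 1
        return t

    t = _build_tree(logp_grad, theta, p, grad, log_u, direction, depth - 1, eps, joint0, metric, rng)
    if t.keep_going:
        if direction == -1:
            t2 = _build_tree(
                logp_grad, t.theta_minus, t.p_minus, t.grad_minus,
                log_u, direction, depth - 1, eps, joint0, metric, rng,
            )
            t.theta_minus, t.p_minus, t.grad_minus = t2.theta_minus, t2.p_minus, t2.grad_minus
        else:
            t2 = _build_tree(
                logp_grad, t.theta_plus, t.p_plus, t.grad_plus,
                log_u, direction, depth - 1, eps, joint0, metric, rng,
            )
            t.theta_plus, t.p_plus, t.grad_plus = t2.theta_plus, t2.p_plus, t2.grad_plus
        total = t.n_valid + t2.n_valid
        if total > 0 and rng.random() < t2.n_valid / total:
            t.theta_prop, t.logp_prop, t.grad_prop = t2.theta_prop, t2.logp_prop, t2.grad_prop
        t.n_valid = total
        t.sum_accept += t2.sum_accept
        t.n_accept += t2.n_accept
        t.divergent = t.divergent or t2.divergent
        dtheta = t.theta_plus - t.theta_minus
        no_uturn = (
            np.dot(dtheta, metric.vel(t.p_minus)) >= 0
            and np.dot(dtheta, metric.vel(t.p_plus)) >= 0
        )
        t.keep_going = t2.keep_going and not t.divergent and no_uturn
    return t


def _find_initial_step(logp_grad, theta, metric, rng):
    eps = 1.0
    logp, grad = logp_grad(theta)
    p = metric.sample_p(rng)
    joint0 = _joint(logp, p, metric)
    _, p1, logp1, _ = _leapfrog(logp_grad, theta, p, grad, eps, metric)
    joint1 = _joint(logp1, p1, metric)
    a = 1.0 if joint1 - joint0 > math.log(0.5) else -1.0
    for _ in range(100):
        eps *= 2.0**a
        _, p1, logp1, _ = _leapfrog(logp_grad, theta, p, grad, eps, metric)
        joint1 = _joint(logp1, p1, metric)
        if a * (joint1 - joint0) <= a * math.log(0.5):
            break
    return eps


class _Welford:
    """Streaming mean/covariance accumulator."""

    def __init__(self, dim: int):
        self.n = 0
        self.mean = np.zeros(dim)
        self.m2 = np.zeros((dim, dim))

    def push(self, x: np.ndarray) -> None:
        self.n += 1
        delta = x - self.mean
        self.mean += delta / self.n
        self.m2 += np.outer(delta, x - self.mean)

    def cov(self) -> np.ndarray:
        return self.m2 / (self.n - 1)


def _run_chain(
    logp_grad: Callable,
    theta0: np.ndarray,
    n_iter: int,
    warmup: int,
    rng: np.random.Generator,
    target_accept: float,
    max_treedepth: int,
):
    dim = theta0.size
    metric = _Metric(dim)
    theta = theta0.copy()
    logp, grad = logp_grad(theta)
    if not np.isfinite(logp):
        raise ValueError("non-finite log density at the initial point")

    eps = _find_initial_step(logp_grad, theta, metric, rng)
    # dual averaging state
    mu = math.log(10.0 * eps)
    log_eps_bar, h_bar = 0.0, 0.0
    gamma, t0, kappa = 0.05, 10.0, 0.75
    adapt_count = 0

    # expanding slow windows for the metric (Stan-style schedule); the
    # terminal buffer is generous so the step size settles after the final
    # metric update
    init_buffer, term_buffer, base_window = 75, 100, 25
    if warmup < 400:
        init_buffer, term_buffer, base_window = max(20, warmup // 5), max(30, warmup // 5), 20
    window_ends: list[int] = []
    if warmup >= init_buffer + term_buffer + base_window:
        pos, w = init_buffer, base_window
        while pos + w < warmup - term_buffer:
            # absorb the tail into the last window if doubling would overrun
            if pos + 3 * w >= warmup - term_buffer:
                w = warmup - term_buffer - pos
            window_ends.append(pos + w)
            pos += w
            w *= 2
    welford = _Welford(dim)
    in_slow = lambda it: window_ends and init_buffer <= it < window_ends[-1]  # noqa: E731

    draws = np.empty((n_iter - warmup, dim))
    n_div = 0
    accept_sum = 0.0
    depth_hits = 0

    for it in range(n_iter):
        p0 = metric.sample_p(rng)
        joint0 = _joint(logp, p0, metric)
        log_u = joint0 + math.log(rng.random())
        tm = tp = theta
        pm = pp = p0
        gm = gp = grad
        depth, n_valid, keep_going = 0, 1, True
        accept_stat, n_accept_stat = 0.0, 0
        while keep_going:
            direction = 1 if rng.random() < 0.5 else -1
            if direction == -1:
                t = _build_tree(logp_grad, tm, pm, gm, log_u, -1, depth, eps, joint0, metric, rng)
                tm, pm, gm = t.theta_minus, t.p_minus, t.grad_minus
            else:
                t = _build_tree(logp_grad, tp, pp, gp, log_u, 1, depth, eps, joint0, metric, rng)
                tp, pp, gp = t.theta_plus, t.p_plus, t.grad_plus
            if t.keep_going and t.n_valid > 0 and rng.random() < t.n_valid / n_valid:
                theta, logp, grad = t.theta_prop, t.logp_prop, t.grad_prop
            n_valid += t.n_valid
            accept_stat += t.sum_accept
            n_accept_stat += t.n_accept
            if t.divergent and it >= warmup:
                n_div += 1
            depth += 1
            dtheta = tp - tm
            keep_going = (
                t.keep_going
                and depth < max_treedepth
                and np.dot(dtheta, metric.vel(pm)) >= 0
                and np.dot(dtheta, metric.vel(pp)) >= 0
            )
            if depth >= max_treedepth:
                depth_hits += 1

        alpha = accept_stat / max(n_accept_stat, 1)
        if it < warmup:
            adapt_count += 1
            frac = 1.0 / (adapt_count + t0)
            h_bar = (1 - frac) * h_bar + frac * (target_accept - alpha)
            log_eps = mu - math.sqrt(adapt_count) / gamma * h_bar
            eta = adapt_count ** (-kappa)
            log_eps_bar = eta * log_eps + (1 - eta) * log_eps_bar
            eps = math.exp(log_eps)
            if in_slow(it):
                welford.push(theta)
            if it + 1 in window_ends and welford.n > 10:
                cov = welford.cov()
                # dense metric once the window supports it, else diagonal
                if welford.n >= max(dim, 100):
                    metric.update_dense(cov, welford.n)
                else:
                    metric.update_diag(np.diag(cov), welford.n)
                welford = _Welford(dim)
                eps = _find_initial_step(logp_grad, theta, metric, rng)
                mu = math.log(10.0 * eps)
                log_eps_bar, h_bar, adapt_count = 0.0, 0.0, 0
            if it == warmup - 1:
                eps = math.exp(log_eps_bar)
        else:
            accept_sum += alpha
            draws[it - warmup] = theta

    return draws, eps, n_div, accept_sum / max(n_iter - warmup, 1), depth_hits


def nuts_sample(
    logp_grad: Callable,
    init: np.ndarray | Callable[[np.random.Generator], np.ndarray],
    dim: int,
    chains: int = 4,
    iterations: int = 2000,
    warmup: int = 1000,
    thin: int = 1,
    seed: int = 0,
    target_accept: float = 0.8,
    max_treedepth: int = 10,
) -> tuple[np.ndarray, NUTSStats]:
    """Sample with NUTS; returns (draws[chains, kept, dim], stats)."""
    if warmup >= iterations:
        raise ValueError("warmup must be < iterations")
    child_seeds = np.random.SeedSequence(seed).spawn(chains)
    all_draws = []
    eps_out = np.zeros(chains)
    div_out = np.zeros(chains, dtype=int)
    acc_out = np.zeros(chains)
    depth_out = np.zeros(chains, dtype=int)
    for ch in range(chains):
        rng = np.random.default_rng(child_seeds[ch])
        theta0 = init(rng) if callable(init) else np.asarray(init, dtype=float)
        draws, eps, ndiv, macc, dhits = _run_chain(
            logp_grad, theta0, iterations, warmup, rng, target_accept, max_treedepth
        )
        all_draws.append(draws[::thin])
        eps_out[ch], div_out[ch], acc_out[ch], depth_out[ch] = eps, ndiv, macc, dhits
        if ndiv > 0:
            logger.warning("chain %d: %d post-warmup divergences", ch, ndiv)
    stats = NUTSStats(eps_out, div_out, acc_out, depth_out)
    return np.stack(all_draws), stats
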