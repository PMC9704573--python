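"""No-U-Turn Hamiltonian Monte Carlo with dual-averaging adaptation.

A self-contained gradient-based MCMC sampler used by the hierarchical
fitting module: the canonical recursive NUTS tree construction with slice
sampling, a diagonal mass matrix estimated during warmup, step size tuned
by dual averaging to a target acceptance statistic, and divergence
counting (a transition is divergent when the Hamiltonian error exceeds
``DIVERGENCE_ENERGY``).

The public entry points are :func:`nuts_sample` (one chain) and
:func:`split_rhat` (the between/within-chain convergence diagnostic).
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass
from typing import Callable, Tuple

import numpy as np

__all__ = ["nuts_sample", "split_rhat", "NutsDiagnostics"]

DIVERGENCE_ENERGY = 1000.0
_LogpGrad = Callable[[np.ndarray], Tuple[float, np.ndarray]]


@dataclass
class NutsDiagnostics:
    n_divergent: int
    step_size: float
    mean_accept: float
    max_treedepth_hits: int


def _leapfrog(logp_grad, theta, p, grad, eps, inv_mass):
    p = p + 0.5 * eps * grad
    theta = theta + eps * inv_mass * p
    logp, grad = logp_grad(theta)
    p = p + 0.5 * eps * grad
    return theta, p, logp, grad


def _kinetic(p, inv_mass):
    return 0.5 * float(np.sum(inv_mass * p * p))


def _find_initial_step(logp_grad, theta, rng, inv_mass, mass):
    """Heuristic: double/halve eps until the one-step accept ratio crosses 1/2."""
    eps = 1.0
    logp, grad = logp_grad(theta)
    p = rng.normal(size=theta.size) * np.sqrt(mass)
    h0 = logp - _kinetic(p, inv_mass)
    _, p1, logp1, _ = _leapfrog(logp_grad, theta, p, grad, eps, inv_mass)
    h1 = logp1 - _kinetic(p1, inv_mass)
    if not np.isfinite(h1):
        h1 = -np.inf
    direction = 1.0 if (h1 - h0) > math.log(0.5) else -1.0
    for _ in range(64):
        eps *= 2.0**direction
        _, p1, logp1, _ = _leapfrog(logp_grad, theta, p, grad, eps, inv_mass)
        h1 = logp1 - _kinetic(p1, inv_mass)
        if not np.isfinite(h1):
            h1 = -np.inf
        if direction * (h1 - h0) <= direction * math.log(0.5):
            break
    return eps


class _Tree:
    """State bundle for recursive tree doubling."""

    __slots__ = (
        "theta_minus", "p_minus", "grad_minus",
        "theta_plus", "p_plus", "grad_plus",
        "theta_prop", "n_valid", "keep_going", "alpha_sum", "n_alpha", "divergent",
    )


def _build_tree(logp_grad, theta, p, grad, log_u, v, depth, eps, h0, inv_mass, rng):
    t = _Tree()
    if depth == 0:
        theta1, p1, logp1, grad1 = _leapfrog(logp_grad, theta, p, grad, v * eps, inv_mass)
        h1 = logp1 - _kinetic(p1, inv_mass)
        if not np.isfinite(h1):
            h1 = -np.inf
        t.divergent = (h0 - h1) > DIVERGENCE_ENERGY if np.isfinite(h1) else True
        t.n_valid = 1 if log_u <= h1 else 0
        t.keep_going = not t.divergent
        t.theta_minus = t.theta_plus = t.theta_prop = theta1
        t.p_minus = t.p_plus = p1
        t.grad_minus = t.grad_plus = grad1
        t.alpha_sum = min(1.0, math.exp(h1 - h0)) if np.isfinite(h1) else 0.0
        t.n_alpha = 1
        return t
    t1 = _build_tree(logp_grad, theta, p, grad, log_u, v, depth - 1, eps, h0, inv_mass, rng)
    t.theta_minus, t.p_minus, t.grad_minus = t1.theta_minus, t1.p_minus, t1.grad_minus
    t.theta_plus, t.p_plus, t.grad_plus = t1.theta_plus, t1.p_plus, t1.grad_plus
    t.theta_prop = t1.theta_prop
    t.n_valid = t1.n_valid
    t.alpha_sum, t.n_alpha = t1.alpha_sum, t1.n_alpha
    t.divergent = t1.divergent
    t.keep_going = t1.keep_going
    if t1.keep_going:
        if v == -1:
            t2 = _build_tree(
                logp_grad, t1.theta_minus, t1.p_minus, t1.grad_minus,
                log_u, v, depth - 1, eps, h0, inv_mass, rng,
            )
            t.theta_minus, t.p_minus, t.grad_minus = t2.theta_minus, t2.p_minus, t2.grad_minus
        else:
            t2 = _build_tree(
                logp_grad, t1.theta_plus, t1.p_plus, t1.grad_plus,
                log_u, v, depth - 1, eps, h0, inv_mass, rng,
            )
            t.theta_plus, t.p_plus, t.grad_plus = t2.theta_plus, t2.p_plus, t2.grad_plus
        total = t1.n_valid + t2.n_valid
        if total > 0 and rng.random() < t2.n_valid / total:
            t.theta_prop = t2.theta_prop
        t.n_valid = total
        t.alpha_sum += t2.alpha_sum
        t.n_alpha += t2.n_alpha
        t.divergent = t1.divergent or t2.divergent
        t.keep_going = t2.keep_going and _no_u_turn(
            t.theta_minus, t.theta_plus, t.p_minus, t.p_plus, inv_mass
        )
    return t


def _no_u_turn(theta_minus, theta_plus, p_minus, p_plus, inv_mass):
    d = theta_plus - theta_minus
    return (d @ (inv_mass * p_minus)) >= 0 and (d @ (inv_mass * p_plus)) >= 0


def nuts_sample(
    logp_grad: _LogpGrad,
    theta0: np.ndarray,
    n_warmup: int,
    n_samples: int,
    rng: np.random.Generator,
    max_treedepth: int = 10,
    target_accept: float = 0.8,
) -> Tuple[np.ndarray, NutsDiagnostics]:
    """Run one NUTS chain; returns post-warmup draws and diagnostics.

    Warmup schedule: dual averaging of the step size throughout, with the
    diagonal mass matrix re-estimated from the draws of a middle window
    (15%..85% of warmup) and the step size re-initialised afterwards.
    Divergences are counted on post-warmup iterations only.
    """
    theta = np.asarray(theta0, dtype=float).copy()
    dim = theta.size
    mass = np.ones(dim)
    inv_mass = 1.0 / mass
    logp, grad = logp_grad(theta)
    if not np.isfinite(logp):
        raise ValueError("initial point has non-finite log density")

    eps = _find_initial_step(logp_grad, theta, rng, inv_mass, mass)
    mu = math.log(10.0 * eps)
    log_eps_bar, h_bar = 0.0, 0.0
    gamma, t0, kappa = 0.05, 10.0, 0.75
    adapt_iter = 0

    win_lo, win_hi = int(0.15 * n_warmup), int(0.85 * n_warmup)
    window: list[np.ndarray] = []

    draws = np.empty((n_samples, dim))
    n_div = 0
    depth_hits = 0
    accept_sum, accept_n = 0.0, 0

    for it in range(n_warmup + n_samples):
        p0 = rng.normal(size=dim) * np.sqrt(mass)
        h0 = logp - _kinetic(p0, inv_mass)
        log_u = h0 + math.log(max(rng.random(), 1e-300))
        theta_minus = theta_plus = theta
        p_minus = p_plus = p0
        grad_minus = grad_plus = grad
        theta_prop = theta
        n_valid = 1
        keep = True
        depth = 0
        alpha_sum, n_alpha = 0.0, 1
        divergent = False
        while keep and depth < max_treedepth:
            v = -1 if rng.random() < 0.5 else 1
            if v == -1:
                t = _build_tree(
                    logp_grad, theta_minus, p_minus, grad_minus,
                    log_u, v, depth, eps, h0, inv_mass, rng,
                )
                theta_minus, p_minus, grad_minus = t.theta_minus, t.p_minus, t.grad_minus
            else:
                t = _build_tree(
                    logp_grad, theta_plus, p_plus, grad_plus,
                    log_u, v, depth, eps, h0, inv_mass, rng,
                )
                theta_plus, p_plus, grad_plus = t.theta_plus, t.p_plus, t.grad_plus
            if t.keep_going and t.n_valid > 0 and rng.random() < min(1.0, t.n_valid / n_valid):
                theta_prop = t.theta_prop
            n_valid += t.n_valid
            alpha_sum, n_alpha = t.alpha_sum, t.n_alpha
            divergent = divergent or t.divergent
            keep = t.keep_going and _no_u_turn(theta_minus, theta_plus, p_minus, p_plus, inv_mass)
            depth += 1
        if depth >= max_treedepth:
            depth_hits += 1
        theta = theta_prop
        logp, grad = logp_grad(theta)
        accept_stat = alpha_sum / max(n_alpha, 1)

        if it < n_warmup:
            adapt_iter += 1
            frac = 1.0 / (adapt_iter + t0)
            h_bar = (1.0 - frac) * h_bar + frac * (target_accept - accept_stat)
            log_eps = mu - math.sqrt(adapt_iter) / gamma * h_bar
            w = adapt_iter ** (-kappa)
            log_eps_bar = w * log_eps + (1.0 - w) * log_eps_bar
            eps = math.exp(log_eps)
            if win_lo <= it < win_hi:
                window.append(theta.copy())
            if it == win_hi - 1 and len(window) >= 10:
                var = np.var(np.asarray(window), axis=0, ddof=1)
                n_w = len(window)
                # Stan-style regularisation toward unit scale
                mass = 1.0 / ((n_w / (n_w + 5.0)) * var + 1e-3 * (5.0 / (n_w + 5.0)))
                inv_mass = 1.0 / mass
                eps = _find_initial_step(logp_grad, theta, rng, inv_mass, mass)
                mu = math.log(10.0 * eps)
                log_eps_bar, h_bar, adapt_iter = 0.0, 0.0, 0
            if it == n_warmup - 1:
                eps = math.exp(log_eps_bar)
        else:
            draws[it - n_warmup] = theta
            accept_sum += accept_stat
            accept_n += 1
            if divergent:
                n_div += 1

    diag = NutsDiagnostics(
        n_divergent=n_div,
        step_size=eps,
        mean_accept=accept_sum / max(accept_n, 1),
        max_treedepth_hits=depth_hits,
    )
    return draws, diag


def split_rhat(chains: np.ndarray) -> float:
    """Split-R-hat of a scalar quantity.

    ``chains`` has shape (n_chains, n_draws). Each chain is split in half,
    then the classic between/within variance ratio is computed. Constant
    chains (zero within-chain variance everywhere) return 1.0 with a
    warning, by convention.
    """
    chains = np.atleast_2d(np.asarray(chains, dtype=float))
    if chains.shape[0] < 2:
        raise ValueError("need at least 2 chains for R-hat")
    n = chains.shape[1]
    half = n // 2
    if half < 2:
        raise ValueError("chains too short to split")
    split = np.concatenate([chains[:, :half], chains[:, n - half:]], axis=0)
    m, n2 = split.shape
    within = split.var(axis=1, ddof=1)
    w = within.mean()
    if w == 0:
        warnings.warn("all chains constant; R-hat undefined, returning 1.0")
        return 1.0
    b = n2 * split.mean(axis=1).var(ddof=1)
    var_hat = (n2 - 1) / n2 * w + b / n2
    return float(np.sqrt(var_hat / w))
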