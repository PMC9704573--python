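"""Exact per-subject likelihood of a trial log under the hybrid agent.

Two routes are provided:

* :func:`negative_log_likelihood` — a readable replay built from the
  agent-module operations, returning per-trial stage-1 and stage-2 terms
  (the reference implementation, used for diagnostics and tests);
* :func:`nll_and_grad` — a numba-compiled kernel returning the total
  negative log-likelihood and its analytic gradient with respect to the
  five parameters, obtained by forward accumulation of the value
  recursion. This is the inner loop of MAP and hierarchical fitting.

Missing trials (any of choice1/choice2/reward absent) contribute no
likelihood term and trigger no value update.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Optional, Tuple

import numpy as np
from numba import njit
from scipy import optimize, special

from .agent import (
    AgentParams,
    AgentState,
    ParameterError,
    compute_mb_values,
    stage1_choice_probs,
    stage2_choice_probs,
    update_stage1_mf,
    update_stage2_value,
)
from .cohort import ConditionLog
from .task import TaskConfig

__all__ = [
    "SubjectLogLik",
    "negative_log_likelihood",
    "nll_and_grad",
    "MapPriors",
    "MapResult",
    "fit_map",
]


@dataclass(frozen=True)
class SubjectLogLik:
    """Total NLL and the per-trial stage-wise terms (NaN where missing)."""

    total_nll: float
    stage1_nll: np.ndarray
    stage2_nll: np.ndarray


def negative_log_likelihood(
    log: ConditionLog, params: AgentParams, config: TaskConfig
) -> SubjectLogLik:
    """Replay a trial log and accumulate -log p of the observed choices."""
    from dataclasses import replace

    n = len(log)
    s1 = np.full(n, np.nan)
    s2n = np.full(n, np.nan)
    state = AgentState.initial()
    valid = log.valid
    for t in range(n):
        if not valid[t]:
            continue
        c1, st2, c2, r = int(log.choice1[t]), int(log.state2[t]), int(log.choice2[t]), int(log.reward[t])
        p1 = stage1_choice_probs(state, params, config.p_common)
        s1[t] = -math.log(p1[c1])
        p2 = stage2_choice_probs(state, st2, params.beta_2)
        s2n[t] = -math.log(p2[c2])
        state = update_stage2_value(state, st2, c2, r, params.alpha, config.delta_rule)
        state = update_stage1_mf(state, c1, r, params.alpha, config.delta_rule)
        state = replace(state, prev_choice=c1)
    total = float(np.nansum(s1) + np.nansum(s2n))
    return SubjectLogLik(total_nll=total, stage1_nll=s1, stage2_nll=s2n)


# ---------------------------------------------------------------------------
# Compiled kernel: NLL + analytic gradient by forward accumulation
# ---------------------------------------------------------------------------

@njit(cache=True)
def _nll_grad_core(c1, s2, c2, rew, valid, alpha, bmb, bmf, b2, rho, p_common, delta_rule):
    q2 = np.full((2, 2), 0.5)
    dq2 = np.zeros((2, 2))  # dQ2/dalpha
    qmf = np.full(2, 0.5)
    dqmf = np.zeros(2)
    prev = -1
    nll = 0.0
    g = np.zeros(5)  # order: alpha, beta_mb, beta_mf, beta_2, rho
    pr = 1.0 - p_common
    for t in range(c1.shape[0]):
        if not valid[t]:
            continue
        a0 = 0 if q2[0, 0] >= q2[0, 1] else 1
        a1 = 0 if q2[1, 0] >= q2[1, 1] else 1
        qmb_l = p_common * q2[0, a0] + pr * q2[1, a1]
        qmb_r = p_common * q2[1, a1] + pr * q2[0, a0]
        dqmb_l = p_common * dq2[0, a0] + pr * dq2[1, a1]
        dqmb_r = p_common * dq2[1, a1] + pr * dq2[0, a0]
        il = 1.0 if prev == 0 else 0.0
        ir = 1.0 if prev == 1 else 0.0
        xl = bmb * qmb_l + bmf * qmf[0] + rho * il
        xr = bmb * qmb_r + bmf * qmf[1] + rho * ir
        m = xl if xl > xr else xr
        el = math.exp(xl - m)
        er = math.exp(xr - m)
        pl = el / (el + er)
        c = c1[t]
        pc = pl if c == 0 else 1.0 - pl
        nll -= math.log(pc)
        e_mb = pl * qmb_l + (1.0 - pl) * qmb_r
        e_mf = pl * qmf[0] + (1.0 - pl) * qmf[1]
        e_i = pl * il + (1.0 - pl) * ir
        e_dmb = pl * dqmb_l + (1.0 - pl) * dqmb_r
        e_dmf = pl * dqmf[0] + (1.0 - pl) * dqmf[1]
        if c == 0:
            g[1] -= qmb_l - e_mb
            g[2] -= qmf[0] - e_mf
            g[4] -= il - e_i
            g[0] -= bmb * (dqmb_l - e_dmb) + bmf * (dqmf[0] - e_dmf)
        else:
            g[1] -= qmb_r - e_mb
            g[2] -= qmf[1] - e_mf
            g[4] -= ir - e_i
            g[0] -= bmb * (dqmb_r - e_dmb) + bmf * (dqmf[1] - e_dmf)
        s = s2[t]
        cc = c2[t]
        y0 = b2 * q2[s, 0]
        y1 = b2 * q2[s, 1]
        m2 = y0 if y0 > y1 else y1
        f0 = math.exp(y0 - m2)
        f1 = math.exp(y1 - m2)
        p0 = f0 / (f0 + f1)
        pc2 = p0 if cc == 0 else 1.0 - p0
        nll -= math.log(pc2)
        e_q = p0 * q2[s, 0] + (1.0 - p0) * q2[s, 1]
        e_dq = p0 * dq2[s, 0] + (1.0 - p0) * dq2[s, 1]
        g[3] -= q2[s, cc] - e_q
        g[0] -= b2 * (dq2[s, cc] - e_dq)
        r = float(rew[t])
        old2 = q2[s, cc]
        oldm = qmf[c]
        if delta_rule:
            q2[s, cc] = old2 + alpha * (r - old2)
            dq2[s, cc] = (1.0 - alpha) * dq2[s, cc] + (r - old2)
            qmf[c] = oldm + alpha * (r - oldm)
            dqmf[c] = (1.0 - alpha) * dqmf[c] + (r - oldm)
        else:
            q2[s, cc] = (1.0 - alpha) * old2 + r
            dq2[s, cc] = (1.0 - alpha) * dq2[s, cc] - old2
            qmf[c] = (1.0 - alpha) * oldm + r
            dqmf[c] = (1.0 - alpha) * dqmf[c] - oldm
        prev = c
    return nll, g


@njit(cache=True)
def _nll_grad_batch(C1, S2, C2, R, V, params, p_common, delta_rule):
    n_sub = C1.shape[0]
    nll = np.empty(n_sub)
    grad = np.empty((n_sub, 5))
    for i in range(n_sub):
        nll[i], grad[i] = _nll_grad_core(
            C1[i], S2[i], C2[i], R[i], V[i],
            params[i, 0], params[i, 1], params[i, 2], params[i, 3], params[i, 4],
            p_common, delta_rule,
        )
    return nll, grad


def _check_params(params: AgentParams) -> None:
    if not (0.0 < params.alpha < 1.0):
        raise ParameterError(f"alpha must be in (0, 1), got {params.alpha}")
    if params.beta_mb < 0 or params.beta_mf < 0:
        raise ParameterError("beta_mb and beta_mf must be non-negative")


def log_arrays(log: ConditionLog) -> Tuple[np.ndarray, ...]:
    """Int64/bool arrays (choice1, state2, choice2, reward, valid) for the kernel."""
    v = log.valid
    return (
        np.ascontiguousarray(log.choice1),
        np.ascontiguousarray(log.state2),
        np.ascontiguousarray(log.choice2),
        np.ascontiguousarray(log.reward),
        np.ascontiguousarray(v),
    )


def nll_and_grad(
    log: ConditionLog, params: AgentParams, config: TaskConfig
) -> Tuple[float, np.ndarray]:
    """Total NLL and its gradient w.r.t. (alpha, beta_mb, beta_mf, beta_2, rho)."""
    _check_params(params)
    c1, s2, c2, r, v = log_arrays(log)
    nll, g = _nll_grad_core(
        c1, s2, c2, r, v,
        params.alpha, params.beta_mb, params.beta_mf, params.beta_2, params.rho,
        config.p_common, config.delta_rule,
    )
    return float(nll), g


# ---------------------------------------------------------------------------
# MAP fitting on the unconstrained scale
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class MapPriors:
    """Independent normal priors on the unconstrained parameters.

    The parameterization is alpha = expit(a), beta_mb = exp(b_mb),
    beta_mf = exp(b_mf), with beta_2 and rho unconstrained, so the prior
    mode (the return value for data carrying no information) is
    alpha = 0.5, beta_mb = beta_mf = 1, beta_2 = rho = 0.
    """

    alpha_scale: float = 2.5
    log_beta_scale: float = 1.5
    beta2_scale: float = 10.0
    rho_scale: float = 10.0

    @property
    def scales(self) -> np.ndarray:
        return np.array(
            [self.alpha_scale, self.log_beta_scale, self.log_beta_scale,
             self.beta2_scale, self.rho_scale]
        )


@dataclass(frozen=True)
class MapResult:
    params: AgentParams
    neg_log_posterior: float
    converged: bool
    n_restarts: int


def unconstrain(params: AgentParams) -> np.ndarray:
    return np.array(
        [
            special.logit(params.alpha),
            np.log(max(params.beta_mb, 1e-10)),
            np.log(max(params.beta_mf, 1e-10)),
            params.beta_2,
            params.rho,
        ]
    )


def constrain(u: np.ndarray) -> AgentParams:
    return AgentParams(
        alpha=float(special.expit(u[0])),
        beta_mb=float(np.exp(u[1])),
        beta_mf=float(np.exp(u[2])),
        beta_2=float(u[3]),
        rho=float(u[4]),
    )


def fit_map(
    log: ConditionLog,
    priors: Optional[MapPriors] = None,
    n_restarts: int = 3,
    rng: Optional[np.random.Generator] = None,
    config: Optional[TaskConfig] = None,
    min_trials: int = 30,
) -> MapResult:
    """Maximum a posteriori fit of one subject-condition trial log.

    Multi-start L-BFGS on the unconstrained scale with analytic gradients;
    the best optimum is returned. Non-convergence of every restart yields
    a flagged result rather than an exception. Logs with fewer than
    ``min_trials`` usable trials are rejected unless fully empty (in which
    case the prior mode is returned).
    """
    priors = priors or MapPriors()
    rng = rng or np.random.default_rng()
    config = config or TaskConfig()
    c1, s2, c2, r, v = log_arrays(log)
    n_usable = int(v.sum())
    if 0 < n_usable < min_trials:
        raise ValueError(f"need at least {min_trials} usable trials, got {n_usable}")
    scales = priors.scales

    def objective(u):
        p = constrain(u)
        if n_usable:
            nll, g = _nll_grad_core(
                c1, s2, c2, r, v, p.alpha, p.beta_mb, p.beta_mf, p.beta_2, p.rho,
                config.p_common, config.delta_rule,
            )
        else:
            nll, g = 0.0, np.zeros(5)
        # chain rule to unconstrained scale
        gu = np.empty(5)
        gu[0] = g[0] * p.alpha * (1.0 - p.alpha)
        gu[1] = g[1] * p.beta_mb
        gu[2] = g[2] * p.beta_mf
        gu[3] = g[3]
        gu[4] = g[4]
        nlp = nll + 0.5 * np.sum((u / scales) ** 2)
        return nlp, gu + u / scales**2

    best = None
    any_ok = False
    starts = [np.zeros(5)] + [rng.normal(0.0, 1.0, size=5) for _ in range(max(0, n_restarts - 1))]
    for u0 in starts:
        res = optimize.minimize(objective, u0, jac=True, method="L-BFGS-B")
        any_ok = any_ok or bool(res.success)
        if best is None or res.fun < best.fun:
            best = res
    return MapResult(
        params=constrain(best.x),
        neg_log_posterior=float(best.fun),
        converged=any_ok,
        n_restarts=len(starts),
    )
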