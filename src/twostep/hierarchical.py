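"""Hierarchical Bayesian estimation of the five agent parameters.

One group x condition cell of subjects is fitted jointly: each subject's
parameters are group mean plus group scale times a subject error
(non-centred parameterization), with

* ``alpha`` built on the unconstrained scale and mapped through the
  inverse logit, group-mean prior Normal(0, 2.5);
* ``beta_mb`` / ``beta_mf`` group means positive (Normal(0, 100)
  truncated at zero, sampled through a log transform) and half-normal
  subject errors, so subject values stay non-negative;
* ``beta_2`` / ``rho`` group means Normal(0, 100) with standard-normal
  subject errors;
* all group scales half-Cauchy(0, 2.5).

Sampling uses the in-package No-U-Turn HMC (:mod:`twostep.hmc`) with the
analytic likelihood gradients of :mod:`twostep.likelihood`. Defaults are
4 chains x 2000 post-warmup draws after 2000 warmup draws; a fit is
flagged unless every split-R-hat is below 1.1 and divergences are rare.
Per-subject posterior means (across chains) are the point estimates used
downstream.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, List, Optional, Sequence

import numpy as np
import pandas as pd
from scipy import special

from .cohort import ConditionLog
from .hmc import NutsDiagnostics, nuts_sample, split_rhat
from .likelihood import _nll_grad_batch, log_arrays
from .task import TaskConfig

__all__ = [
    "PARAM_NAMES",
    "PriorSpec",
    "SamplerConfig",
    "PosteriorSummary",
    "fit_hierarchical",
    "compute_rhat",
]

PARAM_NAMES = ("alpha", "beta_mb", "beta_mf", "beta_2", "rho")
_POSITIVE = (False, True, True, False, False)  # beta_mb, beta_mf group means > 0


@dataclass(frozen=True)
class PriorSpec:
    """Hyperpriors of the hierarchical model."""

    alpha_mean_scale: float = 2.5   # Normal(0, .) on the pre-logit scale
    mean_scale: float = 100.0       # Normal(0, .) for the other four means
    scale_cauchy: float = 2.5       # half-Cauchy(0, .) for all group scales

    def __post_init__(self) -> None:
        if min(self.alpha_mean_scale, self.mean_scale, self.scale_cauchy) <= 0:
            raise ValueError("prior scales must be positive")


@dataclass(frozen=True)
class SamplerConfig:
    """NUTS settings; defaults reproduce the full-scale fitting protocol."""

    n_chains: int = 4
    n_warmup: int = 2000
    n_samples: int = 2000
    rhat_threshold: float = 1.1
    max_treedepth: int = 10
    target_accept: float = 0.8
    max_divergence_frac: float = 0.1
    seed: Optional[int] = None

    def __post_init__(self) -> None:
        if self.n_chains < 2:
            raise ValueError("need at least 2 chains for R-hat")


@dataclass
class PosteriorSummary:
    """Posterior means and diagnostics for one group x condition cell."""

    subject_ids: List[str]
    group: str
    condition: str
    subject_means: np.ndarray          # (n_subjects, 5), constrained scale
    group_mean: Dict[str, float]       # constrained scale
    group_scale: Dict[str, float]
    rhat: Dict[str, float]
    max_rhat: float
    n_divergent: int
    converged: bool
    diagnostics: List[NutsDiagnostics] = field(default_factory=list)

    def to_frame(self) -> pd.DataFrame:
        rows = []
        for i, sid in enumerate(self.subject_ids):
            for k, name in enumerate(PARAM_NAMES):
                rows.append(
                    {
                        "subject_id": sid,
                        "group": self.group,
                        "condition": self.condition,
                        "parameter": name,
                        "posterior_mean": self.subject_means[i, k],
                    }
                )
        return pd.DataFrame(rows)


def compute_rhat(chains: np.ndarray) -> float:
    """Split-R-hat of one scalar quantity across >= 2 equal-length chains."""
    return split_rhat(chains)


def _unpack(theta: np.ndarray, n_sub: int):
    mu = theta[:5]
    log_sigma = theta[5:10]
    eps = theta[10:].reshape(n_sub, 5)
    return mu, log_sigma, eps


def _constrained_subjects(theta: np.ndarray, n_sub: int) -> np.ndarray:
    """Map an unconstrained state vector to (n_sub, 5) constrained params."""
    mu, log_sigma, eps = _unpack(theta, n_sub)
    sigma = np.exp(log_sigma)
    out = np.empty((n_sub, 5))
    # clip matches the likelihood path and keeps alpha strictly inside (0,1)
    out[:, 0] = special.expit(np.clip(mu[0] + sigma[0] * eps[:, 0], -30, 30))
    out[:, 1] = np.exp(mu[1]) + sigma[1] * np.abs(eps[:, 1])
    out[:, 2] = np.exp(mu[2]) + sigma[2] * np.abs(eps[:, 2])
    out[:, 3] = mu[3] + sigma[3] * eps[:, 3]
    out[:, 4] = mu[4] + sigma[4] * eps[:, 4]
    return out


def _group_means_constrained(mu: np.ndarray) -> np.ndarray:
    return np.array(
        [special.expit(mu[0]), np.exp(mu[1]), np.exp(mu[2]), mu[3], mu[4]]
    )


def make_logp_grad(
    logs: Sequence[ConditionLog], priors: PriorSpec, config: TaskConfig
):
    """Log posterior and gradient of one cell as a closure over the data."""
    n_sub = len(logs)
    arrays = [log_arrays(lg) for lg in logs]
    C1 = np.stack([a[0] for a in arrays])
    S2 = np.stack([a[1] for a in arrays])
    C2 = np.stack([a[2] for a in arrays])
    R = np.stack([a[3] for a in arrays])
    V = np.stack([a[4] for a in arrays])
    p_common = config.p_common
    delta_rule = config.delta_rule
    s_alpha2 = priors.alpha_mean_scale**2
    s_mean2 = priors.mean_scale**2
    c_scale = priors.scale_cauchy

    def logp_grad(theta: np.ndarray):
        mu, log_sigma, eps = _unpack(theta, n_sub)
        sigma = np.exp(log_sigma)
        params = np.empty((n_sub, 5))
        a_lin = mu[0] + sigma[0] * eps[:, 0]
        alpha = special.expit(np.clip(a_lin, -30, 30))
        params[:, 0] = alpha
        m_mb, m_mf = np.exp(mu[1]), np.exp(mu[2])
        abs1, abs2 = np.abs(eps[:, 1]), np.abs(eps[:, 2])
        params[:, 1] = m_mb + sigma[1] * abs1
        params[:, 2] = m_mf + sigma[2] * abs2
        params[:, 3] = mu[3] + sigma[3] * eps[:, 3]
        params[:, 4] = mu[4] + sigma[4] * eps[:, 4]

        nll, g = _nll_grad_batch(C1, S2, C2, R, V, params, p_common, delta_rule)
        logp = -float(nll.sum())
        grad = np.zeros_like(theta)
        g_mu = np.zeros(5)
        g_ls = np.zeros(5)
        g_eps = np.empty((n_sub, 5))

        # likelihood terms, chain rule to the unconstrained scale
        da = g[:, 0] * alpha * (1.0 - alpha)  # dNLL/d(a_lin)
        g_mu[0] = -da.sum()
        g_eps[:, 0] = -da * sigma[0]
        g_ls[0] = -np.sum(da * eps[:, 0]) * sigma[0]

        g_mu[1] = -np.sum(g[:, 1]) * m_mb
        g_eps[:, 1] = -g[:, 1] * sigma[1] * np.sign(eps[:, 1])
        g_ls[1] = -np.sum(g[:, 1] * abs1) * sigma[1]
        g_mu[2] = -np.sum(g[:, 2]) * m_mf
        g_eps[:, 2] = -g[:, 2] * sigma[2] * np.sign(eps[:, 2])
        g_ls[2] = -np.sum(g[:, 2] * abs2) * sigma[2]

        g_mu[3] = -np.sum(g[:, 3])
        g_eps[:, 3] = -g[:, 3] * sigma[3]
        g_ls[3] = -np.sum(g[:, 3] * eps[:, 3]) * sigma[3]
        g_mu[4] = -np.sum(g[:, 4])
        g_eps[:, 4] = -g[:, 4] * sigma[4]
        g_ls[4] = -np.sum(g[:, 4] * eps[:, 4]) * sigma[4]

        # priors: alpha mean on pre-logit scale
        logp += -0.5 * mu[0] ** 2 / s_alpha2
        g_mu[0] += -mu[0] / s_alpha2
        # positive means via log transform (+ Jacobian)
        for k, m in ((1, m_mb), (2, m_mf)):
            logp += -0.5 * m * m / s_mean2 + mu[k]
            g_mu[k] += -m * m / s_mean2 + 1.0
        for k in (3, 4):
            logp += -0.5 * mu[k] ** 2 / s_mean2
            g_mu[k] += -mu[k] / s_mean2
        # half-Cauchy scales (+ Jacobian of exp)
        q = (sigma / c_scale) ** 2
        logp += float(np.sum(-np.log1p(q) + log_sigma))
        g_ls += -2.0 * q / (1.0 + q) + 1.0
        # subject errors (half-normal via |eps| is the same kernel in eps)
        logp += -0.5 * float(np.sum(eps * eps))
        g_eps += -eps

        grad[:5] = g_mu
        grad[5:10] = g_ls
        grad[10:] = g_eps.ravel()
        return logp, grad

    return logp_grad, n_sub


def _initial_state(n_sub: int, rng: np.random.Generator) -> np.ndarray:
    theta = np.empty(10 + 5 * n_sub)
    theta[0] = 0.0 + 0.2 * rng.normal()          # alpha location ~ 0.5
    theta[1] = 0.0 + 0.2 * rng.normal()          # beta_mb mean ~ 1
    theta[2] = 0.0 + 0.2 * rng.normal()
    theta[3] = 0.5 + 0.3 * rng.normal()
    theta[4] = 0.5 + 0.3 * rng.normal()
    theta[5:10] = np.log(0.5) + 0.2 * rng.normal(size=5)
    theta[10:] = 0.1 * rng.normal(size=5 * n_sub)
    return theta


def fit_hierarchical(
    logs: Sequence[ConditionLog],
    priors: Optional[PriorSpec] = None,
    sampler: Optional[SamplerConfig] = None,
    config: Optional[TaskConfig] = None,
    subject_ids: Optional[Sequence[str]] = None,
    group: str = "",
    condition: str = "",
) -> PosteriorSummary:
    """Fit one group x condition cell of trial logs hierarchically.

    Returns per-subject posterior means on the constrained scale together
    with group-level posterior means/scales and convergence diagnostics.
    The result is flagged (``converged=False``) when any split-R-hat
    reaches the threshold or divergences exceed the tolerated fraction.
    """
    if len(logs) < 2:
        raise ValueError("hierarchical fitting needs at least 2 subjects")
    priors = priors or PriorSpec()
    sampler = sampler or SamplerConfig()
    config = config or TaskConfig()
    subject_ids = list(subject_ids or [f"sub-{i + 1:03d}" for i in range(len(logs))])

    logp_grad, n_sub = make_logp_grad(logs, priors, config)
    seed_seq = np.random.SeedSequence(sampler.seed)
    chain_seeds = seed_seq.spawn(sampler.n_chains)

    chain_subject = []   # per chain: (n_samples, n_sub, 5)
    chain_group = []     # per chain: (n_samples, 10) constrained means + scales
    diags = []
    for cs in chain_seeds:
        rng = np.random.default_rng(cs)
        theta0 = _initial_state(n_sub, rng)
        draws, diag = nuts_sample(
            logp_grad,
            theta0,
            sampler.n_warmup,
            sampler.n_samples,
            rng,
            max_treedepth=sampler.max_treedepth,
            target_accept=sampler.target_accept,
        )
        subj = np.empty((draws.shape[0], n_sub, 5))
        grp = np.empty((draws.shape[0], 10))
        for i, th in enumerate(draws):
            subj[i] = _constrained_subjects(th, n_sub)
            grp[i, :5] = _group_means_constrained(th[:5])
            grp[i, 5:] = np.exp(th[5:10])
        chain_subject.append(subj)
        chain_group.append(grp)
        diags.append(diag)

    subj_all = np.stack(chain_subject)   # (chains, draws, n_sub, 5)
    grp_all = np.stack(chain_group)      # (chains, draws, 10)

    rhats: Dict[str, float] = {}
    for k, name in enumerate(PARAM_NAMES):
        rhats[f"mean_{name}"] = split_rhat(grp_all[:, :, k])
        rhats[f"scale_{name}"] = split_rhat(grp_all[:, :, 5 + k])
    subj_rhat = 1.0
    for i in range(n_sub):
        for k in range(5):
            subj_rhat = max(subj_rhat, split_rhat(subj_all[:, :, i, k]))
    rhats["max_subject"] = subj_rhat
    max_rhat = max(rhats.values())

    n_div = sum(d.n_divergent for d in diags)
    total_draws = sampler.n_chains * sampler.n_samples
    converged = (max_rhat < sampler.rhat_threshold) and (
        n_div <= sampler.max_divergence_frac * total_draws
    )

    grp_mean = grp_all.reshape(-1, 10).mean(axis=0)
    return PosteriorSummary(
        subject_ids=subject_ids,
        group=group,
        condition=condition,
        subject_means=subj_all.reshape(-1, n_sub, 5).mean(axis=0),
        group_mean={name: float(grp_mean[k]) for k, name in enumerate(PARAM_NAMES)},
        group_scale={name: float(grp_mean[5 + k]) for k, name in enumerate(PARAM_NAMES)},
        rhat=rhats,
        max_rhat=float(max_rhat),
        n_divergent=int(n_div),
        converged=bool(converged),
        diagnostics=diags,
    )
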