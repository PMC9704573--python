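"""Trial-log containers and the synthetic cohort generator.

A *cohort* is a list of subjects, each with one 150-trial log per
condition (neutral ``NT`` and body-image ``BID``), a group label
(healthy control ``HC`` or eating-disorder ``ED``), a condition order,
and questionnaire/demographic covariates (age, EAT-26, AAI, OCI-R totals).

The generator draws per-subject agent parameters from group x condition
distributions (``beta_mb``/``beta_mf`` truncated-normal at zero, ``alpha``
logit-normal, ``beta_2``/``rho`` normal), simulates the task with the
hybrid agent, and draws covariates with a requested correlation to the
subject's condition effect on model-based weight
(``delta beta_mb = beta_mb(BID) - beta_mb(NT)``) through a Gaussian
copula: a latent standard-normal score mixes the standardised delta with
independent noise and is then mapped to each group's covariate mean/SD.

Default cell means follow the fitted group/condition pattern of the study
population this generator emulates (model-based weight reduced in ED and
further reduced under BID); see ``docs/methods.md`` for the full table
and the rationale for the between-subject SDs.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from typing import Dict, Iterator, List, Optional, Tuple

import numpy as np
import pandas as pd
from scipy import special, stats

from .agent import AgentParams, simulate_condition
from .task import TaskConfig

__all__ = [
    "CONDITIONS",
    "GROUPS",
    "COVARIATES",
    "TrialRecord",
    "ConditionLog",
    "SubjectDataset",
    "CohortSpec",
    "simulate_subject",
    "simulate_cohort",
    "cohort_to_frame",
    "write_cohort_csv",
    "read_cohort_csv",
]

CONDITIONS = ("NT", "BID")
GROUPS = ("HC", "ED")
COVARIATES = ("age", "eat26", "aai", "ocir")

_CHOICE_LABELS = {0: "L", 1: "R", -1: ""}
_STATE_LABELS = {0: "1", 1: "2", -1: ""}


class SpecError(ValueError):
    """Raised for infeasible cohort specifications."""


@dataclass(frozen=True)
class TrialRecord:
    """One trial of one condition (1-based index; -1 encodes missing)."""

    trial: int
    condition: str
    choice1: int
    transition: str
    state2: int
    choice2: int
    reward: int


@dataclass
class ConditionLog:
    """Per-trial arrays for one subject-condition (ints, -1 = missing)."""

    choice1: np.ndarray
    transition: np.ndarray  # "common" / "rare" / ""
    state2: np.ndarray
    choice2: np.ndarray
    reward: np.ndarray
    block: np.ndarray

    def __len__(self) -> int:
        return len(self.choice1)

    @property
    def valid(self) -> np.ndarray:
        return (self.choice1 >= 0) & (self.choice2 >= 0) & (self.reward >= 0)

    def records(self, condition: str) -> Iterator[TrialRecord]:
        for t in range(len(self)):
            yield TrialRecord(
                trial=t + 1,
                condition=condition,
                choice1=int(self.choice1[t]),
                transition=str(self.transition[t]),
                state2=int(self.state2[t]),
                choice2=int(self.choice2[t]),
                reward=int(self.reward[t]),
            )


@dataclass
class SubjectDataset:
    """One subject: group, condition order, covariates, and both trial logs."""

    subject_id: str
    group: str
    condition_order: str  # "NT-first" or "BID-first"
    covariates: Dict[str, float]
    trials: Dict[str, ConditionLog]
    true_params: Optional[Dict[str, AgentParams]] = None

    def conditions_in_order(self) -> Tuple[str, ...]:
        return ("NT", "BID") if self.condition_order == "NT-first" else ("BID", "NT")


# Cell means of the generating parameter distributions, by parameter ->
# (group, condition). The pattern encodes a lower model-based weight in the
# ED group and a further reduction under the BID condition.
DEFAULT_CELL_MEANS: Dict[str, Dict[Tuple[str, str], float]] = {
    "beta_mb": {("HC", "NT"): 1.42, ("HC", "BID"): 1.64, ("ED", "NT"): 0.81, ("ED", "BID"): 0.54},
    "beta_mf": {("HC", "NT"): 1.56, ("HC", "BID"): 1.24, ("ED", "NT"): 0.86, ("ED", "BID"): 1.06},
    "alpha": {("HC", "NT"): 0.61, ("HC", "BID"): 0.76, ("ED", "NT"): 0.52, ("ED", "BID"): 0.57},
    "beta_2": {("HC", "NT"): 1.63, ("HC", "BID"): 1.60, ("ED", "NT"): 1.03, ("ED", "BID"): 1.12},
    "rho": {(g, c): 1.0 for g in GROUPS for c in CONDITIONS},
}

# Between-subject SDs (alpha on the logit scale).
DEFAULT_SDS: Dict[str, float] = {
    "beta_mb": 0.96,
    "beta_mf": 0.79,
    "alpha": 0.8,
    "beta_2": 0.68,
    "rho": 0.5,
}

# Covariate (mean, SD) per group, matching the cohort the generator emulates.
DEFAULT_COVARIATE_MOMENTS: Dict[str, Dict[str, Tuple[float, float]]] = {
    "age": {"HC": (26.38, 4.61), "ED": (30.57, 4.45)},
    "eat26": {"HC": (2.94, 2.72), "ED": (25.83, 10.67)},
    "aai": {"HC": (4.59, 2.87), "ED": (23.94, 7.26)},
    "ocir": {"HC": (5.5, 3.59), "ED": (22.83, 11.09)},
}

# Target Pearson correlation between each covariate and delta beta_mb.
DEFAULT_COVARIATE_CORR: Dict[str, float] = {
    "age": -0.147,
    "eat26": -0.312,
    "aai": -0.314,
    "ocir": -0.316,
}


@dataclass
class CohortSpec:
    """Generating distributions for a synthetic cohort."""

    n_per_group: Dict[str, int] = field(default_factory=lambda: {"HC": 32, "ED": 35})
    cell_means: Dict[str, Dict[Tuple[str, str], float]] = field(
        default_factory=lambda: {k: dict(v) for k, v in DEFAULT_CELL_MEANS.items()}
    )
    sds: Dict[str, float] = field(default_factory=lambda: dict(DEFAULT_SDS))
    covariate_moments: Dict[str, Dict[str, Tuple[float, float]]] = field(
        default_factory=lambda: {k: dict(v) for k, v in DEFAULT_COVARIATE_MOMENTS.items()}
    )
    covariate_corr: Dict[str, float] = field(
        default_factory=lambda: dict(DEFAULT_COVARIATE_CORR)
    )

    def __post_init__(self) -> None:
        for cov, r in self.covariate_corr.items():
            if abs(r) > 1:
                raise SpecError(f"requested correlation for {cov!r} is infeasible: {r}")
        for p, sd in self.sds.items():
            if sd < 0:
                raise SpecError(f"negative SD for {p!r}")
        for g, n in self.n_per_group.items():
            if n < 0:
                raise SpecError(f"group {g!r} has negative size")
        if sum(self.n_per_group.values()) < 1:
            raise SpecError("cohort must contain at least one subject")

    def to_json(self) -> str:
        payload = {
            "n_per_group": self.n_per_group,
            "cell_means": {
                p: {f"{g}/{c}": m for (g, c), m in cells.items()}
                for p, cells in self.cell_means.items()
            },
            "sds": self.sds,
            "covariate_moments": self.covariate_moments,
            "covariate_corr": self.covariate_corr,
        }
        return json.dumps(payload, indent=2)

    @classmethod
    def from_json(cls, text: str) -> "CohortSpec":
        payload = json.loads(text)
        cells = {
            p: {tuple(k.split("/")): v for k, v in cellmap.items()}
            for p, cellmap in payload.get("cell_means", {}).items()
        }
        kwargs = {}
        if "n_per_group" in payload:
            kwargs["n_per_group"] = payload["n_per_group"]
        if cells:
            kwargs["cell_means"] = cells
        for k in ("sds", "covariate_corr"):
            if k in payload:
                kwargs[k] = payload[k]
        if "covariate_moments" in payload:
            kwargs["covariate_moments"] = {
                cov: {g: tuple(v) for g, v in per_group.items()}
                for cov, per_group in payload["covariate_moments"].items()
            }
        return cls(**kwargs)


def _draw_params(
    spec: CohortSpec, group: str, condition: str, rng: np.random.Generator
) -> AgentParams:
    cell = (group, condition)
    mu_mb = spec.cell_means["beta_mb"][cell]
    mu_mf = spec.cell_means["beta_mf"][cell]
    beta_mb = _truncnorm_at_zero(mu_mb, spec.sds["beta_mb"], rng)
    beta_mf = _truncnorm_at_zero(mu_mf, spec.sds["beta_mf"], rng)
    loc = special.logit(spec.cell_means["alpha"][cell])
    alpha = float(special.expit(rng.normal(loc, spec.sds["alpha"])))
    alpha = min(max(alpha, 1e-6), 1 - 1e-6)
    beta_2 = float(rng.normal(spec.cell_means["beta_2"][cell], spec.sds["beta_2"]))
    rho = float(rng.normal(spec.cell_means["rho"][cell], spec.sds["rho"]))
    return AgentParams(alpha=alpha, beta_mb=beta_mb, beta_mf=beta_mf, beta_2=beta_2, rho=rho)


def _truncnorm_at_zero(mu: float, sd: float, rng: np.random.Generator) -> float:
    if sd == 0:
        return max(mu, 0.0)
    a = (0.0 - mu) / sd
    return float(stats.truncnorm.rvs(a, np.inf, loc=mu, scale=sd, random_state=rng))


def _log_from_sim(sim: dict) -> ConditionLog:
    return ConditionLog(
        choice1=sim["choice1"].astype(np.int64),
        transition=np.asarray(sim["transition"], dtype=object),
        state2=sim["state2"].astype(np.int64),
        choice2=sim["choice2"].astype(np.int64),
        reward=sim["reward"].astype(np.int64),
        block=sim["block"].astype(np.int64),
    )


def simulate_subject(
    params_per_condition: Dict[str, AgentParams],
    config: TaskConfig,
    condition_order: str,
    rng: np.random.Generator,
    subject_id: str = "sub-001",
    group: str = "HC",
    covariates: Optional[Dict[str, float]] = None,
) -> SubjectDataset:
    """Simulate both conditions for one subject.

    The agent state and the reward walks are re-initialised for each
    condition; conditions are run in the given order so walk realisations
    differ between orders under a shared random stream.
    """
    order = ("NT", "BID") if condition_order == "NT-first" else ("BID", "NT")
    if condition_order not in ("NT-first", "BID-first"):
        raise SpecError(f"unknown condition order {condition_order!r}")
    trials: Dict[str, ConditionLog] = {}
    for cond in order:
        sim = simulate_condition(params_per_condition[cond], config, rng)
        trials[cond] = _log_from_sim(sim)
    return SubjectDataset(
        subject_id=subject_id,
        group=group,
        condition_order=condition_order,
        covariates=dict(covariates or {}),
        trials=trials,
        true_params=dict(params_per_condition),
    )


def simulate_cohort(
    spec: CohortSpec, config: TaskConfig, rng: np.random.Generator
) -> List[SubjectDataset]:
    """Simulate a full cohort with balanced condition order per group.

    Covariates are drawn after all subjects' parameters so that the
    standardised ``delta beta_mb`` can seed the Gaussian copula.
    """
    subjects: List[SubjectDataset] = []
    sid = 0
    for group in GROUPS:
        n = spec.n_per_group.get(group, 0)
        for i in range(n):
            sid += 1
            order = "NT-first" if i < (n + 1) // 2 else "BID-first"
            params = {c: _draw_params(spec, group, c, rng) for c in CONDITIONS}
            subjects.append(
                simulate_subject(
                    params,
                    config,
                    order,
                    rng,
                    subject_id=f"sub-{sid:03d}",
                    group=group,
                    covariates={},
                )
            )
    _attach_covariates(subjects, spec, rng)
    return subjects


def _attach_covariates(
    subjects: List[SubjectDataset], spec: CohortSpec, rng: np.random.Generator
) -> None:
    delta = np.array(
        [s.true_params["BID"].beta_mb - s.true_params["NT"].beta_mb for s in subjects]
    )
    sd = delta.std(ddof=1) if len(delta) > 1 else 0.0
    z = (delta - delta.mean()) / sd if sd > 0 else np.zeros_like(delta)
    for cov in COVARIATES:
        r = spec.covariate_corr.get(cov, 0.0)
        latent = r * z + np.sqrt(1.0 - r * r) * rng.normal(size=len(subjects))
        for s, v in zip(subjects, latent):
            mean, csd = spec.covariate_moments[cov][s.group]
            s.covariates[cov] = float(mean + csd * v)


# ---------------------------------------------------------------------------
# CSV interchange
# ---------------------------------------------------------------------------

CSV_COLUMNS = [
    "subject_id",
    "group",
    "condition",
    "condition_order",
    "block",
    "trial",
    "choice1",
    "transition",
    "state2",
    "choice2",
    "reward",
]


def cohort_to_frame(subjects: List[SubjectDataset]) -> pd.DataFrame:
    """Long-format trial table; missing responses become empty fields."""
    frames = []
    for s in subjects:
        for cond in s.conditions_in_order():
            log = s.trials[cond]
            n = len(log)
            frames.append(
                pd.DataFrame(
                    {
                        "subject_id": s.subject_id,
                        "group": s.group,
                        "condition": cond,
                        "condition_order": s.condition_order,
                        "block": log.block,
                        "trial": np.arange(1, n + 1),
                        "choice1": [_CHOICE_LABELS[int(c)] for c in log.choice1],
                        "transition": log.transition,
                        "state2": [_STATE_LABELS[int(v)] for v in log.state2],
                        "choice2": [_CHOICE_LABELS[int(c)] for c in log.choice2],
                        "reward": ["" if r < 0 else int(r) for r in log.reward],
                    }
                )
            )
    return pd.concat(frames, ignore_index=True)[CSV_COLUMNS]


def write_cohort_csv(subjects: List[SubjectDataset], path) -> None:
    cohort_to_frame(subjects).to_csv(path, index=False)


def covariates_to_frame(subjects: List[SubjectDataset]) -> pd.DataFrame:
    rows = [
        {"subject_id": s.subject_id, "group": s.group, **s.covariates} for s in subjects
    ]
    return pd.DataFrame(rows)


def read_cohort_csv(path, covariates: Optional[pd.DataFrame] = None) -> List[SubjectDataset]:
    """Read trial logs written by :func:`write_cohort_csv`.

    ``covariates`` may be a table with a ``subject_id`` column plus
    covariate columns; values are attached to the matching subjects.
    """
    df = pd.read_csv(path, keep_default_na=False)
    inv_choice = {"L": 0, "R": 1, "": -1}
    inv_state = {"1": 0, "2": 1, "": -1, 1: 0, 2: 1}
    subjects = []
    cov_map = {}
    if covariates is not None:
        for _, row in covariates.iterrows():
            cov_map[str(row["subject_id"])] = {
                k: float(row[k]) for k in covariates.columns if k not in ("subject_id", "group")
            }
    for sid, sub_df in df.groupby("subject_id", sort=False):
        trials: Dict[str, ConditionLog] = {}
        for cond, cdf in sub_df.groupby("condition", sort=False):
            cdf = cdf.sort_values("trial")
            trials[cond] = ConditionLog(
                choice1=np.array([inv_choice[str(v)] for v in cdf["choice1"]], dtype=np.int64),
                transition=cdf["transition"].to_numpy(dtype=object),
                state2=np.array([inv_state[str(v)] for v in cdf["state2"]], dtype=np.int64),
                choice2=np.array([inv_choice[str(v)] for v in cdf["choice2"]], dtype=np.int64),
                reward=np.array(
                    [int(v) if str(v) != "" else -1 for v in cdf["reward"]], dtype=np.int64
                ),
                block=cdf["block"].to_numpy(dtype=np.int64),
            )
        first = sub_df.iloc[0]
        subjects.append(
            SubjectDataset(
                subject_id=str(sid),
                group=str(first["group"]),
                condition_order=str(first["condition_order"]),
                covariates=cov_map.get(str(sid), {}),
                trials=trials,
            )
        )
    return subjects
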