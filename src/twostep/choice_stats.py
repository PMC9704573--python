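"""Model-agnostic choice statistics and regression design construction.

Covers the frequency-based analyses that need no fitted model:

* stay probabilities — the probability of repeating the previous stage-1
  choice, conditioned on the previous trial's reward and transition type;
* the MB score, the double difference
  ``p(stay|rew,common) - p(stay|rew,rare) - p(stay|unrew,common)
  + p(stay|unrew,rare)`` that isolates the model-based reward x
  transition signature;
* the per-subject condition effect on the model-based weight,
  ``delta beta_mb = beta_mb(BID) - beta_mb(NT)`` (negative means the
  body-image condition reduced model-based control);
* the trial-level design matrix for the mixed-effects logistic regression
  of stay on reward (+1/-1), transition (+1/-1), group, condition and
  z-scored age, with per-subject random-effect grouping;
* Pearson correlations of delta beta_mb with covariates.

Stay conditioning is computed within blocks: the first trial after the
mid-condition break has no immediately preceding context and is skipped.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np
import pandas as pd
from scipy import stats

from .cohort import CONDITIONS, ConditionLog, SubjectDataset

__all__ = [
    "StayTable",
    "stay_table",
    "mb_score",
    "delta_beta_mb",
    "build_stay_regression",
    "correlate_delta_with_covariates",
    "stay_tables_frame",
]

# cell order used throughout: (reward, transition)
CELLS = ((1, "common"), (1, "rare"), (0, "common"), (0, "rare"))


@dataclass(frozen=True)
class StayTable:
    """Four conditional stay probabilities with their cell counts.

    ``probs[(reward, transition)]`` is NaN when the cell has no trials.
    """

    probs: Dict[Tuple[int, str], float]
    counts: Dict[Tuple[int, str], int]

    @property
    def complete(self) -> bool:
        return all(np.isfinite(self.probs[c]) for c in CELLS)

    def as_array(self) -> np.ndarray:
        return np.array([self.probs[c] for c in CELLS])


def _stay_pairs(log: ConditionLog):
    """Yield (prev_reward, prev_transition, stayed) for usable trial pairs."""
    valid = log.valid
    for t in range(1, len(log)):
        if log.block[t] != log.block[t - 1]:
            continue  # first trial after the break: no preceding context
        if not (valid[t] and valid[t - 1]):
            continue
        yield int(log.reward[t - 1]), str(log.transition[t - 1]), int(
            log.choice1[t] == log.choice1[t - 1]
        )


def stay_table(log: ConditionLog) -> StayTable:
    """Conditional relative frequencies of repeating the stage-1 choice."""
    if len(log) < 2:
        raise ValueError("need at least 2 trials for stay probabilities")
    stays = {c: 0 for c in CELLS}
    counts = {c: 0 for c in CELLS}
    for r, trans, stayed in _stay_pairs(log):
        counts[(r, trans)] += 1
        stays[(r, trans)] += stayed
    if sum(counts.values()) == 0:
        raise ValueError("no usable trial pairs in log")
    probs = {
        c: (stays[c] / counts[c] if counts[c] > 0 else float("nan")) for c in CELLS
    }
    return StayTable(probs=probs, counts=counts)


def mb_score(table: StayTable) -> float:
    """Double difference of the four stay probabilities; range [-2, 2].

    NaN when any cell is undefined (propagates as missing downstream).
    """
    p = table.probs
    return (
        p[(1, "common")] - p[(1, "rare")] - p[(0, "common")] + p[(0, "rare")]
    )


def delta_beta_mb(beta_bid: float, beta_nt: float) -> float:
    """Condition effect on the model-based weight: BID minus neutral."""
    return beta_bid - beta_nt


def stay_tables_frame(subjects: Sequence[SubjectDataset]) -> pd.DataFrame:
    """Per subject-condition stay probabilities and MB score, long format."""
    rows = []
    for s in subjects:
        for cond in CONDITIONS:
            if cond not in s.trials:
                continue
            tab = stay_table(s.trials[cond])
            row = {
                "subject_id": s.subject_id,
                "group": s.group,
                "condition": cond,
                "mb_score": mb_score(tab),
            }
            for (r, trans) in CELLS:
                row[f"p_stay_{'rew' if r else 'unrew'}_{trans}"] = tab.probs[(r, trans)]
            rows.append(row)
    return pd.DataFrame(rows)


def build_stay_regression(
    subjects: Sequence[SubjectDataset],
    covariates: Optional[pd.DataFrame] = None,
) -> pd.DataFrame:
    """Trial-level design matrix for the stay ~ reward x transition GLMM.

    One row per usable trial pair: ``stay`` in {0,1}; ``reward`` and
    ``transition`` are the previous trial's outcomes coded +1 (rewarded /
    common) and -1; ``group`` and ``condition`` as labels plus 0/1
    indicator columns (``group_ed``, ``condition_bid``); ``age_z`` the
    cohort-z-scored age; ``subject_id`` for random-effect grouping.
    Fitting is left to a standard mixed-model routine.
    """
    ages = {}
    for s in subjects:
        age = s.covariates.get("age")
        if age is None and covariates is not None:
            match = covariates.loc[covariates["subject_id"] == s.subject_id, "age"]
            age = float(match.iloc[0]) if len(match) else None
        ages[s.subject_id] = age
    vals = [a for a in ages.values() if a is not None]
    mu = float(np.mean(vals)) if vals else 0.0
    sd = float(np.std(vals, ddof=1)) if len(vals) > 1 else 1.0
    sd = sd if sd > 0 else 1.0

    rows = []
    for s in subjects:
        age_z = (ages[s.subject_id] - mu) / sd if ages[s.subject_id] is not None else 0.0
        for cond in CONDITIONS:
            if cond not in s.trials:
                raise ValueError(f"subject {s.subject_id} lacks condition {cond!r}")
            for r, trans, stayed in _stay_pairs(s.trials[cond]):
                rows.append(
                    {
                        "subject_id": s.subject_id,
                        "group": s.group,
                        "condition": cond,
                        "group_ed": int(s.group == "ED"),
                        "condition_bid": int(cond == "BID"),
                        "age_z": age_z,
                        "reward": 1 if r == 1 else -1,
                        "transition": 1 if trans == "common" else -1,
                        "stay": stayed,
                    }
                )
    df = pd.DataFrame(rows)
    if len(df):
        bad = set(df["condition"]) - set(CONDITIONS)
        if bad:
            raise ValueError(f"unknown condition labels: {bad}")
    return df


def correlate_delta_with_covariates(
    delta: Sequence[float],
    covariates: pd.DataFrame,
    columns: Optional[Sequence[str]] = None,
) -> pd.DataFrame:
    """Pearson r (and two-sided p) of delta beta_mb with each covariate.

    ``covariates`` holds one row per subject, aligned with ``delta``;
    covariate columns are z-scored before correlating (which leaves r
    unchanged and matches the reporting convention). Zero-variance
    covariates yield NaN with a flag column.
    """
    delta = np.asarray(delta, dtype=float)
    if len(delta) != len(covariates):
        raise ValueError("delta and covariates must align row-wise")
    if len(delta) < 3:
        raise ValueError("need at least 3 complete pairs")
    cols = list(columns) if columns is not None else [
        c for c in covariates.columns if c not in ("subject_id", "group")
    ]
    rows = []
    for c in cols:
        x = covariates[c].to_numpy(dtype=float)
        ok = np.isfinite(x) & np.isfinite(delta)
        defined = ok.sum() >= 3 and np.std(x[ok]) > 0 and np.std(delta[ok]) > 0
        if defined:
            xz = (x[ok] - x[ok].mean()) / x[ok].std(ddof=1)
            r, p = stats.pearsonr(delta[ok], xz)
        else:
            r, p = float("nan"), float("nan")
        rows.append({"covariate": c, "r": r, "p": p, "n": int(ok.sum()), "defined": defined})
    return pd.DataFrame(rows)


def fit_stay_glmm(design: pd.DataFrame):
    """Convenience variational fit of the stay GLMM (statsmodels backend).

    The contractual product is the design matrix from
    :func:`build_stay_regression`; this helper exists so the pipeline can
    report coefficient signs on synthetic cohorts.
    """
    from statsmodels.genmod.bayes_mixed_glm import BinomialBayesMixedGLM  # lazy

    formula = "stay ~ reward * transition * (group_ed * condition_bid + age_z)"

    md = BinomialBayesMixedGLM.from_formula(
        formula, {"sub": "0 + C(subject_id)"}, design
    )
    return md.fit_vb()
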