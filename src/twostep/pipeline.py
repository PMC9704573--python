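"""End-to-end orchestration: simulate/load -> exclude -> analyse -> fit.

``run_pipeline`` composes the package stages into the full analysis of a
cohort: synthetic-cohort simulation (or a loaded trial CSV), data-quality
exclusions, stay probabilities and MB scores, per group x condition
parameter fits, condition effects on the model-based weight and their
covariate correlations, and optionally a parameter-recovery report.
Every output is a CSV/JSON file under the configured directory, and a
manifest records the seed and configuration so any run can be repeated.

The default exclusion thresholds (more than 20% missing trials, or a
stage-1 choice repetition/alternation rate above 95% in any condition)
are package-defined stand-ins for study-specific criteria and are marked
``canonical: false`` in the manifest.
"""

from __future__ import annotations

import dataclasses
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Dict, List, Optional, Tuple

import numpy as np
import pandas as pd

from . import __version__
from .choice_stats import (
    build_stay_regression,
    correlate_delta_with_covariates,
    delta_beta_mb,
    stay_tables_frame,
)
from .cohort import (
    CONDITIONS,
    GROUPS,
    CohortSpec,
    SubjectDataset,
    covariates_to_frame,
    simulate_cohort,
    write_cohort_csv,
)
from .hierarchical import PARAM_NAMES, PriorSpec, SamplerConfig, fit_hierarchical
from .likelihood import MapPriors, fit_map
from .recovery import run_recovery
from .task import TaskConfig

__all__ = ["ExclusionThresholds", "PipelineConfig", "apply_exclusions", "run_pipeline"]

log = logging.getLogger("twostep")


@dataclass(frozen=True)
class ExclusionThresholds:
    """Data-quality screens applied per subject (any condition triggers)."""

    max_missing_frac: float = 0.20
    max_repeat_frac: float = 0.95
    enabled: bool = True


@dataclass
class PipelineConfig:
    task: TaskConfig = field(default_factory=TaskConfig)
    cohort: CohortSpec = field(default_factory=CohortSpec)
    priors: PriorSpec = field(default_factory=PriorSpec)
    sampler: SamplerConfig = field(default_factory=SamplerConfig)
    exclusions: ExclusionThresholds = field(default_factory=ExclusionThresholds)
    fit_method: str = "map"  # "map" or "hierarchical"
    with_recovery: bool = False
    out_dir: str = "twostep_out"
    seed: int = 0


def _stage1_repeat_stats(choice1: np.ndarray) -> Tuple[float, float]:
    c = choice1[choice1 >= 0]
    if len(c) < 2:
        return 0.0, 0.0
    same = np.mean(c[1:] == c[:-1])
    return float(same), float(1.0 - same)


def apply_exclusions(
    subjects: List[SubjectDataset], thresholds: ExclusionThresholds
) -> Tuple[List[SubjectDataset], List[Dict]]:
    """Filter a cohort; every exclusion is logged with its reason."""
    if not thresholds.enabled:
        return list(subjects), []
    kept, excluded = [], []
    for s in subjects:
        reasons = []
        for cond, trials in s.trials.items():
            missing = 1.0 - trials.valid.mean()
            if missing > thresholds.max_missing_frac:
                reasons.append(f"{cond}: {missing:.0%} trials missing")
            rep, alt = _stage1_repeat_stats(trials.choice1)
            if rep > thresholds.max_repeat_frac:
                reasons.append(f"{cond}: stage-1 repetition rate {rep:.0%}")
            elif alt > thresholds.max_repeat_frac:
                reasons.append(f"{cond}: stage-1 alternation rate {alt:.0%}")
        if reasons:
            excluded.append({"subject_id": s.subject_id, "reason": "; ".join(reasons)})
            log.info("excluding %s: %s", s.subject_id, "; ".join(reasons))
        else:
            kept.append(s)
    return kept, excluded


def _fit_all_cells(
    subjects: List[SubjectDataset], cfg: PipelineConfig, rng: np.random.Generator
) -> pd.DataFrame:
    frames = []
    for gi, group in enumerate(GROUPS):
        cell = [s for s in subjects if s.group == group]
        if not cell:
            continue
        for ci, cond in enumerate(CONDITIONS):
            logs = [s.trials[cond] for s in cell]
            ids = [s.subject_id for s in cell]
            if cfg.fit_method == "hierarchical":
                seed = cfg.seed * 97 + 13 * gi + ci + 1
                sampler = dataclasses.replace(cfg.sampler, seed=seed % (2**31 - 1))
                summary = fit_hierarchical(
                    logs, cfg.priors, sampler, config=cfg.task,
                    subject_ids=ids, group=group, condition=cond,
                )
                frames.append(summary.to_frame())
            else:
                rows = []
                for sid, lg in zip(ids, logs):
                    res = fit_map(lg, MapPriors(), n_restarts=2, rng=rng, config=cfg.task)
                    for k, name in enumerate(PARAM_NAMES):
                        rows.append(
                            {
                                "subject_id": sid,
                                "group": group,
                                "condition": cond,
                                "parameter": name,
                                "posterior_mean": res.params.as_array()[k],
                            }
                        )
                frames.append(pd.DataFrame(rows))
    return pd.concat(frames, ignore_index=True)


def beta_mb_contrasts(fits: pd.DataFrame) -> Dict[str, float]:
    """Group and group x condition contrasts on the fitted beta_mb.

    ``group_nt``: ED minus HC in the neutral condition (negative = reduced
    model-based weight in ED); ``group_by_condition``: the difference-in-
    differences (ED BID effect minus HC BID effect).
    """
    mb = fits[fits["parameter"] == "beta_mb"]
    cell = {
        (g, c): mb[(mb["group"] == g) & (mb["condition"] == c)]["posterior_mean"].mean()
        for g in GROUPS
        for c in CONDITIONS
    }
    return {
        "group_nt": cell[("ED", "NT")] - cell[("HC", "NT")],
        "group_by_condition": (cell[("ED", "BID")] - cell[("ED", "NT")])
        - (cell[("HC", "BID")] - cell[("HC", "NT")]),
    }


def run_pipeline(cfg: PipelineConfig, subjects: Optional[List[SubjectDataset]] = None) -> Dict:
    """Run the full analysis; returns a dict of artifact paths and key numbers."""
    out = Path(cfg.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    rng = np.random.default_rng(cfg.seed)
    artifacts: Dict[str, object] = {}

    if subjects is None:
        subjects = simulate_cohort(cfg.cohort, cfg.task, rng)
    if not subjects:
        raise ValueError("empty cohort: no subjects to analyse (input 'cohort')")

    write_cohort_csv(subjects, out / "trials.csv")
    covariates_to_frame(subjects).to_csv(out / "covariates.csv", index=False)

    kept, excluded = apply_exclusions(subjects, cfg.exclusions)
    pd.DataFrame(excluded, columns=["subject_id", "reason"]).to_csv(
        out / "exclusions.csv", index=False
    )
    if not kept:
        raise ValueError("all subjects excluded; nothing to analyse")

    stay = stay_tables_frame(kept)
    stay.to_csv(out / "stay_tables.csv", index=False)
    design = build_stay_regression(kept)
    design.to_csv(out / "stay_regression_design.csv", index=False)

    fits = _fit_all_cells(kept, cfg, rng)
    fits.to_csv(out / "parameter_estimates.csv", index=False)
    contrasts = beta_mb_contrasts(fits)
    with open(out / "beta_mb_contrasts.json", "w") as fh:
        json.dump(contrasts, fh, indent=2)

    mb = fits[fits["parameter"] == "beta_mb"].pivot_table(
        index="subject_id", columns="condition", values="posterior_mean"
    )
    ids = [s.subject_id for s in kept if s.subject_id in mb.index]
    delta = pd.Series(
        [delta_beta_mb(mb.loc[i, "BID"], mb.loc[i, "NT"]) for i in ids], index=ids,
        name="delta_beta_mb",
    )
    delta.rename_axis("subject_id").reset_index().to_csv(
        out / "delta_beta_mb.csv", index=False
    )
    cov = covariates_to_frame([s for s in kept if s.subject_id in mb.index])
    corr = correlate_delta_with_covariates(delta.to_numpy(), cov)
    corr.to_csv(out / "delta_correlations.csv", index=False)

    if cfg.with_recovery:
        report = run_recovery(
            cfg.cohort, cfg.task, fit=cfg.fit_method, sampler=cfg.sampler,
            rng=np.random.default_rng(cfg.seed + 1),
        )
        report.to_frame().to_csv(out / "recovery.csv", index=False)
        artifacts["average_pcc"] = report.average_pcc

    manifest = {
        "package_version": __version__,
        "seed": cfg.seed,
        "fit_method": cfg.fit_method,
        "n_subjects": len(subjects),
        "n_excluded": len(excluded),
        "exclusion_thresholds": {
            **dataclasses.asdict(cfg.exclusions),
            "canonical": False,
        },
        "outputs": sorted(p.name for p in out.glob("*.csv")) + ["beta_mb_contrasts.json"],
    }
    with open(out / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=2)

    artifacts.update(
        {
            "out_dir": str(out),
            "contrasts": contrasts,
            "n_excluded": len(excluded),
            "fits": fits,
            "delta_correlations": corr,
        }
    )
    return artifacts
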