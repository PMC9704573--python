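"""Group comparisons from summary statistics and t-test power analysis.

Two-sample t statistics are computed from printed group means/SDs/sizes
with pooled (Student) variance. Power calculations use the noncentral-t
distribution exactly (no normal approximation), for both independent-
and paired-samples designs, matching standard a-priori sample-size
calculators:

* independent: noncentrality ``d * sqrt(n1*n2/(n1+n2))``, df ``n1+n2-2``;
* paired: noncentrality ``dz * sqrt(n)``, df ``n-1``.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional, Tuple

import numpy as np
from scipy import stats

__all__ = [
    "GroupSummary",
    "two_sample_t_from_summary",
    "achieved_power_t",
    "required_n_t_independent",
    "required_n_t_paired",
]


@dataclass(frozen=True)
class GroupSummary:
    mean: float
    sd: float
    n: int

    def __post_init__(self) -> None:
        if self.sd < 0:
            raise ValueError("sd must be non-negative")
        if self.n < 2:
            raise ValueError("need n >= 2 per group")


def two_sample_t_from_summary(
    a: GroupSummary, b: GroupSummary
) -> Tuple[float, int, float]:
    """Pooled-variance two-sample t, df = n1 + n2 - 2, two-sided p."""
    t, p = stats.ttest_ind_from_stats(
        a.mean, a.sd, a.n, b.mean, b.sd, b.n, equal_var=True
    )
    return float(t), a.n + b.n - 2, float(p)


def _power(ncp: float, df: int, alpha: float) -> float:
    tcrit = stats.t.ppf(1.0 - alpha / 2.0, df)
    upper = stats.nct.sf(tcrit, df, ncp)
    lower = stats.nct.cdf(-tcrit, df, ncp)
    if not np.isfinite(lower):  # underflows for extreme noncentrality
        lower = 0.0
    return float(upper + lower)


def achieved_power_t(
    d: float,
    n1: Optional[int] = None,
    n2: Optional[int] = None,
    n: Optional[int] = None,
    alpha: float = 0.05,
    design: str = "independent",
) -> float:
    """Power of a two-tailed t test at effect size d.

    ``design="independent"`` needs n1 and n2 (n2 defaults to n1);
    ``design="paired"`` needs n and interprets d as dz.
    """
    if design == "independent":
        if n1 is None:
            raise ValueError("independent design needs n1")
        n2 = n2 if n2 is not None else n1
        ncp = d * np.sqrt(n1 * n2 / (n1 + n2))
        df = n1 + n2 - 2
    elif design == "paired":
        if n is None:
            raise ValueError("paired design needs n")
        ncp = d * np.sqrt(n)
        df = n - 1
    else:
        raise ValueError(f"unknown design {design!r}")
    if df < 1:
        raise ValueError("not enough observations for a t test")
    return _power(float(ncp), int(df), alpha)


def _scan_n(power_fn, target: float, n_max: int = 1_000_000) -> int:
    for n in range(2, n_max + 1):
        if power_fn(n) >= target:
            return n
    raise RuntimeError("no sample size below the scan limit reaches the target power")


def required_n_t_independent(d: float, power: float = 0.8, alpha: float = 0.05) -> int:
    """Smallest per-group n reaching the target power (equal group sizes)."""
    if not (0 < power < 1) or d <= 0:
        raise ValueError("need 0 < power < 1 and d > 0")
    return _scan_n(lambda n: achieved_power_t(d, n1=n, n2=n, alpha=alpha), power)


def required_n_t_paired(dz: float, power: float = 0.8, alpha: float = 0.05) -> int:
    """Smallest n of pairs reaching the target power."""
    if not (0 < power < 1) or dz <= 0:
        raise ValueError("need 0 < power < 1 and dz > 0")
    return _scan_n(lambda n: achieved_power_t(dz, n=n, alpha=alpha, design="paired"), power)
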