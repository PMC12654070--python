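"""Post hoc power for a single-instrument MR test on a binary outcome.

The non-centrality of the Wald z statistic for a summary-level MR test with
a binary outcome is approximately

    ncp = |ln OR| · sqrt(N · R² · K · (1 − K))

where N is the outcome GWAS size, K = n_cases/N its case fraction, R² the
instrument's variance explained on the exposure, and OR the true odds ratio
per 1-SD exposure.  Power at two-sided level α is then

    power = Φ(ncp − z_{1−α/2})        (one-sided tail approximation)

optionally plus the mirror tail Φ(−ncp − z_{1−α/2}), which matters only near
the null (it contributes at most α/2).  The K(1−K) factor is exactly the
"accounting for the case–control ratio" of the screen's design.
"""

from __future__ import annotations

import itertools
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

DEFAULT_OR_TARGETS = (0.90, 1.20, 1.50)


@dataclass
class PowerScenario:
    """One cell of the power grid (outcome × metabolite × target OR)."""

    outcome_id: str
    n_total: int
    n_cases: int
    r2: float
    or_target: float
    alpha: float = 0.05
    metabolite_id: str = ""
    power: float | None = None

    @property
    def case_fraction(self) -> float:
        return self.n_cases / self.n_total


def noncentrality(n_total: float, case_fraction: float, r2: float, or_target: float) -> float:
    return abs(np.log(or_target)) * np.sqrt(
        n_total * r2 * case_fraction * (1.0 - case_fraction)
    )


def posthoc_power(
    n_total: int,
    n_cases: int,
    r2: float,
    or_target: float,
    alpha: float = 0.05,
    mirror_tail: bool = False,
) -> float:
    """Closed-form power of the two-sided Wald test at level ``alpha``.

    Degenerate inputs (case fraction 0 or 1, or a null instrument with a
    non-null target OR) return α/2 with a warning rather than raising.
    """
    if not 0.0 < alpha < 1.0:
        raise ValueError("alpha must be in (0, 1)")
    z = stats.norm.ppf(1.0 - alpha / 2.0)
    k = n_cases / n_total
    if not 0.0 < k < 1.0 or (r2 <= 0.0 and or_target != 1.0):
        warnings.warn(
            f"degenerate power scenario (K={k}, r2={r2}); reporting alpha/2",
            stacklevel=2,
        )
        return float(stats.norm.cdf(-z))
    ncp = noncentrality(n_total, k, r2, or_target)
    power = stats.norm.cdf(ncp - z)
    if mirror_tail:
        power += stats.norm.cdf(-ncp - z)
    return float(power)


def power_table(
    outcomes: dict[str, tuple[int, int]],
    r2_per_metabolite: dict[str, float],
    or_targets: tuple[float, ...] = DEFAULT_OR_TARGETS,
    alpha: float = 0.05,
    mirror_tail: bool = False,
) -> pd.DataFrame:
    """Power for every outcome × metabolite × target-OR combination.

    ``outcomes`` maps outcome_id → (n_total, n_cases); ``r2_per_metabolite``
    maps metabolite_id → instrument R².  One row per combination.
    """
    rows = []
    for (outcome_id, (n_total, n_cases)), (met, r2), or_t in itertools.product(
        sorted(outcomes.items()), sorted(r2_per_metabolite.items()), or_targets
    ):
        rows.append(
            {
                "outcome": outcome_id,
                "metabolite": met,
                "n_total": n_total,
                "n_cases": n_cases,
                "r2": r2,
                "or_target": or_t,
                "power": posthoc_power(
                    n_total, n_cases, r2, or_t, alpha=alpha, mirror_tail=mirror_tail
                ),
            }
        )
    return pd.DataFrame(
        rows,
        columns=["outcome", "metabolite", "n_total", "n_cases", "r2", "or_target", "power"],
    )


@dataclass(frozen=True)
class ValidationPoint:
    """One grid point for formula-vs-simulation validation."""

    case_fraction: float
    n_total: int
    r2: float
    or_target: float


#: grid spanning rare (biobank-like) to common (case-control-like) case
#: fractions and weak-to-strong instruments, used to validate the closed
#: form against Monte-Carlo rejection rates
DEFAULT_VALIDATION_GRID: tuple[ValidationPoint, ...] = tuple(
    ValidationPoint(k, n, r2, or_t)
    for (k, n, r2) in (
        (0.001, 500_000, 0.02),
        (0.01, 100_000, 0.02),
        (0.01, 100_000, 0.05),
        (0.1, 5_000, 0.02),
    )
    for or_t in DEFAULT_OR_TARGETS
)
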