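"""Cohort summaries and grouped rate comparisons for editing-outcome QC.

Per-clone counts of unique variants (clone-specific SNVs, indels, SVs) are
summarised as arithmetic means, and rates of unintended events are compared
between groups of clones (by Cas protein, or by delivery method) with the
pooled-variance two-sample Student's t-test:

    t = (x̄₁ − x̄₂) / √(s_p² (1/n₁ + 1/n₂)),   s_p² = (S₁ + S₂) / (n₁ + n₂ − 2)

with S the within-group sums of squares and df = n₁ + n₂ − 2. The two-sided
p-value uses the t-distribution survival function, computed here through the
regularised incomplete beta function.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass

from scipy.special import betainc


@dataclass(frozen=True)
class CloneRecord:
    """One clone's metadata and per-clone counts."""

    clone_id: str
    coverage: float
    n_unique_snv: int
    n_unique_indel: int
    n_unique_sv: int
    cas_label: str  # Cas9 | Cas12a
    delivery: str  # RNP | plasmid
    n_unintended_events: int = 0

    def __post_init__(self) -> None:
        if min(self.n_unique_snv, self.n_unique_indel, self.n_unique_sv) < 0:
            raise ValueError("counts must be >= 0")
        if self.n_unintended_events < 0:
            raise ValueError("counts must be >= 0")
        if self.coverage <= 0:
            raise ValueError("coverage must be > 0")


@dataclass(frozen=True)
class RateComparison:
    group_labels: tuple[str, str]
    group_means: tuple[float, float]
    t_statistic: float
    degrees_of_freedom: int
    p_two_sided: float


def student_t_sf(x: float, df: int) -> float:
    """Upper-tail P(T > x) of Student's t with ``df`` degrees of freedom,
    via I_{df/(df+x²)}(df/2, 1/2)."""
    if df < 1:
        raise ValueError("df must be >= 1")
    if x != x:
        raise ValueError("x is NaN")
    half = 0.5 * float(betainc(df / 2.0, 0.5, df / (df + x * x)))
    return half if x >= 0 else 1.0 - half


def cohort_means(records: list[CloneRecord]) -> dict[str, float]:
    """Arithmetic means of coverage and unique-variant counts, at full
    precision; display rounding is the caller's concern."""
    if not records:
        raise ValueError("cohort_means requires at least one record")
    n = len(records)
    return {
        "coverage": sum(r.coverage for r in records) / n,
        "n_unique_snv": sum(r.n_unique_snv for r in records) / n,
        "n_unique_indel": sum(r.n_unique_indel for r in records) / n,
        "n_unique_sv": sum(r.n_unique_sv for r in records) / n,
    }


def student_t_two_sample(
    x: list[float],
    y: list[float],
    labels: tuple[str, str] = ("x", "y"),
) -> RateComparison:
    """Pooled-variance (equal-variance) two-sample t-test, two-sided."""
    n1, n2 = len(x), len(y)
    if n1 < 2 or n2 < 2:
        raise ValueError("each group needs at least 2 observations")
    m1 = sum(x) / n1
    m2 = sum(y) / n2
    df = n1 + n2 - 2
    ss = sum((v - m1) ** 2 for v in x) + sum((v - m2) ** 2 for v in y)
    pooled_var = ss / df
    if pooled_var == 0.0:
        if m1 == m2:
            t, p = 0.0, 1.0
        else:
            warnings.warn("degenerate zero pooled variance with unequal means")
            t = math.inf if m1 > m2 else -math.inf
            p = 0.0
    else:
        t = (m1 - m2) / math.sqrt(pooled_var * (1.0 / n1 + 1.0 / n2))
        p = 2.0 * student_t_sf(abs(t), df)
    return RateComparison((labels[0], labels[1]), (m1, m2), t, df, p)


GROUP_ORDERS = {
    "delivery": ("plasmid", "RNP"),
    "cas_label": ("Cas9", "Cas12a"),
}


def rate_comparison(records: list[CloneRecord], grouping: str) -> RateComparison:
    """Compare per-clone unintended-event counts between the two levels of
    ``grouping`` ("delivery" or "cas_label")."""
    if grouping not in GROUP_ORDERS:
        raise ValueError(f"grouping must be one of {sorted(GROUP_ORDERS)}")
    g1, g2 = GROUP_ORDERS[grouping]
    x = [float(r.n_unintended_events) for r in records if getattr(r, grouping) == g1]
    y = [float(r.n_unintended_events) for r in records if getattr(r, grouping) == g2]
    for label, group in ((g1, x), (g2, y)):
        if len(group) < 2:
            raise ValueError(
                f"group {label!r} has {len(group)} clone(s); need at least 2"
            )
    return student_t_two_sample(x, y, labels=(g1, g2))
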