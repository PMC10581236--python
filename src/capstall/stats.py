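"""Occlusion incidence rates and the two-proportion z-test.

Trials of photosensitizer excitation end in one of three categorical
outcomes — BLOCKAGE (confirmed flow interruption without hemorrhage),
HEMORRHAGE, or NONE.  Comparing blockage incidence between a
photosensitizer group and a control-dye group at matched optical power
separates photochemical clotting from nonspecific laser damage; the test
statistic is the pooled two-proportion z.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import pandas as pd
from scipy.stats import norm

from .synthdata import OUTCOMES

__all__ = [
    "ProportionTestResult",
    "incidence_rates",
    "two_proportion_ztest",
    "outcome_comparison",
    "hemorrhage_comparison",
    "summary_table",
]

REQUIRED_COLUMNS = ("group", "outcome")


def _validate_table(table: pd.DataFrame) -> pd.DataFrame:
    for col in REQUIRED_COLUMNS:
        if col not in table.columns:
            raise ValueError(f"trial table is missing column {col!r}")
    if table.empty:
        raise ValueError("trial table is empty")
    bad = sorted(set(table["outcome"]) - set(OUTCOMES))
    if bad:
        raise ValueError(f"unknown outcome labels {bad}; expected one of {list(OUTCOMES)}")
    return table


def incidence_rates(table: pd.DataFrame, outcome: str) -> dict[str, dict]:
    """Per-group count, total and rate of one outcome.

    Returns ``{group: {"k": successes, "n": trials, "rate": k/n}}``.
    """
    _validate_table(table)
    if outcome not in OUTCOMES:
        raise ValueError(f"unknown outcome {outcome!r}; expected one of {list(OUTCOMES)}")
    out: dict[str, dict] = {}
    for group, sub in table.groupby("group", sort=True):
        n = len(sub)
        k = int((sub["outcome"] == outcome).sum())
        out[str(group)] = {"k": k, "n": n, "rate": k / n}
    return out


@dataclass(frozen=True)
class ProportionTestResult:
    k1: int
    n1: int
    k2: int
    n2: int
    p1: float
    p2: float
    z: float
    p_value: float
    sided: str              # "two" or "one"
    continuity: bool = False


def two_proportion_ztest(
    k1: int, n1: int, k2: int, n2: int,
    sided: str = "two",
    continuity: bool = False,
) -> ProportionTestResult:
    """Pooled two-proportion z-test.

    z = (p1 - p2) / sqrt(p*(1-p*)(1/n1 + 1/n2)) with p* the pooled
    proportion (k1+k2)/(n1+n2).  ``sided="one"`` tests p1 > p2.  The
    optional Yates continuity correction shrinks |p1 - p2| by
    (1/n1 + 1/n2)/2 before standardizing.  A pooled proportion of 0 or 1
    leaves z undefined and raises.
    """
    if n1 <= 0 or n2 <= 0:
        raise ValueError("sample sizes must be positive")
    if not (0 <= k1 <= n1) or not (0 <= k2 <= n2):
        raise ValueError("counts must satisfy 0 <= k <= n")
    if sided not in ("two", "one"):
        raise ValueError("sided must be 'two' or 'one'")
    p1, p2 = k1 / n1, k2 / n2
    pooled = (k1 + k2) / (n1 + n2)
    if pooled <= 0.0 or pooled >= 1.0:
        raise ValueError("pooled proportion is 0 or 1; z is undefined")
    se = math.sqrt(pooled * (1.0 - pooled) * (1.0 / n1 + 1.0 / n2))
    diff = p1 - p2
    if continuity:
        correction = 0.5 * (1.0 / n1 + 1.0 / n2)
        diff = math.copysign(max(abs(diff) - correction, 0.0), diff)
    z = diff / se
    if sided == "two":
        p_value = 2.0 * norm.sf(abs(z))
    else:
        p_value = float(norm.sf(z))
    return ProportionTestResult(
        k1=int(k1), n1=int(n1), k2=int(k2), n2=int(n2),
        p1=p1, p2=p2, z=float(z), p_value=float(min(max(p_value, 0.0), 1.0)),
        sided=sided, continuity=continuity,
    )


def outcome_comparison(
    table: pd.DataFrame,
    outcome: str,
    group_order: tuple[str, str] | None = None,
    sided: str = "two",
) -> ProportionTestResult:
    """Two-proportion z-test of one outcome between exactly two groups.

    ``group_order`` fixes which group is p1 (swapping groups negates z);
    by default groups are taken in sorted order.
    """
    rates = incidence_rates(table, outcome)
    if group_order is None:
        groups = tuple(sorted(rates))
    else:
        groups = group_order
    if len(groups) != 2 or any(g not in rates for g in groups):
        raise ValueError(f"need exactly two groups among {sorted(rates)}")
    g1, g2 = groups
    return two_proportion_ztest(
        rates[g1]["k"], rates[g1]["n"], rates[g2]["k"], rates[g2]["n"], sided=sided,
    )


def hemorrhage_comparison(
    table: pd.DataFrame,
    group_order: tuple[str, str] | None = None,
    sided: str = "two",
) -> ProportionTestResult:
    """Two-proportion z-test on the HEMORRHAGE outcome (report wrapper)."""
    return outcome_comparison(table, "HEMORRHAGE", group_order=group_order, sided=sided)


def summary_table(table: pd.DataFrame) -> str:
    """Plain-text incidence summary: one row per group, one column per outcome."""
    _validate_table(table)
    lines = [f"{'group':<14}{'n':>6}" + "".join(f"{o:>16}" for o in OUTCOMES)]
    for group, sub in table.groupby("group", sort=True):
        n = len(sub)
        cells = []
        for o in OUTCOMES:
            k = int((sub['outcome'] == o).sum())
            cells.append(f"{k:>5} ({100.0 * k / n:5.1f}%)")
        lines.append(f"{str(group):<14}{n:>6}" + "".join(f"{c:>16}" for c in cells))
    return "\n".join(lines)
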