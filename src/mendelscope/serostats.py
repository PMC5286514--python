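"""Small-sample group comparison: median/IQR summaries and an exact
two-tailed Mann–Whitney U test.

Plasma-serotonin comparisons in tiny families (two affected children
against a handful of controls) are far below the regime where the
normal approximation to the U distribution is trustworthy, so the test
here enumerates the full null distribution: all C(n1+n2, n1) ways of
labeling the pooled values. Ties are handled with midranks. Beyond a
configurable pooled-size cap the tie-corrected normal approximation is
used instead and labeled as such.

A consequence worth knowing when planning such comparisons: for group
sizes (2, 5) the smallest achievable exact two-tailed p is 2/21 ≈ 0.095
— no outcome can reach p < 0.05.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from decimal import ROUND_HALF_UP, Decimal
from itertools import combinations
from pathlib import Path

import numpy as np
import pandas as pd
from scipy.stats import mannwhitneyu, rankdata


class SerostatsError(ValueError):
    pass


# -- summaries --------------------------------------------------------------


def round_display(x: float, ndigits: int = 2) -> float:
    """Half-up decimal rounding for printed summaries (28.075 -> 28.08).

    Plain round() uses round-half-even on binary floats, which disagrees
    with how such tables are conventionally printed.
    """
    q = Decimal(1).scaleb(-ndigits)
    return float(Decimal(repr(x)).quantize(q, rounding=ROUND_HALF_UP))


def median_iqr(values: list[float]) -> tuple[float, float, float]:
    """(median, q1, q3) with inclusive linear-interpolation quartiles.

    The median of an even-sized sample is the mean of the middle two
    order statistics. With only two values the quartiles degenerate to
    (min, max) — the convention used when a summary like
    "28.08 (27.83–28.32)" is printed for an n = 2 group.
    """
    if len(values) == 0:
        raise SerostatsError("median_iqr needs at least one value")
    arr = np.sort(np.asarray(values, dtype=float))
    med = float(np.median(arr))
    if len(arr) == 1:
        return med, med, med
    if len(arr) == 2:
        return med, float(arr[0]), float(arr[1])
    q1, q3 = (float(q) for q in np.percentile(arr, [25, 75], method="linear"))
    return med, q1, q3


# -- exact Mann-Whitney -----------------------------------------------------


@dataclass(frozen=True)
class MannWhitneyResult:
    u: float  # U statistic for group_a
    p_two_tailed: float
    method: str  # "exact" or "normal_approx"


def _u_from_rank_sum(rank_sum_doubled: int, n1: int) -> float:
    # ranks are midranks, so 2*rank is integral; work in doubled units
    return (rank_sum_doubled - n1 * (n1 + 1)) / 2.0


def mann_whitney_exact(
    group_a: list[float],
    group_b: list[float],
    exact_cap: int = 12,
) -> MannWhitneyResult:
    """Two-tailed Mann–Whitney U test, exact by full enumeration.

    The exact two-tailed p is the null probability of a U at least as
    far from its mean n1*n2/2 as the observed one, enumerated over all
    C(n1+n2, n1) group labelings of the pooled values (midranks for
    ties). For pooled sizes above ``exact_cap`` the tie-corrected
    normal approximation is used and flagged in the result.
    """
    n1, n2 = len(group_a), len(group_b)
    if n1 == 0 or n2 == 0:
        raise SerostatsError("both groups must be non-empty")
    pooled = np.asarray(list(group_a) + list(group_b), dtype=float)
    ranks2 = np.rint(2 * rankdata(pooled)).astype(int)  # doubled midranks

    obs_u = _u_from_rank_sum(int(ranks2[:n1].sum()), n1)

    if n1 + n2 > exact_cap:
        res = mannwhitneyu(group_a, group_b, alternative="two-sided", method="asymptotic")
        return MannWhitneyResult(u=obs_u, p_two_tailed=float(res.pvalue), method="normal_approx")

    mean_u = n1 * n2 / 2.0
    # compare doubled deviations as integers to dodge float equality
    obs_dev2 = abs(round(2 * (obs_u - mean_u)))
    n_extreme = 0
    n_total = math.comb(n1 + n2, n1)
    for idx in combinations(range(n1 + n2), n1):
        u = _u_from_rank_sum(int(ranks2[list(idx)].sum()), n1)
        if abs(round(2 * (u - mean_u))) >= obs_dev2:
            n_extreme += 1
    p = min(1.0, n_extreme / n_total)
    return MannWhitneyResult(u=obs_u, p_two_tailed=p, method="exact")


# -- measurement tables -----------------------------------------------------

VALID_GROUPS = {"affected", "control"}


def read_measurements(path: str | Path) -> pd.DataFrame:
    """Read a sample_id/group/value CSV (values in ng/mL, non-negative)."""
    df = pd.read_csv(path)
    required = {"sample_id", "group", "value"}
    if not required <= set(df.columns):
        raise SerostatsError(f"measurement table needs columns {sorted(required)}")
    bad_groups = set(df["group"]) - VALID_GROUPS
    if bad_groups:
        raise SerostatsError(f"unknown group labels: {sorted(bad_groups)}")
    if (df["value"] < 0).any():
        raise SerostatsError("negative measurement values")
    return df


def compare_groups(df: pd.DataFrame, exact_cap: int = 12) -> dict:
    """Per-group median/IQR plus the exact two-tailed U test, as a dict
    ready for JSON rendering (medians displayed at 2 decimals, ng/mL)."""
    groups = {}
    for name in ("affected", "control"):
        values = df.loc[df["group"] == name, "value"].tolist()
        if not values:
            raise SerostatsError(f"no measurements in group {name!r}")
        med, q1, q3 = median_iqr(values)
        groups[name] = {
            "n": len(values),
            "median": round_display(med),
            "q1": round_display(q1),
            "q3": round_display(q3),
        }
    result = mann_whitney_exact(
        df.loc[df["group"] == "affected", "value"].tolist(),
        df.loc[df["group"] == "control", "value"].tolist(),
        exact_cap=exact_cap,
    )
    return {
        "groups": groups,
        "test": {
            "name": "mann_whitney_u_two_tailed",
            "U": result.u,
            "p": result.p_two_tailed,
            "method": result.method,
        },
    }
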