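"""Multiplicity control: Max-Stat family-wise error control and BH FDR.

The Max-Stat procedure rejects every unit whose statistic exceeds the
(1 - alpha) quantile of the family maximum under the global null — a
step-down max-t test. For the z-based tests (normal, PRR, ROR) that
quantile is the (1 - alpha/2)^(1/J) standard-normal quantile (the
published approximation to the maximum of J independent |N(0,1)|
variables; the exact quantile is available by switch), and the adjusted
p-value is 1 - (1 - p_raw)^J. For the LR test the maximum's null is the
Monte-Carlo MLR distribution from :mod:`aedisparity.mcnull`.

Benjamini-Hochberg is the usual step-up rule on the raw p-values; for the
LR test those come from per-unit Monte-Carlo nulls.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
from scipy.stats import norm
from statsmodels.stats.multitest import multipletests

from .mcnull import NullSamples, mc_p_value, mlr_quantile
from .stats import TestResult

__all__ = [
    "AdjustedFamily",
    "maxstat_normal_critical",
    "maxstat_adjust_normal",
    "maxstat_adjust_lrt",
    "bh_adjust",
]


@dataclass
class AdjustedFamily:
    """Results of one multiplicity adjustment over one family."""

    results: list[TestResult]
    adjustment: str  # "maxstat" | "bh"
    alpha: float
    rejected: set[str] = field(default_factory=set)
    critical_value: float | None = None  # Max-Stat only


def maxstat_normal_critical(J: int, alpha: float, exact: bool = False) -> float:
    """Critical |z| for the max of J independent standard-normal tests.

    Default is the published approximation Phi^-1((1 - alpha/2)^(1/J));
    ``exact=True`` uses Phi^-1((1 + (1 - alpha)^(1/J)) / 2), the true
    quantile of max_j |Z_j|. The two agree to ~3 decimals for J in the
    hundreds.
    """
    if J < 1:
        raise ValueError("J must be >= 1")
    if exact:
        return float(norm.ppf((1.0 + (1.0 - alpha) ** (1.0 / J)) / 2.0))
    return float(norm.ppf((1.0 - alpha / 2.0) ** (1.0 / J)))


def maxstat_adjust_normal(
    results: Sequence[TestResult],
    alpha: float = 0.05,
    J: int | None = None,
    exact: bool = False,
) -> AdjustedFamily:
    """Max-Stat adjustment for z-based tests (normal, PRR, ROR).

    Adjusted p = 1 - (1 - p_raw)^J (the chance that the max of J
    independent tests is at least as extreme), clipped to [0, 1];
    rejection where |z| exceeds the max-|z| critical value.
    """
    J = len(results) if J is None else J
    if J < 1:
        raise ValueError("empty family")
    c = maxstat_normal_critical(J, alpha, exact=exact)
    out = []
    rejected: set[str] = set()
    for r in results:
        if r.p_raw is None:
            raise ValueError(f"unit {r.unit_id!r} has no raw p-value")
        p_adj = float(np.clip(1.0 - (1.0 - r.p_raw) ** J, 0.0, 1.0))
        rej = bool(abs(r.statistic) > c)
        out.append(TestResult(r.unit_id, r.method, r.statistic, r.point_estimate,
                              r.p_raw, p_adj, rej, r.diagnostics))
        if rej:
            rejected.add(r.unit_id)
    return AdjustedFamily(out, "maxstat", alpha, rejected, critical_value=c)


def maxstat_adjust_lrt(
    results: Sequence[TestResult],
    samples: NullSamples,
    alpha: float = 0.05,
) -> AdjustedFamily:
    """Max-Stat adjustment for the LR test via the Monte-Carlo MLR null.

    Adjusted p for unit j is the inclusive tail proportion of the MLR
    draws at LR_j; rejection where LR_j exceeds the empirical (1 - alpha)
    MLR quantile. ``samples`` must have been built on the same family.
    """
    unit_set = {r.unit_id for r in results}
    if unit_set != set(samples.unit_ids()):
        raise ValueError("null samples were built on a different family "
                         f"(units differ: {sorted(unit_set ^ set(samples.unit_ids()))})")
    crit = mlr_quantile(samples, alpha)
    out = []
    rejected: set[str] = set()
    for r in results:
        p_adj = mc_p_value(r.statistic, samples.mlr_draws)
        rej = bool(r.statistic > crit)
        out.append(TestResult(r.unit_id, r.method, r.statistic, r.point_estimate,
                              r.p_raw, p_adj, rej, r.diagnostics))
        if rej:
            rejected.add(r.unit_id)
    return AdjustedFamily(out, "maxstat", alpha, rejected, critical_value=crit)


def bh_adjust(results: Sequence[TestResult], alpha: float = 0.05) -> AdjustedFamily:
    """Benjamini-Hochberg step-up over the family's raw p-values.

    Rejects the k smallest p-values where k is the largest index with
    P(k) <= (k/J) alpha; adjusted p is the usual step-up-monotone
    transform min_{l>=k} (J/l) P(l), clipped at 1. Ties are ordered by
    unit_id for deterministic output (the rejection set is
    order-invariant regardless).
    """
    if not results:
        raise ValueError("empty family")
    ordered = sorted(results, key=lambda r: (_checked_p(r), r.unit_id))
    pvals = np.array([r.p_raw for r in ordered])
    reject, p_adj, _, _ = multipletests(pvals, alpha=alpha, method="fdr_bh")
    out = []
    rejected: set[str] = set()
    for r, pa, rej in zip(ordered, p_adj, reject):
        out.append(TestResult(r.unit_id, r.method, r.statistic, r.point_estimate,
                              r.p_raw, float(pa), bool(rej), r.diagnostics))
        if rej:
            rejected.add(r.unit_id)
    return AdjustedFamily(out, "bh", alpha, rejected)


def _checked_p(r: TestResult) -> float:
    if r.p_raw is None:
        raise ValueError(f"unit {r.unit_id!r} has no raw p-value (run the "
                         "Monte-Carlo null first for the LR test)")
    if not 0.0 <= r.p_raw <= 1.0:
        raise ValueError(f"p-value {r.p_raw} outside [0, 1] for unit {r.unit_id!r}")
    return r.p_raw
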