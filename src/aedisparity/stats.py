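"""The four disparity test statistics on a 2x2 host-factor table.

Model: conditioning on the table margins, the exposed group-1 count a1 is
Binomial(n, p) under the null of no drug-host interaction, with
n = a1 + a2 and p = M1/N the overall group-1 share. Four statistics
measure departure from that null:

* ``lr_statistic`` — the Poisson-likelihood log likelihood ratio
  LR = -n log(n/N) + a1 log(a1/M1) + a2 log(a2/M2), equivalently
  sum_s n_s log(n_s / E_s) with E_s = M_s * n / N. Its null distribution
  is approximated by Monte Carlo (:mod:`aedisparity.mcnull`).
* ``z_statistic`` — the binomial z-score
  z = sqrt(n) (a1/n - p) / sqrt(p(1-p)), approximately standard normal.
* ``prr_statistic`` / ``ror_statistic`` — the proportional reporting
  ratio and reporting odds ratio applied to the host-factor split, with
  delta-method z-scores against their null centering.

All statistics use natural logarithms, with the convention 0*log 0 = 0.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np
from scipy.stats import norm

from .tables import HostTable, TableFamily

__all__ = [
    "TestResult",
    "lr_statistic",
    "mlr",
    "z_statistic",
    "prr_statistic",
    "ror_statistic",
    "normal_p_two_sided",
    "test_family",
    "lr_statistic_arrays",
    "z_statistic_arrays",
    "prr_z_arrays",
    "ror_z_arrays",
]

METHODS = ("lrt", "normal", "prr", "ror")


@dataclass
class TestResult:
    """Outcome of one test on one table.

    ``statistic`` is the LR value for lrt and the signed z-score
    otherwise; ``point_estimate`` carries the PRR/ROR value where one
    exists. ``p_raw`` is absent for lrt until a Monte-Carlo null supplies
    it. ``p_adjusted`` and ``rejected`` are filled by
    :mod:`aedisparity.multiplicity`.
    """

    unit_id: str
    method: str
    statistic: float
    point_estimate: float | None = None
    p_raw: float | None = None
    p_adjusted: float | None = None
    rejected: bool | None = None
    diagnostics: str = ""


# ---------------------------------------------------------------- array core

def _xlogx_ratio(x: np.ndarray, denom: np.ndarray) -> np.ndarray:
    """x * log(x/denom) with 0*log 0 = 0; denom assumed positive."""
    x = np.asarray(x, dtype=float)
    out = np.zeros(np.broadcast(x, denom).shape, dtype=float)
    pos = x > 0
    np.multiply(x, np.log(np.where(pos, x, 1.0) / denom), out=out, where=pos)
    return out


def lr_statistic_arrays(a1, a2, m1, m2) -> np.ndarray:
    """Vectorized log likelihood ratio; margins must be positive."""
    a1 = np.asarray(a1, dtype=float)
    a2 = np.asarray(a2, dtype=float)
    n = a1 + a2
    N = np.asarray(m1, dtype=float) + np.asarray(m2, dtype=float)
    lr = -_xlogx_ratio(n, N) + _xlogx_ratio(a1, m1) + _xlogx_ratio(a2, m2)
    # clip tiny negative round-off; LR is non-negative analytically
    return np.maximum(lr, 0.0)


def z_statistic_arrays(a1, n, p) -> np.ndarray:
    a1 = np.asarray(a1, dtype=float)
    n = np.asarray(n, dtype=float)
    p = np.asarray(p, dtype=float)
    return np.sqrt(n) * (a1 / n - p) / np.sqrt(p * (1.0 - p))


def prr_z_arrays(a1, a2, m1, m2, variant: str = "consistent"):
    """PRR point estimate and delta-method z-score, vectorized.

    variant="consistent" centers log PRR at its null plug-in value
    log(p / ((M1 - n p)/(N - n))); variant="printed" uses the
    published centering with denominator (N - M1) instead of (N - n),
    which is badly miscalibrated (kept for sensitivity analysis).
    """
    a1 = np.asarray(a1, dtype=float)
    a2 = np.asarray(a2, dtype=float)
    m1 = np.asarray(m1, dtype=float)
    m2 = np.asarray(m2, dtype=float)
    n = a1 + a2
    N = m1 + m2
    p = m1 / N
    with np.errstate(divide="ignore", invalid="ignore"):
        prr = (a1 / n) / ((m1 - a1) / (N - n))
        denom = (N - m1) if variant == "printed" else (N - n)
        center = np.log(p / ((m1 - n * p) / denom))
        sigma2 = p * (1.0 - p) * (m1 / (p * (m1 - n * p))) ** 2
        z = np.sqrt(n) * (np.log(prr) - center) / np.sqrt(sigma2)
    return prr, z


def ror_z_arrays(a1, a2, m1, m2, variant: str = "consistent"):
    """ROR point estimate and delta-method z-score, vectorized.

    variant="consistent" uses the symmetric variance
    sigma2 = p(1-p) [ (M1/n)/(p(M1/n - p)) + (M2/n)/((1-p)(M2/n - (1-p))) ]^2;
    variant="printed" substitutes the data-dependent term
    (a1/n - (1-p)) in the second denominator as published (degenerate in
    balanced data; kept for sensitivity analysis).
    """
    a1 = np.asarray(a1, dtype=float)
    a2 = np.asarray(a2, dtype=float)
    m1 = np.asarray(m1, dtype=float)
    m2 = np.asarray(m2, dtype=float)
    n = a1 + a2
    p = m1 / (m1 + m2)
    q = 1.0 - p
    with np.errstate(divide="ignore", invalid="ignore"):
        ror = (a1 / a2) / ((m1 - a1) / (m2 - a2))
        center = np.log((p / q) / ((m1 / n - p) / (m2 / n - q)))
        second = (a1 / n - q) if variant == "printed" else (m2 / n - q)
        bracket = (m1 / n) / (p * (m1 / n - p)) + (m2 / n) / (q * second)
        sigma2 = p * q * bracket**2
        z = np.sqrt(n) * (np.log(ror) - center) / np.sqrt(sigma2)
    return ror, z


# ------------------------------------------------------------- table wrappers

def _check_margins(table: HostTable) -> None:
    if table.m1 <= 0 or table.m2 <= 0:
        side = "group-1" if table.m1 <= 0 else "group-2"
        raise ValueError(f"{side} margin is zero for unit {table.unit_id!r}")


def lr_statistic(table: HostTable) -> float:
    """Log likelihood ratio for one table (natural log, 0*log 0 = 0)."""
    _check_margins(table)
    return float(lr_statistic_arrays(table.a1, table.a2, table.m1, table.m2))


def mlr(statistics: Iterable[float]) -> float:
    """Maximum of the per-unit LR statistics (the family max-statistic)."""
    stats = list(statistics)
    if not stats:
        raise ValueError("mlr of an empty collection")
    return max(stats)


def z_statistic(table: HostTable) -> float:
    """Signed binomial z-score; positive when group 1 is over-represented."""
    _check_margins(table)
    p = table.p_null
    if not 0.0 < p < 1.0:
        raise ValueError(f"degenerate null proportion p={p} for unit {table.unit_id!r}")
    if table.n_exposed == 0:
        raise ValueError(f"no exposed reports for unit {table.unit_id!r}")
    return float(z_statistic_arrays(table.a1, table.n_exposed, p))


def prr_statistic(table: HostTable, variant: str = "consistent") -> tuple[float, float]:
    """(PRR, delta-method z). Requires all four cells positive."""
    if min(table.cells()) <= 0:
        raise ValueError(f"degenerate table for PRR at unit {table.unit_id!r}: "
                         f"cells {table.cells()}")
    prr, z = prr_z_arrays(table.a1, table.a2, table.m1, table.m2, variant=variant)
    return float(prr), float(z)


def ror_statistic(table: HostTable, variant: str = "consistent") -> tuple[float, float]:
    """(ROR, delta-method z). Requires all four cells positive."""
    if min(table.cells()) <= 0:
        raise ValueError(f"degenerate table for ROR at unit {table.unit_id!r}: "
                         f"cells {table.cells()}")
    ror, z = ror_z_arrays(table.a1, table.a2, table.m1, table.m2, variant=variant)
    return float(ror), float(z)


def normal_p_two_sided(z: float) -> float:
    """Two-sided standard-normal p-value, p = 2(1 - Phi(|z|))."""
    if not math.isfinite(z):
        return 0.0 if abs(z) == math.inf else math.nan
    return float(2.0 * norm.sf(abs(z)))


def test_family(
    family: TableFamily, method: str, variant: str = "consistent"
) -> list[TestResult]:
    """Apply one test to every table of a family.

    For "lrt" the raw p is left unset (a Monte-Carlo null from
    :mod:`aedisparity.mcnull` supplies it); the normal, PRR and ROR tests
    carry two-sided normal p-values immediately.
    """
    if method not in METHODS:
        raise ValueError(f"unknown method {method!r}; expected one of {METHODS}")
    results = []
    for t in family:
        if method == "lrt":
            results.append(TestResult(t.unit_id, "lrt", lr_statistic(t)))
            continue
        if method == "normal":
            z = z_statistic(t)
            est = None
        elif method == "prr":
            est, z = prr_statistic(t, variant=variant)
        else:
            est, z = ror_statistic(t, variant=variant)
        diag = "" if math.isfinite(z) else "non-finite z from degenerate cells"
        results.append(
            TestResult(t.unit_id, method, z, point_estimate=est,
                       p_raw=normal_p_two_sided(z), diagnostics=diag)
        )
    return results


def results_frame(results: Sequence[TestResult], context_id: str = "") -> "pd.DataFrame":
    """Tidy results table (one row per unit x method)."""
    import pandas as pd

    return pd.DataFrame(
        [
            {"context_id": context_id, "unit_id": r.unit_id, "method": r.method,
             "statistic": r.statistic, "point_estimate": r.point_estimate,
             "p_raw": r.p_raw, "p_adjusted": r.p_adjusted,
             "rejected": r.rejected, "diagnostics": r.diagnostics}
            for r in results
        ]
    )
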