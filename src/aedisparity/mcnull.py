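"""Monte-Carlo null distributions for the likelihood-ratio statistic.

The LR statistic has no convenient closed-form null distribution, so it is
simulated: conditioning on the margins, each exposed group-1 count is
drawn a1* ~ Binomial(n_exposed, p) with p = M1/N, a2* = n_exposed - a1*,
and LR recomputed. Per-unit draws give raw p-values; the per-replicate
maximum across the family gives the null of the maximal statistic (MLR)
used for family-wise error control.

Draws for different units are independent binomials (the sum constraint on
the group-1 margin is ignored), matching the conditional model stated per
table. Per-unit streams are derived from (seed, unit index), so results do
not depend on iteration order.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .stats import lr_statistic_arrays
from .tables import TableFamily

__all__ = ["NullSamples", "sample_null", "mc_p_value", "mlr_quantile"]


@dataclass
class NullSamples:
    """Sorted Monte-Carlo LR draws, per unit and for the family maximum."""

    per_unit: dict[str, np.ndarray]  # unit_id -> m sorted LR draws
    mlr_draws: np.ndarray  # m sorted draws of max_j LR_j
    m: int
    seed: int

    def unit_ids(self) -> list[str]:
        return list(self.per_unit)


def sample_null(family: TableFamily, m: int = 100_000, seed: int = 0) -> NullSamples:
    """Draw ``m`` null replicates of LR for every unit and of the maximum.

    The k-th entry of the (pre-sort) maximum series is the max over units
    of the k-th replicate, preserving the joint structure needed for the
    max-statistic null. Deterministic given ``seed``.
    """
    if m < 1:
        raise ValueError("m must be >= 1")
    arrs = family.arrays()
    n = arrs["n"].astype(np.int64)
    m1 = arrs["m1"]
    m2 = arrs["m2"]
    p = m1 / (m1 + m2)

    draws = np.empty((family.J, m))
    for j, unit in enumerate(family.unit_ids):
        rng = np.random.default_rng(np.random.SeedSequence([int(seed), j]))
        a1 = rng.binomial(n[j], p[j], size=m)
        draws[j] = lr_statistic_arrays(a1, n[j] - a1, m1[j], m2[j])
    mlr_draws = draws.max(axis=0)
    per_unit = {unit: np.sort(draws[j]) for j, unit in enumerate(family.unit_ids)}
    return NullSamples(per_unit=per_unit, mlr_draws=np.sort(mlr_draws), m=m, seed=seed)


def mc_p_value(observed: float, draws: np.ndarray) -> float:
    """Inclusive upper-tail Monte-Carlo p: (# draws >= observed) / m.

    Ties count toward the tail; with a discrete simulated null, using the
    strict inequality instead is known to inflate FDR downstream. The
    estimate can be exactly 0 (no +1 correction); report such values as
    "< 1/m" in presentation layers.
    """
    draws = np.asarray(draws)
    if draws.size == 0:
        raise ValueError("empty draw vector")
    return float(draws.size - np.searchsorted(draws, observed, side="left")) / draws.size


def mc_p_values(observed: np.ndarray, draws: np.ndarray) -> np.ndarray:
    """Vectorized :func:`mc_p_value` for many observed values."""
    draws = np.asarray(draws)
    obs = np.asarray(observed)
    return (draws.size - np.searchsorted(draws, obs, side="left")) / draws.size


def mlr_quantile(samples: NullSamples, alpha: float) -> float:
    """Empirical (1 - alpha) quantile of the family-maximum null draws.

    Uses the 'higher' interpolation convention so that empirically
    P(MLR > q) <= alpha, keeping the max-statistic test conservative on
    the discrete simulated null.
    """
    if not 0.0 < alpha < 1.0:
        raise ValueError("alpha must be in (0, 1)")
    return float(np.quantile(samples.mlr_draws, 1.0 - alpha, method="higher"))
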