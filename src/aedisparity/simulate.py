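"""Simulation harness: empirical FWER, FDR and sensitivity of the tests.

The design mirrors a reporting-database calibration study. A base of
2x2-table families (real marginals, or synthetic ones from
:func:`generate_synthetic_base`) is stratified by total event count into
"small" / "medium" / "large" at the 25% and 50% quantiles (674 and 1337
in the FAERS-derived base). Within each stratum, families are sampled and
their exposed group-1 counts re-drawn from the conditional binomial model:
a randomly chosen fraction (default 1/5, rounded to the nearest whole
number of drugs) of each family's units follows a disparity alternative

    p'_ij = p_i + Delta * (-1)^{1(p_i > 0.5)}

while the rest follow the null proportion p_i. Every test x adjustment
combination is applied to each simulated family, and rejections are
scored against the truth labels to estimate the family-wise error rate
(Delta = 0), the false discovery rate and the sensitivity.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Callable, Iterable, Sequence

import numpy as np
import pandas as pd

from .mcnull import sample_null, mlr_quantile
from .multiplicity import maxstat_normal_critical
from .stats import (METHODS, lr_statistic_arrays, prr_z_arrays, ror_z_arrays,
                    z_statistic_arrays)
from .tables import (HostTable, TableFamily, filter_exposed_exceeds_margin,
                     filter_min_cell, filter_min_units)

__all__ = [
    "SimScenario",
    "SimOutcome",
    "generate_synthetic_base",
    "alternative_proportion",
    "simulate_family",
    "run_simulation",
    "fwer_estimate",
    "fdr_estimate",
    "sensitivity_estimate",
]

STRATA = ("small", "medium", "large")
ADJUSTMENTS = ("maxstat", "bh")


# ------------------------------------------------------------- configuration

@dataclass
class SimScenario:
    """One simulation configuration.

    ``strata_cutpoints`` default to the 25%/50% quantiles of the base's
    family totals; pass (674, 1337) to pin the FAERS-derived values.
    ``m_null`` is the Monte-Carlo replicate count for the per-family LR
    nulls (5000 resolves p to 2e-4, ample for alpha = 0.05 decisions).
    """

    base: list[TableFamily]
    delta: float = 0.0
    alt_fraction: float = 0.2
    aes_per_stratum: int = 250
    iterations_per_ae: int = 2000
    alpha: float = 0.05
    seed: int = 0
    strata_cutpoints: tuple[float, float] | None = None
    m_null: int = 5000
    variant: str = "consistent"  # PRR/ROR formula variant

    def __post_init__(self) -> None:
        if self.delta < 0:
            raise ValueError("delta must be >= 0")
        if not 0.0 <= self.alt_fraction <= 1.0:
            raise ValueError("alt_fraction must be in [0, 1]")
        if self.strata_cutpoints is not None:
            lo, hi = self.strata_cutpoints
            if not lo < hi:
                raise ValueError("strata cutpoints must be increasing")

    def cutpoints(self) -> tuple[float, float]:
        if self.strata_cutpoints is not None:
            return self.strata_cutpoints
        totals = np.array([fam.tables[0].n for fam in self.base], dtype=float)
        return (float(np.quantile(totals, 0.25)), float(np.quantile(totals, 0.50)))


@dataclass
class SimOutcome:
    """Empirical error rates per method x adjustment x stratum."""

    table: pd.DataFrame  # columns: method, adjustment, stratum, delta,
    #                      n_runs, fwer, fdr, sensitivity, fwer_se, fdr_se, sensitivity_se

    def rate(self, method: str, adjustment: str, metric: str,
             stratum: str = "all") -> float:
        t = self.table
        row = t[(t.method == method) & (t.adjustment == adjustment)
                & (t.stratum == stratum)]
        if row.empty:
            raise KeyError((method, adjustment, stratum))
        return float(row.iloc[0][metric])


# ------------------------------------------------------- synthetic base data

def generate_synthetic_base(
    n_aes: int,
    seed: int = 0,
    total_dist: Callable[[np.random.Generator], int] | None = None,
    drug_count_dist: Callable[[np.random.Generator], int] | None = None,
    group_prop_dist: Callable[[np.random.Generator], float] | None = None,
    exposed_dist: Callable[[np.random.Generator], int] | None = None,
    min_cell: int = 5,
    min_units: int = 5,
    max_attempts_factor: int = 60,
) -> list[TableFamily]:
    """Generate synthetic by-drug families emulating FAERS-derived marginals.

    Defaults (chosen once, to match the reported scale of the real base):
    AE totals n_i. lognormal with 25%/50% quantiles at 674/1337; group-1
    proportion p_i ~ Beta(47.4, 52.6) (mean 0.474, the male share of the
    analgesic liver-toxicity family, sd ~0.05); drugs per AE 6 +
    Poisson(4); per-drug exposed totals lognormal with median 30, floored
    at 12. Each candidate family is passed through the standard filters
    (min cell 5, more than ``min_units`` drugs, no unit with exposed total
    above the smaller margin); only survivors are emitted, so the output
    is analysis-ready. Deterministic given ``seed``.
    """
    # sigma chosen so exp(mu - 0.6745 sigma) = 674 with median 1337
    sigma = math.log(1337 / 674) / 0.6745
    total_dist = total_dist or (lambda r: int(max(150, r.lognormal(math.log(1337), sigma))))
    drug_count_dist = drug_count_dist or (lambda r: 6 + int(r.poisson(4)))
    group_prop_dist = group_prop_dist or (lambda r: float(r.beta(47.4, 52.6)))
    exposed_dist = exposed_dist or (lambda r: int(max(12, r.lognormal(math.log(30), 0.6))))

    rng = np.random.default_rng(np.random.SeedSequence([int(seed), 0xBA5E]))
    families: list[TableFamily] = []
    attempts = 0
    max_attempts = max_attempts_factor * n_aes
    while len(families) < n_aes:
        attempts += 1
        if attempts > max_attempts:
            raise RuntimeError(
                f"generated only {len(families)}/{n_aes} families in "
                f"{max_attempts} attempts; distributions look infeasible")
        total = total_dist(rng)
        p = group_prop_dist(rng)
        if not 0.0 < p < 1.0:
            raise ValueError(f"group proportion {p} outside (0, 1)")
        J = drug_count_dist(rng)
        n_ij = np.array([exposed_dist(rng) for _ in range(J)], dtype=np.int64)
        if n_ij.sum() > 0.5 * total:
            continue  # drug totals would dominate the AE total
        m1 = int(rng.binomial(total, p))
        m2 = total - m1
        a1 = rng.binomial(n_ij, p)
        if a1.sum() > m1 or (n_ij - a1).sum() > m2:
            continue
        context = f"synthAE{len(families):04d}"
        tables = [
            HostTable("by_drug", f"drug{j:03d}", context,
                      int(a1[j]), int(n_ij[j] - a1[j]),
                      m1 - int(a1[j]), m2 - int(n_ij[j] - a1[j]))
            for j in range(J)
        ]
        try:
            fam = filter_min_cell(TableFamily(tables), min_cell)
        except ValueError:
            continue
        if not filter_min_units([fam], min_units):
            continue
        fam2 = filter_exposed_exceeds_margin(fam)
        if fam2 is None:
            continue
        families.append(fam2)
    return families


# ------------------------------------------------------------- sim mechanics

def alternative_proportion(p_i: float, delta: float) -> float:
    """Alternative group-1 proportion p' = p_i + Delta * (-1)^{1(p_i > 0.5)}.

    The shift is added below (and at) p_i = 0.5 and subtracted above, so
    the disparity always moves toward the interior. Results outside (0, 1)
    are clipped to [0.001, 0.999].
    """
    if not 0.0 < p_i < 1.0:
        raise ValueError("p_i must be in (0, 1)")
    p = p_i + delta if p_i <= 0.5 else p_i - delta
    return float(min(max(p, 0.001), 0.999))


def _round_half_away(x: float) -> int:
    """Round to the nearest whole number, halves away from zero."""
    return int(math.floor(x + 0.5)) if x >= 0 else -int(math.floor(-x + 0.5))


def _select_alternatives(J: int, alt_fraction: float,
                         rng: np.random.Generator) -> np.ndarray:
    m_k = _round_half_away(J * alt_fraction)
    mask = np.zeros(J, dtype=bool)
    if m_k > 0:
        mask[rng.choice(J, size=m_k, replace=False)] = True
    return mask


def simulate_family(
    family: TableFamily,
    delta: float,
    alt_fraction: float = 0.2,
    seed: int | np.random.Generator = 0,
) -> tuple[TableFamily, dict[str, bool]]:
    """Redraw one family's exposed counts under a partial alternative.

    m_k = round(J * alt_fraction) units (nearest whole number) are chosen
    uniformly without replacement to follow Binomial(n_exposed, p'_i);
    the rest follow Binomial(n_exposed, p_i). Returns the re-drawn family
    (margins unchanged) and a truth label per unit (True = alternative).
    Families prepared with :func:`filter_exposed_exceeds_margin` always
    yield valid (non-negative) cells.
    """
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    arrs = family.arrays()
    n = arrs["n"].astype(np.int64)
    p_null = arrs["m1"] / (arrs["m1"] + arrs["m2"])
    # at delta = 0 the "alternative" coincides with the null: label all null
    alt_mask = (np.zeros(family.J, dtype=bool) if delta == 0.0
                else _select_alternatives(family.J, alt_fraction, rng))
    p_draw = np.array([
        alternative_proportion(p_null[j], delta) if alt_mask[j] else p_null[j]
        for j in range(family.J)
    ])
    a1 = rng.binomial(n, p_draw)
    tables = [
        HostTable(t.orientation, t.unit_id, t.context_id,
                  int(a1[j]), int(n[j] - a1[j]),
                  t.m1 - int(a1[j]), t.m2 - int(n[j] - a1[j]))
        for j, t in enumerate(family.tables)
    ]
    truth = {t.unit_id: bool(alt_mask[j]) for j, t in enumerate(family.tables)}
    return TableFamily(tables), truth


def _bh_reject_matrix(p: np.ndarray, alpha: float) -> np.ndarray:
    """Row-wise BH step-up rejection on a (runs x J) p-value matrix."""
    runs, J = p.shape
    ps = np.sort(p, axis=1)
    thresh = alpha * np.arange(1, J + 1) / J
    ok = ps <= thresh
    any_ok = ok.any(axis=1)
    kmax = np.where(any_ok, J - 1 - np.argmax(ok[:, ::-1], axis=1), -1)
    cutoff = np.where(any_ok, ps[np.arange(runs), np.maximum(kmax, 0)], -np.inf)
    return p <= cutoff[:, None]


def _stratum_of(total: float, cutpoints: tuple[float, float]) -> str:
    lo, hi = cutpoints
    return "small" if total <= lo else ("medium" if total <= hi else "large")


def run_simulation(
    scenario: SimScenario,
    methods: Sequence[str] = METHODS,
    adjustments: Sequence[str] = ADJUSTMENTS,
) -> SimOutcome:
    """Run the full calibration study for one scenario.

    Per stratum, ``aes_per_stratum`` families are sampled (with
    replacement when the base stratum is smaller) and each is re-drawn
    ``iterations_per_ae`` times under the scenario's Delta. Every method x
    adjustment pair is applied at ``scenario.alpha`` to every simulated
    family. A simulation run is one family iteration; FWER counts runs
    with at least one rejection (Delta = 0 only), FDR averages
    false/total rejections with 0/0 = 0, and sensitivity averages
    correct/true-alternative proportions over runs that contain
    alternatives. Replicable given ``scenario.seed``.
    """
    unknown = set(methods) - set(METHODS)
    if unknown:
        raise ValueError(f"unknown methods: {sorted(unknown)}")
    unknown = set(adjustments) - set(ADJUSTMENTS)
    if unknown:
        raise ValueError(f"unknown adjustments: {sorted(unknown)}")
    if not scenario.base:
        raise ValueError("scenario base is empty after filtering")

    cutpoints = scenario.cutpoints()
    by_stratum: dict[str, list[TableFamily]] = {s: [] for s in STRATA}
    for fam in scenario.base:
        by_stratum[_stratum_of(fam.tables[0].n, cutpoints)].append(fam)

    acc: dict[tuple[str, str, str], dict[str, float]] = {}

    def bucket(method: str, adj: str, stratum: str) -> dict[str, float]:
        return acc.setdefault((method, adj, stratum), {
            "fwer_num": 0, "fwer_den": 0, "fdr_sum": 0.0, "fdr_den": 0,
            "sens_sum": 0.0, "sens_den": 0})

    root = np.random.SeedSequence(int(scenario.seed))
    ss_pick, ss_fam = root.spawn(2)
    pick_rng = np.random.default_rng(ss_pick)
    global_null = scenario.delta == 0.0 or scenario.alt_fraction == 0.0
    T = scenario.iterations_per_ae

    for stratum in STRATA:
        pool = by_stratum[stratum]
        if not pool:
            continue
        idx = pick_rng.choice(len(pool), size=scenario.aes_per_stratum,
                              replace=len(pool) < scenario.aes_per_stratum)
        for fam_no, i in enumerate(idx):
            fam = pool[int(i)]
            ss_null, ss_alt, ss_draw = ss_fam.spawn(3)
            null_seed = int(ss_null.generate_state(1)[0] % (2**31))
            arrs = fam.arrays()
            n = arrs["n"].astype(np.int64)
            m1, m2 = arrs["m1"], arrs["m2"]
            p_null = m1 / (m1 + m2)
            J = fam.J

            # per-family LR null (reused across iterations)
            need_lrt = "lrt" in methods
            if need_lrt:
                samples = sample_null(fam, m=scenario.m_null, seed=null_seed)
                mlr_crit = mlr_quantile(samples, scenario.alpha)
                sorted_draws = np.stack([samples.per_unit[u] for u in fam.unit_ids])

            alt_rng = np.random.default_rng(ss_alt)
            alt_mask = (np.zeros(J, dtype=bool) if global_null
                        else _select_alternatives(J, scenario.alt_fraction, alt_rng))
            p_draw = np.where(
                alt_mask,
                [alternative_proportion(pj, scenario.delta) for pj in p_null],
                p_null,
            )

            draw_rng = np.random.default_rng(ss_draw)
            A1 = draw_rng.binomial(n[None, :], p_draw[None, :], size=(T, J))
            A2 = n[None, :] - A1

            rejects: dict[tuple[str, str], np.ndarray] = {}
            if need_lrt:
                LR = lr_statistic_arrays(A1, A2, m1[None, :], m2[None, :])
                if "maxstat" in adjustments:
                    rejects[("lrt", "maxstat")] = LR > mlr_crit
                if "bh" in adjustments:
                    p_lr = np.empty_like(LR)
                    for j in range(J):
                        p_lr[:, j] = (scenario.m_null - np.searchsorted(
                            sorted_draws[j], LR[:, j], side="left")) / scenario.m_null
                    rejects[("lrt", "bh")] = _bh_reject_matrix(p_lr, scenario.alpha)

            zmats: dict[str, np.ndarray] = {}
            if "normal" in methods:
                zmats["normal"] = z_statistic_arrays(A1, n[None, :], p_null[None, :])
            if "prr" in methods:
                zmats["prr"] = prr_z_arrays(A1, A2, m1[None, :], m2[None, :],
                                            variant=scenario.variant)[1]
            if "ror" in methods:
                zmats["ror"] = ror_z_arrays(A1, A2, m1[None, :], m2[None, :],
                                            variant=scenario.variant)[1]
            if zmats:
                c_norm = maxstat_normal_critical(J, scenario.alpha)
                from scipy.stats import norm as _norm
                for method, Z in zmats.items():
                    absz = np.abs(Z)
                    absz = np.where(np.isnan(absz), 0.0, absz)  # degenerate -> no evidence
                    if "maxstat" in adjustments:
                        rejects[(method, "maxstat")] = absz > c_norm
                    if "bh" in adjustments:
                        rejects[(method, "bh")] = _bh_reject_matrix(
                            2.0 * _norm.sf(absz), scenario.alpha)

            n_alt = int(alt_mask.sum())
            for (method, adj), rej in rejects.items():
                b = bucket(method, adj, stratum)
                total = rej.sum(axis=1)
                if global_null:
                    b["fwer_num"] += int((total > 0).sum())
                    b["fwer_den"] += T
                else:
                    false = (rej & ~alt_mask[None, :]).sum(axis=1)
                    ratio = np.where(total > 0, false / np.maximum(total, 1), 0.0)
                    b["fdr_sum"] += float(ratio.sum())
                    b["fdr_den"] += T
                    if n_alt > 0:
                        correct = (rej & alt_mask[None, :]).sum(axis=1)
                        b["sens_sum"] += float((correct / n_alt).sum())
                        b["sens_den"] += T

    rows = []
    strata_plus = list(STRATA) + ["all"]
    for method in methods:
        for adj in adjustments:
            per_stratum = [acc.get((method, adj, s)) for s in STRATA]
            for stratum in strata_plus:
                if stratum == "all":
                    parts = [b for b in per_stratum if b]
                    if not parts:
                        continue
                    b = {k: sum(p[k] for p in parts) for k in parts[0]}
                else:
                    b = acc.get((method, adj, stratum))
                    if b is None:
                        continue
                row = {"method": method, "adjustment": adj, "stratum": stratum,
                       "delta": scenario.delta,
                       "n_runs": int(b["fwer_den"] or b["fdr_den"])}
                for metric, (num, den) in {
                    "fwer": (b["fwer_num"], b["fwer_den"]),
                    "fdr": (b["fdr_sum"], b["fdr_den"]),
                    "sensitivity": (b["sens_sum"], b["sens_den"]),
                }.items():
                    rate = num / den if den else float("nan")
                    row[metric] = rate
                    row[f"{metric}_se"] = (
                        math.sqrt(max(rate * (1 - rate), 0.0) / den) if den else float("nan"))
                rows.append(row)
    return SimOutcome(pd.DataFrame(rows))


# ---------------------------------------------------------------- estimators

def fwer_estimate(indicators: Iterable[int]) -> float:
    """Share of global-null runs with one or more rejections."""
    ind = np.asarray(list(indicators), dtype=float)
    if ind.size == 0:
        raise ValueError("no runs")
    if not np.isin(ind, (0.0, 1.0)).all():
        raise ValueError("indicators must be 0/1")
    return float(ind.mean())


def fdr_estimate(counts: Iterable[tuple[int, int]]) -> float:
    """Mean over runs of (false rejections / total rejections), 0/0 = 0."""
    pairs = list(counts)
    if not pairs:
        raise ValueError("no runs")
    total = 0.0
    for false, tot in pairs:
        if false > tot:
            raise ValueError(f"false rejections {false} exceed total {tot}")
        total += false / tot if tot > 0 else 0.0
    return total / len(pairs)


def sensitivity_estimate(counts: Iterable[tuple[int, int]]) -> float:
    """Mean over runs of (correct rejections / true alternatives)."""
    pairs = list(counts)
    if not pairs:
        raise ValueError("no runs")
    total = 0.0
    for correct, alts in pairs:
        if alts <= 0:
            raise ValueError("a contributing run must have true alternatives "
                             "(global-null runs belong to FWER accounting)")
        if correct > alts:
            raise ValueError(f"correct rejections {correct} exceed alternatives {alts}")
        total += correct / alts
    return total / len(pairs)
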