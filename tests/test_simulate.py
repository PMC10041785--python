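import numpy as np
import pytest

from aedisparity import (SimScenario, alternative_proportion, fdr_estimate,
                         fwer_estimate, generate_synthetic_base,
                         run_simulation, sensitivity_estimate, simulate_family)
from aedisparity.simulate import (_bh_reject_matrix, _round_half_away,
                                  _stratum_of)


class TestAlternativeProportion:
    @pytest.mark.parametrize("p, delta, expected", [
        (0.6, 0.2, 0.4),    # above 0.5: shift down
        (0.4, 0.2, 0.6),    # below 0.5: shift up
        (0.5, 0.1, 0.6),    # boundary: indicator is strict, shift up
        (0.3, 0.0, 0.3),
    ])
    def test_direction(self, p, delta, expected):
        assert alternative_proportion(p, delta) == pytest.approx(expected)

    def test_clipped_into_unit_interval(self):
        assert alternative_proportion(0.9, 0.0) == 0.9
        assert alternative_proportion(0.95, 0.5) == pytest.approx(0.45)
        assert alternative_proportion(0.02, 0.5) == pytest.approx(0.52)
        assert alternative_proportion(0.999, 0.999) == 0.001  # clip floor

    def test_domain(self):
        with pytest.raises(ValueError):
            alternative_proportion(0.0, 0.1)


class TestRounding:
    @pytest.mark.parametrize("J, expected", [(12, 2), (7, 1), (10, 2), (13, 3), (2, 0)])
    def test_nearest_whole_number_of_drugs(self, J, expected):
        # 1/5 of the drugs, rounded to the nearest whole number
        assert _round_half_away(J / 5) == expected

    def test_half_away_from_zero(self):
        assert _round_half_away(2.5) == 3
        assert _round_half_away(0.5) == 1


class TestSyntheticBase:
    def test_deterministic(self):
        b1 = generate_synthetic_base(10, seed=5)
        b2 = generate_synthetic_base(10, seed=5)
        assert len(b1) == len(b2) == 10
        for f1, f2 in zip(b1, b2):
            assert f1.to_frame().equals(f2.to_frame())

    def test_families_pass_filters(self):
        for fam in generate_synthetic_base(15, seed=2):
            assert fam.J > 5
            assert all(min(t.cells()) >= 5 for t in fam)
            assert all(t.n_exposed <= min(t.m1, t.m2) for t in fam)

    def test_stratum_assignment_matches_direct_classification(self):
        base = generate_synthetic_base(40, seed=3)
        cuts = (674.0, 1337.0)
        for fam in base:
            total = fam.tables[0].n
            direct = ("small" if total <= 674 else
                      "medium" if total <= 1337 else "large")
            assert _stratum_of(total, cuts) == direct

    def test_degenerate_group_proportion_gives_balanced_margins(self):
        base = generate_synthetic_base(8, seed=4, group_prop_dist=lambda r: 0.5)
        for fam in base:
            t = fam.tables[0]
            # margins are a Binomial(N, 0.5) draw around N/2
            assert abs(t.m1 / t.n - 0.5) < 0.05

    def test_infeasible_distributions_raise(self):
        with pytest.raises(RuntimeError, match="infeasible"):
            generate_synthetic_base(
                5, seed=0, max_attempts_factor=3,
                exposed_dist=lambda r: 10_000_000)


class TestSimulateFamily:
    def test_null_draw_labels_all_null(self, analgesics):
        sim, truth = simulate_family(analgesics, delta=0.0, seed=1)
        assert set(truth.values()) == {False}
        assert sim.unit_ids == analgesics.unit_ids
        for t0, t1 in zip(analgesics, sim):
            assert t1.m1 == t0.m1 and t1.m2 == t0.m2
            assert t1.n_exposed == t0.n_exposed

    def test_alternative_count_follows_rounding(self, analgesics):
        _, truth = simulate_family(analgesics, delta=0.1, alt_fraction=0.2, seed=0)
        assert sum(truth.values()) == 2  # round(12/5)

    def test_null_mean_matches_p(self):
        # law of large numbers: group-1 share of exposed counts -> p_i
        base = generate_synthetic_base(1, seed=6)
        fam = base[0]
        p = fam.tables[0].p_null
        rng = np.random.default_rng(8)
        tot_a1 = tot_n = 0
        for _ in range(200):
            sim, _ = simulate_family(fam, delta=0.0, seed=rng)
            tot_a1 += sum(t.a1 for t in sim)
            tot_n += sum(t.n_exposed for t in sim)
        se = np.sqrt(p * (1 - p) / tot_n)
        assert abs(tot_a1 / tot_n - p) < 3 * se


class TestEstimators:
    def test_fwer(self):
        assert fwer_estimate([1, 0, 0, 0]) == 0.25
        assert fwer_estimate([0, 0]) == 0.0
        rng = np.random.default_rng(0)
        ind = rng.integers(0, 2, size=100)
        assert fwer_estimate(ind) == pytest.approx(ind.mean())

    def test_fdr_zero_over_zero_is_zero(self):
        assert fdr_estimate([(1, 2), (0, 0)]) == 0.25
        assert fdr_estimate([(0, 0), (0, 0)]) == 0.0

    def test_fdr_validation(self):
        with pytest.raises(ValueError):
            fdr_estimate([(3, 2)])

    def test_sensitivity(self):
        assert sensitivity_estimate([(2, 4), (1, 4)]) == 0.375
        assert sensitivity_estimate([(4, 4)]) == 1.0
        with pytest.raises(ValueError):
            sensitivity_estimate([(1, 0)])

    def test_permutation_invariance(self):
        rng = np.random.default_rng(1)
        pairs = [(int(f), int(f) + int(t)) for f, t in
                 zip(rng.integers(0, 3, 50), rng.integers(0, 4, 50))]
        perm = [pairs[i] for i in rng.permutation(50)]
        assert fdr_estimate(pairs) == pytest.approx(fdr_estimate(perm))


class TestBhMatrix:
    def test_matches_statsmodels_rowwise(self):
        from statsmodels.stats.multitest import multipletests
        rng = np.random.default_rng(2)
        P = rng.uniform(size=(50, 8)) ** 2
        got = _bh_reject_matrix(P, 0.05)
        for i in range(50):
            expect, _, _, _ = multipletests(P[i], alpha=0.05, method="fdr_bh")
            assert np.array_equal(got[i], expect)


@pytest.fixture(scope="module")
def small_base():
    return generate_synthetic_base(30, seed=10)


class TestRunSimulation:

    def test_replicable_and_shaped(self, small_base):
        sc = SimScenario(base=small_base, delta=0.0, aes_per_stratum=4,
                         iterations_per_ae=50, m_null=1000, seed=3)
        out1 = run_simulation(sc, methods=("lrt", "normal"))
        out2 = run_simulation(sc, methods=("lrt", "normal"))
        assert out1.table.equals(out2.table)
        assert set(out1.table.method) == {"lrt", "normal"}
        assert {"maxstat", "bh"} == set(out1.table.adjustment)
        # global-null runs populate FWER, not FDR/sensitivity
        assert out1.table.fwer.notna().all()

    def test_delta_positive_populates_fdr_and_sensitivity(self, small_base):
        sc = SimScenario(base=small_base, delta=0.2, aes_per_stratum=4,
                         iterations_per_ae=50, m_null=1000, seed=3)
        out = run_simulation(sc, methods=("normal",), adjustments=("bh",))
        row = out.table[(out.table.stratum == "all")].iloc[0]
        assert 0 <= row.fdr <= 1
        assert 0 <= row.sensitivity <= 1
        assert np.isnan(row.fwer)

    def test_sensitivity_rises_with_delta(self, small_base):
        rates = []
        for delta in (0.05, 0.2):
            sc = SimScenario(base=small_base, delta=delta, aes_per_stratum=5,
                             iterations_per_ae=60, m_null=1000, seed=7)
            out = run_simulation(sc, methods=("normal",), adjustments=("maxstat",))
            rates.append(out.rate("normal", "maxstat", "sensitivity"))
        assert rates[1] > rates[0]

    def test_empty_base_raises(self):
        with pytest.raises(ValueError, match="empty"):
            run_simulation(SimScenario(base=[], delta=0.0))

    def test_unknown_method_rejected(self, small_base):
        sc = SimScenario(base=small_base)
        with pytest.raises(ValueError):
            run_simulation(sc, methods=("fisher",))
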