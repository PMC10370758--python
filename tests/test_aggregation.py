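import math

import numpy as np
import pytest
from scipy import stats

from helixcov.aggregation import (
    METHODS,
    HelixCovariation,
    aggregate_fisher,
    aggregate_lancaster,
    aggregate_sidak,
    aggregate_weighted_fisher,
    analyze,
    helix_evalues,
    k_unaggregated_support,
    pair_evalues,
    power_to_weights,
)
from helixcov.msa_io import Alignment, PairStats, PairStatsTable


def _rng():
    return np.random.default_rng(1234)


class TestFisher:
    def test_single_pvalue_is_identity(self):
        for p in (0.001, 0.05, 0.3, 0.999):
            assert aggregate_fisher([p]) == pytest.approx(p, rel=1e-12)

    def test_all_ones_aggregate_to_one(self):
        assert aggregate_fisher([1.0, 1.0, 1.0]) == pytest.approx(1.0)

    def test_two_005_closed_form(self):
        # chi2 with 4 df: sf(T) = exp(-T/2) (1 + T/2), T = -4 ln 0.05
        t = -4 * math.log(0.05)
        expected = math.exp(-t / 2) * (1 + t / 2)
        assert aggregate_fisher([0.05, 0.05]) == pytest.approx(expected, rel=1e-12)
        assert expected == pytest.approx(0.017479, abs=5e-7)

    def test_matches_scipy_combine_pvalues(self):
        rng = _rng()
        for _ in range(20):
            p = rng.uniform(0.001, 1.0, size=rng.integers(2, 9))
            ref = stats.combine_pvalues(p, method="fisher").pvalue
            assert aggregate_fisher(p) == pytest.approx(ref, rel=1e-10)

    def test_empty_and_invalid_errors(self):
        with pytest.raises(ValueError, match="no pairs"):
            aggregate_fisher([])
        with pytest.raises(ValueError):
            aggregate_fisher([0.0, 0.5])


class TestLancaster:
    def test_weight_two_reduces_to_fisher(self):
        rng = _rng()
        for _ in range(50):
            p = rng.uniform(1e-6, 1.0, size=rng.integers(1, 10))
            assert aggregate_lancaster(p, [2] * p.size) == pytest.approx(
                aggregate_fisher(p), rel=1e-12
            )

    def test_single_pair_any_weight_is_identity(self):
        for w in (1, 2, 5, 17):
            assert aggregate_lancaster([0.07], [w]) == pytest.approx(0.07, rel=1e-9)

    def test_uniform_under_null_weights_1_3(self):
        rng = _rng()
        agg = [
            aggregate_lancaster(rng.uniform(size=2), [1, 3]) for _ in range(10_000)
        ]
        assert stats.kstest(agg, "uniform").pvalue > 0.01

    def test_zero_weights_dropped(self):
        p = aggregate_lancaster([0.01, 0.5], [4, 0])
        assert p == pytest.approx(aggregate_lancaster([0.01], [4]), rel=1e-12)

    def test_all_zero_weights_warn_and_return_one(self):
        with pytest.warns(RuntimeWarning, match="no informative"):
            assert aggregate_lancaster([0.01, 0.5], [0, 0]) == 1.0

    def test_non_integer_weights_rejected(self):
        with pytest.raises(ValueError, match="integer"):
            aggregate_lancaster([0.5], [1.5])


class TestWeightedFisher:
    def test_weight_two_reduces_to_fisher(self):
        rng = _rng()
        for _ in range(50):
            p = rng.uniform(1e-6, 1.0, size=rng.integers(1, 10))
            assert aggregate_weighted_fisher(p, [2.0] * p.size) == pytest.approx(
                aggregate_fisher(p), rel=1e-12
            )

    def test_single_pair_is_identity(self):
        for w in (0.5, 1.0, 3.7):
            assert aggregate_weighted_fisher([0.2], [w]) == pytest.approx(0.2, rel=1e-9)

    def test_real_weights_against_monte_carlo(self):
        # weights (1.5, 2.5), pvals (0.5, 0.5)
        rng = _rng()
        w = np.array([1.5, 2.5])
        t_obs = np.sum(stats.gamma.isf([0.5, 0.5], a=w / 2, scale=2.0))
        draws = stats.gamma.rvs(
            a=w / 2, scale=2.0, size=(200_000, 2), random_state=rng
        ).sum(axis=1)
        mc = np.mean(draws >= t_obs)
        assert aggregate_weighted_fisher([0.5, 0.5], w) == pytest.approx(mc, abs=3e-3)

    def test_matches_lancaster_for_integer_weights(self):
        rng = _rng()
        for _ in range(20):
            n = rng.integers(1, 8)
            p = rng.uniform(1e-4, 1.0, size=n)
            w = rng.integers(1, 9, size=n)
            assert aggregate_weighted_fisher(p, w.astype(float)) == pytest.approx(
                aggregate_lancaster(p, w), rel=1e-9
            )


class TestSidak:
    def test_single_pvalue_is_identity(self):
        assert aggregate_sidak([0.37]) == pytest.approx(0.37)

    def test_exact_arithmetic(self):
        assert aggregate_sidak([0.01] + [0.5] * 9) == pytest.approx(
            1 - 0.99**10, rel=1e-12
        )
        assert 1 - 0.99**10 == pytest.approx(0.095618, abs=5e-7)

    def test_small_pmin_is_bonferroni(self):
        p = aggregate_sidak([1e-12] + [0.9] * 49)
        assert p == pytest.approx(50e-12, rel=1e-6)


class TestCrossMethodProperties:
    def test_all_methods_in_unit_interval_and_permutation_invariant(self):
        rng = _rng()
        for _ in range(30):
            n = int(rng.integers(1, 10))
            p = rng.uniform(1e-8, 1.0, size=n)
            w_int = rng.integers(1, 12, size=n)
            w_real = rng.uniform(0.1, 4.0, size=n)
            perm = rng.permutation(n)
            for value, permuted in [
                (aggregate_fisher(p), aggregate_fisher(p[perm])),
                (aggregate_lancaster(p, w_int), aggregate_lancaster(p[perm], w_int[perm])),
                (
                    aggregate_weighted_fisher(p, w_real),
                    aggregate_weighted_fisher(p[perm], w_real[perm]),
                ),
                (aggregate_sidak(p), aggregate_sidak(p[perm])),
            ]:
                assert 0.0 < value <= 1.0
                assert value == pytest.approx(permuted, rel=1e-12)

    def test_monte_carlo_oracle_all_methods(self):
        """Aggregated p equals the null exceedance probability of its statistic,
        estimated by direct simulation of the null statistic."""
        rng = _rng()
        n_draws = 100_000
        for _ in range(8):
            n = int(rng.integers(2, 8))
            p = rng.uniform(0.005, 0.95, size=n)
            w_int = rng.integers(1, 10, size=n)
            w_real = rng.uniform(0.2, 4.0, size=n)

            t = -2 * np.sum(np.log(p))
            null_t = -2 * np.sum(np.log(rng.uniform(size=(n_draws, n))), axis=1)
            self._check(aggregate_fisher(p), null_t, t, n_draws)

            t = np.sum(stats.chi2.isf(p, df=w_int))
            null_t = stats.chi2.rvs(df=w_int, size=(n_draws, n), random_state=rng).sum(1)
            self._check(aggregate_lancaster(p, w_int), null_t, t, n_draws)

            t = np.sum(stats.gamma.isf(p, a=w_real / 2, scale=2.0))
            null_t = stats.gamma.rvs(
                a=w_real / 2, scale=2.0, size=(n_draws, n), random_state=rng
            ).sum(1)
            self._check(aggregate_weighted_fisher(p, w_real), null_t, t, n_draws)

            pm = p.min()
            null_t = np.min(rng.uniform(size=(n_draws, n)), axis=1)
            mc = np.mean(null_t <= pm)
            se = math.sqrt(max(mc * (1 - mc), 1e-12) / n_draws)
            assert abs(aggregate_sidak(p) - mc) <= 3 * se + 1e-9

    @staticmethod
    def _check(p_agg, null_t, t_obs, n_draws):
        mc = np.mean(null_t >= t_obs)
        se = math.sqrt(max(mc * (1 - mc), 1e-12) / n_draws)
        assert abs(p_agg - mc) <= 3 * se + 1e-9


class TestWeightsAndEvalues:
    def test_power_weights_printed_example(self):
        w = power_to_weights([0.1, 0.3])
        assert np.allclose(w, [1.0, 3.0])
        assert w.sum() == pytest.approx(4.0)

    def test_equal_powers_give_fisher_weights(self):
        assert np.allclose(power_to_weights([0.4, 0.4, 0.4]), 2.0)

    def test_weights_sum_to_2n(self):
        rng = _rng()
        for _ in range(200):
            n = int(rng.integers(1, 20))
            powers = rng.uniform(0.01, 1.0, size=n)
            assert power_to_weights(powers).sum() == pytest.approx(2 * n)

    def test_all_zero_powers(self):
        with pytest.warns(RuntimeWarning):
            assert np.allclose(power_to_weights([0.0, 0.0]), 0.0)

    def test_helix_evalues(self):
        assert helix_evalues([0.005], 10) == [pytest.approx(0.05)]
        assert helix_evalues([0.3], 1) == [pytest.approx(0.3)]
        es = helix_evalues([0.5, 0.9], 4)
        assert es[0] < es[1]  # ranking preserved
        assert helix_evalues([0.9], 5)[0] > 1  # expected-count semantics

    def _table(self):
        records = {}
        for k in range(10):
            records[(k + 1, 40 - k)] = PairStats(
                score=1.0, p_value=0.004 if k == 0 else 0.5,
                substitutions=2, power=0.5, in_proposed_structure=True,
            )
        for k in range(90):
            records[(k + 1, 300 - k)] = PairStats(
                score=0.0, p_value=0.004 if k == 0 else 0.8,
                substitutions=1, power=0.2, in_proposed_structure=False,
            )
        return PairStatsTable(records=records)

    def test_two_set_correction(self):
        out = pair_evalues(self._table(), "two_set")
        assert out[(1, 40)].e_value == pytest.approx(0.04)   # 0.004 * 10
        assert out[(1, 300)].e_value == pytest.approx(0.36)  # 0.004 * 90

    def test_one_set_correction(self):
        out = pair_evalues(self._table(), "one_set")
        assert out[(1, 40)].e_value == pytest.approx(0.4)  # 0.004 * 100

    def test_proposed_two_set_never_exceeds_one_set(self):
        two = pair_evalues(self._table(), "two_set")
        one = pair_evalues(self._table(), "one_set")
        for key, rec in two.items():
            if rec.in_proposed_structure:
                assert rec.e_value <= one[key].e_value

    def test_two_set_without_structure_errors(self):
        table = PairStatsTable(
            records={(1, 5): PairStats(score=0, p_value=0.5, substitutions=1, power=0.1)}
        )
        with pytest.raises(ValueError, match="proposed structure"):
            pair_evalues(table, "two_set")

    def test_k_unaggregated_support(self):
        assert k_unaggregated_support([0.04, 0.5, 0.9], k=1)
        assert not k_unaggregated_support([0.04, 0.5], k=2)
        assert not k_unaggregated_support([0.05, 0.8], k=1)


class TestAnalyze:
    def test_one_result_per_helix_per_method(self, sim_alignment):
        res = analyze(sim_alignment, method="all", seed=3, n_null=5)
        from helixcov.structure import decompose_helices, parse_wuss

        h = len(decompose_helices(parse_wuss(sim_alignment.ss_cons)))
        assert len(res.helix_results) == h * len(METHODS)
        for m in METHODS:
            assert len(res.for_method(m)) == h

    def test_deterministic_given_seed(self, sim_alignment):
        r1 = analyze(sim_alignment, seed=11, n_null=5)
        r2 = analyze(sim_alignment, seed=11, n_null=5)
        assert r1.to_dataframe().equals(r2.to_dataframe())

    def test_pair_stats_table_bypasses_null_and_matches(self, sim_alignment):
        res = analyze(sim_alignment, method=("fisher", "lancaster"), seed=3, n_null=5)
        # strip E-values: analyze must recompute them identically
        stripped = PairStatsTable(
            records={
                k: PairStats(
                    score=r.score, p_value=r.p_value, substitutions=r.substitutions,
                    power=r.power, in_proposed_structure=r.in_proposed_structure,
                )
                for k, r in res.pair_table.items()
            }
        )
        res2 = analyze(
            sim_alignment, method=("fisher", "lancaster"), pair_stats=stripped
        )
        df1 = res.to_dataframe()
        df2 = res2.to_dataframe()
        for col in ("p_aggregated", "e_value", "statistic_T"):
            assert np.allclose(df1[col], df2[col])
        assert list(df1["helix_id"]) == list(df2["helix_id"])

    def test_missing_structure_and_table_errors(self):
        aln = Alignment(names=["a", "b"], rows=["ACGU", "ACGU"])
        with pytest.raises(ValueError, match="SS_cons"):
            HelixCovariation(aln)

    def test_aggregation_detects_borderline_helix(self):
        """A helix of 8 pairs each at p = 0.2 aggregates below any single
        pair's E-value in a 50-pair structure (no pair is significant)."""
        records = {}
        # target helix: 8 stacked pairs, borderline p, decent substitution counts
        for d in range(8):
            records[(1 + d, 250 - d)] = PairStats(
                score=2.0, p_value=0.2, substitutions=4, power=0.4,
                in_proposed_structure=True,
            )
        # 42 more proposed pairs elsewhere, unremarkable
        rng = np.random.default_rng(0)
        pos = 30
        for h in range(7):
            for d in range(6):
                records[(pos + d, pos + 20 - d)] = PairStats(
                    score=0.5, p_value=float(rng.uniform(0.3, 0.99)),
                    substitutions=3, power=0.3, in_proposed_structure=True,
                )
            pos += 25
        table = PairStatsTable(records=records)
        aln = Alignment(names=["x", "y"], rows=["A" * 260, "A" * 260])
        res = analyze(aln, method="lancaster", pair_stats=table)
        target = [r for r in res.helix_results if r.n_pairs == 8][0]
        min_pair_e = min(r.e_value for r in res.pair_table.records.values())
        assert target.e_value < min_pair_e
        assert target.n_significant_pairs == 0

    def test_summary_and_reports(self, sim_alignment, tmp_path):
        res = analyze(sim_alignment, seed=3, n_null=5)
        text = res.summary()
        assert "helix" in text and "lancaster" in text
        res.to_helixcov(tmp_path / "h.tsv")
        res.to_pair_tsv(tmp_path / "p.tsv")
        import pandas as pd

        df = pd.read_csv(tmp_path / "h.tsv", sep="\t")
        assert set(df["method"]) == {"lancaster"}
        assert (df["e_value"] >= 0).all()

    def test_results_sorted_by_evalue(self, sim_alignment):
        res = analyze(sim_alignment, method="all", seed=3, n_null=5)
        es = [r.e_value for r in res.helix_results]
        assert es == sorted(es)
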