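"""Statistical engine tests: enumeration and Monte-Carlo oracles, calibration
simulations, and hand-worked cases."""

import numpy as np
import pandas as pd
import pytest
from scipy.stats import hypergeom, kstest

from xenosplit import (
    DEFAULT_SIGNATURE,
    QpcrMeasurement,
    bh_adjust,
    differential_expression,
    estimate_dispersion,
    fisher_exact,
    nb_exact_test,
    qpcr_ratio,
    read_gmt,
    simulate_counts,
    stromal_score,
    wallenius_enrichment,
)
from xenosplit.stats import SignatureDefinition


class TestBhAdjust:
    @pytest.mark.parametrize(
        "p,expected",
        [
            ([0.03], [0.03]),
            ([0.01, 0.02, 0.03, 0.04], [0.04, 0.04, 0.04, 0.04]),
            ([1.0, 1.0, 1.0], [1.0, 1.0, 1.0]),
        ],
    )
    def test_hand_cases(self, p, expected):
        assert np.allclose(bh_adjust(p), expected)

    def test_step_up_definition_on_random_inputs(self):
        rng = np.random.default_rng(0)
        p = rng.random(25)
        q = bh_adjust(p)
        # oracle: q_(i) = min_{j>=i} p_(j) m / j applied to sorted p
        order = np.argsort(p)
        m = len(p)
        q_sorted = np.minimum.accumulate(
            (p[order] * m / np.arange(1, m + 1))[::-1]
        )[::-1]
        assert np.allclose(q[order], np.minimum(q_sorted, 1.0))
        assert ((q >= p - 1e-15) & (q <= 1.0)).all()

    def test_out_of_range_raises(self):
        with pytest.raises(ValueError):
            bh_adjust([0.5, 1.5])


class TestDispersionEstimation:
    def test_poisson_counts_give_near_zero_dispersion(self):
        cm, _ = simulate_counts(300, 50, dispersion=0.0, seed=1)
        d = estimate_dispersion(cm, ["A"] * 50 + ["B"] * 50)
        assert d.median() <= 0.05

    def test_constant_counts_give_zero(self):
        df = pd.DataFrame(np.full((10, 6), 37.0))
        d = estimate_dispersion(df, ["A"] * 3 + ["B"] * 3)
        assert (d == 0).all()

    def test_recovers_planted_dispersion(self):
        cm, _ = simulate_counts(500, 50, dispersion=0.4, seed=2)
        d = estimate_dispersion(cm, ["A"] * 50 + ["B"] * 50)
        assert 0.25 <= d.median() <= 0.55

    def test_single_sample_groups_warn(self):
        df = pd.DataFrame(np.arange(8.0).reshape(4, 2))
        with pytest.warns(UserWarning):
            d = estimate_dispersion(df, ["A", "B"])
        assert (d == 0).all()


class TestNbExactTest:
    def test_identical_groups_give_p_one(self):
        assert nb_exact_test([5, 7, 6], [5, 7, 6], dispersion=0.2) == pytest.approx(1.0)

    def test_poisson_limit_matches_binomial_enumeration(self):
        # A sums to 5, B to 0 of pooled 5, equal libraries, dispersion 0:
        # conditional distribution is Binomial(5, 1/2)
        from scipy.stats import binom

        p = nb_exact_test([5], [0], dispersion=0.0)
        pmf = binom.pmf(np.arange(6), 5, 0.5)
        obs = pmf[0]
        oracle = pmf[pmf <= obs + 1e-12].sum()
        assert p == pytest.approx(oracle)

    def test_small_cases_match_enumeration_oracle(self):
        from scipy.stats import binom

        rng = np.random.default_rng(5)
        for _ in range(20):
            a = list(rng.integers(0, 8, size=2))
            b = list(rng.integers(0, 8, size=3))
            p = nb_exact_test(a, b, dispersion=0.0)
            total = sum(a) + sum(b)
            pmf = binom.pmf(np.arange(total + 1), total, 3 / 5)
            obs = pmf[sum(b)]
            oracle = pmf[pmf <= obs * (1 + 1e-9)].sum()
            assert p == pytest.approx(oracle, rel=1e-9)

    def test_tiny_dispersion_approaches_poisson_limit(self):
        p0 = nb_exact_test([9, 4], [1, 2], dispersion=0.0)
        p_eps = nb_exact_test([9, 4], [1, 2], dispersion=1e-9)
        assert p_eps == pytest.approx(p0, rel=1e-4)

    def test_negative_dispersion_raises(self):
        with pytest.raises(ValueError):
            nb_exact_test([1], [1], dispersion=-0.1)


class TestDifferentialExpression:
    def test_planted_fold_change_recovered_with_fdr_control(self):
        cm, truth = simulate_counts(
            2000, 5, de_fraction=0.05, fold_change=6, dispersion=0.1, seed=11
        )
        res = differential_expression(cm, ["A"] * 5 + ["B"] * 5)
        flagged = res["is_de"].to_numpy()
        tp = (flagged & truth).sum()
        fp = (flagged & ~truth).sum()
        assert tp / truth.sum() >= 0.5
        assert fp / max(flagged.sum(), 1) <= 0.10

    def test_null_simulation_type_one_control(self):
        fracs = []
        for seed in (101, 102, 103):
            cm, _ = simulate_counts(1000, 5, de_fraction=0.0, dispersion=0.1, seed=seed)
            res = differential_expression(cm, ["A"] * 5 + ["B"] * 5)
            fracs.append(res["is_de"].mean())
        assert np.mean(fracs) <= 0.05

    def test_null_p_values_are_near_uniform(self):
        cm, _ = simulate_counts(2000, 5, de_fraction=0.0, dispersion=0.1, seed=100)
        res = differential_expression(cm, ["A"] * 5 + ["B"] * 5)
        assert kstest(res["p_value"], "uniform").statistic <= 0.05

    def test_all_zero_gene_is_not_de(self):
        counts = pd.DataFrame(
            {"a1": [0, 10], "a2": [0, 12], "b1": [0, 11], "b2": [0, 9]},
            index=["dead", "alive"],
        )
        from xenosplit import CountMatrix

        cm = CountMatrix(counts, pd.Series(100.0, index=counts.columns))
        res = differential_expression(cm, ["A", "A", "B", "B"])
        assert res.loc["dead", "p_value"] == 1.0
        assert not res.loc["dead", "is_de"]

    def test_single_group_raises(self):
        cm, _ = simulate_counts(10, 4, seed=1)
        with pytest.raises(ValueError):
            differential_expression(cm, ["A"] * 8)


class TestWalleniusEnrichment:
    def _flags(self, universe_size, de_idx):
        flags = pd.Series(False, index=[f"g{i}" for i in range(universe_size)])
        flags.iloc[de_idx] = True
        return flags

    def test_uniform_weights_reduce_to_central_hypergeometric(self):
        flags = self._flags(40, range(10))
        sets = {"S": {f"g{i}" for i in range(0, 20, 2)}}  # 10 genes, 5 of them DE
        res = wallenius_enrichment(flags, sets)
        k, K, n, N = 5, 10, 10, 40
        assert res.loc["S", "p_over"] == hypergeom(N, K, n).sf(k - 1)
        assert res.loc["S", "p_under"] == hypergeom(N, K, n).cdf(k)

    def test_weighted_reduces_to_central_when_weights_equal(self):
        flags = self._flags(30, range(8))
        sets = {"S": {f"g{i}" for i in range(12)}}
        w = pd.Series(2.5, index=flags.index)
        res_w = wallenius_enrichment(flags, sets, bias_weights=w)
        res_u = wallenius_enrichment(flags, sets)
        assert res_w.loc["S", "p_over"] == res_u.loc["S", "p_over"]

    def test_empty_set_and_empty_de_list(self):
        flags = self._flags(20, range(4))
        res = wallenius_enrichment(flags, {"empty": set()})
        assert res.loc["empty", "p_over"] == 1.0
        none_de = self._flags(20, [])
        res2 = wallenius_enrichment(none_de, {"S": {"g1", "g2"}})
        assert res2.loc["S", "p_over"] == 1.0
        assert res2.loc["S", "p_under"] == 1.0

    def test_biased_tail_matches_sequential_sampling_oracle(self):
        """Wallenius tail vs 10^6 sequential weighted draws without
        replacement (universe 20, set 6, 8 draws, odds 2.5)."""
        N, K, n, odds = 20, 6, 8, 2.5
        from scipy.stats import nchypergeom_wallenius

        dist = nchypergeom_wallenius(N, K, n, odds)
        rng = np.random.default_rng(123)
        n_sim = 1_000_000
        in_left = np.full(n_sim, K, dtype=np.int64)
        out_left = np.full(n_sim, N - K, dtype=np.int64)
        for _ in range(n):
            p_in = in_left * odds / (in_left * odds + out_left)
            take = rng.random(n_sim) < p_in
            in_left -= take
            out_left -= ~take
        drawn = K - in_left
        for k in (3, 4, 5):
            mc = (drawn >= k).mean()
            se = np.sqrt(mc * (1 - mc) / n_sim)
            assert abs(dist.sf(k - 1) - mc) <= 3 * se

    def test_enrichment_uses_observed_overlap(self):
        flags = self._flags(100, range(20))
        sets = {"hit": {f"g{i}" for i in range(10)}, "miss": {f"g{i}" for i in range(90, 100)}}
        res = wallenius_enrichment(flags, sets)
        assert res.loc["hit", "n_de_in_set"] == 10
        assert res.loc["hit", "p_over"] < 1e-6
        assert res.loc["miss", "p_under"] < 0.2


class TestFisherExact:
    def test_engraftment_comparison_reproduces_printed_p(self):
        # flank vs kidney-capsule engraftment: 3/14 vs 26/45
        assert round(fisher_exact([[3, 11], [26, 19]]), 2) == 0.03

    def test_empty_first_column_gives_p_one(self):
        assert fisher_exact([[0, 5], [0, 7]]) == 1.0

    @staticmethod
    def _enumeration_oracle(a, b, c, d):
        r1, c1, n = a + b, a + c, a + b + c + d
        pmf_at = lambda x: hypergeom.pmf(x, n, r1, c1)
        p_obs = pmf_at(a)
        lo, hi = max(0, c1 - (n - r1)), min(r1, c1)
        xs = np.arange(lo, hi + 1)
        pmf = pmf_at(xs)
        return float(pmf[pmf <= p_obs * (1 + 1e-7)].sum())

    def test_random_tables_match_enumeration(self):
        rng = np.random.default_rng(9)
        for _ in range(100):
            a, b, c, d = (int(x) for x in rng.integers(0, 12, 4))
            p = fisher_exact([[a, b], [c, d]])
            assert p == pytest.approx(self._enumeration_oracle(a, b, c, d), abs=1e-10)

    def test_symmetry_under_row_and_column_swaps(self):
        rng = np.random.default_rng(13)
        for _ in range(30):
            a, b, c, d = (int(x) for x in rng.integers(0, 10, 4))
            p = fisher_exact([[a, b], [c, d]])
            assert fisher_exact([[c, d], [a, b]]) == pytest.approx(p)
            assert fisher_exact([[b, a], [d, c]]) == pytest.approx(p)

    def test_non_integer_table_rejected(self):
        with pytest.raises(ValueError):
            fisher_exact([[0.5, 1], [2, 3]])


class TestStromalScore:
    def _expr(self, stromal_level, epithelial_level):
        genes = list(DEFAULT_SIGNATURE.stromal_genes) + list(
            DEFAULT_SIGNATURE.epithelial_genes
        )
        vals = [stromal_level] * len(DEFAULT_SIGNATURE.stromal_genes) + [
            epithelial_level
        ] * len(DEFAULT_SIGNATURE.epithelial_genes)
        return pd.Series(vals, index=genes, dtype=float)

    def test_epithelial_dominant_sample_is_cx(self):
        score, call = stromal_score(self._expr(0.0, 10.0))
        assert score < 0
        assert call == "CX"

    def test_symmetric_expression_is_boundary_cx(self):
        score, call = stromal_score(self._expr(5.0, 5.0))
        assert score == pytest.approx(0.0)
        assert call == "CX"  # strict > threshold for SX

    def test_planted_profiles_are_called_correctly(self):
        rng = np.random.default_rng(6)
        for _ in range(20):
            base = rng.uniform(1, 5)
            cx = self._expr(base, base + 5) + pd.Series(
                rng.normal(0, 0.3, 15), index=self._expr(0, 0).index
            )
            sx_expr = self._expr(base + np.log2(32), base) + pd.Series(
                rng.normal(0, 0.3, 15), index=self._expr(0, 0).index
            )
            assert stromal_score(cx)[1] == "CX"
            assert stromal_score(sx_expr)[1] == "SX"

    def test_missing_signature_genes_raise(self):
        expr = pd.Series([1.0], index=["FN1"])
        with pytest.raises(ValueError):
            stromal_score(expr)

    def test_overlapping_lists_rejected(self):
        with pytest.raises(ValueError):
            SignatureDefinition(stromal_genes=("A",), epithelial_genes=("A", "B"))


class TestQpcr:
    def _m(self, n0, detectable=True):
        return QpcrMeasurement("gene", n0, detectable)

    def test_identical_measurements_give_ratio_one(self):
        r = qpcr_ratio(self._m(3.0), self._m(3.0), self._m(2.0), self._m(2.0), 0.1)
        assert r.ratio == pytest.approx(1.0)
        assert r.flag is None

    def test_hand_case_ratio_two(self):
        # (8/4) / (2/2) = 2
        r = qpcr_ratio(self._m(8.0), self._m(2.0), self._m(4.0), self._m(2.0), 0.1)
        assert r.ratio == pytest.approx(2.0)

    def test_undetectable_numerator_uses_floor_and_flags_down(self):
        r = qpcr_ratio(
            self._m(None, False), self._m(2.0), self._m(4.0), self._m(2.0), 0.5
        )
        assert r.flag == "down"
        assert r.ratio == pytest.approx((0.5 / 4.0) / (2.0 / 2.0))

    def test_both_undetectable_is_indeterminate(self):
        r = qpcr_ratio(
            self._m(None, False), self._m(None, False), self._m(1.0), self._m(1.0), 0.5
        )
        assert r.flag == "indeterminate"

    def test_undetectable_gapdh_raises(self):
        with pytest.raises(ValueError, match="GAPDH"):
            qpcr_ratio(
                self._m(1.0), self._m(1.0), self._m(None, False), self._m(1.0), 0.5
            )


def test_read_gmt_roundtrip(tmp_path):
    path = tmp_path / "sets.gmt"
    path.write_text(
        "SET_A\tdescription\tFN1\tVIM\tMMP2\nSET_B\tna\tEPCAM\tCDH1\n"
    )
    sets = read_gmt(path)
    assert sets == {"SET_A": {"FN1", "VIM", "MMP2"}, "SET_B": {"EPCAM", "CDH1"}}
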