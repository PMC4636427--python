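import itertools
import math

import numpy as np
import pytest
from scipy import stats

from reefrange import datasets
from reefrange import model_support as ms


class TestAicc:
    def test_arithmetic(self):
        # -2(-100) + 2*3 + 2*3*4/26
        assert ms.aicc(-100.0, 3, 30) == pytest.approx(206.0 + 24.0 / 26.0)

    def test_large_n_limit_is_aic(self):
        assert ms.aicc(-50.0, 4, 10 ** 9) == pytest.approx(ms.aic(-50.0, 4), abs=1e-4)

    def test_matches_independent_formula_on_random_triples(self):
        rng = np.random.default_rng(15)
        for _ in range(50):
            logl = rng.normal(-80, 20)
            k = int(rng.integers(1, 8))
            n = int(rng.integers(k + 2, 200))
            expect = -2 * logl + 2 * k + (2 * k * (k + 1)) / (n - k - 1)
            assert ms.aicc(logl, k, n) == pytest.approx(expect, rel=1e-12)

    def test_undefined_when_n_too_small(self):
        with pytest.raises(ValueError, match="undefined"):
            ms.aicc(-10.0, 3, 4)


class TestRankModels:
    def test_single_candidate(self):
        out = ms.rank_models([ms.ModelCandidate("only", aicc=12.3)])
        assert out[0].delta_aicc == 0.0 and out[0].weight == 1.0

    def test_weights_invariant_to_constant_shift(self):
        rng = np.random.default_rng(16)
        aiccs = rng.uniform(50, 70, 5)
        w1 = [c.weight for c in ms.rank_models(
            [ms.ModelCandidate(f"m{i}", aicc=a) for i, a in enumerate(aiccs)])]
        w2 = [c.weight for c in ms.rank_models(
            [ms.ModelCandidate(f"m{i}", aicc=a + 1000) for i, a in enumerate(aiccs)])]
        assert np.allclose(w1, w2)
        assert sum(w1) == pytest.approx(1.0, abs=1e-12)

    def test_deterministic_tie_break_by_label(self):
        out = ms.rank_models([ms.ModelCandidate("b", aicc=5.0),
                              ms.ModelCandidate("a", aicc=5.0)])
        assert [c.label for c in out] == ["a", "b"]

    @pytest.mark.parametrize("panel,weights", [
        ("core", [0.43, 0.31, 0.16, 0.10]),
        ("home", [0.49, 0.28, 0.14, 0.09]),
    ])
    def test_published_comparison_table_reproduced(self, panel, weights):
        table = datasets.load_model_candidates(panel)
        ranked = ms.rank_models_frame(table)
        assert [round(w, 2) for w in ranked["weight"]] == weights
        assert ranked["supported"].all()
        # recomputed dAICc agrees with the printed column to its precision
        printed = table.sort_values("aicc")["delta_aicc_printed"].to_numpy()
        assert np.all(np.abs(ranked["delta_aicc"].to_numpy() - printed) <= 0.0100001)


class TestModelAveraging:
    def test_identical_coefficient_unchanged(self):
        cands = ms.rank_models([ms.ModelCandidate("a", aicc=1.0),
                                ms.ModelCandidate("b", aicc=2.0)])
        avg, _ = ms.model_average(cands, {"a": {"x": 3.5}, "b": {"x": 3.5}})
        assert avg["x"] == pytest.approx(3.5)

    def test_manual_two_model_example(self):
        cands = ms.rank_models([ms.ModelCandidate("a", aicc=10.0),
                                ms.ModelCandidate("b", aicc=12.0)])
        wa, wb = cands[0].weight, cands[1].weight
        avg, imp = ms.model_average(cands, {"a": {"x": 1.0, "z": 2.0},
                                            "b": {"x": 3.0}})
        assert avg["x"] == pytest.approx(wa * 1.0 + wb * 3.0)
        assert avg["z"] == pytest.approx(wa * 2.0)  # absent treated as zero
        assert imp["z"] == pytest.approx(wa)
        assert imp["x"] == pytest.approx(1.0)

    @pytest.mark.parametrize("panel,term,expect", [
        ("core", "maturity", 0.41),   # 0.31 + 0.10 from the printed weights
        ("core", "spawn", 0.26),      # 0.16 + 0.10
    ])
    def test_term_importance_identities(self, panel, term, expect):
        table = datasets.load_model_candidates(panel)
        cands = ms.rank_models([
            ms.ModelCandidate(r["label"], aicc=r["aicc"],
                              formula_terms=frozenset(
                                  t for t in r["terms"].split("+") if t))
            for _, r in table.iterrows()])
        assert round(ms.term_importance(cands, term), 2) == expect


class TestWilcoxon:
    def test_extreme_consistent_shift_n6(self):
        pairs = [(i + 1.0, i + 1.0 + 0.5) for i in range(6)]
        w, p = ms.wilcoxon_signed_rank(pairs)
        assert p == pytest.approx(2 / 64)

    def test_exact_branch_matches_scipy_exact(self):
        rng = np.random.default_rng(17)
        for _ in range(10):
            d = rng.normal(0.3, 1.0, 8)
            d = np.where(d == 0, 0.1, d)
            pairs = [(float(x), 0.0) for x in d]
            _, p = ms.wilcoxon_signed_rank(pairs)
            p_ref = stats.wilcoxon(d, method="exact").pvalue
            assert p == pytest.approx(p_ref, abs=1e-12)

    def test_exact_handles_ties_sensibly(self):
        pairs = [(1.0, 0.0), (1.0, 0.0), (-0.5, 0.0), (2.0, 0.0)]
        _, p = ms.wilcoxon_signed_rank(pairs)
        assert 0.0 < p <= 1.0

    def test_approx_close_to_exact_at_n20(self):
        rng = np.random.default_rng(18)
        d = rng.normal(0.2, 1.0, 20)
        pairs = [(float(x), 0.0) for x in d]
        _, p_approx = ms.wilcoxon_signed_rank(pairs)
        p_exact = stats.wilcoxon(d, method="exact").pvalue
        assert abs(p_approx - p_exact) < 0.01

    def test_all_zero_differences_error(self):
        with pytest.raises(ValueError, match="degenerate"):
            ms.wilcoxon_signed_rank([(1.0, 1.0), (2.0, 2.0)])


class TestSpearman:
    def test_perfect_and_reversed(self):
        x = [1.0, 2.0, 3.0, 5.0, 8.0]
        assert ms.rank_correlation(x, x)[0] == pytest.approx(1.0)
        assert ms.rank_correlation(x, x[::-1])[0] == pytest.approx(-1.0)

    def test_exact_p_matches_full_permutation_enumeration(self):
        rng = np.random.default_rng(19)
        x = rng.normal(size=6)
        y = 0.5 * x + rng.normal(size=6)
        rho, p = ms.rank_correlation(x, y)
        count = 0
        for perm in itertools.permutations(y):
            r = stats.spearmanr(x, perm).statistic
            if abs(r) >= abs(rho) - 1e-12:
                count += 1
        assert p == pytest.approx(count / math.factorial(6))

    def test_constant_vector_error(self):
        with pytest.raises(ValueError, match="rank variance"):
            ms.rank_correlation([1.0, 1.0, 1.0], [1.0, 2.0, 3.0])


class TestMannWhitney:
    def test_shifted_samples_detected(self):
        rng = np.random.default_rng(20)
        x = rng.normal(0, 1, 12)
        y = rng.normal(2, 1, 12)
        u, p = ms.mann_whitney(x, y)
        assert p < 0.01
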