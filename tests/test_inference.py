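"""The five inference algorithms and their scoring primitives."""

import itertools
import math

import numpy as np
import pytest

from bnpval import (
    BNp,
    TimeSeries,
    TruthTable,
    adjacency,
    best_fit_error,
    count_transitions,
    fit_function,
    generate_random_bnp,
    generate_time_series,
    infer,
    infer_best_fit,
    infer_mdl,
    infer_reveal,
    infer_umdl,
    mdl_score,
    nml_complexity,
)
from bnpval.generate import GenConfig
from bnpval.inference import TransitionCounts, conditional_entropy, mutual_information

from conftest import full_coverage_series


def series_from_rows(rows):
    return [TimeSeries(np.array(rows, dtype=np.uint8))]


class TestCounting:
    def test_one_series_counts_consecutive_pairs(self):
        net = generate_random_bnp(GenConfig(n=4, K=2, seed=0))
        series = generate_time_series(net, M=10, seed=1)
        counts = count_transitions(series, target=1, regulators=[1, 2])
        assert counts.total == 10

    def test_never_bridges_series_gap(self):
        net = generate_random_bnp(GenConfig(n=4, K=2, seed=0))
        series = generate_time_series(net, M=10, seed=1, n_series=2)
        assert all(s.states.shape[0] == 6 for s in series)
        counts = count_transitions(series, target=2, regulators=[3])
        assert counts.total == 10

    def test_manual_tally(self):
        # target gene 2, regulator gene 1: transitions (x1 -> x2')
        # rows: x1 = 1,0,1,1,0 ; x2 = 0,1,1,0,0
        series = series_from_rows([[1, 0], [0, 1], [1, 1], [1, 0], [0, 0]])
        counts = count_transitions(series, target=2, regulators=[1])
        # pattern 0: next x2 in {1(from row2->3)}: rows (0,1)->(1,1): n1
        assert counts.n0.tolist() == [0, 2]  # (1,*)->x2'=0 twice
        assert counts.n1.tolist() == [1, 1]


class TestBestFitError:
    def test_consistent_data_zero_error(self):
        counts = TransitionCounts(1, (1,), np.array([3, 0]), np.array([0, 5]))
        assert best_fit_error(counts) == 0

    def test_majority_error(self):
        counts = TransitionCounts(1, (1,), np.array([2, 0]), np.array([1, 0]))
        assert best_fit_error(counts) == 1

    @pytest.mark.parametrize("k", [1, 2, 3])
    def test_equals_function_enumeration(self, k):
        """Oracle: minimum misclassification over all 2^(2^k) Boolean functions."""
        rng = np.random.default_rng(k)
        n0 = rng.integers(0, 5, size=2 ** k)
        n1 = rng.integers(0, 5, size=2 ** k)
        counts = TransitionCounts(1, tuple(range(1, k + 1)), n0, n1)
        best = min(
            sum(n1[w] if g[w] == 0 else n0[w] for w in range(2 ** k))
            for g in itertools.product((0, 1), repeat=2 ** k)
        )
        assert best_fit_error(counts) == best


class TestFitFunction:
    def test_pure_full_coverage_recovers_table(self):
        net = generate_random_bnp(GenConfig(n=3, K=2, p=0.0, seed=5))
        series = full_coverage_series(net)
        for t in net.tables:
            counts = count_transitions(series, t.gene, t.regulators)
            outputs, n_unseen, _ = fit_function(counts)
            assert n_unseen == 0
            assert np.array_equal(outputs, t.outputs)

    def test_tie_breaks_to_zero(self):
        counts = TransitionCounts(1, (1,), np.array([1, 0]), np.array([1, 0]))
        outputs, _, _ = fit_function(counts)
        assert outputs[0] == 0

    def test_unseen_rows_filled_with_gene_majority(self):
        counts = TransitionCounts(1, (1, 2), np.array([0, 1, 0, 0]), np.array([4, 0, 0, 0]))
        outputs, n_unseen, fill = fit_function(counts)
        assert n_unseen == 2
        assert fill == 1  # 4 ones vs 1 zero overall
        assert outputs.tolist() == [1, 0, 1, 1]


def xor_and_network(p=0.0):
    """Three genes with minimal, fully sensitive functions:
    x1' = x2 xor x3, x2' = x1, x3' = x1 and x2."""
    return BNp(
        (
            TruthTable(1, (2, 3), np.array([0, 1, 1, 0])),
            TruthTable(2, (1,), np.array([0, 1])),
            TruthTable(3, (1, 2), np.array([0, 0, 0, 1])),
        ),
        p,
    )


class TestBestFit:
    def test_exact_recovery_from_full_coverage(self):
        net = xor_and_network()
        inferred = infer_best_fit(full_coverage_series(net), K=3, p=0.01)
        for t_true, t_inf in zip(net.tables, inferred.net.tables):
            assert t_inf.regulators == t_true.regulators
            assert np.array_equal(t_inf.outputs, t_true.outputs)

    def test_constant_gene_gets_single_lexicographic_regulator(self):
        # gene 2 always observed as 1 -> any singleton is error-free; (1,) wins
        series = series_from_rows([[0, 1], [1, 1], [0, 1], [1, 1]])
        inferred = infer_best_fit(series, K=2, p=0.01)
        assert inferred.net.tables[1].regulators == (1,)
        assert inferred.fits[1].score == 0.0

    def test_respects_max_in_degree(self):
        net = generate_random_bnp(GenConfig(n=6, K=3, p=0.01, seed=2))
        series = generate_time_series(net, M=30, seed=3)
        for algo in ("bestfit", "reveal", "bic", "mdl", "umdl"):
            inferred = infer(series, K=2, algorithm=algo)
            assert all(t.k <= 2 for t in inferred.net.tables)


class TestReveal:
    def test_exact_recovery_from_full_coverage(self):
        net = xor_and_network()
        inferred = infer_reveal(full_coverage_series(net), K=3, p=0.01)
        for t_true, t_inf in zip(net.tables, inferred.net.tables):
            assert t_inf.regulators == t_true.regulators
            assert np.array_equal(t_inf.outputs, t_true.outputs)

    def test_constant_target_accepts_first_singleton(self):
        series = series_from_rows([[0, 1], [1, 1], [0, 1], [1, 1]])
        inferred = infer_reveal(series, K=2, p=0.01)
        assert inferred.net.tables[1].regulators == (1,)

    def test_consistency_is_conditional_determinism(self):
        net = xor_and_network()
        counts = count_transitions(full_coverage_series(net), 1, (2, 3))
        assert conditional_entropy(counts) == pytest.approx(0.0, abs=1e-12)
        assert mutual_information(counts) == pytest.approx(1.0, abs=1e-12)

    def test_reveal_at_least_as_dense_as_best_fit(self):
        """On noisy, scarce data REVEAL pads regulator sets to fit the sample."""
        reveal_k, bestfit_k = [], []
        for seed in range(40):
            net = generate_random_bnp(GenConfig(n=6, K=3, p=0.01, seed=seed))
            series = generate_time_series(net, M=15, seed=1000 + seed)
            reveal_k.append(np.mean([t.k for t in infer_reveal(series, 3).net.tables]))
            bestfit_k.append(np.mean([t.k for t in infer_best_fit(series, 3).net.tables]))
        assert np.mean(reveal_k) >= np.mean(bestfit_k)


class TestMDL:
    def test_deterministic_data_leaves_only_model_term(self):
        counts = TransitionCounts(1, (1,), np.array([5, 0]), np.array([0, 5]))
        score = mdl_score(counts, k=1, M=10, n=7, lam=0.3, variant="mdl")
        assert score == pytest.approx(0.3 * (math.log2(7) + 2))

    def test_model_lengths(self):
        counts = TransitionCounts(1, (1,), np.array([5, 0]), np.array([0, 5]))
        mdl = mdl_score(counts, 1, 10, 7, 1.0, "mdl")
        bic = mdl_score(counts, 1, 10, 7, 1.0, "bic")
        assert mdl == pytest.approx(math.log2(7) + 2)  # ~4.807
        assert bic == pytest.approx((2 ** 1 / 2) * math.log2(10))

    def test_redundant_regulator_strictly_raises_model_term(self):
        net = xor_and_network()
        series = full_coverage_series(net)
        c2 = count_transitions(series, 2, (1,))
        c3 = count_transitions(series, 2, (1, 3))
        for variant in ("mdl", "bic"):
            s2 = mdl_score(c2, 1, 16, 3, 0.5, variant)
            s3 = mdl_score(c3, 2, 16, 3, 0.5, variant)
            assert s3 > s2  # data term can't improve, model term grows

    def test_huge_lambda_forces_single_regulators(self):
        net = generate_random_bnp(GenConfig(n=5, K=3, p=0.01, seed=7))
        series = generate_time_series(net, M=40, seed=8)
        inferred = infer_mdl(series, K=3, lam=1e6, variant="mdl")
        assert all(t.k == 1 for t in inferred.net.tables)

    def test_zero_lambda_reduces_to_max_likelihood(self):
        net = generate_random_bnp(GenConfig(n=4, K=2, p=0.01, seed=9))
        series = generate_time_series(net, M=25, seed=10)
        inferred = infer_mdl(series, K=2, lam=0.0, variant="mdl")
        from itertools import combinations

        for t, fitrec in zip(inferred.net.tables, inferred.fits):
            best = min(
                conditional_entropy(count_transitions(series, t.gene, W))
                for k in (1, 2)
                for W in combinations(range(1, 5), k)
            )
            got = conditional_entropy(count_transitions(series, t.gene, t.regulators))
            assert got == pytest.approx(25 * best / 25, abs=1e-12)


class TestUMDL:
    @pytest.mark.parametrize("m,expected", [(0, 0.0), (1, 1.0), (2, math.log2(2.5))])
    def test_bernoulli_nml_complexity(self, m, expected):
        assert nml_complexity(m) == pytest.approx(expected, abs=1e-12)

    def test_nml_complexity_monotone(self):
        vals = [nml_complexity(m) for m in range(0, 60)]
        assert all(b >= a for a, b in zip(vals, vals[1:]))

    def test_single_pure_pattern_costs_only_complexity(self):
        counts = TransitionCounts(1, (1,), np.array([0, 0]), np.array([8, 0]))
        from bnpval.inference import _umdl_code_length

        assert _umdl_code_length(counts, {}) == pytest.approx(nml_complexity(8))

    def test_predictive_regulator_lowers_code_length(self):
        """Noise-free data: conditioning on the true regulator removes the
        data-term entropy by more than the added complexity."""
        net = xor_and_network()
        series = full_coverage_series(net)
        from bnpval.inference import _umdl_code_length

        uninformative = count_transitions(series, 1, (1,))
        true_pair = count_transitions(series, 1, (2, 3))
        assert _umdl_code_length(true_pair, {}) < _umdl_code_length(uninformative, {})

    def test_exact_recovery_from_full_coverage(self):
        net = xor_and_network()
        inferred = infer_umdl(full_coverage_series(net), K=3, p=0.01)
        assert [t.regulators for t in inferred.net.tables] == [
            t.regulators for t in net.tables
        ]


class TestAdjacency:
    def test_melanoma_s100p_column_single_edge(self, melanoma):
        A = adjacency(melanoma)
        col = A[:, 2]  # S100P regulated only by MART1 (gene 7)
        assert col.sum() == 1 and col[6] == 1

    def test_disjoint_edge_sets_add(self):
        a = BNp((TruthTable(1, (1,), np.array([0, 1])),
                 TruthTable(2, (1,), np.array([0, 1]))), 0.1)
        b = BNp((TruthTable(1, (2,), np.array([0, 1])),
                 TruthTable(2, (2,), np.array([0, 1]))), 0.1)
        Aa, Ab = adjacency(a), adjacency(b)
        assert np.abs(Aa.astype(int) - Ab.astype(int)).sum() == Aa.sum() + Ab.sum()
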