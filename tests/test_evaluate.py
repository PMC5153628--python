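import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from cosine.data_io import InteractionDataset, SimilarityMatrix
from cosine.evaluate import (
    UndefinedMetricError,
    auc,
    aupr,
    chemical_cv_split,
    coldstart_stratify,
    cutoff_rank,
    fold_significance,
    loocv_top1,
    lt_bin_label,
    mcs_bin_label,
    tpr_at_top_percent,
    worst_ranks,
)
from cosine.optimizer import ModelConfig, OptimizerConfig
from cosine.cold_start import ColdStartConfig
from cosine.synthetic import ColdStartFixture, SyntheticSpec, make_coldstart_fixture


# ---------------------------------------------------------------- oracles


def auc_pairwise_oracle(scores, labels):
    """O(n^2) Mann-Whitney: fraction of (pos, neg) pairs ranked correctly, ties 1/2."""
    pos = [s for s, l in zip(scores, labels) if l == 1]
    neg = [s for s, l in zip(scores, labels) if l == 0]
    total = 0.0
    for p in pos:
        for q in neg:
            total += 1.0 if p > q else (0.5 if p == q else 0.0)
    return total / (len(pos) * len(neg))


def aupr_sweep_oracle(scores, labels):
    """Step-wise precision-recall integration at every distinct threshold."""
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels)
    n_pos = int((labels == 1).sum())
    thresholds = np.unique(scores)[::-1]
    area, prev_recall = 0.0, 0.0
    for t in thresholds:
        predicted = scores >= t
        tp = int(((labels == 1) & predicted).sum())
        precision = tp / int(predicted.sum())
        recall = tp / n_pos
        area += (recall - prev_recall) * precision
        prev_recall = recall
    return area


# ---------------------------------------------------------------- AUC / AUPR


class TestAuc:
    def test_perfect_separation(self):
        assert auc([3, 4, 1, 2], [1, 1, 0, 0]) == 1.0

    def test_all_tied_scores_give_half(self):
        assert auc([1, 1, 1, 1], [1, 0, 1, 0]) == 0.5

    @pytest.mark.parametrize("seed", range(20))
    def test_matches_pairwise_oracle(self, seed):
        rng = np.random.default_rng(seed)
        scores = np.round(rng.random(20), 2)  # rounding forces some ties
        labels = (rng.random(20) < 0.4).astype(int)
        if labels.sum() in (0, 20):
            labels[0], labels[1] = 0, 1
        assert auc(scores, labels) == pytest.approx(auc_pairwise_oracle(scores, labels), abs=1e-12)

    def test_single_class_rejected(self):
        with pytest.raises(UndefinedMetricError):
            auc([1, 2, 3], [1, 1, 1])

    def test_label_permutation_null_centers_at_half(self):
        rng = np.random.default_rng(0)
        scores = rng.random(50)
        labels = np.array([1] * 10 + [0] * 40)
        vals = []
        for _ in range(200):
            vals.append(auc(scores, rng.permutation(labels)))
        assert 0.45 <= np.mean(vals) <= 0.55


class TestAupr:
    def test_all_positives_ranked_first(self):
        assert aupr([4, 3, 2, 1], [1, 1, 0, 0]) == 1.0

    @pytest.mark.parametrize("k,n", [(1, 5), (3, 7), (10, 10)])
    def test_single_positive_at_rank_k_gives_one_over_k(self, k, n):
        scores = -np.arange(n, dtype=float)  # strictly decreasing, rank = index + 1
        labels = np.zeros(n, dtype=int)
        labels[k - 1] = 1
        assert aupr(scores, labels) == pytest.approx(1.0 / k, abs=1e-12)
        assert aupr_sweep_oracle(scores, labels) == pytest.approx(1.0 / k, abs=1e-12)

    @pytest.mark.parametrize("seed", range(20))
    def test_matches_threshold_sweep_oracle(self, seed):
        rng = np.random.default_rng(seed + 50)
        scores = rng.random(25)
        labels = (rng.random(25) < 0.3).astype(int)
        if labels.sum() == 0:
            labels[0] = 1
        assert aupr(scores, labels) == pytest.approx(aupr_sweep_oracle(scores, labels), abs=1e-12)

    def test_no_positives_rejected(self):
        with pytest.raises(UndefinedMetricError):
            aupr([1, 2], [0, 0])


# ---------------------------------------------------------------- ranks / TPR


class TestTprAtTopPercent:
    def test_cutoff_rank_rule(self):
        assert cutoff_rank(3500, 1) == 35
        assert cutoff_rank(3500, 10) == 350
        assert cutoff_rank(50, 10) == 5

    def test_top_ranked_single_target_always_recovered(self):
        scores = np.array([0.9, 0.1, 0.2, 0.3, 0.15, 0.05, 0.4, 0.6, 0.02, 0.01])
        assert tpr_at_top_percent(scores, [0], 10.0) == 1.0

    def test_worst_rank_tie_convention(self):
        scores = np.array([0.5, 0.5, 0.5, 0.1] + [0.0] * 16)
        # the three tied leaders all get worst rank 3
        assert worst_ranks(scores)[0] == 3
        assert tpr_at_top_percent(scores, [0], 10.0) == 0.0  # cutoff rank 2 < 3
        assert tpr_at_top_percent(scores, [0], 15.0) == 1.0  # cutoff rank 3

    @settings(max_examples=30, derandomize=True, deadline=None)
    @given(st.integers(0, 10_000))
    def test_monotone_in_r(self, seed):
        rng = np.random.default_rng(seed)
        scores = rng.random(40)
        true = rng.choice(40, size=5, replace=False)
        values = [tpr_at_top_percent(scores, true, r) for r in (5, 10, 20, 50, 100)]
        assert all(a <= b + 1e-12 for a, b in zip(values, values[1:]))

    def test_random_scores_null_rate_matches_r(self):
        """With random scores the expected TPR@10% is ~0.10."""
        rng = np.random.default_rng(1)
        vals = []
        for _ in range(1000):
            scores = rng.random(100)
            true = rng.choice(100, size=10, replace=False)
            vals.append(tpr_at_top_percent(scores, true, 10.0))
        assert np.mean(vals) == pytest.approx(0.10, abs=0.01)


# ---------------------------------------------------------------- splits


class TestChemicalCvSplit:
    def test_five_disjoint_folds_of_two(self):
        folds = chemical_cv_split(10, 5, seed=0)
        tests = [set(t) for _, t in folds]
        assert all(len(t) == 2 for t in tests)
        assert set().union(*tests) == set(range(10))
        for a in range(5):
            for b in range(a + 1, 5):
                assert not tests[a] & tests[b]

    def test_partition_property_each_round(self):
        folds = chemical_cv_split(23, 10, rounds=5, seed=3)
        assert len(folds) == 50
        for r in range(5):
            union = np.concatenate([folds[r * 10 + f][1] for f in range(10)])
            assert sorted(union) == list(range(23))
        sizes = {len(t) for _, t in folds}
        assert max(sizes) - min(sizes) <= 1

    def test_train_test_complementary(self):
        for train, test in chemical_cv_split(11, 3, seed=1):
            assert sorted(np.concatenate([train, test])) == list(range(11))

    def test_seed_determinism(self):
        a = chemical_cv_split(20, 5, seed=4)
        b = chemical_cv_split(20, 5, seed=4)
        c = chemical_cv_split(20, 5, seed=5)
        assert all((x[1] == y[1]).all() for x, y in zip(a, b))
        assert any((x[1] != y[1]).any() for x, y in zip(a, c))

    def test_too_many_folds_rejected(self):
        with pytest.raises(ValueError):
            chemical_cv_split(3, 5)


# ---------------------------------------------------------------- significance


class TestFoldSignificance:
    def test_identical_lists_reported_degenerate(self):
        res = fold_significance([0.8, 0.9, 0.7], [0.8, 0.9, 0.7])
        assert res.degenerate and not res.significant

    def test_large_constant_shift_is_significant(self):
        a = [0.9, 0.91, 0.89, 0.92, 0.9]
        b = [0.5, 0.51, 0.49, 0.52, 0.5]
        res = fold_significance(a, b)
        assert res.p_value < 1e-6 and res.significant

    def test_matches_closed_form_t_statistic(self):
        a = np.array([0.80, 0.85, 0.78, 0.90, 0.82])
        b = np.array([0.75, 0.80, 0.79, 0.84, 0.77])
        d = a - b
        t_expected = d.mean() / (d.std(ddof=1) / np.sqrt(len(d)))
        res = fold_significance(a, b)
        assert res.statistic == pytest.approx(t_expected, rel=1e-12)


# ---------------------------------------------------------------- stratification


class TestColdstartStratify:
    def test_bin_labels(self):
        assert lt_bin_label(7) == "6-10"
        assert lt_bin_label(1) == "1-5"
        assert lt_bin_label(20) == "16-20"
        assert lt_bin_label(21) == ">20"
        assert mcs_bin_label(0.05) == "0.0-0.1"
        assert mcs_bin_label(0.95) == "0.9-1.0"
        assert mcs_bin_label(1.0) == "0.9-1.0"

    def test_each_chemical_in_exactly_one_bin_per_criterion(self):
        fx = make_coldstart_fixture(SyntheticSpec(seed=2))
        strata = coldstart_stratify(fx, seed=0)
        for kind in ("ligands_per_target", "max_chemical_similarity"):
            assigned = [j for s in strata if s.kind == kind for j in s.chemicals]
            assert sorted(assigned) == sorted(fx.cold_chemicals)

    def test_halving_partitions_each_stratum(self):
        fx = make_coldstart_fixture(SyntheticSpec(seed=2))
        for s in coldstart_stratify(fx, seed=1):
            assert sorted(s.test_half + s.train_half) == s.chemicals
            assert abs(len(s.test_half) - len(s.train_half)) <= 1


# ---------------------------------------------------------------- LOOCV Top-1


class TestLoocvTop1:
    def _duplicate_fixture(self):
        """Each chemical 2k+1 duplicates chemical 2k: same targets, similarity 1."""
        rng = np.random.default_rng(9)
        m, n = 8, 6
        base = (rng.random((m, n // 2)) < 0.35).astype(float)
        base[:, base.sum(axis=0) == 0] = 0.0
        for col in range(n // 2):  # ensure at least one interaction per chemical
            if base[:, col].sum() == 0:
                base[rng.integers(m), col] = 1.0
        R = np.repeat(base, 2, axis=1)
        data = InteractionDataset([f"t{i}" for i in range(m)], [f"c{j}" for j in range(n)], R)
        S = np.full((n, n), 0.05)
        for k in range(n // 2):
            S[2 * k, 2 * k + 1] = S[2 * k + 1, 2 * k] = 1.0
        np.fill_diagonal(S, 1.0)
        N = SimilarityMatrix([f"c{j}" for j in range(n)], S)
        A = rng.random((m, m))
        SM = (A + A.T) / 2
        np.fill_diagonal(SM, 1.0)
        M = SimilarityMatrix([f"t{i}" for i in range(m)], SM)
        return data, M, N

    def test_duplicate_chemicals_give_perfect_top1(self):
        data, M, N = self._duplicate_fixture()
        report = loocv_top1(
            data, M, N,
            model_cfg=ModelConfig(rank=3),
            opt_cfg=OptimizerConfig(iterations=200, seed=0),
            cold_cfg=ColdStartConfig(J=1, v=0.0),
            mode="full",
        )
        mean, _ = report.aggregate("top1")
        assert mean == 1.0

    def test_tie_at_rank_one_counted_conservatively(self):
        # constructed tie: two targets share the max score -> worst rank 2 -> miss
        scores = np.array([0.7, 0.7, 0.1])
        assert worst_ranks(scores)[0] == 2
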