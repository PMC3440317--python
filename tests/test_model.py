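"""SVM training, ROC/max-F evaluation, DeLong comparison, weights, tendency."""

import numpy as np
import pytest

import tripitope as tp
from tripitope.encoding import EncodingConfig, PropensityTable
from tripitope.matrices import TriPeptideIndex
from tripitope.model import l2_normalize, mean_ci
from _oracles import pair_counting_auc


class TestRocAndMaxF:
    def test_perfect_separation(self):
        scores = np.array([3.0, 2.5, 2.0, -1.0, -2.0])
        labels = np.array([1, 1, 1, 0, 0])
        roc, ev = tp.roc_and_max_f(scores, labels)
        assert ev.auc == 1.0 and ev.f == 1.0 and ev.sn == 1.0 and ev.p == 1.0

    def test_hand_listed_pairs_match_pair_counting(self):
        scores = np.array([0.9, 0.8, 0.8, 0.4, 0.3, 0.1])
        labels = np.array([1, 0, 1, 0, 1, 0])
        _, ev = tp.roc_and_max_f(scores, labels)
        # 9 pairs: concordant 6.5 of 9 (one tie counts half) -> 0.7222...
        assert ev.auc == pytest.approx(pair_counting_auc(scores, labels))
        assert ev.auc == pytest.approx((6 + 0.5) / 9)

    def test_trapezoid_equals_pair_counting_on_random_sets(self):
        rng = np.random.default_rng(17)
        for _ in range(20):
            n = int(rng.integers(10, 200))
            labels = rng.integers(0, 2, size=n)
            if labels.min() == labels.max():
                labels[0] = 1 - labels[0]
            scores = np.round(rng.normal(size=n) + labels, 1)  # forces ties
            _, ev = tp.roc_and_max_f(scores, labels)
            assert ev.auc == pytest.approx(pair_counting_auc(scores, labels))

    def test_f_measure_consistency_and_threshold(self):
        rng = np.random.default_rng(3)
        labels = rng.integers(0, 2, size=100)
        labels[:2] = [0, 1]
        scores = rng.normal(size=100) + 0.8 * labels
        _, ev = tp.roc_and_max_f(scores, labels)
        assert ev.f == pytest.approx(2 * ev.sn * ev.p / (ev.sn + ev.p))
        # recompute metrics at the reported threshold
        calls = scores >= ev.threshold
        tp_ = (calls & (labels == 1)).sum()
        assert ev.sn == pytest.approx(tp_ / (labels == 1).sum())
        assert ev.p == pytest.approx(tp_ / calls.sum())

    def test_single_class_rejected(self):
        with pytest.raises(ValueError, match="both classes"):
            tp.roc_and_max_f(np.array([1.0, 2.0]), np.array([1, 1]))


class TestDelong:
    labels = np.array([1] * 8 + [0] * 10)
    a = np.array([0.92, 0.81, 0.75, 0.66, 0.58, 0.44, 0.35, 0.31,
                  0.72, 0.61, 0.49, 0.42, 0.36, 0.29, 0.25, 0.18, 0.12, 0.07])
    b = np.array([0.88, 0.73, 0.61, 0.57, 0.53, 0.41, 0.38, 0.27,
                  0.80, 0.69, 0.55, 0.46, 0.33, 0.31, 0.22, 0.15, 0.11, 0.05])

    def test_identical_scores_give_p_one(self):
        r = tp.compare_roc(self.a, self.a, self.labels)
        assert r.p_value == 1.0 and r.z == 0.0

    def test_matches_independent_reference(self):
        """Frozen expected values from an independent paired DeLong
        implementation (R pROC) on this fixed score set."""
        r = tp.compare_roc(self.a, self.b, self.labels)
        assert r.auc_a == pytest.approx(0.80, abs=1e-12)
        assert r.auc_b == pytest.approx(0.725, abs=1e-12)
        assert r.z == pytest.approx(1.5181824820, abs=1e-9)
        assert r.p_value == pytest.approx(0.1289684024, abs=1e-9)

    def test_strong_separation_vs_noise_is_significant(self):
        rng = np.random.default_rng(0)
        labels = np.array([1] * 150 + [0] * 150)
        strong = labels + rng.normal(scale=0.3, size=300)
        noise = rng.normal(size=300)
        r = tp.compare_roc(strong, noise, labels)
        assert r.p_value < 1e-6

    def test_degenerate_variance_is_not_reported_as_zero(self):
        labels = np.array([1, 1, 0, 0])
        r = tp.compare_roc(np.array([2.0, 1.0, 0.5, 0.1]),
                           np.array([0.1, 0.5, 1.0, 2.0]), labels)
        assert r.p_value != 0.0  # either a real p or nan, never a fake zero

    def test_shape_mismatch_rejected(self):
        with pytest.raises(ValueError, match="same labeled instances"):
            tp.compare_roc(self.a[:-1], self.b[:-1], self.labels)


def test_mean_ci_matches_t_interval():
    vals = [0.6, 0.7, 0.65, 0.72, 0.68]
    mean, half = mean_ci(vals)
    from scipy import stats

    sd = np.std(vals, ddof=1)
    assert mean == pytest.approx(np.mean(vals))
    assert half == pytest.approx(stats.t.ppf(0.975, 4) * sd / np.sqrt(5))


def _toy_config():
    return EncodingConfig(
        matrix=tp.load_substitution_matrix("blosum62"), mode="similarity_only"
    )


class TestTraining:
    def test_separable_toy_data_fits_perfectly(self):
        peps = ["QQPQQPQQPQ", "QPQPQPQQPP", "PPQQPPQQPP",
                "MKVLWRDSTG", "ACDEFGHIKL", "WWRDSTGHIK"]
        labels = np.array([1, 1, 1, 0, 0, 0])
        model = tp.train_model(peps, labels, _toy_config(), tp.SvmConfig())
        scores = model.score_peptides(peps)
        assert np.array_equal(scores > 0, labels == 1)

    def test_single_class_rejected(self):
        with pytest.raises(ValueError, match="single class"):
            tp.train_model(["AAAA", "CCCC"], np.array([1, 1]), _toy_config())

    def test_mixed_lengths_rejected(self):
        with pytest.raises(ValueError, match="one length"):
            tp.train_model(["AAAA", "CCCCC"], np.array([1, 0]), _toy_config())

    def test_save_load_round_trip(self, tmp_path, small_model):
        path = tmp_path / "model.joblib"
        small_model.save(path)
        again = tp.TrainedModel.load(path)
        peps = ["QQPQQPQQPQQPQQPQQPQQ", "MKVLWRDSTGHACDEFGHIK"]
        assert np.allclose(again.score_peptides(peps),
                           small_model.score_peptides(peps))


class TestAttributeWeights:
    def test_weights_equal_dual_expansion(self, small_model):
        ranked = tp.attribute_weights(small_model)
        assert len(ranked) == tp.N_TRIPEPTIDES
        w = small_model.dual_coefficients @ small_model.support_vectors
        top_trip, top_w = ranked[0]
        assert top_w == pytest.approx(w.max())
        weights = sorted((v for _, v in ranked), reverse=True)
        assert weights == [v for _, v in ranked]

    def test_weights_permute_with_feature_order(self, small_benchmark):
        dataset, background = small_benchmark
        seqs = dataset.sequences()[:40] + dataset.sequences()[-40:]
        labels = np.array([1] * 40 + [0] * 40)
        rng = np.random.default_rng(21)
        perm = rng.permutation(tp.N_TRIPEPTIDES)
        base_cfg = _toy_config()
        model = tp.train_model(seqs, labels, base_cfg)
        idx = TriPeptideIndex(permutation=perm)
        cfg_p = EncodingConfig(matrix=base_cfg.matrix, mode="similarity_only",
                               index=idx)
        model_p = tp.train_model(seqs, labels, cfg_p)
        w = dict(tp.attribute_weights(model))
        w_p = dict(tp.attribute_weights(model_p))
        for t in ("QQP", "AAA", "MKV"):
            assert w_p[t] == pytest.approx(w[t], rel=1e-9, abs=1e-12)


class TestCrossValidation:
    def test_planted_signal_recovered(self, small_benchmark):
        dataset, background = small_benchmark
        cv = tp.cross_validate(dataset, background)
        assert cv.mean_auc > 0.75
        assert len(cv.fold_results) == 5
        for r in cv.fold_results:
            assert r.f == pytest.approx(2 * r.sn * r.p / (r.sn + r.p))

    def test_deterministic_given_identical_inputs(self, small_benchmark):
        dataset, background = small_benchmark
        a = tp.cross_validate(dataset, background)
        b = tp.cross_validate(dataset, background)
        assert a.summary() == b.summary()
        assert np.array_equal(a.pooled_scores, b.pooled_scores)

    def test_grid_search_returns_max_f_config(self, small_benchmark):
        dataset, background = small_benchmark
        grid = [tp.SvmConfig(c=32, g=0.05, p=0.5),
                tp.SvmConfig(c=2**-10, g=2**-12, p=2**-5)]
        res = tp.grid_search_cv(dataset, background, grid)
        best_f = max(r.mean_f for r in res.all_results)
        assert res.best.mean_f == best_f
        assert len(res.all_results) == 2
        again = tp.grid_search_cv(dataset, background, grid)
        assert again.best_config == res.best_config
        assert again.best.summary() == res.best.summary()

    def test_empty_grid_rejected(self, small_benchmark):
        dataset, background = small_benchmark
        with pytest.raises(ValueError, match="grid is empty"):
            tp.grid_search_cv(dataset, background, [])

    def test_default_grid_spans_stated_ranges(self):
        grid = tp.default_grid()
        cs = {cfg.c for cfg in grid}
        assert 2.0**-10 in cs and 2.0**-1 in cs and 32.0 in cs
        assert len(grid) == 10 * 10 * 4 + 1


class _ConstantScorer:
    """Stub standing in for a model that scores every peptide equally."""

    def score_peptides(self, peptides):
        return np.zeros(len(peptides))


class TestTendency:
    def test_separated_pools(self, small_model):
        enriched = ["QQPQQPQQPQQPQQPQQPQQ", "QPQPQPQPQPQPQPQPQPQP"]
        neutral = ["MKVLWRDSTGHACDEFGHIK", "LIVMSTGHKRDEANCWYFPQ"]
        comp = tp.tendency_test(small_model, enriched, neutral, [2])
        assert comp[2] == (2, 0)

    def test_constant_scores_follow_input_order(self):
        comp = tp.tendency_test(
            _ConstantScorer(), ["AAA", "CCC"], ["DDD", "EEE"], [1, 2, 3]
        )
        assert comp[1] == (1, 0) and comp[2] == (2, 0) and comp[3] == (2, 1)

    def test_top_n_exceeding_pool_rejected(self, small_model):
        with pytest.raises(ValueError, match="exceeds the pooled size"):
            tp.tendency_test(small_model, ["A" * 20], ["C" * 20], [5])


def test_l2_normalize_handles_zero_rows():
    x = np.array([[3.0, 4.0], [0.0, 0.0]])
    out = l2_normalize(x)
    assert np.allclose(out[0], [0.6, 0.8])
    assert np.all(out[1] == 0)
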