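"""Endpoint model fitting, scoring, threshold selection and cross-validation."""

import numpy as np
import pytest

from cpirank import (
    CPIMatrix,
    IndicationLabels,
    auroc,
    build_endpoints,
    cross_validate,
    fit_endpoint_model,
    predict_scores,
    select_threshold,
)
from cpirank.classifier import EndpointModel
from cpirank.synthetic import SyntheticConfig, generate, permute_labels


def max_f_oracle(scores, y):
    """Exhaustive sweep over every cut position; returns (best_f, thresholds attaining it)."""
    scores = np.asarray(scores, float)
    y = np.asarray(y, int)
    u = np.unique(scores)
    low = u[0] - 0.5 * (u[-1] - u[0]) if u.size > 1 else u[0] - 0.5
    high = u[-1] + 0.5 * (u[-1] - u[0]) if u.size > 1 else u[-1] + 0.5
    cands = [low] + [(a + b) / 2 for a, b in zip(u[:-1], u[1:])] + [high]
    results = []
    for t in cands:
        tp = sum(1 for s, l in zip(scores, y) if s >= t and l == 1)
        fp = sum(1 for s, l in zip(scores, y) if s >= t and l == 0)
        fn = sum(1 for s, l in zip(scores, y) if s < t and l == 1)
        f = 0.0 if tp == 0 else 2 * tp / (2 * tp + fp + fn)
        results.append((t, f))
    best = max(f for _, f in results)
    return best, [t for t, f in results if f == best]


class TestFit:
    def test_separable_toy_perfect_training_auroc(self):
        X = np.array([[-9.0, -5.0], [-8.5, -5.2], [-5.0, -8.8], [-5.3, -9.1]])
        y = np.array([1, 1, 0, 0])
        m = fit_endpoint_model(X, y)
        assert auroc(predict_scores(m, X), y) == 1.0

    def test_single_class_rejected(self):
        X = np.zeros((4, 2))
        with pytest.raises(ValueError, match="single class"):
            fit_endpoint_model(X, np.ones(4))

    def test_non_finite_feature_rejected(self):
        X = np.array([[1.0, np.nan], [0.0, 1.0]])
        with pytest.raises(ValueError, match="non-finite"):
            fit_endpoint_model(X, np.array([0, 1]))

    def test_duplicated_columns_share_weight(self):
        # L2 symmetry: two identical feature columns get equal weights, each
        # half of the weight a merged single column would carry in effect
        rng = np.random.default_rng(3)
        x = rng.normal(size=60)
        y = (x + 0.3 * rng.normal(size=60) > 0).astype(int)
        X = np.column_stack([x, x, rng.normal(size=60)])
        m = fit_endpoint_model(X, y)
        assert m.weights[0] == pytest.approx(m.weights[1], abs=1e-6)

    def test_zero_variance_feature_gets_zero_weight(self):
        rng = np.random.default_rng(4)
        x = rng.normal(size=50)
        y = (x > 0).astype(int)
        X = np.column_stack([x, np.full(50, -7.0)])
        m = fit_endpoint_model(X, y)
        assert m.weights[1] == 0.0
        assert m.feature_sds[1] == 1.0


class TestPredict:
    def test_zero_model_scores_half(self):
        m = EndpointModel("", np.zeros(3), 0.0, np.zeros(3), np.ones(3), 1.0)
        np.testing.assert_allclose(predict_scores(m, np.zeros((5, 3))), 0.5)

    def test_monotone_in_positive_weight_feature(self):
        m = EndpointModel("", np.array([1.0, -0.5]), 0.1, np.zeros(2), np.ones(2), 1.0)
        base = predict_scores(m, np.array([[0.2, 0.3]]))[0]
        bumped = predict_scores(m, np.array([[0.7, 0.3]]))[0]
        assert bumped > base

    def test_dimension_mismatch_rejected(self):
        m = EndpointModel("", np.zeros(3), 0.0, np.zeros(3), np.ones(3), 1.0)
        with pytest.raises(ValueError, match="feature count"):
            predict_scores(m, np.zeros((2, 4)))

    def test_deterministic_across_runs(self):
        rng = np.random.default_rng(5)
        X = rng.normal(size=(30, 4))
        y = (X[:, 0] > 0).astype(int)
        s1 = predict_scores(fit_endpoint_model(X, y), X)
        s2 = predict_scores(fit_endpoint_model(X.copy(), y.copy()), X.copy())
        assert np.array_equal(s1, s2)


class TestSelectThreshold:
    def test_perfect_separation_returns_midpoint(self):
        t = select_threshold(np.array([0.9, 0.8, 0.4, 0.2]), np.array([1, 1, 0, 0]))
        assert t == pytest.approx(0.6)

    def test_all_positive_returns_low_sentinel(self):
        scores = np.array([0.3, 0.6, 0.9])
        t = select_threshold(scores, np.ones(3, dtype=int))
        assert t < scores.min()  # predict everything positive

    def test_two_point_inversion_prefers_all_positive(self):
        # scores [0.2, 0.9], y [1, 0]: predicting both positive gives
        # F = 2/3, the best attainable; the low sentinel wins
        scores = np.array([0.2, 0.9])
        y = np.array([1, 0])
        t = select_threshold(scores, y)
        best, attaining = max_f_oracle(scores, y)
        assert best == pytest.approx(2 / 3)
        assert t == pytest.approx(min(attaining))

    def test_no_positives_rejected(self):
        with pytest.raises(ValueError, match="F-score"):
            select_threshold(np.array([0.1, 0.2]), np.array([0, 0]))

    def test_matches_exhaustive_oracle_on_random_instances(self):
        rng = np.random.default_rng(12)
        for _ in range(500):
            n = rng.integers(2, 15)
            scores = np.round(rng.random(n), 2)  # deliberate ties
            y = rng.integers(0, 2, n)
            if y.sum() == 0:
                y[rng.integers(n)] = 1
            t = select_threshold(scores, y)
            best, attaining = max_f_oracle(scores, y)
            assert t == pytest.approx(min(attaining)), (scores, y)


class TestCrossValidate:
    @staticmethod
    def _toy(seed=0, n=20, nt=4):
        rng = np.random.default_rng(seed)
        drugs = [f"D{i}" for i in range(n)]
        scores = rng.normal(-7, 1, size=(n, nt))
        cpi = CPIMatrix(drugs, [f"T{j}" for j in range(nt)], scores)
        strong = scores[:, 0] < np.median(scores[:, 0])
        pairs = {(d, "250.00") for d, s in zip(drugs, strong) if s}
        pairs |= {(d, "401.1") for d in drugs[:8]}
        labels = IndicationLabels(frozenset(drugs), frozenset(pairs))
        eps = build_endpoints(labels, "disease")
        return cpi, labels, eps

    def test_deterministic_given_seed(self):
        cpi, labels, eps = self._toy()
        p1, r1 = cross_validate(cpi, labels, eps, k=5, repeats=2, seed=7)
        p2, r2 = cross_validate(cpi, labels, eps, k=5, repeats=2, seed=7)
        for a, b in zip(p1, p2):
            np.testing.assert_array_equal(a.scores, b.scores)
        assert r1.metrics["auroc"] == r2.metrics["auroc"]

    def test_every_drug_scored_once_per_repeat(self):
        cpi, labels, eps = self._toy()
        preds, _ = cross_validate(cpi, labels, eps, k=10, repeats=2, seed=1)
        for ps in preds:
            assert np.isfinite(ps.scores).all()
            folds = np.array([ps.provenance["fold_map"][d] for d in cpi.drug_ids])
            sizes = np.bincount(folds, minlength=10)
            assert sizes.max() - sizes.min() <= 1

    def test_k_larger_than_drugs_rejected(self):
        cpi, labels, eps = self._toy()
        with pytest.raises(ValueError, match="exceeds"):
            cross_validate(cpi, labels, eps, k=100, repeats=1, seed=0)

    def test_out_of_fold_score_ignores_own_label(self):
        # corrupting one held-out drug's label must not change its score
        cpi, labels, eps = self._toy()
        preds, _ = cross_validate(cpi, labels, eps, k=5, repeats=1, seed=3)
        target_drug = cpi.drug_ids[0]
        flipped = set(labels.positives)
        key = (target_drug, "250.00")
        if key in flipped:
            flipped.discard(key)
        else:
            flipped.add(key)
        labels2 = IndicationLabels(labels.drug_universe, frozenset(flipped))
        eps2 = build_endpoints(labels2, "disease", min_positives=eps.min_positives)
        preds2, _ = cross_validate(cpi, labels2, eps2, k=5, repeats=1, seed=3)
        i = cpi.drug_ids.index(target_drug)
        fold_of_target = preds[0].provenance["fold_map"][target_drug]
        # all drugs in the same fold as the target are scored by models that
        # never saw the flipped label
        same_fold = [
            j for j, d in enumerate(cpi.drug_ids)
            if preds[0].provenance["fold_map"][d] == fold_of_target
        ]
        j250 = preds[0].endpoint_codes.index("250.00")
        np.testing.assert_array_equal(
            preds[0].scores[same_fold, j250], preds2[0].scores[same_fold, j250]
        )

    def test_null_labels_give_chance_auroc(self):
        # permuted labels: pooled out-of-fold AUROC near 0.5 (the pooled
        # statistic carries a small finite-sample bias that shrinks with the
        # drug count, so this runs at the generator's default scale)
        cfg = SyntheticConfig(seed=21)
        cpi, labels, _ = generate(cfg)
        null = permute_labels(labels, seed=22)
        eps = build_endpoints(null, "disease")
        _, rep = cross_validate(cpi, null, eps, k=10, repeats=2, seed=23)
        assert rep.metrics["auroc"].mean == pytest.approx(0.5, abs=0.04)

    def test_constant_fallback_for_sparse_endpoint(self):
        # an endpoint with exactly 5 positives under 10-fold CV will hit
        # training splits with <2 positives; scores must still fill in [0,1]
        rng = np.random.default_rng(9)
        drugs = [f"D{i}" for i in range(20)]
        cpi = CPIMatrix(drugs, ["T0", "T1"], rng.normal(-7, 1, (20, 2)))
        pairs = {(d, "300.4") for d in drugs[:5]}
        labels = IndicationLabels(frozenset(drugs), frozenset(pairs))
        eps = build_endpoints(labels, "disease")
        preds, _ = cross_validate(cpi, labels, eps, k=10, repeats=1, seed=0)
        assert np.isfinite(preds[0].scores).all()
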