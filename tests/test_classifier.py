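import json

import numpy as np
import pandas as pd
import pytest

from prognoset.classifier import (
    LinearClassifier,
    decision_scores,
    fit_svm_arrays,
    train_linear_svm,
)
from prognoset.cohorts import CohortLabeling
from prognoset.io import ExpressionMatrix


def matrix_from(rows: dict[str, list[float]], cohort="A") -> ExpressionMatrix:
    values = pd.DataFrame.from_dict(rows, orient="index")
    values.columns = [f"s{i}" for i in range(values.shape[1])]
    return ExpressionMatrix(values=values,
                            cohort_of_sample={c: cohort for c in values.columns})


def labeling(positives, negatives) -> CohortLabeling:
    return CohortLabeling(positives=list(positives), negatives=list(negatives))


class TestSignConvention:
    x = matrix_from({"g": [10.0, 9.5, 9.8, 2.0, 2.5, 2.2]})
    pos, neg = ["s0", "s1", "s2"], ["s3", "s4", "s5"]

    def test_high_expression_in_recurrence_gives_positive_weight(self):
        c = train_linear_svm(self.x, labeling(self.pos, self.neg))
        assert c.weights[0] > 0

    def test_label_flip_negates_weight(self):
        c1 = train_linear_svm(self.x, labeling(self.pos, self.neg))
        c2 = train_linear_svm(self.x, labeling(self.neg, self.pos))
        assert c2.weights[0] == pytest.approx(-c1.weights[0], abs=1e-6)


def _brute_force_direction(x, y, n_angles=3600):
    """Hard-margin maximizer over a fine grid of 2-D weight directions."""
    best = (-np.inf, None)
    for theta in np.linspace(0, np.pi, n_angles, endpoint=False):
        w = np.array([np.cos(theta), np.sin(theta)])
        proj = x @ w
        for sign in (1, -1):
            p = sign * proj
            margin = (p[y == 1].min() - p[y == -1].max()) / 2.0
            if margin > best[0]:
                best = (margin, sign * w)
    return best


def test_separator_matches_grid_search_margin_maximizer():
    # 6-point, 2-gene, linearly separable toy set; high cost approximates the
    # hard-margin solution the exhaustive grid search computes
    x = np.array([[2.0, 2.0], [2.5, 1.5], [3.0, 2.5],
                  [0.0, 0.0], [0.5, -0.5], [-0.5, 0.5]])
    y = np.array([1, 1, 1, -1, -1, -1])
    margin, w_dir = _brute_force_direction(x, y)
    w, b, center, scale = fit_svm_arrays(x, y, cost=1e4, standardize=False)
    fitted_dir = w / np.linalg.norm(w)
    assert fitted_dir == pytest.approx(w_dir, abs=1e-2)
    assert 1.0 / np.linalg.norm(w) == pytest.approx(margin, abs=1e-2)


def test_solver_matches_reference_svm_implementations(strong_meta):
    """liblinear-level fit equals LinearSVC and the exact libsvm solution."""
    from sklearn.svm import SVC, LinearSVC

    x = strong_meta.features("TRAIN", ["FAM01", "FAM02", "FAM03"])
    y = strong_meta.class_labels("TRAIN")
    w, b, center, scale = fit_svm_arrays(x, y, cost=1.0)
    z = (x - center) / scale
    lsvc = LinearSVC(loss="hinge", C=1.0, tol=1e-6, max_iter=200000,
                     random_state=0).fit(z, y)
    np.testing.assert_allclose(w, lsvc.coef_.ravel(), atol=1e-9)
    assert b == pytest.approx(float(lsvc.intercept_[0]), abs=1e-9)
    svc = SVC(kernel="linear", C=1.0, tol=1e-7).fit(z, y)
    np.testing.assert_allclose(w, svc.coef_.ravel(), atol=1e-4)
    assert b == pytest.approx(float(svc.intercept_[0]), abs=1e-4)


class TestDecisionScores:
    def test_hand_computed_dot_product(self):
        c = LinearClassifier(
            gene_ids=["g1", "g2"], weights=[0.5, -0.25], bias=0.1,
            center=[1.0, 2.0], scale=[2.0, 4.0], cost=1.0,
        )
        x = matrix_from({"g1": [3.0, 1.0, 5.0], "g2": [2.0, 6.0, 10.0]})
        got = decision_scores(c, x)
        expected = [0.5 * 1.0 - 0.25 * 0.0 + 0.1,
                    0.5 * 0.0 - 0.25 * 1.0 + 0.1,
                    0.5 * 2.0 - 0.25 * 2.0 + 0.1]
        np.testing.assert_allclose(got.to_numpy(), expected, atol=1e-9)

    def test_zero_weights_constant_bias(self):
        c = LinearClassifier(gene_ids=["g"], weights=[0.0], bias=0.7,
                             center=[0.0], scale=[1.0], cost=1.0)
        x = matrix_from({"g": [1.0, 5.0, 9.0]})
        assert set(decision_scores(c, x)) == {0.7}

    def test_separating_classifier_ranks_training_classes(self):
        x = matrix_from({"g": [10.0, 9.5, 2.0, 2.5]})
        lab = labeling(["s0", "s1"], ["s2", "s3"])
        c = train_linear_svm(x, lab)
        s = decision_scores(c, x)
        assert min(s[lab.positives]) > max(s[lab.negatives])

    def test_missing_gene_error(self):
        c = LinearClassifier(gene_ids=["absent"], weights=[1.0], bias=0.0,
                             center=[0.0], scale=[1.0], cost=1.0)
        with pytest.raises(ValueError, match="absent"):
            decision_scores(c, matrix_from({"g": [1.0]}))


class TestInvariances:
    x = matrix_from(
        {"g1": [9.0, 8.0, 8.7, 3.0, 3.5, 2.8], "g2": [1.0, 1.5, 0.6, 4.0, 4.4, 3.9]}
    )
    lab = labeling(["s0", "s1", "s2"], ["s3", "s4", "s5"])

    def test_gene_order_permutes_weights_not_scores(self):
        c1 = train_linear_svm(self.x, self.lab)
        flipped = ExpressionMatrix(
            values=self.x.values.loc[["g2", "g1"]],
            cohort_of_sample=dict(self.x.cohort_of_sample),
        )
        c2 = train_linear_svm(flipped, self.lab)
        np.testing.assert_allclose(c2.weights, c1.weights[::-1], atol=1e-9)
        np.testing.assert_allclose(
            decision_scores(c2, flipped), decision_scores(c1, self.x), atol=1e-9
        )

    def test_constant_gene_shift_absorbed_by_centering(self):
        c1 = train_linear_svm(self.x, self.lab)
        shifted = ExpressionMatrix(
            values=self.x.values + np.array([[5.0], [0.0]]),
            cohort_of_sample=dict(self.x.cohort_of_sample),
        )
        c2 = train_linear_svm(shifted, self.lab)
        s1 = decision_scores(c1, self.x)
        s2 = decision_scores(c2, shifted)
        np.testing.assert_allclose(s2.to_numpy(), s1.to_numpy(), atol=1e-6)

    def test_duplicating_samples_keeps_separator_at_high_cost(self):
        c1 = train_linear_svm(self.x, self.lab, cost=1e3)
        doubled = ExpressionMatrix(
            values=pd.concat(
                [self.x.values,
                 self.x.values.rename(columns=lambda s: s + "d")], axis=1
            ),
            cohort_of_sample={
                **self.x.cohort_of_sample,
                **{s + "d": "A" for s in self.x.sample_ids},
            },
        )
        lab2 = labeling(
            self.lab.positives + [s + "d" for s in self.lab.positives],
            self.lab.negatives + [s + "d" for s in self.lab.negatives],
        )
        c2 = train_linear_svm(doubled, lab2, cost=1e3)
        np.testing.assert_allclose(c2.weights, c1.weights, atol=1e-4)
        assert c2.bias == pytest.approx(c1.bias, abs=1e-4)


def test_training_errors_and_zero_variance(caplog):
    x = matrix_from({"g": [1.0, 2.0, 3.0, 4.0]})
    with pytest.raises(ValueError, match="single class"):
        train_linear_svm(x, labeling(["s0", "s1", "s2", "s3"], []))
    flat = matrix_from({"g": [5.0, 5.0, 5.0, 5.0], "h": [1.0, 2.0, 6.0, 7.0]})
    with caplog.at_level("WARNING"):
        c = train_linear_svm(flat, labeling(["s2", "s3"], ["s0", "s1"]))
    assert c.scale[0] == 1.0
    assert "zero-variance" in caplog.text


def test_json_round_trip(tmp_path):
    c = LinearClassifier(gene_ids=["g1", "g2"], weights=[0.4, -0.2], bias=-0.05,
                         center=[8.0, 7.5], scale=[1.5, 1.2], cost=2.0,
                         training_cohort="TRAIN")
    path = tmp_path / "clf.json"
    c.to_json(path)
    back = LinearClassifier.from_json(path)
    assert back.gene_ids == c.gene_ids
    np.testing.assert_allclose(back.weights, c.weights)
    np.testing.assert_allclose(back.center, c.center)
    assert back.bias == c.bias and back.cost == c.cost
    assert back.training_cohort == "TRAIN"
    assert json.loads(c.to_json())["cost"] == 2.0
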