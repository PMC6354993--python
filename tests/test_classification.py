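"""Classification: accuracy accounting, fold partitions, CV mechanics, ANOVA."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from aeromode.classification import (
    CVConfig,
    accuracy,
    extract_features,
    kfold_partition,
    mode_sweep,
    one_way_anova,
    pairwise_misclassification,
    predict,
    run_cv,
    train_classifier,
)


# ------------------------------------------------------------- Eq-style accounting

def test_accuracy_trivial_confusions():
    assert accuracy(np.diag([5, 7, 9])) == 1.0
    assert accuracy(np.array([[0, 3], [4, 0]])) == 0.0
    with pytest.raises(ValueError):
        accuracy(np.zeros((2, 2)))


def test_worked_example_from_printed_misclassification_addends():
    # POD-RF with 25 retained modes: pair rates 0.7%, 20.7%, 1.5%, 3.0%
    # sum to 25.9% total misclassification, i.e. 74.1% accuracy.
    total = 1000
    c = np.zeros((5, 5), dtype=int)
    c[1, 2] = 7    # A1-A2: 0.7%
    c[2, 3] = 207  # A2-A3: 20.7%
    c[2, 4] = 15   # A2-A4: 1.5%
    c[3, 4] = 30   # A3-A4: 3.0%
    correct = total - c.sum()
    np.fill_diagonal(c, [correct // 5 + (i < correct % 5) for i in range(5)])
    assert round(100 * accuracy(c), 1) == 74.1
    rates = pairwise_misclassification(c)
    assert round(100 * sum(rates.values()), 1) == 25.9
    assert rates[("A1", "A2")] == 0.007
    assert rates[("A2", "A3")] == 0.207


def test_pairwise_rates_toy_and_zero_cases():
    rates = pairwise_misclassification(np.array([[3, 1], [2, 4]]), labels=("x", "y"))
    assert rates[("x", "y")] == 3 / 10
    none = pairwise_misclassification(np.diag([2, 3, 4]), labels=("a", "b", "c"))
    assert all(v == 0.0 for v in none.values())


@settings(derandomize=True, max_examples=40)
@given(st.integers(0, 10**6))
def test_rates_and_accuracy_always_sum_to_one(seed):
    g = np.random.default_rng(seed)
    c = g.integers(0, 50, size=(5, 5))
    c[0, 0] += 1  # nonempty
    rates = pairwise_misclassification(c)
    # integer-level identity: pair counts account for every off-diagonal entry
    assert sum(rates.values()) * c.sum() == pytest.approx(c.sum() - np.trace(c), abs=1e-9)
    assert accuracy(c) + sum(rates.values()) == pytest.approx(1.0, abs=1e-12)


# --------------------------------------------------------------- fold partitions

def test_kfold_covers_every_sample_with_balanced_sizes():
    assignment = kfold_partition(405, 10, seed=0)
    sizes = np.bincount(assignment, minlength=10)
    assert sorted(sizes) == [40] * 5 + [41] * 5
    assert np.array_equal(kfold_partition(405, 10, seed=0), assignment)
    assert not np.array_equal(kfold_partition(405, 10, seed=1), assignment)


def test_stratified_kfold_preserves_class_proportions():
    labels = np.repeat([f"A{i}" for i in range(5)], 81)
    assignment = kfold_partition(405, 10, seed=3, stratify=True, labels=labels)
    for fold in range(10):
        in_fold = labels[assignment == fold]
        counts = [np.sum(in_fold == f"A{i}") for i in range(5)]
        assert all(c in (8, 9) for c in counts)


def test_kfold_rejects_more_folds_than_samples():
    with pytest.raises(ValueError):
        kfold_partition(5, 10, seed=0)


# ------------------------------------------------------------------ classifiers

@pytest.mark.parametrize("clf", ["RF", "SVM"])
def test_separable_blobs_classify_perfectly(clf):
    g = np.random.default_rng(0)
    X = np.vstack([g.normal(0, 0.1, (20, 3)), g.normal(10, 0.1, (20, 3))])
    y = np.array(["lo"] * 20 + ["hi"] * 20)
    cfg = CVConfig(classifier=clf, n_folds=5, repeats=1, seed=1, rf_trees=50)
    res = run_cv(X, cfg, labels=y)
    assert res.mean_accuracy == 1.0


def test_single_class_and_nonfinite_features_rejected():
    X = np.zeros((10, 2))
    cfg = CVConfig(repeats=1)
    with pytest.raises(ValueError):
        train_classifier(X, np.array(["a"] * 10), cfg)
    bad = X.copy()
    bad[0, 0] = np.nan
    with pytest.raises(ValueError):
        train_classifier(bad, np.array(["a"] * 5 + ["b"] * 5), cfg)


def test_permuted_labels_score_at_chance(small_dataset):
    dataset, _ = small_dataset
    table = extract_features(dataset, "PCA", 10)
    g = np.random.default_rng(0)
    perm_labels = g.permutation(table.labels)
    cfg = CVConfig(classifier="SVM", repeats=20, seed=2)
    res = run_cv(table.features, cfg, labels=perm_labels)
    assert 0.12 <= res.mean_accuracy <= 0.28  # chance = 0.20 for 5 classes


def test_no_leakage_from_test_fold_outliers():
    g = np.random.default_rng(1)
    X = g.normal(size=(40, 4))
    y = np.array(["a", "b"] * 20)
    cfg = CVConfig(classifier="SVM", repeats=1, seed=0)
    model = train_classifier(X[:30], y[:30], cfg)
    clean = predict(model, X[30:])
    spiked = np.vstack([X[30:], 1e6 * np.ones((1, 4))])
    assert np.array_equal(predict(model, spiked)[:-1], clean)
    scaler = model.named_steps["scale"]
    assert np.allclose(scaler.mean_, X[:30].mean(axis=0))


# ------------------------------------------------------------------------- CV

def test_perfect_features_and_per_repeat_identity():
    labels = np.repeat([f"A{i}" for i in range(5)], 20)
    onehot = np.eye(5)[np.repeat(np.arange(5), 20)]
    cfg = CVConfig(classifier="RF", repeats=1, seed=4, rf_trees=20)
    res = run_cv(onehot, cfg, labels=labels)
    assert res.accuracies[0] == 1.0
    assert res.pooled_accuracy() == 1.0
    assert res.confusion.to_numpy().sum() == 1 * 100


def test_pooled_accuracy_equals_mean_of_repeats(small_dataset):
    dataset, _ = small_dataset
    table = extract_features(dataset, "PCA", 5)
    cfg = CVConfig(classifier="SVM", repeats=3, seed=9)
    res = run_cv(table, cfg)
    assert res.pooled_accuracy() == pytest.approx(res.accuracies.mean(), abs=1e-12)
    assert res.confusion.to_numpy().sum() == 3 * 405
    # identical rerun under the same master seed
    res2 = run_cv(table, cfg)
    assert np.array_equal(res.accuracies, res2.accuracies)
    assert res.confusion.equals(res2.confusion)


# ---------------------------------------------------------------------- ANOVA

def test_anova_identical_groups():
    g = np.array([1.0, 2.0, 3.0])
    F, p = one_way_anova(g, g, g)
    assert F == pytest.approx(0.0, abs=1e-12)
    assert p == pytest.approx(1.0)


def test_anova_two_groups_equals_squared_t():
    from scipy import stats

    g = np.random.default_rng(2)
    a, b = g.normal(0, 1, 12), g.normal(0.7, 1, 15)
    F, p = one_way_anova(a, b)
    t, pt = stats.ttest_ind(a, b, equal_var=True)
    assert F == pytest.approx(t**2, abs=1e-10)
    assert p == pytest.approx(pt, abs=1e-10)


def test_anova_textbook_toy_matches_sum_of_squares_oracle():
    groups = [
        np.array([6.0, 8, 4, 5, 3, 4]),
        np.array([8.0, 12, 9, 11, 6, 8]),
        np.array([13.0, 9, 11, 8, 7, 12]),
    ]
    allv = np.concatenate(groups)
    grand = allv.mean()
    ss_between = sum(len(g) * (g.mean() - grand) ** 2 for g in groups)
    ss_within = sum(((g - g.mean()) ** 2).sum() for g in groups)
    df_b, df_w = len(groups) - 1, len(allv) - len(groups)
    F_oracle = (ss_between / df_b) / (ss_within / df_w)
    F, _ = one_way_anova(*groups)
    assert F == pytest.approx(F_oracle, abs=1e-6)


def test_anova_rejects_degenerate_groups():
    with pytest.raises(ValueError):
        one_way_anova(np.array([1.0, 2.0]))
    with pytest.raises(ValueError):
        one_way_anova(np.array([1.0]), np.array([2.0]))


# ---------------------------------------------------------------------- sweep

def test_mode_sweep_factorial_counts_and_determinism(small_dataset):
    dataset, _ = small_dataset
    cfg = CVConfig(repeats=1, seed=5, rf_trees=10)
    sweep = mode_sweep(dataset, r_list=(3,), config=cfg)
    assert len(sweep) == 4 * 2 * 1
    sweep2 = mode_sweep(dataset, r_list=(3,), config=cfg)
    assert sweep.equals(sweep2)
    partial = mode_sweep(
        dataset, methods=("POD",), classifiers=("SVM",), r_list=(3, 5), config=cfg
    )
    assert len(partial) == 2
    assert set(partial["r"]) == {3, 5}


def test_mode_sweep_skips_unreachable_ranks(small_dataset, caplog):
    dataset, _ = small_dataset
    cfg = CVConfig(repeats=1, seed=5, rf_trees=10)
    with caplog.at_level("WARNING"):
        sweep = mode_sweep(
            dataset, methods=("POD",), classifiers=("SVM",), r_list=(3, 2000), config=cfg
        )
    assert len(sweep) == 1
    assert "skipping" in caplog.text
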