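import numpy as np
import pandas as pd
import pytest

from netperturb.features import NETWORK_FEATURE_NAMES
from netperturb.model import (
    LabeledDataset,
    VariantClassifier,
    balance_training_set,
    cross_validate,
    feature_importances,
    gene_holdout_folds,
)


def make_dataset(n_per_gene, genes_pos, genes_neg=None, seed=0, n_features=4):
    """Dataset with ``genes_pos[g]`` positives (and fill-up negatives) per gene."""
    rng = np.random.default_rng(seed)
    rows, labels, genes = [], [], []
    for gene, n_pos in genes_pos.items():
        total = max(n_per_gene, n_pos)
        for i in range(total):
            rows.append(rng.normal(size=n_features))
            labels.append(1 if i < n_pos else 0)
            genes.append(gene)
    for gene, n_neg in (genes_neg or {}).items():
        for _ in range(n_neg):
            rows.append(rng.normal(size=n_features))
            labels.append(0)
            genes.append(gene)
    X = pd.DataFrame(rows, columns=[f"f{i}" for i in range(n_features)])
    return LabeledDataset(X, np.array(labels), np.array(genes, dtype=object),
                          keys=list(range(len(rows))))


# ---------------------------------------------------------------------------
# balancing
# ---------------------------------------------------------------------------


def test_cap_is_median_positive_count():
    ds = make_dataset(0, {"g1": 2, "g2": 16, "g3": 30}, genes_neg={"g4": 100})
    balanced = balance_training_set(ds, ratio=4.0, seed=0)
    # cap = median{2, 16, 30} = 16 -> at most 16 negatives from g4
    n_neg_g4 = int(((balanced.genes == "g4") & (balanced.labels == 0)).sum())
    assert n_neg_g4 == 16


def test_balancing_keeps_all_positives_and_hits_ratio_target():
    ds = make_dataset(0, {f"g{i}": 3 for i in range(10)},
                      genes_neg={f"n{i}": 3 for i in range(60)})
    balanced = balance_training_set(ds, ratio=4.0, seed=1)
    assert balanced.n_pos == ds.n_pos == 30
    # pool = 180 capped negatives >= 4 * 30
    assert balanced.n_neg == 120


def test_balancing_caps_each_gene():
    ds = make_dataset(0, {"g1": 16, "g2": 16}, genes_neg={"big": 40, "small": 3})
    balanced = balance_training_set(ds, ratio=10.0, seed=2)
    assert int(((balanced.genes == "big") & (balanced.labels == 0)).sum()) <= 16
    assert balanced.n_pos == 32


def test_balancing_requires_both_classes():
    ds = make_dataset(0, {"g1": 5})
    with pytest.raises(ValueError):
        balance_training_set(ds, seed=0)


def test_balancing_is_seed_reproducible():
    ds = make_dataset(0, {f"g{i}": 2 for i in range(6)},
                      genes_neg={f"n{i}": 10 for i in range(20)})
    k1 = balance_training_set(ds, seed=9).keys
    k2 = balance_training_set(ds, seed=9).keys
    k3 = balance_training_set(ds, seed=10).keys
    assert k1 == k2
    assert k1 != k3


# ---------------------------------------------------------------------------
# folds
# ---------------------------------------------------------------------------


def test_folds_partition_genes():
    ds = make_dataset(4, {f"g{i}": 2 for i in range(10)})
    folds = gene_holdout_folds(ds, k=5, seed=0)
    assert set(folds) == set(ds.genes)
    assert set(folds.values()) == set(range(5))


def test_equal_genes_spread_one_per_fold():
    ds = make_dataset(10, {f"g{i}": 10 for i in range(5)})
    folds = gene_holdout_folds(ds, k=5, seed=3)
    assert sorted(folds.values()) == [0, 1, 2, 3, 4]


def test_folds_balance_positives():
    ds = make_dataset(6, {f"g{i}": c for i, c in enumerate([20, 10, 10, 5, 5, 5, 3, 2])})
    folds = gene_holdout_folds(ds, k=4, seed=1)
    fold_pos = [0] * 4
    for gene, fold in folds.items():
        fold_pos[fold] += int(ds.labels[ds.genes == gene].sum())
    assert max(fold_pos) - min(fold_pos) <= 20  # largest gene bounds imbalance


def test_folds_reproducible_and_require_enough_genes():
    ds = make_dataset(4, {f"g{i}": 2 for i in range(7)})
    assert gene_holdout_folds(ds, k=5, seed=4) == gene_holdout_folds(ds, k=5, seed=4)
    with pytest.raises(ValueError):
        gene_holdout_folds(ds, k=8, seed=0)


# ---------------------------------------------------------------------------
# cross-validation
# ---------------------------------------------------------------------------


def separable_dataset(n_genes=40, per_gene=8, seed=0):
    rng = np.random.default_rng(seed)
    rows, labels, genes = [], [], []
    for g in range(n_genes):
        for i in range(per_gene):
            label = int(i < per_gene // 2)
            x = rng.normal(size=16)
            x[0] = label * 3 + rng.normal(0, 0.3)  # strongly separating column
            rows.append(x)
            labels.append(label)
            genes.append(f"g{g}")
    X = pd.DataFrame(rows, columns=list(NETWORK_FEATURE_NAMES))
    return LabeledDataset(X, np.array(labels), np.array(genes, dtype=object),
                          keys=list(range(len(rows))))


def test_separable_data_scores_high():
    ds = separable_dataset()
    cv = cross_validate(ds, k=5, seed=0, feature_subset="net")
    assert cv.report.auroc >= 0.95


def test_null_labels_score_near_chance():
    rng = np.random.default_rng(5)
    n = 1000
    X = pd.DataFrame(rng.normal(size=(n, 16)), columns=list(NETWORK_FEATURE_NAMES))
    ds = LabeledDataset(X, rng.integers(0, 2, size=n),
                        np.array([f"g{i % 50}" for i in range(n)], dtype=object),
                        keys=list(range(n)))
    cv = cross_validate(ds, k=5, seed=0, feature_subset="net")
    assert 0.4 <= cv.report.auroc <= 0.6


def test_identical_seed_gives_identical_scores():
    ds = separable_dataset(n_genes=15, per_gene=6, seed=2)
    s1 = cross_validate(ds, k=5, seed=11, feature_subset="net").scores
    s2 = cross_validate(ds, k=5, seed=11, feature_subset="net").scores
    np.testing.assert_array_equal(s1, s2)


def test_unknown_feature_subset_rejected():
    ds = separable_dataset(n_genes=10, per_gene=4)
    with pytest.raises(ValueError):
        cross_validate(ds, feature_subset="bogus")


def test_feature_subset_column_selection(recovery_dataset):
    from netperturb.model import _subset_columns

    cols = list(recovery_dataset.matrix.columns)
    assert len(_subset_columns("net", cols)) == 16
    assert len(_subset_columns("prot", cols)) == 7
    assert len(_subset_columns("res", cols)) == 9


# ---------------------------------------------------------------------------
# importances and the Model/Results surface
# ---------------------------------------------------------------------------


def test_importances_normalised_and_degree_signal_recovered():
    rng = np.random.default_rng(6)
    n = 600
    X = pd.DataFrame(rng.normal(size=(n, 16)), columns=list(NETWORK_FEATURE_NAMES))
    labels = (X["degree"] + rng.normal(0, 0.5, n) > 0).astype(int).to_numpy()
    ds = LabeledDataset(X, labels,
                        np.array([f"g{i % 30}" for i in range(n)], dtype=object),
                        keys=list(range(n)))
    results = VariantClassifier(ds, features="net").fit(k=5, seed=0)
    imp = results.importances
    assert imp.sum() == pytest.approx(1.0, abs=1e-9)
    # only the degree column carries signal -> it must rank first
    assert imp.index[0] == "degree"


def test_pure_noise_importances_near_uniform():
    rng = np.random.default_rng(8)
    n = 1000
    X = pd.DataFrame(rng.normal(size=(n, 16)), columns=list(NETWORK_FEATURE_NAMES))
    ds = LabeledDataset(X, rng.integers(0, 2, size=n),
                        np.array([f"g{i % 40}" for i in range(n)], dtype=object),
                        keys=list(range(n)))
    results = VariantClassifier(ds, features="net").fit(k=5, seed=0)
    imp = results.importances
    assert imp.max() < 3 * imp.min()


def test_untrained_model_has_no_importances():
    from sklearn.ensemble import RandomForestClassifier

    with pytest.raises(ValueError):
        feature_importances(RandomForestClassifier(), ["a"])


def test_results_summary_reports_metrics():
    ds = separable_dataset(n_genes=12, per_gene=6, seed=4)
    results = VariantClassifier(ds, features="net").fit(k=5, seed=0)
    text = results.summary()
    assert "auROC" in text and "MCC" in text
    preds = results.predict(ds.matrix)
    assert preds.shape == (len(ds),)
    assert ((preds >= 0) & (preds <= 1)).all()
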