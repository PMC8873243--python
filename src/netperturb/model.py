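"""Random-forest variant classification with gene-holdout cross-validation.

The modelling objects follow the fit/results idiom: a
:class:`VariantClassifier` is built from a :class:`LabeledDataset` (feature
matrix + binary labels + gene ids), and :meth:`VariantClassifier.fit` runs
gene-holdout cross-validation plus a final full-data fit, returning a
:class:`VariantClassifierResults` with out-of-fold scores, the pooled
evaluation report, Gini feature importances and a ``summary()`` table.

Protocol details:

* **Balancing** — positives are kept in full; negatives are first capped
  per gene at the median per-gene positive count (so no single gene
  dominates), then subsampled uniformly to roughly ``ratio`` negatives per
  positive (default 4).
* **Gene holdout** — every mutation of a gene lands in the same fold, so a
  classifier can never recognise a held-out gene from training rows.  Genes
  are shuffled, sorted by positive count, and greedily assigned to the fold
  with the fewest positives (then fewest rows), which balances the classes
  across folds.
* **Ensemble** — a random forest with 1000 trees and sqrt(p) candidate
  features per split; the prediction score is the fraction of trees voting
  for the positive class.
* **Feature subsets** — ``net`` (all 16 network features), ``prot`` (7
  protein-level), ``res`` (9 residue-level), ``aa`` (the external
  amino-acid block), ``res_aa`` and ``net_aa`` combinations.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
from sklearn.ensemble import RandomForestClassifier

from .centrality import PROTEIN_FEATURE_NAMES
from .features import NETWORK_FEATURE_NAMES, RESIDUE_FEATURE_NAMES, FeaturizeResult
from .metrics import EvalReport, evaluate

__all__ = [
    "LabeledDataset",
    "balance_training_set",
    "gene_holdout_folds",
    "cross_validate",
    "CrossValidationResult",
    "VariantClassifier",
    "VariantClassifierResults",
    "feature_importances",
    "FEATURE_SUBSETS",
]

N_TREES = 1000


def _subset_columns(name: str, all_columns: list[str]) -> list[str]:
    """Resolve a feature-subset name to concrete column names."""
    name = name.lower().replace("+", "_").replace(" ", "")
    aa_cols = [c for c in all_columns if c not in NETWORK_FEATURE_NAMES]
    subsets = {
        "net": list(NETWORK_FEATURE_NAMES),
        "prot": list(PROTEIN_FEATURE_NAMES),
        "res": list(RESIDUE_FEATURE_NAMES),
        "aa": aa_cols,
        "res_aa": list(RESIDUE_FEATURE_NAMES) + aa_cols,
        "net_aa": list(NETWORK_FEATURE_NAMES) + aa_cols,
    }
    if name not in subsets:
        raise ValueError(
            f"unknown feature subset {name!r}; expected one of {sorted(subsets)}"
        )
    cols = subsets[name]
    missing = [c for c in cols if c not in all_columns]
    if missing:
        raise ValueError(f"feature subset {name!r} needs missing columns {missing}")
    return cols


FEATURE_SUBSETS = ("net", "prot", "res", "aa", "res_aa", "net_aa")


@dataclass
class LabeledDataset:
    """Feature matrix with binary labels, gene ids and row keys."""

    matrix: pd.DataFrame
    labels: np.ndarray
    genes: np.ndarray
    keys: list

    def __post_init__(self):
        self.labels = np.asarray(self.labels, dtype=int)
        self.genes = np.asarray(self.genes, dtype=object)
        n = len(self.matrix)
        if not (len(self.labels) == len(self.genes) == len(self.keys) == n):
            raise ValueError("matrix, labels, genes and keys must align")
        if len(set(self.keys)) != n:
            raise ValueError("duplicate mutation keys in dataset")

    def __len__(self) -> int:
        return len(self.matrix)

    @property
    def n_pos(self) -> int:
        return int(self.labels.sum())

    @property
    def n_neg(self) -> int:
        return int(len(self) - self.labels.sum())

    @classmethod
    def from_featurize(cls, result: FeaturizeResult) -> "LabeledDataset":
        """Build from :func:`netperturb.features.featurize` output (drops
        rows without a label)."""
        table = result.table
        labels = table.attrs["labels"]
        genes = table.attrs["genes"]
        mask = labels.notna().to_numpy()
        table = table.loc[mask]
        return cls(
            matrix=table,
            labels=labels.to_numpy()[mask].astype(int),
            genes=genes.to_numpy()[mask],
            keys=list(table.index),
        )

    @classmethod
    def from_dataframe(
        cls,
        df: pd.DataFrame,
        label_col: str = "label",
        gene_col: str = "gene",
    ) -> "LabeledDataset":
        feature_cols = [c for c in df.columns if c not in (label_col, gene_col)]
        return cls(
            matrix=df[feature_cols],
            labels=df[label_col].to_numpy(),
            genes=df[gene_col].to_numpy(),
            keys=list(df.index),
        )

    def subset(self, row_mask: np.ndarray) -> "LabeledDataset":
        idx = np.flatnonzero(row_mask)
        return LabeledDataset(
            matrix=self.matrix.iloc[idx],
            labels=self.labels[idx],
            genes=self.genes[idx],
            keys=[self.keys[i] for i in idx],
        )


def balance_training_set(
    ds: LabeledDataset, ratio: float = 4.0, seed: int = 0
) -> LabeledDataset:
    """Subsample negatives to ~``ratio`` per positive with a per-gene cap.

    The cap is the median (rounded to nearest integer) of per-gene positive
    counts over genes that have positives; each gene contributes at most
    that many negatives (sampled without replacement), and the final
    negative set is a uniform draw from the capped pool.  Positives are
    always kept in full.
    """
    if ds.n_pos == 0:
        raise ValueError("dataset has no positives to balance against")
    if ds.n_neg == 0:
        raise ValueError("dataset has no negatives; balancing is degenerate")
    rng = np.random.default_rng(seed)
    pos_counts = (
        pd.Series(ds.labels, index=pd.Index(ds.genes, name="gene"))
        .groupby(level=0)
        .sum()
    )
    cap = int(np.rint(float(np.median(pos_counts[pos_counts > 0]))))

    keep = np.zeros(len(ds), dtype=bool)
    keep[ds.labels == 1] = True

    neg_idx = np.flatnonzero(ds.labels == 0)
    pool: list[int] = []
    for gene in sorted(set(ds.genes[neg_idx])):
        gene_neg = neg_idx[ds.genes[neg_idx] == gene]
        if len(gene_neg) > cap:
            gene_neg = rng.choice(gene_neg, size=cap, replace=False)
        pool.extend(int(i) for i in gene_neg)
    pool_arr = np.array(sorted(pool), dtype=int)
    target = min(int(np.rint(ratio * ds.n_pos)), len(pool_arr))
    chosen = rng.choice(pool_arr, size=target, replace=False)
    keep[chosen] = True
    return ds.subset(keep)


def gene_holdout_folds(ds: LabeledDataset, k: int = 5, seed: int = 0) -> dict:
    """Partition genes into ``k`` folds, balancing positives across folds.

    Genes are shuffled (seeded), stably sorted by positive count
    descending, and greedily assigned to the fold with the fewest
    positives, breaking ties by fewest total rows then lowest fold index.
    Returns a mapping ``gene -> fold``.
    """
    genes = sorted(set(ds.genes))
    if len(genes) < k:
        raise ValueError(f"need at least k={k} genes, have {len(genes)}")
    rng = np.random.default_rng(seed)
    shuffled = list(rng.permutation(np.array(genes, dtype=object)))
    pos_per_gene = {
        g: int(ds.labels[ds.genes == g].sum()) for g in genes
    }
    rows_per_gene = {g: int((ds.genes == g).sum()) for g in genes}
    shuffled.sort(key=lambda g: -pos_per_gene[g])  # stable: keeps shuffle order

    fold_pos = [0] * k
    fold_rows = [0] * k
    assignment: dict = {}
    for gene in shuffled:
        fold = min(range(k), key=lambda f: (fold_pos[f], fold_rows[f], f))
        assignment[gene] = fold
        fold_pos[fold] += pos_per_gene[gene]
        fold_rows[fold] += rows_per_gene[gene]
    return assignment


def _fold_seed(seed: int, fold: int) -> int:
    """Deterministic per-fold RNG stream, decoupled from fold membership."""
    return int(np.random.SeedSequence([seed, fold]).generate_state(1)[0] % (2**31))


def _make_forest(seed: int) -> RandomForestClassifier:
    return RandomForestClassifier(
        n_estimators=N_TREES, max_features="sqrt", random_state=seed, n_jobs=1
    )


@dataclass
class CrossValidationResult:
    """Out-of-fold scores and pooled evaluation of one CV run."""

    scores: np.ndarray  # aligned to the dataset rows
    labels: np.ndarray
    fold_of_row: np.ndarray
    folds: dict
    report: EvalReport
    feature_columns: list


def cross_validate(
    ds: LabeledDataset,
    k: int = 5,
    seed: int = 0,
    feature_subset: str = "net",
    threshold: float = 0.5,
) -> CrossValidationResult:
    """Gene-holdout k-fold cross-validation of the random forest.

    For each fold the forest is trained on the other k-1 folds and scores
    the held-out rows; the pooled out-of-fold scores are evaluated once.
    """
    cols = _subset_columns(feature_subset, list(ds.matrix.columns))
    X = ds.matrix[cols].to_numpy(dtype=float)
    folds = gene_holdout_folds(ds, k=k, seed=seed)
    fold_of_row = np.array([folds[g] for g in ds.genes], dtype=int)
    scores = np.full(len(ds), np.nan)
    for fold in range(k):
        test = fold_of_row == fold
        train = ~test
        if not test.any():
            continue
        clf = _make_forest(_fold_seed(seed, fold))
        clf.fit(X[train], ds.labels[train])
        pos_col = int(np.flatnonzero(clf.classes_ == 1)[0])
        scores[test] = clf.predict_proba(X[test])[:, pos_col]
    report = evaluate(scores, ds.labels, threshold=threshold)
    return CrossValidationResult(
        scores=scores,
        labels=ds.labels.copy(),
        fold_of_row=fold_of_row,
        folds=folds,
        report=report,
        feature_columns=cols,
    )


def feature_importances(model: RandomForestClassifier, columns: list) -> pd.Series:
    """Normalised Gini (mean-decrease-in-impurity) importances, descending."""
    if not hasattr(model, "feature_importances_"):
        raise ValueError("model is not fitted; no importances available")
    imp = np.asarray(model.feature_importances_, dtype=float)
    total = imp.sum()
    if total > 0:
        imp = imp / total
    return pd.Series(imp, index=columns).sort_values(ascending=False)


class VariantClassifier:
    """Random-forest model over a labelled mutation feature set.

    Parameters
    ----------
    dataset:
        Feature matrix, labels and gene ids.
    features:
        Feature-subset name (see :data:`FEATURE_SUBSETS`).
    balance_ratio:
        When set, the training set is rebalanced to this many negatives per
        positive (with the per-gene cap) before fitting; None uses the
        dataset as given.
    """

    def __init__(
        self,
        dataset: LabeledDataset,
        features: str = "net",
        balance_ratio: float | None = None,
    ):
        self.dataset = dataset
        self.features = features
        self.balance_ratio = balance_ratio

    @classmethod
    def from_dataframe(
        cls,
        df: pd.DataFrame,
        label_col: str = "label",
        gene_col: str = "gene",
        **kwargs,
    ) -> "VariantClassifier":
        return cls(LabeledDataset.from_dataframe(df, label_col, gene_col), **kwargs)

    def fit(self, k: int = 5, seed: int = 0, threshold: float = 0.5):
        """Cross-validate and fit the final full-data forest."""
        ds = self.dataset
        if self.balance_ratio is not None:
            ds = balance_training_set(ds, ratio=self.balance_ratio, seed=seed)
        cv = cross_validate(
            ds, k=k, seed=seed, feature_subset=self.features, threshold=threshold
        )
        final = _make_forest(_fold_seed(seed, k))
        final.fit(ds.matrix[cv.feature_columns].to_numpy(dtype=float), ds.labels)
        return VariantClassifierResults(
            model=self, dataset=ds, cv=cv, final_model=final, seed=seed, k=k
        )


@dataclass
class VariantClassifierResults:
    """Fitted-model results: out-of-fold scores, metrics and importances."""

    model: VariantClassifier
    dataset: LabeledDataset
    cv: CrossValidationResult
    final_model: RandomForestClassifier
    seed: int
    k: int
    _importances: pd.Series | None = field(default=None, repr=False)

    @property
    def report(self) -> EvalReport:
        return self.cv.report

    @property
    def oof_scores(self) -> np.ndarray:
        return self.cv.scores

    @property
    def importances(self) -> pd.Series:
        if self._importances is None:
            self._importances = feature_importances(
                self.final_model, self.cv.feature_columns
            )
        return self._importances

    def predict(self, X: pd.DataFrame) -> np.ndarray:
        """Score new feature rows with the final full-data forest
        (fraction of trees voting positive)."""
        cols = self.cv.feature_columns
        pos_col = int(np.flatnonzero(self.final_model.classes_ == 1)[0])
        return self.final_model.predict_proba(X[cols].to_numpy(dtype=float))[
            :, pos_col
        ]

    def summary(self) -> str:
        r = self.report
        lines = [
            "Variant classifier (random forest, gene-holdout CV)",
            "=" * 51,
            f"features: {self.model.features}   folds: {self.k}   seed: {self.seed}",
            f"rows: {len(self.dataset)}  (+{r.n_pos} / -{r.n_neg})",
            "",
            f"auROC    {r.auroc:8.4f}",
            f"auPRC    {r.auprc:8.4f}",
            f"accuracy {r.accuracy:8.4f}  (threshold {r.threshold})",
            f"F1       {r.f1:8.4f}",
            f"MCC      {r.mcc:8.4f}",
            "",
            "top feature importances (Gini):",
        ]
        for name, value in self.importances.head(10).items():
            lines.append(f"  {name:<28s} {value:7.4f}")
        return "\n".join(lines)
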