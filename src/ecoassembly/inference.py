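"""Random-forest model classification over summary-statistic tables.

A classifier is trained on labeled simulation summary statistics under an
"axis mask" — the subset of data axes (SAD, genetic, trait) assumed
available, mirroring what empirical datasets actually provide — and
evaluated by stratified k-fold cross-validation pooled into a confusion
matrix.  Class probabilities for new tables are the forest's per-class
vote fractions; because the pairwise and beta competition models are
mechanistically near-identical, a collapsed view merging them is provided
throughout.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.decomposition import PCA
from sklearn.ensemble import RandomForestClassifier
from sklearn.model_selection import StratifiedKFold, cross_val_predict
from sklearn.preprocessing import StandardScaler

from ecoassembly.sumstats import AXIS_COLUMNS, _CROSS_COLUMNS

__all__ = [
    "AXIS_MASKS",
    "RFConfig",
    "TrainingSet",
    "FittedClassifier",
    "ConfusionMatrix",
    "ClassProbabilities",
    "mask_columns",
    "train_classifier",
    "cross_validate",
    "classify",
    "pca_projection",
]

#: Named axis masks matching the three data configurations studied:
#: SAD+genetic (spider/weevil-style data), trait+genetic (tree/snail-style
#: data), and the ideal all-axes case.
AXIS_MASKS = {
    "sad+gen": frozenset({"abundance", "genetic"}),
    "trait+gen": frozenset({"trait", "genetic"}),
    "all": frozenset({"abundance", "genetic", "trait"}),
}

COMPETITION_COLLAPSE = ("pairwise", "beta")


def mask_columns(mask) -> list[str]:
    """Feature columns available under an axis mask.

    Accepts a mask name from :data:`AXIS_MASKS` or a set of axis names.
    Richness S is always included (a species list exists whenever any axis
    does); lam is simulation metadata, never a feature.  Cross-axis
    Spearman columns are included when both of their axes are available.
    """
    axes = AXIS_MASKS[mask] if isinstance(mask, str) else frozenset(mask)
    cols = ["S"]
    for ax in ("abundance", "genetic", "trait"):
        if ax in axes:
            cols.extend(AXIS_COLUMNS[ax])
    for col, (a, b) in _CROSS_COLUMNS.items():
        if a in axes and b in axes:
            cols.append(col)
    return cols


@dataclass(frozen=True)
class RFConfig:
    """Random-forest settings (library defaults except where noted)."""

    n_trees: int = 1000
    max_depth: int | None = None
    seed: int = 0
    n_jobs: int = 1


@dataclass
class TrainingSet:
    """Labeled feature table plus the axis mask it was built under."""

    features: pd.DataFrame
    labels: np.ndarray
    mask: str | frozenset = "all"

    def __post_init__(self) -> None:
        self.labels = np.asarray(self.labels)
        if len(self.features) != len(self.labels):
            raise ValueError("features and labels must have equal length")
        if len(np.unique(self.labels)) < 2:
            raise ValueError("training set must contain at least 2 classes")

    def masked(self) -> pd.DataFrame:
        """Feature columns under the mask; sentinel-free by contract."""
        cols = [c for c in mask_columns(self.mask) if c in self.features.columns]
        X = self.features[cols]
        bad = X.columns[X.isna().any()].tolist()
        if bad:
            raise ValueError(
                f"sentinel (NaN) values remain in masked columns: {bad}; "
                "mask an axis out rather than passing partial data"
            )
        return X

    @classmethod
    def from_table(cls, table: pd.DataFrame, mask="all", label_col="model"):
        """Build from a labeled summary-statistics table (run_batch output).

        Rows with sentinel values inside the masked columns (e.g. a
        single-species community whose shape moments are undefined) are
        dropped with a warning rather than imputed.
        """
        cols = [c for c in mask_columns(mask) if c in table.columns]
        keep = table[cols].notna().all(axis=1)
        if not keep.all():
            warnings.warn(
                f"dropping {(~keep).sum()} rows with undefined features",
                RuntimeWarning,
                stacklevel=2,
            )
        sub = table.loc[keep]
        return cls(features=sub[cols].copy(), labels=sub[label_col].to_numpy(), mask=mask)


@dataclass
class FittedClassifier:
    """A fitted forest plus the schema it expects."""

    forest: RandomForestClassifier
    feature_names: list[str]
    classes: np.ndarray
    mask: str | frozenset

    @property
    def feature_importances(self) -> pd.Series:
        return pd.Series(self.forest.feature_importances_, index=self.feature_names)


@dataclass
class ConfusionMatrix:
    """Pooled out-of-fold confusion counts, rows = true model."""

    labels: list[str]
    counts: np.ndarray

    def __post_init__(self) -> None:
        self.counts = np.asarray(self.counts, int)
        if np.any(self.counts < 0):
            raise ValueError("confusion counts must be nonnegative")

    @property
    def accuracy(self) -> float:
        return float(np.trace(self.counts) / self.counts.sum())

    @property
    def row_percent(self) -> np.ndarray:
        return 100.0 * self.counts / self.counts.sum(axis=1, keepdims=True)

    def collapse(self, group=COMPETITION_COLLAPSE) -> "ConfusionMatrix":
        """Merge a group of labels (default pairwise+beta) into one class."""
        present = [g for g in group if g in self.labels]
        if len(present) < 2:
            return self
        merged_name = "+".join(present)
        keep = [l for l in self.labels if l not in present]
        new_labels = keep + [merged_name]
        idx = {l: i for i, l in enumerate(self.labels)}
        k = len(new_labels)
        out = np.zeros((k, k), int)
        for i, li in enumerate(self.labels):
            for j, lj in enumerate(self.labels):
                ni = new_labels.index(merged_name if li in present else li)
                nj = new_labels.index(merged_name if lj in present else lj)
                out[ni, nj] += self.counts[i, j]
        return ConfusionMatrix(labels=new_labels, counts=out)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.counts, index=self.labels, columns=self.labels)

    @property
    def largest_offdiagonal(self) -> tuple[str, str, int]:
        """(true, predicted, count) of the biggest misclassification cell."""
        c = self.counts.copy()
        np.fill_diagonal(c, -1)
        i, j = np.unravel_index(np.argmax(c), c.shape)
        return (self.labels[i], self.labels[j], int(self.counts[i, j]))


@dataclass
class ClassProbabilities:
    """Per-row model class probabilities (forest vote fractions)."""

    table: pd.DataFrame  # one column per model class

    def __post_init__(self) -> None:
        sums = self.table.sum(axis=1).to_numpy()
        if np.any(np.abs(sums - 1.0) > 1e-9):
            raise ValueError("class probabilities must sum to 1 within 1e-9")

    def collapsed(self, group=COMPETITION_COLLAPSE) -> pd.DataFrame:
        present = [g for g in group if g in self.table.columns]
        if len(present) < 2:
            return self.table.copy()
        out = self.table.drop(columns=present)
        out["+".join(present)] = self.table[present].sum(axis=1)
        return out


def train_classifier(training: TrainingSet, config: RFConfig | None = None) -> FittedClassifier:
    """Fit a random forest on the masked features; deterministic under seed."""
    if config is None:
        config = RFConfig()
    X = training.masked()
    forest = RandomForestClassifier(
        n_estimators=config.n_trees,
        max_depth=config.max_depth,
        random_state=config.seed,
        n_jobs=config.n_jobs,
        oob_score=True,
    )
    forest.fit(X.to_numpy(), training.labels)
    return FittedClassifier(
        forest=forest,
        feature_names=list(X.columns),
        classes=forest.classes_,
        mask=training.mask,
    )


def cross_validate(
    training: TrainingSet,
    k: int = 5,
    config: RFConfig | None = None,
) -> ConfusionMatrix:
    """Stratified k-fold CV pooled into one confusion matrix.

    Every row is predicted exactly once, out of fold; `.accuracy` is
    trace/total and `.collapse()` gives the pairwise+beta-merged view.
    """
    if config is None:
        config = RFConfig()
    X = training.masked().to_numpy()
    y = training.labels
    classes, class_counts = np.unique(y, return_counts=True)
    if k > class_counts.min():
        raise ValueError(
            f"k={k} exceeds the smallest class count {class_counts.min()}"
        )
    if class_counts.max() / class_counts.min() > 2:
        warnings.warn("classes are unbalanced (max/min ratio > 2)",
                      RuntimeWarning, stacklevel=2)
    forest = RandomForestClassifier(
        n_estimators=config.n_trees,
        max_depth=config.max_depth,
        random_state=config.seed,
        n_jobs=config.n_jobs,
    )
    cv = StratifiedKFold(n_splits=k, shuffle=True, random_state=config.seed)
    pred = cross_val_predict(forest, X, y, cv=cv, n_jobs=1)
    labels = list(classes)
    idx = {l: i for i, l in enumerate(labels)}
    counts = np.zeros((len(labels), len(labels)), int)
    for t, p in zip(y, pred):
        counts[idx[t], idx[p]] += 1
    return ConfusionMatrix(labels=labels, counts=counts)


def classify(
    fitted: FittedClassifier,
    table: pd.DataFrame,
    collapse_competition: bool = False,
) -> ClassProbabilities | pd.DataFrame:
    """Predict model class probabilities for each row of ``table``.

    The table must carry exactly the feature columns the classifier was
    trained on (extra non-feature metadata columns are ignored only if all
    trained features are present and no unexpected feature columns appear
    among the known summary statistics).
    """
    from ecoassembly.sumstats import FEATURE_COLUMNS

    missing = [c for c in fitted.feature_names if c not in table.columns]
    extra = [
        c
        for c in table.columns
        if c in FEATURE_COLUMNS and c not in fitted.feature_names and c != "lam"
    ]
    if missing:
        raise ValueError(f"input is missing feature columns: {missing}; "
                         f"unexpected feature columns: {extra}")
    X = table[fitted.feature_names]
    if X.isna().to_numpy().any():
        raise ValueError("input rows contain sentinel (NaN) feature values")
    proba = fitted.forest.predict_proba(X.to_numpy())
    out = ClassProbabilities(
        table=pd.DataFrame(proba, columns=list(fitted.classes), index=table.index)
    )
    if collapse_competition:
        return out.collapsed()
    return out


@dataclass
class PCAProjection:
    scores: pd.DataFrame  # PC1, PC2 per row (+ label / lambda bin if given)
    explained_variance_ratio: np.ndarray
    dropped_columns: list[str] = field(default_factory=list)


def pca_projection(
    features: pd.DataFrame,
    labels=None,
    lam=None,
    lambda_bins=(0.25, 0.5, 0.75, 1.0),
    n_components: int = 2,
) -> PCAProjection:
    """Column-standardized PCA of a summary-statistic table.

    Zero-variance columns are dropped with a warning before scaling.
    Returns per-row scores on the first ``n_components`` components plus
    all explained-variance ratios; rows are tagged by model label and
    Lambda bin when provided, for plotting.
    """
    X = features.select_dtypes(include=[np.number]).dropna(axis=1, how="any")
    variances = X.var(axis=0, ddof=0)
    dropped = list(X.columns[variances == 0.0])
    if dropped:
        warnings.warn(f"dropping zero-variance columns: {dropped}",
                      RuntimeWarning, stacklevel=2)
        X = X.drop(columns=dropped)
    if X.shape[1] < 2 or X.shape[0] < 3:
        raise ValueError("PCA needs at least 2 usable features and 3 rows")
    Z = StandardScaler().fit_transform(X.to_numpy())
    pca = PCA()
    scores = pca.fit_transform(Z)
    k = min(n_components, scores.shape[1])
    out = pd.DataFrame(
        scores[:, :k], columns=[f"PC{i + 1}" for i in range(k)], index=features.index
    )
    if labels is not None:
        out["model"] = np.asarray(labels)
    if lam is not None:
        lam = np.asarray(lam, float)
        edges = np.asarray(lambda_bins, float)
        out["lambda_bin"] = edges[np.clip(np.searchsorted(edges, lam), 0, len(edges) - 1)]
    return PCAProjection(
        scores=out,
        explained_variance_ratio=pca.explained_variance_ratio_,
        dropped_columns=dropped,
    )
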