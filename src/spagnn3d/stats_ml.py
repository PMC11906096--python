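"""Cell phenotyping, group statistics and the classifier comparison harness.

Group comparisons use a two-sided Mann-Whitney-Wilcoxon test; the
significance level alpha is corrected by Bonferroni for the number of
comparisons, while the star annotation follows the raw p-value legend:

    ns   : 5.00e-2 < p <= 1.00
    *    : 1.00e-2 < p <= 5.00e-2
    **   : 1.00e-3 < p <= 1.00e-2
    ***  : 1.00e-4 < p <= 1.00e-3
    **** : p <= 1.00e-4

Four per-cell feature sets can be compared across four standard
classifiers (logistic regression, SVM, random forest, kNN): raw RNA
counts, patch gene correlation, variation in local gene neighborhood
networks, and pooled autoencoder embeddings.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.stats import mannwhitneyu
from sklearn.ensemble import RandomForestClassifier
from sklearn.cluster import KMeans
from sklearn.decomposition import PCA
from sklearn.linear_model import LogisticRegression
from sklearn.metrics import confusion_matrix, roc_auc_score
from sklearn.model_selection import train_test_split
from sklearn.neighbors import KNeighborsClassifier
from sklearn.preprocessing import StandardScaler
from sklearn.svm import SVC

#: star-annotation thresholds on the raw p-value (upper bounds, inclusive)
STAR_LEGEND = [(1e-4, "****"), (1e-3, "***"), (1e-2, "**"), (5e-2, "*"), (1.0, "ns")]

CLASSIFIERS = {
    "logistic_regression": lambda seed: LogisticRegression(max_iter=2000, random_state=seed),
    "svm": lambda seed: SVC(probability=True, random_state=seed),
    "random_forest": lambda seed: RandomForestClassifier(random_state=seed),
    "knn": lambda seed: KNeighborsClassifier(),
}


def star_annotation(p: float) -> str:
    """Map a raw p-value to the printed significance legend."""
    for bound, stars in STAR_LEGEND:
        if p <= bound:
            return stars
    return "ns"


@dataclass
class GroupComparison:
    feature: str
    p_value: float
    statistic: float
    corrected_alpha: float
    significant: bool  # p <= corrected alpha
    stars: str


@dataclass
class ClassificationReport:
    classifier: str
    feature_set: str
    accuracy: float
    auc: float
    confusion: np.ndarray
    seed: int

    def __post_init__(self) -> None:
        assert self.confusion.sum() > 0
        # accuracy must equal trace/total by construction
        assert abs(self.accuracy - np.trace(self.confusion) / self.confusion.sum()) < 1e-9


def phenotype_cells(counts: pd.DataFrame, n_clusters: int | None = None,
                    resolution: float | None = None, seed: int = 0,
                    tsne: bool = False) -> tuple[np.ndarray, np.ndarray | None]:
    """Cluster cells from a cell x gene count matrix.

    Counts are library-size normalized and log1p transformed, reduced by
    PCA, then clustered with k-means (``n_clusters``) or Leiden on a kNN
    graph (``resolution``).  Optionally returns tSNE coordinates for
    plotting.  Deterministic given seed.
    """
    X = counts.to_numpy(dtype=float)
    lib = X.sum(axis=1, keepdims=True)
    lib[lib == 0] = 1.0
    X = np.log1p(X / lib * np.median(lib))
    n_comp = min(20, X.shape[1], max(1, X.shape[0] - 1))
    Xp = PCA(n_components=n_comp, random_state=seed).fit_transform(X) if X.shape[1] > n_comp else X
    if n_clusters is not None:
        labels = KMeans(n_clusters=n_clusters, random_state=seed, n_init=10).fit_predict(Xp)
    else:
        import igraph as ig
        import leidenalg

        from .spatial_graphs import symmetric_knn_edges

        k = min(15, len(Xp) - 1)
        edges = symmetric_knn_edges(Xp, k)
        g = ig.Graph(n=len(Xp), edges=[(int(u), int(v)) for u, v in edges])
        part = leidenalg.find_partition(
            g, leidenalg.RBConfigurationVertexPartition,
            resolution_parameter=resolution if resolution is not None else 1.0,
            seed=int(seed), n_iterations=2)
        labels = np.asarray(part.membership, dtype=np.int64)
    coords = None
    if tsne:
        from sklearn.manifold import TSNE

        perp = min(30, max(2, len(Xp) // 4))
        coords = TSNE(n_components=2, random_state=seed, perplexity=perp).fit_transform(Xp)
    return labels, coords


def compare_groups(values_a: np.ndarray, values_b: np.ndarray, feature: str = "",
                   n_comparisons: int = 1, alpha: float = 0.05) -> GroupComparison:
    """Two-sided Mann-Whitney test with Bonferroni-corrected alpha.

    Stars come from the raw p-value per the legend; ``significant`` refers
    to the Bonferroni-corrected threshold alpha / n_comparisons.  Both
    groups need >= 3 values.
    """
    a, b = np.asarray(values_a, dtype=float), np.asarray(values_b, dtype=float)
    if len(a) < 3 or len(b) < 3:
        raise ValueError("each group needs >= 3 values")
    stat, p = mannwhitneyu(a, b, alternative="two-sided")
    corrected = alpha / max(1, n_comparisons)
    return GroupComparison(feature=feature, p_value=float(p), statistic=float(stat),
                           corrected_alpha=corrected, significant=bool(p <= corrected),
                           stars=star_annotation(float(p)))


def network_variation_features(z_matrix: np.ndarray, defined: np.ndarray) -> np.ndarray:
    """Per-gene-pair variation of the local gene neighborhood network.

    For one cell: the sample standard deviation (ddof=1) of the proximity
    score across the cell's patches, over defined entries only.  Pairs
    defined in fewer than two patches get 0.
    """
    z = np.asarray(z_matrix, dtype=float)
    d = np.asarray(defined, dtype=bool)
    out = np.zeros(z.shape[1])
    for j in range(z.shape[1]):
        vals = z[d[:, j], j]
        if len(vals) >= 2:
            out[j] = float(np.std(vals, ddof=1))
    return out


def correlation_features(corr: pd.DataFrame) -> np.ndarray:
    """Upper triangle of a per-cell patch gene-correlation matrix, with
    undefined entries as 0 (feature vector for classification)."""
    m = corr.to_numpy(dtype=float)
    iu = np.triu_indices(m.shape[0], k=1)
    vals = m[iu]
    return np.nan_to_num(vals, nan=0.0)


def classify(features: np.ndarray, labels: np.ndarray, classifier: str = "svm",
             test_fraction: float = 0.2, seed: int = 0,
             split: tuple | None = None) -> ClassificationReport:
    """Train/test one classifier on per-cell features.

    Stratified 80/20 split, feature standardization fit on the training set
    only; reports accuracy, one-vs-rest AUC and the confusion matrix.
    A precomputed ``split`` (X_tr, X_te, y_tr, y_te) lets harness cells
    share identical splits.
    """
    if classifier not in CLASSIFIERS:
        raise ValueError(f"unknown classifier {classifier!r}")
    X = np.asarray(features, dtype=float)
    y = np.asarray(labels)
    if len(np.unique(y)) < 2:
        raise ValueError("need >= 2 classes")
    if split is None:
        split = train_test_split(X, y, test_size=test_fraction, stratify=y, random_state=seed)
    X_tr, X_te, y_tr, y_te = split
    scaler = StandardScaler().fit(X_tr)
    X_tr, X_te = scaler.transform(X_tr), scaler.transform(X_te)
    clf = CLASSIFIERS[classifier](seed)
    clf.fit(X_tr, y_tr)
    pred = clf.predict(X_te)
    proba = clf.predict_proba(X_te)
    classes = np.unique(y)
    if len(classes) == 2:
        auc = roc_auc_score(y_te, proba[:, 1])
    else:
        auc = roc_auc_score(y_te, proba, multi_class="ovr")
    cm = confusion_matrix(y_te, pred, labels=classes)
    return ClassificationReport(classifier=classifier, feature_set="",
                                accuracy=float((pred == y_te).mean()), auc=float(auc),
                                confusion=cm, seed=seed)


def harness(feature_sets: dict[str, np.ndarray], labels: np.ndarray,
            seeds=(0,), test_fraction: float = 0.2) -> pd.DataFrame:
    """Full cross of feature sets x the four classifiers.

    Within one seed, every grid cell uses the identical train/test row
    split so that feature sets are compared on the same cells.  Returns a
    tidy DataFrame of reports (one row per seed x feature set x
    classifier).
    """
    y = np.asarray(labels)
    rows = []
    n = len(y)
    for seed in seeds:
        idx_tr, idx_te = train_test_split(np.arange(n), test_size=test_fraction,
                                          stratify=y, random_state=seed)
        for fname, X in feature_sets.items():
            X = np.asarray(X, dtype=float)
            split = (X[idx_tr], X[idx_te], y[idx_tr], y[idx_te])
            for cname in CLASSIFIERS:
                rep = classify(X, y, cname, seed=seed, split=split)
                rows.append(dict(seed=seed, feature_set=fname, classifier=cname,
                                 accuracy=rep.accuracy, auc=rep.auc,
                                 confusion=rep.confusion))
    return pd.DataFrame(rows)
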