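"""Stability-based relative clustering validation for subtype discovery.

The number of clusters k is treated as the solution that is most
*reproducible* rather than the one optimising an internal index: the train
split is repeatedly partitioned in two, each half is clustered
independently with k-means, a k-nearest-neighbour classifier carries labels
from one half to the other, and the (optimally aligned) disagreement
between carried and native labels is the misclassification error. Averaged
over repeats and divided by the asymptotic random-labelling error
(k-1)/k, this gives the *normalized stability*; the best k minimises it.
The chosen solution is then clustered afresh in a held-out validation
split, and the fraction of validation subjects whose native cluster agrees
with a classifier trained on the train split is the *generalization
accuracy*. Finally a Monte-Carlo test against a single multivariate
Gaussian null (2-means cluster index, eigenvalue-based null covariance
with a robust noise floor) guards against clustering pure continua.

Features are standardised (mean 0, SD 1) and embedded with UMAP
(n_neighbors=30, min_dist=0.0, 2 components, Euclidean, fixed random
state) before clustering; scaler and embedder are fit on the train split
only and applied in transform mode to the validation split.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.optimize import linear_sum_assignment
from sklearn.cluster import KMeans
from sklearn.neighbors import KNeighborsClassifier
from sklearn.preprocessing import StandardScaler

from ._fastkmeans import kmeans_labels
from ._seeding import substream, substream_seed

logger = logging.getLogger(__name__)

FEATURES = ("md", "ac", "bl")


class DegenerateInputError(Exception):
    """Features carry no variance; no clustering is meaningful."""


@dataclass
class RevalConfig:
    k_range: tuple = tuple(range(2, 11))
    cv_folds: int = 2
    cv_repeats: int = 100
    split_fraction: float = 0.70
    stratify_on: tuple = ("study_id", "sex", "module")
    umap_n_neighbors: int = 30
    umap_min_dist: float = 0.0
    umap_n_components: int = 2
    umap_metric: str = "euclidean"
    umap_random_state: int = 42
    knn_neighbors: int = 5
    kmeans_n_init: int = 10
    seed: int = 0

    def __post_init__(self) -> None:
        if min(self.k_range) < 2:
            raise ValueError("candidate k must be >= 2")
        if self.cv_folds < 2:
            raise ValueError("need >= 2 folds")


@dataclass
class SubtypeModel:
    best_k: int
    scaler: StandardScaler
    embedder: object
    clusterer: KMeans
    classifier: KNeighborsClassifier
    train_labels: pd.Series
    validation_labels: pd.Series
    generalization_accuracy: float
    label_semantics: dict  # cluster index -> "High" / "Low" (k=2) or rank name
    stability_curve: pd.DataFrame
    unmatched_validation_clusters: int = 0


@dataclass
class SigClustResult:
    cluster_index: float
    null_samples: int
    p_value: float
    seed: int


# ---------------------------------------------------------------------------
# splitting and label alignment


def stratified_split(
    table: pd.DataFrame, cfg: RevalConfig
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Disjoint, exhaustive train/validation split, ~70% train per stratum.

    Strata are the observed combinations of the balancing covariates;
    strata with fewer than 2 subjects are pooled (with a warning) so each
    stratum can contribute to both sides.
    """
    rng = substream(cfg.seed, "split")
    strata = table[list(cfg.stratify_on)].astype(str).agg("|".join, axis=1)
    counts = strata.value_counts()
    small = counts[counts < 2].index
    if len(small) > 0:
        logger.warning("pooling %d singleton strata", len(small))
        strata = strata.where(~strata.isin(small), "__pooled__")

    train_idx: list[int] = []
    for _, idx in table.groupby(strata.to_numpy()).groups.items():
        idx = np.asarray(list(idx))
        perm = rng.permutation(len(idx))
        n_train = int(round(cfg.split_fraction * len(idx)))
        train_idx.extend(idx[perm[:n_train]])
    mask = table.index.isin(train_idx)
    return table[mask], table[~mask]


def align_labels(
    reference: np.ndarray, candidate: np.ndarray
) -> tuple[np.ndarray, float]:
    """Optimally relabel ``candidate`` to match ``reference``.

    Solves the assignment problem on the confusion matrix (padded with
    zeros when the two labelings use different numbers of clusters) and
    returns the relabelled candidate plus the minimised disagreement
    fraction.
    """
    reference = np.asarray(reference)
    candidate = np.asarray(candidate)
    if reference.shape != candidate.shape:
        raise ValueError("label vectors differ in length")
    k = int(max(reference.max(), candidate.max())) + 1
    confusion = np.zeros((k, k))
    np.add.at(confusion, (candidate, reference), 1)
    rows, cols = linear_sum_assignment(-confusion)
    mapping = dict(zip(rows, cols))
    mapped = np.array([mapping[c] for c in candidate])
    error = float(np.mean(mapped != reference))
    return mapped, error


# ---------------------------------------------------------------------------
# normalized stability


def _kmeans_labels(Z: np.ndarray, k: int, cfg: RevalConfig, seed: int) -> np.ndarray:
    labels, _ = kmeans_labels(Z, k, n_init=cfg.kmeans_n_init, seed=seed)
    if len(np.unique(labels)) < k:
        # rare with multiple restarts; re-seed once as a fallback
        labels, _ = kmeans_labels(Z, k, n_init=cfg.kmeans_n_init, seed=seed + 1)
    return labels


def normalized_stability(
    Z: np.ndarray, k: int, cfg: RevalConfig, rng: np.random.Generator | None = None
) -> dict:
    """Normalized stability of k-means(k) on embedded train features.

    Each repeat partitions the rows into ``cv_folds`` folds; every fold
    serves once as internal test: both sides are clustered independently, a
    k-NN classifier carries the internal-training labels over, and the
    aligned disagreement with the internal-test side's own labels is
    recorded. Stability is the mean error; dividing by (k-1)/k — the
    asymptotic error of uniformly random labelling — makes curves
    comparable across k.
    """
    n = Z.shape[0]
    if n < 2 * k:
        raise ValueError(f"need at least 2k={2*k} points, got {n}")
    if rng is None:
        rng = substream(cfg.seed, f"stability:k={k}")
    errors = []
    for rep in range(cfg.cv_repeats):
        perm = rng.permutation(n)
        folds = np.array_split(perm, cfg.cv_folds)
        rep_errors = []
        for f in range(cfg.cv_folds):
            test = folds[f]
            train = np.concatenate([folds[g] for g in range(cfg.cv_folds) if g != f])
            if len(train) < k or len(test) < k:
                continue
            seed = int(rng.integers(2**31))
            lab_tr = _kmeans_labels(Z[train], k, cfg, seed)
            lab_te = _kmeans_labels(Z[test], k, cfg, seed + 7)
            if len(np.unique(lab_tr)) < k or len(np.unique(lab_te)) < k:
                logger.warning("empty cluster at k=%d; recording worst-case error", k)
                rep_errors.append((k - 1) / k)
                continue
            knn = KNeighborsClassifier(n_neighbors=min(cfg.knn_neighbors, len(train)))
            knn.fit(Z[train], lab_tr)
            pred = knn.predict(Z[test])
            _, err = align_labels(lab_te, pred)
            rep_errors.append(err)
        errors.append(np.mean(rep_errors))
    errors = np.asarray(errors)
    stability = float(errors.mean())
    return {
        "k": k,
        "misclassification": stability,
        "normalized_stability": stability / ((k - 1) / k),
        "dispersion": float(errors.std(ddof=1)),
    }


def _fit_embedding(train_features: np.ndarray, cfg: RevalConfig):
    """Standardise then embed with UMAP; both fit on the train split only."""
    import umap  # deferred: numba compilation on import

    if np.allclose(train_features.std(axis=0), 0.0):
        raise DegenerateInputError("all features are constant")
    scaler = StandardScaler().fit(train_features)
    Xs = scaler.transform(train_features)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        embedder = umap.UMAP(
            n_neighbors=cfg.umap_n_neighbors,
            min_dist=cfg.umap_min_dist,
            n_components=cfg.umap_n_components,
            metric=cfg.umap_metric,
            random_state=cfg.umap_random_state,
        ).fit(Xs)
    return scaler, embedder, embedder.embedding_


def select_best_k(
    train: pd.DataFrame, cfg: RevalConfig, features: tuple = FEATURES
) -> tuple[int, pd.DataFrame, StandardScaler, object]:
    """Stability curve over ``cfg.k_range``; best k = argmin (ties -> smaller k)."""
    X = train[list(features)].to_numpy(float)
    if np.isnan(X).any():
        raise ValueError("clustering requires complete feature rows")
    scaler, embedder, Z = _fit_embedding(X, cfg)
    entries = [normalized_stability(Z, k, cfg) for k in cfg.k_range]
    curve = pd.DataFrame(entries)
    best_k = int(curve.loc[curve["normalized_stability"].idxmin(), "k"])
    return best_k, curve, scaler, embedder


def fit_and_generalize(
    train: pd.DataFrame,
    validation: pd.DataFrame,
    best_k: int,
    cfg: RevalConfig,
    scaler: StandardScaler,
    embedder,
    curve: pd.DataFrame | None = None,
    features: tuple = FEATURES,
    total_column: str = "total",
) -> SubtypeModel:
    """Cluster both splits at best k; score validation generalisation.

    Train and validation are clustered *independently*; the classifier fit
    on the train labels predicts the validation rows, and generalization
    accuracy is 1 minus the aligned disagreement between predicted and
    native validation labels. Cluster semantics (High/Low for k=2) come
    from the mean corrected Total score.
    """
    Z_tr = embedder.transform(scaler.transform(train[list(features)].to_numpy(float)))
    Z_va = embedder.transform(scaler.transform(validation[list(features)].to_numpy(float)))
    seed = substream_seed(cfg.seed, "final-clustering")
    km = KMeans(n_clusters=best_k, n_init=cfg.kmeans_n_init, random_state=seed).fit(Z_tr)
    lab_tr = km.labels_
    lab_va_native = KMeans(
        n_clusters=best_k, n_init=cfg.kmeans_n_init, random_state=seed + 1
    ).fit_predict(Z_va)
    knn = KNeighborsClassifier(n_neighbors=min(cfg.knn_neighbors, len(train)))
    knn.fit(Z_tr, lab_tr)
    pred_va = knn.predict(Z_va)
    # map the validation set's native clusters into the train label space
    aligned_va, err = align_labels(pred_va, lab_va_native)
    unmatched = max(0, len(np.unique(lab_va_native)) - len(np.unique(lab_tr)))
    if unmatched:
        logger.warning("%d validation cluster(s) had no train counterpart", unmatched)

    labels_all = pd.concat(
        [
            pd.Series(lab_tr, index=train["subject_id"]),
            pd.Series(aligned_va, index=validation["subject_id"]),
        ]
    )
    totals = pd.concat([train, validation]).set_index("subject_id")[total_column]
    mean_total = totals.groupby(labels_all).mean().sort_values()
    if best_k == 2:
        semantics = {int(mean_total.index[0]): "Low", int(mean_total.index[1]): "High"}
    else:
        semantics = {int(c): f"rank{r + 1}" for r, c in enumerate(mean_total.index)}
    return SubtypeModel(
        best_k=best_k,
        scaler=scaler,
        embedder=embedder,
        clusterer=km,
        classifier=knn,
        train_labels=pd.Series(lab_tr, index=train["subject_id"], name="cluster"),
        validation_labels=pd.Series(aligned_va, index=validation["subject_id"], name="cluster"),
        generalization_accuracy=1.0 - err,
        label_semantics=semantics,
        stability_curve=curve if curve is not None else pd.DataFrame(),
        unmatched_validation_clusters=unmatched,
    )


def run_subtype_discovery(
    corrected_autism: pd.DataFrame, cfg: RevalConfig
) -> tuple[SubtypeModel, pd.DataFrame]:
    """Full stage: split, select best k, generalise. Returns (model, labels).

    ``labels`` has one row per autism subject: subject_id, cluster, subtype
    (High/Low semantics), split (train/validation).
    """
    complete = corrected_autism.dropna(subset=list(FEATURES))
    dropped = len(corrected_autism) - len(complete)
    if dropped:
        logger.warning("%d subjects dropped from clustering (incomplete subscales)", dropped)
    train, validation = stratified_split(complete, cfg)
    best_k, curve, scaler, embedder = select_best_k(train, cfg)
    model = fit_and_generalize(train, validation, best_k, cfg, scaler, embedder, curve)
    labels = pd.concat(
        [
            model.train_labels.to_frame().assign(split="train"),
            model.validation_labels.to_frame().assign(split="validation"),
        ]
    ).reset_index()
    labels["subtype"] = labels["cluster"].map(model.label_semantics)
    return model, labels


# ---------------------------------------------------------------------------
# significance against a single-Gaussian null


def _cluster_index(X: np.ndarray, n_init: int, seed: int) -> float:
    """2-means within-cluster SS divided by total SS (lower = more clustered)."""
    X = X - X.mean(axis=0)
    tss = float((X**2).sum())
    _, inertia = kmeans_labels(X, 2, n_init=n_init, seed=seed)
    return inertia / tss


def sigclust(
    features: np.ndarray, n_sim: int = 1000, seed: int = 0, n_init: int = 10
) -> SigClustResult:
    """Monte-Carlo test of the single multivariate Gaussian null.

    The statistic is the 2-means cluster index. Null datasets are drawn
    from a zero-mean Gaussian whose diagonal covariance holds the sample
    covariance eigenvalues, each floored at a background-noise variance
    estimated robustly (scaled MAD of all centred data entries) so that
    near-singular directions do not make the null trivially clusterable.
    """
    X = np.asarray(features, dtype=float)
    n, p = X.shape
    if n < 10:
        raise ValueError("need at least 10 observations")
    if n_sim < 100:
        warnings.warn("n_sim < 100 gives unstable p-values", stacklevel=2)
    rng = substream(seed, "sigclust")
    observed = _cluster_index(X, n_init, int(rng.integers(2**31)))

    eigvals = np.linalg.eigvalsh(np.cov(X.T if p > 1 else X.reshape(1, -1)))
    eigvals = np.atleast_1d(eigvals)
    centred = X - np.median(X)
    mad = np.median(np.abs(centred - np.median(centred)))
    sigma2_bg = (1.4826 * mad) ** 2
    lam = np.maximum(eigvals, sigma2_bg)

    null_ci = np.empty(n_sim)
    for s in range(n_sim):
        Z = rng.normal(size=(n, p)) * np.sqrt(lam)[None, :]
        null_ci[s] = _cluster_index(Z, n_init, int(rng.integers(2**31)))
    p_value = (1 + int(np.sum(null_ci <= observed))) / (n_sim + 1)
    return SigClustResult(observed, n_sim, float(p_value), seed)
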