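"""Per-timepoint multivariate decoding of Experimental vs Novel cue epochs.

For every time point, the channel vector of the (4-20 Hz band-passed)
epochs is classified with LDA and a linear SVM under stratified 5-fold
cross-validation with 2 repetitions; within each training fold the z-scoring
parameters and a 20-component PCA basis are fit on training data only and
applied to the held-out fold.  Performance is summarised as accuracy (ACC,
fold-size weighted) and AUC (rank / Mann-Whitney form on the decision
scores); group-level inference on the resulting time courses delegates to
the cluster permutation machinery with chance (0.5) as the null value.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import signal as sps
from scipy import stats
from sklearn.decomposition import PCA
from sklearn.discriminant_analysis import LinearDiscriminantAnalysis
from sklearn.model_selection import StratifiedKFold
from sklearn.svm import LinearSVC

from .cluster import ClusterResult, ClusterTestConfig, cluster_test_timecourse
from .pipeline import EpochSet

CLASSIFIERS = ("LDA", "SVM")
METRICS = ("ACC", "AUC")


@dataclass
class DecodingConfig:
    classifiers: tuple[str, ...] = CLASSIFIERS
    metrics: tuple[str, ...] = METRICS
    folds: int = 5
    repetitions: int = 2
    pca_components: int = 20
    feature_band: tuple[float, float] | None = (4.0, 20.0)
    time_decim: int = 1          # decode every k-th sample (1 = native 2 ms grid)
    zscore: bool = True
    seed: int = 0

    def __post_init__(self) -> None:
        if self.folds < 2:
            raise ValueError("folds must be >= 2")
        if self.repetitions < 1:
            raise ValueError("repetitions must be >= 1")
        unknown = set(self.classifiers) - set(CLASSIFIERS)
        if unknown:
            raise ValueError(f"unknown classifiers: {unknown}")


@dataclass
class DecodingSeries:
    """Per-timepoint classifier performance, chance = 0.5."""

    times: np.ndarray
    performance: dict              # (classifier, metric) -> array over times, in [0, 1]
    n_trials: dict                 # class label -> count
    chance: float = 0.5


def _rank_auc(y_true: np.ndarray, scores: np.ndarray) -> float:
    """AUC in Mann-Whitney rank form: P(score_pos > score_neg) with tie credit."""
    pos = scores[y_true == 1]
    neg = scores[y_true == 0]
    ranks = stats.rankdata(scores)
    u = ranks[y_true == 1].sum() - pos.size * (pos.size + 1) / 2
    return float(u / (pos.size * neg.size))


def _make_classifier(name: str):
    if name == "LDA":
        return LinearDiscriminantAnalysis()
    return LinearSVC(C=1.0, max_iter=5000)


def decode_timecourse(epochs: EpochSet, config: DecodingConfig | None = None,
                      label_column: str = "sound_type",
                      positive_class: str = "Experimental") -> DecodingSeries:
    """Cross-validated single-subject decoding of the two epoch classes.

    The fold assignment is fixed across time points within a repetition, as
    in standard per-timepoint MVPA, so time courses are comparable bin to
    bin.
    """
    config = config or DecodingConfig()
    labels = epochs.metadata[label_column].to_numpy()
    classes = np.unique(labels)
    if classes.size != 2:
        raise ValueError(f"decoding needs exactly 2 classes, found {classes.tolist()}")
    y = (labels == positive_class).astype(int)
    counts = {str(c): int(np.sum(labels == c)) for c in classes}
    if min(counts.values()) < config.folds:
        raise ValueError(f"each class needs >= {config.folds} trials for "
                         f"{config.folds}-fold CV; got {counts}")
    n_features = epochs.data.shape[1]
    if config.pca_components > n_features:
        raise ValueError(f"pca_components={config.pca_components} exceeds "
                         f"{n_features} channel features")
    if not np.all(np.isfinite(epochs.data)):
        raise ValueError("epoch features contain non-finite values")

    data = epochs.data
    if config.feature_band is not None:
        low, high = config.feature_band
        sos = sps.butter(2, [low, high], btype="bandpass",
                         fs=epochs.sampling_rate, output="sos")
        data = sps.sosfiltfilt(sos, data, axis=-1)

    t_idx = np.arange(0, data.shape[2], config.time_decim)
    times = epochs.times[t_idx]
    perf = {(clf, met): np.zeros(t_idx.size)
            for clf in config.classifiers for met in config.metrics}

    splits_per_rep = []
    for rep in range(config.repetitions):
        skf = StratifiedKFold(n_splits=config.folds, shuffle=True,
                              random_state=config.seed + rep)
        splits_per_rep.append(list(skf.split(np.zeros(y.size), y)))

    n_cv = config.repetitions * config.folds
    for ti, t in enumerate(t_idx):
        X = data[:, :, t]
        acc_acc = {clf: 0.0 for clf in config.classifiers}
        acc_w = 0
        auc_acc = {clf: 0.0 for clf in config.classifiers}
        for splits in splits_per_rep:
            for train, test in splits:
                Xtr, Xte = X[train], X[test]
                if config.zscore:
                    mu = Xtr.mean(axis=0)
                    sd = Xtr.std(axis=0)
                    sd[sd == 0] = 1.0
                    Xtr, Xte = (Xtr - mu) / sd, (Xte - mu) / sd
                pca = PCA(n_components=config.pca_components,
                          svd_solver="full").fit(Xtr)
                Xtr, Xte = pca.transform(Xtr), pca.transform(Xte)
                for clf_name in config.classifiers:
                    clf = _make_classifier(clf_name).fit(Xtr, y[train])
                    if "ACC" in config.metrics:
                        acc_acc[clf_name] += np.sum(clf.predict(Xte) == y[test])
                    if "AUC" in config.metrics:
                        scores = clf.decision_function(Xte)
                        auc_acc[clf_name] += _rank_auc(y[test], scores)
                acc_w += len(test)
        for clf_name in config.classifiers:
            if "ACC" in config.metrics:
                perf[(clf_name, "ACC")][ti] = acc_acc[clf_name] / acc_w
            if "AUC" in config.metrics:
                perf[(clf_name, "AUC")][ti] = auc_acc[clf_name] / n_cv

    return DecodingSeries(times=times, performance=perf, n_trials=counts)


def group_decoding_test(series: list[DecodingSeries],
                        config: ClusterTestConfig | None = None,
                        classifier: str = "SVM", metric: str = "AUC") -> list[ClusterResult]:
    """Between-subject cluster permutation test of decoding vs chance (0.5)."""
    if len(series) < 2:
        raise ValueError("group test needs at least 2 subjects")
    key = (classifier, metric)
    data = np.stack([s.performance[key] for s in series])
    return cluster_test_timecourse(data, null_value=series[0].chance, config=config,
                                   times=series[0].times)


def cluster_scores(series: list[DecodingSeries], cluster: ClusterResult | np.ndarray,
                   classifier: str = "SVM", metric: str = "AUC") -> pd.DataFrame:
    """Per-subject mean and peak performance within a significant cluster."""
    bins = cluster.bins if isinstance(cluster, ClusterResult) else np.asarray(cluster)
    bins = np.atleast_1d(bins).astype(int)
    if bins.size == 0:
        raise ValueError("cluster has no member bins")
    rows = []
    for k, s in enumerate(series):
        vals = s.performance[(classifier, metric)][bins]
        rows.append({"subject": k, "mean": float(vals.mean()), "peak": float(vals.max())})
    return pd.DataFrame(rows)
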