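"""Stimulus-related information in trial ensembles of firing rates.

Two scalar measures quantify what an ideal observer could read out of
single-trial firing rates:

* information detection -- how separable evoked responses (rate at
  stimulus offset) are from spontaneous activity (rate sampled before
  onset), for one stimulus intensity;
* information differentiation -- how separable evoked responses to
  different intensities are from each other.

Both are scored by clustering the pooled scalar samples with K-means
under stratified 10-fold cross-validation: centroids are fitted on the
training folds, test samples are assigned to the nearest centroid, and
the agreement between assignments and true labels is summarised by
normalised mutual information (NMI), averaged over folds with a 95%
confidence interval.  Supervised (logistic classification),
significance-test (t-test / ANOVA) and information-theoretic (plug-in
mutual information) variants of the same readouts serve as robustness
checks.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import stats
from sklearn.cluster import KMeans
from sklearn.linear_model import LogisticRegression
from sklearn.model_selection import StratifiedKFold

__all__ = [
    "LabeledSamples",
    "InfoResult",
    "nmi",
    "info_detection",
    "info_differentiation",
    "supervised_detection",
    "supervised_differentiation",
    "significance_detection",
    "significance_differentiation",
    "mi_stimulus_response",
]

N_FOLDS = 10
KMEANS_RESTARTS = 10


@dataclass(frozen=True)
class LabeledSamples:
    """Scalar firing-rate samples with integer class labels."""

    values: np.ndarray
    labels: np.ndarray

    def __post_init__(self) -> None:
        object.__setattr__(self, "values", np.asarray(self.values, dtype=float).ravel())
        object.__setattr__(self, "labels", np.asarray(self.labels).ravel())
        if self.values.shape != self.labels.shape:
            raise ValueError("values and labels must have equal length")
        if self.values.size == 0:
            raise ValueError("empty sample set")

    @property
    def n_classes(self) -> int:
        return len(np.unique(self.labels))

    @classmethod
    def from_arrays(cls, *groups) -> "LabeledSamples":
        """Stack per-class sample arrays; class k gets label k."""
        values = np.concatenate([np.asarray(g, dtype=float).ravel() for g in groups])
        labels = np.concatenate([np.full(np.asarray(g).size, k) for k, g in enumerate(groups)])
        return cls(values, labels)


@dataclass
class InfoResult:
    """Cross-validated information score.

    per_fold holds the fold NMI values; ci95 is the half-width of the
    95% confidence interval from the t distribution with n_folds - 1
    degrees of freedom.  ``p_value`` / ``bits`` are set by the
    significance-test and mutual-information variants.
    """

    per_fold: np.ndarray = field(default_factory=lambda: np.empty(0))
    mean: float = float("nan")
    ci95: float = float("nan")
    method: str = "kmeans"
    p_value: float | None = None
    bits: float | None = None

    @classmethod
    def from_folds(cls, scores, method: str) -> "InfoResult":
        scores = np.asarray(scores, dtype=float)
        half = 0.0
        if scores.size > 1:
            half = float(stats.t.ppf(0.975, scores.size - 1) * scores.std(ddof=1)
                         / np.sqrt(scores.size))
        return cls(per_fold=scores, mean=float(scores.mean()), ci95=half, method=method)


# ---------------------------------------------------------------------------
# normalised mutual information
# ---------------------------------------------------------------------------

def _entropy(p: np.ndarray) -> float:
    p = p[p > 0]
    return float(-(p * np.log2(p)).sum())


def nmi(true_labels, predicted_labels) -> float:
    """Normalised mutual information between two labelings, in [0, 1].

    MI of the joint label contingency (in bits) normalised by the
    geometric mean of the two marginal entropies; defined as 0 when
    either labeling is constant (zero entropy), the "random clustering"
    convention.
    """
    a = np.asarray(true_labels).ravel()
    b = np.asarray(predicted_labels).ravel()
    if a.size == 0 or a.shape != b.shape:
        raise ValueError("label vectors must be non-empty and of equal length")
    _, ai = np.unique(a, return_inverse=True)
    _, bi = np.unique(b, return_inverse=True)
    joint = np.zeros((ai.max() + 1, bi.max() + 1))
    np.add.at(joint, (ai, bi), 1.0)
    joint /= joint.sum()
    pa = joint.sum(axis=1)
    pb = joint.sum(axis=0)
    ha, hb = _entropy(pa), _entropy(pb)
    if ha <= 0.0 or hb <= 0.0:
        return 0.0
    outer = pa[:, None] * pb[None, :]
    mask = joint > 0
    mi = float((joint[mask] * np.log2(joint[mask] / outer[mask])).sum())
    return max(0.0, min(1.0, mi / np.sqrt(ha * hb)))


# ---------------------------------------------------------------------------
# cross-validated clustering / classification harness
# ---------------------------------------------------------------------------

def _cv_scores(samples: LabeledSamples, n_clusters: int, seed, fit_predict) -> np.ndarray:
    x = samples.values.reshape(-1, 1)
    y = samples.labels
    rng = np.random.default_rng(seed)
    skf = StratifiedKFold(n_splits=N_FOLDS, shuffle=True,
                          random_state=int(rng.integers(2**31 - 1)))
    scores = []
    for train, test in skf.split(x, y):
        pred = fit_predict(x[train], y[train], x[test],
                           int(rng.integers(2**31 - 1)), n_clusters)
        scores.append(nmi(y[test], pred))
    return np.asarray(scores)


def _kmeans_fold(x_train, y_train, x_test, seed, k):
    km = KMeans(n_clusters=k, init="random", n_init=KMEANS_RESTARTS,
                random_state=seed)
    km.fit(x_train)
    return km.predict(x_test)


def _logistic_fold(x_train, y_train, x_test, seed, k):
    clf = LogisticRegression(max_iter=1000)
    clf.fit(x_train, y_train)
    return clf.predict(x_test)


def info_detection(spont_samples, evoked_samples, seed=0) -> InfoResult:
    """Separability of evoked offset rates from spontaneous rates.

    K-means with two clusters (spontaneous / evoked, random centroid
    initialisation) under stratified 10-fold cross-validation, scored by
    NMI between test-fold assignments and the true class.
    """
    samples = LabeledSamples.from_arrays(spont_samples, evoked_samples)
    scores = _cv_scores(samples, 2, seed, _kmeans_fold)
    return InfoResult.from_folds(scores, "kmeans")


def info_differentiation(evoked_by_intensity, seed=0) -> InfoResult:
    """Separability of evoked responses across stimulus intensities.

    As :func:`info_detection`, with one class per intensity and the
    cluster count equal to the number of intensities.
    """
    groups = list(evoked_by_intensity)
    if len(groups) < 2:
        raise ValueError("differentiation needs at least two intensities")
    samples = LabeledSamples.from_arrays(*groups)
    scores = _cv_scores(samples, len(groups), seed, _kmeans_fold)
    return InfoResult.from_folds(scores, "kmeans")


def supervised_detection(spont_samples, evoked_samples, seed=0) -> InfoResult:
    """Detection scored with a logistic classifier in the same CV harness."""
    samples = LabeledSamples.from_arrays(spont_samples, evoked_samples)
    scores = _cv_scores(samples, 2, seed, _logistic_fold)
    return InfoResult.from_folds(scores, "logistic")


def supervised_differentiation(evoked_by_intensity, seed=0) -> InfoResult:
    """Differentiation scored with a multinomial logistic classifier."""
    groups = list(evoked_by_intensity)
    samples = LabeledSamples.from_arrays(*groups)
    scores = _cv_scores(samples, len(groups), seed, _logistic_fold)
    return InfoResult.from_folds(scores, "logistic")


def significance_detection(spont_samples, evoked_samples) -> InfoResult:
    """Two-sample t-test between evoked and spontaneous rates."""
    a = np.asarray(spont_samples, dtype=float).ravel()
    b = np.asarray(evoked_samples, dtype=float).ravel()
    if a.std() == 0 and b.std() == 0:
        raise ValueError("degenerate (zero-variance) samples")
    t_stat, p = stats.ttest_ind(a, b)
    res = InfoResult(method="ttest", p_value=float(p))
    res.mean = float(t_stat)
    return res


def significance_differentiation(evoked_by_intensity) -> InfoResult:
    """One-way ANOVA across the evoked responses per intensity."""
    groups = [np.asarray(g, dtype=float).ravel() for g in evoked_by_intensity]
    if len(groups) < 2:
        raise ValueError("ANOVA needs at least two groups")
    f_stat, p = stats.f_oneway(*groups)
    res = InfoResult(method="anova", p_value=float(p))
    res.mean = float(f_stat)
    return res


def mi_stimulus_response(evoked_by_intensity, bin_count: int = 20) -> InfoResult:
    """Plug-in mutual information (bits) between stimulus and response.

    The stimulus prior is uniform over the intensities; responses are
    discretised into ``bin_count`` equal-width bins over the pooled
    range.  Bounded by log2(number of intensities); no bias correction
    is applied.
    """
    groups = [np.asarray(g, dtype=float).ravel() for g in evoked_by_intensity]
    if len(groups) < 2:
        raise ValueError("mutual information needs at least two intensities")
    pooled = np.concatenate(groups)
    lo, hi = pooled.min(), pooled.max()
    if hi == lo:
        hi = lo + 1e-12
    edges = np.linspace(lo, hi, bin_count + 1)
    joint = np.zeros((len(groups), bin_count))
    for k, g in enumerate(groups):
        idx = np.clip(np.searchsorted(edges, g, side="right") - 1, 0, bin_count - 1)
        np.add.at(joint[k], idx, 1.0)
    joint /= joint.sum()
    ps = joint.sum(axis=1)
    pr = joint.sum(axis=0)
    outer = ps[:, None] * pr[None, :]
    mask = joint > 0
    bits = float((joint[mask] * np.log2(joint[mask] / outer[mask])).sum())
    res = InfoResult(method="mi", bits=bits)
    res.mean = bits
    return res
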