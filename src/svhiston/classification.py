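"""PCA + linear-SVM classification of histon features with split evaluation.

The evaluation protocol mirrors a common neuroimaging design: the cohort is
randomly split ten times into 80% training / 20% testing, stratified so each
split preserves the cohort's diagnosis, gender and age-decade composition.
Features are standardized and reduced by PCA (components fit on training rows
only), a soft-margin SVM with default parameters (cost 1, no hyperparameter
search) is trained, and seven metrics are reported per split: accuracy,
balanced accuracy, NPV, PPV, sensitivity, specificity and F-score, with AD as
the positive class.  Paired classifiers are compared with McNemar's
chi-square test on discordant predictions.
"""

from __future__ import annotations

import dataclasses
import logging
import math
import warnings
from typing import Optional, Sequence

import numpy as np
from scipy import stats
from sklearn.model_selection import StratifiedKFold
from sklearn.svm import SVC

from .io_volumes import SubjectRecord

logger = logging.getLogger(__name__)

METRIC_NAMES = ("Acc", "Bacc", "NPV", "PPV", "Sen", "Spe", "Fscore")
KERNELS = ("linear", "polynomial", "radial")
_SKLEARN_KERNEL = {"linear": "linear", "polynomial": "poly", "radial": "rbf"}


# ---------------------------------------------------------------------------
# splits


@dataclasses.dataclass
class SplitPlan:
    """n_splits (train, test) index pairs with the stratification used."""

    splits: list  # list of (train_indices, test_indices) int arrays
    strata: np.ndarray  # stratum key per subject
    test_frac: float
    seed: int


def _age_decade(age: float) -> int:
    return int(age // 10)


def make_splits(
    subjects: Sequence[SubjectRecord],
    n_splits: int = 10,
    test_frac: float = 0.2,
    seed: int = 0,
) -> SplitPlan:
    """Stratified random 80/20 splits preserving label, gender and age decade.

    Test slots are allocated to (label, gender, age-decade) strata
    proportionally with largest-remainder rounding.  Strata containing a
    single subject trigger a coarser stratification (drop age, then gender),
    with a warning.
    """
    n = len(subjects)
    if n < 10:
        raise ValueError("need at least 10 subjects")
    labels = np.array([s.label for s in subjects])
    if len(set(labels)) < 2:
        raise ValueError("both classes must be present")

    key_builders = [
        lambda s: (s.label, s.gender, _age_decade(s.age)),
        lambda s: (s.label, s.gender),
        lambda s: (s.label,),
    ]
    for depth, build in enumerate(key_builders):
        keys = [build(s) for s in subjects]
        _, counts = np.unique([str(k) for k in keys], return_counts=True)
        if counts.min() >= 2:
            break
        if depth < len(key_builders) - 1:
            logger.warning(
                "stratum with a single subject; collapsing strata (%s)",
                "dropping age" if depth == 0 else "dropping gender",
            )
    strata = np.array([str(k) for k in keys])
    uniq = np.unique(strata)
    stratum_idx = {k: np.flatnonzero(strata == k) for k in uniq}

    def _largest_remainder(sizes: np.ndarray, total: int) -> np.ndarray:
        exact = sizes * total / sizes.sum()
        base = np.floor(exact).astype(int)
        short = total - base.sum()
        # ties in remainder go to the larger stratum, then to key order
        order = np.lexsort((np.arange(len(sizes)), -sizes, -(exact - base)))
        quota = base.copy()
        for j in order[: max(0, short)]:
            quota[j] += 1
        return quota

    # allocate hierarchically — per diagnosis label first, then across the
    # gender/age strata within each label — so class balance never depends on
    # remainder tie-breaking
    total_test = int(round(n * test_frac))
    label_of_stratum = np.array([labels[stratum_idx[k][0]] for k in uniq])
    label_names, label_counts = np.unique(labels, return_counts=True)
    label_quota = _largest_remainder(label_counts.astype(float), total_test)
    quota = np.zeros(len(uniq), dtype=int)
    for lname, lquota in zip(label_names, label_quota):
        sel = np.flatnonzero(label_of_stratum == lname)
        sizes = np.array([len(stratum_idx[uniq[j]]) for j in sel], dtype=float)
        quota[sel] = _largest_remainder(sizes, int(lquota))

    rng = np.random.default_rng(seed)
    splits = []
    for _ in range(n_splits):
        test = []
        for k, q in zip(uniq, quota):
            members = stratum_idx[k]
            pick = rng.choice(members, size=min(q, len(members)), replace=False)
            test.extend(pick.tolist())
        test = np.sort(np.array(test, dtype=int))
        train = np.setdiff1d(np.arange(n), test)
        splits.append((train, test))
    return SplitPlan(splits=splits, strata=strata, test_frac=test_frac, seed=seed)


# ---------------------------------------------------------------------------
# PCA


@dataclasses.dataclass
class PcaModel:
    """Standardization + PCA learned from training rows only."""

    mean: np.ndarray
    scale: np.ndarray
    keep: np.ndarray  # boolean: columns with non-zero training variance
    components: np.ndarray  # (n_components, n_kept) orthonormal rows
    explained_variance: np.ndarray
    n_components: int

    def transform(self, X: np.ndarray) -> np.ndarray:
        Z = (X[:, self.keep] - self.mean) / self.scale
        return Z @ self.components.T


def select_scree(eigenvalues: np.ndarray, floor: int = 2, ceiling: int = 30,
                 fallback: int = 5) -> int:
    """Automated scree elbow: the component count before the largest drop in
    consecutive eigenvalue differences, clamped to [floor, ceiling]."""
    ev = np.asarray(eigenvalues, dtype=float)[:ceiling]
    if len(ev) < 4:
        return min(fallback, max(len(ev), 1))
    d = ev[:-1] - ev[1:]  # first differences
    drops = d[:-1] - d[1:]  # how much the decline flattens after component i+1
    k = int(np.argmax(drops)) + 1
    return int(np.clip(k, floor, min(ceiling, len(ev))))


def fit_pca(train: np.ndarray, n_components="scree") -> PcaModel:
    """Center, unit-variance scale and PCA-reduce using training rows only.

    Zero-variance columns are dropped (logged).  ``n_components`` may be an
    integer or ``"scree"`` for automated elbow selection (default fallback 5).
    """
    X = np.asarray(train, dtype=np.float64)
    if X.shape[0] < 3:
        raise ValueError("need at least 3 training rows for PCA")
    mean_all = X.mean(axis=0)
    sd_all = X.std(axis=0)
    keep = sd_all > 0
    if not keep.all():
        logger.info("dropping %d zero-variance columns before PCA",
                    int((~keep).sum()))
    Z = (X[:, keep] - mean_all[keep]) / sd_all[keep]

    # full eigendecomposition via SVD of the centered, scaled matrix
    U, S, Vt = np.linalg.svd(Z, full_matrices=False)
    eigenvalues = S**2 / X.shape[0]

    if n_components == "scree":
        k = select_scree(eigenvalues)
    else:
        k = int(n_components)
    max_k = min(X.shape[0] - 1, int(keep.sum()))
    if k > max_k:
        raise ValueError(f"n_components={k} exceeds {max_k}")
    return PcaModel(
        mean=mean_all[keep],
        scale=sd_all[keep],
        keep=keep,
        components=Vt[:k],
        explained_variance=eigenvalues[:k],
        n_components=k,
    )


# ---------------------------------------------------------------------------
# SVM and metrics


def train_svm(X: np.ndarray, y: Sequence[str], kernel: str = "linear",
              cost: float = 1.0) -> SVC:
    """Soft-margin SVM with default parameters (no hyperparameter search).

    gamma = 1/n_features and degree 3, the customary defaults.  ``y`` holds
    the string labels; AD is the positive class.
    """
    if kernel not in KERNELS:
        raise ValueError(f"kernel must be one of {KERNELS}")
    y = np.asarray(y)
    if len(set(y)) < 2:
        raise ValueError("training set contains a single class")
    clf = SVC(kernel=_SKLEARN_KERNEL[kernel], C=cost, degree=3, gamma="auto")
    clf.fit(X, y)
    return clf


@dataclasses.dataclass
class MetricsReport:
    """Confusion counts and the seven derived performance measures."""

    TP: int
    TN: int
    FP: int
    FN: int
    Acc: float = dataclasses.field(init=False)
    Bacc: float = dataclasses.field(init=False)
    NPV: float = dataclasses.field(init=False)
    PPV: float = dataclasses.field(init=False)
    Sen: float = dataclasses.field(init=False)
    Spe: float = dataclasses.field(init=False)
    Fscore: float = dataclasses.field(init=False)

    def __post_init__(self) -> None:
        def ratio(num, den, name):
            if den == 0:
                warnings.warn(f"{name} undefined (zero denominator)")
                return math.nan
            return num / den

        tp, tn, fp, fn = self.TP, self.TN, self.FP, self.FN
        self.Acc = ratio(tp + tn, tp + tn + fp + fn, "Acc")
        self.Sen = ratio(tp, tp + fn, "Sen")
        self.Spe = ratio(tn, tn + fp, "Spe")
        self.NPV = ratio(tn, tn + fn, "NPV")
        self.PPV = ratio(tp, tp + fp, "PPV")
        self.Bacc = (self.Sen + self.Spe) / 2
        if math.isnan(self.Sen) or math.isnan(self.PPV) or (self.Sen + self.PPV) == 0:
            warnings.warn("Fscore undefined")
            self.Fscore = math.nan
        else:
            self.Fscore = 2 * (self.Sen * self.PPV) / (self.Sen + self.PPV)

    def as_dict(self) -> dict:
        d = {"TP": self.TP, "TN": self.TN, "FP": self.FP, "FN": self.FN}
        d.update({k: getattr(self, k) for k in METRIC_NAMES})
        return d


def confusion_metrics(tp: int, tn: int, fp: int, fn: int) -> MetricsReport:
    """Seven performance measures from the confusion counts (AD positive)."""
    return MetricsReport(TP=tp, TN=tn, FP=fp, FN=fn)


def metrics_from_predictions(pred, truth) -> MetricsReport:
    pred = np.asarray(pred)
    truth = np.asarray(truth)
    if pred.shape != truth.shape:
        raise ValueError("prediction/truth length mismatch")
    tp = int(np.sum((pred == "AD") & (truth == "AD")))
    tn = int(np.sum((pred == "CN") & (truth == "CN")))
    fp = int(np.sum((pred == "AD") & (truth == "CN")))
    fn = int(np.sum((pred == "CN") & (truth == "AD")))
    return confusion_metrics(tp, tn, fp, fn)


def mean_metrics(reports: Sequence[MetricsReport]) -> dict:
    """Mean over splits of each metric, ignoring undefined (NaN) entries."""
    out = {}
    for name in METRIC_NAMES:
        vals = np.array([getattr(r, name) for r in reports], dtype=float)
        out[name] = float(np.nanmean(vals))
    return out


# ---------------------------------------------------------------------------
# McNemar


def mcnemar_compare(pred_a, pred_b, truth, exact: bool = False) -> dict:
    """McNemar's test on discordant predictions of two paired classifiers.

    b = a correct & b wrong, c = a wrong & b correct.  The default statistic
    is continuity-corrected, (|b-c|-1)^2/(b+c), against chi-square with 1 df;
    ``exact=True`` uses the binomial version instead (preferred for small
    b+c).  b+c = 0 yields p = 1.
    """
    pred_a, pred_b, truth = (np.asarray(x) for x in (pred_a, pred_b, truth))
    if not (len(pred_a) == len(pred_b) == len(truth)):
        raise ValueError("predictions and truth must have equal length")
    a_ok = pred_a == truth
    b_ok = pred_b == truth
    b = int(np.sum(a_ok & ~b_ok))
    c = int(np.sum(~a_ok & b_ok))
    if b + c == 0:
        return {"statistic": 0.0, "p_value": 1.0, "b": b, "c": c}
    if exact:
        p = stats.binomtest(min(b, c), b + c, 0.5).pvalue
        return {"statistic": float(min(b, c)), "p_value": float(p), "b": b, "c": c}
    statistic = (abs(b - c) - 1) ** 2 / (b + c)
    p = float(stats.chi2.sf(statistic, df=1))
    return {"statistic": float(statistic), "p_value": p, "b": b, "c": c}


# ---------------------------------------------------------------------------
# split-protocol evaluation and the voxel baseline


def run_split_protocol(
    X: np.ndarray,
    labels: Sequence[str],
    plan: SplitPlan,
    n_components="scree",
    kernel: str = "linear",
    cost: float = 1.0,
) -> dict:
    """Standardize + PCA + SVM on every split of ``plan``.

    All statistics (scaling, PCA, SVM) are fit on training rows only.
    Returns per-split reports, mean metrics, and per-split predictions for
    paired comparisons.
    """
    labels = np.asarray(labels)
    reports, predictions = [], []
    for train_idx, test_idx in plan.splits:
        pca = fit_pca(X[train_idx], n_components=n_components)
        clf = train_svm(pca.transform(X[train_idx]), labels[train_idx],
                        kernel=kernel, cost=cost)
        pred = clf.predict(pca.transform(X[test_idx]))
        reports.append(metrics_from_predictions(pred, labels[test_idx]))
        predictions.append({"test_indices": test_idx, "pred": pred})
    return {
        "per_split": reports,
        "mean": mean_metrics(reports),
        "predictions": predictions,
    }


COST_GRID = tuple(2.0**k for k in range(-5, 6))


def voxel_baseline(
    train_X: np.ndarray,
    train_labels: Sequence[str],
    test_X: np.ndarray,
    test_labels: Sequence[str],
    seed: int = 0,
) -> dict:
    """Linear-kernel Gram-matrix SVM on flattened GM voxel vectors.

    The cost parameter is chosen by exhaustive grid search over 2^-5..2^5,
    maximizing inner 5-fold cross-validated balanced accuracy on the training
    set; ties go to the smallest cost.  Training and test rows must be
    disjoint (leakage guard: identical rows across the two sets are an error).
    """
    train_X = np.asarray(train_X, dtype=np.float64)
    test_X = np.asarray(test_X, dtype=np.float64)
    train_labels = np.asarray(train_labels)
    test_labels = np.asarray(test_labels)
    # leakage guard: a test row identical to a training row
    for row in test_X:
        if np.any(np.all(train_X == row, axis=1)):
            raise ValueError("test subject identical to a training subject")

    gram_train = train_X @ train_X.T
    n = len(train_labels)
    kf = StratifiedKFold(n_splits=5, shuffle=True, random_state=seed)
    best_cost, best_bacc = None, -np.inf
    for cost in COST_GRID:
        baccs = []
        for tr, va in kf.split(np.zeros(n), train_labels):
            clf = SVC(kernel="precomputed", C=cost)
            clf.fit(gram_train[np.ix_(tr, tr)], train_labels[tr])
            pred = clf.predict(gram_train[np.ix_(va, tr)])
            rep = metrics_from_predictions(pred, train_labels[va])
            baccs.append(rep.Bacc)
        bacc = float(np.nanmean(baccs))
        if bacc > best_bacc:  # strict: ties keep the smaller (earlier) cost
            best_bacc, best_cost = bacc, cost
    clf = SVC(kernel="precomputed", C=best_cost)
    clf.fit(gram_train, train_labels)
    pred = clf.predict(test_X @ train_X.T)
    report = metrics_from_predictions(pred, test_labels)
    return {"report": report, "pred": pred, "cost": best_cost,
            "inner_bacc": best_bacc}
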