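"""Supervised trait classification and run-level comparison.

Two classifier families mirror the study design: multiclass gentle boosting
(one-vs-all ensembles of depth-1 regression stumps, robust to the strong class
imbalance of clinical trait labels) and a multiclass SVM baseline.  Evaluation
is stratified k-fold cross-validation reporting accuracy (%) and macro
one-vs-rest AUC, and one-way ANOVA compares per-run accuracies across feature
sets.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, asdict

import numpy as np
from scipy import stats
from sklearn.model_selection import StratifiedKFold
from sklearn.metrics import roc_auc_score
from sklearn.svm import SVC


__all__ = [
    "GentleBoostClassifier",
    "SVMClassifier",
    "make_classifier",
    "train_gentle_boost",
    "train_svm",
    "cross_validate",
    "anova_compare",
    "CVReport",
]


def _fit_stump(X, y, w):
    """Weighted-least-squares depth-1 regression stump.

    Returns (feature, threshold, left_value, right_value) minimising
    sum w * (y - f(x))^2 with f piecewise constant around the threshold.
    """
    n, d = X.shape
    sw = w.sum()
    swy = (w * y).sum()
    best = (np.inf, 0, -np.inf, 0.0, 0.0)
    for j in range(d):
        order = np.argsort(X[:, j], kind="stable")
        xs = X[order, j]
        ws = w[order]
        wys = (w * y)[order]
        wy2s = (w * y * y)[order]
        cw = np.cumsum(ws)
        cwy = np.cumsum(wys)
        cwy2 = np.cumsum(wy2s)
        # candidate splits between distinct consecutive values
        distinct = np.nonzero(np.diff(xs) > 0)[0]
        if len(distinct) == 0:
            continue
        wl, wyl = cw[distinct], cwy[distinct]
        wr, wyr = sw - wl, swy - wyl
        with np.errstate(divide="ignore", invalid="ignore"):
            ml = np.where(wl > 0, wyl / wl, 0.0)
            mr = np.where(wr > 0, wyr / wr, 0.0)
        # SSE = sum w y^2 - wl*ml^2 - wr*mr^2 (constant term shared)
        score = -(wl * ml**2 + wr * mr**2)
        i = int(np.argmin(score))
        if score[i] < best[0]:
            thr = 0.5 * (xs[distinct[i]] + xs[distinct[i] + 1])
            best = (score[i], j, thr, float(ml[i]), float(mr[i]))
    _, j, thr, ml, mr = best
    return j, thr, ml, mr


class GentleBoostClassifier:
    """Multiclass gentle boosting: one-vs-all stages of regression stumps.

    Each round fits a stump to the weighted residual targets y in {-1, +1}
    (gentle AdaBoost's weighted least squares step), adds it to the class
    score F_c and reweights w <- w * exp(-y * f).  Prediction is the argmax
    over class scores.
    """

    def __init__(self, rounds: int = 100):
        if rounds < 1:
            raise ValueError("rounds must be >= 1")
        self.rounds = rounds
        self.classes_ = None
        self.ensembles_ = None

    def fit(self, X, y):
        X = np.asarray(X, dtype=float)
        y = np.asarray(y)
        self.classes_ = np.unique(y)
        if len(self.classes_) < 2:
            raise ValueError("need at least 2 classes")
        self.ensembles_ = []
        for c in self.classes_:
            t = np.where(y == c, 1.0, -1.0)
            w = np.ones(len(t)) / len(t)
            stumps = []
            for _ in range(self.rounds):
                j, thr, ml, mr = _fit_stump(X, t, w)
                if not np.isfinite(thr):
                    break
                f = np.where(X[:, j] <= thr, ml, mr)
                stumps.append((j, thr, ml, mr))
                w = w * np.exp(-t * f)
                s = w.sum()
                if s <= 0 or not np.isfinite(s):
                    break
                w = w / s
            self.ensembles_.append(stumps)
        return self

    def decision_scores(self, X):
        X = np.asarray(X, dtype=float)
        scores = np.zeros((len(X), len(self.classes_)))
        for ci, stumps in enumerate(self.ensembles_):
            for j, thr, ml, mr in stumps:
                scores[:, ci] += np.where(X[:, j] <= thr, ml, mr)
        return scores

    def predict(self, X):
        return self.classes_[np.argmax(self.decision_scores(X), axis=1)]


class SVMClassifier:
    """Multiclass SVM via scikit-learn SVC with one-vs-rest decision scores."""

    def __init__(self, kernel: str = "rbf", C: float = 1.0, seed: int = 0):
        if kernel not in ("linear", "rbf"):
            raise ValueError("kernel must be linear or rbf")
        self.kernel = kernel
        self.C = C
        self.seed = seed
        self._svc = None
        self.classes_ = None

    def fit(self, X, y):
        y = np.asarray(y)
        if len(np.unique(y)) < 2:
            raise ValueError("need at least 2 classes")
        self._svc = SVC(
            kernel=self.kernel,
            C=self.C,
            decision_function_shape="ovr",
            random_state=self.seed,
        )
        self._svc.fit(np.asarray(X, dtype=float), y)
        self.classes_ = self._svc.classes_
        return self

    def decision_scores(self, X):
        s = self._svc.decision_function(np.asarray(X, dtype=float))
        if s.ndim == 1:  # binary: expand to per-class scores
            s = np.column_stack([-s, s])
        return s

    def predict(self, X):
        return self._svc.predict(np.asarray(X, dtype=float))


def make_classifier(name: str, seed: int = 0, **params):
    if name in ("boost", "gentleboost"):
        return GentleBoostClassifier(rounds=params.get("rounds", 100))
    if name in ("svm", "svm_rbf"):
        return SVMClassifier(kernel=params.get("kernel", "rbf"), seed=seed)
    if name == "svm_linear":
        return SVMClassifier(kernel="linear", seed=seed)
    raise ValueError(f"unknown classifier {name!r}")


def train_gentle_boost(X, y, rounds: int = 100) -> GentleBoostClassifier:
    return GentleBoostClassifier(rounds=rounds).fit(X, y)


def train_svm(X, y, kernel: str = "rbf", seed: int = 0) -> SVMClassifier:
    return SVMClassifier(kernel=kernel, seed=seed).fit(X, y)


@dataclass
class CVReport:
    """Cross-validated accuracy (%) and macro one-vs-rest AUC."""

    classifier: str
    folds: int
    seed: int
    fold_accuracy: list
    mean_accuracy: float
    fold_auc: list
    mean_auc: float

    def to_json(self, path=None):
        payload = json.dumps(asdict(self), indent=2)
        if path is not None:
            with open(path, "w") as fh:
                fh.write(payload)
        return payload


def _macro_ovr_auc(y_true, scores, classes):
    aucs = []
    for ci, c in enumerate(classes):
        mask = y_true == c
        if mask.all() or not mask.any():
            continue
        aucs.append(roc_auc_score(mask.astype(int), scores[:, ci]))
    return float(np.mean(aucs)) if aucs else np.nan


def cross_validate(spec, X, y, folds: int = 5, seed: int = 0) -> CVReport:
    """Stratified k-fold cross-validation of a classifier spec.

    ``spec`` is a classifier name ("boost", "svm", "svm_linear") or a factory
    returning a fresh classifier with fit/predict/decision_scores.
    """
    X = np.asarray(X, dtype=float)
    y = np.asarray(y)
    classes, counts = np.unique(y, return_counts=True)
    if counts.min() < folds:
        raise ValueError(
            f"class {classes[np.argmin(counts)]!r} has fewer members than folds"
        )
    if isinstance(spec, str):
        name = spec
        factory = lambda: make_classifier(name, seed=seed)  # noqa: E731
    else:
        name = getattr(spec, "__name__", "custom")
        factory = spec
    skf = StratifiedKFold(n_splits=folds, shuffle=True, random_state=seed)
    accs, aucs = [], []
    for train, test in skf.split(X, y):
        clf = factory().fit(X[train], y[train])
        pred = clf.predict(X[test])
        accs.append(100.0 * float(np.mean(pred == y[test])))
        scores = clf.decision_scores(X[test])
        aucs.append(_macro_ovr_auc(y[test], scores, clf.classes_))
    return CVReport(
        classifier=name,
        folds=folds,
        seed=seed,
        fold_accuracy=[float(a) for a in accs],
        mean_accuracy=float(np.mean(accs)),
        fold_auc=[float(a) for a in aucs],
        mean_auc=float(np.nanmean(aucs)),
    )


def anova_compare(groups):
    """One-way ANOVA over >= 2 groups of per-run accuracies.

    Returns (F, p, MS_between, MS_within) with F on (g-1, N-g) degrees of
    freedom.
    """
    groups = [np.asarray(g, dtype=float) for g in groups]
    if len(groups) < 2 or any(len(g) < 2 for g in groups):
        raise ValueError("anova_compare needs >= 2 groups of >= 2 values")
    N = sum(len(g) for g in groups)
    g = len(groups)
    grand = np.concatenate(groups).mean()
    ssb = sum(len(x) * (x.mean() - grand) ** 2 for x in groups)
    ssw = sum(((x - x.mean()) ** 2).sum() for x in groups)
    df_b, df_w = g - 1, N - g
    ms_b, ms_w = ssb / df_b, ssw / df_w
    if ms_w == 0:
        if ssb == 0:
            raise ValueError("zero variance everywhere: F undefined")
        return np.inf, 0.0, ms_b, ms_w
    F = ms_b / ms_w
    p = float(stats.f.sf(F, df_b, df_w))
    return float(F), p, float(ms_b), float(ms_w)
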