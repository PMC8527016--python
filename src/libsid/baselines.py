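"""KNN and SVM reference classifiers with their selection protocols.

Both consume exactly the preprocessing pipeline's outputs (masked,
area-normalized spectra), so comparisons with the networks are
like-for-like.  KNN chooses k in 3..20 by validation accuracy (ties
to the smallest k); the RBF-kernel SVM chooses (c, g) on a
powers-of-ten grid spanning 1e-8..1e8 by stratified five-fold
cross-validation accuracy on the calibration set, then refits on all
of it.  Multiclass reduction is one-vs-one.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from sklearn.model_selection import StratifiedKFold
from sklearn.neighbors import KNeighborsClassifier
from sklearn.svm import SVC

__all__ = ["KNNSearchSpec", "SVMSearchSpec", "fit_knn", "fit_svm"]


def _powers_of_ten():
    return tuple(10.0 ** e for e in range(-8, 9))


@dataclass(frozen=True)
class KNNSearchSpec:
    k_min: int = 3
    k_max: int = 20

    def __post_init__(self):
        if self.k_min < 1 or self.k_max < self.k_min:
            raise ValueError("need 1 <= k_min <= k_max")


@dataclass(frozen=True)
class SVMSearchSpec:
    kernel: str = "rbf"
    c_grid: tuple = field(default_factory=_powers_of_ten)
    g_grid: tuple = field(default_factory=_powers_of_ten)
    cv_folds: int = 5

    def __post_init__(self):
        if not self.c_grid or not self.g_grid:
            raise ValueError("grids must be nonempty")
        if self.cv_folds < 2:
            raise ValueError("need at least 2 folds")


def fit_knn(X_cal, y_cal, X_val, y_val,
            spec: KNNSearchSpec = KNNSearchSpec()):
    """Euclidean KNN; k maximizes validation accuracy, ties to smallest."""
    X_cal = np.asarray(X_cal)
    y_cal = np.asarray(y_cal)
    if spec.k_max > len(X_cal):
        raise ValueError("k range exceeds calibration size")
    best_k, best_acc = None, -1.0
    for k in range(spec.k_min, spec.k_max + 1):
        m = KNeighborsClassifier(n_neighbors=k, metric="euclidean")
        m.fit(X_cal, y_cal)
        acc = float((m.predict(X_val) == np.asarray(y_val)).mean())
        if acc > best_acc:            # strict: ties keep the smaller k
            best_k, best_acc = k, acc
    model = KNeighborsClassifier(n_neighbors=best_k, metric="euclidean")
    model.fit(X_cal, y_cal)
    return model, best_k


def fit_svm(X_cal, y_cal, spec: SVMSearchSpec = SVMSearchSpec(),
            rng_seed: int = 0):
    """RBF SVM; (c, g) by stratified k-fold CV accuracy, refit on all.

    Ties keep the first grid point in (c, g) iteration order, which
    makes the selection deterministic for a fixed fold seed.
    """
    X_cal = np.asarray(X_cal)
    y_cal = np.asarray(y_cal)
    if len(np.unique(y_cal)) < 2:
        raise ValueError("calibration set contains a single class")
    skf = StratifiedKFold(n_splits=spec.cv_folds, shuffle=True,
                          random_state=rng_seed)
    folds = list(skf.split(X_cal, y_cal))
    best = None
    for c in spec.c_grid:
        for g in spec.g_grid:
            accs = []
            for tr, te in folds:
                m = SVC(kernel=spec.kernel, C=c, gamma=g,
                        decision_function_shape="ovo")
                m.fit(X_cal[tr], y_cal[tr])
                accs.append(float((m.predict(X_cal[te])
                                   == y_cal[te]).mean()))
            cv = float(np.mean(accs))
            if best is None or cv > best[0]:
                best = (cv, c, g)
    _, c, g = best
    model = SVC(kernel=spec.kernel, C=c, gamma=g,
                decision_function_shape="ovo")
    model.fit(X_cal, y_cal)
    return model, c, g
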