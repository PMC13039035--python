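"""EMG-based age-group classification (control analysis).

Binary young/older classification of time-normalized phasic EMG waveforms,
per muscle or on the concatenated muscle set, with stratified 5-fold
cross-validation (folds balanced jointly on group and movement direction) and
a chance-level "fairness" bound. The exact construction of the published
bound is not described; both an exact-binomial bound and a label-permutation
bound are provided.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import stats as sstats
from sklearn.discriminant_analysis import (
    LinearDiscriminantAnalysis,
    QuadraticDiscriminantAnalysis,
)
from sklearn.model_selection import StratifiedKFold
from sklearn.decomposition import PCA
from sklearn.pipeline import make_pipeline
from sklearn.preprocessing import StandardScaler
from sklearn.svm import SVC

__all__ = [
    "FeatureMatrix",
    "CvResult",
    "build_feature_matrix",
    "crossval_classify",
    "chance_threshold",
]

#: 16 electrodes minus the left ESL1 (defective for several participants).
DEFAULT_EXCLUDE = ("left_ESL1",)


@dataclass(frozen=True)
class FeatureMatrix:
    """Rows = phasic traces (or participant means), columns = L samples per
    muscle concatenated in ``muscle_order``; ``y`` = group, ``strata`` =
    movement direction."""

    X: np.ndarray
    y: np.ndarray
    strata: np.ndarray
    muscle_order: tuple[str, ...]

    def __post_init__(self):
        X = np.asarray(self.X, dtype=float)
        object.__setattr__(self, "X", X)
        object.__setattr__(self, "y", np.asarray(self.y))
        object.__setattr__(self, "strata", np.asarray(self.strata))
        if X.ndim != 2 or X.shape[0] != len(self.y) or len(self.y) != len(self.strata):
            raise ValueError("inconsistent feature-matrix shapes")
        if not np.all(np.isfinite(X)):
            raise ValueError("feature matrix contains non-finite values")


@dataclass(frozen=True)
class CvResult:
    fold_accuracies: np.ndarray
    n_per_fold: np.ndarray

    @property
    def mean_accuracy(self) -> float:
        return float(np.mean(self.fold_accuracies))

    @property
    def sd_accuracy(self) -> float:
        return float(np.std(self.fold_accuracies, ddof=1))


def build_feature_matrix(
    traces: list[dict],
    muscles: tuple[str, ...] | None = None,
    exclude: tuple[str, ...] = DEFAULT_EXCLUDE,
) -> FeatureMatrix:
    """Assemble per-row concatenated muscle waveforms.

    ``traces`` is a list of records with keys ``group``, ``direction`` and one
    array per muscle channel (``<side>_<muscle>`` or plain muscle label).
    Channels listed in ``exclude`` or flagged defective anywhere are dropped
    entirely (rows must be complete). Standardization is NOT applied here: it
    belongs inside the cross-validation pipeline so scaling parameters are fit
    on training folds only.
    """
    if not traces:
        raise ValueError("no traces")
    groups = {r["group"] for r in traces}
    if len(groups) < 2:
        raise ValueError("both classes must be present")
    if muscles is None:
        keys = set.intersection(
            *({k for k, v in r.items() if isinstance(v, np.ndarray)} for r in traces)
        )
        muscles = tuple(sorted(k for k in keys if k not in exclude))
    if not muscles:
        raise ValueError("no usable muscle channels")
    X = np.stack([np.concatenate([np.asarray(r[m], float) for m in muscles]) for r in traces])
    y = np.array([r["group"] for r in traces])
    strata = np.array([r["direction"] for r in traces])
    return FeatureMatrix(X=X, y=y, strata=strata, muscle_order=tuple(muscles))


def _make_model(model: str, max_dim: int | None = None):
    if model == "lda":
        clf = LinearDiscriminantAnalysis(solver="svd")
    elif model == "qda":
        # per-class covariances need fewer dimensions than class samples:
        # reduce with PCA fit on the training fold
        clf = QuadraticDiscriminantAnalysis(reg_param=1e-3)
        if max_dim is not None:
            return make_pipeline(StandardScaler(), PCA(n_components=max_dim), clf)
    elif model == "svm":
        clf = SVC(kernel="linear", C=1.0)
    else:
        raise ValueError("model must be 'lda', 'qda' or 'svm'")
    return make_pipeline(StandardScaler(), clf)


def crossval_classify(
    fm: FeatureMatrix,
    model: str = "lda",
    seed: int = 0,
    n_splits: int = 5,
) -> CvResult:
    """Stratified k-fold cross-validated accuracy.

    Folds are stratified jointly on (group, direction) so each test set keeps
    equal representation of both movement directions. Deterministic given
    ``seed``. Per-column standardization is fit on each training fold only.
    """
    classes, counts = np.unique(fm.y, return_counts=True)
    if len(classes) != 2:
        raise ValueError("binary classification requires exactly 2 classes")
    if counts.min() < n_splits:
        raise ValueError(f"need >= {n_splits} rows per class")
    joint = np.char.add(fm.y.astype(str), np.char.add("|", fm.strata.astype(str)))
    skf = StratifiedKFold(n_splits=n_splits, shuffle=True, random_state=seed)
    accs, ns = [], []
    for train, test in skf.split(fm.X, joint):
        if len(np.unique(fm.y[train])) < 2:
            raise ValueError("a training fold contains a single class")
        max_dim = None
        if model == "qda" and fm.X.shape[1] >= np.bincount(
            np.searchsorted(classes, fm.y[train])
        ).min():
            max_dim = int(np.bincount(np.searchsorted(classes, fm.y[train])).min()) - 1
        clf = _make_model(model, max_dim=max_dim)
        clf.fit(fm.X[train], fm.y[train])
        accs.append(float(np.mean(clf.predict(fm.X[test]) == fm.y[test])))
        ns.append(len(test))
    return CvResult(fold_accuracies=np.array(accs), n_per_fold=np.array(ns))


def chance_threshold(
    n_samples: int,
    n_classes: int = 2,
    alpha: float = 0.05,
    method: str = "binomial",
    fm: FeatureMatrix | None = None,
    model: str = "lda",
    n_permutations: int = 0,
    seed: int = 0,
) -> float:
    """Accuracy bound above which classification beats chance at level alpha.

    ``binomial``: smallest a with P(Binom(n, 1/n_classes) >= a*n) <= alpha.
    ``permutation``: the (1 - alpha) quantile of cross-validated accuracies
    obtained under random label permutations (requires ``fm`` and
    ``n_permutations`` > 0).
    """
    if not 0 < alpha <= 1:
        raise ValueError("alpha must be in (0, 1]")
    if n_samples <= 0:
        raise ValueError("n_samples must be > 0")
    if method == "binomial":
        p = 1.0 / n_classes
        k = np.arange(n_samples + 1)
        tail = sstats.binom.sf(k - 1, n_samples, p)  # P(X >= k)
        ok = np.flatnonzero(tail <= alpha)
        return float(ok[0] / n_samples) if ok.size else 1.0
    if method == "permutation":
        if fm is None or n_permutations <= 0:
            raise ValueError("permutation method needs a FeatureMatrix and n_permutations > 0")
        rng = np.random.default_rng(seed)
        accs = []
        for i in range(n_permutations):
            perm = rng.permutation(len(fm.y))
            fm_p = FeatureMatrix(fm.X, fm.y[perm], fm.strata, fm.muscle_order)
            accs.append(crossval_classify(fm_p, model=model, seed=seed + i).mean_accuracy)
        return float(np.quantile(accs, 1.0 - alpha))
    raise ValueError("method must be 'binomial' or 'permutation'")
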