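"""Chemotherapy-response prediction from the habitat feature table.

The modelling chain mirrors a standard imbalanced radiomics workflow:

1. response labels from the modified-response (MR) grade — MR 1–2
   (<30% size reduction) is non-responder, MR 3–5 (>30% reduction or
   very low residual cellularity) is responder;
2. SMOTE oversampling of the training minority class to parity;
3. mRMR ranking (mutual-information difference criterion on 3-bin
   discretized features) reducing 56 features to 21;
4. sequential forward selection (SFS) maximizing 5-fold cross-validated
   accuracy of an AdaBoost decision-tree classifier, stopping at 4
   features;
5. AdaBoost (depth-2 trees) training on the oversampled training set
   and a single evaluation on the untouched test split.

Sensitivity is recall on the non-responder class (the clinically
actionable minority) and specificity recall on responders.  SMOTE,
ranking and selection only ever see training rows; inside SFS the
oversampling is redone within each training fold.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.ensemble import AdaBoostClassifier
from sklearn.metrics import mutual_info_score, roc_auc_score, roc_curve
from sklearn.model_selection import StratifiedKFold
from sklearn.neighbors import NearestNeighbors
from sklearn.tree import DecisionTreeClassifier

from .features import FEATURE_NAMES

__all__ = [
    "CORE_FEATURES",
    "CORE_MARGIN_FEATURES",
    "CLINICAL_FEATURES",
    "PredictionResult",
    "label_response",
    "smote_oversample",
    "mrmr_rank",
    "sfs_select",
    "make_classifier",
    "train_classifier",
    "evaluate",
    "split_cohort",
    "run_experiment",
]

# Feature subsets for the comparison experiments: whole-core only,
# core + margin, and standard clinical variables.
CORE_FEATURES = tuple(
    f"{s}_C_{m}" for m in ("ESD", "EAC", "MBF", "SI") for s in ("M", "SNR")
)
CORE_MARGIN_FEATURES = CORE_FEATURES + tuple(
    f"{s}_m_{m}" for m in ("ESD", "EAC", "MBF", "SI") for s in ("M", "SNR")
)
CLINICAL_FEATURES = ("tumor_size", "er", "pr", "her2", "age")

RESPONDER, NON_RESPONDER = "responder", "non-responder"


def label_response(
    mr_score: int | None = None,
    size_reduction_pct: float | None = None,
    low_cellularity: bool = False,
) -> str:
    """Binary response label from the MR grade or a raw size reduction.

    MR 1–2 → non-responder; MR 3–5 → responder.  From a raw percentage:
    <30% reduction is non-responder unless very low residual cellularity
    was determined histopathologically.
    """
    if mr_score is not None:
        if not 1 <= mr_score <= 5:
            raise ValueError("MR score must be in 1..5")
        return RESPONDER if mr_score >= 3 else NON_RESPONDER
    if size_reduction_pct is None:
        raise ValueError("need an MR score or a size-reduction percentage")
    if not 0 <= size_reduction_pct <= 100:
        raise ValueError("size reduction must be a percentage in [0, 100]")
    if size_reduction_pct >= 30 or low_cellularity:
        return RESPONDER
    return NON_RESPONDER


def smote_oversample(
    X: np.ndarray, y: np.ndarray, seed: int = 0, k_neighbors: int = 5
) -> tuple[np.ndarray, np.ndarray]:
    """Synthetic minority oversampling to class parity.

    New minority samples are convex combinations ``x + u·(x_nn − x)`` of a
    minority point and one of its k nearest minority neighbors
    (k shrunk when the minority class is small).  Majority rows pass
    through unchanged; already-balanced input is returned as-is.
    """
    X = np.asarray(X, dtype=float)
    y = np.asarray(y)
    classes, counts = np.unique(y, return_counts=True)
    if classes.size < 2:
        raise ValueError("SMOTE requires both classes in the training set")
    minority = classes[np.argmin(counts)]
    n_min, n_maj = counts.min(), counts.max()
    n_new = int(n_maj - n_min)
    if n_new == 0:
        return X, y
    Xm = X[y == minority]
    if Xm.shape[0] < 2:
        raise ValueError("minority class must have at least 2 samples")
    k = min(k_neighbors, Xm.shape[0] - 1)
    nn = NearestNeighbors(n_neighbors=k + 1).fit(Xm)
    _, idx = nn.kneighbors(Xm)
    rng = np.random.default_rng(seed)
    base = rng.integers(0, Xm.shape[0], n_new)
    pick = rng.integers(1, k + 1, n_new)
    gaps = rng.random((n_new, 1))
    neigh = Xm[idx[base, pick]]
    X_new = Xm[base] + gaps * (neigh - Xm[base])
    return (
        np.vstack([X, X_new]),
        np.concatenate([y, np.full(n_new, minority, dtype=y.dtype)]),
    )


def _discretize(x: np.ndarray) -> np.ndarray:
    """Classic mRMR 3-bin discretization at μ ± σ."""
    mu, sd = x.mean(), x.std()
    if sd == 0:
        return np.zeros_like(x, dtype=int)
    return np.digitize(x, [mu - sd, mu + sd])


def mrmr_rank(
    X: np.ndarray, y: np.ndarray, feature_names: list[str], n_keep: int = 21
) -> list[str]:
    """Greedy minimal-redundancy-maximal-relevance feature ranking.

    Uses the mutual-information difference (MID) criterion on features
    discretized into three bins at μ ± σ.  Constant features have zero
    relevance and rank last.  Returns the ordered top ``n_keep`` names.
    """
    X = np.asarray(X, dtype=float)
    if n_keep > X.shape[1]:
        raise ValueError("n_keep exceeds the number of features")
    disc = np.column_stack([_discretize(X[:, j]) for j in range(X.shape[1])])
    relevance = np.array([mutual_info_score(disc[:, j], y) for j in range(X.shape[1])])
    constant = np.array([np.unique(disc[:, j]).size == 1 for j in range(X.shape[1])])
    selected: list[int] = []
    remaining = list(range(X.shape[1]))
    mi_cache: dict[tuple[int, int], float] = {}

    def mi(a: int, b: int) -> float:
        key = (min(a, b), max(a, b))
        if key not in mi_cache:
            mi_cache[key] = mutual_info_score(disc[:, a], disc[:, b])
        return mi_cache[key]

    while remaining and len(selected) < n_keep:
        best, best_score = None, -np.inf
        for j in remaining:
            if constant[j]:
                score = -np.inf  # rank constants last
            elif not selected:
                score = relevance[j]
            else:
                score = relevance[j] - np.mean([mi(j, s) for s in selected])
            if score > best_score:
                best, best_score = j, score
        if best is None or best_score == -np.inf:
            # only constants left: append in original order
            best = remaining[0]
        selected.append(best)
        remaining.remove(best)
    return [feature_names[j] for j in selected]


def make_classifier(
    seed: int = 0,
    n_estimators: int = 100,
    max_depth: int = 2,
    learning_rate: float = 1.0,
) -> AdaBoostClassifier:
    """AdaBoost over depth-limited decision trees (the response classifier)."""
    return AdaBoostClassifier(
        estimator=DecisionTreeClassifier(max_depth=max_depth, random_state=seed),
        n_estimators=n_estimators,
        learning_rate=learning_rate,
        random_state=seed,
    )


def sfs_select(
    X: np.ndarray,
    y: np.ndarray,
    ranked_features: list[str],
    feature_names: list[str],
    target_size: int = 4,
    folds: int = 5,
    seed: int = 0,
    classifier_factory=None,
    min_improvement: float | None = None,
) -> list[str]:
    """Sequential forward selection by 5-fold cross-validated accuracy.

    Candidates are taken from the mRMR-ranked list; at each step the
    feature raising mean CV accuracy the most is added (ties prefer the
    higher mRMR rank).  SMOTE is applied inside each training fold only.
    Stops at ``target_size`` features, or earlier if ``min_improvement``
    is set and no candidate improves accuracy by at least that much.
    """
    if not ranked_features:
        raise ValueError("ranked feature list is empty")
    X = np.asarray(X, dtype=float)
    name_to_col = {n: feature_names.index(n) for n in ranked_features}
    if classifier_factory is None:
        classifier_factory = lambda: make_classifier(seed=seed)  # noqa: E731

    skf = StratifiedKFold(n_splits=folds, shuffle=True, random_state=seed)
    splits = list(skf.split(X, y))

    def cv_accuracy(cols: list[int]) -> float:
        accs = []
        for f, (tr, va) in enumerate(splits):
            Xb, yb = smote_oversample(X[tr][:, cols], y[tr], seed=seed + f)
            clf = classifier_factory()
            clf.fit(Xb, yb)
            accs.append(np.mean(clf.predict(X[va][:, cols]) == y[va]))
        return float(np.mean(accs))

    selected: list[str] = []
    current = -np.inf
    while len(selected) < target_size:
        best_name, best_acc = None, -np.inf
        for name in ranked_features:  # rank order ⇒ ties keep higher mRMR rank
            if name in selected:
                continue
            acc = cv_accuracy([name_to_col[s] for s in selected] + [name_to_col[name]])
            if acc > best_acc:
                best_name, best_acc = name, acc
        if best_name is None:
            break
        if min_improvement is not None and best_acc < current + min_improvement:
            break
        selected.append(best_name)
        current = best_acc
    return selected


def train_classifier(
    X: np.ndarray,
    y: np.ndarray,
    seed: int = 0,
    oversample: bool = True,
    **clf_kwargs,
) -> AdaBoostClassifier:
    """SMOTE-balance the training set (optionally) and fit the AdaBoost model."""
    if np.unique(y).size < 2:
        raise ValueError("training set must contain both classes")
    if oversample:
        X, y = smote_oversample(X, y, seed=seed)
    clf = make_classifier(seed=seed, **clf_kwargs)
    clf.fit(X, y)
    return clf


@dataclass
class PredictionResult:
    """Test-set performance of a fitted response model."""

    accuracy: float
    sensitivity: float  # recall on non-responders
    specificity: float  # recall on responders
    auc: float
    roc_fpr: np.ndarray
    roc_tpr: np.ndarray
    predictions: np.ndarray
    scores: np.ndarray
    selected_features: list[str] = field(default_factory=list)
    feature_importances: dict[str, float] = field(default_factory=dict)

    def to_dict(self) -> dict:
        return {
            "accuracy": self.accuracy,
            "sensitivity": self.sensitivity,
            "specificity": self.specificity,
            "auc": self.auc,
            "selected_features": self.selected_features,
            "feature_importances": self.feature_importances,
        }


def evaluate(
    model: AdaBoostClassifier,
    X_test: np.ndarray,
    y_test: np.ndarray,
    selected_features: list[str] | None = None,
) -> PredictionResult:
    """Single evaluation on the held-out test split.

    Sensitivity is recall on the non-responder class, specificity recall
    on responders; AUC is the trapezoidal area under the ROC of the
    non-responder score.  A single-class test set has no defined AUC and
    raises.
    """
    y_test = np.asarray(y_test)
    if np.unique(y_test).size < 2:
        raise ValueError("AUC undefined on a single-class test set")
    pred = model.predict(X_test)
    classes = list(model.classes_)
    score = model.predict_proba(X_test)[:, classes.index(NON_RESPONDER)]
    is_nr = y_test == NON_RESPONDER
    sens = float(np.mean(pred[is_nr] == NON_RESPONDER))
    spec = float(np.mean(pred[~is_nr] == RESPONDER))
    acc = float(np.mean(pred == y_test))
    auc = float(roc_auc_score(is_nr.astype(int), score))
    fpr, tpr, _ = roc_curve(is_nr.astype(int), score)
    importances = {}
    if selected_features is not None:
        importances = dict(zip(selected_features,
                               np.round(model.feature_importances_, 6).tolist()))
    return PredictionResult(
        accuracy=acc, sensitivity=sens, specificity=spec, auc=auc,
        roc_fpr=fpr, roc_tpr=tpr, predictions=pred, scores=score,
        selected_features=selected_features or [],
        feature_importances=importances,
    )


def split_cohort(
    df: pd.DataFrame, test_fraction: float = 0.3, seed: int = 0
) -> pd.DataFrame:
    """Assign a stratified 70/30 train/test split (adds a ``split`` column)."""
    rng = np.random.default_rng(seed)
    df = df.copy()
    df["split"] = "train"
    for label in df["response"].unique():
        idx = df.index[df["response"] == label].to_numpy()
        n_test = int(round(test_fraction * idx.size))
        test_idx = rng.permutation(idx)[:n_test]
        df.loc[test_idx, "split"] = "test"
    return df


FEATURE_SETS = {
    "habitats": list(FEATURE_NAMES),
    "core": list(CORE_FEATURES),
    "core+margin": list(CORE_MARGIN_FEATURES),
    "clinical": list(CLINICAL_FEATURES),
    "habitats+clinical": list(FEATURE_NAMES) + list(CLINICAL_FEATURES),
}


def run_experiment(
    df: pd.DataFrame,
    feature_set: str = "habitats",
    seed: int = 0,
    target_size: int = 4,
    mrmr_keep: int = 21,
    sfs_classifier_factory=None,
    n_estimators: int = 100,
) -> tuple[AdaBoostClassifier, PredictionResult, list[str]]:
    """One full modelling experiment on a cohort with a ``split`` column.

    mRMR runs only when the candidate pool exceeds ``mrmr_keep`` (the
    small core/margin/clinical pools go straight to SFS, as in the
    comparison experiments).  Returns the fitted model, the test-set
    result and the selected feature names.
    """
    pool = FEATURE_SETS[feature_set]
    if sfs_classifier_factory is None:
        # wrapper search uses a lighter ensemble; the final model keeps 100 trees
        sfs_classifier_factory = lambda: make_classifier(seed=seed, n_estimators=10)  # noqa: E731
    train = df[df["split"] == "train"]
    test = df[df["split"] == "test"]
    Xtr = train[pool].to_numpy(dtype=float)
    ytr = train["response"].to_numpy()
    if len(pool) > mrmr_keep:
        ranked = mrmr_rank(Xtr, ytr, pool, n_keep=mrmr_keep)
    else:
        ranked = list(pool)
    target = min(target_size, len(ranked))
    selected = sfs_select(Xtr, ytr, ranked, pool, target_size=target, seed=seed,
                          classifier_factory=sfs_classifier_factory)
    cols = [pool.index(s) for s in selected]
    model = train_classifier(Xtr[:, cols], ytr, seed=seed,
                             n_estimators=n_estimators)
    result = evaluate(model, test[pool].to_numpy(dtype=float)[:, cols],
                      test["response"].to_numpy(), selected_features=selected)
    return model, result, selected
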