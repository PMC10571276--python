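"""Super Learner stacking classifier for gut permanence.

The Super Learner is a stacking ensemble: each of 9 base classifiers
(logistic regression, decision tree, SVM, Gaussian naive Bayes, k-nearest
neighbors, AdaBoost, bagging, random forest, extra trees) is run in k-fold
cross-validation over the training data to produce an n × 9 matrix of
*out-of-fold* positive-class probabilities; a logistic-regression
meta-model is fitted on that matrix against the true labels; the base
models are then refit on the full training data. At prediction time the
refit base models score the new molecules and the meta-model combines
their probabilities. Because the meta-features are out-of-fold, the stack
does not overfit to any single base learner and asymptotically performs at
least as well as the best of them.

Features are the 10 physicochemical descriptors plus one-hot encodings of
the ionization class (4 levels) and the chemical class (17 named levels;
"Other" and unseen labels map to the all-zero block) — 31 predictors,
standardized with training-set statistics.

Two train/test split strategies are provided: stratified random folds that
preserve chemical-class proportions, and structure-disjoint splits from
Butina sphere-exclusion clustering of path fingerprints at a Tanimoto
similarity threshold (whole clusters go to one side only).

Evaluation reports accuracy, precision, recall, F1, AUROC and AUPRC
(average precision) for the whole test set and separately for its
fatty-lipid (FL) and non-FL subsets; "standardized" metrics average the FL
and noFL values to adjust for the dominance of the large homogeneous FL
stratum. AUROC is undefined (None) for a one-class subset.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
from rdkit.ML.Cluster import Butina
from rdkit.DataStructs import BulkTanimotoSimilarity
from sklearn.base import clone
from sklearn.ensemble import (
    AdaBoostClassifier,
    BaggingClassifier,
    ExtraTreesClassifier,
    RandomForestClassifier,
)
from sklearn.linear_model import LogisticRegression
from sklearn.metrics import (
    accuracy_score,
    average_precision_score,
    f1_score,
    precision_score,
    recall_score,
    roc_auc_score,
)
from sklearn.naive_bayes import GaussianNB
from sklearn.neighbors import KNeighborsClassifier
from sklearn.svm import SVC
from sklearn.tree import DecisionTreeClassifier

from .descriptors import DescriptorVector, compute_descriptors, path_fingerprint
from .ionization import DEFAULT_PH, IonClass, assign_ionization_class
from .records import CompoundRecord
from .set_assembly import CHEM_CLASSES, LINGERER

# SVC(probability=True) matches the probability-emitting SVM base learner;
# scikit-learn 1.9 deprecates the flag but it remains the documented route here
warnings.filterwarnings(
    "ignore", message="The `probability` parameter", category=FutureWarning
)

DEFAULT_CV_FOLDS = 7
DEFAULT_OUTER_FOLDS = 8
BUTINA_THRESHOLD = 0.8

ION_LEVELS = tuple(c.value for c in IonClass)
CHEM_LEVELS = tuple(c for c in CHEM_CLASSES if c != "Other")
FEATURE_NAMES = tuple(DescriptorVector.NAMES) + tuple(f"ion_{v}" for v in ION_LEVELS) + tuple(
    f"class_{v}" for v in CHEM_LEVELS
)
N_FEATURES = len(FEATURE_NAMES)  # 10 + 4 + 17 = 31


# ---------------------------------------------------------------------------
# Feature matrix
# ---------------------------------------------------------------------------


@dataclass
class Standardizer:
    """Per-column affine standardization fitted on training rows."""

    mean: np.ndarray
    scale: np.ndarray  # constant columns get scale 1

    @classmethod
    def fit(cls, x: np.ndarray) -> "Standardizer":
        mean = x.mean(axis=0)
        sd = x.std(axis=0, ddof=0)
        sd[sd == 0] = 1.0
        return cls(mean=mean, scale=sd)

    def transform(self, x: np.ndarray) -> np.ndarray:
        return (x - self.mean) / self.scale

    def inverse_transform(self, x: np.ndarray) -> np.ndarray:
        return x * self.scale + self.mean


def raw_feature_matrix(
    records: Sequence[CompoundRecord], ph: float = DEFAULT_PH
) -> np.ndarray:
    """Unstandardized n × 31 matrix: descriptors + ion-class and chem-class one-hots."""
    rows = np.zeros((len(records), N_FEATURES))
    for i, r in enumerate(records):
        d = compute_descriptors(r.smiles)
        rows[i, :10] = d.as_array()
        call = assign_ionization_class(r.pka_strongest_acidic, r.pka_strongest_basic, ph)
        rows[i, 10 + ION_LEVELS.index(call.ion_class.value)] = 1.0
        if r.chem_class in CHEM_LEVELS:
            rows[i, 14 + CHEM_LEVELS.index(r.chem_class)] = 1.0
    return rows


def build_feature_matrix(
    records: Sequence[CompoundRecord],
    standardizer: Optional[Standardizer] = None,
    ph: float = DEFAULT_PH,
) -> tuple[np.ndarray, Standardizer]:
    """Standardized feature matrix.

    Without a ``standardizer`` the statistics are fitted on these records
    (training use); with one, it is applied unchanged (test use).
    """
    raw = raw_feature_matrix(records, ph)
    if standardizer is None:
        standardizer = Standardizer.fit(raw)
    return standardizer.transform(raw), standardizer


def permanence_targets(records: Sequence[CompoundRecord]) -> np.ndarray:
    """Binary target vector: 1 = Lingerer (positive class), 0 = Traverser."""
    y = np.empty(len(records), dtype=int)
    for i, r in enumerate(records):
        if r.permanence_label is None:
            raise ValueError(f"record {r.id} has no permanence label")
        y[i] = int(r.permanence_label == LINGERER)
    return y


# ---------------------------------------------------------------------------
# Splits
# ---------------------------------------------------------------------------


def stratified_folds(
    records: Sequence[CompoundRecord], k: int = DEFAULT_OUTER_FOLDS, seed: int = 0
) -> np.ndarray:
    """Fold index per record, stratified by chemical class.

    Within each class, records are shuffled with ``seed`` and dealt
    round-robin starting from a class-dependent offset, so per-class fold
    sizes differ by at most one and overall fold sizes stay balanced.
    """
    if k < 2:
        raise ValueError("k must be >= 2")
    if k > len(records):
        raise ValueError(f"k={k} exceeds the number of records ({len(records)})")
    rng = np.random.default_rng(seed)
    folds = np.empty(len(records), dtype=int)
    by_class: dict[str, list[int]] = {}
    for i, r in enumerate(records):
        by_class.setdefault(r.chem_class, []).append(i)
    offset = 0
    for cls in sorted(by_class):
        idx = np.array(by_class[cls])
        rng.shuffle(idx)
        for pos, i in enumerate(idx):
            folds[i] = (offset + pos) % k
        offset += len(idx)
    return folds


def butina_clusters(fingerprints: Sequence, threshold: float = BUTINA_THRESHOLD) -> list[tuple]:
    """Butina sphere-exclusion clusters at a Tanimoto *similarity* threshold."""
    n = len(fingerprints)
    dists = []
    for i in range(1, n):
        sims = BulkTanimotoSimilarity(fingerprints[i], list(fingerprints[:i]))
        dists.extend(1.0 - s for s in sims)
    return list(Butina.ClusterData(dists, n, 1.0 - threshold, isDistData=True))


def butina_split(
    fingerprints: Sequence,
    threshold: float = BUTINA_THRESHOLD,
    test_fraction: float = 1.0 / DEFAULT_OUTER_FOLDS,
    seed: int = 0,
) -> tuple[np.ndarray, np.ndarray]:
    """Structure-disjoint train/test split from whole Butina clusters.

    Clusters are shuffled with ``seed`` and assigned to the test side until
    ``test_fraction`` of the molecules is reached; no cluster spans both
    sides. Raises if a single cluster is too large to leave a usable split.
    """
    if not 0.0 < threshold < 1.0:
        raise ValueError("threshold must be in (0, 1)")
    n = len(fingerprints)
    clusters = butina_clusters(fingerprints, threshold)
    if max(len(c) for c in clusters) > n * (1.0 - test_fraction):
        raise ValueError(
            "a single cluster dominates the data; lower the similarity threshold"
        )
    rng = np.random.default_rng(seed)
    order = rng.permutation(len(clusters))
    target = test_fraction * n
    test: list[int] = []
    for ci in order:
        if len(test) >= target:
            break
        test.extend(clusters[ci])
    test_idx = np.array(sorted(test), dtype=int)
    train_idx = np.array(sorted(set(range(n)) - set(test)), dtype=int)
    return train_idx, test_idx


# ---------------------------------------------------------------------------
# The stack
# ---------------------------------------------------------------------------


def default_base_learners(seed: int = 0) -> list[tuple[str, object]]:
    """The 9 base classifiers with library-default hyperparameters."""
    return [
        ("logistic_regression", LogisticRegression(max_iter=1000, random_state=seed)),
        ("decision_tree", DecisionTreeClassifier(random_state=seed)),
        ("svm", SVC(probability=True, random_state=seed)),
        ("gaussian_nb", GaussianNB()),
        ("knn", KNeighborsClassifier()),
        ("adaboost", AdaBoostClassifier(random_state=seed)),
        ("bagging", BaggingClassifier(random_state=seed)),
        ("random_forest", RandomForestClassifier(random_state=seed)),
        ("extra_trees", ExtraTreesClassifier(random_state=seed)),
    ]


@dataclass
class StackedModel:
    base_names: list[str]
    fitted_base: list[object]
    meta_model: LogisticRegression
    meta_features: np.ndarray  # n x 9 out-of-fold probabilities
    cv_folds: int
    seed: int
    standardizer: Optional[Standardizer] = None
    base_auroc: dict = field(default_factory=dict)  # out-of-fold AUROC per base learner


def _cv_fold_indices(y: np.ndarray, k: int, seed: int) -> np.ndarray:
    """Label-stratified fold assignment for the inner CV, deterministic."""
    rng = np.random.default_rng(seed)
    folds = np.empty(len(y), dtype=int)
    for label in np.unique(y):
        idx = np.flatnonzero(y == label)
        rng.shuffle(idx)
        folds[idx] = np.arange(len(idx)) % k
    return folds


def fit_superlearner(
    x: np.ndarray,
    y: np.ndarray,
    cv_folds: int = DEFAULT_CV_FOLDS,
    seed: int = 0,
    standardizer: Optional[Standardizer] = None,
) -> StackedModel:
    """Fit the stack on (already standardized) training data.

    Steps: (1) every base learner is trained/evaluated over the same
    ``cv_folds`` label-stratified folds, yielding out-of-fold positive-class
    probabilities (the n × 9 meta matrix); (2) the logistic meta-model is
    fitted on that matrix (near-unpenalized, inputs kept as probabilities);
    (3) the base learners are refit on the full training data.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=int)
    if len(np.unique(y)) < 2:
        raise ValueError("training data must contain both classes")
    if len(y) < cv_folds:
        raise ValueError("fewer instances than CV folds")
    specs = default_base_learners(seed)
    folds = _cv_fold_indices(y, cv_folds, seed)
    meta = np.zeros((len(y), len(specs)))
    for m, (name, proto) in enumerate(specs):
        for f in range(cv_folds):
            train = folds != f
            hold = ~train
            model = clone(proto)
            try:
                model.fit(x[train], y[train])
            except Exception as exc:
                raise RuntimeError(f"base learner {name!r} failed on fold {f}: {exc}") from exc
            meta[hold, m] = model.predict_proba(x[hold])[:, 1]
    meta_model = LogisticRegression(C=1e6, max_iter=5000)
    meta_model.fit(meta, y)
    fitted = []
    for name, proto in specs:
        model = clone(proto)
        model.fit(x, y)
        fitted.append(model)
    base_auroc = {
        name: float(roc_auc_score(y, meta[:, m])) for m, (name, _) in enumerate(specs)
    }
    return StackedModel(
        base_names=[n for n, _ in specs],
        fitted_base=fitted,
        meta_model=meta_model,
        meta_features=meta,
        cv_folds=cv_folds,
        seed=seed,
        standardizer=standardizer,
        base_auroc=base_auroc,
    )


def predict_proba(model: StackedModel, x_new: np.ndarray) -> np.ndarray:
    """Positive-class probability per instance (class = probability >= 0.5)."""
    x_new = np.asarray(x_new, dtype=float)
    if x_new.ndim != 2 or x_new.shape[1] != N_FEATURES:
        raise ValueError(f"expected {N_FEATURES} feature columns, got {x_new.shape}")
    base = np.column_stack([m.predict_proba(x_new)[:, 1] for m in model.fitted_base])
    return model.meta_model.predict_proba(base)[:, 1]


def base_predict_proba(model: StackedModel, x_new: np.ndarray) -> np.ndarray:
    """Positive-class probabilities of the refit base learners (n × 9)."""
    return np.column_stack([m.predict_proba(x_new)[:, 1] for m in model.fitted_base])


MODEL_FORMAT_VERSION = 1


def save_model(model: StackedModel, path) -> None:
    """Persist a fitted stack (standardization parameters, base learners,
    meta coefficients) as a versioned joblib archive."""
    import joblib

    payload = {
        "format_version": MODEL_FORMAT_VERSION,
        "base_names": model.base_names,
        "fitted_base": model.fitted_base,
        "meta_model": model.meta_model,
        "meta_features": model.meta_features,
        "cv_folds": model.cv_folds,
        "seed": model.seed,
        "standardizer_mean": None if model.standardizer is None else model.standardizer.mean,
        "standardizer_scale": None if model.standardizer is None else model.standardizer.scale,
        "base_auroc": model.base_auroc,
    }
    joblib.dump(payload, path)


def load_model(path) -> StackedModel:
    import joblib

    payload = joblib.load(path)
    if payload.get("format_version") != MODEL_FORMAT_VERSION:
        raise ValueError(f"unsupported model archive version: {payload.get('format_version')}")
    std = None
    if payload["standardizer_mean"] is not None:
        std = Standardizer(mean=payload["standardizer_mean"], scale=payload["standardizer_scale"])
    return StackedModel(
        base_names=payload["base_names"],
        fitted_base=payload["fitted_base"],
        meta_model=payload["meta_model"],
        meta_features=payload["meta_features"],
        cv_folds=payload["cv_folds"],
        seed=payload["seed"],
        standardizer=std,
        base_auroc=payload["base_auroc"],
    )


# ---------------------------------------------------------------------------
# Evaluation
# ---------------------------------------------------------------------------

METRIC_NAMES = ("accuracy", "precision", "recall", "f1", "auroc", "auprc")


@dataclass
class EvaluationReport:
    """Metrics for the full test set and its FL / noFL subsets.

    Each scope maps metric name to value; ``auroc``/``auprc`` are ``None``
    when undefined (one-class subset, or hard-label predictors). The
    ``standardized`` scope is the metric-wise mean of the FL and noFL
    scopes, adjusting for subset imbalance.
    """

    scopes: dict[str, dict[str, Optional[float]]]

    def __getitem__(self, scope: str) -> dict[str, Optional[float]]:
        return self.scopes[scope]


def _scope_metrics(
    y: np.ndarray, proba: np.ndarray, scores_are_probabilities: bool
) -> dict[str, Optional[float]]:
    pred = (proba >= 0.5).astype(int)
    out: dict[str, Optional[float]] = {
        "accuracy": float(accuracy_score(y, pred)),
        "precision": float(precision_score(y, pred, zero_division=0)),
        "recall": float(recall_score(y, pred, zero_division=0)),
        "f1": float(f1_score(y, pred, zero_division=0)),
    }
    if scores_are_probabilities and len(np.unique(y)) == 2:
        out["auroc"] = float(roc_auc_score(y, proba))
    else:
        out["auroc"] = None
    if scores_are_probabilities and y.sum() > 0:
        out["auprc"] = float(average_precision_score(y, proba))
    else:
        out["auprc"] = None
    return out


def standardized_metrics(
    fl: dict[str, Optional[float]], nofl: dict[str, Optional[float]]
) -> dict[str, Optional[float]]:
    """Metric-wise mean of the FL and noFL scopes; None if either side lacks it."""
    out: dict[str, Optional[float]] = {}
    for name in METRIC_NAMES:
        a, b = fl.get(name), nofl.get(name)
        out[name] = None if a is None or b is None else (a + b) / 2.0
    return out


def evaluate(
    y_true: np.ndarray,
    proba: np.ndarray,
    fl_mask: Optional[np.ndarray] = None,
    scores_are_probabilities: bool = True,
) -> EvaluationReport:
    """Evaluate predictions at threshold 0.5 over all / FL / noFL / standardized scopes."""
    y_true = np.asarray(y_true, dtype=int)
    proba = np.asarray(proba, dtype=float)
    if y_true.shape != proba.shape:
        raise ValueError("y_true and proba lengths differ")
    scopes = {"all": _scope_metrics(y_true, proba, scores_are_probabilities)}
    if fl_mask is not None:
        fl_mask = np.asarray(fl_mask, dtype=bool)
        if fl_mask.shape != y_true.shape:
            raise ValueError("fl_mask length differs")
        if fl_mask.any():
            scopes["FL"] = _scope_metrics(y_true[fl_mask], proba[fl_mask], scores_are_probabilities)
        if (~fl_mask).any():
            scopes["noFL"] = _scope_metrics(
                y_true[~fl_mask], proba[~fl_mask], scores_are_probabilities
            )
        if "FL" in scopes and "noFL" in scopes:
            scopes["standardized"] = standardized_metrics(scopes["FL"], scopes["noFL"])
    return EvaluationReport(scopes=scopes)
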