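"""Repeated shared-fold cross-validation benchmarking of classifiers.

The protocol: a stratified 80/20 holdout, then R repeats (default 100) of
stratified K-fold (default 10) cross-validation on the training portion.
The fold plan is built once and reused by every descriptor x model
combination, so the comparison across feature sets and classifiers is
free of fold-sampling bias.  Per repeat, validation-fold predictions are
pooled into one confusion matrix; reported metrics are means over
repeats.  All randomness flows from one master seed through a fixed
counter scheme.
"""
from __future__ import annotations

import hashlib
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.stats import rankdata
from sklearn.ensemble import AdaBoostClassifier, RandomForestClassifier
from sklearn.linear_model import LogisticRegression
from sklearn.model_selection import StratifiedKFold
from sklearn.naive_bayes import GaussianNB
from sklearn.neighbors import KNeighborsClassifier
from sklearn.neural_network import MLPClassifier
from sklearn.pipeline import Pipeline
from sklearn.preprocessing import StandardScaler
from sklearn.svm import SVC
from sklearn.tree import DecisionTreeClassifier

from .seqio import MP, LabeledDataset

POSITIVE = MP  # moonlighting proteins are the positive class throughout

#: model families fitted with feature standardization by default
_SCALED_FAMILIES = frozenset({"SVM", "MLP", "KNN", "LR"})
#: families whose fit involves their own randomness
STOCHASTIC_FAMILIES = frozenset({"RF", "MLP", "ADA"})

# seed offsets of the master-seed counter scheme
_SEED_SPLIT, _SEED_FOLDS, _SEED_MODEL = 1, 2, 3


def derive_seed(master: int, offset: int, index: int = 0) -> int:
    """Derive a stream-specific 31-bit seed from the master seed."""
    digest = hashlib.sha256(f"{master}:{offset}:{index}".encode()).digest()
    return int.from_bytes(digest[:4], "big") % (2 ** 31)


@dataclass(frozen=True)
class ClassifierConfig:
    """One of the eight benchmark classifier families plus hyperparameters.

    Defaults follow the benchmarked settings: KNN with k=5 and Euclidean
    distance; RBF-kernel SVM with C=1; Gini decision tree with max depth
    3 and a minimum of 5 samples per split; AdaBoost with 200 weak
    learners; random forest with 50 trees; an MLP with hidden layers
    (20, 3), SGD solver and at most 150 iterations; Gaussian naive
    Bayes; regularized logistic regression.
    """

    family: str
    params: dict = field(default_factory=dict)
    scale: bool | None = None  # None -> family default

    def __post_init__(self) -> None:
        if self.family not in _BUILDERS:
            raise ValueError(f"unknown family {self.family!r}; "
                             f"valid: {sorted(_BUILDERS)}")

    @property
    def scaled(self) -> bool:
        return self.family in _SCALED_FAMILIES if self.scale is None else self.scale

    def build(self, seed: int | None = None):
        est = _BUILDERS[self.family](self.params, seed)
        if self.scaled:
            est = Pipeline([("scale", StandardScaler()), ("model", est)])
        return est

    def to_dict(self) -> dict:
        return {"family": self.family, "params": dict(self.params),
                "scale": self.scale}

    @classmethod
    def from_dict(cls, d: dict) -> "ClassifierConfig":
        return cls(d["family"], dict(d.get("params", {})), d.get("scale"))


def _build_svm(p, seed):
    return SVC(kernel="rbf", C=1.0, random_state=seed, **p)


def _build_knn(p, seed):
    return KNeighborsClassifier(n_neighbors=5, metric="euclidean", **p)


def _build_nb(p, seed):
    return GaussianNB(**p)


def _build_dt(p, seed):
    return DecisionTreeClassifier(criterion="gini", max_depth=3,
                                  min_samples_split=5, random_state=seed, **p)


def _build_rf(p, seed):
    return RandomForestClassifier(n_estimators=50, random_state=seed, **p)


def _build_mlp(p, seed):
    return MLPClassifier(hidden_layer_sizes=(20, 3), max_iter=150,
                         solver="sgd", random_state=seed, **p)


def _build_ada(p, seed):
    return AdaBoostClassifier(n_estimators=200, random_state=seed, **p)


def _build_lr(p, seed):
    return LogisticRegression(max_iter=1000, random_state=seed, **p)


_BUILDERS = {"SVM": _build_svm, "KNN": _build_knn, "NB": _build_nb,
             "DT": _build_dt, "RF": _build_rf, "MLP": _build_mlp,
             "ADA": _build_ada, "LR": _build_lr}

CLASSIFIER_FAMILIES = tuple(sorted(_BUILDERS))


# --------------------------------------------------------------------------
# splits and fold plans
# --------------------------------------------------------------------------

@dataclass(frozen=True)
class SplitPlan:
    """A stratified train/test holdout of protein ids."""

    train_ids: tuple[str, ...]
    test_ids: tuple[str, ...]
    seed: int

    def __post_init__(self) -> None:
        if set(self.train_ids) & set(self.test_ids):
            raise ValueError("train and test ids overlap")


def _round_half_up(x: float) -> int:
    return int(np.floor(x + 0.5))


def make_split(dataset: LabeledDataset, test_fraction: float = 0.2,
               seed: int = 0) -> SplitPlan:
    """Stratified random holdout reserving ``test_fraction`` of each class.

    The total test size is round(test_fraction * n) (half away from
    zero), apportioned over classes by largest remainder so both classes
    appear on both sides.
    """
    if not 0 < test_fraction < 1:
        raise ValueError("test_fraction must be in (0, 1)")
    dataset.require_trainable()
    n_test = _round_half_up(test_fraction * len(dataset))
    by_class: dict[str, list[str]] = {}
    for rec in dataset:
        by_class.setdefault(rec.label, []).append(rec.id)
    # largest-remainder apportionment of n_test over classes
    quotas = {lab: n_test * len(ids) / len(dataset)
              for lab, ids in by_class.items()}
    take = {lab: int(np.floor(q)) for lab, q in quotas.items()}
    remainder = sorted(quotas, key=lambda lab: quotas[lab] - take[lab],
                       reverse=True)
    for lab in remainder[: n_test - sum(take.values())]:
        take[lab] += 1
    rng = np.random.default_rng(derive_seed(seed, _SEED_SPLIT))
    test: list[str] = []
    for lab, ids in sorted(by_class.items()):
        if not 0 < take[lab] < len(ids):
            raise ValueError(f"class {lab}: degenerate test allocation")
        test.extend(rng.choice(ids, size=take[lab], replace=False))
    test_set = set(test)
    train = tuple(i for i in dataset.ids if i not in test_set)
    return SplitPlan(train, tuple(sorted(test, key=dataset.ids.index)), seed)


@dataclass(frozen=True)
class FoldPlan:
    """R repeats of a stratified K-fold partition of the same id set.

    ``assignment[r][pid]`` is the validation fold (0..K-1) of protein
    ``pid`` in repeat ``r``; within each repeat every id appears in
    exactly one validation fold.  The checksum identifies the plan so
    reports can prove that all benchmark cells shared folds.
    """

    ids: tuple[str, ...]
    repeats: int
    folds: int
    assignment: tuple[dict[str, int], ...]
    seed: int

    def validation_ids(self, repeat: int, fold: int) -> list[str]:
        a = self.assignment[repeat]
        return [i for i in self.ids if a[i] == fold]

    @property
    def checksum(self) -> str:
        payload = repr((self.ids, self.repeats, self.folds,
                        tuple(tuple(sorted(a.items()))
                              for a in self.assignment)))
        return hashlib.sha256(payload.encode()).hexdigest()[:16]

    def to_frame(self) -> pd.DataFrame:
        rows = [(pid, r, a[pid]) for r, a in enumerate(self.assignment)
                for pid in self.ids]
        return pd.DataFrame(rows, columns=["id", "repeat", "fold"]).set_index("id")


def make_fold_plan(ids, labels: dict[str, str], repeats: int = 100,
                   folds: int = 10, seed: int = 0) -> FoldPlan:
    """Build R independent stratified K-fold partitions of ``ids``."""
    ids = tuple(ids)
    if len(ids) < folds:
        raise ValueError(f"{len(ids)} ids cannot fill {folds} folds")
    y = np.array([labels[i] for i in ids])
    assignment = []
    for r in range(repeats):
        skf = StratifiedKFold(n_splits=folds, shuffle=True,
                              random_state=derive_seed(seed, _SEED_FOLDS, r))
        a: dict[str, int] = {}
        for fold, (_, val) in enumerate(skf.split(np.zeros(len(ids)), y)):
            for j in val:
                a[ids[j]] = fold
        assignment.append(a)
    return FoldPlan(ids, repeats, folds, tuple(assignment), seed)


# --------------------------------------------------------------------------
# metrics
# --------------------------------------------------------------------------

@dataclass(frozen=True)
class ConfusionCounts:
    tp: int
    fp: int
    tn: int
    fn: int

    def __post_init__(self) -> None:
        if min(self.tp, self.fp, self.tn, self.fn) < 0:
            raise ValueError("negative confusion counts")
        if self.total == 0:
            raise ValueError("empty confusion table")

    @property
    def total(self) -> int:
        return self.tp + self.fp + self.tn + self.fn


@dataclass(frozen=True)
class MetricSet:
    acc: float
    precision: float
    recall: float
    f_measure: float
    mcc: float
    auc: float | None = None

    def as_dict(self) -> dict:
        d = {"acc": self.acc, "precision": self.precision,
             "recall": self.recall, "f_measure": self.f_measure,
             "mcc": self.mcc}
        if self.auc is not None:
            d["auc"] = self.auc
        return d


def auc_score(scores, labels) -> float:
    """Rank-based (Mann-Whitney) AUC of positive-class scores; ties count 1/2."""
    scores = np.asarray(scores, dtype=float)
    pos = np.asarray(labels) == POSITIVE
    n_pos, n_neg = pos.sum(), (~pos).sum()
    if n_pos == 0 or n_neg == 0:
        raise ValueError("AUC needs both classes present")
    ranks = rankdata(scores)
    return float((ranks[pos].sum() - n_pos * (n_pos + 1) / 2) / (n_pos * n_neg))


def compute_metrics(cc: ConfusionCounts,
                    scores: tuple | None = None) -> MetricSet:
    """Accuracy, precision, recall, F-measure, MCC and (optionally) AUC.

    acc = (TP+TN)/(TP+FP+TN+FN); precision = TP/(TP+FP);
    recall = TP/(TP+FN); F = 2 pr·rc/(pr+rc);
    MCC = (TP·TN − FP·FN)/sqrt((TP+FP)(TP+FN)(TN+FP)(TN+FN)).
    Zero denominators yield 0 for precision, recall, F and MCC.  When
    ``scores`` (score, label) arrays are given, AUC is the rank statistic
    of :func:`auc_score`.
    """
    tp, fp, tn, fn = cc.tp, cc.fp, cc.tn, cc.fn
    acc = (tp + tn) / cc.total
    precision = tp / (tp + fp) if tp + fp else 0.0
    recall = tp / (tp + fn) if tp + fn else 0.0
    f = (2 * precision * recall / (precision + recall)
         if precision + recall else 0.0)
    denom = (tp + fp) * (tp + fn) * (tn + fp) * (tn + fn)
    mcc = (tp * tn - fp * fn) / np.sqrt(denom) if denom else 0.0
    auc = auc_score(*scores) if scores is not None else None
    return MetricSet(acc, precision, recall, f, float(mcc), auc)


def _confusion(y_true: np.ndarray, y_pred: np.ndarray) -> ConfusionCounts:
    pos_t, pos_p = y_true == POSITIVE, y_pred == POSITIVE
    return ConfusionCounts(tp=int(np.sum(pos_t & pos_p)),
                           fp=int(np.sum(~pos_t & pos_p)),
                           tn=int(np.sum(~pos_t & ~pos_p)),
                           fn=int(np.sum(pos_t & ~pos_p)))


def _positive_scores(est, X: np.ndarray) -> np.ndarray:
    """Monotone positive-class score: probability if available, else margin."""
    model = est[-1] if isinstance(est, Pipeline) else est
    if hasattr(model, "predict_proba"):
        proba = est.predict_proba(X)
        return proba[:, list(est.classes_).index(POSITIVE)]
    margin = est.decision_function(X)
    return margin if est.classes_[1] == POSITIVE else -margin


# --------------------------------------------------------------------------
# CV engine
# --------------------------------------------------------------------------

def run_cv(features: pd.DataFrame, labels: dict[str, str],
           config: ClassifierConfig, plan: FoldPlan,
           seed: int = 0) -> tuple[pd.DataFrame, MetricSet]:
    """Run the full repeated-CV protocol for one descriptor x model cell.

    Per repeat and fold, the model is fitted on the other K-1 folds
    (standardization, when enabled, is fitted on those folds only via a
    Pipeline) and predicts the validation fold.  Returns the prediction
    log — one row per (protein, repeat) — and the mean over repeats of
    the per-repeat pooled metrics.
    """
    missing = set(plan.ids) - set(features.index)
    if missing:
        raise KeyError(f"plan ids missing from features: {sorted(missing)[:5]}")
    X = features.loc[list(plan.ids)].to_numpy()
    y = np.array([labels[i] for i in plan.ids])
    id_arr = np.array(plan.ids)
    pos_index = {pid: j for j, pid in enumerate(plan.ids)}

    rows = []
    per_repeat: list[MetricSet] = []
    for r in range(plan.repeats):
        fold_of = np.array([plan.assignment[r][i] for i in plan.ids])
        y_pred = np.empty_like(y)
        score = np.empty(len(y))
        for fold in range(plan.folds):
            val = fold_of == fold
            est = config.build(derive_seed(seed, _SEED_MODEL, r * plan.folds + fold))
            try:
                est.fit(X[~val], y[~val])
            except Exception as exc:  # surface with CV context
                raise RuntimeError(
                    f"{config.family} failed at repeat {r} fold {fold}: {exc}"
                ) from exc
            y_pred[val] = est.predict(X[val])
            score[val] = _positive_scores(est, X[val])
        per_repeat.append(compute_metrics(_confusion(y, y_pred), (score, y)))
        for j in range(len(y)):
            rows.append((id_arr[j], r, int(fold_of[j]), y[j], y_pred[j],
                         float(score[j]), y[j] == y_pred[j]))

    log = pd.DataFrame(rows, columns=["id", "repeat", "fold", "true",
                                      "predicted", "score", "correct"])
    mean = MetricSet(*(float(np.mean([getattr(m, f) for m in per_repeat]))
                       for f in ("acc", "precision", "recall", "f_measure",
                                 "mcc", "auc")))
    return log, mean


def holdout_eval(features: pd.DataFrame, labels: dict[str, str],
                 config: ClassifierConfig, split: SplitPlan,
                 seed: int = 0) -> MetricSet:
    """Fit on the training ids, evaluate once on the reserved test ids."""
    Xtr = features.loc[list(split.train_ids)].to_numpy()
    Xte = features.loc[list(split.test_ids)].to_numpy()
    ytr = np.array([labels[i] for i in split.train_ids])
    yte = np.array([labels[i] for i in split.test_ids])
    est = config.build(derive_seed(seed, _SEED_MODEL, 10 ** 6))
    est.fit(Xtr, ytr)
    return compute_metrics(_confusion(yte, est.predict(Xte)),
                           (_positive_scores(est, Xte), yte))


def benchmark(dataset: LabeledDataset, descriptor_specs, configs,
              split: SplitPlan, plan: FoldPlan, seed: int = 0,
              keep_logs: bool = False):
    """Evaluate every descriptor x model combination on shared folds.

    Returns a report DataFrame with one row per cell (CV and holdout
    metrics, plus the fold-plan checksum) and, when ``keep_logs`` is
    set, a dict of per-cell prediction logs.
    """
    from .descriptors import extract, get_spec

    labels = dataset.labels
    rows, logs = [], {}
    for spec in descriptor_specs:
        if isinstance(spec, str):
            spec = get_spec(spec)
        feats = extract(spec, dataset)
        for config in configs:
            if isinstance(config, str):
                config = ClassifierConfig(config)
            log, cv = run_cv(feats, labels, config, plan, seed=seed)
            ho = holdout_eval(feats, labels, config, split, seed=seed)
            row = {"descriptor": spec.name, "model": config.family,
                   "fold_checksum": plan.checksum}
            row.update({f"cv_{k}": v for k, v in cv.as_dict().items()})
            row.update({f"test_{k}": v for k, v in ho.as_dict().items()})
            rows.append(row)
            if keep_logs:
                logs[(spec.name, config.family)] = log
    report = pd.DataFrame(rows)
    return (report, logs) if keep_logs else report
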