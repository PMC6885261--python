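"""Stratified cross-validation and the classification metric suite.

Headline metrics are computed from the *pooled* out-of-fold confusion
matrix (every instance predicted exactly once while held out); per-fold
accuracies are also reported.  Conventions:

* accuracy is a percentage (100 · trace / N);
* precision/recall/F are per class (one-vs-rest) plus a
  prevalence-weighted average; 0/0 cases are defined as 0 with a warning;
* AUC is the rank-sum (Mann–Whitney) statistic per class one-vs-rest with
  half-credit for ties, averaged with prevalence weights;
* Cohen's kappa K = (P₀ − P_e)/(1 − P_e) with P₀ the observed agreement
  and P_e the chance agreement from the marginals.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field

import numpy as np
from scipy.stats import rankdata

from ._util import derive_seed, rng_from
from .errors import EvaluationError, StratificationError
from .learners import Dataset, Model
from .wpd import FeatureTable

logger = logging.getLogger(__name__)


@dataclass
class ConfusionMatrix:
    """K×K counts; rows are true classes, columns predicted."""

    counts: np.ndarray
    class_names: tuple[str, ...]

    def __post_init__(self) -> None:
        self.counts = np.asarray(self.counts, dtype=int)
        K = len(self.class_names)
        if self.counts.shape != (K, K):
            raise EvaluationError("confusion matrix shape inconsistent with classes")
        if np.any(self.counts < 0):
            raise EvaluationError("confusion matrix entries must be >= 0")

    @property
    def total(self) -> int:
        return int(self.counts.sum())

    def one_vs_rest(self, k: int) -> tuple[int, int, int, int]:
        """(TP, FP, FN, TN) for class k."""
        tp = int(self.counts[k, k])
        fp = int(self.counts[:, k].sum() - tp)
        fn = int(self.counts[k, :].sum() - tp)
        tn = self.total - tp - fp - fn
        return tp, fp, fn, tn


def confusion(true_labels, predicted_labels, class_names: tuple[str, ...]) -> ConfusionMatrix:
    """Count (true, predicted) pairs; labels may be names or class indices."""
    index = {c: i for i, c in enumerate(class_names)}

    def encode(values):
        out = np.empty(len(values), dtype=int)
        for i, v in enumerate(values):
            if isinstance(v, (int, np.integer)):
                iv = int(v)
                if not 0 <= iv < len(class_names):
                    raise EvaluationError(f"class index {iv} out of range")
                out[i] = iv
            elif v in index:
                out[i] = index[v]
            else:
                raise EvaluationError(f"unknown label {v!r}")
        return out

    t, p = encode(list(true_labels)), encode(list(predicted_labels))
    if len(t) != len(p):
        raise EvaluationError("true and predicted label sequences differ in length")
    K = len(class_names)
    counts = np.zeros((K, K), dtype=int)
    np.add.at(counts, (t, p), 1)
    return ConfusionMatrix(counts, tuple(class_names))


def precision_recall_f(cm: ConfusionMatrix, k: int) -> tuple[float, float, float]:
    """One-vs-rest precision, recall and F for class k (0/0 → 0)."""
    tp, fp, fn, _ = cm.one_vs_rest(k)

    def safe(num, den, what):
        if den == 0:
            logger.warning("%s for class %s is 0/0; defined as 0", what, cm.class_names[k])
            return 0.0
        return num / den

    precision = safe(tp, tp + fp, "precision")
    recall = safe(tp, tp + fn, "recall")
    f = 0.0 if precision + recall == 0 else 2 * precision * recall / (precision + recall)
    return precision, recall, f


def accuracy(cm: ConfusionMatrix) -> float:
    """Total classification accuracy in percent."""
    if cm.total == 0:
        raise EvaluationError("empty confusion matrix")
    return 100.0 * float(np.trace(cm.counts)) / cm.total


def kappa(cm: ConfusionMatrix) -> float:
    """Cohen's chance-corrected agreement."""
    if cm.total == 0:
        raise EvaluationError("empty confusion matrix")
    n = cm.total
    p0 = float(np.trace(cm.counts)) / n
    pe = float((cm.counts.sum(axis=1) * cm.counts.sum(axis=0)).sum()) / n**2
    if pe >= 1.0:
        logger.warning("constant truth and prediction (P_e = 1); kappa defined as 0")
        return 0.0
    return (p0 - pe) / (1.0 - pe)


def kappa_components(cm: ConfusionMatrix) -> tuple[float, float]:
    """(P₀, P_e) — observed and chance agreement."""
    n = cm.total
    p0 = float(np.trace(cm.counts)) / n
    pe = float((cm.counts.sum(axis=1) * cm.counts.sum(axis=0)).sum()) / n**2
    return p0, pe


def auc_ovr(score_matrix: np.ndarray, true_labels, class_names: tuple[str, ...]) -> float:
    """Prevalence-weighted one-vs-rest AUC via the rank-sum statistic.

    Classes lacking positives or negatives are skipped with a warning;
    score ties receive half credit.
    """
    scores = np.atleast_2d(np.asarray(score_matrix, dtype=float))
    index = {c: i for i, c in enumerate(class_names)}
    try:
        y = np.array(
            [int(v) if isinstance(v, (int, np.integer)) else index[v] for v in true_labels],
            dtype=int,
        )
    except KeyError as exc:
        raise EvaluationError(f"unknown label {exc.args[0]!r}") from exc
    if len(np.unique(y)) < 2:
        raise EvaluationError("AUC undefined for single-class truth")
    aucs, weights = [], []
    for k in range(len(class_names)):
        pos = y == k
        n_pos, n_neg = int(pos.sum()), int((~pos).sum())
        if n_pos == 0 or n_neg == 0:
            logger.warning("class %s has no positives or no negatives; skipped in AUC",
                           class_names[k])
            continue
        ranks = rankdata(scores[:, k])  # average ranks → half credit for ties
        auc_k = (ranks[pos].sum() - n_pos * (n_pos + 1) / 2) / (n_pos * n_neg)
        aucs.append(auc_k)
        weights.append(n_pos)
    if not aucs:
        raise EvaluationError("no class had both positives and negatives")
    return float(np.average(aucs, weights=weights))


@dataclass
class MetricsReport:
    """Full metric suite for one experiment."""

    confusion_matrix: ConfusionMatrix
    accuracy_pct: float
    per_class: dict[str, dict[str, float]]
    weighted_precision: float
    weighted_recall: float
    weighted_f: float
    auc: float
    kappa: float
    p0: float
    pe: float
    fold_accuracies: list[float] = field(default_factory=list)

    @classmethod
    def from_predictions(cls, true_labels, predicted_labels, score_matrix,
                         class_names, fold_accuracies=None) -> "MetricsReport":
        cm = confusion(true_labels, predicted_labels, class_names)
        prevalence = cm.counts.sum(axis=1)
        per_class = {}
        precisions, recalls, fs = [], [], []
        for k, name in enumerate(class_names):
            p, r, f = precision_recall_f(cm, k)
            per_class[name] = {"precision": p, "recall": r, "f": f}
            precisions.append(p)
            recalls.append(r)
            fs.append(f)
        w = prevalence / prevalence.sum()
        p0, pe = kappa_components(cm)
        return cls(
            confusion_matrix=cm,
            accuracy_pct=accuracy(cm),
            per_class=per_class,
            weighted_precision=float(np.dot(w, precisions)),
            weighted_recall=float(np.dot(w, recalls)),
            weighted_f=float(np.dot(w, fs)),
            auc=auc_ovr(score_matrix, true_labels, class_names),
            kappa=kappa(cm),
            p0=p0,
            pe=pe,
            fold_accuracies=list(fold_accuracies or []),
        )

    def to_dict(self) -> dict:
        return {
            "class_names": list(self.confusion_matrix.class_names),
            "confusion_matrix": self.confusion_matrix.counts.tolist(),
            "accuracy_pct": self.accuracy_pct,
            "per_class": self.per_class,
            "weighted_precision": self.weighted_precision,
            "weighted_recall": self.weighted_recall,
            "weighted_f": self.weighted_f,
            "auc": self.auc,
            "kappa": self.kappa,
            "p0": self.p0,
            "pe": self.pe,
            "fold_accuracies": self.fold_accuracies,
        }

    def to_json(self) -> str:
        return json.dumps(self.to_dict(), indent=2)

    def to_text(self) -> str:
        cm = self.confusion_matrix
        lines = [
            f"accuracy: {self.accuracy_pct:.2f}%",
            f"kappa: {self.kappa:.4f}  (P0={self.p0:.4f}, Pe={self.pe:.4f})",
            f"AUC (weighted one-vs-rest): {self.auc:.4f}",
            f"weighted precision/recall/F: {self.weighted_precision:.4f} / "
            f"{self.weighted_recall:.4f} / {self.weighted_f:.4f}",
            "per-class:",
        ]
        for name, m in self.per_class.items():
            lines.append(
                f"  {name}: precision={m['precision']:.4f} recall={m['recall']:.4f} "
                f"F={m['f']:.4f}"
            )
        lines.append("confusion matrix (rows = true):")
        header = "        " + " ".join(f"{c:>11s}" for c in cm.class_names)
        lines.append(header)
        for k, name in enumerate(cm.class_names):
            lines.append(f"  {name:>6s}" + " ".join(f"{v:11d}" for v in cm.counts[k]))
        if self.fold_accuracies:
            folds = " ".join(f"{a:.2f}" for a in self.fold_accuracies)
            lines.append(f"per-fold accuracy (%): {folds}")
        return "\n".join(lines) + "\n"


@dataclass(frozen=True)
class CvConfig:
    k_folds: int = 10
    seed: int = 0
    grouping: str = "frame"  # or "recording"

    def __post_init__(self) -> None:
        if self.k_folds < 2:
            raise EvaluationError("k_folds must be >= 2")
        if self.grouping not in ("frame", "recording"):
            raise EvaluationError("grouping must be 'frame' or 'recording'")


def stratified_fold_indices(labels, k: int, seed: int = 0) -> list[np.ndarray]:
    """k disjoint index sets with per-class counts proportional within ±1."""
    labels = np.asarray(labels, dtype=object)
    n = len(labels)
    if not 2 <= k <= n:
        raise StratificationError(f"need 2 <= k <= n, got k={k}, n={n}")
    if k == n:  # leave-one-out: stratification is vacuous, singleton folds
        return [np.array([i]) for i in range(n)]
    rng = rng_from(seed, "folds")
    folds: list[list[int]] = [[] for _ in range(k)]
    for cls in dict.fromkeys(labels):  # deterministic class order
        idx = np.flatnonzero(labels == cls)
        if len(idx) < k:
            raise StratificationError(
                f"class {cls!r} has {len(idx)} instance(s), fewer than k={k}"
            )
        idx = rng.permutation(idx)
        for f in range(k):
            folds[f].extend(idx[f::k])
    return [np.sort(np.array(f, dtype=int)) for f in folds]


def cross_validate(
    train_fn,
    table: FeatureTable,
    cv: CvConfig | None = None,
) -> MetricsReport:
    """k-fold stratified CV of ``train_fn(dataset, seed) -> Model``.

    Each fold is held out once; predictions are pooled into a single
    confusion matrix.  With ``grouping='recording'`` whole recordings are
    assigned to folds (no frame of one recording spans train and test).
    """
    cv = cv or CvConfig()
    dataset = Dataset.from_table(table)
    labels = np.asarray(table.labels, dtype=object)

    if cv.grouping == "recording":
        if len(table.groups) != table.n:
            raise EvaluationError("recording-grouped CV requires per-row group ids")
        group_ids = list(dict.fromkeys(table.groups))
        group_label = {g: labels[table.groups == g][0] for g in group_ids}
        group_folds = stratified_fold_indices(
            [group_label[g] for g in group_ids], cv.k_folds, cv.seed
        )
        folds = []
        for gf in group_folds:
            keep = {group_ids[i] for i in gf}
            folds.append(np.flatnonzero(np.isin(table.groups, list(keep))))
    else:
        folds = stratified_fold_indices(labels, cv.k_folds, cv.seed)

    n = table.n
    predicted = np.empty(n, dtype=int)
    scores = np.empty((n, len(table.class_labels)))
    fold_accuracies = []
    for f, test_idx in enumerate(folds):
        train_mask = np.ones(n, dtype=bool)
        train_mask[test_idx] = False
        train_data = Dataset(
            dataset.X[train_mask], dataset.y[train_mask], dataset.class_names
        )
        try:
            model: Model = train_fn(train_data, derive_seed(cv.seed, "fold", f))
        except Exception as exc:
            raise EvaluationError(f"training failed on fold {f}: {exc}") from exc
        s = model.score(dataset.X[test_idx])
        scores[test_idx] = s
        predicted[test_idx] = np.argmax(s, axis=1)
        fold_accuracies.append(
            100.0 * float(np.mean(predicted[test_idx] == dataset.y[test_idx]))
        )
    return MetricsReport.from_predictions(
        dataset.y, predicted, scores, tuple(table.class_labels), fold_accuracies
    )
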