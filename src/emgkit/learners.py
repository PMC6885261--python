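"""Base classifiers over continuous features with instance weights.

All models implement the same contract: ``predict(X)`` returns integer
class indices and ``score(X)`` returns a per-row nonnegative vector summing
to one whose argmax agrees with ``predict``.  Ties are always broken in
favour of the smallest class index (canonical order Normal < Myopathy <
Neuropathy for the EMG task).

The decision tree follows the C4.5 selection heuristic on continuous
attributes: binary splits at midpoints between consecutive distinct sorted
values; among all candidate splits whose information gain is at least the
mean gain of the candidates, the one with the highest gain ratio
(gain / split information) is chosen.  Entropies are computed from instance
weights.  Trees are unpruned.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace

import numpy as np

from ._util import rng_from
from .errors import ParameterError, TrainingError
from .wpd import FeatureTable


@dataclass
class Dataset:
    """Instances × features with integer-coded labels and positive weights.

    Weights sum to n by convention (uniform weights are all ones).
    """

    X: np.ndarray
    y: np.ndarray
    class_names: tuple[str, ...]
    weights: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.X = np.asarray(self.X, dtype=float)
        self.y = np.asarray(self.y, dtype=int)
        if self.X.ndim != 2 or len(self.y) != self.X.shape[0]:
            raise ParameterError("X and y have inconsistent shapes")
        if self.weights is None:
            self.weights = np.ones(len(self.y))
        else:
            self.weights = np.asarray(self.weights, dtype=float)
            if self.weights.shape != self.y.shape:
                raise ParameterError("weights and y have inconsistent shapes")
            if np.any(self.weights <= 0):
                raise ParameterError("instance weights must be positive")
        if len(self.y) and (self.y.min() < 0 or self.y.max() >= len(self.class_names)):
            raise ParameterError("labels outside the class set")

    @property
    def n(self) -> int:
        return self.X.shape[0]

    @property
    def d(self) -> int:
        return self.X.shape[1]

    @property
    def n_classes(self) -> int:
        return len(self.class_names)

    @classmethod
    def from_table(cls, table: FeatureTable) -> "Dataset":
        index = {c: i for i, c in enumerate(table.class_labels)}
        y = np.array([index[lab] for lab in table.labels], dtype=int)
        return cls(X=table.X, y=y, class_names=tuple(table.class_labels))

    def subset(self, indices: np.ndarray, renormalize: bool = True) -> "Dataset":
        w = self.weights[indices]
        if renormalize and w.sum() > 0:
            w = w * (len(w) / w.sum())
        return Dataset(self.X[indices], self.y[indices], self.class_names, w)


def weighted_resample(dataset: Dataset, weights: np.ndarray, seed: int) -> Dataset:
    """Draw n instances with probability proportional to ``weights``.

    Used to emulate instance weighting for learners that cannot consume
    weights directly; the resampled set carries uniform weights.
    """
    rng = rng_from(seed, "resample")
    p = np.asarray(weights, dtype=float)
    p = p / p.sum()
    idx = rng.choice(dataset.n, size=dataset.n, replace=True, p=p)
    return Dataset(dataset.X[idx], dataset.y[idx], dataset.class_names)


class Model:
    """Fitted classifier contract."""

    class_names: tuple[str, ...]

    def predict(self, X: np.ndarray) -> np.ndarray:
        return np.argmax(self.score(X), axis=1)

    def score(self, X: np.ndarray) -> np.ndarray:  # pragma: no cover - abstract
        raise NotImplementedError


class _Standardizer:
    """z-scoring fitted on training data only (sd floored to avoid 0/0)."""

    def __init__(self, X: np.ndarray) -> None:
        self.mean = X.mean(axis=0)
        sd = X.std(axis=0)
        self.sd = np.where(sd < 1e-12, 1.0, sd)

    def __call__(self, X: np.ndarray) -> np.ndarray:
        return (np.asarray(X, dtype=float) - self.mean) / self.sd


# ---------------------------------------------------------------------------
# Gain-ratio decision tree

@dataclass(frozen=True)
class TreeSpec:
    max_depth: int | None = None
    min_leaf: int = 1
    features_per_split: int | None = None  # None = all features (plain tree)

    def __post_init__(self) -> None:
        if self.min_leaf < 1:
            raise ParameterError("min_leaf must be >= 1")
        if self.max_depth is not None and self.max_depth < 1:
            raise ParameterError("max_depth must be >= 1 or None")


class _Node:
    __slots__ = ("feature", "threshold", "left", "right", "dist")

    def __init__(self, dist=None, feature=None, threshold=None, left=None, right=None):
        self.dist = dist
        self.feature = feature
        self.threshold = threshold
        self.left = left
        self.right = right


def _entropy(counts: np.ndarray, total: float) -> float:
    if total <= 0:
        return 0.0
    p = counts[counts > 0] / total
    return float(-(p * np.log2(p)).sum())


def _plogp(p: np.ndarray) -> np.ndarray:
    # p * log2(p) with 0 log 0 = 0 (clip keeps the product exactly 0 at p=0)
    return p * np.log2(np.maximum(p, 1e-300))


class _TreeContext:
    """Shared per-fit arrays; recursion passes index views, never copies X."""

    __slots__ = ("X", "y", "w", "wo", "K")

    def __init__(self, X, y, w, K):
        self.X = X
        self.y = y
        self.w = w
        self.K = K
        self.wo = np.zeros((len(y), K))
        self.wo[np.arange(len(y)), y] = w


def _node_candidates(ctx: _TreeContext, idx, features, min_leaf):
    """All candidate (feature, threshold) splits with gain/ratio arrays.

    Returns parallel lists over features of
    (feature, thresholds, gains, ratios); empty arrays if none valid.
    """
    n = len(idx)
    wo = ctx.wo[idx]
    counts_parent = wo.sum(axis=0)
    total_w = counts_parent.sum()
    h_parent = _entropy(counts_parent, total_w)
    out = []
    for f in features:
        xs_all = ctx.X[idx, f]
        order = np.argsort(xs_all, kind="mergesort")
        xs = xs_all[order]
        cum = np.cumsum(wo[order], axis=0)  # weighted class counts left of cut
        # Cut after position i (0-based): left = 0..i, right = i+1..n-1.
        pos = np.arange(n - 1)
        valid = xs[:-1] < xs[1:]
        if min_leaf > 1:
            valid &= (pos + 1 >= min_leaf) & (n - pos - 1 >= min_leaf)
        if not np.any(valid):
            out.append((f, np.empty(0), np.empty(0), np.empty(0)))
            continue
        pos = pos[valid]
        left = cum[pos]
        right = counts_parent[None, :] - left
        wl = left.sum(axis=1)
        wr = total_w - wl
        h_left = -(_plogp(left / wl[:, None])).sum(axis=1)
        h_right = -(_plogp(right / wr[:, None])).sum(axis=1)
        gain = h_parent - (wl * h_left + wr * h_right) / total_w
        pl, pr = wl / total_w, wr / total_w
        split_info = -(_plogp(pl) + _plogp(pr))
        ratio = gain / split_info
        thresholds = 0.5 * (xs[pos] + xs[pos + 1])
        out.append((f, thresholds, gain, ratio))
    return out


def _choose_split(ctx: _TreeContext, idx, features, min_leaf):
    """C4.5 rule: max gain ratio among splits with gain >= mean candidate gain."""
    cands = _node_candidates(ctx, idx, features, min_leaf)
    all_gains = np.concatenate([g for _, _, g, _ in cands]) if cands else np.empty(0)
    if all_gains.size == 0:
        return None
    mean_gain = all_gains.mean()
    best = None  # (ratio, feature, threshold)
    for f, thresholds, gains, ratios in cands:
        ok = (gains >= mean_gain - 1e-12) & (gains > 1e-12)
        if not np.any(ok):
            continue
        i = int(np.argmax(np.where(ok, ratios, -np.inf)))
        if best is None or ratios[i] > best[0] + 1e-12:
            best = (float(ratios[i]), f, float(thresholds[i]))
    if best is None:
        return None
    return best[1], best[2]


class TreeModel(Model):
    """Fitted (possibly randomized) gain-ratio decision tree."""

    def __init__(self, root: _Node, class_names: tuple[str, ...], standardizer=None):
        self.root = root
        self.class_names = class_names
        self._std = standardizer

    def score(self, X: np.ndarray) -> np.ndarray:
        X = np.atleast_2d(np.asarray(X, dtype=float))
        if self._std is not None:
            X = self._std(X)
        out = np.empty((len(X), len(self.class_names)))
        self._route(self.root, X, np.arange(len(X)), out)
        return out

    def _route(self, node: _Node, X, idx, out) -> None:
        if node.feature is None:
            out[idx] = node.dist
            return
        mask = X[idx, node.feature] <= node.threshold
        self._route(node.left, X, idx[mask], out)
        self._route(node.right, X, idx[~mask], out)

    def depth(self) -> int:
        def d(node):
            if node.feature is None:
                return 0
            return 1 + max(d(node.left), d(node.right))
        return d(self.root)


def _leaf(ctx: _TreeContext, idx) -> _Node:
    counts = ctx.wo[idx].sum(axis=0)
    total = counts.sum()
    dist = counts / total if total > 0 else np.full(ctx.K, 1.0 / ctx.K)
    return _Node(dist=dist)


def _grow(ctx: _TreeContext, idx, spec: TreeSpec, depth: int,
          rng: np.random.Generator | None) -> _Node:
    n, d = len(idx), ctx.X.shape[1]
    y_node = ctx.y[idx]
    if (
        np.all(y_node == y_node[0])
        or n < 2 * spec.min_leaf
        or (spec.max_depth is not None and depth >= spec.max_depth)
    ):
        return _leaf(ctx, idx)
    if spec.features_per_split is not None and spec.features_per_split < d:
        if rng is None:
            raise ParameterError("feature subsampling requires a seed")
        features = np.sort(rng.choice(d, size=spec.features_per_split, replace=False))
    else:
        features = np.arange(d)
    split = _choose_split(ctx, idx, features, spec.min_leaf)
    if split is None:
        return _leaf(ctx, idx)
    f, thr = split
    mask = ctx.X[idx, f] <= thr
    node = _Node(feature=f, threshold=thr)
    node.left = _grow(ctx, idx[mask], spec, depth + 1, rng)
    node.right = _grow(ctx, idx[~mask], spec, depth + 1, rng)
    node.dist = _leaf(ctx, idx).dist
    return node


def train_gain_ratio_tree(dataset: Dataset, spec: TreeSpec | None = None) -> TreeModel:
    """Fit an unpruned binary gain-ratio tree on continuous features."""
    spec = spec or TreeSpec()
    if dataset.n < 1:
        raise TrainingError("empty dataset")
    ctx = _TreeContext(dataset.X, dataset.y, dataset.weights, dataset.n_classes)
    root = _grow(ctx, np.arange(dataset.n), replace(spec, features_per_split=None), 0, None)
    return TreeModel(root, dataset.class_names)


def train_random_tree(dataset: Dataset, spec: TreeSpec | None = None, seed: int = 0) -> TreeModel:
    """Gain-ratio tree with a fresh random feature subset at every node.

    Default subset size is ceil(sqrt(d)).  Unpruned; deterministic given
    the seed.
    """
    spec = spec or TreeSpec()
    m = spec.features_per_split or math.ceil(math.sqrt(dataset.d))
    if m > dataset.d:
        raise ParameterError("features_per_split cannot exceed the feature count")
    rng = rng_from(seed, "random-tree")
    ctx = _TreeContext(dataset.X, dataset.y, dataset.weights, dataset.n_classes)
    root = _grow(ctx, np.arange(dataset.n), replace(spec, features_per_split=m), 0, rng)
    return TreeModel(root, dataset.class_names)


# ---------------------------------------------------------------------------
# Gaussian naive Bayes

class NaiveBayesModel(Model):
    def __init__(self, priors, means, variances, class_names):
        self.priors = priors
        self.means = means
        self.variances = variances
        self.class_names = class_names

    def score(self, X: np.ndarray) -> np.ndarray:
        X = np.atleast_2d(np.asarray(X, dtype=float))
        log_post = np.log(self.priors)[None, :] + np.stack(
            [
                -0.5 * (
                    np.log(2 * np.pi * self.variances[k])
                    + (X - self.means[k]) ** 2 / self.variances[k]
                ).sum(axis=1)
                for k in range(len(self.priors))
            ],
            axis=1,
        )
        log_post -= log_post.max(axis=1, keepdims=True)
        post = np.exp(log_post)
        return post / post.sum(axis=1, keepdims=True)


def train_naive_bayes(dataset: Dataset, var_floor: float = 1e-9) -> NaiveBayesModel:
    """Weighted Gaussian naive Bayes: per-class, per-feature normal models."""
    if dataset.n < 2:
        raise TrainingError("naive Bayes needs at least 2 instances")
    K = dataset.n_classes
    priors = np.empty(K)
    means = np.empty((K, dataset.d))
    variances = np.empty((K, dataset.d))
    for k in range(K):
        mask = dataset.y == k
        wk = dataset.weights[mask]
        if wk.size == 0:
            raise TrainingError(
                f"class {dataset.class_names[k]!r} absent from the training data"
            )
        total = wk.sum()
        priors[k] = total / dataset.weights.sum()
        mu = (wk[:, None] * dataset.X[mask]).sum(axis=0) / total
        var = (wk[:, None] * (dataset.X[mask] - mu) ** 2).sum(axis=0) / total
        means[k] = mu
        variances[k] = np.maximum(var, var_floor)
    return NaiveBayesModel(priors, means, variances, dataset.class_names)


# ---------------------------------------------------------------------------
# k-nearest neighbours

class KnnModel(Model):
    def __init__(self, X, y, weights, k, class_names, standardizer):
        self.X_train = X
        self.y_train = y
        self.w_train = weights
        self.k = k
        self.class_names = class_names
        self._std = standardizer

    def score(self, X: np.ndarray) -> np.ndarray:
        X = np.atleast_2d(np.asarray(X, dtype=float))
        if self._std is not None:
            X = self._std(X)
        K = len(self.class_names)
        d2 = (
            (X**2).sum(axis=1)[:, None]
            - 2 * X @ self.X_train.T
            + (self.X_train**2).sum(axis=1)[None, :]
        )
        nearest = np.argsort(d2, axis=1, kind="mergesort")[:, : self.k]
        scores = np.zeros((len(X), K))
        for k_cls in range(K):
            scores[:, k_cls] = np.where(
                self.y_train[nearest] == k_cls, self.w_train[nearest], 0.0
            ).sum(axis=1)
        return scores / scores.sum(axis=1, keepdims=True)


def train_knn(dataset: Dataset, k: int = 5, standardize: bool = True) -> KnnModel:
    """Lazy learner: stores the (optionally z-scored) training set.

    Prediction is the weighted majority among the k Euclidean-nearest
    training instances.
    """
    if not 1 <= k <= dataset.n:
        raise ParameterError(f"k={k} outside 1..n={dataset.n}")
    std = _Standardizer(dataset.X) if standardize else None
    X = std(dataset.X) if std else dataset.X
    return KnnModel(X, dataset.y, dataset.weights, k, dataset.class_names, std)


# ---------------------------------------------------------------------------
# Random forest

class VoteModel(Model):
    """Unweighted plurality vote over member models (vote-fraction scores)."""

    def __init__(self, members, class_names):
        if not members:
            raise TrainingError("forest has no members")
        self.members = members
        self.class_names = class_names

    def score(self, X: np.ndarray) -> np.ndarray:
        X = np.atleast_2d(np.asarray(X, dtype=float))
        K = len(self.class_names)
        votes = np.zeros((len(X), K))
        for m in self.members:
            votes[np.arange(len(X)), m.predict(X)] += 1.0
        return votes / votes.sum(axis=1, keepdims=True)


@dataclass(frozen=True)
class ForestSpec:
    n_trees: int = 25
    features_per_split: int | None = None
    max_depth: int | None = None
    min_leaf: int = 1
    bootstrap: bool = True

    def __post_init__(self) -> None:
        if self.n_trees < 1:
            raise ParameterError("n_trees must be >= 1")


def train_random_forest(dataset: Dataset, spec: ForestSpec | None = None, seed: int = 0) -> VoteModel:
    """Bagged random trees; bootstrap draws respect instance weights."""
    spec = spec or ForestSpec()
    tree_spec = TreeSpec(
        max_depth=spec.max_depth,
        min_leaf=spec.min_leaf,
        features_per_split=spec.features_per_split,
    )
    members = []
    p = dataset.weights / dataset.weights.sum()
    for t in range(spec.n_trees):
        rng = rng_from(seed, "forest-bootstrap", t)
        if spec.bootstrap:
            idx = rng.choice(dataset.n, size=dataset.n, replace=True, p=p)
            fit_data = Dataset(dataset.X[idx], dataset.y[idx], dataset.class_names)
        else:
            fit_data = dataset
        members.append(train_random_tree(fit_data, tree_spec, seed=int(rng.integers(2**31))))
    return VoteModel(members, dataset.class_names)


# ---------------------------------------------------------------------------
# Adapter for external estimators (ANN/SVM-style) + learner registry

class SklearnModel(Model):
    def __init__(self, estimator, class_names, standardizer):
        self.estimator = estimator
        self.class_names = class_names
        self._std = standardizer

    def score(self, X: np.ndarray) -> np.ndarray:
        X = np.atleast_2d(np.asarray(X, dtype=float))
        if self._std is not None:
            X = self._std(X)
        if hasattr(self.estimator, "predict_proba"):
            proba = self.estimator.predict_proba(X)
            full = np.zeros((len(X), len(self.class_names)))
            full[:, np.asarray(self.estimator.classes_, dtype=int)] = proba
            return full
        pred = np.asarray(self.estimator.predict(X), dtype=int)
        full = np.zeros((len(X), len(self.class_names)))
        full[np.arange(len(X)), pred] = 1.0
        return full


def train_sklearn(estimator, dataset: Dataset, standardize: bool = True) -> SklearnModel:
    """Fit any scikit-learn style classifier through the Model contract."""
    std = _Standardizer(dataset.X) if standardize else None
    X = std(dataset.X) if std else dataset.X
    try:
        estimator.fit(X, dataset.y, sample_weight=dataset.weights)
    except TypeError:
        estimator.fit(X, dataset.y)
    return SklearnModel(estimator, dataset.class_names, std)


@dataclass
class Learner:
    """Named trainer usable standalone or inside an ensemble.

    ``train(dataset, seed)`` must be a pure function of its arguments;
    ``supports_weights`` tells ensembles whether instance weights can be
    passed directly (otherwise they fall back to weighted resampling).
    """

    name: str
    train_fn: "callable"
    supports_weights: bool = True
    hyperparameters: dict = field(default_factory=dict)

    def train(self, dataset: Dataset, seed: int = 0) -> Model:
        return self.train_fn(dataset, seed)


def make_learner(name: str, **hyper) -> Learner:
    """Registry of the built-in base learners by name."""
    name = name.lower().replace("-", "_")
    if name in ("gain_ratio_tree", "c45", "tree"):
        spec = TreeSpec(
            max_depth=hyper.pop("max_depth", None),
            min_leaf=hyper.pop("min_leaf", 1),
        )
        _check_empty(hyper, name)
        return Learner(name, lambda ds, seed: train_gain_ratio_tree(ds, spec),
                       hyperparameters={"spec": spec})
    if name in ("naive_bayes", "nb"):
        _check_empty(hyper, name)
        return Learner(name, lambda ds, seed: train_naive_bayes(ds))
    if name == "knn":
        k = hyper.pop("k", 5)
        standardize = hyper.pop("standardize", True)
        _check_empty(hyper, name)
        return Learner(name, lambda ds, seed: train_knn(ds, k=k, standardize=standardize),
                       hyperparameters={"k": k})
    if name == "random_tree":
        spec = TreeSpec(
            max_depth=hyper.pop("max_depth", None),
            min_leaf=hyper.pop("min_leaf", 1),
            features_per_split=hyper.pop("features_per_split", None),
        )
        _check_empty(hyper, name)
        return Learner(name, lambda ds, seed: train_random_tree(ds, spec, seed=seed),
                       hyperparameters={"spec": spec})
    if name == "random_forest":
        spec = ForestSpec(
            n_trees=hyper.pop("n_trees", 25),
            features_per_split=hyper.pop("features_per_split", None),
            max_depth=hyper.pop("max_depth", None),
            min_leaf=hyper.pop("min_leaf", 1),
            bootstrap=hyper.pop("bootstrap", True),
        )
        _check_empty(hyper, name)
        return Learner(name, lambda ds, seed: train_random_forest(ds, spec, seed=seed),
                       hyperparameters={"spec": spec})
    raise ParameterError(f"unknown learner {name!r}")


def _check_empty(hyper: dict, name: str) -> None:
    if hyper:
        raise ParameterError(f"unknown hyperparameters for {name!r}: {sorted(hyper)}")
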