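"""Committee meta-learners: bagging, AdaBoost.M1 and MultiBoosting.

All three wrap any :class:`~emgkit.learners.Learner` and produce a
:class:`Committee` — an ordered list of fitted members with voting weights:

* **bagging** — each member fits an independent bootstrap resample; all
  votes count equally.
* **AdaBoost.M1** — members are fitted sequentially on reweighted data;
  after round t with weighted error ε_t < 1/2, correctly classified
  instances are down-weighted by β_t = ε_t/(1−ε_t), weights renormalised
  to sum n, and the member votes with log(1/β_t).  ε_t ≥ 1/2 discards the
  member and stops; ε_t = 0 accepts the member with a capped weight
  log(1/β_min) and stops.
* **MultiBoosting** — the T rounds are partitioned into ⌈√T⌉ contiguous
  sub-committees of near-equal size; at each sub-committee start the
  instance weights are reset by *wagging* (random weights, by default
  continuous-Poisson −log U noise), and the AdaBoost update runs inside
  each sub-committee, with ε_t ≥ 1/2 or ε_t = 0 ending only the current
  sub-committee.

Instance weights are passed to the base learner directly when it supports
them, otherwise realised by weighted resampling.  Every trainer is a pure
function of (dataset, spec, seed).
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field

import numpy as np

from ._util import derive_seed, rng_from
from .errors import ParameterError, PredictionError
from .learners import Dataset, Learner, Model, weighted_resample

logger = logging.getLogger(__name__)

BETA_MIN = 1e-10


@dataclass
class Committee(Model):
    """Ordered, weighted set of fitted member models."""

    members: list[Model]
    member_weights: np.ndarray
    method: str
    T: int
    class_names: tuple[str, ...] = ()

    def __post_init__(self) -> None:
        self.member_weights = np.asarray(self.member_weights, dtype=float)
        if len(self.members) != len(self.member_weights):
            raise ParameterError("members and member_weights differ in length")
        if np.any(self.member_weights <= 0):
            raise ParameterError("member weights must be positive")
        if not self.class_names and self.members:
            self.class_names = self.members[0].class_names

    def score(self, X: np.ndarray) -> np.ndarray:
        label, scores = committee_predict(self, X)
        return scores


def committee_predict(committee: Committee, X: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Weighted plurality vote: per-class score = weight share of its votes."""
    if len(committee.members) == 0:
        raise PredictionError("empty committee")
    X = np.atleast_2d(np.asarray(X, dtype=float))
    K = len(committee.class_names)
    votes = np.zeros((len(X), K))
    for model, w in zip(committee.members, committee.member_weights):
        votes[np.arange(len(X)), model.predict(X)] += w
    scores = votes / votes.sum(axis=1, keepdims=True)
    return np.argmax(scores, axis=1), scores


def _bootstrap(dataset: Dataset, seed: int) -> Dataset:
    rng = rng_from(seed, "bootstrap")
    p = dataset.weights / dataset.weights.sum()
    idx = rng.choice(dataset.n, size=dataset.n, replace=True, p=p)
    return Dataset(dataset.X[idx], dataset.y[idx], dataset.class_names)


def bagging_train(
    learner: Learner, dataset: Dataset, T: int = 10, seed: int = 0, resample: bool = True
) -> Committee:
    """Bootstrap-aggregated committee with equal voting weights."""
    if T < 1:
        raise ParameterError("T must be >= 1")
    members: list[Model] = []
    for t in range(T):
        round_seed = derive_seed(seed, "round", t)
        fit_data = _bootstrap(dataset, round_seed) if resample else dataset
        try:
            members.append(learner.train(fit_data, round_seed))
        except Exception as exc:  # noqa: BLE001 - spec: skip failed rounds
            logger.warning("bagging round %d skipped: %s", t, exc)
    return Committee(members, np.ones(len(members)), "bagging", T, dataset.class_names)


def _fit_weighted(learner: Learner, dataset: Dataset, w: np.ndarray, seed: int) -> Model:
    if learner.supports_weights:
        return learner.train(
            Dataset(dataset.X, dataset.y, dataset.class_names, w.copy()), seed
        )
    return learner.train(weighted_resample(dataset, w, seed), seed)


def adaboost_m1_train(
    learner: Learner,
    dataset: Dataset,
    T: int = 10,
    seed: int = 0,
    samme: bool = False,
) -> Committee:
    """AdaBoost.M1 over an arbitrary base learner.

    With ``samme=True`` the multiclass log(K−1) correction is added to the
    member weights and the acceptance threshold becomes the chance error
    1 − 1/K instead of 1/2.
    """
    if T < 1:
        raise ParameterError("T must be >= 1")
    if dataset.n_classes < 2 or len(np.unique(dataset.y)) < 2:
        logger.warning("degenerate single-class dataset: trivial committee")
        model = learner.train(dataset, derive_seed(seed, "round", 0))
        return Committee([model], np.ones(1), "adaboost", T, dataset.class_names)

    n = dataset.n
    K = dataset.n_classes
    err_cap = (1 - 1 / K) if samme else 0.5
    extra = math.log(K - 1) if samme else 0.0
    w = dataset.weights.copy()
    members: list[Model] = []
    alphas: list[float] = []
    for t in range(T):
        round_seed = derive_seed(seed, "round", t)
        model = _fit_weighted(learner, dataset, w, round_seed)
        miss = model.predict(dataset.X) != dataset.y
        eps = float(w[miss].sum() / w.sum())
        if eps >= err_cap:
            logger.warning(
                "boosting round %d: weighted error %.3f >= %.3f; member discarded, stopping",
                t, eps, err_cap,
            )
            break
        if eps == 0.0:
            members.append(model)
            alphas.append(math.log(1.0 / BETA_MIN) + extra)
            logger.info("boosting round %d: zero training error; stopping", t)
            break
        beta = eps / (1.0 - eps)
        members.append(model)
        alphas.append(math.log(1.0 / beta) + extra)
        w[~miss] *= beta
        w *= n / w.sum()
    if not members:
        logger.warning("no boosting round accepted; falling back to the unweighted base model")
        model = learner.train(dataset, derive_seed(seed, "fallback"))
        return Committee([model], np.ones(1), "adaboost", T, dataset.class_names)
    return Committee(members, np.array(alphas), "adaboost", T, dataset.class_names)


def wagging_weights(
    n: int,
    noise_model: str = "continuous_poisson",
    noise_scale: float = 2.0,
    seed: int = 0,
) -> np.ndarray:
    """Random instance weights, positive and renormalised to sum n.

    ``continuous_poisson`` draws −log(U), U ~ Uniform(0,1) (the MultiBoost
    convention); ``gaussian`` draws max(0, 1 + N(0, noise_scale)) with
    zeros floored at 1e−10 (the Bauer–Kohavi formulation).
    """
    if n < 1:
        raise ParameterError("n must be >= 1")
    rng = rng_from(seed, "wagging")
    if noise_model == "continuous_poisson":
        w = -np.log(rng.uniform(0.0, 1.0, size=n))
        w = np.maximum(w, 1e-10)
    elif noise_model == "gaussian":
        w = np.maximum(0.0, 1.0 + rng.normal(0.0, noise_scale, size=n))
        w = np.where(w == 0.0, 1e-10, w)
    else:
        raise ParameterError(f"unknown wagging noise model {noise_model!r}")
    return w * (n / w.sum())


def subcommittee_sizes(T: int, n_subcommittees: int | None = None) -> list[int]:
    """Near-equal contiguous block sizes; default ⌈√T⌉ blocks.

    T=10 → 4 sub-committees of sizes [3, 3, 2, 2].
    """
    s = n_subcommittees or math.ceil(math.sqrt(T))
    if not 1 <= s <= T:
        raise ParameterError("need 1 <= n_subcommittees <= T")
    base, rem = divmod(T, s)
    return [base + 1] * rem + [base] * (s - rem)


def multiboost_train(
    learner: Learner,
    dataset: Dataset,
    T: int = 10,
    n_subcommittees: int | None = None,
    seed: int = 0,
    noise_model: str = "continuous_poisson",
    noise_scale: float = 2.0,
    wagging_noise: bool = True,
    samme: bool = False,
) -> Committee:
    """MultiBoosting: wagging-restarted AdaBoost sub-committees.

    With one sub-committee and ``wagging_noise=False`` this reproduces
    :func:`adaboost_m1_train` member-by-member; with ``n_subcommittees=T``
    every member is a single weighted fit (wagging alone).
    """
    if dataset.n_classes < 2 or len(np.unique(dataset.y)) < 2:
        logger.warning("degenerate single-class dataset: trivial committee")
        model = learner.train(dataset, derive_seed(seed, "round", 0))
        return Committee([model], np.ones(1), "multiboost", T, dataset.class_names)

    sizes = subcommittee_sizes(T, n_subcommittees)
    n = dataset.n
    K = dataset.n_classes
    err_cap = (1 - 1 / K) if samme else 0.5
    extra = math.log(K - 1) if samme else 0.0
    members: list[Model] = []
    alphas: list[float] = []
    t = 0
    for b, size in enumerate(sizes):
        if wagging_noise:
            w = wagging_weights(
                n, noise_model, noise_scale, seed=derive_seed(seed, "wagging", b)
            )
            w = w * dataset.weights
            w *= n / w.sum()
        else:
            w = dataset.weights.copy()
        for _ in range(size):
            round_seed = derive_seed(seed, "round", t)
            model = _fit_weighted(learner, dataset, w, round_seed)
            t += 1
            miss = model.predict(dataset.X) != dataset.y
            eps = float(w[miss].sum() / w.sum())
            if eps >= err_cap:
                logger.warning(
                    "multiboost round %d: error %.3f >= %.3f; ending sub-committee %d",
                    t - 1, eps, err_cap, b,
                )
                break
            if eps == 0.0:
                members.append(model)
                alphas.append(math.log(1.0 / BETA_MIN) + extra)
                break
            beta = eps / (1.0 - eps)
            members.append(model)
            alphas.append(math.log(1.0 / beta) + extra)
            w = w.copy()
            w[~miss] *= beta
            w *= n / w.sum()
    if not members:
        logger.warning("no multiboost round accepted; falling back to the unweighted base model")
        model = learner.train(dataset, derive_seed(seed, "fallback"))
        return Committee([model], np.ones(1), "multiboost", T, dataset.class_names)
    return Committee(members, np.array(alphas), "multiboost", T, dataset.class_names)


@dataclass(frozen=True)
class EnsembleSpec:
    """Configuration of one committee trainer (for the CLI / pipelines)."""

    method: str = "adaboost"  # none | bagging | adaboost | multiboost
    T: int = 10
    n_subcommittees: int | None = None
    noise_model: str = "continuous_poisson"
    noise_scale: float = 2.0
    samme: bool = False

    def __post_init__(self) -> None:
        if self.method not in ("none", "bagging", "adaboost", "multiboost"):
            raise ParameterError(f"unknown ensemble method {self.method!r}")
        if self.T < 1:
            raise ParameterError("T must be >= 1")


def train_ensemble(
    learner: Learner, dataset: Dataset, spec: EnsembleSpec, seed: int = 0
) -> Model:
    """Dispatch on the ensemble method; 'none' fits the bare learner."""
    if spec.method == "none":
        return learner.train(dataset, derive_seed(seed, "single"))
    if spec.method == "bagging":
        return bagging_train(learner, dataset, spec.T, seed)
    if spec.method == "adaboost":
        return adaboost_m1_train(learner, dataset, spec.T, seed, samme=spec.samme)
    return multiboost_train(
        learner,
        dataset,
        spec.T,
        spec.n_subcommittees,
        seed,
        noise_model=spec.noise_model,
        noise_scale=spec.noise_scale,
        samme=spec.samme,
    )
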