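"""The three deep-ensemble meta-algorithms over pluggable neural CLUs.

Deep aggregated learning (DAL)
    bagging: each member CLU is trained on its own bootstrap subset of the
    training data and the ensemble score is the plain mean of member
    probabilities, P = (1/n)·Σ P_i.

Gradient deep-learning boosting (GDLB)
    gradient boosting with regression CLUs: the base prediction is the mean
    of the training labels; booster i is fitted to the residuals left by the
    running prediction, whose output enters the sum scaled by a learning
    rate λ_i drawn uniformly from (0,1) (or fixed, for testing):
    P = P_base + Σ λ_i·O_i.

Deep stacked generalization ensemble learning (DeSGEL)
    two-level stacking: n level-0 probability CLUs produce a "metadata"
    matrix of scores (columns = members), on which a level-1 classifier f is
    fitted to yield P = f(∪ P_i).  The metadata used for fitting f comes
    from a partition the level-0 members did not train on, so the
    meta-learner never sees in-sample member scores.

All three are reproducible from (spec, seed); member i derives its own seed
as ``seed + i``.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Callable, Sequence

import numpy as np
from sklearn.linear_model import LogisticRegression

from .clu import CLU, CLUSpec, NotFittedError, build_clu, derive_rng, train_clu

logger = logging.getLogger(__name__)

__all__ = [
    "PredictionVector",
    "DALModel",
    "GDLBModel",
    "DeSGELModel",
    "ColumnMeanMeta",
    "fit_dal",
    "predict_dal",
    "fit_gdlb",
    "predict_gdlb",
    "fit_desgel",
    "predict_desgel",
    "build_metadata",
]


@dataclass
class PredictionVector:
    """Positive-class scores in [0,1] plus thresholded class labels."""

    scores: np.ndarray
    threshold: float = 0.5

    def __post_init__(self) -> None:
        self.scores = np.asarray(self.scores, dtype=float)

    @property
    def classes(self) -> np.ndarray:
        return (self.scores >= self.threshold).astype(int)


def _as_xy(data) -> tuple[np.ndarray, np.ndarray]:
    X, y = data
    return np.asarray(X, dtype=float), np.asarray(y, dtype=float).reshape(-1)


# ---------------------------------------------------------------------------
# DAL — deep aggregated learning (bagging)
# ---------------------------------------------------------------------------


@dataclass
class DALModel:
    members: list[CLU]
    subset_assignments: list[np.ndarray]
    aggregator: str = "mean"
    threshold: float = 0.5

    def __post_init__(self) -> None:
        if not self.members:
            raise ValueError("DAL needs at least one member")
        if any(m.spec.output_mode != "probability" for m in self.members):
            raise ValueError("DAL members must output probabilities")


def fit_dal(
    train,
    val,
    clu_spec: CLUSpec,
    n_members: int,
    seed: int = 0,
    aggregator: str = "mean",
    subset_mode: str = "bootstrap",
) -> DALModel:
    """Train ``n_members`` CLUs on bootstrap (or disjoint) subsets of train.

    Member i uses spec seed ``seed + i`` and its own resampled subset;
    validation is shared.  ``subset_mode='disjoint'`` partitions the
    training set into n contiguous random blocks instead of resampling.
    """
    if n_members < 1:
        raise ValueError("n_members must be >= 1")
    if clu_spec.output_mode != "probability":
        raise ValueError("DAL members must be probability CLUs")
    X, y = _as_xy(train)
    n = len(X)
    members: list[CLU] = []
    subsets: list[np.ndarray] = []
    if subset_mode == "disjoint":
        perm = derive_rng(seed, 20).permutation(n)
        blocks = np.array_split(perm, n_members)
    for i in range(n_members):
        if subset_mode == "bootstrap":
            idx = derive_rng(seed, 21, i).integers(0, n, size=n)
        elif subset_mode == "disjoint":
            idx = np.sort(blocks[i])
        else:
            raise ValueError(f"unknown subset_mode {subset_mode!r}")
        if len(idx) < clu_spec.batch_size and len(idx) < n:
            raise ValueError(f"member subset of {len(idx)} rows is smaller than one batch")
        member = build_clu(clu_spec.replace(seed=seed + i))
        member, _ = train_clu(member, (X[idx], y[idx]), val)
        members.append(member)
        subsets.append(np.asarray(idx))
    return DALModel(members=members, subset_assignments=subsets, aggregator=aggregator)


def predict_dal(model: DALModel, inputs: np.ndarray) -> PredictionVector:
    """Aggregate member probabilities: mean (Eq.-style sum/n) or mode vote.

    The mean is accumulated member-by-member in list order so it agrees
    bitwise with an explicit loop-and-average oracle.
    """
    preds = [m.predict_proba(inputs) for m in model.members]
    n = len(preds)
    if model.aggregator == "mean":
        total = np.zeros_like(preds[0])
        for p in preds:
            total = total + p
        scores = total / n
    elif model.aggregator == "mode":
        votes = np.zeros_like(preds[0])
        for p in preds:
            votes = votes + (p >= model.threshold)
        # ties (possible for even n) break toward the positive class
        scores = (votes >= n / 2).astype(float)
    else:
        raise ValueError(f"unknown aggregator {model.aggregator!r}")
    return PredictionVector(scores, model.threshold)


# ---------------------------------------------------------------------------
# GDLB — gradient deep-learning boosting
# ---------------------------------------------------------------------------


@dataclass
class GDLBModel:
    p_base: float
    boosters: list
    learning_rates: list[float]
    threshold: float = 0.5
    staged_train_mse: list[float] = field(default_factory=list)

    def __post_init__(self) -> None:
        if len(self.boosters) != len(self.learning_rates):
            raise ValueError("one learning rate per booster")
        # λ=1 is admitted for exact-correction analyses
        if any(not (0 < lam <= 1) for lam in self.learning_rates):
            raise ValueError("learning rates must lie in (0, 1]")


def _default_booster_fitter(clu_spec: CLUSpec, seed: int):
    def fit(i: int, X: np.ndarray, target: np.ndarray, val: tuple[np.ndarray, np.ndarray]):
        booster = build_clu(clu_spec.replace(seed=seed + i + 1))
        booster, _ = train_clu(booster, (X, target), val)
        return booster

    return fit


def fit_gdlb(
    train,
    val,
    clu_spec: CLUSpec,
    n_boosters: int,
    lr_policy: float | Sequence[float] | str = "uniform",
    seed: int = 0,
    booster_fitter: Callable | None = None,
) -> GDLBModel:
    """Stagewise residual boosting with regression CLUs.

    The running prediction starts at the label mean (the "basement"
    prediction); each booster is fitted to the current residuals and its
    output is added scaled by λ_i.  ``lr_policy`` is ``"uniform"`` (one
    uniform(0,1) draw per booster from the run seed), a fixed float, or an
    explicit sequence.  ``booster_fitter(i, X, target, val) -> regressor``
    may replace CLU training (used for oracle analyses in tests).
    """
    if n_boosters < 1:
        raise ValueError("n_boosters must be >= 1")
    if clu_spec.output_mode != "regression" or clu_spec.loss != "mean_squared_error":
        raise ValueError("GDLB boosters must be regression CLUs with mean_squared_error loss")
    X, y = _as_xy(train)
    Xv, yv = _as_xy(val)
    if booster_fitter is None:
        booster_fitter = _default_booster_fitter(clu_spec, seed)

    if lr_policy == "uniform":
        lam_rng = derive_rng(seed, 30)
        lams = [float(lam_rng.uniform(0.0, 1.0)) for _ in range(n_boosters)]
    elif np.isscalar(lr_policy):
        lams = [float(lr_policy)] * n_boosters
    else:
        lams = [float(v) for v in lr_policy]
        if len(lams) != n_boosters:
            raise ValueError("lr_policy sequence length must equal n_boosters")

    p_base = float(y.mean())
    current = np.full(len(y), p_base)
    current_val = np.full(len(yv), p_base)
    boosters = []
    staged = [float(np.mean((y - current) ** 2))]
    for i in range(n_boosters):
        target = y - current
        booster = booster_fitter(i, X, target, (Xv, yv - current_val))
        boosters.append(booster)
        current = current + lams[i] * np.asarray(booster.predict_proba(X) if isinstance(booster, CLU) else booster.predict(X))
        current_val = current_val + lams[i] * np.asarray(
            booster.predict_proba(Xv) if isinstance(booster, CLU) else booster.predict(Xv)
        )
        staged.append(float(np.mean((y - current) ** 2)))
    return GDLBModel(p_base=p_base, boosters=boosters, learning_rates=lams, staged_train_mse=staged)


def predict_gdlb(model: GDLBModel, inputs: np.ndarray) -> PredictionVector:
    """Raw score P_base + Σ λ_i·O_i(inputs), clipped to [0,1] for reporting."""
    raw = np.full(len(inputs), model.p_base)
    for lam, booster in zip(model.learning_rates, model.boosters):
        out = booster.predict_proba(inputs) if isinstance(booster, CLU) else booster.predict(inputs)
        raw = raw + lam * np.asarray(out, dtype=float)
    return PredictionVector(np.clip(raw, 0.0, 1.0), model.threshold)


# ---------------------------------------------------------------------------
# DeSGEL — deep stacked generalization
# ---------------------------------------------------------------------------


class ColumnMeanMeta:
    """Degenerate meta-learner averaging the metadata columns.

    With this as level-1, stacking reduces exactly to bagging's mean
    aggregation; it exists as an analytic reference point.
    """

    def fit(self, M: np.ndarray, y: np.ndarray) -> "ColumnMeanMeta":
        return self

    def predict_proba_scores(self, M: np.ndarray) -> np.ndarray:
        total = np.zeros(len(M))
        for j in range(M.shape[1]):
            total = total + M[:, j]
        return total / M.shape[1]


@dataclass
class DeSGELModel:
    level0: list[CLU]
    level1: object
    threshold: float = 0.5

    def __post_init__(self) -> None:
        if not self.level0:
            raise ValueError("DeSGEL needs at least one level-0 member")


def build_metadata(level0: list[CLU], inputs: np.ndarray) -> np.ndarray:
    """Metadata matrix: column i is member i's score on ``inputs``."""
    if not level0:
        raise ValueError("no level-0 members")
    cols = [m.predict_proba(inputs) for m in level0]
    return np.column_stack(cols)


def _meta_scores(level1, M: np.ndarray) -> np.ndarray:
    if hasattr(level1, "predict_proba_scores"):
        return np.asarray(level1.predict_proba_scores(M), dtype=float)
    if hasattr(level1, "predict_proba"):
        return np.asarray(level1.predict_proba(M), dtype=float)[:, 1]
    raise TypeError("level-1 classifier must expose predict_proba or predict_proba_scores")


def fit_desgel(
    train,
    val,
    clu_spec: CLUSpec,
    n_members: int,
    level1_spec: object = "logistic",
    seed: int = 0,
) -> DeSGELModel:
    """Train level-0 CLUs on the training split, then the level-1 classifier
    on their held-out (validation-split) metadata.

    ``level1_spec`` is ``"logistic"`` (regularised logistic regression),
    ``"mean"`` (column averaging), or any object with fit/predict_proba.
    """
    if n_members < 1:
        raise ValueError("n_members must be >= 1")
    if clu_spec.output_mode != "probability":
        raise ValueError("DeSGEL level-0 members must be probability CLUs")
    X, y = _as_xy(train)
    Xv, yv = _as_xy(val)
    level0 = []
    for i in range(n_members):
        member = build_clu(clu_spec.replace(seed=seed + i))
        member, _ = train_clu(member, (X, y), (Xv, yv))
        level0.append(member)
    M = build_metadata(level0, Xv)
    if len(M) < 2:
        raise ValueError("too few held-out rows to fit the level-1 classifier")
    if level1_spec == "logistic":
        level1 = LogisticRegression(max_iter=1000, random_state=seed)
    elif level1_spec == "mean":
        level1 = ColumnMeanMeta()
    else:
        level1 = level1_spec
    if len(np.unique(yv)) < 2 and isinstance(level1, LogisticRegression):
        logger.warning("validation split single-class; falling back to column-mean meta-learner")
        level1 = ColumnMeanMeta()
    level1.fit(M, yv.astype(int))
    return DeSGELModel(level0=level0, level1=level1)


def predict_desgel(model: DeSGELModel, inputs: np.ndarray) -> PredictionVector:
    """f applied to the members' metadata on ``inputs``."""
    M = build_metadata(model.level0, inputs)
    return PredictionVector(_meta_scores(model.level1, M), model.threshold)
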