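"""Optimal-model-complexity (OMC) nested-CV feature selection.

High-dimensional profiles (up to ~450k CpG probes for 70 patients) drown
most learners in noise. OMC wraps any base classifier in a nested CV: on
each outer-fold training set, features are ranked by a two-group ANOVA
F-test, a grid of "top k" feature counts from 2 to half the training size
is evaluated by an inner merged-CV MCC, and the k with the best inner MCC
(ties broken toward the smallest k) is used to refit the base model for the
outer fold. The ranking is recomputed inside every inner training split, so
feature selection never sees any data the model is evaluated on.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Callable, Dict, List, Optional, Sequence, Tuple

import numpy as np
import pandas as pd
from sklearn.feature_selection import f_classif

from .cv import CVConfig, PredictorFactory, classify_scores, stratified_folds
from .metrics import UNDEFINED, ConfusionMatrix, is_defined, mcc


@dataclass(frozen=True)
class OMCConfig:
    """Knobs of the nested selection.

    inner_k : folds of the inner merged CV run on each outer training set.
    k_min / k_step : the candidate grid is ``k_min, k_min+k_step, ...`` up
        to half the outer-training sample count (the per-fold reading of
        "top 2 to n/2"); ``k_cap`` optionally caps it at a fixed value
        instead. Step 1 is the exhaustive grid; a coarser step trades
        resolution for speed.
    trace_top : how many ranked features to snapshot into the trace.
    """

    inner_k: int = 10
    k_min: int = 2
    k_step: int = 1
    k_cap: Optional[int] = None
    trace_top: int = 50


@dataclass
class OMCTrace:
    """Record of one outer fold's selection decision."""

    ranking_head: pd.DataFrame  # top region of the outer-training ranking
    k_grid: List[int]
    inner_mcc: Dict[int, object]  # k -> inner merged MCC (or UNDEFINED)
    chosen_k: int
    selected_features: List[str]


def rank_features_anova(X: pd.DataFrame, y) -> pd.DataFrame:
    """Rank features by a one-way two-group ANOVA F-test on training data.

    Returns a DataFrame ``(feature_id, F, p)`` sorted ascending by p-value
    (low p = high discriminative power), ties broken by feature ID for
    determinism. Constant features get F=0, p=1 and rank last. For two
    groups the F statistic equals the square of the pooled-variance t
    statistic.
    """
    y = np.asarray(y).astype(int)
    if len(np.unique(y)) < 2:
        raise ValueError("ANOVA ranking needs both classes in the training labels")
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")  # constant features raise RuntimeWarnings
        f_stat, p_val = f_classif(X.to_numpy(dtype=float), y)
    f_stat = np.where(np.isfinite(f_stat), f_stat, 0.0)
    p_val = np.where(np.isfinite(p_val), p_val, 1.0)
    ranking = pd.DataFrame(
        {"feature_id": [str(c) for c in X.columns], "F": f_stat, "p": p_val}
    )
    ranking = ranking.sort_values(["p", "feature_id"], kind="mergesort").reset_index(
        drop=True
    )
    return ranking


def k_grid_for(n_train: int, config: OMCConfig, n_features: int) -> List[int]:
    """Candidate feature counts: k_min up to min(n_train // 2, caps)."""
    k_max = n_train // 2
    if config.k_cap is not None:
        k_max = min(k_max, config.k_cap)
    k_max = min(k_max, n_features)
    if k_max < config.k_min:
        return [min(config.k_min, n_features)]
    return list(range(config.k_min, k_max + 1, config.k_step))


def inner_select_k(
    X: pd.DataFrame,
    y,
    factory: PredictorFactory,
    k_grid: Sequence[int],
    inner_k: int,
    seed: int,
    threshold: float = 0.5,
) -> Tuple[int, Dict[int, object]]:
    """Choose the top-k feature count by inner merged-CV MCC.

    For every inner fold the ANOVA ranking is recomputed on that fold's
    training part (fully nested — selection never touches inner test data);
    for each candidate k the base model is fit on the top-k features and the
    held-out samples are scored. Per k, the inner out-of-sample predictions
    are merged and a single MCC computed. Returns the argmax k (ties →
    smallest k, for parsimony) and the per-k inner MCC map. If every k is
    undefined, falls back to the smallest k with a warning.
    """
    y = np.asarray(y).astype(int)
    folds = stratified_folds(y, inner_k, seed)
    n = len(y)
    scores_per_k = {k: np.full(n, np.nan) for k in k_grid}
    score_type = "probability"
    for fold in range(inner_k):
        test_mask = folds == fold
        train_mask = ~test_mask
        X_tr, y_tr = X.iloc[train_mask], y[train_mask]
        X_te = X.iloc[test_mask]
        ranking = rank_features_anova(X_tr, y_tr)
        ranked_ids = ranking["feature_id"].to_numpy()
        for k in k_grid:
            feats = ranked_ids[: min(k, len(ranked_ids))]
            predictor = factory(seed)
            predictor.fit(X_tr[feats], y_tr)
            scores_per_k[k][test_mask] = np.asarray(
                predictor.score_samples(X_te[feats]), dtype=float
            )
            score_type = predictor.score_type
    inner_mcc: Dict[int, object] = {}
    for k in k_grid:
        predicted = classify_scores(scores_per_k[k], score_type, threshold)
        inner_mcc[k] = mcc(ConfusionMatrix.from_predictions(y, predicted))
    defined = [(k, v) for k, v in inner_mcc.items() if is_defined(v)]
    if not defined:
        warnings.warn("all candidate k gave undefined inner MCC; falling back to smallest k")
        return min(k_grid), inner_mcc
    best_mcc = max(v for _, v in defined)
    chosen_k = min(k for k, v in defined if v == best_mcc)
    return chosen_k, inner_mcc


class OMCClassifier:
    """Predictor wrapping a base learner with OMC feature selection.

    ``fit`` performs the full nested selection on its training data and
    refits the base model on the chosen top-k features; ``score_samples``
    uses exactly those k features. The selection decision is recorded in
    ``trace_``.
    """

    def __init__(self, base_factory: PredictorFactory, config: OMCConfig, seed: int,
                 threshold: float = 0.5):
        self.base_factory = base_factory
        self.config = config
        self.seed = seed
        self.threshold = threshold
        self.score_type = "probability"
        self.trace_: Optional[OMCTrace] = None
        self._fitted = None
        self.selected_features_: Optional[List[str]] = None

    def fit(self, X: pd.DataFrame, y) -> "OMCClassifier":
        y = np.asarray(y).astype(int)
        ranking = rank_features_anova(X, y)
        k_grid = k_grid_for(len(y), self.config, X.shape[1])
        chosen_k, inner_mcc = inner_select_k(
            X, y, self.base_factory, k_grid, self.config.inner_k, self.seed,
            self.threshold,
        )
        selected = ranking["feature_id"].head(chosen_k).tolist()
        self._fitted = self.base_factory(self.seed)
        self._fitted.fit(X[selected], y)
        self.score_type = self._fitted.score_type
        self.selected_features_ = selected
        self.trace_ = OMCTrace(
            ranking_head=ranking.head(self.config.trace_top).copy(),
            k_grid=list(k_grid),
            inner_mcc=inner_mcc,
            chosen_k=chosen_k,
            selected_features=selected,
        )
        return self

    def score_samples(self, X: pd.DataFrame) -> np.ndarray:
        if self._fitted is None:
            raise RuntimeError("OMCClassifier is not fitted")
        return self._fitted.score_samples(X[self.selected_features_])


def make_omc_factory(
    base_factory: PredictorFactory, config: OMCConfig, threshold: float = 0.5
) -> PredictorFactory:
    """Factory producing a fresh OMC wrapper around a fresh base learner."""

    def build(seed: int) -> OMCClassifier:
        return OMCClassifier(base_factory, config, seed, threshold)

    return build


def feature_selection_frequency(traces: Sequence[OMCTrace]) -> pd.Series:
    """How often each feature was selected across outer folds/repetitions.

    Stable features surface at the top; this is how a consensus signature
    (like a small mRNA or CpG panel) is nominated. Sorted by descending
    count, ties by feature ID.
    """
    if not traces:
        raise ValueError("no traces given")
    counts: Dict[str, int] = {}
    for trace in traces:
        for feat in trace.selected_features:
            counts[feat] = counts.get(feat, 0) + 1
    series = pd.Series(counts, name="selection_count")
    return series.sort_index().sort_values(ascending=False, kind="mergesort")
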