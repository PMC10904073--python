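"""Merged stratified K-fold cross-validation engine.

With only ~70 patients, per-fold test sets are too small for a stable MCC,
so each metric is computed *once* from the merged out-of-sample predictions:
every sample is predicted exactly once per repetition (by the model trained
on the folds it does not belong to), the n predictions are pooled, and one
confusion matrix / one ROC-AUC is computed over all n samples. Per-fold
metrics are never averaged. The protocol is repeated with several seeds and
summarised by the median (mMCC), excluding undefined repetitions.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Callable, Dict, List, Optional, Protocol, Sequence, Tuple

import numpy as np
import pandas as pd
from sklearn.model_selection import StratifiedKFold

from .metrics import (
    UNDEFINED,
    ConfusionMatrix,
    is_defined,
    mcc,
    median_defined,
    roc_auc,
)


class Predictor(Protocol):
    """Contract every classifier in the pipeline satisfies.

    ``score_type`` is ``"probability"`` for learners that emit class
    probabilities (thresholded at the configured cutoff, default 0.5) and
    ``"margin"`` for decision-function scores (thresholded at 0). ROC-AUC is
    rank-invariant, so either score feeds it directly.
    """

    score_type: str

    def fit(self, X: pd.DataFrame, y: np.ndarray) -> "Predictor": ...

    def score_samples(self, X: pd.DataFrame) -> np.ndarray: ...


PredictorFactory = Callable[[int], "Predictor"]


@dataclass(frozen=True)
class CVConfig:
    """Cross-validation protocol: K folds, seeded repetitions, score cutoff."""

    k: int = 10
    seeds: Tuple[int, ...] = (0, 1, 2, 3, 4)
    threshold: float = 0.5

    def __post_init__(self) -> None:
        if self.k < 2:
            raise ValueError("K must be at least 2")
        if not self.seeds:
            raise ValueError("at least one repetition seed required")

    @property
    def n_repetitions(self) -> int:
        return len(self.seeds)


def stratified_folds(labels, k: int, seed: int) -> np.ndarray:
    """Assign each sample to one of *k* folds, preserving class balance.

    Per-fold class counts deviate from proportional allocation by at most
    one. ``k == n`` degenerates to leave-one-out, where stratification is
    vacuous and each fold is a singleton. Deterministic for a fixed seed.
    """
    labels = np.asarray(labels).astype(int)
    n = len(labels)
    if k > n:
        raise ValueError(f"K={k} exceeds the number of samples ({n})")
    assignment = np.empty(n, dtype=int)
    if k == n:
        order = np.random.default_rng(seed).permutation(n)
        assignment[order] = np.arange(n)
        return assignment
    if len(np.unique(labels)) < 2:
        raise ValueError("stratified folds need both classes present")
    skf = StratifiedKFold(n_splits=k, shuffle=True, random_state=seed)
    for fold, (_, test_idx) in enumerate(skf.split(np.zeros((n, 1)), labels)):
        assignment[test_idx] = fold
    return assignment


def classify_scores(scores: np.ndarray, score_type: str, threshold: float = 0.5) -> np.ndarray:
    """Hard classes from ranking scores: probabilities cut at *threshold*
    (above → responder), margins cut at zero."""
    cut = threshold if score_type == "probability" else 0.0
    return (np.asarray(scores, dtype=float) > cut).astype(int)


@dataclass
class RepetitionResult:
    """One CV repetition: merged predictions and the metrics computed once."""

    seed: int
    predictions: pd.DataFrame  # sample_id, fold, score, predicted_class, label
    mcc: object  # float or UNDEFINED
    auc: object  # float or UNDEFINED
    traces: List[object] = field(default_factory=list)  # one OMCTrace per fold, if any


@dataclass
class EvaluationResult:
    """All repetitions of one (dataset, model) evaluation plus summaries."""

    repetitions: List[RepetitionResult]

    @property
    def mcc_values(self) -> List[object]:
        return [r.mcc for r in self.repetitions]

    @property
    def auc_values(self) -> List[object]:
        return [r.auc for r in self.repetitions]

    @property
    def mmcc(self):
        return median_defined(self.mcc_values)[0]

    @property
    def median_auc(self):
        return median_defined(self.auc_values)[0]

    @property
    def n_undefined(self) -> int:
        return median_defined(self.mcc_values)[1]

    @property
    def traces(self) -> List[object]:
        return [t for r in self.repetitions for t in r.traces if t is not None]


def run_merged_cv(
    X: pd.DataFrame,
    y,
    factory: PredictorFactory,
    cv: CVConfig,
    sample_ids: Optional[Sequence[str]] = None,
) -> EvaluationResult:
    """Evaluate a model by merged stratified K-fold CV with seeded repetitions.

    For each repetition seed: build folds, train on each fold's complement,
    score the held-out fold, merge the n out-of-sample scores, threshold
    them into classes, and compute one MCC and one ROC-AUC over all n
    samples. The repetition seed also seeds the learner, so a repetition is
    a single reproducible unit.

    Parameters
    ----------
    X : DataFrame, samples x features (row order defines the label order)
    y : binary labels, 1 = responder
    factory : callable(seed) returning a fresh unfitted predictor
    """
    y = np.asarray(y).astype(int)
    if len(X) != len(y):
        raise ValueError("X and y length mismatch")
    if sample_ids is None:
        sample_ids = [str(s) for s in X.index]
    repetitions = []
    for seed in cv.seeds:
        folds = stratified_folds(y, cv.k, seed)
        scores = np.full(len(y), np.nan)
        score_type = None
        trace_list: List[object] = []
        for fold in range(cv.k):
            test_mask = folds == fold
            train_mask = ~test_mask
            predictor = factory(seed)
            try:
                predictor.fit(X.iloc[train_mask], y[train_mask])
                fold_scores = np.asarray(
                    predictor.score_samples(X.iloc[test_mask]), dtype=float
                )
            except Exception as exc:  # noqa: BLE001 - re-raise with fold context
                raise RuntimeError(
                    f"model failed on fold {fold} of repetition seed {seed}: {exc}"
                ) from exc
            scores[test_mask] = fold_scores
            score_type = predictor.score_type
            trace_list.append(getattr(predictor, "trace_", None))
        if np.isnan(scores).any():
            raise AssertionError("merged-CV contract violated: unscored samples")
        predicted = classify_scores(scores, score_type, cv.threshold)
        cm = ConfusionMatrix.from_predictions(y, predicted)
        predictions = pd.DataFrame(
            {
                "sample_id": list(sample_ids),
                "seed": seed,
                "fold": folds,
                "score": scores,
                "predicted_class": predicted,
                "label": y,
            }
        )
        repetitions.append(
            RepetitionResult(
                seed=seed,
                predictions=predictions,
                mcc=mcc(cm),
                auc=roc_auc(scores, y),
                traces=trace_list,
            )
        )
    return EvaluationResult(repetitions)


def summarize_repetitions(mcc_values: Sequence) -> Tuple[object, int]:
    """Median MCC across repetitions, excluding undefined ones.

    Returns ``(median, n_undefined)``; the median is the undefined sentinel
    when every repetition is undefined (rendered as a blank cell).
    """
    return median_defined(mcc_values)


@dataclass
class GridCell:
    profile: str
    algorithm: str
    mode: str
    result: Optional[EvaluationResult]
    error: Optional[str] = None


@dataclass
class EvaluationGrid:
    """Profile x (algorithm, mode) evaluation matrix (the mMCC heatmap)."""

    cells: List[GridCell]

    def to_frame(self) -> pd.DataFrame:
        """Long-format table: one row per (cell, repetition seed)."""
        rows = []
        for cell in self.cells:
            if cell.result is None:
                continue
            for rep in cell.result.repetitions:
                rows.append(
                    {
                        "profile": cell.profile,
                        "algorithm": cell.algorithm,
                        "mode": cell.mode,
                        "seed": rep.seed,
                        "mcc": rep.mcc if is_defined(rep.mcc) else np.nan,
                        "mcc_undefined": not is_defined(rep.mcc),
                        "auc": rep.auc if is_defined(rep.auc) else np.nan,
                    }
                )
        return pd.DataFrame(rows)

    def summary_frame(self) -> pd.DataFrame:
        """One row per cell: mMCC, median AUC, undefined counts, errors."""
        rows = []
        for cell in self.cells:
            row = {
                "profile": cell.profile,
                "algorithm": cell.algorithm,
                "mode": cell.mode,
                "error": cell.error,
            }
            if cell.result is None:
                row.update(
                    {"mmcc": np.nan, "median_auc": np.nan, "n_undefined": np.nan, "blank": True}
                )
            else:
                mmcc = cell.result.mmcc
                mauc = cell.result.median_auc
                row.update(
                    {
                        "mmcc": mmcc if is_defined(mmcc) else np.nan,
                        "median_auc": mauc if is_defined(mauc) else np.nan,
                        "n_undefined": cell.result.n_undefined,
                        "blank": not is_defined(mmcc),
                    }
                )
            rows.append(row)
        return pd.DataFrame(rows)


def evaluate_grid(
    datasets: Dict[str, Tuple[pd.DataFrame, np.ndarray]],
    model_specs: Sequence,
    cv: CVConfig,
    omc_config=None,
) -> EvaluationGrid:
    """Run merged CV for every (profile, algorithm, mode) cell.

    *datasets* maps profile name to ``(X, y)``. Cells are independent: the
    grid is identical regardless of execution order because every cell
    derives its randomness only from the shared repetition seeds. Per-cell
    failures are recorded and the grid completes.
    """
    from .models import make_model  # local import to avoid a cycle

    cells = []
    for profile_name, (X, y) in datasets.items():
        for spec in model_specs:
            factory = make_model(spec, omc_config=omc_config)
            try:
                result = run_merged_cv(X, y, factory, cv)
                cells.append(GridCell(profile_name, spec.algorithm_id, spec.mode, result))
            except Exception as exc:  # noqa: BLE001 - grid completes, failure recorded
                warnings.warn(
                    f"grid cell ({profile_name}, {spec.algorithm_id}, {spec.mode}) failed: {exc}"
                )
                cells.append(
                    GridCell(profile_name, spec.algorithm_id, spec.mode, None, error=str(exc))
                )
    return EvaluationGrid(cells)
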