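"""Classifier registry, single-gene baseline, and the class-permutation null.

Eight algorithms span tree, ensemble, boosting, linear, kernel and
instance-based learners: CART, random forest, XGBoost, LightGBM, logistic
regression, linear- and RBF-kernel SVC, and k-nearest neighbours. Each runs
in two modes — on all features, or behind OMC nested-CV feature selection —
giving 16 model variants per molecular profile. Hyperparameters are the
underlying libraries' defaults, snapshotted verbatim into the run manifest:
with no tuning reported anywhere, reproducibility comes from recording, not
guessing.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, List, Optional, Sequence

import numpy as np
import pandas as pd
from lightgbm import LGBMClassifier
from sklearn.ensemble import RandomForestClassifier
from sklearn.linear_model import LogisticRegression
from sklearn.neighbors import KNeighborsClassifier
from sklearn.svm import SVC
from sklearn.tree import DecisionTreeClassifier
from xgboost import XGBClassifier

from .cv import CVConfig, EvaluationResult, run_merged_cv
from .metrics import is_defined
from .omc import OMCConfig, make_omc_factory

ALGORITHM_IDS = (
    "cart",
    "rf",
    "xgboost",
    "lgbm",
    "logistic",
    "svc_linear",
    "svc_rbf",
    "knn",
)

MODES = ("all_features", "omc")

#: learners whose ranking score is a class probability (cut at 0.5) vs a
#: decision margin (cut at 0); AUC is rank-invariant so either feeds it.
_SCORE_TYPES = {
    "cart": "probability",
    "rf": "probability",
    "xgboost": "probability",
    "lgbm": "probability",
    "logistic": "probability",
    "knn": "probability",
    "svc_linear": "margin",
    "svc_rbf": "margin",
}


@dataclass(frozen=True)
class ModelSpec:
    """One cell of the algorithm panel: which learner, which mode.

    ``seed=None`` means the learner is seeded by the CV repetition seed, so
    folds and stochastic fitting form one reproducible unit.
    """

    algorithm_id: str
    mode: str = "all_features"
    hyperparameters: tuple = ()  # ((name, value), ...) overrides, rarely used
    seed: Optional[int] = None

    def __post_init__(self) -> None:
        if self.algorithm_id not in ALGORITHM_IDS:
            raise ValueError(
                f"unknown algorithm {self.algorithm_id!r}; valid ids: {', '.join(ALGORITHM_IDS)}"
            )
        if self.mode not in MODES:
            raise ValueError(f"unknown mode {self.mode!r}; valid modes: {', '.join(MODES)}")


def _build_estimator(algorithm_id: str, seed: int, overrides: Dict):
    params = dict(overrides)
    if algorithm_id == "cart":
        return DecisionTreeClassifier(random_state=seed, **params)
    if algorithm_id == "rf":
        return RandomForestClassifier(random_state=seed, **params)
    if algorithm_id == "xgboost":
        params.setdefault("n_jobs", 1)
        params.setdefault("verbosity", 0)
        return XGBClassifier(random_state=seed, **params)
    if algorithm_id == "lgbm":
        params.setdefault("n_jobs", 1)
        params.setdefault("verbose", -1)
        return LGBMClassifier(random_state=seed, **params)
    if algorithm_id == "logistic":
        return LogisticRegression(**params)
    if algorithm_id == "svc_linear":
        params.setdefault("kernel", "linear")
        return SVC(**params)
    if algorithm_id == "svc_rbf":
        return SVC(**params)
    if algorithm_id == "knn":
        return KNeighborsClassifier(**params)
    raise ValueError(f"unknown algorithm {algorithm_id!r}")


class SklearnPredictor:
    """Adapter giving any sklearn-style estimator the pipeline's contract."""

    def __init__(self, estimator, score_type: str):
        self.estimator = estimator
        self.score_type = score_type

    def fit(self, X: pd.DataFrame, y) -> "SklearnPredictor":
        self.estimator.fit(X.to_numpy(dtype=float), np.asarray(y).astype(int))
        return self

    def score_samples(self, X: pd.DataFrame) -> np.ndarray:
        arr = X.to_numpy(dtype=float)
        if self.score_type == "probability":
            proba = self.estimator.predict_proba(arr)
            classes = list(self.estimator.classes_)
            if 1 in classes:
                return proba[:, classes.index(1)]
            return np.zeros(len(arr))  # single-class training set: never responder
        return np.asarray(self.estimator.decision_function(arr), dtype=float)

    def get_params(self) -> Dict:
        return self.estimator.get_params()


def make_model(spec: ModelSpec, omc_config: Optional[OMCConfig] = None,
               threshold: float = 0.5):
    """Predictor factory for *spec*: ``factory(seed) -> fresh predictor``.

    OMC-mode specs wrap the base learner in the nested-CV selector.
    """
    overrides = dict(spec.hyperparameters)
    score_type = _SCORE_TYPES[spec.algorithm_id]

    def base_factory(seed: int) -> SklearnPredictor:
        effective = spec.seed if spec.seed is not None else seed
        return SklearnPredictor(
            _build_estimator(spec.algorithm_id, effective, overrides), score_type
        )

    if spec.mode == "omc":
        return make_omc_factory(base_factory, omc_config or OMCConfig(), threshold)
    return base_factory


def model_manifest(specs: Sequence[ModelSpec]) -> List[Dict]:
    """Verbatim hyperparameter snapshot for every spec (run manifest)."""
    entries = []
    for spec in specs:
        est = _build_estimator(spec.algorithm_id, 0, dict(spec.hyperparameters))
        entries.append(
            {
                "algorithm_id": spec.algorithm_id,
                "mode": spec.mode,
                "score_type": _SCORE_TYPES[spec.algorithm_id],
                "hyperparameters": {k: repr(v) for k, v in sorted(est.get_params().items())},
            }
        )
    return entries


def full_panel(modes: Sequence[str] = MODES) -> List[ModelSpec]:
    """The 16 specs (8 algorithms x 2 modes) of the standard panel."""
    return [ModelSpec(alg, mode) for alg in ALGORITHM_IDS for mode in modes]


def single_gene_model(
    X: pd.DataFrame,
    y,
    feature_id: str,
    algorithm_ids: Sequence[str],
    cv: CVConfig,
) -> Dict[str, EvaluationResult]:
    """Merged-CV evaluation of a single named feature (the hENT1-style baseline).

    Restricts the matrix to one column and runs the identical merged-CV
    protocol, so a literature single-gene marker competes on exactly the
    same footing as the multivariate models.
    """
    if feature_id not in X.columns:
        raise KeyError(f"feature {feature_id!r} not present in the profile")
    X_single = X[[feature_id]]
    results = {}
    for alg in algorithm_ids:
        factory = make_model(ModelSpec(alg, "all_features"))
        results[alg] = run_merged_cv(X_single, y, factory, cv)
    return results


@dataclass
class NullDistribution:
    """Class-permutation null of the merged-CV mMCC.

    ``p_value`` uses the +1-corrected empirical formula
    ``(1 + #{null >= observed}) / (1 + n_perm)`` and is therefore never 0.
    Undefined null summaries are stored as NaN and never count as
    exceedances.
    """

    observed_mmcc: float
    null_mmcc: np.ndarray
    n_perm: int

    @property
    def p_value(self) -> float:
        exceed = int(np.nansum(self.null_mmcc >= self.observed_mmcc))
        return (1 + exceed) / (1 + self.n_perm)


def permutation_null(
    X: pd.DataFrame,
    y,
    spec: ModelSpec,
    cv: CVConfig,
    n_perm: int = 50,
    seed: int = 0,
    omc_config: Optional[OMCConfig] = None,
) -> NullDistribution:
    """Estimate chance-level mMCC by rerunning the full pipeline on shuffled labels.

    Each permutation shuffles the labels once (seeded) and reruns the entire
    protocol — including OMC feature selection when the spec is in OMC mode,
    so selection bias is part of the null — recording the summary mMCC.
    """
    if n_perm < 1:
        raise ValueError("n_perm must be >= 1")
    y = np.asarray(y).astype(int)
    factory = make_model(spec, omc_config=omc_config)
    observed = run_merged_cv(X, y, factory, cv).mmcc
    rng = np.random.default_rng(seed)
    null_values = np.full(n_perm, np.nan)
    for i in range(n_perm):
        y_perm = rng.permutation(y)
        mmcc = run_merged_cv(X, y_perm, factory, cv).mmcc
        if is_defined(mmcc):
            null_values[i] = mmcc
    obs = observed if is_defined(observed) else np.nan
    return NullDistribution(observed_mmcc=obs, null_mmcc=null_values, n_perm=n_perm)
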