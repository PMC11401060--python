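"""Gradient-boosting training, sample weighting, greedy forward feature
selection, and the generic + per-protein model bank.

Default hyperparameters (n_estimators=80, learning_rate=0.1, max_depth=7)
come from an upstream halving random search and are shipped as fixed
configuration; the weighted models up-weight the target protein's rows
at 11:1.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .dataset import Dataset, FeatureMatrix
from .evaluation import mcc_score

__all__ = [
    "ModelConfig",
    "WeightConfig",
    "TrainedModel",
    "ModelBank",
    "DEFAULT_GENERIC_ROUTED",
    "make_weights",
    "train",
    "greedy_select",
    "build_bank",
]

# proteins routed to the generic model by default (weighted models degrade)
DEFAULT_GENERIC_ROUTED = frozenset({"APOE", "PSEN2"})

_ALGORITHMS = {
    "gradient_boosting": "GradientBoostingClassifier",
    "random_forest": "RandomForestClassifier",
    "extra_trees": "ExtraTreesClassifier",
    "adaboost": "AdaBoostClassifier",
    "decision_tree": "DecisionTreeClassifier",
    "logistic_regression": "LogisticRegression",
}


@dataclass(frozen=True)
class ModelConfig:
    algorithm: str = "gradient_boosting"
    n_estimators: int = 80
    learning_rate: float = 0.1
    max_depth: int = 7
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_estimators <= 0 or self.learning_rate <= 0 or self.max_depth <= 0:
            raise ValueError("hyperparameters must be positive")
        if self.algorithm not in _ALGORITHMS:
            raise ValueError(f"unknown algorithm {self.algorithm!r}")

    def estimator(self):
        if self.algorithm == "gradient_boosting":
            from sklearn.ensemble import GradientBoostingClassifier

            return GradientBoostingClassifier(
                n_estimators=self.n_estimators,
                learning_rate=self.learning_rate,
                max_depth=self.max_depth,
                random_state=self.seed,
            )
        if self.algorithm == "random_forest":
            from sklearn.ensemble import RandomForestClassifier

            return RandomForestClassifier(
                n_estimators=self.n_estimators, max_depth=self.max_depth, random_state=self.seed
            )
        if self.algorithm == "extra_trees":
            from sklearn.ensemble import ExtraTreesClassifier

            return ExtraTreesClassifier(
                n_estimators=self.n_estimators, max_depth=self.max_depth, random_state=self.seed
            )
        if self.algorithm == "adaboost":
            from sklearn.ensemble import AdaBoostClassifier

            return AdaBoostClassifier(
                n_estimators=self.n_estimators,
                learning_rate=self.learning_rate,
                random_state=self.seed,
            )
        if self.algorithm == "decision_tree":
            from sklearn.tree import DecisionTreeClassifier

            return DecisionTreeClassifier(max_depth=self.max_depth, random_state=self.seed)
        from sklearn.linear_model import LogisticRegression

        return LogisticRegression(max_iter=2000, random_state=self.seed)


@dataclass(frozen=True)
class WeightConfig:
    target_protein: str | None = None
    w_target: float = 11.0
    w_other: float = 1.0

    def __post_init__(self) -> None:
        if self.w_target <= 0 or self.w_other <= 0:
            raise ValueError("sample weights must be positive")


def make_weights(groups: list[tuple[str, int]], config: WeightConfig) -> np.ndarray:
    """Per-row sample weights: target-protein rows w_target, rest w_other.

    With no target protein configured, every weight is 1.0 regardless of
    ``w_other`` (the weighting is a no-op).
    """
    if config.target_protein is None:
        return np.ones(len(groups))
    proteins = [g[0] for g in groups]
    if config.target_protein not in proteins:
        warnings.warn(f"target protein {config.target_protein} absent from the dataset")
        return np.ones(len(groups))
    return np.array(
        [config.w_target if p == config.target_protein else config.w_other for p in proteins]
    )


@dataclass
class TrainedModel:
    """A fitted classifier plus the exact configuration that produced it."""

    estimator: object
    feature_names: list[str]
    config: ModelConfig
    weight_config: WeightConfig | None = None

    def predict_proba(self, X: pd.DataFrame) -> np.ndarray:
        """Probability of the Disease-causing class, row-aligned with X."""
        cols = X[self.feature_names]  # invariant to external column order
        proba = self.estimator.predict_proba(cols.to_numpy())
        classes = list(self.estimator.classes_)
        return proba[:, classes.index(1.0)]

    def predict(self, X: pd.DataFrame, cutoff: float = 0.5) -> np.ndarray:
        return (self.predict_proba(X) >= cutoff).astype(int)

    def save(self, path) -> None:
        """Serialize the model with config, seed, and feature list embedded."""
        import joblib

        joblib.dump(
            {
                "estimator": self.estimator,
                "feature_names": self.feature_names,
                "config": self.config,
                "weight_config": self.weight_config,
            },
            path,
        )

    @classmethod
    def load(cls, path) -> "TrainedModel":
        import joblib

        payload = joblib.load(path)
        return cls(
            payload["estimator"],
            payload["feature_names"],
            payload["config"],
            payload.get("weight_config"),
        )


def train(
    matrix: FeatureMatrix,
    config: ModelConfig | None = None,
    weights: np.ndarray | None = None,
) -> TrainedModel:
    """Fit a classifier on labeled rows of ``matrix``.

    Deterministic for a fixed seed, data, and weights; single-class
    labels are an error.
    """
    config = config or ModelConfig()
    mask = matrix.y.notna()
    X = matrix.X[mask]
    y = matrix.y[mask]
    if y.nunique() < 2:
        raise ValueError("training labels contain a single class")
    est = config.estimator()
    w = None if weights is None else np.asarray(weights, float)[mask.to_numpy()]
    est.fit(X.to_numpy(), y.to_numpy(), sample_weight=w)
    return TrainedModel(est, list(X.columns), config)


def greedy_select(
    train_matrix: FeatureMatrix,
    val_matrix: FeatureMatrix,
    config: ModelConfig | None = None,
    tolerance: float = 1e-6,
    max_features: int = 30,
    candidates: list[str] | None = None,
) -> tuple[list[str], list[float]]:
    """Forward feature selection maximizing validation MCC.

    At each step the single feature whose addition maximizes validation
    MCC (model refit from scratch) is added; ties break by column order.
    Stops when no candidate improves MCC by more than ``tolerance`` or
    ``max_features`` is reached. Returns the ordered selection and the
    per-step validation MCC.
    """
    config = config or ModelConfig()
    pool = list(candidates) if candidates is not None else list(train_matrix.X.columns)
    if not pool:
        raise ValueError("empty candidate feature pool")
    selected: list[str] = []
    scores: list[float] = []
    best_so_far = -np.inf
    val_y = val_matrix.y[val_matrix.y.notna()].to_numpy()
    while len(selected) < max_features:
        step_best = None
        step_score = -np.inf
        for feat in pool:
            if feat in selected:
                continue
            cols = selected + [feat]
            model = train(train_matrix.restrict(cols), config)
            pred = model.predict(val_matrix.restrict(cols).X[val_matrix.y.notna()])
            score = mcc_score(val_y, pred)
            if score > step_score + 1e-12:  # strict improvement; ties keep earlier column
                step_best, step_score = feat, score
        if step_best is None or step_score <= best_so_far + tolerance:
            break
        selected.append(step_best)
        scores.append(step_score)
        best_so_far = step_score
    if not selected:  # never return an empty model: keep the best single feature
        raise ValueError("no feature improved validation MCC above the tolerance")
    return selected, scores


@dataclass
class ModelBank:
    """One generic model, per-protein weighted models, and the routing rule."""

    generic: TrainedModel
    weighted: dict[str, TrainedModel] = field(default_factory=dict)
    routed_to_generic: frozenset[str] = DEFAULT_GENERIC_ROUTED

    def resolve(self, protein_id: str) -> tuple[TrainedModel, str]:
        """Model for a protein and the route taken ('generic' or 'weighted')."""
        if protein_id in self.routed_to_generic or protein_id not in self.weighted:
            return self.generic, "generic"
        return self.weighted[protein_id], "weighted"


def build_bank(
    matrix: FeatureMatrix,
    protein_list: list[str],
    config: ModelConfig | None = None,
    weight_config: WeightConfig | None = None,
    routed_to_generic: frozenset[str] | None = None,
) -> ModelBank:
    """Train the generic model plus one weighted model per listed protein.

    Proteins without training rows keep no weighted model and resolve to
    the generic one.
    """
    config = config or ModelConfig()
    base_weights = weight_config or WeightConfig()
    generic = train(matrix, config)
    weighted: dict[str, TrainedModel] = {}
    present = {g[0] for g in matrix.groups}
    for pid in protein_list:
        if pid not in present:
            warnings.warn(f"{pid}: no training mutations; routed to the generic model")
            continue
        wc = WeightConfig(pid, base_weights.w_target, base_weights.w_other)
        w = make_weights(matrix.groups, wc)
        model = train(matrix, config, weights=w)
        model.weight_config = wc
        weighted[pid] = model
    routing = DEFAULT_GENERIC_ROUTED if routed_to_generic is None else routed_to_generic
    return ModelBank(generic, weighted, frozenset(routing))
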