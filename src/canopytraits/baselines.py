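"""Shallow comparison regressors: SVR and random forest on screened features.

One single-output model per trait (only the CNN is multi-output).  Features
are standardized inside the fit using training statistics only; the scaler is
stored in the fitted results and reused at prediction time.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Mapping

import numpy as np
import pandas as pd
from sklearn.ensemble import RandomForestRegressor
from sklearn.preprocessing import StandardScaler
from sklearn.svm import SVR

from .exceptions import DomainError

logger = logging.getLogger(__name__)

__all__ = ["BaselineModelSpec", "TraitBaselineModel", "TraitBaselineResults",
           "fit_baseline", "predict_baseline"]

_DEFAULT_HYPERS = {
    "svr": {"kernel": "rbf", "C": 10.0, "epsilon": 0.1},
    "rf": {"n_trees": 500, "max_depth": None, "min_leaf": 1},
}


@dataclass(frozen=True)
class BaselineModelSpec:
    kind: str  # "svr" or "rf"
    hyperparameters: Mapping[str, object] = field(default_factory=dict)
    rng_seed: int = 0

    def __post_init__(self) -> None:
        if self.kind not in ("svr", "rf"):
            raise DomainError(f"unknown baseline kind {self.kind!r}")
        hp = self.resolved_hyperparameters()
        if self.kind == "svr" and (hp["C"] <= 0 or hp["epsilon"] <= 0):
            raise DomainError("SVR C and epsilon must be positive")
        if self.kind == "rf" and hp["n_trees"] <= 0:
            raise DomainError("RF n_trees must be positive")

    def resolved_hyperparameters(self) -> dict:
        hp = dict(_DEFAULT_HYPERS[self.kind])
        hp.update(self.hyperparameters)
        return hp


class TraitBaselineModel:
    """Single-trait shallow regressor built from a feature table."""

    def __init__(self, features: pd.DataFrame, target: pd.Series,
                 spec: BaselineModelSpec) -> None:
        if features.isna().any().any() or pd.Series(target).isna().any():
            raise DomainError("missing values in features or target")
        if len(features) < 10:
            raise DomainError("need at least 10 training samples")
        if len(features) != len(target):
            raise DomainError("feature table and target lengths differ")
        self.features = features
        self.target = np.asarray(target, dtype=float)
        self.spec = spec

    def fit(self) -> "TraitBaselineResults":
        hp = self.spec.resolved_hyperparameters()
        if self.spec.kind == "svr":
            est = SVR(kernel=hp["kernel"], C=hp["C"], epsilon=hp["epsilon"])
        else:
            est = RandomForestRegressor(
                n_estimators=int(hp["n_trees"]), max_depth=hp["max_depth"],
                min_samples_leaf=int(hp["min_leaf"]),
                random_state=self.spec.rng_seed)
        scaler = StandardScaler().fit(self.features.to_numpy(dtype=float))
        est.fit(scaler.transform(self.features.to_numpy(dtype=float)),
                self.target)
        return TraitBaselineResults(spec=self.spec, estimator=est,
                                    scaler=scaler,
                                    columns=tuple(self.features.columns))


class TraitBaselineResults:
    """Fitted shallow regressor with its feature scaler and column order."""

    def __init__(self, spec: BaselineModelSpec, estimator, scaler: StandardScaler,
                 columns: tuple[str, ...]) -> None:
        self.spec = spec
        self.estimator = estimator
        self.scaler = scaler
        self.columns = columns

    def predict(self, features: pd.DataFrame) -> np.ndarray:
        """Trait predictions; negatives clamped to 0 (count logged)."""
        missing = [c for c in self.columns if c not in features.columns]
        if missing:
            raise DomainError(f"missing feature columns: {missing}")
        x = features[list(self.columns)].to_numpy(dtype=float)
        pred = self.estimator.predict(self.scaler.transform(x))
        if not np.isfinite(pred).all():
            raise DomainError("non-finite baseline prediction")
        n_neg = int((pred < 0).sum())
        if n_neg:
            logger.info("clamped %d negative baseline predictions to 0", n_neg)
            pred = np.clip(pred, 0.0, None)
        return pred

    def summary(self) -> str:
        hp = self.spec.resolved_hyperparameters()
        return (f"{self.spec.kind.upper()} baseline on {len(self.columns)} "
                f"features; hyperparameters: {hp}")


def fit_baseline(spec: BaselineModelSpec, features: pd.DataFrame,
                 target: pd.Series) -> TraitBaselineResults:
    return TraitBaselineModel(features, target, spec).fit()


def predict_baseline(fitted: TraitBaselineResults,
                     features: pd.DataFrame) -> np.ndarray:
    return fitted.predict(features)
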