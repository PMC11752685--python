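"""Per-transporter IC50 regression panel.

Eight hepatic transporters whose inhibition is mechanistically linked to
cholestasis — BCRP, MRP2, MRP3, MRP4, OATP1B1, OATP1B3, BSEP and P-gp —
each get a regressor of a fixed algorithm: random forest for BCRP, MRP2,
MRP4, OATP1B1 and P-gp; an RBF support vector machine for MRP3 and
OATP1B3; gradient-boosted trees (XGBoost) for BSEP.

Models are trained on pIC50 (-log10 of the molar IC50); predictions are
converted back to µM via ``ic50_uM = 10**(6 - pic50)``, so the returned
IC50 is always positive.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Dict, Optional

import joblib
import numpy as np
from sklearn.ensemble import RandomForestRegressor
from sklearn.model_selection import GridSearchCV, KFold
from sklearn.pipeline import Pipeline
from sklearn.preprocessing import StandardScaler
from sklearn.svm import SVR
from xgboost import XGBRegressor

from .descriptors import FEATURE_SPEC_ID, VECTOR_LENGTH

TRANSPORTERS = ("BCRP", "MRP2", "MRP3", "MRP4", "OATP1B1", "OATP1B3", "BSEP", "P-gp")

#: transporter -> learning algorithm, fixed by design
DEFAULT_ALGORITHM_MAP: Dict[str, str] = {
    "BCRP": "random_forest",
    "MRP2": "random_forest",
    "MRP3": "svm",
    "MRP4": "random_forest",
    "OATP1B1": "random_forest",
    "OATP1B3": "svm",
    "BSEP": "xgboost",
    "P-gp": "random_forest",
}

MIN_TRAINING_SIZE = 20


class UntrainedTransporterError(RuntimeError):
    """Prediction requested for a transporter with no fitted estimator."""


@dataclass(frozen=True)
class IC50Prediction:
    """Predicted half-maximal inhibitory concentration for one transporter."""

    transporter: str
    pic50: float

    @property
    def ic50_uM(self) -> float:
        return float(10.0 ** (6.0 - self.pic50))


def pic50_to_ic50_uM(pic50):
    """pIC50 (-log10 molar) -> IC50 in µM."""
    return 10.0 ** (6.0 - np.asarray(pic50, dtype=float))


def ic50_uM_to_pic50(ic50_uM):
    """IC50 in µM -> pIC50 (-log10 molar)."""
    ic50 = np.asarray(ic50_uM, dtype=float)
    if np.any(ic50 <= 0):
        raise ValueError("IC50 must be > 0 to take its log")
    return 6.0 - np.log10(ic50)


def _make_estimator(algorithm: str, seed: int):
    if algorithm == "random_forest":
        return RandomForestRegressor(n_estimators=500, random_state=seed, n_jobs=1)
    if algorithm == "svm":
        grid = {"svr__C": [10.0, 100.0, 1000.0], "svr__gamma": ["scale", 1e-3, 1e-4]}
        pipe = Pipeline([("scale", StandardScaler()), ("svr", SVR(kernel="rbf"))])
        return GridSearchCV(
            pipe, grid, cv=KFold(n_splits=5, shuffle=True, random_state=seed), n_jobs=1
        )
    if algorithm == "xgboost":
        return XGBRegressor(
            n_estimators=300,
            max_depth=6,
            learning_rate=0.05,
            random_state=seed,
            n_jobs=1,
            verbosity=0,
        )
    raise ValueError(f"unknown algorithm {algorithm!r}")


@dataclass
class TransporterPanel:
    """The eight-transporter QSAR panel with its algorithm assignments."""

    algorithm_map: Dict[str, str] = field(default_factory=lambda: dict(DEFAULT_ALGORITHM_MAP))
    estimators: Dict[str, object] = field(default_factory=dict)
    feature_spec_id: str = FEATURE_SPEC_ID
    seeds: Dict[str, int] = field(default_factory=dict)

    @property
    def transporters(self) -> tuple:
        return tuple(self.algorithm_map)

    def is_trained(self, transporter: str) -> bool:
        return transporter in self.estimators

    def train(self, transporter: str, features: np.ndarray, pic50: np.ndarray, seed: int = 0):
        """Fit the mapped algorithm on (features, pIC50) pairs.

        Requires at least ``MIN_TRAINING_SIZE`` samples with finite targets
        and feature rows of the panel's fixed length.  Reproducible under
        ``seed``.  Returns the fitted estimator.
        """
        if transporter not in self.algorithm_map:
            raise KeyError(f"unknown transporter {transporter!r}")
        X = np.asarray(features, dtype=float)
        y = np.asarray(pic50, dtype=float)
        if X.ndim != 2 or X.shape[0] != y.shape[0]:
            raise ValueError("features and targets are misaligned")
        if X.shape[0] < MIN_TRAINING_SIZE:
            raise ValueError(
                f"need >= {MIN_TRAINING_SIZE} training pairs, got {X.shape[0]}"
            )
        if X.shape[1] != VECTOR_LENGTH:
            raise ValueError(
                f"feature length {X.shape[1]} != expected {VECTOR_LENGTH} "
                f"for spec {self.feature_spec_id!r}"
            )
        if not np.all(np.isfinite(y)):
            raise ValueError("non-finite pIC50 targets")
        est = _make_estimator(self.algorithm_map[transporter], seed)
        est.fit(X, y)
        self.estimators[transporter] = est
        self.seeds[transporter] = seed
        return est

    def predict_pic50(self, transporter: str, features: np.ndarray) -> np.ndarray:
        if transporter not in self.algorithm_map:
            raise KeyError(f"unknown transporter {transporter!r}")
        if transporter not in self.estimators:
            raise UntrainedTransporterError(
                f"{transporter}: no fitted estimator; train it first"
            )
        X = np.atleast_2d(np.asarray(features, dtype=float))
        if X.shape[1] != VECTOR_LENGTH:
            raise ValueError("feature length mismatch with panel feature spec")
        return np.asarray(self.estimators[transporter].predict(X), dtype=float)

    def predict_ic50(self, transporter: str, features: np.ndarray) -> IC50Prediction:
        """Single-compound IC50 prediction (µM via the pIC50 transform)."""
        pic50 = float(self.predict_pic50(transporter, features)[0])
        return IC50Prediction(transporter=transporter, pic50=pic50)

    # -- persistence ----------------------------------------------------

    def save(self, directory) -> None:
        """Persist fitted estimators plus a manifest to ``directory``."""
        directory = Path(directory)
        directory.mkdir(parents=True, exist_ok=True)
        manifest = {
            "feature_spec_id": self.feature_spec_id,
            "algorithm_map": self.algorithm_map,
            "seeds": self.seeds,
            "trained": sorted(self.estimators),
        }
        (directory / "panel_manifest.json").write_text(json.dumps(manifest, indent=2))
        for transporter, est in self.estimators.items():
            joblib.dump(est, directory / f"{_slug(transporter)}.joblib")

    @classmethod
    def load(cls, directory) -> "TransporterPanel":
        directory = Path(directory)
        manifest = json.loads((directory / "panel_manifest.json").read_text())
        panel = cls(
            algorithm_map=dict(manifest["algorithm_map"]),
            feature_spec_id=manifest["feature_spec_id"],
            seeds={k: int(v) for k, v in manifest.get("seeds", {}).items()},
        )
        for transporter in manifest["trained"]:
            panel.estimators[transporter] = joblib.load(
                directory / f"{_slug(transporter)}.joblib"
            )
        return panel


def _slug(transporter: str) -> str:
    return transporter.replace("-", "").lower()


def default_panel() -> TransporterPanel:
    """The untrained eight-transporter panel with the fixed algorithm map."""
    return TransporterPanel()


def train_transporter_model(panel, transporter, features, pic50, seed=0):
    """Functional wrapper around :meth:`TransporterPanel.train`."""
    return panel.train(transporter, features, pic50, seed=seed)


def predict_ic50(panel, transporter, features) -> IC50Prediction:
    """Functional wrapper around :meth:`TransporterPanel.predict_ic50`."""
    return panel.predict_ic50(transporter, features)
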