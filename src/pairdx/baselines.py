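"""Comparator classifiers run on the same retained-pair features.

Four standard families with fixed hyperparameters: a multilayer perceptron,
logistic regression, a random forest and a linear support-vector machine.
These delegate to scikit-learn — they are benchmarks, not the contribution —
while the SDSAE itself is implemented in-repo.  Unstated hyperparameters take
the scikit-learn defaults, which ``baseline_provenance`` records verbatim.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from sklearn.ensemble import RandomForestClassifier
from sklearn.linear_model import LogisticRegression
from sklearn.neural_network import MLPClassifier
from sklearn.svm import SVC

from .metrics import DiagnosticReport

__all__ = ["BaselineSpec", "BASELINES", "fit_baseline", "evaluate_all", "baseline_provenance"]


@dataclass(frozen=True)
class BaselineSpec:
    family: str
    hyperparameters: dict = field(default_factory=dict)


BASELINES: dict[str, BaselineSpec] = {
    "mlp": BaselineSpec(
        "multilayer-perceptron",
        {
            "hidden_layer_sizes": (200, 100),
            "solver": "sgd",
            "early_stopping": True,
            "alpha": 0.1,
            "validation_fraction": 0.20,
        },
    ),
    "lr": BaselineSpec("logistic-regression", {"solver": "lbfgs"}),
    "rf": BaselineSpec(
        "random-forest", {"n_estimators": 200, "max_depth": 7, "max_features": 10}
    ),
    "svm": BaselineSpec("linear-svm", {"kernel": "linear", "C": 0.1}),
}

_FAMILIES = {
    "multilayer-perceptron": MLPClassifier,
    "logistic-regression": LogisticRegression,
    "random-forest": RandomForestClassifier,
    "linear-svm": SVC,
}


def fit_baseline(spec: BaselineSpec | str, features, labels, seed: int = 0):
    """Fit one comparator with its stated hyperparameters.

    ``spec`` may be a short name ("mlp", "lr", "rf", "svm") or a BaselineSpec.
    """
    if isinstance(spec, str):
        if spec not in BASELINES:
            raise ValueError(f"unknown baseline {spec!r}; choose from {sorted(BASELINES)}")
        spec = BASELINES[spec]
    if spec.family not in _FAMILIES:
        raise ValueError(f"unknown baseline family {spec.family!r}")
    X = np.asarray(features, dtype=float)
    y = np.asarray(labels, dtype=int)
    if len(np.unique(y)) < 2:
        raise ValueError("baseline fitting requires both classes in the labels")
    cls = _FAMILIES[spec.family]
    kwargs = dict(spec.hyperparameters)
    if "random_state" in cls().get_params():
        kwargs.setdefault("random_state", seed)
    if cls is RandomForestClassifier:
        kwargs["max_features"] = min(kwargs.get("max_features", X.shape[1]), X.shape[1])
    return cls(**kwargs).fit(X, y)


def _scores(estimator, X) -> np.ndarray:
    """Continuous malignancy score for AUC: probability if available, else margin."""
    if hasattr(estimator, "predict_proba"):
        try:
            return estimator.predict_proba(X)[:, 1]
        except AttributeError:
            pass
    if hasattr(estimator, "decision_function"):
        return estimator.decision_function(X)
    return estimator.predict(X).astype(float)


def evaluate_all(models: dict, features, labels) -> dict[str, DiagnosticReport]:
    """One diagnostic report per model on the same test data.

    Models are anything with ``predict`` (sklearn estimators, fitted SDSAE
    results).  Identical predictions yield identical reports.
    """
    X = np.asarray(features, dtype=float)
    y = np.asarray(labels, dtype=int)
    reports = {}
    for name, m in models.items():
        calls = np.asarray(m.predict(X), dtype=int)
        scores = m.predict_proba(X) if hasattr(m, "predict_proba") else _scores(m, X)
        scores = np.asarray(scores, dtype=float)
        if scores.ndim == 2:
            scores = scores[:, 1]
        reports[name] = DiagnosticReport.from_calls(calls, y, scores=scores)
    return reports


def baseline_provenance(estimator) -> dict:
    """All effective hyperparameters of a fitted comparator, for the run log."""
    return {k: repr(v) for k, v in estimator.get_params().items()}
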