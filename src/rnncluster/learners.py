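"""Pluggable base-learner factories.

A base learner is any scikit-learn style estimator with ``fit(X, y)`` and
``predict(X) -> +/-1`` over a real-valued feature matrix. Each learner is
wrapped in a pipeline that z-scores features on its own training rows, so
standardization never leaks across learners or into evaluation data.

The default, ``"mlp"``, is a one-hidden-layer feed-forward classifier (the
classic back-propagation network). ``"logistic"`` is a fast linear
alternative useful for large smoke runs. Additional kinds can be
registered with :func:`register_learner`.
"""

from __future__ import annotations

from typing import Callable

from sklearn.linear_model import LogisticRegression
from sklearn.neural_network import MLPClassifier
from sklearn.pipeline import Pipeline, make_pipeline
from sklearn.preprocessing import StandardScaler

LearnerFactory = Callable[[dict, int], Pipeline]

_REGISTRY: dict[str, LearnerFactory] = {}


def register_learner(kind: str, factory: LearnerFactory) -> None:
    """Register a factory ``(params, random_state) -> estimator`` under ``kind``."""
    _REGISTRY[kind] = factory


def available_learners() -> tuple[str, ...]:
    return tuple(sorted(_REGISTRY))


def make_learner(kind: str, params: dict | None, random_state: int) -> Pipeline:
    """Instantiate an unfitted learner of the given kind."""
    try:
        factory = _REGISTRY[kind]
    except KeyError:
        raise ValueError(f"unknown learner kind {kind!r}; available: {available_learners()}") from None
    return factory(dict(params or {}), int(random_state))


def _mlp_factory(params: dict, random_state: int) -> Pipeline:
    defaults = dict(
        hidden_layer_sizes=(10,),
        solver="lbfgs",
        alpha=0.1,
        max_iter=200,
    )
    defaults.update(params)
    return make_pipeline(StandardScaler(), MLPClassifier(random_state=random_state, **defaults))


def _logistic_factory(params: dict, random_state: int) -> Pipeline:
    defaults = dict(C=1.0, max_iter=200)
    defaults.update(params)
    return make_pipeline(StandardScaler(), LogisticRegression(random_state=random_state, **defaults))


register_learner("mlp", _mlp_factory)
register_learner("logistic", _logistic_factory)
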