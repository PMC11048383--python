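"""The six classical comparison models per task, behind one fit/predict surface.

Regression: linear regression (LR), Bayesian ridge (BR), gradient boosting
("XGBoost" — the published hyperparameters `loss='squared_error'`,
`criterion='friedman_mse'` are those of scikit-learn's gradient-boosting
machine, and it is implemented as such), random forest (RF), RBF support
vector regression (SVR, C=15, ε=0.2) and a ten-layer-of-17 MLP trained with
ADAM (lr 0.01, batch 10, early stopping).

Classification: logistic regression (LR), k-nearest neighbours (KNN, k=5),
gradient boosting, random forest, RBF SVC and the same MLP.

All models are scikit-learn estimators constructed with the published
hyperparameter values; anything stochastic is seeded through ``fit_baseline``
so repeated fits are identical.
"""

from __future__ import annotations

from sklearn.ensemble import (
    GradientBoostingClassifier,
    GradientBoostingRegressor,
    RandomForestClassifier,
    RandomForestRegressor,
)
from sklearn.linear_model import BayesianRidge, LinearRegression, LogisticRegression
from sklearn.neighbors import KNeighborsClassifier
from sklearn.neural_network import MLPClassifier, MLPRegressor
from sklearn.svm import SVC, SVR

__all__ = [
    "REGRESSORS",
    "CLASSIFIERS",
    "BaselineError",
    "make_baseline",
    "fit_baseline",
    "predict_baseline",
]


class BaselineError(ValueError):
    pass


_MLP_COMMON = dict(
    activation="relu",
    alpha=1e-4,
    batch_size=10,
    beta_1=0.9,
    beta_2=0.999,
    early_stopping=True,
    epsilon=1e-8,
    hidden_layer_sizes=(17,) * 10,
    learning_rate="constant",
    learning_rate_init=0.01,
    max_fun=15000,
    max_iter=1000,
    momentum=0.9,
    n_iter_no_change=10,
    nesterovs_momentum=True,
    power_t=0.5,
    shuffle=True,
    solver="adam",
    tol=1e-4,
    validation_fraction=0.1,
)


def _regressors() -> dict:
    return {
        "LR": (LinearRegression, {}),
        "BR": (BayesianRidge, dict(
            alpha_1=1e-6, alpha_2=1e-6, lambda_1=1e-6, lambda_2=1e-6,
            max_iter=300, tol=1e-3, fit_intercept=True, compute_score=False,
        )),
        "XGBoost": (GradientBoostingRegressor, dict(
            loss="squared_error", criterion="friedman_mse", learning_rate=0.1,
            n_estimators=100, max_depth=3, alpha=0.9, subsample=1.0,
            min_samples_split=2, min_samples_leaf=1, min_weight_fraction_leaf=0.0,
            min_impurity_decrease=0.0, ccp_alpha=0.0, tol=1e-4, validation_fraction=0.1,
        )),
        "RF": (RandomForestRegressor, dict(
            n_estimators=100, criterion="squared_error", bootstrap=True,
            max_features=1.0, min_samples_split=2, min_samples_leaf=1,
            min_weight_fraction_leaf=0.0, min_impurity_decrease=0.0,
            ccp_alpha=0.0, oob_score=False,
        )),
        "SVR": (SVR, dict(
            C=15.0, epsilon=0.2, kernel="rbf", gamma="scale", degree=3,
            coef0=0.0, shrinking=True, tol=1e-3, cache_size=200, max_iter=-1,
        )),
        "MLP": (MLPRegressor, dict(_MLP_COMMON)),
    }


def _classifiers() -> dict:
    return {
        "LR": (LogisticRegression, dict(
            C=1.0, penalty="l2", solver="lbfgs", max_iter=100, tol=1e-4,
            fit_intercept=True, intercept_scaling=1, dual=False,
        )),
        "KNN": (KNeighborsClassifier, dict(
            n_neighbors=5, weights="uniform", algorithm="auto", leaf_size=30,
            metric="minkowski", p=2,
        )),
        "XGBoost": (GradientBoostingClassifier, dict(
            learning_rate=0.1, n_estimators=100, max_depth=3, subsample=1.0,
            min_samples_split=2, min_samples_leaf=1, min_weight_fraction_leaf=0.0,
            min_impurity_decrease=0.0, ccp_alpha=0.0, tol=1e-4, validation_fraction=0.1,
        )),
        "RF": (RandomForestClassifier, dict(
            n_estimators=100, criterion="gini", bootstrap=True,
            max_features="sqrt", min_samples_split=2, min_samples_leaf=1,
            min_weight_fraction_leaf=0.0, min_impurity_decrease=0.0,
            ccp_alpha=0.0, oob_score=False,
        )),
        "SVC": (SVC, dict(
            C=1.0, kernel="rbf", gamma="scale", degree=3, coef0=0.0,
            shrinking=True, probability=False, tol=1e-3, cache_size=200,
            max_iter=-1, break_ties=False, decision_function_shape="ovr",
        )),
        "MLP": (MLPClassifier, dict(_MLP_COMMON)),
    }


REGRESSORS = tuple(_regressors())
CLASSIFIERS = tuple(_classifiers())

def make_baseline(name: str, task: str, seed: int | None = None, **overrides):
    """Instantiate a named baseline with the published hyperparameters.

    ``overrides`` replace individual hyperparameters (validated by the
    estimator itself at fit time).
    """
    registry = _regressors() if task == "regression" else _classifiers()
    if name not in registry:
        raise BaselineError(f"unknown {task} baseline {name!r}; valid names: {sorted(registry)}")
    cls, kwargs = registry[name]
    kwargs = dict(kwargs)
    kwargs.update(overrides)
    if seed is not None and "random_state" in cls().get_params():
        kwargs.setdefault("random_state", seed)
    return cls(**kwargs)


def fit_baseline(name_or_model, X, y, seed: int = 0, task: str | None = None):
    """Fit a baseline (by name, or a pre-built estimator) on preprocessed data."""
    if isinstance(name_or_model, str):
        if task is None:
            raise BaselineError("task ('regression' or 'classification') required with a model name")
        model = make_baseline(name_or_model, task, seed=seed)
    else:
        model = name_or_model
    return model.fit(X, y)


def predict_baseline(model, X):
    from sklearn.exceptions import NotFittedError
    from sklearn.utils.validation import check_is_fitted

    try:
        check_is_fitted(model)
    except NotFittedError as exc:
        raise RuntimeError("baseline model is not fitted") from exc
    return model.predict(X)
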