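"""Scikit-learn style estimators over the cutoff and combination machinery.

`CutoffClassifier` learns a single-score decision threshold from labeled
variants under one of three ROC strategies; `ComboClassifier` evaluates a
conjunction of predictor filters with pass-if-missing semantics.  Both
follow the sklearn estimator contract (``get_params``/``set_params``,
fitted attributes with trailing underscores, ``fit``/``predict``/``score``)
and therefore compose with pipelines and model selection utilities.
"""

from __future__ import annotations

from typing import Optional, Sequence

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator, ClassifierMixin
from sklearn.utils.validation import check_is_fitted

from .combo import ComboMember, ComboModel, SelectionCriteria, evaluate_model
from .registry import Direction, Family, PredictorSpec, Transform
from .roc import (
    STRATEGIES,
    CutoffEstimate,
    RocCurve,
    cutoff_at_sensitivity,
    cutoff_sens_eq_spec,
    cutoff_youden,
    roc_curve,
)
from .scores import LABEL_BENIGN, LABEL_PATHOGENIC, LabeledScores


def _as_labeled(X, y, name: str) -> LabeledScores:
    X = np.asarray(X, dtype=float)
    if X.ndim == 2:
        if X.shape[1] != 1:
            raise ValueError("CutoffClassifier expects a single score column")
        X = X[:, 0]
    y = np.asarray(y)
    frame = pd.DataFrame({
        "variant_id": [f"r{i}" for i in range(len(X))],
        "label": np.where(y.astype(bool), LABEL_PATHOGENIC, LABEL_BENIGN),
        "splicing_subset": False,
        name: X,
    })
    return LabeledScores(frame, predictors=[name])


class CutoffClassifier(ClassifierMixin, BaseEstimator):
    """Threshold classifier calibrated on a ROC curve.

    Parameters
    ----------
    strategy : {'youden', 'senspec', 'sens90'}
        Cutoff-selection rule: maximize Youden's J, equalize sensitivity and
        specificity, or take the strictest threshold with sensitivity >=
        ``target``.
    target : float
        Sensitivity floor for the 'sens90' strategy.
    direction : {'higher-is-risk', 'lower-is-risk'}
        Whether large or small scores indicate the positive class.
    pass_if_missing : bool
        Predicted class for NaN scores at predict time.

    Attributes
    ----------
    cutoff_ : float
        Selected threshold on the native score scale (inclusive).
    sensitivity_, specificity_, fp_rate_ : float
        Operating characteristics at ``cutoff_`` on the training data.
    auc_ : float
        Mann-Whitney AUC with DeLong 95% CI in ``auc_ci95_``.
    roc_ : RocCurve
        The full curve (native-scale thresholds).
    """

    def __init__(
        self,
        strategy: str = "sens90",
        target: float = 0.90,
        direction: str = "higher-is-risk",
        pass_if_missing: bool = False,
    ):
        self.strategy = strategy
        self.target = target
        self.direction = direction
        self.pass_if_missing = pass_if_missing

    def fit(self, X, y):
        if self.strategy not in STRATEGIES:
            raise ValueError(f"unknown strategy {self.strategy!r}")
        spec = PredictorSpec(
            name="score",
            family=Family.NON_SPLICING,
            direction=Direction(self.direction),
            transform=(Transform.NEGATE_FOR_ROC
                       if Direction(self.direction) is Direction.LOWER
                       else Transform.NONE),
            optimal_cutoff=0.0,
            pass_if_missing=self.pass_if_missing,
        )
        data = _as_labeled(X, y, "score")
        roc = roc_curve(data, "score", spec)
        est: CutoffEstimate = STRATEGIES[self.strategy](roc, self.target)
        self.classes_ = np.array([0, 1])
        self.roc_ = roc
        self.cutoff_ = est.cutoff
        self.sensitivity_ = est.sensitivity
        self.specificity_ = est.specificity
        self.fp_rate_ = est.fp_rate
        self.auc_ = roc.auc
        self.auc_ci95_ = roc.auc_ci95
        self.estimate_ = est
        return self

    def decision_function(self, X):
        check_is_fitted(self, "cutoff_")
        X = np.asarray(X, dtype=float)
        if X.ndim == 2:
            X = X[:, 0]
        sign = 1.0 if Direction(self.direction) is Direction.HIGHER else -1.0
        return sign * (X - self.cutoff_)

    def predict(self, X):
        d = self.decision_function(X)
        out = d >= 0
        out = np.where(np.isnan(d), self.pass_if_missing, out)
        return out.astype(int)


class ComboClassifier(ClassifierMixin, BaseEstimator):
    """Conjunction-of-filters classifier over a score DataFrame.

    ``members`` is a sequence of (predictor, cutoff, direction) triples or
    :class:`ComboMember` instances; a variant is predicted positive iff
    every member score is missing or beyond its cutoff.  ``fit`` measures
    TP/FP/missing rates on labeled data and records whether the model meets
    the selection criteria.
    """

    def __init__(
        self,
        members: Sequence = (),
        family: str = "non-splicing",
        criteria: Optional[SelectionCriteria] = None,
    ):
        self.members = members
        self.family = family
        self.criteria = criteria

    def _model(self) -> ComboModel:
        members = []
        for m in self.members:
            if isinstance(m, ComboMember):
                members.append(m)
            else:
                pred, cutoff, direction = m
                members.append(ComboMember(pred, float(cutoff), Direction(direction)))
        return ComboModel(members=tuple(members), family=Family(self.family))

    def fit(self, X: pd.DataFrame, y):
        if not isinstance(X, pd.DataFrame):
            raise TypeError("ComboClassifier needs a DataFrame of predictor scores")
        y = np.asarray(y).astype(bool)
        frame = X.copy()
        frame["variant_id"] = [f"r{i}" for i in range(len(frame))]
        frame["label"] = np.where(y, LABEL_PATHOGENIC, LABEL_BENIGN)
        frame["splicing_subset"] = Family(self.family) is Family.SPLICING
        data = LabeledScores(frame.reset_index(drop=True))
        fitted = evaluate_model(self._model(), data)
        crit = self.criteria or SelectionCriteria()
        self.classes_ = np.array([0, 1])
        self.model_ = fitted
        self.tp_rate_ = fitted.tp_rate
        self.fp_rate_ = fitted.fp_rate
        self.missing_rate_ = fitted.missing_rate
        self.meets_criteria_ = crit.met_by(fitted)
        return self

    def predict(self, X: pd.DataFrame):
        check_is_fitted(self, "model_")
        model = self.model_
        if model.members:
            passing = np.all(
                np.column_stack([
                    m.passes(np.asarray(X[m.predictor], dtype=float))
                    for m in model.members
                ]),
                axis=1,
            )
        else:
            passing = np.ones(len(X), dtype=bool)
        return passing.astype(int)
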