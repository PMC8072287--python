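"""Joint factor screening: forward selection gated on both cohorts.

The screen grows a logistic model on the training cohort one factor at a
time while holding it accountable to an untouched validation cohort:

1. **Ranking.**  At each step every remaining candidate is tentatively
   added and the model refit on the training cohort (a mild ridge keeps
   near-separated fits well-conditioned).  Candidates are ranked by the
   configured objective — by default the training log-likelihood, the
   classical stepwise criterion; AUC-based dual-set objectives
   (``sum``/``min``/``validation``/``train``) are available.

2. **Gates.**  The top candidate is accepted only if
   (a) every slope coefficient of the refit model is Wald-significant at
   ``alpha`` (default 0.05), and
   (b) the evaluation function improves by more than ``k`` (default 2)
   per included factor.  The default evaluation function is the
   **validation-cohort deviance** of the training-fitted model: with ``j``
   factors included, the cumulative improvement over the intercept-only
   model must exceed ``k * j``, so every factor must keep buying
   out-of-sample fit.  A training-AIC evaluation (per-step improvement
   greater than ``k``) is available instead.

3. **Halting.**  The loop stops as soon as the top candidate fails either
   gate, or at ``max_factors``.

Both AUCs are computed and recorded at every step, so the audit trace
reads as a report of training/validation discrimination alongside the
decreasing evaluation-function column.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, asdict

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator

from .models import LogisticIRLS, auc

__all__ = [
    "ScreeningConfig",
    "StepRecord",
    "ScreeningResult",
    "JointAUCScreener",
    "joint_factor_screen",
    "screening_report",
    "validation_deviance",
]


def validation_deviance(model: LogisticIRLS, X_val, y_val) -> float:
    """-2 x log-likelihood of a fitted model scored on held-out data."""
    y_val = np.asarray(y_val).ravel().astype(float)
    if model.n_features_in_ == 0:
        eta = np.full(len(y_val), model.intercept_)
    else:
        eta = model.decision_function(X_val)
    return -2.0 * float(np.sum(y_val * eta - np.logaddexp(0.0, eta)))


@dataclass
class ScreeningConfig:
    """Knobs of the joint screen.

    alpha : Wald significance gate on every slope coefficient (train fit).
    k : minimum evaluation-function improvement per included factor.
    objective : candidate ranking — ``'loglik'`` (training log-likelihood,
        default), or AUC-based: ``'sum'`` (train+val), ``'min'``
        (maximize the smaller of the two, tie-break by sum),
        ``'validation'``, ``'train'``.
    eval_function : ``'val_deviance'`` (default; cumulative improvement
        over the intercept-only model must exceed ``k`` per factor) or
        ``'aic'`` (training AIC, per-step improvement > ``k``).
    max_factors : optional cap on the number of accepted factors.
    ridge : L2 stabilization of the screen's logistic fits.
    """

    alpha: float = 0.05
    k: float = 2.0
    objective: str = "loglik"
    eval_function: str = "val_deviance"
    max_factors: int | None = None
    ridge: float = 1.0

    def __post_init__(self):
        if not (0.0 < self.alpha < 1.0):
            raise ValueError("alpha must be in (0, 1)")
        if self.k < 0:
            raise ValueError("k must be >= 0")
        if self.objective not in ("loglik", "sum", "min", "validation", "train"):
            raise ValueError(f"unknown objective {self.objective!r}")
        if self.eval_function not in ("val_deviance", "aic"):
            raise ValueError(f"unknown eval_function {self.eval_function!r}")


@dataclass
class StepRecord:
    feature: str
    auc_train: float
    auc_val: float
    eval_value: float
    pvalues: dict[str, float]
    accepted: bool
    reason: str = ""


@dataclass
class ScreeningResult:
    """Ordered selection with the full audit trace and the final model."""

    selected: list[str]
    steps: list[StepRecord]
    model: LogisticIRLS | None
    config: ScreeningConfig

    def to_dict(self) -> dict:
        return {
            "selected": list(self.selected),
            "steps": [asdict(s) for s in self.steps],
            "model": self.model.to_dict() if self.model is not None else None,
            "config": asdict(self.config),
        }


class JointAUCScreener(BaseEstimator):
    """Estimator wrapper around the joint factor screen.

    ``fit(X, y, X_val=..., y_val=..., candidates=...)`` runs the forward
    loop; fitted attributes are ``selected_``, ``steps_`` (audit trace,
    including the rejected final tentative step), and ``model_`` (final
    :class:`LogisticIRLS` on the training cohort, or None when nothing was
    accepted).
    """

    def __init__(self, alpha: float = 0.05, k: float = 2.0,
                 objective: str = "loglik", eval_function: str = "val_deviance",
                 max_factors: int | None = None, ridge: float = 1.0):
        self.alpha = alpha
        self.k = k
        self.objective = objective
        self.eval_function = eval_function
        self.max_factors = max_factors
        self.ridge = ridge

    def _config(self) -> ScreeningConfig:
        return ScreeningConfig(
            alpha=self.alpha, k=self.k, objective=self.objective,
            eval_function=self.eval_function, max_factors=self.max_factors,
            ridge=self.ridge,
        )

    def fit(self, X, y, X_val=None, y_val=None, candidates=None):
        cfg = self._config()
        if X_val is None or y_val is None:
            raise ValueError("X_val and y_val are required")
        if not isinstance(X, pd.DataFrame) or not isinstance(X_val, pd.DataFrame):
            raise TypeError("X and X_val must be DataFrames with named columns")
        y = np.asarray(y).ravel().astype(int)
        y_val = np.asarray(y_val).ravel().astype(int)
        if len(np.unique(y)) < 2:
            raise ValueError("training set must contain both classes")
        if len(np.unique(y_val)) < 2:
            raise ValueError("validation set single-class: objective undefined")
        if candidates is None:
            candidates = list(X.columns)
        missing = [c for c in candidates if c not in X_val.columns]
        if missing:
            raise ValueError(f"validation set lacks candidate column(s): {missing}")

        def fit_cols(cols: list[str]) -> LogisticIRLS:
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                return LogisticIRLS(penalty="ridge", alpha=cfg.ridge).fit(
                    X[cols] if cols else X[[]], y
                )

        def objective_key(m: LogisticIRLS, cols: list[str]):
            if cfg.objective == "loglik":
                return (m.loglik_,)
            a_tr = auc(m.decision_function(X[cols]), y)
            a_val = auc(m.decision_function(X_val[cols]), y_val)
            return {
                "sum": (a_tr + a_val,),
                "min": (min(a_tr, a_val), a_tr + a_val),
                "validation": (a_val, a_tr),
                "train": (a_tr, a_val),
            }[cfg.objective]

        selected: list[str] = []
        steps: list[StepRecord] = []
        model: LogisticIRLS | None = None

        null_model = fit_cols([])
        base_val_dev = validation_deviance(null_model, X_val, y_val)
        current_aic = null_model.aic_
        max_factors = cfg.max_factors if cfg.max_factors is not None else len(candidates)

        while len(selected) < max_factors:
            remaining = [
                c for c in candidates
                if c not in selected and not X[c].isna().any() and not X_val[c].isna().any()
            ]
            if not remaining:
                break
            best = None  # (objective key, feature, model)
            for cand in remaining:
                cols = selected + [cand]
                m = fit_cols(cols)
                key = objective_key(m, cols)
                if best is None or key > best[0]:
                    best = (key, cand, m)
            _, feat, m = best
            cols = selected + [feat]
            a_tr = auc(m.decision_function(X[cols]), y)
            a_val = auc(m.decision_function(X_val[cols]), y_val)
            val_dev = validation_deviance(m, X_val[cols], y_val)
            eval_value = val_dev if cfg.eval_function == "val_deviance" else m.aic_
            pvals = dict(zip(m.feature_names_in_, m.pvalues_))

            if not all(p < cfg.alpha for p in pvals.values()):
                steps.append(StepRecord(feat, a_tr, a_val, eval_value, pvals, False,
                                        "coefficient significance gate failed"))
                break
            if cfg.eval_function == "val_deviance":
                ok = (base_val_dev - val_dev) > cfg.k * len(cols)
            else:
                ok = (current_aic - m.aic_) > cfg.k
            if not ok:
                steps.append(StepRecord(feat, a_tr, a_val, eval_value, pvals, False,
                                        "evaluation-function improvement <= k"))
                break
            selected.append(feat)
            model = m
            current_aic = m.aic_
            steps.append(StepRecord(feat, a_tr, a_val, eval_value, pvals, True))

        self.selected_ = selected
        self.steps_ = steps
        self.model_ = model
        return self

    def result(self) -> ScreeningResult:
        return ScreeningResult(
            selected=list(self.selected_),
            steps=list(self.steps_),
            model=self.model_,
            config=self._config(),
        )


def joint_factor_screen(X_train, y_train, X_val, y_val, candidates=None,
                        config: ScreeningConfig | None = None) -> ScreeningResult:
    """Run the forward dual-cohort screen and return its audit trail."""
    cfg = config or ScreeningConfig()
    scr = JointAUCScreener(alpha=cfg.alpha, k=cfg.k, objective=cfg.objective,
                           eval_function=cfg.eval_function,
                           max_factors=cfg.max_factors, ridge=cfg.ridge)
    scr.fit(X_train, y_train, X_val=X_val, y_val=y_val, candidates=candidates)
    return scr.result()


def screening_report(result: ScreeningResult) -> pd.DataFrame:
    """Tabular per-step report of the accepted factors.

    One row per accepted step; the factor column accumulates
    (``A`` then ``A+B`` ...), AUCs are reported on the 0-100 scale, the
    evaluation-function column carries the per-step value (decreasing as
    factors are added for the default validation-deviance criterion), and
    the coefficient p-values of the refit model at that step are joined
    with commas.
    """
    rows = []
    prefix: list[str] = []
    for step in result.steps:
        if not step.accepted:
            continue
        prefix = prefix + [step.feature]
        rows.append({
            "cytokines": "+".join(prefix),
            "auc_train": round(100.0 * step.auc_train, 2),
            "auc_val": round(100.0 * step.auc_val, 2),
            "eval_function": round(step.eval_value, 2),
            "coefficient_p": ", ".join(f"{p:.6g}" for p in step.pvalues.values()),
        })
    return pd.DataFrame(
        rows, columns=["cytokines", "auc_train", "auc_val", "eval_function", "coefficient_p"]
    )
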