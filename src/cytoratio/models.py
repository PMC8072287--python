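"""Classical modeling layer, written from first principles.

Everything here is deliberately self-contained: the rank-based AUC, a
Newton/IRLS logistic regression with Wald tests, greedy AIC stepwise
selection, a pooled-covariance linear discriminant, and seed-controlled
k-fold cross-validated AUC.  These are the building blocks the factor
screening and ratio-biomarker layers compose; external libraries are used
only for fold bookkeeping.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.base import BaseEstimator, ClassifierMixin
from sklearn.model_selection import KFold, StratifiedKFold

__all__ = [
    "auc",
    "LogisticIRLS",
    "fit_logistic",
    "StepwiseAICSelector",
    "StepwiseResult",
    "stepwise_aic",
    "PooledCovLDA",
    "fit_lda",
    "lda_apparent_error",
    "CvAucResult",
    "cv_auc",
]


def _as_matrix(X):
    """Return (values, feature_names) from a DataFrame or array."""
    if isinstance(X, pd.DataFrame):
        return X.to_numpy(dtype=float), list(X.columns)
    X = np.asarray(X, dtype=float)
    if X.ndim == 1:
        X = X[:, None]
    return X, [f"x{i}" for i in range(X.shape[1])]


def auc(scores, labels) -> float:
    """Rank-based area under the ROC curve.

    Equals the fraction of (positive, negative) pairs in which the positive
    scores strictly higher, ties counting one half (the Mann-Whitney
    definition).  Requires both classes present.
    """
    scores = np.asarray(scores, dtype=float).ravel()
    labels = np.asarray(labels).ravel().astype(int)
    if scores.shape != labels.shape:
        raise ValueError("scores and labels must have the same length")
    if np.isnan(scores).any():
        raise ValueError("scores must not contain NaN")
    n1 = int(labels.sum())
    n0 = len(labels) - n1
    if n1 == 0 or n0 == 0:
        raise ValueError("AUC undefined: both classes must be present")
    ranks = stats.rankdata(scores)
    r1 = ranks[labels == 1].sum()
    u = r1 - n1 * (n1 + 1) / 2.0
    return float(u / (n1 * n0))


class LogisticIRLS(BaseEstimator, ClassifierMixin):
    """Binary logistic regression by Newton iteration (IRLS).

    Parameters
    ----------
    penalty
        ``'none'`` for the plain maximum-likelihood fit, ``'ridge'`` for a
        tiny quadratic penalty ``alpha/2 * ||beta||^2`` on the slope
        coefficients (never the intercept), which regularizes degenerate
        designs without materially moving the optimum.
    alpha
        Ridge strength when ``penalty='ridge'``.
    tol
        Convergence: relative change of the penalized log-likelihood.
    max_iter
        Newton iteration cap.

    Fitted attributes
    -----------------
    coef_, intercept_ : slope vector and intercept.
    se_, pvalues_ : Wald standard errors / two-sided p per slope, from the
        observed information matrix; ``intercept_se_``/``intercept_pvalue_``
        for the intercept.
    loglik_ : unpenalized log-likelihood at the fit.
    converged_ : honest flag — False under perfect separation of the fitted
        linear predictor (penalty 'none') or when Newton did not settle.
    """

    def __init__(self, penalty: str = "none", alpha: float = 1e-8,
                 tol: float = 1e-10, max_iter: int = 100):
        self.penalty = penalty
        self.alpha = alpha
        self.tol = tol
        self.max_iter = max_iter

    # -- helpers -----------------------------------------------------------
    @staticmethod
    def _loglik(eta, y):
        # numerically stable sum of y*eta - log(1 + exp(eta))
        return float(np.sum(y * eta - np.logaddexp(0.0, eta)))

    def fit(self, X, y):
        Xm, names = _as_matrix(X)
        y = np.asarray(y).ravel().astype(float)
        if Xm.shape[0] != len(y):
            raise ValueError("X and y length mismatch")
        if set(np.unique(y)) - {0.0, 1.0}:
            raise ValueError("y must be binary 0/1")
        n, p = Xm.shape
        design = np.column_stack([np.ones(n), Xm])
        ridge = np.zeros(p + 1)
        if self.penalty == "ridge":
            ridge[1:] = self.alpha
        elif self.penalty != "none":
            raise ValueError(f"unknown penalty {self.penalty!r}")

        beta = np.zeros(p + 1)
        eta = design @ beta
        ll = self._loglik(eta, y) - 0.5 * np.sum(ridge * beta**2)
        n_iter = 0
        settled = False
        for n_iter in range(1, self.max_iter + 1):
            mu = 1.0 / (1.0 + np.exp(-eta))
            w = mu * (1.0 - mu)
            grad = design.T @ (y - mu) - ridge * beta
            hess = design.T @ (design * w[:, None]) + np.diag(ridge)
            try:
                step = np.linalg.solve(hess, grad)
            except np.linalg.LinAlgError:
                step = np.linalg.lstsq(hess, grad, rcond=None)[0]
            # step-halving keeps Newton monotone on flat likelihoods
            for _ in range(30):
                cand = beta + step
                eta_c = design @ cand
                ll_c = self._loglik(eta_c, y) - 0.5 * np.sum(ridge * cand**2)
                if ll_c >= ll - 1e-12:
                    break
                step = step / 2.0
            beta, eta = cand, eta_c
            if abs(ll_c - ll) <= self.tol * (abs(ll) + 1e-12):
                ll = ll_c
                settled = True
                break
            ll = ll_c

        mu = 1.0 / (1.0 + np.exp(-eta))
        grad = design.T @ (y - mu) - ridge * beta
        info = design.T @ (design * (mu * (1 - mu))[:, None]) + np.diag(ridge)

        separated = False
        if self.penalty == "none" and p > 0:
            s1, s0 = eta[y == 1], eta[y == 0]
            if len(s1) and len(s0) and (s1.min() > s0.max() or s0.min() > s1.max()):
                # the fitted direction perfectly separates the classes: the
                # MLE does not exist and the coefficients are unreliable
                separated = bool(np.abs(beta).max() > 8.0)

        self.classes_ = np.array([0, 1])
        self.n_features_in_ = p
        self.feature_names_in_ = np.asarray(names, dtype=object)
        self.intercept_ = float(beta[0])
        self.coef_ = beta[1:].copy()
        self.loglik_ = self._loglik(eta, y)
        self.n_iter_ = n_iter
        self.gradient_norm_ = float(np.linalg.norm(grad))
        self.converged_ = bool(settled and not separated)
        if separated:
            warnings.warn(
                "perfect separation detected: maximum-likelihood coefficients "
                "do not exist; fit flagged non-converged",
                stacklevel=2,
            )

        try:
            cov = np.linalg.inv(info)
            se = np.sqrt(np.clip(np.diag(cov), 0.0, np.inf))
        except np.linalg.LinAlgError:
            se = np.full(p + 1, np.nan)
        with np.errstate(divide="ignore", invalid="ignore"):
            z = beta / se
        pvals = 2.0 * stats.norm.sf(np.abs(z))
        self.intercept_se_ = float(se[0])
        self.intercept_pvalue_ = float(pvals[0])
        self.se_ = se[1:].copy()
        self.pvalues_ = pvals[1:].copy()
        return self

    # -- prediction --------------------------------------------------------
    def decision_function(self, X):
        Xm, _ = _as_matrix(X)
        return Xm @ self.coef_ + self.intercept_

    def predict_proba(self, X):
        eta = self.decision_function(X)
        p1 = 1.0 / (1.0 + np.exp(-eta))
        return np.column_stack([1.0 - p1, p1])

    def predict(self, X):
        return (self.decision_function(X) > 0).astype(int)

    # -- diagnostics -------------------------------------------------------
    @property
    def n_parameters_(self) -> int:
        """Number of free parameters, intercept included."""
        return int(self.coef_.shape[0]) + 1

    @property
    def aic_(self) -> float:
        """Akaike information criterion, 2k − 2·log-likelihood."""
        return 2.0 * self.n_parameters_ - 2.0 * self.loglik_

    def to_dict(self) -> dict:
        return {
            "feature_ids": list(self.feature_names_in_),
            "coefficients": self.coef_.tolist(),
            "intercept": self.intercept_,
            "coefficient_p": self.pvalues_.tolist(),
            "log_likelihood": self.loglik_,
            "aic": self.aic_,
            "converged": self.converged_,
        }


def fit_logistic(X, y, penalty: str = "none", **kwargs) -> LogisticIRLS:
    """Fit a :class:`LogisticIRLS` model and return it."""
    return LogisticIRLS(penalty=penalty, **kwargs).fit(X, y)


@dataclass
class StepwiseResult:
    """Outcome of a stepwise AIC search."""

    selected: list[str]
    aic_trace: list[float]
    model: LogisticIRLS
    steps: list[dict] = field(default_factory=list)


class StepwiseAICSelector(BaseEstimator):
    """Greedy stepwise logistic-model selection by AIC.

    Forward (or forward-backward with ``direction='both'``) search over the
    candidate columns; a move is accepted only if it strictly decreases the
    AIC, ties between candidates broken by input order.  Fitted attributes:
    ``selected_`` (feature names, selection order), ``aic_trace_`` (AIC after
    each accepted move, starting at the intercept-only model) and ``model_``
    (the final :class:`LogisticIRLS` fit).
    """

    def __init__(self, direction: str = "forward", max_features: int | None = None,
                 penalty: str = "none"):
        self.direction = direction
        self.max_features = max_features
        self.penalty = penalty

    def _fit_subset(self, X: pd.DataFrame, y, cols: list[str]) -> LogisticIRLS:
        sub = X[cols] if cols else pd.DataFrame(index=X.index)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            return LogisticIRLS(penalty=self.penalty).fit(sub, y)

    def fit(self, X, y):
        if self.direction not in ("forward", "both"):
            raise ValueError(f"unknown direction {self.direction!r}")
        if not isinstance(X, pd.DataFrame):
            Xm, names = _as_matrix(X)
            X = pd.DataFrame(Xm, columns=names)
        y = np.asarray(y).ravel().astype(int)
        max_feat = self.max_features if self.max_features is not None else X.shape[1]

        current: list[str] = []
        model = self._fit_subset(X, y, current)
        trace = [model.aic_]
        steps: list[dict] = []
        while len(current) < max_feat:
            best_aic, best_move, best_model = trace[-1], None, None
            for cand in [c for c in X.columns if c not in current]:
                m = self._fit_subset(X, y, current + [cand])
                if m.aic_ < best_aic - 1e-12:
                    best_aic, best_move, best_model = m.aic_, ("add", cand), m
            if self.direction == "both" and len(current) > 1:
                for drop in current:
                    kept = [c for c in current if c != drop]
                    m = self._fit_subset(X, y, kept)
                    if m.aic_ < best_aic - 1e-12:
                        best_aic, best_move, best_model = m.aic_, ("drop", drop), m
            if best_move is None:
                break
            kind, feat = best_move
            if kind == "add":
                current = current + [feat]
            else:
                current = [c for c in current if c != feat]
            model = best_model
            trace.append(best_aic)
            steps.append({"move": kind, "feature": feat, "aic": best_aic})

        self.selected_ = current
        self.aic_trace_ = trace
        self.model_ = model
        self.steps_ = steps
        return self

    def transform(self, X):
        return X[self.selected_] if isinstance(X, pd.DataFrame) else X

    def result(self) -> StepwiseResult:
        return StepwiseResult(
            selected=list(self.selected_),
            aic_trace=list(self.aic_trace_),
            model=self.model_,
            steps=list(self.steps_),
        )


def stepwise_aic(X, y, direction: str = "forward",
                 max_features: int | None = None) -> StepwiseResult:
    """Greedy AIC-minimizing stepwise logistic selection (see the class)."""
    sel = StepwiseAICSelector(direction=direction, max_features=max_features)
    return sel.fit(X, y).result()


class PooledCovLDA(BaseEstimator, ClassifierMixin):
    """Two-class linear discriminant with a pooled covariance estimate.

    Classification is by the larger Gaussian discriminant score; for two
    classes this reduces to thresholding ``x @ coef_`` at ``threshold_``
    where ``coef_ = pooled_cov^{-1} (mu1 - mu0)``.  A singular pooled
    covariance triggers a small ridge on the diagonal with a warning.
    """

    def __init__(self, ridge: float = 1e-8):
        self.ridge = ridge

    def fit(self, X, y):
        Xm, names = _as_matrix(X)
        y = np.asarray(y).ravel().astype(int)
        classes = np.unique(y)
        if len(classes) != 2:
            raise ValueError("PooledCovLDA requires exactly two classes")
        self.classes_ = classes
        self.feature_names_in_ = np.asarray(names, dtype=object)
        n, p = Xm.shape
        means, ss = [], np.zeros((p, p))
        counts = []
        for c in classes:
            sub = Xm[y == c]
            counts.append(len(sub))
            means.append(sub.mean(axis=0))
            dev = sub - sub.mean(axis=0)
            ss += dev.T @ dev
        dof = n - 2
        pooled = ss / dof if dof > 0 else ss
        pooled = (pooled + pooled.T) / 2.0
        try:
            np.linalg.cholesky(pooled + 0.0)
            inv = np.linalg.inv(pooled)
        except np.linalg.LinAlgError:
            warnings.warn(
                "singular pooled covariance: applying diagonal ridge fallback",
                stacklevel=2,
            )
            scale = np.trace(pooled) / p if np.trace(pooled) > 0 else 1.0
            pooled = pooled + self.ridge * scale * np.eye(p) + 1e-12 * np.eye(p)
            inv = np.linalg.inv(pooled)
        self.class_means_ = np.vstack(means)
        self.pooled_covariance_ = pooled
        self.priors_ = np.asarray(counts, dtype=float) / n
        mu0, mu1 = self.class_means_
        self.coef_ = inv @ (mu1 - mu0)
        self.threshold_ = float(
            0.5 * (mu1 + mu0) @ self.coef_ - np.log(self.priors_[1] / self.priors_[0])
        )
        return self

    def decision_function(self, X):
        Xm, _ = _as_matrix(X)
        return Xm @ self.coef_ - self.threshold_

    def predict(self, X):
        d = self.decision_function(X)
        return np.where(d > 0, self.classes_[1], self.classes_[0])


def fit_lda(X, y, **kwargs) -> PooledCovLDA:
    return PooledCovLDA(**kwargs).fit(X, y)


def lda_apparent_error(model: PooledCovLDA, X, y) -> float:
    """Resubstitution (apparent) error rate: misclassified fraction on X."""
    y = np.asarray(y).ravel()
    return float(np.mean(model.predict(X) != y))


@dataclass
class CvAucResult:
    """Per-fold held-out AUCs of a cross-validated classifier."""

    fold_aucs: list[float]
    mean_auc: float
    n_folds: int
    seed: int
    skipped_folds: list[int] = field(default_factory=list)


def cv_auc(X, y, estimator=None, n_folds: int = 5, stratified: bool = True,
           seed: int = 0) -> CvAucResult:
    """K-fold cross-validated AUC (default 5 folds: 80% train / 20% test).

    Folds are stratified by default so small minority classes do not produce
    single-class test folds; the seed fully determines the partition.  A
    fold whose test split still contains one class is skipped with a warning
    and recorded in ``skipped_folds``.
    """
    if estimator is None:
        estimator = LogisticIRLS(penalty="ridge")
    if not isinstance(X, pd.DataFrame):
        Xm, names = _as_matrix(X)
        X = pd.DataFrame(Xm, columns=names)
    y = np.asarray(y).ravel().astype(int)
    splitter_cls = StratifiedKFold if stratified else KFold
    splitter = splitter_cls(n_splits=n_folds, shuffle=True, random_state=seed)
    from sklearn.base import clone

    fold_aucs: list[float] = []
    skipped: list[int] = []
    for i, (tr, te) in enumerate(splitter.split(X, y)):
        if len(np.unique(y[te])) < 2 or len(np.unique(y[tr])) < 2:
            warnings.warn(f"fold {i} has a single class; skipped", stacklevel=2)
            skipped.append(i)
            continue
        est = clone(estimator).fit(X.iloc[tr], y[tr])
        scores = est.decision_function(X.iloc[te])
        fold_aucs.append(auc(scores, y[te]))
    mean = float(np.mean(fold_aucs)) if fold_aucs else float("nan")
    return CvAucResult(fold_aucs=fold_aucs, mean_auc=mean, n_folds=n_folds,
                       seed=seed, skipped_folds=skipped)
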