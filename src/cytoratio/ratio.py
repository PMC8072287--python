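"""Collapse of a two-factor logistic model into a single ratio biomarker.

A two-feature log2-scale logistic model with opposite-sign coefficients,

    logit P(benefit) = b0 + b1 * log2(num_ratio) + b2 * log2(den_ratio),

with ``b1 > 0 > b2``, motivates the single factor ``num_ratio/den_ratio``
(for the discovered model: IP-10(S2/S0) over IL-8(S2/S0)).  On the log2
scale the biomarker score is simply the difference of the two features; it
ranks patients identically to the model's linear predictor exactly when
``|b1| = |b2|``, so the collapse always carries a fidelity report (the AUC
of the ratio score versus the model score) and warns when the two diverge.
Higher score means predicted benefit.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .models import LogisticIRLS, auc, fit_logistic

__all__ = ["RatioBiomarker", "collapse_to_ratio", "compare_model_vs_ratio",
           "CollapseError", "delong_paired_test"]


class CollapseError(ValueError):
    """The model does not admit a ratio interpretation."""


@dataclass
class RatioBiomarker:
    """A single-ratio biomarker on the log2 scale.

    ``score = log2(numerator ratio) − log2(denominator ratio)``; since the
    feature matrix is already log2, this is the column difference.  The
    score is a strictly increasing function of the raw ratio, and higher
    scores predict clinical benefit.  ``cutoff`` (log2 scale) and
    ``raw_cutoff = 2**cutoff`` are set later from a ROC scan.
    """

    numerator_feature: str
    denominator_feature: str
    cutoff: float | None = None
    orientation_note: str = "higher score predicts benefit"

    def score(self, X: pd.DataFrame) -> np.ndarray:
        for f in (self.numerator_feature, self.denominator_feature):
            if f not in X.columns:
                raise KeyError(f"feature matrix lacks column {f!r}")
        return (X[self.numerator_feature] - X[self.denominator_feature]).to_numpy(dtype=float)

    def raw_ratio(self, X: pd.DataFrame) -> np.ndarray:
        return 2.0 ** self.score(X)

    @property
    def raw_cutoff(self) -> float | None:
        return None if self.cutoff is None else float(2.0**self.cutoff)

    def to_dict(self) -> dict:
        return {
            "numerator_feature": self.numerator_feature,
            "denominator_feature": self.denominator_feature,
            "cutoff_log2": self.cutoff,
            "cutoff_raw_ratio": self.raw_cutoff,
            "orientation": self.orientation_note,
        }

    @classmethod
    def from_dict(cls, d: dict) -> "RatioBiomarker":
        return cls(
            numerator_feature=d["numerator_feature"],
            denominator_feature=d["denominator_feature"],
            cutoff=d.get("cutoff_log2"),
            orientation_note=d.get("orientation", "higher score predicts benefit"),
        )


def collapse_to_ratio(model: LogisticIRLS, X: pd.DataFrame | None = None,
                      y=None, tolerance: float = 0.01):
    """Collapse a 2-feature opposite-sign logistic model into a ratio.

    Returns ``(biomarker, fidelity)``.  ``fidelity`` records the two
    coefficient magnitudes and — when data are supplied — the AUC of the
    ratio score, the AUC of the model's linear predictor, and their
    difference; a warning is raised when |ΔAUC| exceeds ``tolerance``
    (the collapse is exactly AUC-preserving only for equal magnitudes).

    Raises :class:`CollapseError` for models with more or fewer than two
    features or same-sign coefficients.
    """
    coefs = np.asarray(model.coef_, dtype=float)
    names = list(model.feature_names_in_)
    if len(coefs) != 2:
        raise CollapseError(
            f"collapse requires exactly 2 features, model has {len(coefs)}"
        )
    if coefs[0] * coefs[1] >= 0:
        raise CollapseError(
            "same-sign coefficients: no ratio interpretation "
            f"({names[0]}: {coefs[0]:.4g}, {names[1]}: {coefs[1]:.4g})"
        )
    pos = int(coefs[0] < 0)  # index of the positive coefficient
    biomarker = RatioBiomarker(
        numerator_feature=names[pos],
        denominator_feature=names[1 - pos],
    )
    fidelity: dict = {
        "beta_numerator": float(coefs[pos]),
        "beta_denominator": float(coefs[1 - pos]),
        "magnitude_gap": float(abs(abs(coefs[0]) - abs(coefs[1]))),
    }
    if X is not None and y is not None:
        report = compare_model_vs_ratio(model, biomarker, X, y)
        fidelity.update(report)
        if abs(report["delta_auc"]) > tolerance:
            warnings.warn(
                f"ratio collapse loses {abs(report['delta_auc']):.4f} AUC "
                f"(> tolerance {tolerance}); coefficient magnitudes differ",
                stacklevel=2,
            )
    return biomarker, fidelity


def compare_model_vs_ratio(model: LogisticIRLS, biomarker: RatioBiomarker,
                           X: pd.DataFrame, y) -> dict:
    """Paired AUC report: model linear predictor vs ratio score.

    Both AUCs use the rank definition (ties at half credit); the report also
    carries a DeLong-style paired test p-value for the difference.
    """
    y = np.asarray(y).ravel().astype(int)
    if len(np.unique(y)) < 2:
        raise ValueError("both classes required in y")
    cols = list(model.feature_names_in_)
    model_scores = model.decision_function(X[cols])
    ratio_scores = biomarker.score(X)
    auc_model = auc(model_scores, y)
    auc_ratio = auc(ratio_scores, y)
    p = delong_paired_test(model_scores, ratio_scores, y)
    return {
        "auc_model": auc_model,
        "auc_ratio": auc_ratio,
        "delta_auc": auc_model - auc_ratio,
        "delong_p": p,
    }


def delong_paired_test(scores_a, scores_b, labels) -> float:
    """DeLong paired test for the AUC difference of two correlated scores.

    Uses the structural-components representation of the AUC covariance;
    returns the two-sided p-value (1.0 when the variance of the difference
    is numerically zero, e.g. for identical rankings).
    """
    labels = np.asarray(labels).ravel().astype(int)
    pos = labels == 1
    neg = ~pos
    m, n = int(pos.sum()), int(neg.sum())

    def components(scores):
        s = np.asarray(scores, dtype=float)
        sp, sn = s[pos], s[neg]
        # V10[i] = P_hat(X_i beats a random negative); V01[j] symmetric
        cmp_ = (sp[:, None] > sn[None, :]).astype(float)
        cmp_ += 0.5 * (sp[:, None] == sn[None, :])
        return cmp_.mean(axis=1), cmp_.mean(axis=0), cmp_.mean()

    v10_a, v01_a, auc_a = components(scores_a)
    v10_b, v01_b, auc_b = components(scores_b)
    s10 = np.cov(np.vstack([v10_a, v10_b]))
    s01 = np.cov(np.vstack([v01_a, v01_b]))
    var = (s10[0, 0] + s10[1, 1] - 2 * s10[0, 1]) / m \
        + (s01[0, 0] + s01[1, 1] - 2 * s01[0, 1]) / n
    if var <= 1e-16:
        return 1.0
    z = (auc_a - auc_b) / np.sqrt(var)
    return float(2.0 * stats.norm.sf(abs(z)))


def refit_on_ratio(biomarker: RatioBiomarker, X: pd.DataFrame, y) -> LogisticIRLS:
    """Univariate logistic refit on the ratio score (orientation check)."""
    score = pd.DataFrame({"ratio_score": biomarker.score(X)}, index=X.index)
    return fit_logistic(score, y, penalty="ridge")
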