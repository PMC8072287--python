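"""ROC cutoffs and survival stratification.

The biomarker score is turned into patient strata via the Youden-optimal
ROC threshold (maximum sensitivity + specificity), and the high/low groups
are compared on PFS and OS with Kaplan-Meier curves (product-limit
estimator with Greenwood variance), the two-group log-rank test (observed
minus expected with hypergeometric variance across event times), and a
univariate proportional-hazards ratio (partial likelihood, Efron ties, via
lifelines).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .models import auc as rank_auc

__all__ = [
    "RocCurve",
    "roc_curve",
    "dichotomize",
    "KMEstimate",
    "km_estimate",
    "LogrankResult",
    "logrank_test",
    "HazardRatioResult",
    "hazard_ratio",
    "SurvivalStrata",
    "stratified_survival",
    "subgroup_run",
]


@dataclass
class RocCurve:
    """Sensitivity/specificity over all thresholds, higher-score-positive.

    ``thresholds`` are the midpoints between adjacent distinct scores with
    −inf/+inf sentinels; predicted positive means ``score > threshold``.
    ``youden_optimal`` maximizes sensitivity + specificity − 1, ties broken
    toward higher sensitivity (the lower threshold).
    """

    thresholds: np.ndarray
    sensitivity: np.ndarray
    specificity: np.ndarray
    auc: float
    youden_optimal: float
    youden_j: float


def roc_curve(scores, labels) -> RocCurve:
    """Exhaustive-threshold ROC scan with the Youden-optimal cutoff."""
    scores = np.asarray(scores, dtype=float).ravel()
    labels = np.asarray(labels).ravel().astype(int)
    n1 = int(labels.sum())
    n0 = len(labels) - n1
    if n1 == 0 or n0 == 0:
        raise ValueError("ROC undefined: both classes must be present")

    uniq = np.unique(scores)
    mids = (uniq[:-1] + uniq[1:]) / 2.0 if len(uniq) > 1 else np.empty(0)
    thresholds = np.concatenate([[-np.inf], mids, [np.inf]])
    sens = np.empty(len(thresholds))
    spec = np.empty(len(thresholds))
    pos = scores[labels == 1]
    neg = scores[labels == 0]
    for i, t in enumerate(thresholds):
        sens[i] = np.mean(pos > t)
        spec[i] = np.mean(neg <= t)

    # trapezoid over the ROC polygon equals the rank AUC (ties at half);
    # points tied in FPR must be ordered by ascending sensitivity so the
    # polygon follows the upper envelope
    fpr = 1.0 - spec
    order = np.lexsort((sens, fpr))
    auc_val = float(np.trapezoid(sens[order], fpr[order]))

    j = sens + spec - 1.0
    best_j = j.max()
    if len(uniq) == 1:
        warnings.warn("all scores identical: Youden J = 0 everywhere; "
                      "returning the -inf sentinel", stacklevel=2)
    # among J-ties prefer higher sensitivity, i.e. the lowest threshold
    tied = np.flatnonzero(j >= best_j - 1e-12)
    best_idx = tied[np.argmax(sens[tied])]
    return RocCurve(
        thresholds=thresholds, sensitivity=sens, specificity=spec,
        auc=auc_val, youden_optimal=float(thresholds[best_idx]),
        youden_j=float(best_j),
    )


def dichotomize(scores, cutoff: float, orientation: str = "high-is-positive"):
    """Split patients at a cutoff: high group iff ``score > cutoff`` (strict).

    Returns ``(high_mask, counts)`` where counts is ``{'high': .., 'low': ..}``;
    an empty group triggers a warning (downstream analyses not evaluable).
    """
    if not np.isfinite(cutoff):
        raise ValueError("cutoff must be finite")
    scores = np.asarray(scores, dtype=float).ravel()
    high = scores > cutoff
    if orientation == "low-is-positive":
        high = ~high
    elif orientation != "high-is-positive":
        raise ValueError(f"unknown orientation {orientation!r}")
    counts = {"high": int(high.sum()), "low": int((~high).sum())}
    if counts["high"] == 0 or counts["low"] == 0:
        warnings.warn("dichotomization produced an empty group; survival "
                      "comparisons are not evaluable", stacklevel=2)
    return high, counts


@dataclass
class KMEstimate:
    """Product-limit survival estimate stepping only at event times."""

    times: np.ndarray          # distinct event times
    survival: np.ndarray       # S(t) just after each event time
    variance: np.ndarray       # Greenwood variance of S(t)
    n_at_risk: np.ndarray
    n_events: np.ndarray
    ci_lower: np.ndarray = field(default=None)
    ci_upper: np.ndarray = field(default=None)

    def at(self, t: float) -> float:
        """S(t), right-continuous."""
        idx = np.searchsorted(self.times, t, side="right") - 1
        return 1.0 if idx < 0 else float(self.survival[idx])


def km_estimate(times, events) -> KMEstimate:
    """Kaplan-Meier estimator with Greenwood variance and log-log 95% CIs."""
    times = np.asarray(times, dtype=float).ravel()
    events = np.asarray(events).ravel().astype(int)
    if len(times) == 0:
        raise ValueError("no observations")
    if (times <= 0).any():
        raise ValueError("times must be positive")
    if events.sum() == 0:
        warnings.warn("no events observed: survival curve is flat at 1",
                      stacklevel=2)
        empty = np.empty(0)
        return KMEstimate(times=empty, survival=empty, variance=empty,
                          n_at_risk=empty, n_events=empty,
                          ci_lower=empty, ci_upper=empty)

    event_times = np.unique(times[events == 1])
    surv, var_sum = 1.0, 0.0
    s_list, v_list, risk_list, d_list = [], [], [], []
    for t in event_times:
        n_risk = int((times >= t).sum())
        d = int(((times == t) & (events == 1)).sum())
        surv *= 1.0 - d / n_risk
        if n_risk > d:
            var_sum += d / (n_risk * (n_risk - d))
        else:
            var_sum = np.inf if surv == 0 else var_sum
        s_list.append(surv)
        v_list.append(surv**2 * var_sum if surv > 0 else 0.0)
        risk_list.append(n_risk)
        d_list.append(d)

    s = np.asarray(s_list)
    v = np.asarray(v_list)
    # log(-log S) transform keeps the interval inside [0, 1]
    with np.errstate(divide="ignore", invalid="ignore"):
        se_cll = np.sqrt(v) / np.abs(s * np.log(s))
        z = stats.norm.ppf(0.975)
        lo = s ** np.exp(z * se_cll)
        hi = s ** np.exp(-z * se_cll)
    lo = np.where((s <= 0) | (s >= 1), s, lo)
    hi = np.where((s <= 0) | (s >= 1), s, hi)
    return KMEstimate(
        times=event_times, survival=s, variance=v,
        n_at_risk=np.asarray(risk_list), n_events=np.asarray(d_list),
        ci_lower=lo, ci_upper=hi,
    )


@dataclass
class LogrankResult:
    chi2: float
    p_value: float
    observed: np.ndarray   # per-group observed events
    expected: np.ndarray   # per-group expected events


def logrank_test(times, events, groups) -> LogrankResult:
    """Two-group log-rank test.

    Sums, across distinct event times, the group-1 observed-minus-expected
    event counts with the hypergeometric variance, and refers
    ``(O − E)^2 / V`` to a 1-df chi-square.
    """
    times = np.asarray(times, dtype=float).ravel()
    events = np.asarray(events).ravel().astype(int)
    groups = np.asarray(groups).ravel().astype(int)
    if set(np.unique(groups)) - {0, 1}:
        raise ValueError("groups must be binary 0/1")
    if events.sum() == 0:
        raise ValueError("log-rank undefined: no events observed")

    o_minus_e, var = 0.0, 0.0
    obs = np.array([0.0, 0.0])
    exp = np.array([0.0, 0.0])
    for t in np.unique(times[events == 1]):
        at_risk = times >= t
        n = int(at_risk.sum())
        n1 = int((at_risk & (groups == 1)).sum())
        d = int(((times == t) & (events == 1)).sum())
        d1 = int(((times == t) & (events == 1) & (groups == 1)).sum())
        e1 = d * n1 / n
        o_minus_e += d1 - e1
        if n > 1:
            var += d * (n1 / n) * (1 - n1 / n) * (n - d) / (n - 1)
        obs += (d - d1, d1)
        exp += (d - e1, e1)
    if var <= 0:
        # all events in risk sets containing one group only: no information
        return LogrankResult(chi2=0.0, p_value=1.0, observed=obs, expected=exp)
    chi2 = o_minus_e**2 / var
    return LogrankResult(chi2=float(chi2), p_value=float(stats.chi2.sf(chi2, 1)),
                         observed=obs, expected=exp)


@dataclass
class HazardRatioResult:
    hazard_ratio: float
    ci_lower: float
    ci_upper: float
    p_value: float
    unbounded: bool = False


def hazard_ratio(times, events, groups) -> HazardRatioResult:
    """Univariate proportional-hazards ratio, group 1 versus group 0.

    Partial-likelihood fit with Efron tie handling (lifelines).  When all
    events fall in a single group the partial likelihood is monotone and
    the HR is reported as unbounded with an infinite CI endpoint.
    """
    times = np.asarray(times, dtype=float).ravel()
    events = np.asarray(events).ravel().astype(int)
    groups = np.asarray(groups).ravel().astype(int)
    if events.sum() == 0:
        raise ValueError("hazard ratio undefined: no events observed")
    ev1 = int(events[groups == 1].sum())
    ev0 = int(events[groups == 0].sum())
    if ev1 == 0 or ev0 == 0:
        warnings.warn("all events in one group: monotone partial likelihood, "
                      "hazard ratio unbounded", stacklevel=2)
        hr = np.inf if ev0 == 0 else 0.0
        return HazardRatioResult(
            hazard_ratio=hr,
            ci_lower=0.0 if hr == 0.0 else np.nan,
            ci_upper=np.inf if hr == np.inf else np.nan,
            p_value=np.nan, unbounded=True,
        )

    from lifelines import CoxPHFitter

    df = pd.DataFrame({"t": times, "e": events, "g": groups})
    cph = CoxPHFitter()
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        cph.fit(df, duration_col="t", event_col="e")
    coef = float(cph.params_["g"])
    se = float(cph.standard_errors_["g"])
    z = stats.norm.ppf(0.975)
    return HazardRatioResult(
        hazard_ratio=float(np.exp(coef)),
        ci_lower=float(np.exp(coef - z * se)),
        ci_upper=float(np.exp(coef + z * se)),
        p_value=float(cph.summary.loc["g", "p"]),
    )


@dataclass
class SurvivalStrata:
    """Full two-group survival comparison for one outcome."""

    outcome: str               # "pfs" or "os"
    km_high: KMEstimate
    km_low: KMEstimate
    logrank: LogrankResult
    hr: HazardRatioResult
    n_high: int
    n_low: int

    def to_dict(self) -> dict:
        return {
            "outcome": self.outcome,
            "n_high": self.n_high,
            "n_low": self.n_low,
            "logrank_chi2": self.logrank.chi2,
            "logrank_p": self.logrank.p_value,
            "hazard_ratio": self.hr.hazard_ratio,
            "hr_ci": [self.hr.ci_lower, self.hr.ci_upper],
            "hr_p": self.hr.p_value,
            "hr_unbounded": self.hr.unbounded,
        }


def stratified_survival(times, events, high_mask, outcome: str = "pfs") -> SurvivalStrata:
    """KM + log-rank + hazard ratio for high vs low biomarker groups."""
    high_mask = np.asarray(high_mask, dtype=bool).ravel()
    times = np.asarray(times, dtype=float).ravel()
    events = np.asarray(events).ravel().astype(int)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        km_hi = km_estimate(times[high_mask], events[high_mask])
        km_lo = km_estimate(times[~high_mask], events[~high_mask])
    lr = logrank_test(times, events, high_mask.astype(int))
    hr = hazard_ratio(times, events, high_mask.astype(int))
    return SurvivalStrata(outcome=outcome, km_high=km_hi, km_low=km_lo,
                          logrank=lr, hr=hr,
                          n_high=int(high_mask.sum()),
                          n_low=int((~high_mask).sum()))


def subgroup_run(cohort, scores, cutoff: float, subset_spec: dict,
                 small_group_n: int = 10) -> dict:
    """Re-run the survival stratification on a cohort subset.

    ``subset_spec`` maps metadata columns to required values, e.g.
    ``{"histology": "squamous"}`` or ``{"drug": "nivolumab"}``.  Returns
    per-outcome :class:`SurvivalStrata` plus the subset size; raises on an
    empty subset; warns when a biomarker group has fewer than
    ``small_group_n`` patients.
    """
    df = cohort.df if hasattr(cohort, "df") else cohort
    scores = np.asarray(scores, dtype=float).ravel()
    mask = np.ones(len(df), dtype=bool)
    for col, val in subset_spec.items():
        if col not in df.columns:
            raise ValueError(f"unknown subset column {col!r}")
        mask &= (df[col] == val).to_numpy()
    if not mask.any():
        raise ValueError(f"empty subset for filter {subset_spec!r}")
    sub = df.loc[mask]
    high, counts = dichotomize(scores[mask], cutoff)
    if 0 < min(counts.values()) < small_group_n:
        warnings.warn(f"subgroup {subset_spec!r}: a biomarker group has "
                      f"fewer than {small_group_n} patients", stacklevel=2)
    out = {"filter": subset_spec, "n": int(mask.sum()), "counts": counts}
    if counts["high"] == 0 or counts["low"] == 0:
        out["evaluable"] = False
        return out
    out["evaluable"] = True
    for outcome, (tcol, ecol) in {"pfs": ("pfs_days", "pfs_event"),
                                  "os": ("os_days", "os_event")}.items():
        out[outcome] = stratified_survival(
            sub[tcol].to_numpy(), sub[ecol].to_numpy(), high, outcome=outcome
        )
    return out
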