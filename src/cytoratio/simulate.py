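"""Synthetic cohort generator.

Emulates the statistical structure the analysis pipeline assumes, so every
stage is testable without patient data.  The generative law:

* **Cohorts.**  A discovery cohort (67 lung-cancer patients) and a
  validation cohort (24 multiple-cancer patients) drawn from the same law,
  each with its responder count fixed at the expected composition
  (19/67 ≈ 28.4%), mirroring an observed trial enrolment rather than a
  binomial draw.

* **Response model (dual hit).**  Objective response requires two
  coordinated marker events: an IP-10 (CXCL10) rise reflecting T-cell
  chemotaxis, and an IL-8 (CXCL8) fall reflecting shrinking tumor burden.
  Responders carry both hits; a fraction of non-responders carry exactly
  one ("partial" biological responses without radiographic response).
  Partial hits keep both markers informative conditional on each other and
  prevent the two-marker model from separating the classes.

* **Cytokine levels.**  Log-normal concentrations around plausible plasma
  medians: a patient factor shared across cytokines (exchangeable
  correlation ``rho``), a stable patient-by-cytokine baseline, and
  per-timepoint assay/biological noise (inflated at S1, the most volatile
  mid-chemotherapy sampling point).  A hit multiplies the S2 level by the
  configured effect (IP-10 x2.0, IL-8 x0.5) and the S1 level by the half
  log-effect (the change is partially developed by weeks 4-6).

* **Survival.**  Weibull PFS and OS with log-hazard linear in the true
  log2 ratio score (the summed planted S2 log-effects of a patient's
  hits), plus uniform right censoring over the second half of the study
  horizon.  Clinical benefit (PFS > 180 d) is therefore correlated with,
  but not identical to, the response label.

The latent truth (responder flag, per-marker hits, true score) is returned
as a sidecar, never stored in the cohort table.  All defaults are declared
synthetic: plausibility choices for a plasma-cytokine panel, not estimates
of any study.
"""

from __future__ import annotations

import copy
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .cohort import CYTOKINES, CohortTable, TIMEPOINTS

__all__ = ["SyntheticConfig", "generate_cohort", "generate_null_cohort",
           "BASELINE_MEDIANS_PG_ML", "DEFAULT_EFFECT_MAP"]

#: Plausible plasma medians (pg/mL) for the 27-plex panel; order-of-magnitude
#: realism only (chemokines like RANTES/PDGF-BB circulate far above the
#: interleukins).  Purely synthetic defaults.
BASELINE_MEDIANS_PG_ML: dict[str, float] = {
    "IL-2": 3.0, "IL-7": 8.0, "IL-12p70": 6.0, "IL-15": 4.0,
    "IFN-gamma": 12.0, "IP-10": 500.0,
    "IL-4": 2.5, "IL-5": 4.0, "IL-13": 3.0,
    "IL-1beta": 2.0, "IL-1RA": 150.0, "IL-6": 6.0, "IL-8": 15.0,
    "IL-17A": 10.0, "TNF-alpha": 20.0,
    "IL-10": 5.0,
    "FGF-basic": 25.0, "VEGF": 60.0, "G-CSF": 40.0, "GM-CSF": 5.0,
    "IL-9": 15.0, "MIP-1alpha": 4.0, "MIP-1beta": 80.0, "MCP-1": 30.0,
    "RANTES": 5000.0, "Eotaxin": 90.0, "PDGF-BB": 2000.0,
}

#: Hit-conditional multiplicative shifts by timepoint.  The S2 shifts
#: (IP-10 x2.0 up, IL-8 x0.5 down) are the planted ground truth; the S1
#: shifts are the half log-effect (sqrt of the S2 multiplier), an effect
#: partially developed by weeks 4-6.
DEFAULT_EFFECT_MAP: dict[str, dict[str, float]] = {
    "IP-10": {"S1": 2.0**0.5, "S2": 2.0},
    "IL-8": {"S1": 0.5**0.5, "S2": 0.5},
}


@dataclass
class SyntheticConfig:
    """Generative law of a synthetic chemo-immunotherapy cohort.

    Parameters with units and defaults:

    n_discovery, n_validation : cohort sizes (67 / 24).
    responder_fraction : fixed responder share per cohort (19/67).
    partial_hit_fraction : share of patients carrying exactly one marker
        hit without being responders (0.10 per marker, exclusive).
    baseline_medians : per-cytokine plasma medians, pg/mL.
    baseline_log2_sd : between-patient spread of log2 baselines (1.3).
    noise_log2_sd : per-timepoint assay + short-term biological noise on
        the log2 scale (0.2 at S0/S2).
    s1_noise_mult : noise inflation at the mid-chemotherapy S1 draw (1.5).
    rho : exchangeable between-cytokine correlation of baselines (0.2).
    effect_map : hit-conditional multiplicative shifts (see module doc).
    response_flip_prob : probability that the recorded best response
        contradicts the latent responder state (radiology misclassification
        noise; keeps R/NR and CB/NCB correlated but not identical).
    pfs_median_days, os_median_days : baseline medians at true score 0.
    gamma : log-hazard slope per unit of true score (-0.5; higher score,
        lower hazard).
    weibull_shape : Weibull shape (1.0 = exponential).
    censor_horizon_days : accrual/follow-up horizon; censoring is uniform
        on its second half.
    seed : RNG seed; fully determines the cohort.
    """

    n_discovery: int = 67
    n_validation: int = 24
    responder_fraction: float = 19.0 / 67.0
    partial_hit_fraction: float = 0.10
    baseline_medians: dict[str, float] = field(
        default_factory=lambda: dict(BASELINE_MEDIANS_PG_ML))
    baseline_log2_sd: float = 1.3
    noise_log2_sd: float = 0.2
    s1_noise_mult: float = 1.5
    rho: float = 0.2
    effect_map: dict[str, dict[str, float]] = field(
        default_factory=lambda: copy.deepcopy(DEFAULT_EFFECT_MAP))
    response_flip_prob: float = 0.005
    pfs_median_days: float = 120.0
    os_median_days: float = 300.0
    gamma: float = -0.5
    weibull_shape: float = 1.0
    censor_horizon_days: float = 730.0
    seed: int = 0

    def __post_init__(self):
        if not (0.0 < self.responder_fraction < 1.0):
            raise ValueError("responder_fraction must be in (0, 1)")
        if not (0.0 <= self.rho < 1.0):
            raise ValueError("rho must be in [0, 1)")
        if self.baseline_log2_sd <= 0 or self.noise_log2_sd <= 0:
            raise ValueError("degenerate config: variances must be positive")
        if not (0.0 <= self.partial_hit_fraction < 0.5):
            raise ValueError("partial_hit_fraction must be in [0, 0.5)")
        for cyt, shifts in self.effect_map.items():
            for tp, mult in shifts.items():
                if mult <= 0:
                    raise ValueError(
                        f"multiplicative effect {cyt}@{tp} must be > 0")

    def true_score_effect(self) -> float:
        """Responder-vs-non-responder difference of the latent log2 ratio
        score when no partial hits occur (``partial_hit_fraction = 0``)."""
        ip = self.effect_map.get("IP-10", {}).get("S2", 1.0)
        il = self.effect_map.get("IL-8", {}).get("S2", 1.0)
        return float(np.log2(ip) - np.log2(il))


def _fixed_count_flags(rng, n: int, k: int) -> np.ndarray:
    flags = np.zeros(n, dtype=bool)
    flags[rng.permutation(n)[:k]] = True
    return flags


def _weibull_times(rng, score, median_days, shape, gamma):
    """Proportional-hazards Weibull: h(t) proportional to exp(gamma*score)."""
    scale = median_days / np.log(2.0) ** (1.0 / shape)
    u = rng.exponential(1.0, size=len(score))
    return scale * (u / np.exp(gamma * score)) ** (1.0 / shape)


def generate_cohort(config: SyntheticConfig | None = None
                    ) -> tuple[CohortTable, pd.DataFrame]:
    """Draw one discovery + validation cohort from the generative law.

    Returns ``(cohort, truth)``: the cohort table ready for the pipeline,
    and a sidecar frame with the latent responder flag, per-marker hit
    indicators, and the realized true log2 ratio score per patient.
    """
    cfg = config or SyntheticConfig()
    rng = np.random.default_rng(cfg.seed)
    n = cfg.n_discovery + cfg.n_validation
    cohort_tag = np.array(["discovery"] * cfg.n_discovery
                          + ["validation"] * cfg.n_validation)

    markers = list(cfg.effect_map)
    m = len(markers)

    # fixed per-cohort composition: responder counts at the expected share,
    # exclusive partial hits distributed among the non-responders
    responder = np.zeros(n, dtype=bool)
    hits = np.zeros((n, m), dtype=bool)
    for lo, hi in ((0, cfg.n_discovery), (cfg.n_discovery, n)):
        size = hi - lo
        k_resp = int(round(size * cfg.responder_fraction))
        responder[lo:hi] = _fixed_count_flags(rng, size, k_resp)
        if m:
            hits[lo:hi][responder[lo:hi]] = True
            non = lo + np.flatnonzero(~responder[lo:hi])
            non = rng.permutation(non)
            k_part = int(round(size * cfg.partial_hit_fraction))
            for i in range(m):
                hits[non[i * k_part:(i + 1) * k_part], i] = True

    u = rng.standard_normal(n)
    z = rng.standard_normal((n, len(CYTOKINES)))
    sd = cfg.baseline_log2_sd
    baseline = (np.sqrt(cfg.rho) * u[:, None] + np.sqrt(1 - cfg.rho) * z) * sd

    data: dict[str, np.ndarray] = {}
    for j, cyt in enumerate(CYTOKINES):
        mu = np.log2(cfg.baseline_medians.get(cyt, 10.0))
        for tp in TIMEPOINTS:
            noise_sd = cfg.noise_log2_sd * (cfg.s1_noise_mult if tp == "S1" else 1.0)
            eps = rng.standard_normal(n) * noise_sd
            shift = 0.0
            if cyt in cfg.effect_map:
                mult = cfg.effect_map[cyt].get(tp, 1.0)
                shift = np.log2(mult) * hits[:, markers.index(cyt)]
            data[f"{cyt}_{tp}"] = 2.0 ** (mu + baseline[:, j] + eps + shift)

    # realized true log2 ratio score: the summed planted S2 log-effects of
    # the patient's hits (IP-10 hit contributes +1, IL-8 hit +1 by default)
    true_score = np.zeros(n)
    for i, cyt in enumerate(markers):
        true_score += abs(np.log2(cfg.effect_map[cyt].get("S2", 1.0))) * hits[:, i]

    pfs = _weibull_times(rng, true_score, cfg.pfs_median_days,
                         cfg.weibull_shape, cfg.gamma)
    os_t = _weibull_times(rng, true_score, cfg.os_median_days,
                          cfg.weibull_shape, cfg.gamma)
    censor = rng.uniform(cfg.censor_horizon_days / 2.0,
                         cfg.censor_horizon_days, size=n)
    pfs_event = (pfs <= censor).astype(int)
    os_event = (os_t <= censor).astype(int)
    pfs_obs = np.minimum(pfs, censor)
    os_obs = np.minimum(os_t, censor)

    flipped = rng.random(n) < cfg.response_flip_prob
    observed_responder = responder ^ flipped
    best = np.where(observed_responder,
                    np.where(rng.random(n) < 0.5, "PR", "SD"), "PD")
    cr = observed_responder & (rng.random(n) < 0.05)
    best = np.where(cr, "CR", best)

    histology = rng.choice(["adenocarcinoma", "squamous", "other"],
                           p=[0.55, 0.30, 0.15], size=n)
    drug = rng.choice(["nivolumab", "pembrolizumab"], p=[0.4, 0.6], size=n)

    df = pd.DataFrame({
        "patient_id": [f"P{i:03d}" for i in range(n)],
        "cohort": cohort_tag,
        "best_response": best,
        "pfs_days": np.round(pfs_obs, 1),
        "pfs_event": pfs_event,
        "os_days": np.round(os_obs, 1),
        "os_event": os_event,
        "histology": histology,
        "drug": drug,
        **{k: np.round(v, 4) for k, v in data.items()},
    })
    truth = pd.DataFrame({
        "patient_id": df["patient_id"],
        "responder": responder.astype(int),
        "true_score": true_score,
        **{f"hit_{c}": hits[:, i].astype(int) for i, c in enumerate(markers)},
    })
    return CohortTable(df), truth


def generate_null_cohort(config: SyntheticConfig | None = None
                         ) -> tuple[CohortTable, pd.DataFrame]:
    """Same generative law with every effect removed (type-I harness).

    The effect map is emptied and the survival coefficient gamma forced to
    0, so labels, cytokines and survival are mutually independent.
    """
    cfg = copy.deepcopy(config) if config is not None else SyntheticConfig()
    cfg.effect_map = {}
    cfg.gamma = 0.0
    return generate_cohort(cfg)
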