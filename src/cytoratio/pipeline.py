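"""End-to-end orchestration.

``run_pipeline`` executes the full discovery analysis in the published
order — cohort, feature construction, volcano screen, the stepwise-AIC
path (with LDA error and cross-validated AUC), the joint dual-set-AUC
screen, ratio collapse, ROC cutoffs, and survival stratification with
subgroups — writing every table as TSV and every report as JSON under one
output directory, together with a manifest that records each stage's
parameters and outputs.  Reruns with the same config and seed are
bit-identical (no timestamps enter any artifact).

``validate_external_cohort`` applies the frozen artifacts of a previous
run (model coefficients, biomarker, cutoffs, pseudocounts) to a new cohort
without any refitting.
"""

from __future__ import annotations

import dataclasses
import json
import logging
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .cohort import CohortTable, FeatureMatrix, build_features, derive_label_frame, load_cohort
from .joint import ScreeningConfig, joint_factor_screen, screening_report
from .models import auc, cv_auc, fit_lda, lda_apparent_error, stepwise_aic
from .ratio import CollapseError, RatioBiomarker, collapse_to_ratio, compare_model_vs_ratio
from .screening import volcano
from .survival import dichotomize, roc_curve, stratified_survival, subgroup_run

logger = logging.getLogger("cytoratio")

__all__ = ["RunConfig", "run_pipeline", "validate_external_cohort"]

ENDPOINTS = {"rnr": ("rnr", "R"), "cbncb": ("cbncb", "CB")}
STAGES = ("cohort", "features", "volcano", "stepwise", "joint_screening",
          "ratio_biomarker", "survival")


@dataclass
class RunConfig:
    """Reproducible run description; round-trips through YAML."""

    cohort_path: str
    out_dir: str
    seed: int
    endpoints: list[str] = field(default_factory=lambda: ["rnr", "cbncb"])
    pfs_threshold_days: float = 180.0
    pseudocount: object = "auto"
    lfc_threshold: float = 1.0
    nlp_threshold: float = 1.3
    alpha: float = 0.05
    k: float = 2.0
    objective: str = "min"
    eval_function: str = "aic"
    max_factors: int | None = None
    candidate_pool: str = "all"          # or "volcano"
    cv_folds: int = 5
    subgroups: list[dict] = field(default_factory=list)
    plots: bool = False
    log_level: str = "INFO"

    def __post_init__(self):
        unknown = set(self.endpoints) - set(ENDPOINTS)
        if unknown:
            raise ValueError(f"unknown endpoint(s): {sorted(unknown)}")
        if self.candidate_pool not in ("all", "volcano"):
            raise ValueError(f"unknown candidate_pool {self.candidate_pool!r}")
        if self.seed is None:
            raise ValueError("seed is mandatory")

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        with open(path) as fh:
            return cls(**yaml.safe_load(fh))

    def to_yaml(self, path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(self.to_dict(), fh, sort_keys=True)


def _json_default(o):
    if isinstance(o, (np.floating, np.integer)):
        return o.item()
    if isinstance(o, np.ndarray):
        return o.tolist()
    if dataclasses.is_dataclass(o):
        return dataclasses.asdict(o)
    raise TypeError(f"not serializable: {type(o)}")


def _write_json(obj, path: Path) -> None:
    with open(path, "w") as fh:
        json.dump(obj, fh, indent=2, sort_keys=True, default=_json_default)
        fh.write("\n")


def _endpoint_y(labels: pd.DataFrame, endpoint: str) -> pd.Series:
    col, positive = ENDPOINTS[endpoint]
    return (labels[col] == positive).astype(int).where(labels[col].notna())


def run_pipeline(config: RunConfig) -> dict:
    """Run the full pipeline; returns the manifest (also written to disk)."""
    logging.basicConfig(level=getattr(logging, config.log_level.upper(), logging.INFO))
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)

    manifest: dict = {"config": config.to_dict(), "stages": {}, "failures": []}

    cohort = load_cohort(config.cohort_path)
    disc, val = cohort.split()
    if disc.n_patients == 0:
        raise ValueError("cohort has no discovery patients")
    manifest["stages"]["cohort"] = {
        "input": str(config.cohort_path),
        "n_patients": cohort.n_patients,
        "n_discovery": disc.n_patients,
        "n_validation": val.n_patients,
    }
    logger.info("cohort: %d discovery / %d validation patients",
                disc.n_patients, val.n_patients)

    fm = build_features(cohort, pseudocount=config.pseudocount)
    fm.write(out / "features.tsv", out / "features_provenance.json")
    disc_idx = cohort.df["cohort"] == "discovery"
    X_disc = fm.values.loc[disc_idx.to_numpy()]
    X_val = fm.values.loc[(~disc_idx).to_numpy()]
    labels_disc = derive_label_frame(disc.df, config.pfs_threshold_days)
    labels_val = derive_label_frame(val.df, config.pfs_threshold_days)
    manifest["stages"]["features"] = {
        "output": "features.tsv",
        "n_features": len(fm.feature_ids),
        "pseudocounts": fm.pseudocounts,
    }

    volcano_out: dict = {}
    stepwise_out: dict = {}
    joint_out: dict = {}
    ratio_out: dict = {}
    survival_out: dict = {}

    for ep in config.endpoints:
        y_disc = _endpoint_y(labels_disc, ep)
        keep = y_disc.notna().to_numpy()
        Xd = X_disc.loc[keep]
        yd = y_disc[keep].astype(int).to_numpy()
        y_val_s = _endpoint_y(labels_val, ep) if val.n_patients else pd.Series(dtype=float)
        keep_v = y_val_s.notna().to_numpy() if val.n_patients else np.array([], bool)
        Xv = X_val.loc[keep_v] if val.n_patients else X_val
        yv = y_val_s[keep_v].astype(int).to_numpy() if val.n_patients else np.array([], int)

        # --- volcano screen (discovery cohort) ---------------------------
        vt = volcano(Xd, yd, lfc_threshold=config.lfc_threshold,
                     nlp_threshold=config.nlp_threshold)
        vt.to_csv(out / f"volcano_{ep}.tsv", sep="\t")
        sig = vt.index[vt["significant"]].tolist()
        volcano_out[ep] = {"output": f"volcano_{ep}.tsv", "n_significant": len(sig)}

        # --- stepwise-AIC path (volcano-significant candidates) ----------
        sw_candidates = sig if sig else list(Xd.columns)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            sw = stepwise_aic(Xd[sw_candidates], yd, direction="forward")
        sw_info: dict = {
            "candidates": len(sw_candidates),
            "candidates_from_volcano": bool(sig),
            "selected": sw.selected,
            "aic_trace": sw.aic_trace,
        }
        if sw.selected:
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                lda = fit_lda(Xd[sw.selected], yd)
                sw_info["lda_apparent_error"] = lda_apparent_error(lda, Xd[sw.selected], yd)
                cv = cv_auc(Xd[sw.selected], yd, n_folds=config.cv_folds,
                            seed=config.seed)
            sw_info["cv_auc"] = {"mean": cv.mean_auc, "folds": cv.fold_aucs,
                                 "skipped": cv.skipped_folds}
        _write_json(sw_info, out / f"stepwise_{ep}.json")
        stepwise_out[ep] = {"output": f"stepwise_{ep}.json",
                            "selected": sw.selected}

        # --- joint dual-set-AUC screen -----------------------------------
        if val.n_patients == 0 or len(np.unique(yv)) < 2:
            joint_out[ep] = {"skipped": "validation set missing or single-class"}
            manifest["failures"].append(f"joint_screening[{ep}]: no usable validation set")
            continue
        candidates = sig if config.candidate_pool == "volcano" and sig else list(Xd.columns)
        cfg = ScreeningConfig(alpha=config.alpha, k=config.k,
                              objective=config.objective,
                              eval_function=config.eval_function,
                              max_factors=config.max_factors)
        js = joint_factor_screen(Xd, yd, Xv, yv, candidates=candidates, config=cfg)
        _write_json(js.to_dict(), out / f"joint_{ep}.json")
        screening_report(js).to_csv(out / f"joint_{ep}_report.tsv", sep="\t", index=False)
        joint_out[ep] = {"output": f"joint_{ep}.json",
                         "report": f"joint_{ep}_report.tsv",
                         "selected": js.selected}

        # --- ratio collapse and cutoffs ----------------------------------
        if js.model is None or len(js.selected) != 2:
            ratio_out[ep] = {"skipped": "selection is not a two-factor model"}
            continue
        try:
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                biomarker, fidelity = collapse_to_ratio(js.model, Xd, yd)
        except CollapseError as exc:
            ratio_out[ep] = {"skipped": f"collapse refused: {exc}"}
            continue
        ratio_scores = biomarker.score(Xd)
        roc_ratio = roc_curve(ratio_scores, yd)
        biomarker.cutoff = roc_ratio.youden_optimal
        # equivalent probability-scale threshold of the logistic model
        probs = js.model.predict_proba(Xd[js.selected])[:, 1]
        roc_prob = roc_curve(probs, yd)
        ratio_info = {
            "biomarker": biomarker.to_dict(),
            "fidelity": fidelity,
            "model": js.model.to_dict(),
            "cutoff_log2": roc_ratio.youden_optimal,
            "cutoff_raw_ratio": biomarker.raw_cutoff,
            "model_probability_threshold": roc_prob.youden_optimal,
            "validation": compare_model_vs_ratio(js.model, biomarker, Xv, yv),
        }
        _write_json(ratio_info, out / f"biomarker_{ep}.json")
        ratio_out[ep] = {"output": f"biomarker_{ep}.json",
                         "cutoff_raw_ratio": biomarker.raw_cutoff}

        # --- survival stratification -------------------------------------
        surv_info: dict = {}
        for tag, frame, scores in (
            ("discovery", disc.df.loc[keep], ratio_scores),
            ("validation", val.df.loc[keep_v], biomarker.score(Xv)),
        ):
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                high, counts = dichotomize(scores, biomarker.cutoff)
            entry: dict = {"counts": counts}
            if 0 in counts.values():
                entry["evaluable"] = False
            else:
                entry["evaluable"] = True
                for outcome, (tcol, ecol) in {
                    "pfs": ("pfs_days", "pfs_event"),
                    "os": ("os_days", "os_event"),
                }.items():
                    st = stratified_survival(frame[tcol].to_numpy(),
                                             frame[ecol].to_numpy(),
                                             high, outcome=outcome)
                    entry[outcome] = st.to_dict()
            surv_info[tag] = entry
        for spec in config.subgroups:
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                try:
                    rep = subgroup_run(disc.subset(keep), ratio_scores,
                                       biomarker.cutoff, spec)
                except ValueError as exc:
                    rep = {"filter": spec, "error": str(exc)}
            key = ",".join(f"{k}={v}" for k, v in spec.items())
            sg = surv_info.setdefault("subgroups", {})
            sg[key] = {
                k: (v.to_dict() if hasattr(v, "to_dict") else v)
                for k, v in rep.items()
            }
        _write_json(surv_info, out / f"survival_{ep}.json")
        survival_out[ep] = {"output": f"survival_{ep}.json"}

        if config.plots:
            from . import plots
            plots.volcano_plot(vt, out / f"volcano_{ep}.png",
                               lfc_threshold=config.lfc_threshold,
                               nlp_threshold=config.nlp_threshold)
            plots.roc_plot(roc_ratio, out / f"roc_{ep}.png")
            if surv_info["discovery"].get("evaluable"):
                plots.km_plot(disc.df.loc[keep], ratio_scores, biomarker.cutoff,
                              out / f"km_{ep}.png")

    manifest["stages"]["volcano"] = volcano_out
    manifest["stages"]["stepwise"] = stepwise_out
    manifest["stages"]["joint_screening"] = joint_out
    manifest["stages"]["ratio_biomarker"] = ratio_out
    manifest["stages"]["survival"] = survival_out
    _write_json(manifest, out / "manifest.json")
    return manifest


def validate_external_cohort(run_dir, cohort: CohortTable,
                             endpoint: str = "rnr",
                             features: pd.DataFrame | None = None) -> dict:
    """Apply a previous run's frozen artifacts to a new cohort.

    No refitting occurs: the stored logistic coefficients, ratio biomarker,
    cutoff, and pseudocounts are applied as-is.  ``features`` may override
    the feature matrix (e.g. a pre-built TSV); missing required feature
    columns raise an error naming them.
    """
    run_dir = Path(run_dir)
    with open(run_dir / f"biomarker_{endpoint}.json") as fh:
        art = json.load(fh)
    with open(run_dir / "features_provenance.json") as fh:
        prov = json.load(fh)

    if features is None:
        fm = build_features(cohort, pseudocount=prov["pseudocounts"])
        features = fm.values
    model = art["model"]
    needed = list(model["feature_ids"])
    missing = [f for f in needed if f not in features.columns]
    if missing:
        raise ValueError(f"cohort lacks required feature(s): {', '.join(missing)}")

    biomarker = RatioBiomarker.from_dict(art["biomarker"])
    labels = derive_label_frame(cohort.df)
    y = _endpoint_y(labels, endpoint)
    keep = y.notna().to_numpy()
    X = features.loc[keep]
    yb = y[keep].astype(int).to_numpy()

    lin = X[needed].to_numpy() @ np.asarray(model["coefficients"]) + model["intercept"]
    ratio_scores = biomarker.score(X)
    report: dict = {
        "endpoint": endpoint,
        "n": int(keep.sum()),
        "auc_model": auc(lin, yb),
        "auc_ratio": auc(ratio_scores, yb),
        "cutoff_raw_ratio": art["cutoff_raw_ratio"],
    }
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        high, counts = dichotomize(ratio_scores, art["cutoff_log2"])
    report["counts"] = counts
    if 0 not in counts.values():
        frame = cohort.df.loc[keep]
        for outcome, (tcol, ecol) in {"pfs": ("pfs_days", "pfs_event"),
                                      "os": ("os_days", "os_event")}.items():
            st = stratified_survival(frame[tcol].to_numpy(),
                                     frame[ecol].to_numpy(), high, outcome)
            report[outcome] = st.to_dict()
    return report
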