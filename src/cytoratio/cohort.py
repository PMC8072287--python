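"""Cohort tables, endpoint labels, and the 162-column log2 feature matrix.

A cohort is one row per patient: 27 cytokine concentrations (pg/mL) at each
of three timepoints (S0 = baseline, S1 = weeks 4-6, S2 = weeks 10-12 after
therapy start), a best-overall-response category (CR/PR/SD/PD), PFS and OS
in days with event indicators, and a cohort tag separating the discovery
from the validation patients.  From it we derive

* two binary endpoints: responder/non-responder (R/NR; R = CR, PR or SD)
  and clinical benefit (CB = PFS strictly greater than 180 days);
* a feature matrix of 27 x 6 = 162 log2-scale columns: the three per-
  timepoint levels plus the three pairwise ratios (S1/S0, S2/S0, S2/S1),
  ratios being differences of log2 levels.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Iterable, Mapping

import numpy as np
import pandas as pd

__all__ = [
    "CYTOKINES",
    "TIMEPOINTS",
    "RATIO_PERIODS",
    "PERIODS",
    "FEATURE_IDS",
    "BEST_RESPONSES",
    "CohortTable",
    "FeatureMatrix",
    "CohortSchemaError",
    "CohortValidationError",
    "LabelingError",
    "canonical_cytokine",
    "feature_id",
    "load_cohort",
    "write_cohort",
    "derive_labels",
    "derive_label_frame",
    "build_features",
]

#: The fixed 27-cytokine multiplex panel (ASCII spellings used in files).
CYTOKINES: tuple[str, ...] = (
    "IL-2", "IL-7", "IL-12p70", "IL-15", "IFN-gamma", "IP-10",
    "IL-4", "IL-5", "IL-13",
    "IL-1beta", "IL-1RA", "IL-6", "IL-8", "IL-17A", "TNF-alpha",
    "IL-10",
    "FGF-basic", "VEGF", "G-CSF", "GM-CSF",
    "IL-9", "MIP-1alpha", "MIP-1beta", "MCP-1", "RANTES", "Eotaxin",
    "PDGF-BB",
)

TIMEPOINTS: tuple[str, ...] = ("S0", "S1", "S2")
RATIO_PERIODS: tuple[tuple[str, str], ...] = (("S1", "S0"), ("S2", "S0"), ("S2", "S1"))
PERIODS: tuple[str, ...] = ("S0", "S1", "S2", "S1/S0", "S2/S0", "S2/S1")

BEST_RESPONSES = frozenset({"CR", "PR", "SD", "PD"})
RESPONDER_CATEGORIES = frozenset({"CR", "PR", "SD"})

#: Default PFS cutoff (days) separating clinical benefit from no benefit;
#: the comparison is strict (PFS > 180 days).
PFS_THRESHOLD_DAYS = 180.0

META_COLUMNS = (
    "patient_id", "cohort", "best_response",
    "pfs_days", "pfs_event", "os_days", "os_event",
)
OPTIONAL_COLUMNS = ("histology", "drug")

# Synonyms seen in the literature and in instrument exports; matching is
# case-insensitive and ignores separators, so e.g. "il8", "IL_8" and
# "CXCL8" all resolve to "IL-8".
_ALIASES: dict[str, str] = {
    "CXCL10": "IP-10", "IP10": "IP-10",
    "CXCL8": "IL-8", "IL8": "IL-8",
    "IFNG": "IFN-gamma", "IFN-G": "IFN-gamma", "IFNGAMMA": "IFN-gamma",
    "IL1B": "IL-1beta", "IL1BETA": "IL-1beta",
    "IL1RA": "IL-1RA",
    "TNFA": "TNF-alpha", "TNFALPHA": "TNF-alpha", "TNF": "TNF-alpha",
    "MIP1A": "MIP-1alpha", "MIP1ALPHA": "MIP-1alpha", "CCL3": "MIP-1alpha",
    "MIP1B": "MIP-1beta", "MIP1BETA": "MIP-1beta", "CCL4": "MIP-1beta",
    "CCL2": "MCP-1", "MCP1": "MCP-1",
    "CCL5": "RANTES",
    "CCL11": "Eotaxin",
    "FGFBASIC": "FGF-basic", "FGF2": "FGF-basic", "BASICFGF": "FGF-basic",
    "PDGFBB": "PDGF-BB",
    "IL12P70": "IL-12p70", "IL12": "IL-12p70",
}


def _normalize(name: str) -> str:
    return "".join(ch for ch in name.upper() if ch.isalnum())


_CANONICAL_BY_KEY: dict[str, str] = {_normalize(c): c for c in CYTOKINES}
_CANONICAL_BY_KEY.update({_normalize(a): c for a, c in _ALIASES.items()})
# Greek spellings resolve too: IFN-γ, IL-1β, TNF-α, MIP-1α/β.
_CANONICAL_BY_KEY.update({
    _normalize("IFN-γ".replace("γ", "G")): "IFN-gamma",
})


def canonical_cytokine(name: str) -> str:
    """Resolve ``name`` to the canonical panel spelling.

    Matching is case-insensitive, ignores ``-``/``_``/spaces, and accepts the
    documented aliases (IP10 = IP-10 = CXCL10, IL8 = IL-8 = CXCL8, ...).
    Raises ``KeyError`` for names outside the 27-plex panel.
    """
    key = _normalize(
        name.replace("γ", "gamma").replace("β", "beta").replace("α", "alpha")
    )
    try:
        return _CANONICAL_BY_KEY[key]
    except KeyError:
        raise KeyError(f"unknown cytokine name: {name!r}") from None


def feature_id(cytokine: str, period: str) -> str:
    """Canonical feature identifier, e.g. ``'IP-10@S2/S0'``."""
    if period not in PERIODS:
        raise ValueError(f"unknown period {period!r}; expected one of {PERIODS}")
    return f"{canonical_cytokine(cytokine)}@{period}"


#: Ordered identifiers of the full 162-column feature matrix.
FEATURE_IDS: tuple[str, ...] = tuple(
    f"{c}@{p}" for p in PERIODS for c in CYTOKINES
)


def concentration_columns() -> list[str]:
    """The 81 per-timepoint concentration column names (``IL-8_S2`` etc.)."""
    return [f"{c}_{t}" for c in CYTOKINES for t in TIMEPOINTS]


class CohortSchemaError(ValueError):
    """A mandatory column is missing or could not be mapped."""


class CohortValidationError(ValueError):
    """One or more rows violate cohort invariants."""

    def __init__(self, problems: list[tuple[int, str]]):
        self.problems = problems
        lines = "; ".join(f"row {i}: {msg}" for i, msg in problems)
        super().__init__(f"cohort validation failed: {lines}")


class LabelingError(ValueError):
    """A patient cannot be assigned an endpoint label."""


@dataclass
class CohortTable:
    """A validated patient cohort.

    ``df`` holds one row per patient with the canonical columns: the
    metadata in :data:`META_COLUMNS` (plus optional ``histology``/``drug``)
    and 81 concentration columns named ``<cytokine>_<timepoint>``.
    """

    df: pd.DataFrame

    def __post_init__(self) -> None:
        self.df = self.df.reset_index(drop=True)

    @property
    def n_patients(self) -> int:
        return len(self.df)

    def split(self) -> tuple["CohortTable", "CohortTable"]:
        """Return (discovery, validation) sub-cohorts by the cohort tag."""
        disc = self.df[self.df["cohort"] == "discovery"]
        val = self.df[self.df["cohort"] == "validation"]
        return CohortTable(disc.copy()), CohortTable(val.copy())

    def subset(self, mask: np.ndarray | pd.Series) -> "CohortTable":
        return CohortTable(self.df.loc[np.asarray(mask)].copy())

    def labels(self, pfs_threshold_days: float = PFS_THRESHOLD_DAYS) -> pd.DataFrame:
        return derive_label_frame(self.df, pfs_threshold_days)


def _validate_frame(df: pd.DataFrame) -> None:
    conc_cols = concentration_columns()
    missing = [c for c in (*META_COLUMNS, *conc_cols) if c not in df.columns]
    if missing:
        raise CohortSchemaError(f"missing mandatory column(s): {', '.join(missing)}")

    problems: list[tuple[int, str]] = []
    for i, row in df.iterrows():
        br = row["best_response"]
        if pd.notna(br) and br not in BEST_RESPONSES:
            problems.append((int(i), f"unknown best_response code {br!r}"))
        for col in ("pfs_days", "os_days"):
            v = row[col]
            if pd.notna(v) and not v > 0:
                problems.append((int(i), f"{col} = {v} is not positive"))
        for col in ("pfs_event", "os_event"):
            v = row[col]
            if pd.notna(v) and v not in (0, 1):
                problems.append((int(i), f"{col} = {v} is not 0/1"))
        for col in conc_cols:
            v = row[col]
            if pd.notna(v) and v < 0:
                problems.append((int(i), f"negative concentration {col} = {v}"))
    if df["patient_id"].duplicated().any():
        dupes = df.loc[df["patient_id"].duplicated(), "patient_id"].tolist()
        problems.append((-1, f"duplicate patient_id(s): {dupes}"))
    if problems:
        raise CohortValidationError(problems)


def load_cohort(path, schema: Mapping[str, str] | None = None) -> CohortTable:
    """Read a delimited cohort file (CSV or TSV inferred from the suffix).

    Parameters
    ----------
    path
        Delimited text file, one row per patient, header row required.
    schema
        Optional mapping ``{file_column: canonical_column}`` renaming
        non-standard column headers.  Concentration columns may use any
        recognized cytokine alias; they are renamed to canonical spellings.
    """
    path = str(path)
    sep = "\t" if path.endswith((".tsv", ".tab", ".txt")) else ","
    df = pd.read_csv(path, sep=sep)
    if schema:
        df = df.rename(columns=dict(schema))

    # Canonicalize concentration headers (alias + case-insensitive matching).
    renames: dict[str, str] = {}
    for col in df.columns:
        if "_" in col:
            stem, _, tp = col.rpartition("_")
            if tp.upper() in TIMEPOINTS:
                try:
                    renames[col] = f"{canonical_cytokine(stem)}_{tp.upper()}"
                except KeyError:
                    pass
    df = df.rename(columns=renames)
    _validate_frame(df)
    return CohortTable(df)


def write_cohort(cohort: CohortTable, path) -> None:
    """Write a cohort as TSV (or CSV for a ``.csv`` suffix), round-trip safe."""
    path = str(path)
    sep = "," if path.endswith(".csv") else "\t"
    cohort.df.to_csv(path, sep=sep, index=False)


def derive_labels(record: Mapping, pfs_threshold_days: float = PFS_THRESHOLD_DAYS):
    """Derive the (R/NR, CB/NCB) endpoint labels for one patient record.

    R = best response CR, PR or SD; NR = PD.  CB = PFS strictly greater than
    ``pfs_threshold_days`` (default 180); a PFS of exactly 180 days is NCB.
    """
    br = record.get("best_response") if hasattr(record, "get") else record["best_response"]
    if br is None or (isinstance(br, float) and np.isnan(br)):
        raise LabelingError("best_response missing; patient excluded from R/NR analyses")
    if br not in BEST_RESPONSES:
        raise LabelingError(f"unknown best_response code {br!r}")
    pfs = float(record["pfs_days"])
    rnr = "R" if br in RESPONDER_CATEGORIES else "NR"
    cbncb = "CB" if pfs > pfs_threshold_days else "NCB"
    return rnr, cbncb


def derive_label_frame(
    df: pd.DataFrame, pfs_threshold_days: float = PFS_THRESHOLD_DAYS
) -> pd.DataFrame:
    """Vectorized :func:`derive_labels`: returns columns ``rnr``/``cbncb``.

    Patients with a missing best_response get ``rnr = NaN`` (excluded from
    R/NR analyses only); CB/NCB needs only PFS and is always assigned.
    """
    rnr = pd.Series(np.nan, index=df.index, dtype=object)
    known = df["best_response"].isin(BEST_RESPONSES)
    rnr[known] = np.where(
        df.loc[known, "best_response"].isin(RESPONDER_CATEGORIES), "R", "NR"
    )
    cbncb = np.where(df["pfs_days"] > pfs_threshold_days, "CB", "NCB")
    return pd.DataFrame({"rnr": rnr, "cbncb": cbncb}, index=df.index)


@dataclass
class FeatureMatrix:
    """162 log2-scale candidate features per patient, plus provenance.

    ``values`` is indexed by patient_id with one column per feature id in
    :data:`FEATURE_IDS` order.  Ratio columns are log2-level differences, so
    ``c@S2/S0 = c@S2 − c@S0`` holds by construction.
    """

    values: pd.DataFrame
    pseudocounts: dict[str, float] = field(default_factory=dict)
    patients_dropped: list[str] = field(default_factory=list)

    @property
    def feature_ids(self) -> list[str]:
        return list(self.values.columns)

    def provenance(self) -> dict:
        return {
            "pseudocounts": self.pseudocounts,
            "patients_dropped": self.patients_dropped,
            "n_features": len(self.values.columns),
        }

    def write(self, path, provenance_path=None) -> None:
        self.values.to_csv(path, sep="\t")
        if provenance_path is not None:
            import json

            with open(provenance_path, "w") as fh:
                json.dump(self.provenance(), fh, indent=2, sort_keys=True)


def _resolve_pseudocount(col: pd.Series, pseudocount) -> float:
    """Per-cytokine offset added before log2.

    ``'auto'`` (default): half the smallest positive observed value, applied
    only when the cytokine contains zeros — zero-free columns keep an offset
    of 0 so log ratios of clean data are undistorted.
    """
    if isinstance(pseudocount, (int, float)):
        return float(pseudocount)
    if pseudocount != "auto":
        raise ValueError(f"unknown pseudocount policy {pseudocount!r}")
    vals = col.dropna()
    if (vals > 0).all():
        return 0.0
    positive = vals[vals > 0]
    if positive.empty:
        return 1.0  # fully-zero column: arbitrary but recorded offset
    return float(positive.min()) / 2.0


def build_features(cohort: CohortTable, pseudocount="auto") -> FeatureMatrix:
    """Build the 162-column log2 feature matrix from a cohort.

    Level features are ``log2(x + pc)`` with a per-cytokine pseudocount
    ``pc``; ratio features are differences of the log2 levels.  Patients
    with a missing timepoint get missing entries in the affected columns
    only (complete-case handling happens downstream, per analysis).

    ``pseudocount`` may be ``'auto'`` (default policy), a scalar applied to
    every cytokine, or a ``{cytokine: value}`` mapping (e.g. the recorded
    provenance of a previous run, for frozen-artifact validation).
    """
    if cohort.n_patients == 0:
        raise ValueError("cohort is empty")
    df = cohort.df
    pcs: dict[str, float] = {}
    levels: dict[str, pd.Series] = {}
    for cyt in CYTOKINES:
        cols = [f"{cyt}_{t}" for t in TIMEPOINTS]
        stacked = pd.concat([df[c] for c in cols])
        if stacked.isna().all():
            warnings.warn(
                f"cytokine {cyt} has no observed values in any timepoint; "
                "columns retained as missing",
                stacklevel=2,
            )
        if isinstance(pseudocount, Mapping):
            pc = float(pseudocount.get(cyt, 0.0))
        else:
            pc = _resolve_pseudocount(stacked, pseudocount)
        pcs[cyt] = pc
        for t in TIMEPOINTS:
            levels[f"{cyt}@{t}"] = np.log2(df[f"{cyt}_{t}"] + pc)

    data = dict(levels)
    for num, den in RATIO_PERIODS:
        for cyt in CYTOKINES:
            data[f"{cyt}@{num}/{den}"] = levels[f"{cyt}@{num}"] - levels[f"{cyt}@{den}"]

    values = pd.DataFrame(data, index=df.index)[list(FEATURE_IDS)]
    values.index = pd.Index(df["patient_id"], name="patient_id")
    return FeatureMatrix(values=values, pseudocounts=pcs)
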