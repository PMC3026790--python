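"""Binned metabolic state space, unit conversion, and estimation from panel data.

The natural-history model tracks four risk factors (total cholesterol, HDL
cholesterol, systolic and diastolic blood pressure) as independent annual
Markov chains on a small number of clinically meaningful bins, while
triglycerides and HbA1c follow deterministic age trends.  This module defines
the bin structure (:class:`Cutpoints`), the fitted dynamics
(:class:`TransitionModel`), medication effect sizes (:class:`EffectTable`),
and the estimators that fit all of them from a longitudinal panel of
patient-visit records.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from importlib import resources
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
import yaml

__all__ = [
    "FACTORS",
    "BINNED_FACTORS",
    "TREND_FACTORS",
    "FACTOR_COLUMNS",
    "MEDICATION_CLASSES",
    "LIPID_CLASSES",
    "BP_CLASSES",
    "Cutpoints",
    "AgeTrend",
    "TransitionModel",
    "EffectTable",
    "convert_units",
    "friedewald_ldl",
    "bin_value",
    "estimate_transition_matrix",
    "fit_age_trend",
    "estimate_treatment_effect",
    "estimate_transition_model",
    "annual_state_sequences",
    "default_cutpoints",
    "default_effect_table",
]

# Risk factors tracked by the model.  The first four are binned Markov
# chains; TG and HbA1c are modelled as functions of age.
BINNED_FACTORS = ("TC", "HDL", "SBP", "DBP")
TREND_FACTORS = ("TG", "HBA1C")
FACTORS = BINNED_FACTORS + TREND_FACTORS

# Column names used in the panel CSV for each factor.
FACTOR_COLUMNS = {
    "TC": "tc_mgdl",
    "HDL": "hdl_mgdl",
    "TG": "tg_mgdl",
    "SBP": "sbp_mmhg",
    "DBP": "dbp_mmhg",
    "HBA1C": "hba1c_pct",
}

LIPID_CLASSES = ("statin", "fibrate")
BP_CLASSES = ("thiazide", "ace_arb", "beta_blocker", "ccb")
MEDICATION_CLASSES = LIPID_CLASSES + BP_CLASSES

# Factors each medication domain is allowed to touch.
_LIPID_FACTORS = {"TC", "HDL"}
_BP_FACTORS = {"SBP", "DBP"}

# mg/dL per mmol/L
_MGDL_PER_MMOL = {"cholesterol": 38.67, "triglyceride": 88.57}


class ValidationError(ValueError):
    """Raised when a configuration or input object violates its contract."""


# ---------------------------------------------------------------------------
# Unit conversion and derived lipid quantities
# ---------------------------------------------------------------------------

def convert_units(value, from_unit: str, to_unit: str, analyte: str):
    """Convert a lipid concentration between mg/dL and mmol/L.

    Cholesterol converts at 38.67 mg/dL per mmol/L, triglyceride at 88.57.
    """
    if analyte not in _MGDL_PER_MMOL:
        raise ValidationError(f"unknown analyte {analyte!r}")
    for unit in (from_unit, to_unit):
        if unit not in ("mg/dL", "mmol/L"):
            raise ValidationError(f"unknown unit {unit!r}")
    if from_unit == to_unit:
        return value
    factor = _MGDL_PER_MMOL[analyte]
    if from_unit == "mmol/L":
        return value * factor
    return value / factor


def friedewald_ldl(tc, hdl, tg):
    """LDL cholesterol (mg/dL) from the Friedewald equation: TC - HDL - TG/5.

    Valid only for triglycerides <= 400 mg/dL; a negative result is rejected
    as out of the formula's domain.
    """
    tc = np.asarray(tc, dtype=float)
    hdl = np.asarray(hdl, dtype=float)
    tg = np.asarray(tg, dtype=float)
    if np.any(tc <= 0) or np.any(hdl <= 0) or np.any(tg < 0):
        raise ValidationError("friedewald_ldl requires tc, hdl > 0 and tg >= 0")
    if np.any(tg > 400):
        raise ValidationError("Friedewald equation is not valid for TG > 400 mg/dL")
    ldl = tc - hdl - tg / 5.0
    if np.any(ldl < 0):
        raise ValidationError("Friedewald equation produced a negative LDL")
    if ldl.ndim == 0:
        return float(ldl)
    return ldl


def bin_value(value, edges: Sequence[float]):
    """Map a value to its half-open bin ``[edge_i, edge_{i+1})``.

    Values below the first edge map to bin 0; values at or above the last
    edge map to the last bin.  With ``k`` edges there are ``k + 1`` bins.
    """
    edges = np.asarray(edges, dtype=float)
    if edges.ndim != 1 or len(edges) < 1 or np.any(np.diff(edges) <= 0):
        raise ValidationError("edges must be strictly increasing")
    idx = np.searchsorted(edges, value, side="right")
    if np.isscalar(value) or np.ndim(value) == 0:
        return int(idx)
    return idx


# ---------------------------------------------------------------------------
# Cutpoints
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class Cutpoints:
    """Bin edges and representative values for the binned risk factors.

    ``edges[f]`` are strictly increasing cut-points for factor ``f``;
    ``representatives[f]`` holds one value per bin, used as the factor value
    whenever the cohort occupies that bin.
    """

    edges: Mapping[str, tuple]
    representatives: Mapping[str, tuple]

    def __post_init__(self):
        for f in BINNED_FACTORS:
            if f not in self.edges or f not in self.representatives:
                raise ValidationError(f"cutpoints missing factor {f}")
            e = np.asarray(self.edges[f], dtype=float)
            r = np.asarray(self.representatives[f], dtype=float)
            if len(e) < 1 or np.any(np.diff(e) <= 0):
                raise ValidationError(f"{f}: edges must be strictly increasing")
            if len(r) != len(e) + 1:
                raise ValidationError(
                    f"{f}: need {len(e) + 1} representatives, got {len(r)}"
                )
            lo = np.concatenate([[-np.inf], e])
            hi = np.concatenate([e, [np.inf]])
            if np.any(r < lo) or np.any(r >= hi):
                raise ValidationError(f"{f}: representatives must lie inside their bins")

    def n_bins(self, factor: str) -> int:
        return len(self.edges[factor]) + 1

    @property
    def shape(self) -> tuple:
        return tuple(self.n_bins(f) for f in BINNED_FACTORS)

    def bin(self, factor: str, value):
        return bin_value(value, self.edges[factor])

    def representative(self, factor: str, bin_index):
        return np.asarray(self.representatives[factor], dtype=float)[bin_index]

    @classmethod
    def from_yaml(cls, path) -> "Cutpoints":
        with open(path) as fh:
            doc = yaml.safe_load(fh)
        return cls.from_dict(doc)

    @classmethod
    def from_dict(cls, doc: Mapping) -> "Cutpoints":
        edges = {f: tuple(doc[f]["edges"]) for f in BINNED_FACTORS}
        reps = {f: tuple(doc[f]["representatives"]) for f in BINNED_FACTORS}
        return cls(edges=edges, representatives=reps)


def _load_packaged_yaml(name: str):
    text = resources.files("guidemark.data").joinpath(name).read_text()
    return yaml.safe_load(text)


def default_cutpoints() -> Cutpoints:
    """Packaged default bin structure.

    The edges place every guideline blood-pressure threshold on a bin
    boundary so initiation rules are exactly representable on binned states.
    """
    return Cutpoints.from_dict(_load_packaged_yaml("cutpoints_default.yaml"))


# ---------------------------------------------------------------------------
# Age trends
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class AgeTrend:
    """Least-squares linear trend of a factor on age.

    Predictions clamp to the fitted age range so the trend is never
    extrapolated beyond the data that produced it.
    """

    intercept: float
    slope: float
    age_min: float = 40.0
    age_max: float = 80.0

    def predict(self, age):
        a = np.clip(age, self.age_min, self.age_max)
        out = self.intercept + self.slope * a
        if np.ndim(age) == 0:
            return float(out)
        return out


def fit_age_trend(panel: pd.DataFrame, factor: str) -> AgeTrend:
    """Fit a least-squares line of a continuous factor on age."""
    if factor not in TREND_FACTORS:
        raise ValidationError(f"age trends are fit for {TREND_FACTORS}, not {factor!r}")
    col = FACTOR_COLUMNS[factor]
    age = panel["age"].to_numpy(dtype=float)
    y = panel[col].to_numpy(dtype=float)
    if len(np.unique(age)) < 2:
        raise ValidationError("age trend requires at least two distinct ages")
    slope, intercept = np.polyfit(age, y, 1)
    return AgeTrend(
        intercept=float(intercept),
        slope=float(slope),
        age_min=float(age.min()),
        age_max=float(age.max()),
    )


# ---------------------------------------------------------------------------
# Transition matrices
# ---------------------------------------------------------------------------

def estimate_transition_matrix(
    state_sequences: Iterable[Sequence[int]],
    n_states: int,
    smoothing: float = 0.5,
) -> np.ndarray:
    """Estimate an annual transition matrix from integer state sequences.

    Each sequence is a run of states at consecutive model-years for one
    patient; every adjacent pair contributes one transition count.  Entry
    (i, j) is ``(count(i->j) + smoothing) / (count(i->.) + n_states *
    smoothing)``.  A row with no counts and no smoothing falls back to the
    uniform distribution.
    """
    if n_states < 2:
        raise ValidationError("n_states must be >= 2")
    if smoothing < 0:
        raise ValidationError("smoothing must be >= 0")
    counts = np.zeros((n_states, n_states), dtype=float)
    for seq in state_sequences:
        s = np.asarray(seq, dtype=int)
        if s.size and (s.min() < 0 or s.max() >= n_states):
            raise ValidationError("state sequence contains out-of-range states")
        if s.size >= 2:
            np.add.at(counts, (s[:-1], s[1:]), 1.0)
    counts += smoothing
    row_sums = counts.sum(axis=1, keepdims=True)
    matrix = np.where(row_sums > 0, counts / np.where(row_sums == 0, 1, row_sums), 1.0 / n_states)
    return matrix


def annual_state_sequences(
    panel: pd.DataFrame, cutpoints: Cutpoints, factor: str
) -> list:
    """Per-patient bin sequences at one-model-year resolution.

    The first measurement in each patient-year is binned; runs of
    consecutive years form sequences, and gaps longer than one year split
    the run (no fractional-year interpolation).
    """
    col = FACTOR_COLUMNS[factor]
    edges = cutpoints.edges[factor]
    sequences = []
    annual = (
        panel.sort_values(["patient_id", "visit_year", "age"])
        .groupby(["patient_id", "visit_year"], sort=True)[col]
        .first()
        .reset_index()
    )
    for _, grp in annual.groupby("patient_id", sort=False):
        years = grp["visit_year"].to_numpy(dtype=int)
        bins = bin_value(grp[col].to_numpy(dtype=float), edges)
        run_start = 0
        for i in range(1, len(years) + 1):
            if i == len(years) or years[i] != years[i - 1] + 1:
                if i - run_start >= 2:
                    sequences.append(bins[run_start:i])
                run_start = i
    return sequences


@dataclass
class TransitionModel:
    """Fitted factor dynamics: one annual transition matrix per binned
    factor plus an age trend for triglycerides and HbA1c."""

    matrices: Mapping[str, np.ndarray]
    trends: Mapping[str, AgeTrend]

    def __post_init__(self):
        for f in BINNED_FACTORS:
            if f not in self.matrices:
                raise ValidationError(f"transition model missing matrix for {f}")
            m = np.asarray(self.matrices[f], dtype=float)
            if m.ndim != 2 or m.shape[0] != m.shape[1]:
                raise ValidationError(f"{f}: transition matrix must be square")
            if np.any(m < 0) or np.any(np.abs(m.sum(axis=1) - 1.0) > 1e-9):
                raise ValidationError(f"{f}: transition matrix rows must sum to 1")
        for f in TREND_FACTORS:
            if f not in self.trends:
                raise ValidationError(f"transition model missing age trend for {f}")

    def to_json(self, path) -> None:
        doc = {
            "matrices": {f: np.asarray(m).tolist() for f, m in self.matrices.items()},
            "trends": {
                f: {
                    "intercept": t.intercept,
                    "slope": t.slope,
                    "age_min": t.age_min,
                    "age_max": t.age_max,
                }
                for f, t in self.trends.items()
            },
        }
        with open(path, "w") as fh:
            json.dump(doc, fh, indent=2)

    @classmethod
    def from_json(cls, path) -> "TransitionModel":
        with open(path) as fh:
            doc = json.load(fh)
        matrices = {f: np.asarray(m, dtype=float) for f, m in doc["matrices"].items()}
        trends = {f: AgeTrend(**t) for f, t in doc["trends"].items()}
        return cls(matrices=matrices, trends=trends)


def estimate_transition_model(
    panel: pd.DataFrame,
    cutpoints: Cutpoints,
    smoothing: float = 0.5,
) -> TransitionModel:
    """Fit the full dynamic model (four chains + two age trends) from a panel."""
    matrices = {}
    for f in BINNED_FACTORS:
        seqs = annual_state_sequences(panel, cutpoints, f)
        matrices[f] = estimate_transition_matrix(seqs, cutpoints.n_bins(f), smoothing)
    trends = {f: fit_age_trend(panel, f) for f in TREND_FACTORS}
    return TransitionModel(matrices=matrices, trends=trends)


# ---------------------------------------------------------------------------
# Medication effect sizes
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class EffectTable:
    """Percent change in each factor caused by starting a medication class.

    Negative values are reductions.  Lipid-lowering classes may only touch
    TC and HDL; antihypertensive classes only SBP and DBP.
    """

    effects: Mapping[str, Mapping[str, float]]

    def __post_init__(self):
        for cls_name, per_factor in self.effects.items():
            if cls_name not in MEDICATION_CLASSES:
                raise ValidationError(f"unknown medication class {cls_name!r}")
            allowed = _LIPID_FACTORS if cls_name in LIPID_CLASSES else _BP_FACTORS
            extra = set(per_factor) - allowed
            if extra:
                raise ValidationError(
                    f"{cls_name} may only affect {sorted(allowed)}, found {sorted(extra)}"
                )

    def percent(self, med_class: str, factor: str) -> float:
        if med_class not in self.effects:
            raise ValidationError(f"unknown medication class {med_class!r}")
        return float(self.effects[med_class].get(factor, 0.0))

    def classes_affecting(self, factor: str) -> tuple:
        return tuple(c for c, pf in self.effects.items() if factor in pf)

    @classmethod
    def from_yaml(cls, path) -> "EffectTable":
        with open(path) as fh:
            return cls(effects=yaml.safe_load(fh))


def default_effect_table() -> EffectTable:
    """Packaged medication effect sizes (percent change on initiation)."""
    return EffectTable(effects=_load_packaged_yaml("effects_table.yaml"))


def estimate_treatment_effect(
    panel: pd.DataFrame,
    med_class: str,
    factor: str,
    effects: EffectTable | None = None,
    with_se: bool = False,
):
    """Estimate a medication's percent effect on a factor from start episodes.

    For every visit at which ``med_class`` first appears in a patient's
    active medication set, the percent change from the last pre-start
    measurement to the first post-start measurement is computed.  Episodes in
    which another class affecting the same factor starts in the same interval
    are discarded (their changes would be confounded).  Returns the mean
    percent change; with ``with_se=True`` also the standard error of the mean.
    """
    if med_class not in MEDICATION_CLASSES:
        raise ValidationError(f"unknown medication class {med_class!r}")
    effects = effects if effects is not None else default_effect_table()
    confounders = set(effects.classes_affecting(factor)) - {med_class}
    col = FACTOR_COLUMNS[factor]

    changes = []
    for _, grp in panel.sort_values(["patient_id", "visit_year", "age"]).groupby(
        "patient_id", sort=False
    ):
        meds = [set(m.split(";")) - {""} for m in grp["meds"].fillna("")]
        values = grp[col].to_numpy(dtype=float)
        for i in range(1, len(meds)):
            if med_class in meds[i] and med_class not in meds[i - 1]:
                started = meds[i] - meds[i - 1]
                if started & confounders:
                    continue
                pre, post = values[i - 1], values[i]
                if pre > 0:
                    changes.append(100.0 * (post - pre) / pre)
    if not changes:
        raise ValidationError(
            f"no eligible start episodes for {med_class} on {factor}"
        )
    changes = np.asarray(changes)
    mean = float(changes.mean())
    if with_se:
        se = float(changes.std(ddof=1) / np.sqrt(len(changes))) if len(changes) > 1 else np.inf
        return mean, se
    return mean
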