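"""Guideline initiation rules, medication sequencing, effects and costs.

A guideline is a declarative pair of initiation rules — a lipid rule over
LDL / TC / HDL / TC:HDL ratio and a blood-pressure rule over SBP / DBP —
revisited once per annual cycle.  When the lipid rule fires and the lipid
sequence (statins, then fibrates) is not exhausted, exactly the next lipid
class starts; the blood-pressure sequence (thiazides, ACE/ARB,
beta-blockers, calcium channel blockers) advances independently.
Medications are never discontinued (perfect adherence), and classes acting
on the same factor combine additively in percent terms.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from importlib import resources
from typing import Mapping, Optional

import numpy as np
import yaml

from .metabolic_states import (
    BP_CLASSES,
    LIPID_CLASSES,
    EffectTable,
    ValidationError,
    convert_units,
)

__all__ = [
    "LIPID_SEQUENCE",
    "BP_SEQUENCE",
    "BP_SEQUENCE_ACE_FIRST",
    "LipidRule",
    "GuidelineSpec",
    "MedicationState",
    "CostTable",
    "lipid_rule_triggers",
    "bp_rule_triggers",
    "annual_decision",
    "treated_factors",
    "annual_cost",
    "discount",
    "load_guideline",
    "packaged_guideline",
    "packaged_guideline_names",
    "default_cost_table",
]

LIPID_SEQUENCE = LIPID_CLASSES  # statins first, then fibrates
BP_SEQUENCE = BP_CLASSES  # thiazide, ACE/ARB, beta-blocker, CCB
BP_SEQUENCE_ACE_FIRST = ("ace_arb", "thiazide", "beta_blocker", "ccb")

_RULE_QUANTITIES = ("LDL", "TC", "HDL", "TC_HDL_RATIO")
_LIPID_ANALYTE = {"LDL": "cholesterol", "TC": "cholesterol", "HDL": "cholesterol"}


@dataclass(frozen=True)
class LipidRule:
    """One lipid initiation predicate, e.g. LDL >= 100 mg/dL."""

    quantity: str
    comparator: str  # ">=" or "<"
    threshold: float
    unit: str = "mg/dL"

    def __post_init__(self):
        if self.quantity not in _RULE_QUANTITIES:
            raise ValidationError(f"unknown lipid rule quantity {self.quantity!r}")
        if self.comparator not in (">=", "<"):
            raise ValidationError(f"unsupported comparator {self.comparator!r}")
        if self.threshold <= 0:
            raise ValidationError("lipid rule threshold must be > 0")

    def threshold_mgdl(self) -> float:
        """Threshold on the model's internal mg/dL scale (ratio: unitless)."""
        if self.quantity == "TC_HDL_RATIO":
            return self.threshold
        return convert_units(
            self.threshold, self.unit, "mg/dL", _LIPID_ANALYTE[self.quantity]
        )

    def holds(self, factors: Mapping):
        if self.quantity == "TC_HDL_RATIO":
            value = np.asarray(factors["TC"], dtype=float) / np.asarray(
                factors["HDL"], dtype=float
            )
        else:
            if self.quantity not in factors:
                raise ValidationError(f"lipid rule needs quantity {self.quantity!r}")
            value = np.asarray(factors[self.quantity], dtype=float)
        thr = self.threshold_mgdl()
        return value >= thr if self.comparator == ">=" else value < thr


@dataclass(frozen=True)
class GuidelineSpec:
    """Declarative guideline: initiation thresholds plus sequencing policy."""

    name: str
    initiate_at_diagnosis: frozenset = frozenset()
    lipid_rules: tuple = ()
    risk_stratified: bool = False
    ldl_thresholds_by_risk: Optional[Mapping[str, float]] = None  # mg/dL
    bp_sbp_threshold: Optional[float] = None  # strict >
    bp_dbp_threshold: Optional[float] = None  # strict >
    intensify: bool = True
    bp_first_line: Optional[str] = None  # e.g. "ace_arb"

    def __post_init__(self):
        for cls_name in self.initiate_at_diagnosis:
            if cls_name not in LIPID_CLASSES + BP_CLASSES:
                raise ValidationError(f"unknown medication class {cls_name!r}")
        if self.risk_stratified:
            t = self.ldl_thresholds_by_risk
            if not t or set(t) != {"high", "moderate", "low"}:
                raise ValidationError(
                    "risk_stratified guideline needs high/moderate/low LDL thresholds"
                )
            if not (t["high"] <= t["moderate"] <= t["low"]):
                raise ValidationError(
                    "risk-stratified LDL thresholds must satisfy high <= moderate <= low"
                )
        for thr in (self.bp_sbp_threshold, self.bp_dbp_threshold):
            if thr is not None and thr <= 0:
                raise ValidationError("blood-pressure thresholds must be > 0")
        if self.bp_first_line is not None and self.bp_first_line not in BP_CLASSES:
            raise ValidationError(f"unknown first-line class {self.bp_first_line!r}")

    @property
    def bp_sequence(self) -> tuple:
        if self.bp_first_line is None:
            return BP_SEQUENCE
        rest = tuple(c for c in BP_SEQUENCE if c != self.bp_first_line)
        return (self.bp_first_line,) + rest

    @classmethod
    def from_dict(cls, doc: Mapping) -> "GuidelineSpec":
        bp = doc.get("bp_rule") or {}
        return cls(
            name=doc["name"],
            initiate_at_diagnosis=frozenset(doc.get("initiate_at_diagnosis") or ()),
            lipid_rules=tuple(LipidRule(**r) for r in doc.get("lipid_rules") or ()),
            risk_stratified=bool(doc.get("risk_stratified", False)),
            ldl_thresholds_by_risk=doc.get("ldl_thresholds_by_risk"),
            bp_sbp_threshold=bp.get("sbp"),
            bp_dbp_threshold=bp.get("dbp"),
            intensify=bool(doc.get("intensify", True)),
            bp_first_line=doc.get("bp_first_line"),
        )


def load_guideline(path) -> GuidelineSpec:
    with open(path) as fh:
        return GuidelineSpec.from_dict(yaml.safe_load(fh))


def packaged_guideline(key: str) -> GuidelineSpec:
    """Load one of the packaged guideline specifications by short key
    (e.g. ``us2``, ``canada``, ``accord``, ``no_treatment``)."""
    res = resources.files("guidemark.data.guidelines").joinpath(f"{key}.yaml")
    try:
        text = res.read_text()
    except FileNotFoundError:
        raise ValidationError(f"no packaged guideline named {key!r}") from None
    return GuidelineSpec.from_dict(yaml.safe_load(text))


def packaged_guideline_names() -> tuple:
    files = resources.files("guidemark.data.guidelines")
    return tuple(
        sorted(p.name[:-5] for p in files.iterdir() if p.name.endswith(".yaml"))
    )


@dataclass(frozen=True)
class MedicationState:
    """Progress along the lipid and blood-pressure medication sequences.

    ``n_lipid`` and ``n_bp`` count how many classes of each sequence are
    active; classes are never removed, so the counters fully determine the
    active set.
    """

    n_lipid: int = 0
    n_bp: int = 0
    bp_sequence: tuple = BP_SEQUENCE

    def __post_init__(self):
        if not 0 <= self.n_lipid <= len(LIPID_SEQUENCE):
            raise ValidationError("n_lipid out of range")
        if not 0 <= self.n_bp <= len(self.bp_sequence):
            raise ValidationError("n_bp out of range")

    @property
    def active_classes(self) -> tuple:
        return LIPID_SEQUENCE[: self.n_lipid] + self.bp_sequence[: self.n_bp]

    @property
    def any_active(self) -> bool:
        return self.n_lipid > 0 or self.n_bp > 0


# ---------------------------------------------------------------------------
# Rule evaluation and the annual decision
# ---------------------------------------------------------------------------

def _stratified_ldl_threshold(spec: GuidelineSpec, ten_year_chd_risk):
    t = spec.ldl_thresholds_by_risk
    risk = np.asarray(ten_year_chd_risk, dtype=float)
    return np.where(risk > 0.20, t["high"], np.where(risk >= 0.10, t["moderate"], t["low"]))


def lipid_rule_triggers(spec: GuidelineSpec, factors: Mapping, ten_year_chd_risk=None):
    """Whether the guideline's lipid arm calls for initiation.

    ``factors`` holds LDL, TC, HDL in mg/dL; predicates stated in mmol/L are
    converted at evaluation time.  For risk-stratified guidelines the LDL
    threshold is chosen by the ten-year CHD risk stratum (> 20% high,
    10-20% moderate, < 10% low).  Accepts scalars or numpy arrays.
    """
    if spec.risk_stratified:
        if ten_year_chd_risk is None:
            raise ValidationError(
                f"{spec.name}: risk-stratified rule needs ten_year_chd_risk"
            )
        thr = _stratified_ldl_threshold(spec, ten_year_chd_risk)
        if "LDL" not in factors:
            raise ValidationError("lipid rule needs quantity 'LDL'")
        out = np.asarray(factors["LDL"], dtype=float) >= thr
    elif spec.lipid_rules:
        out = np.asarray(False)
        for rule in spec.lipid_rules:
            out = out | np.asarray(rule.holds(factors))
    else:
        out = np.asarray(False)
    if out.ndim == 0:
        return bool(out)
    return out


def bp_rule_triggers(spec: GuidelineSpec, factors: Mapping):
    """Whether the blood-pressure arm calls for initiation (strict >)."""
    if spec.bp_sbp_threshold is None and spec.bp_dbp_threshold is None:
        return False
    out = np.asarray(False)
    if spec.bp_sbp_threshold is not None:
        out = out | (np.asarray(factors["SBP"], dtype=float) > spec.bp_sbp_threshold)
    if spec.bp_dbp_threshold is not None:
        out = out | (np.asarray(factors["DBP"], dtype=float) > spec.bp_dbp_threshold)
    if out.ndim == 0:
        return bool(out)
    return out


def initial_medication_state(spec: GuidelineSpec) -> MedicationState:
    """Medication state at model entry (diagnosis, age 40)."""
    n_lipid = sum(1 for c in LIPID_CLASSES if c in spec.initiate_at_diagnosis)
    n_bp = sum(1 for c in BP_CLASSES if c in spec.initiate_at_diagnosis)
    return MedicationState(n_lipid=n_lipid, n_bp=n_bp, bp_sequence=spec.bp_sequence)


def annual_decision(
    spec: GuidelineSpec,
    meds: MedicationState,
    factors: Mapping,
    ten_year_chd_risk=None,
) -> MedicationState:
    """One annual treatment decision: add at most one new class per domain.

    If the guideline does not intensify (pure initiate-at-diagnosis
    strategies), the medication state never changes after entry.
    Medications are never removed.
    """
    if not spec.intensify:
        return meds
    n_lipid, n_bp = meds.n_lipid, meds.n_bp
    if n_lipid < len(LIPID_SEQUENCE) and lipid_rule_triggers(
        spec, factors, ten_year_chd_risk
    ):
        n_lipid += 1
    if n_bp < len(meds.bp_sequence) and bp_rule_triggers(spec, factors):
        n_bp += 1
    if (n_lipid, n_bp) == (meds.n_lipid, meds.n_bp):
        return meds
    return replace(meds, n_lipid=n_lipid, n_bp=n_bp)


# ---------------------------------------------------------------------------
# Treatment effects on observed factors
# ---------------------------------------------------------------------------

def treated_factors(factors: Mapping, meds, effects: EffectTable) -> dict:
    """Observed factor values under active medication.

    Effects of classes acting on the same factor add in percent terms:
    ``observed = untreated * (1 + sum(percent) / 100)``.  ``meds`` may be a
    :class:`MedicationState` or any iterable of class names.
    """
    active = meds.active_classes if isinstance(meds, MedicationState) else tuple(meds)
    out = {}
    for factor, value in factors.items():
        total_pct = sum(effects.percent(c, factor) for c in active)
        if total_pct <= -100.0:
            raise ValidationError(
                f"summed reduction on {factor} is {total_pct}% (<= -100%)"
            )
        out[factor] = np.asarray(value, dtype=float) * (1.0 + total_pct / 100.0)
        if np.ndim(value) == 0:
            out[factor] = float(out[factor])
    return out


# ---------------------------------------------------------------------------
# Costs
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class CostTable:
    """Annual medication cost per class, in US dollars."""

    costs: Mapping[str, float]
    variant: str = "base"

    def __post_init__(self):
        for cls_name, c in self.costs.items():
            if c < 0:
                raise ValidationError(f"negative annual cost for {cls_name}")

    @classmethod
    def from_yaml(cls, path, variant: str = "base") -> "CostTable":
        with open(path) as fh:
            doc = yaml.safe_load(fh)
        if variant not in doc:
            raise ValidationError(f"cost table has no variant {variant!r}")
        return cls(costs=doc[variant], variant=variant)


def default_cost_table(variant: str = "base") -> CostTable:
    """Packaged annual cost table; ``variant`` is 'base' or 'upper'."""
    text = resources.files("guidemark.data").joinpath("costs_table.yaml").read_text()
    doc = yaml.safe_load(text)
    if variant not in doc:
        raise ValidationError(f"cost table has no variant {variant!r}")
    return CostTable(costs=doc[variant], variant=variant)


def annual_cost(meds, costs: CostTable) -> float:
    """Total annual cost of the active medication set."""
    active = meds.active_classes if isinstance(meds, MedicationState) else tuple(meds)
    total = 0.0
    for cls_name in active:
        if cls_name not in costs.costs:
            raise ValidationError(f"cost table missing class {cls_name!r}")
        total += costs.costs[cls_name]
    return float(total)


def discount(amount, years_from_start, rate: float = 0.03):
    """Present value at model entry: ``amount / (1 + rate) ** years``."""
    if rate < 0:
        raise ValidationError("discount rate must be >= 0")
    if np.any(np.asarray(years_from_start) < 0):
        raise ValidationError("years_from_start must be >= 0")
    out = np.asarray(amount, dtype=float) / (1.0 + rate) ** np.asarray(
        years_from_start, dtype=float
    )
    if np.ndim(amount) == 0 and np.ndim(years_from_start) == 0:
        return float(out)
    return out
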