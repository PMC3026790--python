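"""Synthetic longitudinal panel generator.

Stands in for a clinic-based diabetes registry: a few hundred patients
observed over about a decade, with repeated measurements of total
cholesterol, HDL, triglycerides, blood pressure and HbA1c.  Each factor
follows a latent untreated first-order autoregressive (AR(1)) process
around an age-drifting mean — so binned values form an approximate annual
Markov chain — and medication starts overlay multiplicative percent
effects on the latent value.  Deaths from other causes censor subsequent
visits.  Everything is deterministic given the configuration seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from importlib import resources
from typing import Mapping, Optional

import numpy as np
import pandas as pd
import yaml

from .metabolic_states import (
    FACTORS,
    FACTOR_COLUMNS,
    MEDICATION_CLASSES,
    EffectTable,
    ValidationError,
)

__all__ = [
    "PANEL_COLUMNS",
    "CohortConfig",
    "PanelSummary",
    "generate_panel",
    "inject_treatment_starts",
    "summarize_panel",
    "read_panel",
    "write_panel",
    "validate_panel",
    "default_cohort_config",
]

PANEL_COLUMNS = (
    "patient_id",
    "sex",
    "age",
    "visit_year",
    "tc_mgdl",
    "hdl_mgdl",
    "tg_mgdl",
    "sbp_mmhg",
    "dbp_mmhg",
    "hba1c_pct",
    "meds",
    "died",
)

_FLOOR = {f: 1.0 for f in FACTORS}
_FLOOR["HBA1C"] = 3.01
_CEIL = {"HBA1C": 19.99}


@dataclass(frozen=True)
class CohortConfig:
    """Configuration of the synthetic cohort generator."""

    n_patients: int
    age_range: tuple
    years_observed: int
    visit_rate: float
    sex_ratio: float
    baseline_means: Mapping[str, float]
    baseline_sds: Mapping[str, float]
    annual_drift: Mapping[str, float]
    persistence: Mapping[str, float]
    death_rate_other: float
    seed: int = 0

    def __post_init__(self):
        if self.n_patients <= 0:
            raise ValidationError("n_patients must be > 0")
        lo, hi = self.age_range
        if not lo < hi:
            raise ValidationError("age_range low must be < high")
        if self.years_observed <= 0:
            raise ValidationError("years_observed must be > 0")
        if self.visit_rate < 1.0:
            raise ValidationError("visit_rate must be >= 1 (one scheduled visit/year)")
        if not 0.0 <= self.sex_ratio <= 1.0:
            raise ValidationError("sex_ratio must lie in [0, 1]")
        if not 0.0 <= self.death_rate_other <= 1.0:
            raise ValidationError("death_rate_other must lie in [0, 1]")
        for f in FACTORS:
            for name, mapping in (
                ("baseline_means", self.baseline_means),
                ("baseline_sds", self.baseline_sds),
                ("annual_drift", self.annual_drift),
                ("persistence", self.persistence),
            ):
                if f not in mapping:
                    raise ValidationError(f"{name} missing factor {f}")
            if self.baseline_sds[f] < 0:
                raise ValidationError(f"baseline_sds[{f}] must be >= 0")
            if not 0.0 < self.persistence[f] < 1.0:
                raise ValidationError(f"persistence[{f}] must lie in (0, 1)")

    @classmethod
    def from_dict(cls, doc: Mapping) -> "CohortConfig":
        return cls(
            n_patients=int(doc["n_patients"]),
            age_range=tuple(doc["age_range"]),
            years_observed=int(doc["years_observed"]),
            visit_rate=float(doc["visit_rate"]),
            sex_ratio=float(doc["sex_ratio"]),
            baseline_means=dict(doc["baseline_means"]),
            baseline_sds=dict(doc["baseline_sds"]),
            annual_drift=dict(doc["annual_drift"]),
            persistence=dict(doc["persistence"]),
            death_rate_other=float(doc["death_rate_other"]),
            seed=int(doc.get("seed", 0)),
        )

    @classmethod
    def from_yaml(cls, path) -> "CohortConfig":
        with open(path) as fh:
            return cls.from_dict(yaml.safe_load(fh))


def default_cohort_config(seed: Optional[int] = None) -> CohortConfig:
    """Packaged default configuration (registry-scale cohort)."""
    text = resources.files("guidemark.data").joinpath("cohort_default.yaml").read_text()
    doc = yaml.safe_load(text)
    if seed is not None:
        doc["seed"] = int(seed)
    return CohortConfig.from_dict(doc)


def _mean_at(config: CohortConfig, factor: str, age):
    lo = config.age_range[0]
    return config.baseline_means[factor] + config.annual_drift[factor] * (age - lo)


def generate_panel(config: CohortConfig) -> pd.DataFrame:
    """Generate an untreated longitudinal panel.

    Each patient enters at a uniform age inside the configured range and is
    observed for ``years_observed`` years with one scheduled visit per year
    plus Poisson-thinned extra visits reaching ``visit_rate`` on average.
    Latent factor values follow a continuous-time AR(1): over a gap of
    ``dt`` years the autocorrelation is ``persistence ** dt`` and the
    stationary spread stays at ``baseline_sds``.
    """
    rng = np.random.default_rng(config.seed)
    lo, hi = config.age_range
    entry_hi = max(lo, hi - config.years_observed)
    records = []
    for pid in range(config.n_patients):
        entry_age = rng.uniform(lo, entry_hi) if entry_hi > lo else float(lo)
        sex = "male" if rng.random() < config.sex_ratio else "female"

        # visit times (years since entry): one scheduled per year + extras
        times = []
        for y in range(config.years_observed):
            times.append(y + 0.1 * rng.random())
            extras = rng.poisson(max(config.visit_rate - 1.0, 0.0))
            times.extend(y + rng.random(extras))
        times = np.sort(np.asarray(times))

        # other-cause death: geometric in years, censoring later visits
        death_time = np.inf
        if config.death_rate_other > 0:
            death_year = rng.geometric(config.death_rate_other) - 1
            if death_year < config.years_observed:
                death_time = death_year + rng.random()
        died = death_time < config.years_observed
        kept = times < death_time
        kept[0] = True  # the entry visit always happens
        times = times[kept]

        # latent AR(1) per factor along the visit grid
        values = {}
        for f in FACTORS:
            sd = config.baseline_sds[f]
            rho = config.persistence[f]
            x = _mean_at(config, f, entry_age) + sd * rng.standard_normal()
            series = [x]
            for i in range(1, len(times)):
                dt = times[i] - times[i - 1]
                rho_dt = rho**dt
                m_prev = _mean_at(config, f, entry_age + times[i - 1])
                m_now = _mean_at(config, f, entry_age + times[i])
                innov = sd * np.sqrt(max(1.0 - rho_dt**2, 0.0)) * rng.standard_normal()
                x = m_now + rho_dt * (x - m_prev) + innov
                series.append(x)
            arr = np.asarray(series)
            arr = np.clip(arr, _FLOOR[f], _CEIL.get(f, np.inf))
            values[f] = arr

        for i, t in enumerate(times):
            records.append(
                {
                    "patient_id": pid,
                    "sex": sex,
                    "age": entry_age + t,
                    "visit_year": int(np.floor(t)),
                    "tc_mgdl": values["TC"][i],
                    "hdl_mgdl": values["HDL"][i],
                    "tg_mgdl": values["TG"][i],
                    "sbp_mmhg": values["SBP"][i],
                    "dbp_mmhg": values["DBP"][i],
                    "hba1c_pct": values["HBA1C"][i],
                    "meds": "",
                    "died": int(died and i == len(times) - 1),
                }
            )
    return pd.DataFrame.from_records(records, columns=list(PANEL_COLUMNS))


def inject_treatment_starts(
    panel: pd.DataFrame,
    effects: EffectTable,
    start_rate: float,
    seed: int = 0,
    effect_noise_sd: float = 1.0,
) -> pd.DataFrame:
    """Overlay medication starts with known ground-truth effects.

    Each patient-year one new medication class (chosen uniformly among
    classes not yet active) starts with probability ``start_rate``, taking
    effect at the first visit of that year.  From that visit on, every
    factor the class affects is multiplied by ``1 + (percent + eps) / 100``
    with a per-episode Gaussian perturbation ``eps`` of ``effect_noise_sd``
    percentage points.  Multipliers of different classes compound, so the
    per-class percent change remains identifiable from pre/post ratios even
    when other classes are already active.
    """
    if not 0.0 <= start_rate <= 1.0:
        raise ValidationError("start_rate must lie in [0, 1]")
    for cls_name in effects.effects:
        if cls_name not in MEDICATION_CLASSES:
            raise ValidationError(f"unknown medication class {cls_name!r}")
    if start_rate == 0.0:
        return panel.copy()

    rng = np.random.default_rng(seed)
    out = panel.sort_values(["patient_id", "visit_year", "age"]).reset_index(drop=True)
    classes = tuple(effects.effects)

    all_years = out["visit_year"].to_numpy(dtype=int)
    meds_col = np.empty(len(out), dtype=object)
    factor_mult = {f: np.ones(len(out)) for f in FACTORS}

    for _, idx in out.groupby("patient_id", sort=False).groups.items():
        idx = np.asarray(idx)
        years = all_years[idx]
        active: list = []
        multipliers = {f: 1.0 for f in FACTORS}
        for year in np.unique(years):
            inactive = [c for c in classes if c not in active]
            if inactive and rng.random() < start_rate:
                started = inactive[rng.integers(len(inactive))]
                active.append(started)
                for f, pct in effects.effects[started].items():
                    eps = effect_noise_sd * rng.standard_normal()
                    multipliers[f] *= 1.0 + (pct + eps) / 100.0
            mask = idx[years == year]
            meds_col[mask] = ";".join(active)
            for f, mult in multipliers.items():
                if mult != 1.0:
                    factor_mult[f][mask] = mult
    out["meds"] = meds_col
    for f in FACTORS:
        out[FACTOR_COLUMNS[f]] = out[FACTOR_COLUMNS[f]].to_numpy(dtype=float) * factor_mult[f]
    return out


@dataclass(frozen=True)
class PanelSummary:
    n_patients: int
    n_records: int
    fraction_died: float
    factor_means: Mapping[str, float]


def summarize_panel(panel: pd.DataFrame) -> PanelSummary:
    """Headline statistics of a panel: size, mortality, factor means."""
    if len(panel) == 0:
        raise ValidationError("cannot summarize an empty panel")
    n_patients = panel["patient_id"].nunique()
    died = panel.groupby("patient_id")["died"].max().sum()
    means = {
        f: float(panel[FACTOR_COLUMNS[f]].mean()) for f in FACTORS
    }
    return PanelSummary(
        n_patients=int(n_patients),
        n_records=int(len(panel)),
        fraction_died=float(died / n_patients),
        factor_means=means,
    )


def validate_panel(panel: pd.DataFrame) -> None:
    """Check panel invariants; raises :class:`ValidationError` on violation."""
    missing = set(PANEL_COLUMNS) - set(panel.columns)
    if missing:
        raise ValidationError(f"panel missing columns {sorted(missing)}")
    for f in ("TC", "HDL", "TG", "SBP", "DBP"):
        if np.any(panel[FACTOR_COLUMNS[f]].to_numpy(dtype=float) <= 0):
            raise ValidationError(f"non-positive values in {FACTOR_COLUMNS[f]}")
    hba1c = panel["hba1c_pct"].to_numpy(dtype=float)
    if np.any(hba1c <= 3) or np.any(hba1c >= 20):
        raise ValidationError("HbA1c values must lie in (3, 20)")
    grp = panel.groupby("patient_id")
    if (grp["visit_year"].apply(lambda s: (s.diff().dropna() < 0).any())).any():
        raise ValidationError("visit_year must be non-decreasing within a patient")
    if (grp["age"].apply(lambda s: (s.diff().dropna() <= 0).any())).any():
        raise ValidationError("age must be strictly increasing within a patient")


def write_panel(panel: pd.DataFrame, path) -> None:
    panel.to_csv(path, index=False, columns=list(PANEL_COLUMNS))


def read_panel(path) -> pd.DataFrame:
    panel = pd.read_csv(path, dtype={"meds": str}, keep_default_na=False,
                        na_values=[])
    panel["meds"] = panel["meds"].fillna("")
    for col in PANEL_COLUMNS:
        if col not in panel.columns:
            raise ValidationError(f"panel CSV missing column {col}")
    return panel
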