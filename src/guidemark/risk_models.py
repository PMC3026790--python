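"""Annual event risks: CHD and stroke hazards plus other-cause mortality.

First coronary and first stroke events use published diabetes risk engines
of the UKPDS form: a baseline hazard ``q0`` scaled multiplicatively by
centred covariates and grown geometrically with diabetes duration,

    h(t) = q0 * prod_i coef_i ** x_i * d ** t,      p(t) = 1 - exp(-h(t)).

Death from causes other than CHD and stroke comes from a sex/age life
table; the packaged default is a synthetic Gompertz-shaped table (a smooth
exponential increase of mortality with age), clearly labelled as such — any
real life table can be loaded from CSV in its place.  The three annual exit
probabilities are resolved into a competing-risk split by hazard shares.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from importlib import resources
from typing import Mapping

import numpy as np
import pandas as pd
import yaml

from .metabolic_states import ValidationError

__all__ = [
    "RiskProfile",
    "RiskCoefficients",
    "MortalityTable",
    "annual_event_prob",
    "ten_year_chd_risk",
    "other_cause_death_prob",
    "combine_competing",
    "default_risk_coefficients",
    "synthetic_mortality_table",
]

_COVARIATE_KINDS = ("binary", "linear", "log")


@dataclass
class RiskProfile:
    """Covariates entering the annual CHD/stroke risk equations.

    ``hba1c``, ``sbp``, ``tc`` and ``hdl`` may be numpy arrays, in which
    case the risk functions broadcast elementwise.  The lipid ratio is
    derived as TC/HDL.
    """

    sex: str
    current_age: float
    age_at_diagnosis: float
    hba1c: object
    sbp: object
    tc: object
    hdl: object
    smoker: bool = False
    afro_caribbean: bool = False
    atrial_fibrillation: bool = False

    def __post_init__(self):
        if self.sex not in ("male", "female"):
            raise ValidationError("sex must be 'male' or 'female'")
        if np.any(np.asarray(self.current_age) < np.asarray(self.age_at_diagnosis)):
            raise ValidationError("current_age must be >= age_at_diagnosis")
        if np.any(np.asarray(self.hdl, dtype=float) <= 0):
            raise ValidationError("HDL must be > 0")

    @property
    def duration(self):
        return np.asarray(self.current_age) - np.asarray(self.age_at_diagnosis)

    def covariate(self, name: str):
        if name == "female":
            return 1.0 if self.sex == "female" else 0.0
        if name == "lipid_ratio":
            return np.asarray(self.tc, dtype=float) / np.asarray(self.hdl, dtype=float)
        if name in ("smoker", "afro_caribbean", "atrial_fibrillation"):
            return 1.0 if getattr(self, name) else 0.0
        if name in ("hba1c", "sbp", "age_at_diagnosis", "current_age"):
            return np.asarray(getattr(self, name), dtype=float)
        raise ValidationError(f"risk equation references unknown covariate {name!r}")


@dataclass(frozen=True)
class RiskCoefficients:
    """One outcome's risk-engine parameters: baseline hazard ``q0``, annual
    hazard-growth factor ``d``, and multiplicative covariate coefficients."""

    outcome: str
    q0: float
    d: float
    covariates: tuple  # of dicts: name, kind, coef, center, scale

    def __post_init__(self):
        if self.q0 < 0:
            raise ValidationError("q0 must be >= 0")
        if self.d <= 0:
            raise ValidationError("hazard growth d must be > 0")
        for cov in self.covariates:
            if cov.get("kind", "linear") not in _COVARIATE_KINDS:
                raise ValidationError(
                    f"{self.outcome}: unknown covariate kind {cov.get('kind')!r}"
                )
            if "name" not in cov or "coef" not in cov:
                raise ValidationError(f"{self.outcome}: covariate needs name and coef")

    def hazard(self, profile: RiskProfile, duration=None):
        """Annual hazard at the given diabetes duration (default: profile's)."""
        t = profile.duration if duration is None else np.asarray(duration, dtype=float)
        h = self.q0 * np.power(self.d, t)
        for cov in self.covariates:
            x = profile.covariate(cov["name"])
            kind = cov.get("kind", "linear")
            if kind == "binary":
                z = x
            elif kind == "log":
                z = np.log(x) - cov.get("center", 0.0)
            else:
                z = (x - cov.get("center", 0.0)) / cov.get("scale", 1.0)
            h = h * np.power(cov["coef"], z)
        return h

    @classmethod
    def from_dict(cls, outcome: str, doc: Mapping) -> "RiskCoefficients":
        return cls(
            outcome=outcome,
            q0=float(doc["q0"]),
            d=float(doc["d"]),
            covariates=tuple(dict(c) for c in doc["covariates"]),
        )


def default_risk_coefficients() -> dict:
    """Packaged CHD and stroke risk-engine coefficient sets."""
    text = resources.files("guidemark.data").joinpath("ukpds_coefficients.yaml").read_text()
    doc = yaml.safe_load(text)
    return {k: RiskCoefficients.from_dict(k, v) for k, v in doc.items()}


def annual_event_prob(profile: RiskProfile, coeffs: RiskCoefficients, duration=None):
    """Probability of a first event in the coming year: 1 - exp(-h(t))."""
    h = coeffs.hazard(profile, duration=duration)
    p = 1.0 - np.exp(-h)
    if np.ndim(p) == 0:
        return float(p)
    return p


def ten_year_chd_risk(profile: RiskProfile, coeffs: RiskCoefficients):
    """Ten-year first-CHD risk with risk factors frozen at current values.

    The duration-dependent hazard is accumulated over the next ten annual
    cycles: P = 1 - exp(-sum_k h(t + k)), k = 0..9.
    """
    t = profile.duration
    total = 0.0
    for k in range(10):
        total = total + coeffs.hazard(profile, duration=np.asarray(t) + k)
    p = 1.0 - np.exp(-total)
    if np.ndim(p) == 0:
        return float(p)
    return p


# ---------------------------------------------------------------------------
# Other-cause mortality
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class MortalityTable:
    """Annual probability of death from non-CHD/non-stroke causes by sex
    and integer age."""

    rates: Mapping[tuple, float]  # (sex, age) -> probability

    def __post_init__(self):
        for (sex, age), q in self.rates.items():
            if not 0.0 <= q <= 1.0:
                raise ValidationError(f"mortality rate out of [0,1] at ({sex}, {age})")
        for sex in ("male", "female"):
            ages = sorted(a for (s, a) in self.rates if s == sex)
            if ages and not (ages[0] <= 40 and ages[-1] >= 80):
                raise ValidationError(f"{sex}: mortality table must cover ages 40-80")

    @classmethod
    def from_csv(cls, path) -> "MortalityTable":
        df = pd.read_csv(path)
        required = {"sex", "age", "rate"}
        if not required.issubset(df.columns):
            raise ValidationError(f"mortality CSV needs columns {sorted(required)}")
        rates = {
            (str(r.sex), int(r.age)): float(r.rate) for r in df.itertuples(index=False)
        }
        return cls(rates=rates)


def synthetic_mortality_table(
    q40_male: float = 0.0025,
    q40_female: float = 0.0015,
    slope: float = 0.082,
    age_max: int = 100,
) -> MortalityTable:
    """Synthetic Gompertz-shaped life table (default other-cause mortality).

    Annual mortality rises exponentially with age from the age-40 anchor:
    ``q(age) = q40 * exp(slope * (age - 40))``, capped at 1.  This is an
    invented smooth stand-in with realistic orders of magnitude, not a
    national life-table extract; load a real table with
    :meth:`MortalityTable.from_csv` for applied work.
    """
    rates = {}
    for sex, q40 in (("male", q40_male), ("female", q40_female)):
        for age in range(40, age_max + 1):
            rates[(sex, age)] = min(1.0, q40 * np.exp(slope * (age - 40)))
    return MortalityTable(rates=rates)


def other_cause_death_prob(age, sex: str, table: MortalityTable) -> float:
    """Look up the annual other-cause death probability (no interpolation)."""
    key = (sex, int(age))
    if key not in table.rates:
        raise ValidationError(f"age {age} outside mortality table range for {sex}")
    return table.rates[key]


# ---------------------------------------------------------------------------
# Competing risks
# ---------------------------------------------------------------------------

def combine_competing(p_chd, p_stroke, p_death):
    """Resolve three independent annual exit probabilities into a one-cycle
    competing-risk split.

    Total exit probability is ``1 - (1-p_chd)(1-p_stroke)(1-p_death)``;
    each cause receives a share proportional to its hazard
    ``-log(1 - p)``.  Returns ``(P_chd, P_stroke, P_death, P_stay)``,
    which sum to 1.
    """
    probs = [np.asarray(p, dtype=float) for p in (p_chd, p_stroke, p_death)]
    for p in probs:
        if np.any(p < 0) or np.any(p > 1):
            raise ValidationError("competing-risk inputs must lie in [0, 1]")
    # hazards; clip away from 1 to keep -log finite
    hazards = [-np.log1p(-np.minimum(p, 1.0 - 1e-15)) for p in probs]
    h_tot = hazards[0] + hazards[1] + hazards[2]
    p_stay = (1.0 - probs[0]) * (1.0 - probs[1]) * (1.0 - probs[2])
    p_any = 1.0 - p_stay
    safe = np.where(h_tot > 0, h_tot, 1.0)
    shares = [np.where(h_tot > 0, h / safe, 0.0) for h in hazards]
    out = tuple(s * p_any for s in shares) + (p_stay,)
    if np.ndim(p_stay) == 0:
        return tuple(float(v) for v in out)
    return out
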