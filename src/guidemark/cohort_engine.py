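"""Annual-cycle cohort propagation from age 40 to 80 under a guideline.

The live state space is the product of the four binned factor chains with
the medication state (progress along the lipid and blood-pressure
sequences).  :func:`run_cohort` propagates the full probability
distribution exactly — no Monte Carlo — absorbing first-CHD, first-stroke
and other-cause-death mass each cycle and accruing discounted medication
cost.  :func:`run_microsim` is an independent stochastic implementation of
the same cycle (individual patient paths with random draws) used as an
oracle for the exact engine.

Cycle order within a model year: guideline decision -> treated factor
values -> event/death risks -> competing-risk absorption -> factor bin
transitions -> cost accrual.  A year's initiation therefore affects that
same year's risk, and costs accrue to everyone alive and event-free at the
start of the cycle.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Optional

import numpy as np
import pandas as pd

from .metabolic_states import (
    BINNED_FACTORS,
    Cutpoints,
    EffectTable,
    TransitionModel,
    ValidationError,
)
from .risk_models import (
    MortalityTable,
    RiskCoefficients,
    RiskProfile,
    combine_competing,
    other_cause_death_prob,
    ten_year_chd_risk,
)
from .treatment_policy import (
    LIPID_SEQUENCE,
    CostTable,
    GuidelineSpec,
    MedicationState,
    bp_rule_triggers,
    initial_medication_state,
    lipid_rule_triggers,
)

__all__ = [
    "BaselineDistribution",
    "CohortTrajectory",
    "run_cohort",
    "run_microsim",
]

_MASS_TOL = 1e-9


@dataclass(frozen=True)
class BaselineDistribution:
    """Probability mass over initial (untreated) metabolic bins at age 40."""

    mass: np.ndarray  # shape (n_TC, n_HDL, n_SBP, n_DBP)

    def __post_init__(self):
        m = np.asarray(self.mass, dtype=float)
        if np.any(m < 0) or abs(m.sum() - 1.0) > _MASS_TOL:
            raise ValidationError("baseline distribution must be non-negative and sum to 1")

    @classmethod
    def from_panel(
        cls, panel: pd.DataFrame, cutpoints: Cutpoints, age_below: float = 45.0
    ) -> "BaselineDistribution":
        """Empirical entry distribution from the youngest panel visits.

        Takes each patient's first visit at age below ``age_below``, bins
        the four factors, and combines the per-factor marginals as a
        product (the engine's chains are independent).
        """
        from .metabolic_states import FACTOR_COLUMNS

        first = (
            panel.sort_values(["patient_id", "age"]).groupby("patient_id").first()
        )
        young = first[first["age"] < age_below]
        if len(young) == 0:
            raise ValidationError(f"no entry visits below age {age_below}")
        marginals = []
        for f in BINNED_FACTORS:
            bins = cutpoints.bin(f, young[FACTOR_COLUMNS[f]].to_numpy(dtype=float))
            counts = np.bincount(bins, minlength=cutpoints.n_bins(f)).astype(float)
            marginals.append(counts / counts.sum())
        mass = marginals[0]
        for m in marginals[1:]:
            mass = np.multiply.outer(mass, m)
        return cls(mass=mass)

    @classmethod
    def uniform(cls, cutpoints: Cutpoints) -> "BaselineDistribution":
        shape = cutpoints.shape
        return cls(mass=np.full(shape, 1.0 / np.prod(shape)))

    @classmethod
    def point(cls, cutpoints: Cutpoints, bins: tuple) -> "BaselineDistribution":
        mass = np.zeros(cutpoints.shape)
        mass[tuple(bins)] = 1.0
        return cls(mass=mass)


@dataclass
class CohortTrajectory:
    """Age-indexed cohort trajectory with absorbed masses and costs.

    All arrays are indexed by age 40, 41, ..., 40 + horizon.  Absorbed
    masses and costs are cumulative; ``live_mass + cum_chd + cum_stroke +
    cum_death = 1`` at every age.
    """

    ages: np.ndarray
    live_mass: np.ndarray
    cum_chd: np.ndarray
    cum_stroke: np.ndarray
    cum_death: np.ndarray
    discounted_cost: np.ndarray
    ever_treated: np.ndarray
    guideline: str = ""
    n_patients: Optional[int] = None  # set for microsimulation estimates
    patient_event: Optional[np.ndarray] = None
    patient_cost: Optional[np.ndarray] = None
    patient_treated: Optional[np.ndarray] = None

    @property
    def p_event(self) -> float:
        """Probability of a first CHD or stroke event by the horizon."""
        return float(self.cum_chd[-1] + self.cum_stroke[-1])

    @property
    def expected_cost(self) -> float:
        return float(self.discounted_cost[-1])

    @property
    def ever_treated_fraction(self) -> float:
        return float(self.ever_treated[-1])

    def check_mass_conservation(self, tol: float = _MASS_TOL) -> None:
        total = self.live_mass + self.cum_chd + self.cum_stroke + self.cum_death
        if np.any(np.abs(total - 1.0) > tol):
            raise ValidationError("mass not conserved along trajectory")
        for arr in (self.cum_chd, self.cum_stroke, self.cum_death,
                    self.discounted_cost, self.ever_treated):
            if np.any(np.diff(arr) < -tol):
                raise ValidationError("cumulative quantities must be non-decreasing")

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "age": self.ages,
                "live_mass": self.live_mass,
                "cum_p_chd": self.cum_chd,
                "cum_p_stroke": self.cum_stroke,
                "cum_p_death": self.cum_death,
                "discounted_cost": self.discounted_cost,
                "ever_treated": self.ever_treated,
            }
        )

    def to_csv(self, path) -> None:
        self.to_frame().to_csv(path, index=False)


# ---------------------------------------------------------------------------
# Shared cycle machinery
# ---------------------------------------------------------------------------

class _EngineSetup:
    """Precomputed grids and multipliers shared by both engines."""

    def __init__(self, spec, model, coeffs, mortality, costs, cutpoints, effects, sex):
        self.spec = spec
        self.coeffs = coeffs
        self.mortality = mortality
        self.sex = sex
        self.cutpoints = cutpoints
        self.trends = model.trends

        shape = cutpoints.shape
        for f in BINNED_FACTORS:
            m = np.asarray(model.matrices[f])
            if m.shape != (cutpoints.n_bins(f),) * 2:
                raise ValidationError(
                    f"{f}: transition matrix shape {m.shape} does not match "
                    f"{cutpoints.n_bins(f)} bins"
                )
        self.matrices = {f: np.asarray(model.matrices[f], dtype=float)
                         for f in BINNED_FACTORS}
        self.shape = shape

        self.n_lipid_states = len(LIPID_SEQUENCE) + 1
        self.bp_sequence = spec.bp_sequence
        self.n_bp_states = len(self.bp_sequence) + 1

        # additive percent multipliers by sequence progress
        def cum_mult(seq, factor, n):
            return np.array(
                [1.0 + sum(effects.percent(c, factor) for c in seq[:k]) / 100.0
                 for k in range(n)]
            )

        self.mult = {
            "TC": cum_mult(LIPID_SEQUENCE, "TC", self.n_lipid_states),
            "HDL": cum_mult(LIPID_SEQUENCE, "HDL", self.n_lipid_states),
            "SBP": cum_mult(self.bp_sequence, "SBP", self.n_bp_states),
            "DBP": cum_mult(self.bp_sequence, "DBP", self.n_bp_states),
        }
        if np.any(self.mult["TC"] <= 0) or np.any(self.mult["SBP"] <= 0):
            raise ValidationError("summed treatment reduction reaches -100%")

        self.cost = np.zeros((self.n_lipid_states, self.n_bp_states))
        for l in range(self.n_lipid_states):
            for b in range(self.n_bp_states):
                meds = MedicationState(n_lipid=l, n_bp=b, bp_sequence=self.bp_sequence)
                self.cost[l, b] = sum(costs.costs[c] for c in meds.active_classes)

        self.reps = {
            f: np.asarray(cutpoints.representatives[f], dtype=float)
            for f in BINNED_FACTORS
        }
        grids = np.meshgrid(*(self.reps[f] for f in BINNED_FACTORS), indexing="ij")
        self.grid = dict(zip(BINNED_FACTORS, grids))

        m0 = initial_medication_state(spec)
        self.entry_state = (m0.n_lipid, m0.n_bp)

    def treated_values(self, tc, hdl, sbp, dbp, l, b):
        """Observed factor values given untreated values and sequence progress."""
        return (
            tc * self.mult["TC"][l],
            hdl * self.mult["HDL"][l],
            sbp * self.mult["SBP"][b],
            dbp * self.mult["DBP"][b],
        )

    def profile(self, age, hba1c, sbp, tc, hdl, age_at_diagnosis=40.0):
        return RiskProfile(
            sex=self.sex,
            current_age=age,
            age_at_diagnosis=age_at_diagnosis,
            hba1c=hba1c,
            sbp=sbp,
            tc=tc,
            hdl=hdl,
        )

    def decide(self, age, year, tc_t, hdl_t, sbp_t, dbp_t, hba1c, tg, l, b):
        """Intensification flags for arrays of treated factor values.

        Returns boolean arrays (add_lipid, add_bp) of the same shape as the
        inputs; ``l`` and ``b`` may be scalars or arrays.
        """
        if not self.spec.intensify:
            z = np.zeros(np.shape(tc_t), dtype=bool)
            return z, z
        ldl = np.maximum(tc_t - hdl_t - tg / 5.0, 0.0)
        factors = {"LDL": ldl, "TC": tc_t, "HDL": hdl_t, "SBP": sbp_t, "DBP": dbp_t}
        risk10 = None
        if self.spec.risk_stratified:
            prof = self.profile(age, hba1c, sbp_t, tc_t, hdl_t)
            risk10 = ten_year_chd_risk(prof, self.coeffs["chd"])
        lip = np.asarray(lipid_rule_triggers(self.spec, factors, risk10))
        bp = np.asarray(bp_rule_triggers(self.spec, factors))
        add_lipid = lip & (np.asarray(l) < len(LIPID_SEQUENCE))
        add_bp = bp & (np.asarray(b) < len(self.bp_sequence))
        return add_lipid, add_bp

    def event_probs(self, age, tc_t, hdl_t, sbp_t, hba1c, year):
        prof = self.profile(age, hba1c, sbp_t, tc_t, hdl_t)
        p_chd = 1.0 - np.exp(-self.coeffs["chd"].hazard(prof, duration=year))
        p_stroke = 1.0 - np.exp(-self.coeffs["stroke"].hazard(prof, duration=year))
        return p_chd, p_stroke


def _common_setup(spec, model, coeffs, mortality, costs, cutpoints, effects, sex):
    if cutpoints is None:
        from .metabolic_states import default_cutpoints

        cutpoints = default_cutpoints()
    if effects is None:
        from .metabolic_states import default_effect_table

        effects = default_effect_table()
    return _EngineSetup(spec, model, coeffs, mortality, costs, cutpoints, effects, sex)


# ---------------------------------------------------------------------------
# Exact expectation propagation
# ---------------------------------------------------------------------------

def run_cohort(
    spec: GuidelineSpec,
    model: TransitionModel,
    coeffs: Mapping[str, RiskCoefficients],
    mortality: MortalityTable,
    costs: CostTable,
    baseline: BaselineDistribution,
    horizon: int = 40,
    discount_rate: float = 0.03,
    *,
    cutpoints: Cutpoints | None = None,
    effects: EffectTable | None = None,
    sex: str = "male",
    age_start: int = 40,
) -> CohortTrajectory:
    """Propagate the cohort distribution exactly under a guideline.

    Deterministic: identical inputs always produce identical trajectories.
    """
    eng = _common_setup(spec, model, coeffs, mortality, costs, cutpoints, effects, sex)
    if np.asarray(baseline.mass).shape != eng.shape:
        raise ValidationError("baseline distribution shape does not match cutpoints")

    n_l, n_b = eng.n_lipid_states, eng.n_bp_states
    mass = np.zeros((n_l, n_b) + eng.shape)
    mass[eng.entry_state] = baseline.mass

    ages = np.arange(age_start, age_start + horizon + 1)
    live = np.zeros(horizon + 1)
    cchd = np.zeros(horizon + 1)
    cstr = np.zeros(horizon + 1)
    cdth = np.zeros(horizon + 1)
    cost_acc = np.zeros(horizon + 1)
    ever = np.zeros(horizon + 1)

    live[0] = mass.sum()
    treated_absorbed = 0.0
    ever[0] = _treated_live_mass(mass, eng)

    for k in range(horizon):
        age = age_start + k
        tg = eng.trends["TG"].predict(age)
        hba1c = eng.trends["HBA1C"].predict(age)
        p_death = other_cause_death_prob(age, eng.sex, eng.mortality)

        # 1) guideline decision
        new_mass = np.zeros_like(mass)
        for l in range(n_l):
            for b in range(n_b):
                m = mass[l, b]
                if m.sum() <= 0:
                    continue
                tc_t, hdl_t, sbp_t, dbp_t = eng.treated_values(
                    eng.grid["TC"], eng.grid["HDL"], eng.grid["SBP"], eng.grid["DBP"], l, b
                )
                add_l, add_b = eng.decide(
                    age, k, tc_t, hdl_t, sbp_t, dbp_t, hba1c, tg, l, b
                )
                for dl in (0, 1):
                    for db in (0, 1):
                        sel = (add_l == bool(dl)) & (add_b == bool(db))
                        if np.any(sel):
                            new_mass[min(l + dl, n_l - 1), min(b + db, n_b - 1)] += (
                                m * sel
                            )
        mass = new_mass

        # cost accrues to everyone alive and event-free at cycle start,
        # at the newly decided medication set, discounted to entry
        year_cost = sum(
            eng.cost[l, b] * mass[l, b].sum() for l in range(n_l) for b in range(n_b)
        )
        cost_acc[k + 1] = cost_acc[k] + year_cost / (1.0 + discount_rate) ** k

        # 2-4) treated values -> risks -> competing absorption
        chd_k = stroke_k = death_k = 0.0
        for l in range(n_l):
            for b in range(n_b):
                m = mass[l, b]
                if m.sum() <= 0:
                    continue
                tc_t, hdl_t, sbp_t, _ = eng.treated_values(
                    eng.grid["TC"], eng.grid["HDL"], eng.grid["SBP"], eng.grid["DBP"], l, b
                )
                p_chd, p_stroke = eng.event_probs(age, tc_t, hdl_t, sbp_t, hba1c, k)
                P_chd, P_stroke, P_death, P_stay = combine_competing(
                    p_chd, p_stroke, np.full_like(p_chd, p_death)
                )
                chd_k += (m * P_chd).sum()
                stroke_k += (m * P_stroke).sum()
                death_k += (m * P_death).sum()
                if l > 0 or b > 0:
                    treated_absorbed += (m * (P_chd + P_stroke + P_death)).sum()
                mass[l, b] = m * P_stay

        # 5) independent bin transitions of the surviving mass
        flat = mass.reshape((n_l * n_b,) + eng.shape)
        flat = np.einsum("mabcd,ae->mebcd", flat, eng.matrices["TC"])
        flat = np.einsum("mabcd,be->maecd", flat, eng.matrices["HDL"])
        flat = np.einsum("mabcd,ce->mabed", flat, eng.matrices["SBP"])
        flat = np.einsum("mabcd,de->mabce", flat, eng.matrices["DBP"])
        mass = flat.reshape((n_l, n_b) + eng.shape)

        cchd[k + 1] = cchd[k] + chd_k
        cstr[k + 1] = cstr[k] + stroke_k
        cdth[k + 1] = cdth[k] + death_k
        live[k + 1] = mass.sum()
        ever[k + 1] = _treated_live_mass(mass, eng) + treated_absorbed

    traj = CohortTrajectory(
        ages=ages,
        live_mass=live,
        cum_chd=cchd,
        cum_stroke=cstr,
        cum_death=cdth,
        discounted_cost=cost_acc,
        ever_treated=ever,
        guideline=spec.name,
    )
    traj.check_mass_conservation()
    return traj


def _treated_live_mass(mass, eng) -> float:
    total = mass.sum()
    return float(total - mass[0, 0].sum())


# ---------------------------------------------------------------------------
# Microsimulation oracle
# ---------------------------------------------------------------------------

def run_microsim(
    spec: GuidelineSpec,
    model: TransitionModel,
    coeffs: Mapping[str, RiskCoefficients],
    mortality: MortalityTable,
    costs: CostTable,
    baseline: BaselineDistribution,
    n_patients: int,
    seed: int = 0,
    horizon: int = 40,
    discount_rate: float = 0.03,
    *,
    cutpoints: Cutpoints | None = None,
    effects: EffectTable | None = None,
    sex: str = "male",
    age_start: int = 40,
) -> CohortTrajectory:
    """Monte-Carlo estimate of the cohort trajectory.

    Simulates individual patient paths with the same cycle order and
    per-patient random draws; deterministic given the seed.  Per-patient
    outcome, cost and treatment indicators are attached for standard-error
    computation.
    """
    if n_patients <= 0:
        raise ValidationError("n_patients must be > 0")
    eng = _common_setup(spec, model, coeffs, mortality, costs, cutpoints, effects, sex)
    if np.asarray(baseline.mass).shape != eng.shape:
        raise ValidationError("baseline distribution shape does not match cutpoints")

    rng = np.random.default_rng(seed)
    n = n_patients

    # sample initial bins from the joint baseline distribution
    flat_p = np.asarray(baseline.mass, dtype=float).ravel()
    draws = rng.choice(flat_p.size, size=n, p=flat_p)
    bins = list(np.unravel_index(draws, eng.shape))
    bins = [b.astype(np.int64) for b in bins]

    l = np.full(n, eng.entry_state[0], dtype=np.int64)
    b = np.full(n, eng.entry_state[1], dtype=np.int64)
    alive = np.ones(n, dtype=bool)
    event_chd = np.zeros(n, dtype=bool)
    event_stroke = np.zeros(n, dtype=bool)
    dead_other = np.zeros(n, dtype=bool)
    ever_treated = (l + b) > 0
    cost = np.zeros(n)

    ages = np.arange(age_start, age_start + horizon + 1)
    live = np.zeros(horizon + 1)
    cchd = np.zeros(horizon + 1)
    cstr = np.zeros(horizon + 1)
    cdth = np.zeros(horizon + 1)
    cost_acc = np.zeros(horizon + 1)
    ever = np.zeros(horizon + 1)
    live[0] = 1.0
    ever[0] = ever_treated.mean()

    cum_T = {f: np.cumsum(eng.matrices[f], axis=1) for f in BINNED_FACTORS}

    for k in range(horizon):
        age = age_start + k
        tg = eng.trends["TG"].predict(age)
        hba1c = eng.trends["HBA1C"].predict(age)
        p_death = other_cause_death_prob(age, eng.sex, eng.mortality)

        tc_u = eng.reps["TC"][bins[0]]
        hdl_u = eng.reps["HDL"][bins[1]]
        sbp_u = eng.reps["SBP"][bins[2]]
        dbp_u = eng.reps["DBP"][bins[3]]

        # 1) decision at current medication state
        tc_t = tc_u * eng.mult["TC"][l]
        hdl_t = hdl_u * eng.mult["HDL"][l]
        sbp_t = sbp_u * eng.mult["SBP"][b]
        dbp_t = dbp_u * eng.mult["DBP"][b]
        add_l, add_b = eng.decide(age, k, tc_t, hdl_t, sbp_t, dbp_t, hba1c, tg, l, b)
        l = l + (add_l & alive)
        b = b + (add_b & alive)
        ever_treated |= alive & ((l + b) > 0)

        # cost at the newly decided set for everyone alive at cycle start
        year_cost = eng.cost[l, b] * alive
        cost += year_cost / (1.0 + discount_rate) ** k

        # 2-4) treated values -> risks -> sampled competing outcome
        tc_t = tc_u * eng.mult["TC"][l]
        hdl_t = hdl_u * eng.mult["HDL"][l]
        sbp_t = sbp_u * eng.mult["SBP"][b]
        p_chd, p_stroke = eng.event_probs(age, tc_t, hdl_t, sbp_t, hba1c, k)
        P_chd, P_stroke, P_death, P_stay = combine_competing(
            p_chd, p_stroke, np.full_like(p_chd, p_death)
        )
        u = rng.random(n)
        to_chd = alive & (u < P_chd)
        to_stroke = alive & ~to_chd & (u < P_chd + P_stroke)
        to_death = alive & ~to_chd & ~to_stroke & (u < P_chd + P_stroke + P_death)
        event_chd |= to_chd
        event_stroke |= to_stroke
        dead_other |= to_death
        alive = alive & ~(to_chd | to_stroke | to_death)

        # 5) factor bin transitions for survivors
        for fi, f in enumerate(BINNED_FACTORS):
            u2 = rng.random(n)
            nxt = bins[fi].copy()
            for s in range(eng.shape[fi]):
                sel = alive & (bins[fi] == s)
                if np.any(sel):
                    nxt[sel] = np.searchsorted(cum_T[f][s], u2[sel], side="right")
            bins[fi] = np.minimum(nxt, eng.shape[fi] - 1)

        live[k + 1] = alive.mean()
        cchd[k + 1] = event_chd.mean()
        cstr[k + 1] = event_stroke.mean()
        cdth[k + 1] = dead_other.mean()
        cost_acc[k + 1] = cost.mean()
        ever[k + 1] = ever_treated.mean()

    return CohortTrajectory(
        ages=ages,
        live_mass=live,
        cum_chd=cchd,
        cum_stroke=cstr,
        cum_death=cdth,
        discounted_cost=cost_acc,
        ever_treated=ever,
        guideline=spec.name,
        n_patients=n,
        patient_event=(event_chd | event_stroke),
        patient_cost=cost,
        patient_treated=ever_treated,
    )
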