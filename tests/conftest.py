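import numpy as np
import pytest
from hypothesis import settings

import guidemark as gm
from guidemark.metabolic_states import AgeTrend, Cutpoints, TransitionModel
from guidemark.risk_models import MortalityTable, RiskCoefficients

settings.register_profile("ci", deadline=None, derandomize=True)
settings.load_profile("ci")


@pytest.fixture(scope="session")
def default_config():
    return gm.default_cohort_config()


@pytest.fixture(scope="session")
def default_panel(default_config):
    return gm.generate_panel(default_config)


@pytest.fixture(scope="session")
def cutpoints():
    return gm.default_cutpoints()


@pytest.fixture(scope="session")
def effects():
    return gm.default_effect_table()


@pytest.fixture(scope="session")
def fitted_model(default_panel, cutpoints):
    return gm.estimate_transition_model(default_panel, cutpoints)


@pytest.fixture(scope="session")
def baseline(default_panel, cutpoints):
    return gm.BaselineDistribution.from_panel(default_panel, cutpoints)


@pytest.fixture(scope="session")
def coeffs():
    return gm.default_risk_coefficients()


@pytest.fixture(scope="session")
def mortality():
    return gm.synthetic_mortality_table()


@pytest.fixture(scope="session")
def costs():
    return gm.default_cost_table()


@pytest.fixture(scope="session")
def model_inputs(fitted_model, coeffs, mortality, costs, baseline, cutpoints):
    """Bundle of everything run_cohort needs beyond the guideline."""
    return dict(
        model=fitted_model,
        coeffs=coeffs,
        mortality=mortality,
        costs=costs,
        baseline=baseline,
        cutpoints=cutpoints,
    )


def degenerate_inputs(p_annual: float):
    """Single-occupied-state, constant-hazard configuration.

    Identity transition matrices, a point baseline, no covariates, no
    hazard growth and zero other-cause mortality: the cumulative event
    probability has the closed form 1 - (1 - p)^T.
    """
    cp = Cutpoints(
        edges={"TC": (200,), "HDL": (45,), "SBP": (130,), "DBP": (85,)},
        representatives={
            "TC": (180, 220),
            "HDL": (40, 50),
            "SBP": (120, 140),
            "DBP": (80, 90),
        },
    )
    eye = np.eye(2)
    model = TransitionModel(
        matrices={f: eye for f in ("TC", "HDL", "SBP", "DBP")},
        trends={"TG": AgeTrend(100.0, 0.0), "HBA1C": AgeTrend(7.0, 0.0)},
    )
    coeffs = {
        "chd": RiskCoefficients("chd", q0=-np.log(1.0 - p_annual), d=1.0, covariates=()),
        "stroke": RiskCoefficients("stroke", q0=0.0, d=1.0, covariates=()),
    }
    mortality = MortalityTable(
        rates={(s, a): 0.0 for s in ("male", "female") for a in range(40, 101)}
    )
    baseline = gm.BaselineDistribution.point(cp, (0, 0, 0, 0))
    return cp, model, coeffs, mortality, baseline
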