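import numpy as np
import pytest

from tpxcea import load_parameter_set
from tpxcea.cli import default_strategies


@pytest.fixture(scope="session")
def base_params():
    """Default parameter set (session-wide; treat as read-only)."""
    return load_parameter_set()


@pytest.fixture()
def params(base_params):
    """A private deep copy safe to mutate."""
    return base_params.copy()


@pytest.fixture(scope="session")
def strategies():
    """None, Padua >=7 .. >=1 (medical-cohort points), treat-all."""
    return default_strategies()


@pytest.fixture(scope="session")
def elias_strategies():
    return default_strategies("Elias2017")


def zero_risk(ps):
    """Set every acute event risk to zero (in place) and return ps."""
    for name in (
        "p_pe",
        "p_sdvt",
        "p_advt",
        "q_hosp_fatal",
        "q_hosp_ich",
        "q_hosp_other",
        "q_tx_fatal",
        "q_tx_ich",
        "q_tx_other",
    ):
        setattr(ps.risks, name, 0.0)
    return ps


@pytest.fixture()
def zero_risk_params(params):
    return zero_risk(params)


def flat_life_table(q: float, age_max: int = 100):
    """Life table with a constant annual death probability at every age."""
    from tpxcea import LifeTable

    age = np.arange(0, age_max + 1, dtype=float)
    qs = np.full_like(age, q)
    qs[-1] = 1.0
    return LifeTable(age, qs, qs)
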