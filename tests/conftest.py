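import pytest

from simplepda.cohort import CohortConfig, generate_cohort
from simplepda.scoring import InfantRecord, TimepointObservation, VentMode


@pytest.fixture(scope="session")
def default_cohort():
    """One default synthetic cohort, shared across tests (seed 1)."""
    return generate_cohort(CohortConfig(seed=1))


@pytest.fixture
def benign_record():
    return InfantRecord(
        infant_id="A", gestational_age=27.0, birth_weight=1300,
        chorioamnionitis=False, antenatal_steroid_complete=True,
        cord_base_deficit=2.0, fio2_admission=25.0,
    )


@pytest.fixture
def severe_record():
    return InfantRecord(
        infant_id="A", gestational_age=24.0, birth_weight=600,
        chorioamnionitis=True, antenatal_steroid_complete=False,
        cord_base_deficit=20.0, fio2_admission=80.0,
    )


def make_obs(hour=6, **kw):
    base = dict(
        infant_id="A", hour=hour, heart_rate=150, hypotension_inotropes=False,
        vent_mode=VentMode.NONE, pip=None, fio2=25.0, ph=7.40,
        base_deficit=2.0, pco2=40.0, surfactant_doses=0,
    )
    base.update(kw)
    return TimepointObservation(**base)


@pytest.fixture
def obs_factory():
    return make_obs
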