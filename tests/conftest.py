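import numpy as np
import pytest

from atrakin import ApplicationSchedule, GrowthLinkedParams
from atrakin.growth_model import SimulationSettings
from atrakin.synth import NoiseModel, SoilScenario, generate_dissipation


@pytest.fixture(scope="session")
def schedule():
    """The three-application design: doses at days 0, 60 and 88."""
    return ApplicationSchedule()


@pytest.fixture(scope="session")
def single_dose():
    return ApplicationSchedule((0.0,), (100.0,))


@pytest.fixture(scope="session")
def adapting_params():
    """Mid-range parameters of an adapting soil."""
    return GrowthLinkedParams(k1=0.12, Y=45, N0=0.001, mu=0.19, V=0.65, Ks=75)


@pytest.fixture(scope="session")
def settings():
    return SimulationSettings(step=0.01, horizon=116.0)


@pytest.fixture(scope="session")
def noise_free_obs(adapting_params, schedule):
    """Noise-free residue observations on the study sampling grid."""
    scen = SoilScenario("S1", adapting_params, adapting=True,
                        replicate_cv=0.0, n_replicates=1)
    return generate_dissipation(scen, schedule, noise=NoiseModel(cv=0.0, seed=1))


def sfo_observations(k=0.0144, c0=100.0, days=(0, 1, 3, 7, 14, 28, 45, 60),
                     application=1, soil="SFO", cv=0.0, n_reps=1, seed=0):
    """Exact (or noisy) single-first-order residue observations."""
    from atrakin import ResidueObservations
    rng = np.random.default_rng(seed)
    rows = {k_: [] for k_ in ("soil", "app", "day", "rep", "rec")}
    for d in days:
        true = c0 * np.exp(-k * d)
        for r in range(n_reps):
            v = true * rng.normal(1.0, cv) if cv > 0 else true
            rows["soil"].append(soil)
            rows["app"].append(application)
            rows["day"].append(float(d))
            rows["rep"].append(f"R{r + 1}")
            rows["rec"].append(max(v, 0.0))
    return ResidueObservations(np.array(rows["soil"]), np.array(rows["app"]),
                               np.array(rows["day"]), np.array(rows["rep"]),
                               np.array(rows["rec"]))
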