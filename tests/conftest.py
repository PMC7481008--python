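import numpy as np
import pytest
from hypothesis import HealthCheck, settings

settings.register_profile(
    "ci",
    derandomize=True,
    max_examples=50,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")


@pytest.fixture
def fig10_pair():
    """The two single-trajectory datasets behind the printed odds ratio:
    one transition at 0.466 us versus one censored 1-us run."""
    from mdinfer import TransitionData

    a = TransitionData.from_times([0.466], time_unit="us")
    b = TransitionData.from_times(censored_times=[1.0], time_unit="us")
    return a, b


@pytest.fixture(scope="session")
def double_well_windows():
    """A modest umbrella-sampling set on a 5 kT double well, shared by the
    PMF unit tests (the acceptance test runs the full-size version)."""
    import mdinfer as m
    from mdinfer._units import kt_kj_per_mol

    kt = kt_kj_per_mol(298.0)
    model = m.DoubleWellModel(barrier_height=5.0)
    centers = np.linspace(-1.5, 1.5, 13)
    windows = m.gen_umbrella_samples(
        model, centers, force_constant=16 * kt, n_samples=8000, seed=123
    )
    return model, windows
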