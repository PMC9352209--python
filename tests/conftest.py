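import numpy as np
import pytest

from ldmrate import InoculumState, RateParameters, SimulationConfig


@pytest.fixture(scope="session")
def baseline_params() -> RateParameters:
    """Equal growth and conjugation rates at the small-inoculum study
    setting: psi = 1/hr for all strains, gamma_D = gamma_T = 1e-6."""
    return RateParameters(psi_D=1.0, psi_R=1.0, psi_T=1.0,
                          gamma_D=1e-6, gamma_T=1e-6)


@pytest.fixture(scope="session")
def baseline_init() -> InoculumState:
    return InoculumState(D0=100.0, R0=100.0, T0=0.0)


@pytest.fixture(scope="session")
def slow_conj_params() -> RateParameters:
    """Weak, equal conjugation (1e-14) at a large inoculum: the regime
    where the end-point estimator's identicality assumptions hold."""
    return RateParameters(psi_D=1.0, psi_R=1.0, psi_T=1.0,
                          gamma_D=1e-14, gamma_T=1e-14)


@pytest.fixture(scope="session")
def large_init() -> InoculumState:
    return InoculumState(D0=1e5, R0=1e5, T0=0.0)


@pytest.fixture
def baseline_config(baseline_params, baseline_init) -> SimulationConfig:
    return SimulationConfig(params=baseline_params, init=baseline_init,
                            t_max=5.0, engine="gillespie")


@pytest.fixture(scope="session")
def warm_engines(baseline_params, baseline_init):
    """Trigger JIT compilation of both simulation cores once per session
    so individual test timings reflect steady-state throughput."""
    from ldmrate import gillespie_run, hybrid_run

    cfg = SimulationConfig(params=baseline_params, init=baseline_init,
                           t_max=0.01)
    gillespie_run(cfg, seed=0)
    hybrid_run(cfg, seed=0)
    return True


def binomial_envelope(p: float, n: int, alpha: float = 0.01):
    """Two-sided normal-approximation envelope for a binomial fraction."""
    from scipy import stats

    z = stats.norm.ppf(1 - alpha / 2)
    half = z * np.sqrt(p * (1 - p) / n)
    return max(0.0, p - half), min(1.0, p + half)
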