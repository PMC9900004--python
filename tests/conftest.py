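import numpy as np
import pytest

from fishpk import ConcentrationTimeProfile, SimulationConfig, simulate_study
from fishpk.simulate import DEFAULT_SCHEDULE


@pytest.fixture
def noise_free_config():
    return SimulationConfig(noise_cv=0.0)


@pytest.fixture
def noise_free_study(noise_free_config):
    return simulate_study(noise_free_config)


@pytest.fixture
def noisy_config():
    return SimulationConfig(noise_cv=0.15, seed=42)


def exponential_profile(a=100.0, k=0.05, times=None, tissue="plasma", analyte="FF"):
    """Profile sampled from C(t) = a * exp(-k t)."""
    if times is None:
        times = np.asarray(DEFAULT_SCHEDULE[1:])  # skip t=0 (log needs C>0)
    times = np.asarray(times, dtype=float)
    return ConcentrationTimeProfile(
        tissue=tissue, analyte=analyte, times=times,
        concentrations=a * np.exp(-k * times),
    )


@pytest.fixture
def plasma_table_csv(tmp_path):
    """Well-formed 14-row plasma parent table on the standard schedule."""
    rng = np.random.default_rng(7)
    times = np.asarray(DEFAULT_SCHEDULE)
    concs = np.concatenate([[0.0], rng.uniform(10, 300, size=len(times) - 1)])
    lines = ["tissue,analyte,time_h,conc_ugkg"]
    lines += [f"plasma,FF,{t:g},{c:.6g}" for t, c in zip(times, concs)]
    path = tmp_path / "plasma.csv"
    path.write_text("\n".join(lines) + "\n")
    return path
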