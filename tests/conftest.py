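import pytest

from steroidscreen.pipeline import AnalysisBundle, analyze_experiment
from steroidscreen.simulate import SimulationConfig, assemble_experiment, preset


@pytest.fixture(scope="session")
def noisefree_cfg() -> SimulationConfig:
    return SimulationConfig(seed=11, noise_cv=0.0)


@pytest.fixture(scope="session")
def prochloraz_run() -> tuple:
    """Simulated inhibitor experiment at default noise, analyzed once."""
    cfg = SimulationConfig(seed=11)
    plate_sets, truth = assemble_experiment(preset("prochloraz_like"), cfg)
    return plate_sets, truth, analyze_experiment(plate_sets)


@pytest.fixture(scope="session")
def noisefree_run(noisefree_cfg) -> tuple:
    plate_sets, truth = assemble_experiment(preset("prochloraz_like"), noisefree_cfg)
    return plate_sets, truth, analyze_experiment(plate_sets)


@pytest.fixture(scope="session")
def bpa_bundle() -> AnalysisBundle:
    plate_sets, _ = assemble_experiment(preset("bpa_like"), SimulationConfig(seed=3))
    return analyze_experiment(plate_sets)
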