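import pytest

import cellsolute as cs


@pytest.fixture(scope="session")
def final_params() -> cs.ParameterSet:
    """Packaged final-fit parameter values (modeling units)."""
    return cs.final_fit_parameters()


@pytest.fixture(scope="session")
def geometry() -> cs.WellGeometry:
    return cs.default_geometry()


@pytest.fixture(scope="session")
def coarse_settings() -> cs.SolverSettings:
    """Reduced discretization for calibration-heavy tests."""
    return cs.SolverSettings(n_cells=50, gel_fraction=0.2, dt=600.0)


@pytest.fixture(scope="session")
def tiny_settings() -> cs.SolverSettings:
    """Minimal admissible discretization for smoke-level forward runs."""
    return cs.SolverSettings(n_cells=20, gel_fraction=0.2, dt=1800.0)
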