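import numpy as np
import pytest

import asternet as an

# The reference synthetic field used for parameter-recovery checks:
# 750 × 750 μm at 2048 px, lattice constant 11 μm, jitter fraction 0.1,
# default rendering and noise. Built once per session (it drives several
# minutes' worth of tests if rebuilt per test).
FIXTURE_SEED = 11


@pytest.fixture(scope="session")
def default_spec() -> an.AsterFieldSpec:
    return an.AsterFieldSpec(seed=FIXTURE_SEED)


@pytest.fixture(scope="session")
def default_field(default_spec):
    truth, frame = an.simulate_field(default_spec)
    return truth, frame


@pytest.fixture(scope="session")
def default_config(default_spec) -> an.PipelineConfig:
    return an.PipelineConfig(pixel_size_um=default_spec.pixel_size_um)


@pytest.fixture(scope="session")
def default_report(default_field, default_config) -> an.RunReport:
    _, frame = default_field
    return an.run_full_analysis(frame, default_config)


@pytest.fixture(scope="session")
def truth_summary(default_field) -> an.NetworkSummary:
    """Network statistics of the ground-truth vertex positions."""
    truth, _ = default_field
    vs = an.VertexSet(
        truth.vertex_positions, np.ones(truth.n_vertices), 750.0, 750.0
    )
    return an.summarize_network(vs)
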