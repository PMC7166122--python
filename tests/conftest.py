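import numpy as np
import pytest

from myoswarm import (
    CurveSpec,
    EnergyParams,
    SwarmParams,
    build_curve,
    run_convergence_experiment,
)


@pytest.fixture(scope="session")
def straight40():
    return build_curve(CurveSpec(length=40.0))


@pytest.fixture(scope="session")
def arc2020():
    return build_curve(CurveSpec(length=20.0, curvature_radius=20.0))


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)


@pytest.fixture(scope="session")
def standard_runs():
    """Ten replicate runs per ideal distance under the standard conditions.

    Straight 40 µm fibril, S = 60, d_th = 0.5 µm, T_max = 200, for the
    skeletal (0.7 µm), cardiac (1.1 µm) and flight (1.8 µm) ideal distances.
    Shared across the convergence-behavior tests to keep the suite fast.
    """
    runs = {}
    for rm in (0.7, 1.1, 1.8):
        runs[rm] = run_convergence_experiment(
            CurveSpec(length=40.0),
            EnergyParams(ideal_distance=rm, search_distance=0.5),
            SwarmParams(swarm_size=60, t_max=200),
            n_sim=10,
            base_seed=1,
        )
    return runs
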