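import numpy as np
import pytest

import phytoaffect as pa
from phytoaffect.labels import AffectLabels, LabelConfig, quadrant_code
from phytoaffect.synthetic import PlantTrace


@pytest.fixture(scope="session")
def env72():
    """72 h default-condition chamber trace (seed 1)."""
    return pa.simulate_environment(pa.ChamberConfig(duration=72.0, seed=1))


@pytest.fixture(scope="session")
def plant72(env72):
    return pa.simulate_plant(env72, pa.CouplingConfig(seed=101))


@pytest.fixture(scope="session")
def labels72(env72):
    return pa.build_labels(env72)


@pytest.fixture(scope="session")
def env24():
    """Shorter trace for cheaper unit-level checks."""
    return pa.simulate_environment(pa.ChamberConfig(duration=24.0, seed=7))


def make_toy_labels(
    ts: np.ndarray,
    v: np.ndarray,
    a: np.ndarray,
    valid: np.ndarray | None = None,
    V_smooth: np.ndarray | None = None,
    A_smooth: np.ndarray | None = None,
) -> AffectLabels:
    """Hand-built label object for windowing/evaluation unit tests."""
    n = len(ts)
    v = np.asarray(v, dtype=np.int8)
    a = np.asarray(a, dtype=np.int8)
    valid = np.ones(n, dtype=bool) if valid is None else np.asarray(valid, bool)
    Vs = np.where(v > 0, 1.0, -1.0) if V_smooth is None else np.asarray(V_smooth)
    As = np.where(a > 0, 1.0, -1.0) if A_smooth is None else np.asarray(A_smooth)
    return AffectLabels(
        timestamps=np.asarray(ts, dtype=float),
        L_res=np.zeros(n),
        V=Vs.astype(float),
        A=As.astype(float),
        V_smooth=Vs.astype(float),
        A_smooth=As.astype(float),
        v=v,
        a=a,
        q=quadrant_code(v, a),
        valid=valid,
        config=LabelConfig(),
    )


def make_toy_plant(ts: np.ndarray, bio=None, eco2=None, tvoc=None) -> PlantTrace:
    n = len(ts)
    z = np.zeros(n)
    return PlantTrace(
        timestamps=np.asarray(ts, dtype=float),
        bioelectric=z if bio is None else np.asarray(bio, float),
        eco2=z if eco2 is None else np.asarray(eco2, float),
        tvoc=z if tvoc is None else np.asarray(tvoc, float),
    )
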