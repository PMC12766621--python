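"""Shared fixtures: small phantom studies and reference curves.

All fixtures are generated programmatically with fixed seeds; expensive
renders are session-scoped so the many tests that read them pay once.
"""

from __future__ import annotations

import numpy as np
import pytest

from qperf import (
    ConcentrationCurve,
    GammaVariateAif,
    KineticParams,
    PhantomSpec,
    QuantConfig,
    forward_tissue,
    generate_aif,
)
from qperf.phantom import render_study, stress_rest_pair


@pytest.fixture(scope="session")
def config() -> QuantConfig:
    return QuantConfig()


@pytest.fixture(scope="session")
def times_1s() -> np.ndarray:
    return np.arange(0.0, 50.0, 1.0)


@pytest.fixture(scope="session")
def aif_plasma(times_1s, config) -> ConcentrationCurve:
    """Reference plasma AIF: gamma-variate bolus with recirculation."""
    blood = generate_aif(GammaVariateAif(), times_1s)
    return ConcentrationCurve(
        times=times_1s,
        values=blood.values / (1.0 - config.hematocrit),
        role="aif_plasma",
    )


@pytest.fixture(scope="session")
def rest_kinetics() -> KineticParams:
    return KineticParams(F_p=1.0, v_p=0.08, v_e=0.2, PS=0.5, v=0.28)


@pytest.fixture(scope="session")
def tissue_2cxm(aif_plasma, rest_kinetics) -> ConcentrationCurve:
    return forward_tissue(aif_plasma, rest_kinetics, "2cxm")


@pytest.fixture(scope="session")
def small_spec() -> PhantomSpec:
    """Small single-slice phantom used by most image-domain tests."""
    return PhantomSpec(
        matrix=(48, 48), n_frames=50, n_slices=1, lv_radius=6,
        inner_radius=9, outer_radius=14, seed=7,
    )


@pytest.fixture(scope="session")
def clean_study(small_spec):
    """Noise-free, motion-free rendered study with ground truth."""
    return render_study(small_spec)


@pytest.fixture(scope="session")
def tiny_pair():
    """Stress/rest pair on a very small matrix for map-level tests."""
    spec = PhantomSpec(
        matrix=(36, 36), n_frames=50, n_slices=1, lv_radius=5,
        inner_radius=8, outer_radius=12, seed=11,
    )
    return stress_rest_pair(spec, mpr=3.0)
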