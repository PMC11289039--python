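"""Shared fixtures: ground-truth model and synthetic protocol episodes.

The heavy fixtures are session-scoped: the three synthetic protocols and
the full pipeline recovery are computed once and shared by the tests that
need them.
"""

from __future__ import annotations

import numpy as np
import pytest

import aplysia_hill as ah
from aplysia_hill import fitting, pipeline
from aplysia_hill import synthetic_data as sd

# Per-animal fitted coefficient sets (independent characterizations of the
# same muscle type), used for property tests across realistic parameters.
COHORT_A = [
    [1.54, 7.97, 0.34, 8.40],
    [2.90, 6.63, 0.27, 7.11],
    [1.55, 7.90, 0.33, 8.33],
    [0.93, 7.06, 0.27, 6.83],
    [2.82, 6.70, 0.27, 7.17],
]
COHORT_D = [
    [-0.79, 0.054, 0.49, 0.01],
    [-0.77, 0.07, 0.35, 0.07],
    [-0.82, 0.07, 0.37, 0.01],
    [-0.71, 0.06, 0.31, 0.04],
]
COHORT_E = [
    [1.17, 13.52, 1.60, 15.36, -10.78],
    [0.99, 13.03, 1.37, 2.32, -5.71],
    [0.86, 15.37, 1.45, 8.16, -9.14],
    [0.90, 13.74, 1.37, 2.83, -6.19],
]


@pytest.fixture(scope="session")
def shipped_params():
    return ah.best_median_parameters()


@pytest.fixture(scope="session")
def gt_params(shipped_params):
    """Self-consistent ground truth: E refitted to invert the D hyperbolas."""
    e_fit = fitting.refit_inverse_fv_from_forward(shipped_params.D)
    return shipped_params.replace(E=e_fit.coefficients)


@pytest.fixture(scope="session")
def ff_traces(gt_params):
    return sd.synthesize_protocol(gt_params, sd.ProtocolSpec(kind="force_frequency"))


@pytest.fixture(scope="session")
def lt_traces(gt_params):
    return sd.synthesize_protocol(gt_params, sd.ProtocolSpec(kind="length_tension"))


@pytest.fixture(scope="session")
def fv_traces(gt_params):
    return sd.synthesize_protocol(gt_params, sd.ProtocolSpec(kind="force_velocity"))


@pytest.fixture(scope="session")
def recovered_params(ff_traces, lt_traces, fv_traces):
    """Full pipeline run on the noiseless synthetic protocols."""
    return pipeline.characterize_muscle(ff_traces, lt_traces, fv_traces)


@pytest.fixture(scope="session")
def noisy_traces(gt_params):
    """All three protocols with 10 mN force noise."""
    noise = sd.NoiseSpec(force_sd_N=0.010, seed=20240626)
    return {
        kind: sd.synthesize_protocol(gt_params, sd.ProtocolSpec(kind=kind), noise)
        for kind in ("force_frequency", "length_tension", "force_velocity")
    }
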