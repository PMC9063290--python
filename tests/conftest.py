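"""Shared fixtures.

Full-waveform simulations are the expensive ingredient, so one
session-scoped factory memoises them by stimulus override; acceptance and
unit tests share the same trajectories.
"""

from __future__ import annotations

import warnings

import numpy as np
import pytest

import tmas_adapt as ta


@pytest.fixture(scope="session")
def neuron_params() -> ta.NeuronParameters:
    return ta.NeuronParameters()


@pytest.fixture(scope="session")
def rest_state(neuron_params) -> ta.NeuronState:
    return ta.resting_state(neuron_params)


@pytest.fixture(scope="session")
def baseline_stimulus() -> ta.StimulusParameters:
    return ta.StimulusParameters()


@pytest.fixture(scope="session")
def full_run(neuron_params, rest_state, baseline_stimulus):
    """Memoised full-waveform simulation from rest.

    ``full_run(duration=500, **stimulus_overrides)`` returns the
    :class:`MembraneTrace`; identical requests reuse the cached trajectory.
    """
    cache: dict = {}

    def run(duration: float = 500.0, dt: float | None = None,
            neuron: ta.NeuronParameters | None = None, **overrides):
        key = (duration, dt, neuron, tuple(sorted(overrides.items())))
        if key not in cache:
            sp = baseline_stimulus.replace(**overrides) if overrides \
                else baseline_stimulus
            np_ = neuron or neuron_params
            s0 = rest_state if neuron is None else ta.resting_state(np_)
            cfg = ta.SimulationConfig(duration=duration, dt=dt,
                                      analysis_window=(0.0, duration))
            with warnings.catch_warnings():
                warnings.simplefilter("ignore", ta.SoftRangeWarning)
                cache[key] = ta.integrate(s0, np_, sp, cfg)
        return cache[key]

    return run


@pytest.fixture(scope="session")
def baseline_trace(full_run) -> ta.MembraneTrace:
    return full_run()


@pytest.fixture(scope="session")
def baseline_summary(baseline_trace) -> ta.AdaptationSummary:
    return ta.summarize(baseline_trace, (0.0, 500.0))


def assert_rel(value, expected, tol, label=""):
    __tracebackhide__ = True
    err = abs(value - expected) / abs(expected)
    assert err <= tol, (
        f"{label}: {value:.4g} vs expected {expected:.4g} "
        f"(rel err {err:.3%} > {tol:.1%})")
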