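"""Ground-truth fixtures for the analysis layer.

Generators for spike trains with known adaptation structure and for
template membrane traces, so the spike statistics can be validated
independently of the ODE core.  The adapting generator uses time
rescaling: spike times are the integer crossings of the integrated rate

    f(t) = f_inf + (f0 - f_inf) * exp(-t / tau)   [Hz, t in ms]

which gives exact control of the planted onset and steady-state
frequencies; optional Gaussian jitter is added afterwards (seeded,
deterministic).  These fixtures emulate the exponential-like decay of the
model's spike-frequency curves, not its subthreshold dynamics.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.optimize import brentq

from .errors import (InfeasibleGeometryError, InsufficientDurationError,
                     InvalidParameterError, TemplateOverlapError)
from .metrics import SpikeTrain
from .simulate import MembraneTrace

__all__ = [
    "SyntheticTrainSpec",
    "synthetic_adapting_train",
    "synthetic_membrane_trace",
    "synthetic_bursting_train",
]

BASELINE_MV = -65.0
#: spike template knots (offset_ms, mV); upward 0-crossing exactly at 0
_TEMPLATE_KNOTS = np.array([
    (-0.20, BASELINE_MV),
    (0.00, 0.0),
    (0.10, 40.0),
    (0.50, -70.0),
    (0.80, BASELINE_MV),
])
TEMPLATE_SPAN = (-0.20, 0.80)  # ms


@dataclass(frozen=True)
class SyntheticTrainSpec:
    """Parameters of a planted adapting train: onset rate ``f0`` decays to
    ``f_inf`` with time constant ``tau`` (ms) over ``duration`` ms; spike
    times get N(0, jitter_sd) perturbations drawn from ``seed``."""

    f0: float
    f_inf: float
    tau: float
    duration: float
    jitter_sd: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        if not (self.f0 >= self.f_inf > 0.0):
            raise InvalidParameterError("need f0 >= f_inf > 0")
        if self.tau <= 0.0:
            raise InvalidParameterError("tau must be positive")
        if self.duration <= 0.0:
            raise InvalidParameterError("duration must be positive")
        if self.jitter_sd < 0.0:
            raise InvalidParameterError("jitter_sd must be nonnegative")

    def rate(self, t) -> np.ndarray:
        """Instantaneous rate f(t) in Hz (t in ms)."""
        t = np.asarray(t, dtype=np.float64)
        return self.f_inf + (self.f0 - self.f_inf) * np.exp(-t / self.tau)

    def integrated_rate(self, t) -> np.ndarray:
        """Expected spike count on [0, t] (t in ms)."""
        t = np.asarray(t, dtype=np.float64)
        return (self.f_inf * t + (self.f0 - self.f_inf) * self.tau
                * (1.0 - np.exp(-t / self.tau))) / 1000.0


#: latency of the first spike after train onset (ms); keeps the first spike
#: strictly inside the window even under jitter
ONSET_LATENCY = 0.1


def synthetic_adapting_train(spec: SyntheticTrainSpec) -> SpikeTrain:
    """Adapting spike train by time rescaling of the exponential rate.

    The first spike marks train onset (at a small fixed latency); each
    further spike sits where the integrated rate, accumulated from the
    first spike, crosses the next integer.  The inverse first interspike
    interval therefore averages the rate over [0, t] with integral 1,
    recovering the planted f0 up to ISI quantisation.  With ``jitter_sd=0``
    the construction is exact and deterministic.
    """
    span = spec.duration - ONSET_LATENCY
    n_crossings = int(np.floor(float(spec.integrated_rate(span))))
    if n_crossings < 1:
        raise InsufficientDurationError(
            f"duration {spec.duration} ms holds fewer than 2 spikes")
    times = np.empty(n_crossings + 1)
    times[0] = ONSET_LATENCY
    lo = 0.0
    for k in range(1, n_crossings + 1):
        lo = brentq(lambda t, k=k: spec.integrated_rate(t) - k,
                    lo, span, xtol=1e-10)
        times[k] = ONSET_LATENCY + lo
    if spec.jitter_sd > 0.0:
        rng = np.random.default_rng(spec.seed)
        times = times + rng.normal(0.0, spec.jitter_sd, size=times.size)
        times = np.sort(times)
        times = times[(times >= 0.0) & (times <= spec.duration)]
        times = np.maximum.accumulate(times + 1e-9 * np.arange(times.size))
    return SpikeTrain(times, (0.0, spec.duration))


def synthetic_membrane_trace(st: SpikeTrain, dt: float = 0.01) -> MembraneTrace:
    """Template trace: baseline -65 mV with a stereotyped 1-ms action
    potential (peak +40 mV) pasted at each spike time.

    The template's upward 0-mV crossing lies exactly on the spike time, so
    spike detection recovers ``st`` to within one sample step.  Spikes
    closer than the template span raise
    :class:`~tmas_adapt.errors.TemplateOverlapError`.
    """
    if dt <= 0.0:
        raise InvalidParameterError("dt must be positive")
    if len(st) >= 2 and np.any(st.isis < TEMPLATE_SPAN[1] - TEMPLATE_SPAN[0]):
        raise TemplateOverlapError("spike templates overlap")
    lo, hi = st.source_window
    t = np.arange(lo, hi + 0.5 * dt, dt)
    V = np.full(t.size, BASELINE_MV)
    for ts in st.spike_times:
        tau = t - ts
        sel = (tau >= TEMPLATE_SPAN[0]) & (tau <= TEMPLATE_SPAN[1])
        V[sel] = np.interp(tau[sel], _TEMPLATE_KNOTS[:, 0], _TEMPLATE_KNOTS[:, 1])
    return MembraneTrace(t0=lo, dt=dt, V_series=V,
                         stimulus_series=np.zeros_like(V))


def synthetic_bursting_train(burst_rate: float, intra_burst_isi: float,
                             spikes_per_burst: int, duration: float,
                             start: float = 1.0) -> SpikeTrain:
    """Periodic spike clusters: ``spikes_per_burst`` spikes at
    ``intra_burst_isi`` ms spacing, one cluster per 1000/``burst_rate`` ms.

    Raises :class:`~tmas_adapt.errors.InfeasibleGeometryError` if a cluster
    does not fit inside its period.
    """
    if min(burst_rate, intra_burst_isi, duration) <= 0 or spikes_per_burst < 1:
        raise InvalidParameterError("all burst parameters must be positive")
    period = 1000.0 / burst_rate
    span = (spikes_per_burst - 1) * intra_burst_isi
    if span >= period:
        raise InfeasibleGeometryError(
            f"burst span {span} ms does not fit in period {period} ms")
    times = []
    t0 = start
    while t0 + span <= duration:
        times.extend(t0 + np.arange(spikes_per_burst) * intra_burst_isi)
        t0 += period
    return SpikeTrain(np.array(times), (0.0, duration))
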