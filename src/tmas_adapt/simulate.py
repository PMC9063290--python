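"""Trajectory integration and the two stimulation protocols.

The coupled six-state system is integrated with fixed-step fourth-order
Runge–Kutta.  In full-waveform mode the time step must resolve the
ultrasonic carrier (>= 20 samples per cycle; 0.1 us at 500 kHz); in
envelope mode the offset carrier is replaced by its cycle average and a
0.01 ms step suffices.  Identical inputs give bit-identical trajectories.

Two protocols are provided:

* from-rest stimulation (:func:`integrate` started at
  :func:`tmas_adapt.neuron.resting_state`), used for all single-parameter
  sweeps, and
* pre-adapted stimulation (:func:`preadapted_state`), which holds the
  neuron under a constant drive A0 until its adaptation variables settle
  and then probes the onset response to a new stimulus.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from . import _kernel
from .errors import ConfigurationError, DivergenceError, InvalidParameterError
from .neuron import resting_state
from .params import NeuronParameters, NeuronState, StimulusParameters
from .stimulus import A_PER_M2_TO_UA_PER_CM2, current_amplitude

__all__ = [
    "SimulationConfig",
    "MembraneTrace",
    "default_dt",
    "integrate",
    "integrate_constant",
    "preadapted_state",
]

#: minimum number of RK4 steps per ultrasonic cycle in full-waveform mode
SAMPLES_PER_CYCLE = 20

#: coarsest step ever used (envelope mode / slow forcing), ms
DT_CAP = 0.01


def default_dt(sp: StimulusParameters | None, *, envelope: bool = False) -> float:
    """Solver step in ms: min(1/(20 f_u), 0.01 ms) in full mode, 0.01 ms
    in envelope mode."""
    if envelope or sp is None:
        return DT_CAP
    return min(1.0 / (SAMPLES_PER_CYCLE * sp.f_u), DT_CAP)  # f_u in kHz = 1/ms


@dataclass(frozen=True)
class SimulationConfig:
    """Integration and analysis settings.

    duration, dt and record_dt are in ms; ``dt=None`` selects
    :func:`default_dt`.  ``record_dt`` controls decimation of the stored
    samples (0.01 ms resolves spike shape comfortably).  ``seed`` is unused
    by the deterministic core and reserved for stochastic extensions.
    ``analysis_window`` bounds all spike statistics.
    """

    duration: float = 500.0
    dt: float | None = None
    record_dt: float = 0.01
    envelope: bool = False
    analysis_window: tuple[float, float] = (0.0, 500.0)
    seed: int | None = None

    def __post_init__(self) -> None:
        if self.duration <= 0.0:
            raise ConfigurationError(f"duration must be > 0, got {self.duration}")
        if self.dt is not None and self.dt <= 0.0:
            raise ConfigurationError(f"dt must be > 0, got {self.dt}")
        if self.record_dt <= 0.0:
            raise ConfigurationError("record_dt must be > 0")

    def resolve_dt(self, sp: StimulusParameters | None) -> float:
        dt = self.dt if self.dt is not None else default_dt(sp, envelope=self.envelope)
        if (not self.envelope and sp is not None
                and dt > 1.0 / (SAMPLES_PER_CYCLE * sp.f_u) * (1.0 + 1e-12)):
            raise ConfigurationError(
                f"dt={dt} ms is too coarse for f_u={sp.f_u} kHz in full-waveform "
                f"mode (need <= {1.0 / (SAMPLES_PER_CYCLE * sp.f_u):.3g} ms)")
        return dt


@dataclass
class MembraneTrace:
    """Uniformly sampled trajectory.

    ``V_series`` is the membrane potential in mV at ``t0 + k*dt`` (dt in
    ms after decimation); ``stimulus_series`` the applied current in
    uA/cm^2; ``state_series`` the full (n, 6) state record.  If the
    divergence guard (|V| >= 500 mV) tripped, ``diverged`` is True and
    ``truncated_at`` gives the first unreliable sample index.
    """

    t0: float
    dt: float
    V_series: np.ndarray
    stimulus_series: np.ndarray
    state_series: np.ndarray | None = None
    diverged: bool = False
    truncated_at: int | None = None
    gate_excursion: float = 0.0

    def __post_init__(self) -> None:
        if self.dt <= 0.0:
            raise InvalidParameterError("dt must be > 0")
        if len(self.V_series) != len(self.stimulus_series):
            raise InvalidParameterError("series lengths differ")

    @property
    def times(self) -> np.ndarray:
        return self.t0 + self.dt * np.arange(len(self.V_series))

    @property
    def duration(self) -> float:
        return self.dt * (len(self.V_series) - 1)

    def to_frame(self):
        """Two/three-column table (time_ms, V_mV, I_uA_cm2) for CSV export."""
        import pandas as pd

        return pd.DataFrame({"time_ms": self.times, "V_mV": self.V_series,
                             "I_uA_cm2": self.stimulus_series})

    def to_csv(self, path) -> None:
        self.to_frame().to_csv(path, index=False)


def _run(y0: np.ndarray, np_: NeuronParameters, mode: int, amp: float,
         fu_hz: float, rf_hz: float, dc: float, cfg: SimulationConfig,
         dt: float) -> MembraneTrace:
    stride = max(1, int(round(cfg.record_dt / dt)))
    n_steps = int(round(cfg.duration / dt))
    n_steps -= n_steps % stride  # land exactly on a record sample
    states, drive, excursion, diverged_at = _kernel.rk4_run(
        y0, np_.as_vector(), mode, amp, fu_hz, rf_hz, dc, n_steps, dt, stride)
    return MembraneTrace(
        t0=0.0, dt=dt * stride, V_series=states[:, 0], stimulus_series=drive,
        state_series=states, diverged=diverged_at >= 0,
        truncated_at=None if diverged_at < 0 else int(diverged_at),
        gate_excursion=float(excursion))


def integrate(s0: NeuronState, np_: NeuronParameters, sp: StimulusParameters,
              cfg: SimulationConfig | None = None) -> MembraneTrace:
    """Integrate under the magneto-acoustical stimulus from state ``s0``."""
    cfg = cfg or SimulationConfig()
    dt = cfg.resolve_dt(sp)
    amp = A_PER_M2_TO_UA_PER_CM2 * current_amplitude(sp)
    mode = _kernel.DRIVE_ENVELOPE if cfg.envelope else _kernel.DRIVE_FULL
    return _run(s0.as_array(), np_, mode, amp, sp.f_u_hz(), sp.RF, sp.DC,
                cfg, dt)


def integrate_constant(s0: NeuronState, np_: NeuronParameters, I0: float,
                       cfg: SimulationConfig | None = None) -> MembraneTrace:
    """Integrate under a constant drive ``I0`` (uA/cm^2); no gating."""
    cfg = cfg or SimulationConfig(envelope=True)
    dt = cfg.dt if cfg.dt is not None else DT_CAP
    return _run(s0.as_array(), np_, _kernel.DRIVE_CONSTANT, float(I0),
                0.0, 0.0, 1.0, cfg, dt)


def preadapted_state(np_: NeuronParameters, A0: float, *,
                     hold_ms: float = 2500.0, average_ms: float = 200.0,
                     carry_full_state: bool = False) -> NeuronState:
    """State of a neuron adapted to a constant drive ``A0`` (uA/cm^2).

    The neuron is held under I_ext = A0 for ``hold_ms`` (>= 2000 ms).  The
    adaptation variables (w, Ca) of the returned state are the time-average
    over the final ``average_ms``; the fast variables (V, m, h, n) are reset
    to their resting values so the subsequent onset response isolates the
    adaptation state.  With ``carry_full_state=True`` the final full state
    is returned instead.  ``A0 = 0`` returns the resting state exactly.
    """
    if A0 < 0.0:
        raise InvalidParameterError(f"A0 must be >= 0, got {A0}")
    if hold_ms < 2000.0:
        raise InvalidParameterError("hold_ms must be at least 2000 ms")
    rest = resting_state(np_)
    if A0 == 0.0:
        return rest
    cfg = SimulationConfig(duration=hold_ms, envelope=True,
                           analysis_window=(0.0, hold_ms))
    tr = integrate_constant(rest, np_, A0, cfg)
    if tr.diverged:
        raise DivergenceError(f"pre-adaptation run diverged at A0={A0}")
    if carry_full_state:
        return NeuronState.from_array(tr.state_series[-1])
    sel = tr.times >= hold_ms - average_ms
    w_bar = float(tr.state_series[sel, 4].mean())
    ca_bar = float(tr.state_series[sel, 5].mean())
    return rest.replace(w=w_bar, Ca=ca_bar)
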