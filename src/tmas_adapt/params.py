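"""Parameter and state containers for the TMAS-driven adapting neuron.

Two parameter sets drive every simulation: the physical stimulus parameters
(tissue conductivity, static magnetic flux density, ultrasound intensity and
carrier frequency, square-wave modulation) and the membrane parameters of the
reduced one-compartment Traub–Miles ("Ermentrout") model with an M-type and an
AHP-type adaptation current.

Hard invariants (positivity, duty cycle in (0, 1]) raise
:class:`~tmas_adapt.errors.InvalidParameterError`; the tabulated experimental
ranges are soft limits that only emit a warning, so exploratory values outside
the published hardware envelope remain usable.
"""

from __future__ import annotations

import dataclasses
import warnings
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import yaml

from .errors import InvalidParameterError, InvalidStateError

__all__ = [
    "StimulusParameters",
    "NeuronParameters",
    "NeuronState",
    "SoftRangeWarning",
    "table2_defaults",
]


class SoftRangeWarning(UserWarning):
    """A parameter lies outside the tabulated stimulation-hardware range."""


#: Soft ranges of the variable stimulus parameters (hardware envelope).
STIMULUS_SOFT_RANGES = {
    "B_x": (0.5, 8.0),      # T
    "Gamma": (0.2, 4.0),    # W/cm^2
    "f_u": (200.0, 700.0),  # kHz
    "RF": (1.0, 100.0),     # Hz
    "DC": (0.10, 0.95),     # fraction
}


def _positive(name: str, value: float) -> None:
    if not np.isfinite(value) or value <= 0.0:
        raise InvalidParameterError(f"{name} must be strictly positive, got {value!r}")


@dataclass(frozen=True)
class StimulusParameters:
    """Physical parameters of the magneto-acoustical stimulus.

    Defaults are the baseline configuration used throughout the sweep
    protocols: B_x = 2 T, Gamma = 3 W/cm2, f_u = 500 kHz, RF = 1 Hz,
    DC = 50%, in conductive brain tissue (sigma = 0.5 S/m, rho = 1120 kg/m3,
    c0 = 1540 m/s).

    Note that ``Gamma`` is expressed in W/cm2 (the convention of the
    tabulated hardware ranges) and ``f_u`` in kHz; both are converted to SI
    internally where needed.
    """

    sigma: float = 0.5     # tissue conductivity, S/m
    B_x: float = 2.0       # static magnetic flux density, T
    Gamma: float = 3.0     # ultrasonic intensity, W/cm^2
    rho: float = 1120.0    # tissue density, kg/m^3
    c0: float = 1540.0     # speed of sound in tissue, m/s
    f_u: float = 500.0     # fundamental (carrier) ultrasonic frequency, kHz
    RF: float = 1.0        # square-wave modulation frequency, Hz
    DC: float = 0.5        # duty cycle, fraction in (0, 1]

    def __post_init__(self) -> None:
        for name in ("sigma", "rho", "c0", "f_u", "RF"):
            _positive(name, getattr(self, name))
        if not np.isfinite(self.B_x) or self.B_x < 0.0:
            raise InvalidParameterError(f"B_x must be nonnegative, got {self.B_x!r}")
        if not np.isfinite(self.Gamma) or self.Gamma < 0.0:
            raise InvalidParameterError(f"Gamma must be nonnegative, got {self.Gamma!r}")
        if not (0.0 < self.DC <= 1.0):
            raise InvalidParameterError(f"DC must lie in (0, 1], got {self.DC!r}")
        if self.B_x == 0.0 or self.Gamma == 0.0:
            warnings.warn(
                "zero-amplitude stimulus (B_x or Gamma is 0)", SoftRangeWarning,
                stacklevel=3,
            )
        for name, (lo, hi) in STIMULUS_SOFT_RANGES.items():
            v = getattr(self, name)
            if v and not (lo <= v <= hi):
                warnings.warn(
                    f"{name}={v} outside the tabulated range [{lo}, {hi}]",
                    SoftRangeWarning,
                    stacklevel=3,
                )

    def replace(self, **kwargs) -> "StimulusParameters":
        return dataclasses.replace(self, **kwargs)

    def f_u_hz(self) -> float:
        """Carrier frequency in Hz (stored in kHz)."""
        return self.f_u * 1e3


@dataclass(frozen=True)
class NeuronParameters:
    """Membrane parameters of the adapting Ermentrout-type neuron.

    Defaults are the fixed published values for this model: a fast
    sodium/potassium spike generator, a high-threshold calcium current, a
    leak, and the two adaptation currents. The AHP conductance defaults to
    zero, so adaptation is carried by the M-type current alone.

    ``ca_influx_sign`` selects how the calcium influx term enters the
    calcium balance: ``"as_printed"`` uses +0.002*I_Ca literally (I_Ca is an
    inward, negative current, so calcium is pinned at zero by the
    nonnegativity guard), ``"negated"`` uses the standard-literature
    -0.002*I_Ca so spikes raise calcium. With g_AHP = 0 the choice has no
    effect on any result.
    """

    C_m: float = 1.0        # membrane capacitance, uF/cm^2
    g_Na: float = 100.0     # mS/cm^2
    g_K: float = 80.0       # mS/cm^2
    g_L: float = 0.1        # mS/cm^2
    g_Ca: float = 1.0       # mS/cm^2
    g_M: float = 16.0       # M-type adaptation conductance, mS/cm^2
    g_AHP: float = 0.0      # AHP-type adaptation conductance, mS/cm^2
    E_Na: float = 50.0      # mV
    E_K: float = -80.0      # mV
    E_L: float = -67.0      # mV
    E_Ca: float = 120.0     # mV
    tau_w: float = 100.0    # M-current time constant, ms
    ca_influx_sign: str = "as_printed"

    def __post_init__(self) -> None:
        _positive("C_m", self.C_m)
        _positive("tau_w", self.tau_w)
        for name in ("g_Na", "g_K", "g_L", "g_Ca", "g_M", "g_AHP"):
            v = getattr(self, name)
            if not np.isfinite(v) or v < 0.0:
                raise InvalidParameterError(f"{name} must be nonnegative, got {v!r}")
        if self.ca_influx_sign not in ("as_printed", "negated"):
            raise InvalidParameterError(
                "ca_influx_sign must be 'as_printed' or 'negated', "
                f"got {self.ca_influx_sign!r}"
            )
        if not (self.E_K < self.E_L < 0.0 < self.E_Na < self.E_Ca):
            warnings.warn(
                "reversal potentials do not satisfy E_K < E_L < 0 < E_Na < E_Ca; "
                "this leaves the usual excitable regime",
                SoftRangeWarning,
                stacklevel=3,
            )

    def replace(self, **kwargs) -> "NeuronParameters":
        return dataclasses.replace(self, **kwargs)

    def as_vector(self) -> np.ndarray:
        """Pack into the flat float64 layout consumed by the numba kernel."""
        sign = 1.0 if self.ca_influx_sign == "as_printed" else -1.0
        return np.array(
            [self.C_m, self.g_Na, self.g_K, self.g_L, self.g_Ca, self.g_M,
             self.g_AHP, self.E_Na, self.E_K, self.E_L, self.E_Ca, self.tau_w,
             sign],
            dtype=np.float64,
        )


def table2_defaults() -> NeuronParameters:
    """The bundled default membrane-parameter preset."""
    return NeuronParameters()


@dataclass(frozen=True)
class NeuronState:
    """The six dynamical variables of the model.

    V in mV; m, h, n are the Na-activation, Na-inactivation and K-activation
    gates; w is the M-current gate; Ca is the intracellular calcium variable
    (concentration-like, arbitrary units).
    """

    V: float
    m: float
    h: float
    n: float
    w: float
    Ca: float

    def __post_init__(self) -> None:
        if not np.isfinite(self.V) or abs(self.V) >= 500.0:
            raise InvalidStateError(f"V must be finite with |V| < 500 mV, got {self.V!r}")
        for g in ("m", "h", "n", "w"):
            v = getattr(self, g)
            if not np.isfinite(v) or v < -1e-6 or v > 1.0 + 1e-6:
                raise InvalidStateError(f"gate {g} outside [0, 1]: {v!r}")

    def as_array(self) -> np.ndarray:
        return np.array([self.V, self.m, self.h, self.n, self.w, self.Ca],
                        dtype=np.float64)

    @classmethod
    def from_array(cls, y: np.ndarray) -> "NeuronState":
        y = np.asarray(y, dtype=np.float64)
        return cls(V=float(y[0]), m=float(np.clip(y[1], 0, 1)),
                   h=float(np.clip(y[2], 0, 1)), n=float(np.clip(y[3], 0, 1)),
                   w=float(np.clip(y[4], 0, 1)), Ca=float(y[5]))

    def replace(self, **kwargs) -> "NeuronState":
        return dataclasses.replace(self, **kwargs)


# ----------------------------------------------------------------------------
# structured-text (YAML) configuration round-trip
# ----------------------------------------------------------------------------

_SECTIONS = {"stimulus": StimulusParameters, "neuron": NeuronParameters}


def save_config(path, stimulus: StimulusParameters | None = None,
                neuron: NeuronParameters | None = None, **extra) -> None:
    """Write parameters to a YAML key/value config.

    Units follow the dataclass docstrings (Gamma in W/cm2, f_u in kHz,
    conductances in mS/cm2, potentials in mV, tau_w in ms).
    """
    doc: dict = dict(extra)
    if stimulus is not None:
        doc["stimulus"] = dataclasses.asdict(stimulus)
    if neuron is not None:
        doc["neuron"] = dataclasses.asdict(neuron)
    Path(path).write_text(yaml.safe_dump(doc, sort_keys=False))


def load_config(path) -> dict:
    """Read a YAML config; returns a dict with parsed parameter objects.

    Recognised sections ``stimulus`` and ``neuron`` are converted to their
    dataclasses; any other keys are passed through unchanged.
    """
    doc = yaml.safe_load(Path(path).read_text()) or {}
    out: dict = {}
    for key, value in doc.items():
        cls = _SECTIONS.get(key)
        out[key] = cls(**value) if cls is not None else value
    return out
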