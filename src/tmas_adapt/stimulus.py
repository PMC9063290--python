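"""Membrane current induced by magneto-acoustical stimulation.

A focused ultrasound beam of intensity Gamma travelling through conductive
tissue in a static magnetic field B_x drives the tissue ions with a Lorentz
force; the resulting current density is

    J = sigma * B_x * sqrt(2 * Gamma / (rho * c0)) * sin(2*pi*f_u*t)

with Gamma in SI units (W/m^2).  To generate net depolarisation the carrier
is applied with a DC offset, sin(.) + 1, and is gated by a square wave of
modulation frequency RF and duty cycle DC.  The n-th on-phase is the
half-open interval ((n-1)/RF, (n-1+DC)/RF], n = 1, 2, ...; consequently
t = 0 itself is off, and DC = 1 reduces to a continuous wave for all t > 0.

The membrane equation consumes current per membrane area in uA/cm^2; the
conversion from the tissue current density is 1 A/m^2 = 100 uA/cm^2
(:data:`A_PER_M2_TO_UA_PER_CM2`, exposed for sensitivity analyses).
"""

from __future__ import annotations

import numpy as np

from .params import StimulusParameters

__all__ = [
    "A_PER_M2_TO_UA_PER_CM2",
    "current_amplitude",
    "modulation_gate",
    "tmas_current",
]

#: Unit conversion between tissue current density and membrane current.
A_PER_M2_TO_UA_PER_CM2 = 100.0

#: Conversion of the stored ultrasound intensity (W/cm^2) to SI (W/m^2).
W_PER_CM2_TO_W_PER_M2 = 1.0e4


def current_amplitude(p: StimulusParameters) -> float:
    """Peak Lorentz current density sigma*B_x*sqrt(2*Gamma/(rho*c0)), in A/m^2.

    ``p.Gamma`` is converted from W/cm^2 to W/m^2 before use.  Linear in
    sigma and B_x and proportional to sqrt(Gamma).
    """
    gamma_si = p.Gamma * W_PER_CM2_TO_W_PER_M2
    return p.sigma * p.B_x * np.sqrt(2.0 * gamma_si / (p.rho * p.c0))


def modulation_gate(t, RF: float, DC: float):
    """Square-wave gate: 1 inside an on-phase ((n-1)/RF, (n-1+DC)/RF], else 0.

    Parameters
    ----------
    t : float or array
        Time in seconds, t >= 0.
    RF : float
        Modulation frequency in Hz.
    DC : float
        Duty cycle, fraction in (0, 1].

    The gate has period 1/RF and time-average DC over each period.
    """
    t = np.asarray(t, dtype=np.float64)
    u = t * RF
    frac = u - np.floor(u)
    # u exactly integer: t is the right endpoint of a period, which belongs
    # to the previous period's interval -> on iff DC == 1 (and t > 0).
    frac = np.where(frac == 0.0, 1.0, frac)
    gate = ((t > 0.0) & (frac <= DC)).astype(np.int64)
    return gate if gate.ndim else int(gate)


def tmas_current(t, p: StimulusParameters, *,
                 unit_conversion: float = A_PER_M2_TO_UA_PER_CM2,
                 envelope: bool = False):
    """Stimulus membrane current at time ``t`` (seconds), in uA/cm^2.

    During an on-phase the current is ``conv * J0 * (sin(2*pi*f_u*t) + 1)``
    (nonnegative by construction: the offset carrier never swings below
    zero); during an off-phase it is 0.

    With ``envelope=True`` the offset carrier is replaced by its cycle
    average ``conv * J0`` — a fast surrogate for analyses that do not
    resolve the ultrasonic cycle.
    """
    t = np.asarray(t, dtype=np.float64)
    amp = unit_conversion * current_amplitude(p)
    gate = modulation_gate(t, p.RF, p.DC)
    if envelope:
        out = amp * gate
    else:
        out = amp * (np.sin(2.0 * np.pi * p.f_u_hz() * t) + 1.0) * gate
    return out if out.ndim else float(out)


def waveform_table(p: StimulusParameters, duration_ms: float, dt_ms: float, *,
                   envelope: bool = False) -> np.ndarray:
    """Sampled stimulus as an (n, 2) array of (time_ms, current_uA_per_cm2)."""
    t_ms = np.arange(0.0, duration_ms + 0.5 * dt_ms, dt_ms)
    i = tmas_current(t_ms * 1e-3, p, envelope=envelope)
    return np.column_stack([t_ms, i])
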