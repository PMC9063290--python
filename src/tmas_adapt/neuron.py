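"""Model equations of the adapting Ermentrout-type neuron.

A single-compartment, conductance-based reduction of the Traub–Miles
pyramidal-cell model with six state variables (V, m, h, n, w, Ca):

    C_m dV/dt = -I_Na - I_K - I_L - I_Ca - I_M - I_AHP + I_ext

with the fast spike currents

    I_Na = g_Na m^3 h (V - E_Na)
    I_K  = g_K n^4 (V - E_K)
    I_Ca = g_Ca (1 + exp(-(V + 25)/5))^-1 (V - E_Ca)
    I_L  = g_L (V - E_L)

and two slow adaptation currents: the depolarisation-activated M-type
potassium current I_M = g_M w (V - E_K), with

    tau_w dw/dt = w_inf(V) - w,  w_inf(V) = (1 + exp(-(V + 20)/5))^-1,

and the calcium-gated afterhyperpolarisation current
I_AHP = g_AHP Ca/(30 + Ca) (V - E_K), with
d[Ca]/dt = 0.002 I_Ca - 0.0125 [Ca].  The M-type current is active already
below threshold; the AHP current requires spiking (and is off entirely at
the default g_AHP = 0).

The gating rates (in 1/ms) have removable singularities at V = -54 mV
(alpha_m), V = -27 mV (beta_m) and V = -52 mV (alpha_n); the analytic limit
is substituted within 1e-6 mV of each to avoid catastrophic cancellation.
"""

from __future__ import annotations

import numpy as np

from . import _kernel
from .errors import DegenerateStateError, EquilibriumSearchError, InvalidStateError
from .params import NeuronParameters, NeuronState

__all__ = [
    "rate_constants",
    "gate_steady_states",
    "w_inf",
    "ionic_currents",
    "derivatives",
    "resting_state",
]


def _require_finite_V(V: float) -> float:
    V = float(V)
    if not np.isfinite(V):
        raise InvalidStateError(f"membrane potential must be finite, got {V!r}")
    return V


def rate_constants(V: float) -> tuple[float, float, float, float, float, float]:
    """(alpha_m, beta_m, alpha_h, beta_h, alpha_n, beta_n) at V, in 1/ms.

    At the removable singularities the analytic limits are returned:
    alpha_m(-54) = 1.28, beta_m(-27) = 1.4, alpha_n(-52) = 0.16.
    """
    return _kernel.rate_constants_nb(_require_finite_V(V))


def w_inf(V: float) -> float:
    """Steady-state activation of the M-current gate (sigmoid, midpoint -20 mV)."""
    return 1.0 / (1.0 + np.exp(-(_require_finite_V(V) + 20.0) / 5.0))


def gate_steady_states(V: float) -> tuple[float, float, float, float]:
    """(m_inf, h_inf, n_inf, w_inf) = alpha/(alpha+beta) resp. the w sigmoid."""
    a_m, b_m, a_h, b_h, a_n, b_n = rate_constants(V)
    return (a_m / (a_m + b_m), a_h / (a_h + b_h), a_n / (a_n + b_n), w_inf(V))


def ionic_currents(s: NeuronState, p: NeuronParameters
                   ) -> tuple[float, float, float, float, float, float]:
    """(I_Na, I_K, I_Ca, I_L, I_M, I_AHP) in uA/cm^2 for state ``s``."""
    if s.Ca == -30.0:
        raise DegenerateStateError("Ca = -30 makes the AHP activation singular")
    return _kernel.ionic_currents_nb(s.V, s.m, s.h, s.n, s.w, s.Ca,
                                     p.as_vector())


def derivatives(t: float, s: NeuronState, p: NeuronParameters,
                I_ext: float) -> np.ndarray:
    """Time-derivatives of all six state variables (autonomous in t).

    ``I_ext`` is the instantaneous stimulus current in uA/cm^2.  The result
    is returned as a plain (unvalidated) array wrapped via ``from_array`` on
    demand; callers integrating the system should use
    :func:`tmas_adapt.simulate.integrate`.
    """
    if not np.isfinite(I_ext):
        raise InvalidStateError(f"I_ext must be finite, got {I_ext!r}")
    d = _kernel.derivatives_nb(s.V, s.m, s.h, s.n, s.w, s.Ca, float(I_ext),
                               p.as_vector())
    return np.array(d, dtype=np.float64)


def derivatives_vector(y: np.ndarray, p: NeuronParameters,
                       I_ext: float = 0.0) -> np.ndarray:
    """Right-hand side on a raw state array (for root-finding and oracles)."""
    y = np.asarray(y, dtype=np.float64)
    return np.array(
        _kernel.derivatives_nb(y[0], y[1], y[2], y[3], y[4], y[5],
                               float(I_ext), p.as_vector()))


def resting_state(p: NeuronParameters | None = None, *,
                  relax_ms: float = 2000.0, dt: float = 0.01,
                  tol: float = 1.0e-6) -> NeuronState:
    """Stable equilibrium with I_ext = 0, found by long relaxation.

    The system is integrated for ``relax_ms`` (>= 1000 ms) from a
    hyperpolarised start; the returned state satisfies
    ||dy/dt|| < ``tol``.  Raises
    :class:`~tmas_adapt.errors.EquilibriumSearchError` otherwise.
    """
    p = p or NeuronParameters()
    if relax_ms < 1000.0:
        raise ValueError("relax_ms must be at least 1000 ms")
    y0 = np.array([p.E_L, 0.0, 1.0, 0.0, 0.0, 0.0])
    n_steps = int(round(relax_ms / dt))
    states, _, _, diverged = _kernel.rk4_run(
        y0, p.as_vector(), _kernel.DRIVE_CONSTANT, 0.0, 0.0, 0.0, 1.0,
        n_steps, dt, n_steps)
    y = states[-1]
    if diverged >= 0:
        raise EquilibriumSearchError("relaxation diverged")
    d = derivatives_vector(y, p)
    if y[5] == 0.0 and d[5] < 0.0:
        # the literal calcium balance has no nonnegative root (I_Ca is an
        # inward current); the simulated dynamics pin Ca at 0, so the
        # equilibrium is judged on the projected derivative
        d[5] = 0.0
    norm = float(np.linalg.norm(d))
    if norm >= tol:
        raise EquilibriumSearchError(
            f"no equilibrium within {relax_ms} ms (|dy/dt| = {norm:.2e})")
    return NeuronState.from_array(y)
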