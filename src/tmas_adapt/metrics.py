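"""Spike detection and spike-frequency-adaptation statistics.

A spike is an upward crossing of the detection threshold (0 mV by default:
action-potential overshoot is unambiguous in this model).  The
instantaneous spike-frequency curve assigns to every time the inverse of
the interspike interval (ISI) containing it, giving a piecewise-constant
curve on the spike breakpoints.  From it the adaptation statistics are
computed:

* onset frequency f0 = 1000 / (t2 - t1) Hz, the inverse first ISI;
* steady-state frequency f_inf, the time-weighted mean of the curve over
  the final 20% of the analysis window;
* settling time, the earliest time after which the curve stays within
  ``rel_tol * f_inf`` of f_inf (default 5%);
* firing pattern, Bursting if the ISI sequence contains gaps larger than
  3x the median ISI (spike clusters tracking the stimulus envelope), else
  Spiking;
* minimal frequency (duty-cycle protocol), the smallest within-burst curve
  value over the window.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .errors import InsufficientSpikesError
from .params import StimulusParameters
from .simulate import MembraneTrace

__all__ = [
    "SpikeTrain",
    "SpikeFrequencyCurve",
    "AdaptationSummary",
    "detect_spikes",
    "spike_frequency_curve",
    "onset_frequency",
    "steady_state_frequency",
    "settling_time",
    "classify_firing_pattern",
    "min_frequency",
    "summarize",
    "DEFAULT_THRESHOLD",
    "DEFAULT_MIN_SEPARATION",
    "SETTLING_REL_TOL",
    "BURST_GAP_FACTOR",
]

DEFAULT_THRESHOLD = 0.0       # mV
DEFAULT_MIN_SEPARATION = 1.0  # ms refractory gap for detection
#: relative tolerance band of the settling criterion (fraction of f_inf)
SETTLING_REL_TOL = 0.05
#: ISI gaps beyond this multiple of the median ISI separate bursts
BURST_GAP_FACTOR = 3.0
#: fraction of the analysis window (from its end) used for f_inf
STEADY_TAIL_FRACTION = 0.2


@dataclass(frozen=True)
class SpikeTrain:
    """Strictly increasing spike times (ms) within ``source_window``."""

    spike_times: np.ndarray
    source_window: tuple[float, float]
    flagged_empty: bool = False

    def __post_init__(self) -> None:
        st = np.asarray(self.spike_times, dtype=np.float64)
        object.__setattr__(self, "spike_times", st)
        if st.size and np.any(np.diff(st) <= 0.0):
            raise ValueError("spike times must be strictly increasing")
        lo, hi = self.source_window
        if st.size and (st[0] < lo or st[-1] > hi):
            raise ValueError("spike times outside the source window")

    def __len__(self) -> int:
        return int(self.spike_times.size)

    @property
    def isis(self) -> np.ndarray:
        return np.diff(self.spike_times)


@dataclass(frozen=True)
class SpikeFrequencyCurve:
    """Piecewise-constant inverse-ISI curve.

    ``values[i]`` (Hz) holds on [breakpoints[i], breakpoints[i+1]); there is
    one fewer value than breakpoints.
    """

    breakpoints: np.ndarray
    values: np.ndarray

    def __post_init__(self) -> None:
        bp = np.asarray(self.breakpoints, dtype=np.float64)
        v = np.asarray(self.values, dtype=np.float64)
        object.__setattr__(self, "breakpoints", bp)
        object.__setattr__(self, "values", v)
        if v.size != bp.size - 1:
            raise ValueError("need exactly one more breakpoint than values")
        if np.any(v <= 0.0):
            raise ValueError("curve values must be positive")

    def __call__(self, t) -> np.ndarray:
        """Evaluate the curve (NaN outside its support)."""
        t = np.asarray(t, dtype=np.float64)
        idx = np.searchsorted(self.breakpoints, t, side="right") - 1
        inside = (idx >= 0) & (idx < self.values.size) & (t < self.breakpoints[-1])
        out = np.where(inside, self.values[np.clip(idx, 0, self.values.size - 1)],
                       np.nan)
        return out


@dataclass(frozen=True)
class AdaptationSummary:
    """One row of a sweep table: f0, f_inf (Hz), settling time (ms; None if
    the curve never settles inside the window), firing-pattern label, and
    optionally the minimal within-burst frequency (duty-cycle protocol)."""

    f0: float
    f_inf: float
    settling_time: float | None
    pattern: str
    min_frequency: float | None = None
    n_spikes: int = 0
    diverged: bool = False

    @property
    def settled(self) -> bool:
        return self.settling_time is not None

    def settling_label(self, window_ms: float) -> str:
        return (f"{self.settling_time:.0f}" if self.settled
                else f">{window_ms:.0f}")


def detect_spikes(tr: MembraneTrace, threshold: float = DEFAULT_THRESHOLD,
                  min_separation: float = DEFAULT_MIN_SEPARATION) -> SpikeTrain:
    """Upward threshold crossings of a membrane trace.

    Crossing times are linearly interpolated between samples; any crossing
    closer than ``min_separation`` ms to the previously accepted one is
    suppressed.  A divergent trace is truncated at its divergence point and
    an empty/subthreshold trace yields an empty, flagged train.
    """
    V = np.asarray(tr.V_series, dtype=np.float64)
    if tr.diverged and tr.truncated_at is not None:
        V = V[: tr.truncated_at]
    window = (tr.t0, tr.t0 + tr.duration)
    if V.size < 2 or not np.all(np.isfinite(V)):
        return SpikeTrain(np.empty(0), window, flagged_empty=True)
    below = V[:-1] < threshold
    above = V[1:] >= threshold
    idx = np.nonzero(below & above)[0]
    if idx.size == 0:
        return SpikeTrain(np.empty(0), window, flagged_empty=True)
    frac = (threshold - V[idx]) / (V[idx + 1] - V[idx])
    times = tr.t0 + (idx + frac) * tr.dt
    accepted = [times[0]]
    for t in times[1:]:
        if t - accepted[-1] >= min_separation:
            accepted.append(t)
    return SpikeTrain(np.array(accepted), window)


def _require_spikes(st: SpikeTrain, n: int) -> None:
    if len(st) < n:
        raise InsufficientSpikesError(
            f"need at least {n} spikes, got {len(st)}")


def spike_frequency_curve(st: SpikeTrain) -> SpikeFrequencyCurve:
    """Inverse-ISI curve: 1000/(t_{i+1}-t_i) Hz on [t_i, t_{i+1})."""
    _require_spikes(st, 2)
    return SpikeFrequencyCurve(st.spike_times, 1000.0 / st.isis)


def onset_frequency(st: SpikeTrain) -> float:
    """Inverse of the first interspike interval, Hz."""
    _require_spikes(st, 2)
    return float(1000.0 / (st.spike_times[1] - st.spike_times[0]))


def steady_state_frequency(c: SpikeFrequencyCurve,
                           window: tuple[float, float]) -> float:
    """Time-weighted mean of the curve over the final 20% of ``window``."""
    lo, hi = window
    tail_lo = hi - STEADY_TAIL_FRACTION * (hi - lo)
    a = np.maximum(c.breakpoints[:-1], tail_lo)
    b = np.minimum(c.breakpoints[1:], hi)
    weights = np.clip(b - a, 0.0, None)
    total = weights.sum()
    if total <= 0.0:
        raise InsufficientSpikesError(
            "spike-frequency curve does not reach the steady-state window")
    return float((weights * c.values).sum() / total)


def settling_time(c: SpikeFrequencyCurve, f_inf: float,
                  rel_tol: float = SETTLING_REL_TOL) -> float | None:
    """Earliest time T with |f(t) - f_inf| <= rel_tol*f_inf for all t >= T.

    Returns the breakpoint starting the first suffix of the curve that stays
    inside the band, or None if even the final segment leaves it
    (the ">window" sentinel case).
    """
    if f_inf <= 0.0:
        raise ValueError("f_inf must be positive")
    if c.values.size == 0:
        raise InsufficientSpikesError("empty spike-frequency curve")
    inside = np.abs(c.values - f_inf) <= rel_tol * f_inf
    if not inside[-1]:
        return None
    # first index from which all remaining values are inside the band
    outside = np.nonzero(~inside)[0]
    start = 0 if outside.size == 0 else int(outside[-1]) + 1
    return float(c.breakpoints[start])


def classify_firing_pattern(st: SpikeTrain,
                            sp: StimulusParameters | None = None,
                            gap_factor: float = BURST_GAP_FACTOR) -> str:
    """"Bursting" if the ISI sequence contains gaps > ``gap_factor`` x the
    median ISI (clusters separated by stimulus off-phases), else "Spiking"."""
    _require_spikes(st, 3)
    isis = st.isis
    return "Bursting" if np.any(isis > gap_factor * np.median(isis)) else "Spiking"


def min_frequency(c: SpikeFrequencyCurve,
                  window: tuple[float, float],
                  gap_factor: float = BURST_GAP_FACTOR) -> float:
    """Minimal within-burst curve value over ``window`` (Hz).

    Inter-burst gap intervals (ISI > ``gap_factor`` x median ISI) are
    excluded so the statistic tracks the slowing of firing inside a
    cluster, not the silent gaps between clusters.
    """
    lo, hi = window
    isis = np.diff(c.breakpoints)
    sel = ((c.breakpoints[:-1] < hi) & (c.breakpoints[1:] > lo)
           & (isis <= gap_factor * np.median(isis)))
    if not np.any(sel):
        raise InsufficientSpikesError("no within-burst intervals in window")
    return float(c.values[sel].min())


def summarize(tr: MembraneTrace, window: tuple[float, float] | None = None, *,
              threshold: float = DEFAULT_THRESHOLD,
              rel_tol: float = SETTLING_REL_TOL,
              with_min_frequency: bool = False,
              sp: StimulusParameters | None = None) -> AdaptationSummary:
    """Full adaptation summary of one membrane trace."""
    if window is None:
        window = (tr.t0, tr.t0 + tr.duration)
    st = detect_spikes(tr, threshold)
    _require_spikes(st, 3)
    c = spike_frequency_curve(st)
    f_inf = steady_state_frequency(c, window)
    return AdaptationSummary(
        f0=onset_frequency(st),
        f_inf=f_inf,
        settling_time=settling_time(c, f_inf, rel_tol),
        pattern=classify_firing_pattern(st, sp),
        min_frequency=(min_frequency(c, window) if with_min_frequency else None),
        n_spikes=len(st),
        diverged=tr.diverged,
    )
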