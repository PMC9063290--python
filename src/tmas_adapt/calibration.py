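"""Settling-tolerance calibration.

The settling time is defined relative to a tolerance band around the
steady-state frequency; the band width is a convention, not a physical
constant.  This module scans candidate relative tolerances on a reference
trace so the default (:data:`tmas_adapt.metrics.SETTLING_REL_TOL`) can be
chosen and frozen against the published settling values.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .metrics import (detect_spikes, settling_time, spike_frequency_curve,
                      steady_state_frequency)
from .simulate import MembraneTrace

__all__ = ["settling_tolerance_scan"]


def settling_tolerance_scan(tr: MembraneTrace,
                            window: tuple[float, float],
                            tolerances=None) -> pd.DataFrame:
    """Settling time of one trace for a grid of relative tolerances.

    Returns a frame with columns (rel_tol, settling_ms); unsettled entries
    are NaN.
    """
    if tolerances is None:
        tolerances = np.array([0.2, 0.1, 0.07, 0.05, 0.03, 0.02, 0.01,
                               0.005, 0.002, 0.001])
    st = detect_spikes(tr)
    curve = spike_frequency_curve(st)
    f_inf = steady_state_frequency(curve, window)
    rows = []
    for tol in np.asarray(tolerances, dtype=np.float64):
        T = settling_time(curve, f_inf, rel_tol=float(tol))
        rows.append({"rel_tol": float(tol),
                     "settling_ms": np.nan if T is None else T,
                     "f_inf_hz": f_inf})
    return pd.DataFrame(rows)
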