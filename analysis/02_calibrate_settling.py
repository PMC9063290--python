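#!/usr/bin/env python
"""Settling-criterion calibration.

The settling time depends on an arbitrary convention: the width of the
tolerance band around the steady-state frequency within which the
spike-frequency curve must remain.  This script scans candidate relative
tolerances on the baseline trace and on the RF = 100 Hz trace, and compares
the resulting settling times with the bundled reference values (123 ms /
218 ms for the baseline — the reference tables disagree with each other on
this cell — and 31 ms at RF = 100 Hz).

Finding: a 5% band reproduces the 123 ms reference cell and the 31 ms
RF = 100 Hz cell; no band width reaches the alternative 218 ms reference
(the settling time saturates near 190 ms as the band shrinks, then the
criterion degenerates).  The 5% band is therefore the frozen default
(metrics.SETTLING_REL_TOL).

Writes results/settling_calibration.csv.
"""

import sys
from pathlib import Path

import pandas as pd

sys.path.insert(0, str(Path(__file__).resolve().parents[1] / "src"))
import tmas_adapt as ta  # noqa: E402
from tmas_adapt.calibration import settling_tolerance_scan  # noqa: E402

OUT = Path(__file__).resolve().parents[1] / "results"


def main() -> None:
    neuron = ta.NeuronParameters()
    rest = ta.resting_state(neuron)
    cfg = ta.SimulationConfig(duration=500.0, analysis_window=(0.0, 500.0))

    frames = []
    for label, overrides in [("baseline", {}), ("RF=100", {"RF": 100.0})]:
        tr = ta.integrate(rest, neuron, ta.StimulusParameters(**overrides), cfg)
        scan = settling_tolerance_scan(tr, (0.0, 500.0))
        scan.insert(0, "trace", label)
        frames.append(scan)
        print(f"\n--- {label} (f_inf = {scan['f_inf_hz'].iloc[0]:.2f} Hz) ---")
        print(scan[["rel_tol", "settling_ms"]].to_string(index=False))

    out = pd.concat(frames, ignore_index=True)
    OUT.mkdir(exist_ok=True)
    out.to_csv(OUT / "settling_calibration.csv", index=False)

    base = out[out.trace == "baseline"].set_index("rel_tol")["settling_ms"]
    print(f"\nbaseline settling at the 5% band: {base[0.05]:.1f} ms "
          "(reference cells: 123 ms and 218 ms)")
    print(f"smallest-band settling reached: {base.max():.1f} ms "
          "-> the 218 ms reference is unreachable for any band width")
    rf = out[out.trace == "RF=100"].set_index("rel_tol")["settling_ms"]
    print(f"RF=100 settling at the 5% band: {rf[0.05]:.1f} ms (reference 31 ms)")
    print("frozen default: rel_tol = 0.05")


if __name__ == "__main__":
    main()
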