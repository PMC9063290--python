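# tmas-adapt

Spike-frequency adaptation of a conductance-based neuron under
transcranial magneto-acoustical stimulation (TMAS).

TMAS drives neurons noninvasively: a focused ultrasound beam of intensity
Γ travelling through conductive tissue (conductivity σ, density ρ, sound
speed c₀) inside a static magnetic field B_x exerts a Lorentz force on the
tissue ions, inducing a current density

```
J(t) = σ B_x √(2Γ / (ρ c₀)) · sin(2π f_u t)
```

at the ultrasonic carrier frequency f_u. Applied with a DC offset
(`sin + 1`) and gated by a square wave (modulation frequency RF, duty
cycle DC), this current is injected into a single-compartment,
Traub–Miles-type ("Ermentrout") neuron

```
C_m dV/dt = −I_Na − I_K − I_L − I_Ca − I_M − I_AHP + I_ext
```

whose slow M-type potassium current `I_M = g_M w (V − E_K)`
(τ_w = 100 ms) produces **spike-frequency adaptation**: under sustained
drive the instantaneous firing rate decays from an onset value f₀ (the
inverse first interspike interval) to a steady-state value f∞, settling
within a tolerance band after the settling time. The package is aimed at
computational neuroscientists studying how the five stimulation parameters
(B_x, Γ, f_u, RF, DC) shape that adaptation.

It provides:

- `tmas_adapt.stimulus` — the Lorentz-current waveform (full carrier or
  cycle-averaged envelope);
- `tmas_adapt.neuron` — the six-state membrane model (V, m, h, n, w, Ca)
  and its resting state;
- `tmas_adapt.simulate` — deterministic fixed-step RK4 integration
  (≥ 20 steps per ultrasonic cycle; numba-compiled) and the pre-adaptation
  protocol;
- `tmas_adapt.metrics` — spike detection, inverse-ISI spike-frequency
  curves, f₀ / f∞ / settling time / firing-pattern classification;
- `tmas_adapt.sweeps` — the five single-parameter sweep protocols, adapted
  onset curves f₀(X, A₀), and a per-cell comparison report against the
  bundled reference tables;
- `tmas_adapt.synthetic` — time-rescaling generators of adapting and
  bursting spike trains for validating the analysis layer independently of
  the ODE core.

## Worked example

```python
import tmas_adapt as ta

neuron = ta.NeuronParameters()            # standard membrane constants
stim = ta.StimulusParameters()            # B_x=2 T, Γ=3 W/cm², f_u=500 kHz,
                                          # RF=1 Hz, DC=50%
rest = ta.resting_state(neuron)
cfg = ta.SimulationConfig(duration=500.0, analysis_window=(0.0, 500.0))
trace = ta.integrate(rest, neuron, stim, cfg)
print(ta.summarize(trace, (0.0, 500.0)))
```

```
AdaptationSummary(f0=306.0784121179929, f_inf=122.74933209359388,
                  settling_time=116.61160118074915, pattern='Spiking',
                  min_frequency=None, n_spikes=71, diverged=False)
```

The neuron rests at −66.13 mV; the baseline stimulus delivers a mean
on-phase drive of 18.651 µA/cm² and elicits 71 spikes in the first
500 ms on-phase. Firing starts at f₀ = 306.1 Hz, adapts to
f∞ = 122.75 Hz and stays within 5% of f∞ from 116.6 ms onward — the
signature rate decay carried by the slow M-current. Raising B_x or Γ
raises both frequencies; changing f_u leaves them untouched (the membrane
averages over the 500 kHz carrier); RF and DC reshape the firing into
pulse-locked spiking or bursting without moving the onset rate.

The analysis drivers under `analysis/` rerun the complete study:
`01_baseline_adaptation.py` (the run above), `02_calibrate_settling.py`
(why the settling band is 5%), `03_parameter_sweeps.py` (the four sweep
tables and the comparison report), `04_adapted_onset_curves.py`
(f₀(X, A₀) for pre-adaptation drives A₀ ∈ {0, 3, 6, 9} µA/cm²) and
`05_onset_bound_check.py` (an upper bound showing the bundled reference
onset value exceeds what these equations can produce — see
`docs/methods.md`). Outputs land in `results/`. A thin CLI mirrors them:
`tmas-adapt simulate|sweep|tables|adapted`.

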