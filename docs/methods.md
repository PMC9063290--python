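# Methods

## Model

The neuron is a single-compartment, conductance-based reduction of the
Traub–Miles pyramidal-cell model with six state variables
(V, m, h, n, w, Ca) and membrane balance

    C_m dV/dt = −I_Na − I_K − I_L − I_Ca − I_M − I_AHP + I_ext,

with fast spike currents I_Na = g_Na m³h(V−E_Na), I_K = g_K n⁴(V−E_K),
a high-threshold calcium current
I_Ca = g_Ca (1+exp(−(V+25)/5))⁻¹ (V−E_Ca), a leak I_L = g_L(V−E_L), and
two slow adaptation currents: the M-type potassium current
I_M = g_M w (V−E_K), with τ_w dw/dt = w∞(V) − w and
w∞(V) = (1+exp(−(V+20)/5))⁻¹, and the calcium-gated AHP current
I_AHP = g_AHP·Ca/(30+Ca)·(V−E_K) with d[Ca]/dt = 0.002 I_Ca − 0.0125 [Ca].
Gating rates follow the standard Traub–Miles voltage dependence; the
removable singularities at V = −54, −27 and −52 mV are replaced by their
analytic limits within 10⁻⁶ mV (tested for continuity with ±10⁻⁶ mV
probes).

Defaults (`NeuronParameters`): C_m = 1 µF/cm², g_Na = 100, g_K = 80,
g_L = 0.1, g_Ca = 1, g_M = 16, g_AHP = 0 mS/cm², E_Na = +50, E_K = −80,
E_L = −67, E_Ca = +120 mV, τ_w = 100 ms. Two of these deserve comment:

* **g_M = 16 mS/cm²** is roughly an order of magnitude above typical
  M-current literature values; it is kept as the reference configuration
  of this model. It makes adaptation strong (f₀/f∞ ≈ 2.5 at baseline).
* **Calcium sign.** The calcium balance is implemented literally; since
  I_Ca is an inward (negative) current, the literal influx term drives Ca
  negative, so Ca is clipped at 0 (which also protects the 30+Ca
  denominator). A `ca_influx_sign="negated"` switch provides the
  standard-literature alternative where spikes raise Ca. With g_AHP = 0
  (the default and the regime studied here) the choice affects nothing;
  no AHP-regime claims are made.

## Stimulus

The Lorentz current density is σB_x√(2Γ/(ρc₀)) in SI units, with Γ
converted from W/cm² (the tabulated hardware convention) by 10⁴ and the
carrier frequency stored in kHz. The membrane equation consumes µA/cm²;
the conversion **1 A/m² = 100 µA/cm²** is applied inside the stimulus and
exposed as `A_PER_M2_TO_UA_PER_CM2`. This reading is confirmed by the
steady-state frequency columns of the reference sweep tables, which the
model reproduces to ≤ 0.2 Hz in all eight flux-density/intensity rows;
the baseline mean on-phase drive is 18.651 µA/cm².

The square-wave gate takes the n-th on-phase as the half-open interval
((n−1)/RF, (n−1+DC)/RF], so t = 0 is off (immaterial at the time steps
used) and DC = 1 is exactly a continuous wave. The offset carrier
amp·(sin 2πf_u t + 1) is never negative. An **envelope mode** replaces the
offset carrier by its cycle average (the mean drive). It is validated
against full-waveform mode (f₀ and f∞ agree within 2%; in practice to
five digits at 500 kHz) and used only for qualitative and property checks,
never where a number is compared against the reference tables.

## Integration

Fixed-step RK4 with dt = min(1/(20 f_u), 0.01 ms) — 0.1 µs at 500 kHz —
so the carrier is resolved by ≥ 20 steps per cycle (enforced at run
time). The solver is deterministic (bit-identical reruns) and non-stiff at
this resolution; step-halving changes no recorded baseline sample by more
than 0.009 mV (tested bound 0.05 mV). Gates are clipped to [0, 1] after
each step; the worst pre-clip excursion is recorded and must stay below
10⁻⁶ (it is 0 in all acceptance runs). A |V| ≥ 500 mV guard truncates and
flags divergent trajectories. Samples are decimated to a 0.01 ms record
step, ample for interpolated spike timing.

The resting state is found by 2000 ms relaxation at zero input and
verified against an independent reduction (every gate at its voltage
steady state, scalar current balance solved by bracketing): both give
V_rest = −66.127 mV. Because of the literal calcium sign, the equilibrium
is judged on the clipped (projected) dynamics with Ca = 0.

**Pre-adaptation protocol.** For adapted onset curves f₀(X, A₀) the
neuron is held under a constant drive A₀ for 2500 ms; the returned state
carries the time-average of (w, Ca) over the final 200 ms with the fast
variables reset to rest, so the onset response isolates the adaptation
state. Carrying the full final state instead is available via
`carry_full_state=True`. A₀ is in µA/cm² (the only dimensionally
consistent reading of the protocol) with values {0, 3, 6, 9}; A₀ = 0
returns the resting state exactly, making the unadapted curve identical
to the plain onset sweep by construction.

## Spike statistics

Spikes are upward crossings of 0 mV (the action-potential overshoot is
unambiguous in this model) with linear interpolation between samples and a
1 ms minimum separation. The spike-frequency curve assigns each time the
inverse of the interspike interval containing it. Conventions:

* **f₀** = 1000/(t₂ − t₁) Hz, the inverse first ISI.
* **f∞** = time-weighted mean of the curve over the final 20% of the
  analysis window. For strongly modulated regimes (RF ≥ 50 Hz) the curve
  including inter-pulse intervals is used as-is, which reproduces the
  one-spike-per-pulse limit f∞ = RF exactly (80.001 Hz and 99.96 Hz at
  RF = 80 and 100 Hz).
* **Settling time** = earliest time after which the curve stays within
  rel_tol·f∞ of f∞. The band width is a convention; the default
  rel_tol = 0.05 was fixed once against the reference settling values and
  then frozen (`analysis/02_calibrate_settling.py`): a 5% band reproduces
  the 123 ms baseline reference cell (measured 116.6 ms) and the 31 ms
  cell at RF = 100 Hz (measured 31.96 ms). The alternative 218 ms
  baseline reference (the two reference tables disagree on this cell) is
  unreachable for *any* band width — the measured transient decays faster,
  and T(rel_tol) saturates near 189 ms before the criterion degenerates —
  so it is reported as a discrepancy rather than calibrated to.
* **Firing pattern**: Bursting iff the ISI sequence contains gaps larger
  than 3× the median ISI (clusters separated by stimulus off-phases),
  else Spiking; requires ≥ 3 spikes.
* **Minimal frequency** (duty-cycle protocol): the smallest within-burst
  curve value over the window, excluding inter-burst gap intervals. For
  the duty-cycle sweep the analysis window ends at the last complete
  on-phase, so the steady-state tail is never spent in silence; the
  simulation covers two modulation periods (2000 ms at RF = 1 Hz) so the
  inter-cluster gap is observable for classification.

## Synthetic fixtures

`synthetic_adapting_train` plants an exponentially decaying rate
f(t) = f∞ + (f₀−f∞)e^(−t/τ) by time rescaling (first spike at train
onset, then integer crossings of the integrated rate), giving exact
frequency control at zero jitter; Gaussian jitter is seeded and
deterministic. `synthetic_membrane_trace` renders a −65 mV baseline with
a 1 ms action-potential template (peak +40 mV) whose 0 mV upward crossing
sits exactly on each spike time, so detection recovers planted times to
within one sample. `synthetic_bursting_train` builds periodic clusters
for pattern-classification fixtures.

These fixtures validate the analysis layer only: they carry the rate
structure of adapting spike trains but none of the subthreshold dynamics,
carrier ripple or conductance noise of real recordings, so passing
recovery tests demonstrates correctness of the measurement pipeline, not
robustness to biological noise. Inverse-ISI measurement carries an
inherent quantisation bias — the first ISI averages the decaying rate, so
f₀ is underestimated by roughly ISI₁/(2τ) relative terms; the recovery
grid therefore uses rate parameters in the regime the ODE model itself
produces (f₀ 180–400 Hz, τ 40–120 ms), where the bias is ≤ ~2.5% against
a 5% acceptance bound.

## Known limitations and open discrepancies

* The **onset-frequency column** of the bundled reference tables cannot be
  produced by these equations: the reference baseline onset (353.4 Hz)
  exceeds even the unadapted (g_M = 0) steady rate at the exactly-pinned
  baseline drive (325.9 Hz), an upper bound no initialisation can beat
  (`analysis/05_onset_bound_check.py`). The measured onset from rest is
  306.1 Hz, and it is onset-invariant across f_u, RF and DC exactly as
  the reference tables require. The steady-state columns match to
  ≤ 0.2 Hz throughout.
* The reference duty-cycle minima (e.g. 185.6 Hz at DC = 50%) contradict
  the reference steady state (122.8 Hz) for the identical configuration;
  the measured within-burst minimum settles at ≈ 122.75 Hz for every
  duty cycle ≥ 30% at RF = 1 Hz.
* Steady-state values at RF ∈ {20, 50} Hz depend on how inter-burst gaps
  are averaged; the time-weighted curve mean used here yields the mean
  within-window rate (124.3 / 104.3 Hz), not the reference 32.6 / 66.7 Hz,
  and no averaging convention is asserted for these cells.
* At extreme combinations of pre-adaptation and fast modulation
  (A₀ = 9 µA/cm², RF = 100 Hz) the delayed second spike slips into the
  next pulse, so the adapted onset curve is pulse-quantised rather than
  flat there; flatness along RF/DC holds for A₀ ≤ 6 µA/cm²
  (`analysis/04_adapted_onset_curves.py` shows the full grid).
* Problem sizes: quantitative checks run the full 500 kHz carrier
  (5×10⁶ RK4 steps per 500 ms trace); qualitative and property checks use
  envelope mode. No multi-compartment structure, channel noise,
  temperature scaling, or acoustic propagation/skull attenuation is
  modelled; the stimulus is spatially uniform at the neuron.
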