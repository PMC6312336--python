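# msoenergy

Performance and metabolic cost of binaural coincidence detection in a
minimal model of a medial-superior-olive (MSO) principal neuron.

## The scientific problem

Principal cells of the MSO encode the horizontal direction of a sound
source from the interaural time difference (ITD) — the microsecond-scale
delay between the sound reaching the two ears.  Each cell receives
phase-locked excitatory input from both ears, segregated onto its two
dendrites, and fires maximally when the inputs coincide.  The membrane
specializations enabling this (a very leaky membrane and a large
low-threshold potassium conductance, KLT) make these neurons among the
most energy-hungry in the brain.  This package implements a minimal
biophysical model of such a cell together with the full analysis
pipeline needed to ask: *how do morphology and membrane parameters
trade off ITD-detection performance against ATP consumption, and does
the experimentally observed parameter set sit near the pareto-optimal
boundary of that trade-off?*

## Model and metrics

The cell is a single iso-potential soma (1256 μm²) with two identical
cylindrical dendrites (150 μm × 2.5 μm).  Each compartment obeys

    C_m dV_i/dt = −g_L (V_i − E_L) − ḡ_KLT w_i⁴ z (V_i − E_K)
                  + I_syn,i(t) + I_c,i(t)

with the KLT inactivation gate z frozen at rest, axial coupling I_c
from R_a = 200 Ω·cm, and compartments of length 0.02 λ (passive space
constant λ = sqrt(d / 4 R_a g_L) ≈ 191 μm).  Integration is
Crank–Nicolson (tridiagonal solve per 0.01 ms step) with the
activation gate on a staggered half-step grid.  Spikes are read out by
a feed-forward axonal compartment (threshold −50 mV, 1 ms refractory)
that tracks the soma without loading it.

Synaptic drive mimics a 500 Hz pure tone: six fibers per dendrite,
phase-locked with vector strength 0.988, 240 spikes/s per fiber via
random cycle skipping, alpha-function conductances (τ = 0.2 ms,
E_syn = 0 mV), contralateral fibers delayed by the ITD.

* **Performance** is the rate modulation r₀ − r₀.₅ — the output-rate
  difference between in-phase (ITD = 0) and anti-phase (ITD = 0.5 ms)
  input — evaluated at the per-fiber synaptic strength (EPSG peak)
  that maximizes it.
* **Energy** is counted ion by ion: leak and synaptic currents are
  split into Na⁺/K⁺ components (the synaptic split is 2:1 for a 0 mV
  reversal), total sodium influx is integrated over the cell, and
  converted to ATP at 3 Na⁺ per ATP.

## Worked example

```python
from msoenergy import CellSpec, StimulusSpec, itd_tuning

spec = CellSpec()                                  # default MSO model
stim = StimulusSpec(seed=1, duration=5000.0, epsg_peak=20.0)
res = itd_tuning(spec, stim, itds=[0.0, 0.5])
print(f"{res.r0} {res.r05} {res.rate_modulation:.1f}")
```

prints

```
345.6 36.2 309.4
```

i.e. with 20 nS synapses the default cell fires at 345.6 spikes/s for
in-phase input but only 36.2 spikes/s for anti-phase input — a rate
modulation of ~309 spikes/s, meaning the cell separates the two sound
directions on nearly two thirds of the 2500 stimulus cycles.  The
companion energy ledger for the in-phase run gives a mean sodium
influx of ~3.1 nA, i.e. ~6.5×10⁹ ATP/s spent on input processing.

The same machinery is exposed on the command line:

```
msoenergy calibrate --out results
{
  "E_L_mV": -47.39999999999999,
  "space_constant_um": 190.62321291575583,
  "r_in_control_MOhm": 12.022491540769664,
  "r_in_klt_blocked_MOhm": 36.08826677770409
}
```

plus `fit`, `measure`, `itd-curve`, `optimize-epsg`, `sweep`, `pareto`
and `spontaneous` verbs (see `msoenergy --help`).

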