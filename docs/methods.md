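# Methods

## The cell model

The model reduces an MSO principal neuron to a soma plus two identical
unbranched dendrites of constant diameter, with spatially uniform
membrane properties.  Two conductances carry all subthreshold current:
a passive leak (which absorbs every resting conductance other than
KLT, including the h-current) and the low-threshold potassium current
ḡ_KLT·w⁴·z·(V − E_K).  Sodium spike currents are deliberately absent
from soma and dendrites — MSO action potentials are small, axonal, and
do not backpropagate — so spiking is read out by a separate
threshold element (below).  Default parameters:

| parameter | value | meaning |
|---|---|---|
| soma area | 1256 μm² | single iso-potential compartment |
| dendrite length × diameter | 150 μm × 2.5 μm | two identical cables |
| C_m | 1 μF/cm² | specific capacitance |
| R_a | 200 Ω·cm | axial resistivity |
| g_L | 0.86 mS/cm² | leak density |
| ḡ_KLT | 13.6 mS/cm² | KLT peak density |
| E_K / E_Na / E_syn | −106 / 53 / 0 mV | reversal potentials |
| E_L | −47.4 mV (calibrated) | leak reversal |
| V_rest | −60 mV | enforced resting potential |

Every model variant recalibrates E_L in closed form,
E_L = V_r + (ḡ_KLT w∞(V_r)⁴ z∞(V_r) / g_L)(V_r − E_K), so that −60 mV
is an exact fixed point of the dynamics; combinations whose required
E_L would exceed E_Na are rejected as infeasible.

## KLT gating

The gating functions are not uniquely pinned down by the quantities
this model is constrained with, because only the behavior near rest
matters for subthreshold integration.  We therefore adopt the
Rothman–Manis low-threshold-potassium functional forms (the standard
in auditory-brainstem modelling: a fourth-power activation gate w with
a sigmoidal w∞ and a bell-shaped τ_w, and a slow inactivation gate z
that is frozen at its resting value) and fix the three quantities that
actually enter the dynamics against the model's own constraints:

1. **Static KLT conductance at rest.**  z∞ is rescaled by a constant
   (0.34663) so that w∞(−60)⁴·z∞(−60) = 0.017321, the value required
   for the default densities to rest at −60 mV with E_L = −47.4 mV.
   Since z is frozen, only the product w⁴z is dynamically meaningful,
   so this rescaling has no other effect.
2. **Gate speed.**  τ_w is normalized to exactly 1 ms at −60 mV (the
   cells' fast activation time constant at rest), keeping the
   Rothman–Manis voltage dependence of τ_w; `tau_w_scale` multiplies
   this curve in parameter sweeps.
3. **Dynamic stiffness at rest.**  The steepness of w∞ (k = 4.9124 mV,
   half-activation −48 mV) is solved so that the linearized membrane —
   leak, static KLT, and the KLT activation-slope conductance
   ḡ z 4w³ (dw∞/dV)(V−E_K) — yields a DC space constant of 100 μm for
   small deviations from rest, the subthreshold length scale of these
   cells (the purely passive λ is 191 μm).  With the unmodified
   Rothman–Manis steepness the linearized membrane is noticeably too
   soft (control input resistance ≈ 13.5 MΩ instead of the measured
   ≈ 11.4 MΩ); anchoring on the 100 μm length scale brings it to
   ≈ 12.0 MΩ without ever fitting the resistance directly.

A unit test verifies all three anchors against the closed forms.

## Numerics

The cable is discretized into compartments of length 0.02 λ (passive λ
of the *current* parameter set, so Δx shrinks when g_L grows or the
dendrite thins); the most distal compartment absorbs the remainder,
and dendrite tips are sealed.  The soma joins both dendrite chains, so
the whole cell is an open chain and the implicit system is
tridiagonal.  Voltages advance by Crank–Nicolson (Thomas solve per
step, dt = 0.01 ms by default); the activation gate advances on a
staggered half-step grid by exponential integration, so the
conductance entering each voltage step is a midpoint value and the
scheme is second-order overall (verified on the passive step
response).  w∞(V) and exp(−dt/τ_w(V)) are evaluated from linearly
interpolated tables on a 0.02 mV grid whose nodes include −60 mV
exactly, which keeps the calibrated resting state an exact fixed
point; a zero-input simulation drifts by < 10⁻¹² mV.  A non-finite
state aborts the run with an exception rather than returning silently.

The axonal spike detector is first-order and feed-forward:
dV_a/dt = −(V_a − V_rest)/τ_m + (V_soma − V_a)/τ_c with τ_m = 0.2 ms,
τ_c = 0.05 ms, integrated exactly per step.  This is the simplest form
consistent with tight tracking of the soma and zero load on it; its
steady-state gain (ΔV_a = 0.8 ΔV_soma) means the −50 mV axonal
threshold corresponds to a somatic depolarization of ≈ 12.5 mV.
Upward crossings emit a spike, reset V_a to −60 mV, and suppress
detection for 1 ms.

## Synthetic input

The generator emulates the statistics the analysis assumes, not an
auditory periphery.  Per fiber and per 2 ms stimulus cycle an
independent Bernoulli draw (p = rate/frequency = 0.48) decides whether
the fiber fires; firing times are the cycle peak plus independent
Gaussian jitter with SD chosen in closed form from
VS = exp(−(2πfσ)²/2) (σ ≈ 49.5 μs for VS = 0.988 at 500 Hz).
Contralateral fibers use cycle anchors delayed by the ITD, so matched
seeds give identical skip/jitter patterns across ITD conditions and
EPSG values — a variance-reduction choice that makes the modulation
difference r₀ − r₀.₅ far more stable than independent draws would.
Events keep their own cycle anchor (jitter may cross cycle
boundaries).  Each fiber has its own RNG stream spawned from the
master seed; trains are bit-for-bit reproducible.

Synapses contact the midpoints of six equal sub-intervals of the
distal two-thirds [L/3, L] of each dendrite.  Deterministic even
spacing was chosen over random placement for reproducibility;
"uniformly distributed" is ambiguous between the two readings.
Spontaneous (no-tone) activity is homogeneous Poisson at 55 spikes/s
per fiber with the same synapses and EPSG.

What the generator does *not* reproduce: refractoriness and adaptation
of auditory-nerve fibers, rate-level and phase-frequency dependence,
across-fiber correlations, and any cochlear filtering.  Passing tests
therefore show that the *model pipeline* reproduces the published
quantities under the stated input statistics, not that those
statistics exhaust real auditory-nerve behavior.

## Energy accounting

Ion counting: leak and synaptic currents are split into Na and K
components (leak split so the mixture reversal is E_L, giving a
resting Na fraction of 0.369; synaptic split 2:1 Na:K for a 0 mV
reversal; KLT carries K only), summed over all compartments, and
integrated in time — trapezoidal on the voltage nodes, midpoint for
the KLT term to match the staggered gate.  Capacitive and axial
currents carry no net ion-specific transmembrane flux and are
excluded.  Because no pump is modelled, total Na influx equals total K
efflux at rest exactly, and over a long stationary stimulus to < 1%.
ATP rate = |mean Na current| × 6.242×10¹⁸ / 3.  The integrator
accumulates these charges on the fly; an independent post-hoc
accumulation over a fully recorded trace reproduces them to round-off
and is tested against the kernel.

## Measurement protocols

* **Input resistance**: −10 pA somatic step for 50 ms (small enough to
  stay in the KLT's linear regime), deflection averaged over the last
  5 ms, measured from the model's own resting potential (for the
  KLT-blocked variant that is E_L).  The blocked value matches the
  analytic soma-plus-two-sealed-cables formula to < 1%.
* **EPSC protocol**: alpha-shaped current (τ = 0.2 ms) injected at a
  chosen dendritic distance, amplitude bisected (tolerance 0.05 mV on
  the somatic peak, ≤ 40 iterations) until the somatic EPSP is 10 mV;
  reports dendrite/soma attenuation and somatic halfwidth.  Multi-peak
  responses raise instead of returning an ill-defined halfwidth.
* **Dendritic saturation**: all twelve synapses activated once
  synchronously, EPSG bisected for a 10 mV somatic EPSP; saturation is
  the maximal dendritic depolarization divided by the 60 mV driving
  force.
* **Density fitting**: grid search over (g_L, ḡ_KLT); each candidate
  is recalibrated and evaluated on four observables (both input
  resistances, attenuation curve, halfwidth curve at distances
  0–100 μm).  Each observable contributes its mean squared error
  normalized by the squared mean of its targets — dimensionless, so
  the total is invariant to unit changes of any single observable —
  and the sum is minimized.  The published recordings exist only as
  figure points, so the shipped fit tests run against synthetic
  targets generated from a known model, and parameter recovery (exact
  on-grid, nearest-neighbor off-grid) is what is verified; the
  printed default densities are shipped as the canonical parameter
  set.

## Sweeps and the pareto front

Each swept model is rebuilt, recalibrated, and given its own EPSG
optimization (default: 25 log-spaced points on 3–300 nS plus a 5-point
linear refinement around the coarse argmax; sweep helpers accept
smaller grids).  Cost is always reported at the performance-optimal
EPSG under the ITD = 0 stimulus.  The pareto front keeps records
non-dominated in (ATP rate, reciprocal performance = 1000/modulation
ms/spike); the O(n²) filter is tested against a brute-force oracle.
The point-neuron limit is a soma-only spec with all synapses at the
soma; its ATP rate scales with the chosen soma area.

## Problem sizes

The default simulation is 5 s at dt = 0.01 ms over ~81 compartments
(≈ 1.3 s wall time per run).  The test suite exercises the full-length
protocols where a published number is asserted (EPSG sweep at 5 s per
condition; spontaneous-cost ratio at 5 s) and uses shorter stimuli
(0.5–2 s) and coarser EPSG grids (3–10 points) for the qualitative
sweep-structure checks — the dendrite-length sweep over
{25…350} μm and a 4×4 density grid spanning the published ranges —
which probe orderings (peak location, monotonicity, passive-versus-KLT
ranking) that are robust at that scale.

## Known limitations

* The saturated output rate under anti-phase 300 nS input approaches
  but does not exactly meet the 500 spikes/s one-spike-per-cycle
  ceiling: the Bernoulli cycle-skipping input (p = 0.48) leaves ~2% of
  cycles without any event on a given side, giving ≈ 480 spikes/s.
* The exact KLT gating away from rest (where w∞ saturates) is a
  modelling choice constrained only near −60 mV; quantities dominated
  by strongly depolarized dendrites inherit that uncertainty.
* No inhibition, no explicit h-current, no vesicle-cycle or
  neurotransmitter-recycling costs (literature estimates put the
  latter at 10–20% of input-processing costs), and no explicit
  sodium-spike or myelinated-axon costs.
* The fitting machinery is validated on synthetic targets only; the
  experimental curves are not machine-readable.
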