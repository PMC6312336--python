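"""Synthetic synaptic input: phase-locked and spontaneous fiber trains.

Auditory-nerve-like drive for the coincidence detector: each dendrite
receives six excitatory fibers phase-locked to a pure tone.  Phase
locking is modelled per fiber and per stimulus cycle as an independent
Bernoulli "fire this cycle" draw (probability rate/frequency, which
fixes the mean rate through random cycle skipping) followed by Gaussian
jitter of the activation time around the cycle peak.  The jitter SD is
chosen in closed form to hit the target vector strength,
VS = exp(-(2 pi f sigma)^2 / 2).  Contralateral fibers use cycle
anchors delayed by the interaural time difference.  A spontaneous
(no-tone) mode emits homogeneous Poisson events instead.

Each fiber draws from its own RNG stream spawned from the master seed,
so trains are bit-for-bit reproducible and comparable across parameter
sweeps (the same skips and jitters recur whatever the EPSG or ITD).
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

from .model_core import CableGrid

__all__ = [
    "StimulusSpec", "FiberTrains", "place_synapses",
    "generate_phase_locked_trains", "generate_spontaneous_trains",
    "alpha_conductance", "vector_strength", "jitter_sd_for_vs",
    "build_drive", "save_trains", "load_trains",
]


@dataclass(frozen=True)
class StimulusSpec:
    """Pure-tone stimulus and synapse parameters."""

    frequency: float = 500.0        # Hz
    itd: float = 0.0                # ms, contralateral delay
    fibers_per_dendrite: int = 6
    mean_rate: float = 240.0        # spikes/s per fiber
    vector_strength: float = 0.988
    epsg_peak: float = 20.0         # nS per fiber
    tau_syn: float = 0.2            # ms, alpha-function time constant
    e_syn: float = 0.0              # mV
    duration: float = 5000.0        # ms
    seed: int = 0

    def __post_init__(self):
        if not 0.0 <= self.vector_strength <= 1.0:
            raise ValueError("vector strength must lie in [0, 1]")
        if self.mean_rate > self.frequency:
            raise ValueError("cycle-skipping model requires "
                             "mean_rate <= frequency")


@dataclass
class FiberTrains:
    """Per-fiber activation times [ms] and their synaptic contacts."""

    times: list                     # list of sorted float arrays
    comp_idx: np.ndarray | None = None  # target compartment per fiber
    duration: float = 0.0

    @property
    def n_fibers(self) -> int:
        return len(self.times)

    def rates(self) -> np.ndarray:
        """Mean rate per fiber [spikes/s]."""
        return np.array([t.size for t in self.times]) \
            / (self.duration / 1000.0)


def place_synapses(grid: CableGrid, n_fibers: int,
                   dendrite_length: float | None = None) -> np.ndarray:
    """Contact compartments for ``n_fibers`` per dendrite, both dendrites.

    Contacts are placed at the midpoints of ``n_fibers`` equal
    sub-intervals of the distal two-thirds [L/3, L] of each dendrite.
    Returns an array of 2 * n_fibers compartment indices (dendrite 1
    first).  A point neuron (no dendrites) maps every fiber to the soma.
    """
    if n_fibers < 1:
        raise ValueError("need at least one fiber")
    if grid.n_per_dendrite == 0:
        return np.full(2 * n_fibers, grid.soma_index, dtype=np.int64)
    if dendrite_length is None:
        dendrite_length = float(np.max(grid.positions_um)) + 0.5 * grid.dx_um
    lo = dendrite_length / 3.0
    width = (dendrite_length - lo) / n_fibers
    x = lo + (np.arange(n_fibers) + 0.5) * width
    idx = [grid.compartment_at(xi, dendrite=0) for xi in x]
    idx += [grid.compartment_at(xi, dendrite=1) for xi in x]
    return np.asarray(idx, dtype=np.int64)


def jitter_sd_for_vs(vs: float, frequency: float) -> float:
    """Gaussian jitter SD [ms] giving vector strength ``vs`` at ``frequency``.

    Inverts VS = exp(-(2 pi f sigma)^2 / 2); about 49.5 us for
    VS = 0.988 at 500 Hz.
    """
    if vs >= 1.0:
        return 0.0
    omega = 2.0 * math.pi * frequency / 1000.0  # rad/ms
    return math.sqrt(-2.0 * math.log(vs)) / omega


def generate_phase_locked_trains(spec: StimulusSpec) -> FiberTrains:
    """Phase-locked trains for all 2 * fibers_per_dendrite fibers.

    Fibers 0 .. n-1 are ipsilateral (cycle anchors k/f), fibers
    n .. 2n-1 contralateral (anchors delayed by the ITD).  Events keep
    their own cycle anchor, so jitter may cross cycle boundaries.
    """
    n_f = spec.fibers_per_dendrite
    period = 1000.0 / spec.frequency
    p_fire = spec.mean_rate / spec.frequency
    sigma = jitter_sd_for_vs(spec.vector_strength, spec.frequency)
    streams = np.random.SeedSequence(spec.seed).spawn(2 * n_f)
    n_cycles = int(math.ceil(spec.duration / period))
    anchors0 = np.arange(n_cycles) * period
    times = []
    for f in range(2 * n_f):
        rng = np.random.default_rng(streams[f])
        anchors = anchors0 + (spec.itd if f >= n_f else 0.0)
        keep = rng.random(n_cycles) < p_fire
        ev = anchors[keep] + rng.normal(0.0, sigma, int(keep.sum()))
        times.append(np.sort(ev))
    return FiberTrains(times=times, duration=spec.duration)


def generate_spontaneous_trains(rate: float, duration: float, seed: int,
                                n_fibers: int = 12) -> FiberTrains:
    """Homogeneous Poisson trains at ``rate`` spikes/s per fiber."""
    if rate < 0:
        raise ValueError("rate must be non-negative")
    streams = np.random.SeedSequence(seed).spawn(n_fibers)
    times = []
    for f in range(n_fibers):
        rng = np.random.default_rng(streams[f])
        n = rng.poisson(rate * duration / 1000.0)
        times.append(np.sort(rng.uniform(0.0, duration, n)))
    return FiberTrains(times=times, duration=duration)


def alpha_conductance(g_peak: float, tau: float, events: np.ndarray,
                      T: float, dt: float) -> np.ndarray:
    """Summed alpha-function conductance [nS] on the simulation grid.

    Each event contributes g_peak * (t/tau) * exp(1 - t/tau) for
    t >= 0 after the event (peak-normalized: one event reaches g_peak
    at t = tau); overlapping events add linearly.  The kernel is
    truncated at 25 tau (relative amplitude < 1e-9).
    """
    if g_peak < 0:
        raise ValueError("g_peak must be non-negative")
    n_steps = int(round(T / dt))
    g = np.zeros(n_steps + 1)
    if g_peak == 0.0:
        return g
    span = 25.0 * tau
    for t0 in np.asarray(events, dtype=float):
        if t0 >= T or t0 + span <= 0.0:
            continue
        i0 = max(0, int(math.ceil(t0 / dt)))
        i1 = min(n_steps, int(math.floor((t0 + span) / dt)))
        if i1 < i0:
            continue
        trel = np.arange(i0, i1 + 1) * dt - t0
        g[i0:i1 + 1] += g_peak * (trel / tau) * np.exp(1.0 - trel / tau)
    return g


def build_drive(trains: FiberTrains, tau: float, T: float, dt: float,
                e_syn: float = 0.0, g_peak: float = 1.0):
    """Aggregate fiber trains into a per-compartment SynapticDrive.

    Fibers sharing a contact compartment are summed.  The drive is
    built at ``g_peak`` (default unit amplitude) so that the EPSG sweep
    can rescale it through ``SynapticDrive.scale``.
    """
    from .model_core import SynapticDrive

    if trains.comp_idx is None:
        raise ValueError("trains have no synaptic placement; "
                         "assign comp_idx first")
    uniq = np.unique(trains.comp_idx)
    n_steps = int(round(T / dt))
    g = np.zeros((uniq.shape[0], n_steps + 1))
    for f, ev in enumerate(trains.times):
        row = int(np.searchsorted(uniq, trains.comp_idx[f]))
        g[row] += alpha_conductance(g_peak, tau, ev, T, dt)
    return SynapticDrive(comp_idx=uniq, g_nS=g, e_syn=e_syn)


def vector_strength(times: np.ndarray, frequency: float) -> float:
    """Modulus of the mean unit phasor of event phases at ``frequency``.

    ``times`` in ms, ``frequency`` in Hz.
    """
    times = np.asarray(times, dtype=float)
    if times.size == 0:
        raise ValueError("vector strength of an empty train is undefined")
    phases = 2.0 * np.pi * frequency * times / 1000.0
    return float(np.abs(np.mean(np.exp(1j * phases))))


def save_trains(path, trains: FiberTrains) -> None:
    """Write trains as two-column text (fiber id, time in ms)."""
    with open(path, "w") as fh:
        fh.write(f"# duration_ms {trains.duration}\n")
        for f, ev in enumerate(trains.times):
            for t in ev:
                fh.write(f"{f}\t{t:.9f}\n")


def load_trains(path) -> FiberTrains:
    """Read trains written by :func:`save_trains`."""
    duration = 0.0
    by_fiber: dict[int, list] = {}
    with open(path) as fh:
        for line in fh:
            if line.startswith("#"):
                if "duration_ms" in line:
                    duration = float(line.split()[-1])
                continue
            fid, t = line.split()
            by_fiber.setdefault(int(fid), []).append(float(t))
    n = max(by_fiber) + 1 if by_fiber else 0
    times = [np.asarray(by_fiber.get(f, []), dtype=float)
             for f in range(n)]
    return FiberTrains(times=times, duration=duration)
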