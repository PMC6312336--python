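"""Minimal biophysical model of a medial-superior-olive principal neuron.

The cell is a single iso-potential soma joined to two identical
cylindrical dendrites of constant diameter.  Each compartment carries a
passive leak conductance and the low-threshold potassium current
(KLT); all other subthreshold conductances are folded into the leak.
The compartment voltage obeys

    C_m dV_i/dt = -g_L (V_i - E_L) - g_KLT_bar w_i^4 z (V_i - E_K)
                  + I_syn,i(t) + I_c,i(t)

with the slow KLT inactivation gate z frozen at its resting value.  The
axial coupling currents I_c,i follow from the axial resistivity and the
cylinder geometry; the chain is integrated with a Crank-Nicolson scheme
(tridiagonal solve per step) with the activation gate w advanced on a
staggered half-step grid.

KLT gating
----------
The gating functions follow the Rothman-Manis low-threshold-potassium
formulation used throughout the auditory-brainstem modelling
literature, with three constants calibrated against the default
parameter set of this model:

* ``Z_SCALE`` scales the (frozen) inactivation gate so that
  w_inf(-60)^4 * z_inf(-60) = 0.017321, the value required for the
  default densities to rest at -60 mV with E_L = -47.4 mV;
* the activation time constant is normalized to tau_w(-60) = 1 ms;
* the activation steepness ``W_K`` is solved such that the linearized
  membrane (leak + static KLT + KLT activation slope) yields a DC
  space constant of 100 um for small perturbations around rest, the
  experimentally constrained subthreshold length scale of these cells
  (the passive space constant, excluding KLT, is 191 um).

Since z is frozen, only the product w^4 * z enters the dynamics, so the
constant rescaling of z is equivalent to rescaling the peak
conductance density and does not distort the voltage dependence.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, replace

import numpy as np

from ._kernels import TAU_W_NORM, axon_spikes, integrate_cable

__all__ = [
    "CellSpec", "CableGrid", "AxonParams", "StateTrace", "SynapticDrive",
    "IntegrationError", "passive_space_constant", "discretize_cell",
    "calibrate_leak_reversal", "klt_w_inf", "klt_tau_w", "klt_z_inf",
    "klt_current_density", "simulate", "detect_spikes", "input_resistance",
    "save_spike_times",
]

# --- KLT gating constants (see module docstring) -----------------------
W_VHALF = -48.0          # mV, activation half-voltage (Rothman-Manis)
W_K = 4.912434634185781  # mV, activation steepness, calibrated
Z_SCALE = 0.3466297736694189  # frozen-inactivation rescaling, calibrated


def klt_w_inf(v):
    """Steady-state KLT activation (fourth-root sigmoid)."""
    return (1.0 + np.exp(-(np.asarray(v, dtype=float) - W_VHALF) / W_K)) ** -0.25


def klt_tau_w(v, tau_w_scale: float = 1.0):
    """KLT activation time constant [ms]; equals ``tau_w_scale`` at rest."""
    v = np.asarray(v, dtype=float)
    raw = 100.0 / (6.0 * np.exp((v + 60.0) / 6.0)
                   + 16.0 * np.exp(-(v + 60.0) / 45.0)) + 1.5
    return tau_w_scale * raw / TAU_W_NORM


def klt_z_inf(v):
    """Rescaled steady-state KLT inactivation (frozen during simulation)."""
    v = np.asarray(v, dtype=float)
    return Z_SCALE * (0.5 + 0.5 / (1.0 + np.exp((v + 71.0) / 10.0)))


class IntegrationError(RuntimeError):
    """Raised when the integrator produces a non-finite state."""


@dataclass(frozen=True)
class CellSpec:
    """Morphology, membrane densities and reversal potentials.

    Units: areas um^2, lengths/diameters um, densities mS/cm^2,
    capacitance uF/cm^2, axial resistivity Ohm*cm, potentials mV.
    """

    soma_area: float = 1256.0
    dendrite_length: float = 150.0
    dendrite_diameter: float = 2.5
    g_L: float = 0.86
    g_KLT_bar: float = 13.6
    tau_w_scale: float = 1.0
    C_m: float = 1.0
    R_a: float = 200.0
    E_K: float = -106.0
    E_Na: float = 53.0
    E_L: float = -47.4
    V_rest: float = -60.0

    def __post_init__(self):
        if min(self.soma_area, self.dendrite_length,
               self.dendrite_diameter) < 0:
            raise ValueError("geometric parameters must be non-negative")
        if self.dendrite_length > 0 and self.dendrite_diameter <= 0:
            raise ValueError("positive dendrite length requires a "
                             "positive diameter")
        if self.g_L <= 0:
            raise ValueError("g_L must be positive")
        if not (self.E_K < self.V_rest < self.E_Na):
            raise ValueError("V_rest must lie between E_K and E_Na")

    @property
    def z_frozen(self) -> float:
        """Frozen KLT inactivation value z_inf(V_rest)."""
        return float(klt_z_inf(self.V_rest))

    def calibrated(self, target_rest: float | None = None) -> "CellSpec":
        """Return a copy with E_L set so the cell rests at ``target_rest``."""
        vr = self.V_rest if target_rest is None else target_rest
        spec = self if vr == self.V_rest else replace(self, V_rest=vr)
        return replace(spec, E_L=calibrate_leak_reversal(spec, vr))

    def total_area_um2(self) -> float:
        return self.soma_area + 2.0 * math.pi * self.dendrite_diameter \
            * self.dendrite_length


def passive_space_constant(spec: CellSpec) -> float:
    """Passive DC space constant lambda = sqrt(d / (4 R_a g_L)), in um.

    191 um for the default parameter set (excluding KLT).
    """
    if spec.dendrite_diameter <= 0:
        raise ValueError("diameter must be positive")
    d_cm = spec.dendrite_diameter * 1e-4
    g_s = spec.g_L * 1e-3
    lam_cm = math.sqrt(d_cm / (4.0 * spec.R_a * g_s))
    return lam_cm * 1e4


def calibrate_leak_reversal(spec: CellSpec, target_rest: float = -60.0
                            ) -> float:
    """Leak reversal that balances the KLT current at ``target_rest``.

    E_L = V_r + (g_KLT_bar w_inf(V_r)^4 z_inf(V_r) / g_L)(V_r - E_K).
    """
    p = float(klt_w_inf(target_rest)) ** 4 * float(klt_z_inf(target_rest))
    return target_rest + (spec.g_KLT_bar * p / spec.g_L) \
        * (target_rest - spec.E_K)


def klt_current_density(v, w, spec: CellSpec):
    """KLT current density g_KLT_bar w^4 z_inf(V_rest) (V - E_K), uA/cm^2."""
    return spec.g_KLT_bar * np.asarray(w) ** 4 * spec.z_frozen \
        * (np.asarray(v) - spec.E_K)


@dataclass
class CableGrid:
    """Discretized soma + two-dendrite chain.

    Compartments are ordered dendrite-1 tip -> base, soma, dendrite-2
    base -> tip, so nearest neighbours are adjacent and the coupling
    matrix is tridiagonal.  Dendrites are cut into segments of length
    0.02 * lambda (passive); the most distal segment absorbs the
    remainder.
    """

    areas_cm2: np.ndarray          # (n,) membrane area per compartment
    coupling_mS: np.ndarray        # (n-1,) axial conductance i <-> i+1
    soma_index: int
    positions_um: np.ndarray       # distance of compartment centre from soma
    dendrite_of: np.ndarray        # -1 soma, 0 dendrite 1, 1 dendrite 2
    dx_um: float

    @property
    def n(self) -> int:
        return self.areas_cm2.shape[0]

    @property
    def n_per_dendrite(self) -> int:
        return int(np.sum(self.dendrite_of == 0))

    def compartment_at(self, distance_um: float, dendrite: int = 0) -> int:
        """Index of the compartment whose centre is nearest ``distance_um``."""
        mask = self.dendrite_of == dendrite
        if not mask.any():
            return self.soma_index
        idx = np.where(mask)[0]
        return int(idx[np.argmin(np.abs(self.positions_um[idx]
                                        - distance_um))])


def discretize_cell(spec: CellSpec) -> CableGrid:
    """Build the compartment chain for ``spec``.

    Total membrane area equals soma_area + 2 pi d L by construction.
    """
    a_soma = spec.soma_area * 1e-8  # um^2 -> cm^2
    if spec.dendrite_length <= 0:
        return CableGrid(
            areas_cm2=np.array([a_soma]),
            coupling_mS=np.zeros(0),
            soma_index=0,
            positions_um=np.zeros(1),
            dendrite_of=np.array([-1]),
            dx_um=0.0,
        )
    lam = passive_space_constant(spec)
    dx = 0.02 * lam
    nd = int(math.ceil(spec.dendrite_length / dx))
    seg_len = np.full(nd, dx)
    seg_len[-1] = spec.dendrite_length - (nd - 1) * dx
    # centre positions measured from the soma
    edges = np.concatenate(([0.0], np.cumsum(seg_len)))
    centres = 0.5 * (edges[:-1] + edges[1:])

    d_cm = spec.dendrite_diameter * 1e-4
    seg_area = math.pi * d_cm * seg_len * 1e-4          # cm^2
    ax_sect = math.pi * d_cm ** 2 / 4.0                 # cm^2
    # axial conductance between neighbouring centres, in mS
    centre_gap = 0.5 * (seg_len[:-1] + seg_len[1:]) * 1e-4
    g_ax = ax_sect / (spec.R_a * centre_gap) * 1e3
    g_soma = ax_sect / (spec.R_a * (0.5 * seg_len[0] * 1e-4)) * 1e3

    n = 2 * nd + 1
    areas = np.empty(n)
    positions = np.empty(n)
    dend = np.empty(n, dtype=np.int64)
    # dendrite 1 stored tip -> base
    areas[:nd] = seg_area[::-1]
    positions[:nd] = centres[::-1]
    dend[:nd] = 0
    areas[nd] = a_soma
    positions[nd] = 0.0
    dend[nd] = -1
    areas[nd + 1:] = seg_area
    positions[nd + 1:] = centres
    dend[nd + 1:] = 1

    coupling = np.empty(n - 1)
    coupling[:nd - 1] = g_ax[::-1]
    coupling[nd - 1] = g_soma
    coupling[nd] = g_soma
    coupling[nd + 1:] = g_ax
    return CableGrid(areas_cm2=areas, coupling_mS=coupling, soma_index=nd,
                     positions_um=positions, dendrite_of=dend, dx_um=dx)


@dataclass(frozen=True)
class AxonParams:
    """Feed-forward axonal threshold compartment."""

    tau_m: float = 0.2       # ms, membrane time constant
    tau_couple: float = 0.05  # ms, coupling to the soma
    threshold: float = -50.0  # mV
    reset: float = -60.0      # mV
    refractory: float = 1.0   # ms
    v_rest: float = -60.0     # mV

    def __post_init__(self):
        if self.threshold <= self.reset:
            raise ValueError("threshold must exceed reset")
        if self.refractory <= 0:
            raise ValueError("refractory period must be positive")


@dataclass
class SynapticDrive:
    """Per-compartment synaptic conductance time series.

    ``g_nS`` has shape (len(comp_idx), n_steps + 1); values are scaled
    by ``scale`` inside the integrator, so a unit-amplitude drive can be
    reused across synaptic-strength sweeps.
    """

    comp_idx: np.ndarray
    g_nS: np.ndarray
    e_syn: float = 0.0
    scale: float = 1.0


@dataclass
class StateTrace:
    """Result of one integration run."""

    dt: float
    duration: float
    v_soma: np.ndarray              # (n_steps + 1,)
    v_peak: np.ndarray              # (n,) per-compartment max voltage
    fluxes_nC: dict                 # whole-cell charges per ionic pathway
    w_bounds: tuple                 # (min, max) of the gate over the run
    z_frozen: float
    spec: CellSpec
    grid: CableGrid
    v: np.ndarray | None = None     # (n_rec, n_steps+1) recorded voltages
    rec_idx: np.ndarray | None = None
    w: np.ndarray | None = None     # (n, n_steps) gate at half steps
    drive: SynapticDrive | None = None

    @property
    def t(self) -> np.ndarray:
        return np.arange(self.v_soma.shape[0]) * self.dt


_EMPTY_I = np.zeros(0, dtype=np.int64)
_EMPTY_F = np.zeros((0, 1))


def simulate(grid: CableGrid, spec: CellSpec, T: float, dt: float = 0.01,
             drive: SynapticDrive | None = None,
             i_inj: tuple[np.ndarray, np.ndarray] | None = None,
             record_idx: np.ndarray | None = None,
             record_w: bool = False,
             v_init: float | None = None) -> StateTrace:
    """Integrate the compartment chain for ``T`` ms.

    ``drive`` supplies synaptic conductances [nS]; ``i_inj`` is an
    optional (compartment indices, currents [nA]) pair with currents
    sampled on the same time grid.  ``record_idx`` selects compartments
    whose full voltage traces are kept (the soma is always recorded).

    Raises :class:`IntegrationError` if the state becomes non-finite.
    """
    if dt <= 0:
        raise ValueError("dt must be positive")
    n_steps = int(round(T / dt))
    n = grid.n

    v0 = spec.V_rest if v_init is None else v_init
    v = np.full(n, float(v0))
    w = np.full(n, float(klt_w_inf(v0)))

    cap = spec.C_m * grid.areas_cm2 * 1.0        # uF
    g_leak = spec.g_L * grid.areas_cm2 * 1.0     # mS
    g_klt_max = spec.g_KLT_bar * grid.areas_cm2 * spec.z_frozen

    if drive is not None:
        syn_idx = np.asarray(drive.comp_idx, dtype=np.int64)
        syn_g = np.ascontiguousarray(drive.g_nS, dtype=float)
        if syn_g.shape != (syn_idx.shape[0], n_steps + 1):
            raise ValueError("drive shape does not match the time grid")
        if drive.scale < 0 or (syn_g.size and syn_g.min() < -1e-12):
            raise ValueError("synaptic drive must be non-negative")
        e_syn = drive.e_syn
        syn_scale = drive.scale
    else:
        syn_idx, syn_g, e_syn, syn_scale = _EMPTY_I, _EMPTY_F, 0.0, 1.0

    if i_inj is not None:
        inj_idx = np.asarray(i_inj[0], dtype=np.int64)
        inj = np.ascontiguousarray(i_inj[1], dtype=float)
        if inj.shape != (inj_idx.shape[0], n_steps + 1):
            raise ValueError("injection shape does not match the time grid")
    else:
        inj_idx, inj = _EMPTY_I, _EMPTY_F

    if record_idx is None:
        rec_idx = np.array([grid.soma_index], dtype=np.int64)
    else:
        rec_idx = np.unique(np.concatenate(
            [np.asarray(record_idx, dtype=np.int64), [grid.soma_index]]))
    v_rec = np.empty((rec_idx.shape[0], n_steps + 1))
    w_rec = np.empty((n, n_steps)) if record_w else np.empty((1, 1))

    f_leak_na = (spec.E_L - spec.E_K) / (spec.E_Na - spec.E_K)
    if not 0.0 <= f_leak_na <= 1.0:
        raise ValueError("E_L outside [E_K, E_Na]")
    f_syn_na = (e_syn - spec.E_K) / (spec.E_Na - spec.E_K)

    # gating lookup tables; the 0.02 mV grid places V_rest = -60 mV on
    # a node so the calibrated rest stays an exact fixed point
    vmin_tab, dv_tab = -120.0, 0.02
    vgrid = vmin_tab + dv_tab * np.arange(9001)
    winf_tab = np.asarray(klt_w_inf(vgrid))
    wdecay_tab = np.exp(-dt / klt_tau_w(vgrid, spec.tau_w_scale))

    fluxes, v_peak, w_min, w_max, ok = integrate_cable(
        v, w, n_steps, dt, cap, g_leak, g_klt_max,
        spec.E_L, spec.E_K, spec.E_Na, e_syn,
        vmin_tab, 1.0 / dv_tab, winf_tab, wdecay_tab,
        grid.coupling_mS, syn_idx, syn_g, syn_scale, inj_idx, inj,
        f_leak_na, f_syn_na, rec_idx, v_rec, w_rec, record_w)
    if not ok:
        raise IntegrationError("non-finite state during integration "
                               "(reduce dt or input amplitude)")

    soma_row = int(np.where(rec_idx == grid.soma_index)[0][0])
    flux_dict = {
        "leak_na_in": fluxes[0], "leak_k_out": fluxes[1],
        "syn_na_in": fluxes[2], "syn_k_out": fluxes[3],
        "klt_k_out": fluxes[4],
    }
    return StateTrace(
        dt=dt, duration=n_steps * dt, v_soma=v_rec[soma_row].copy(),
        v_peak=v_peak, fluxes_nC=flux_dict, w_bounds=(w_min, w_max),
        z_frozen=spec.z_frozen, spec=spec, grid=grid,
        v=v_rec if record_idx is not None or record_w else None,
        rec_idx=rec_idx,
        w=w_rec if record_w else None, drive=drive)


def save_spike_times(path, times: np.ndarray) -> None:
    """Write spike times as one-column plain text [ms]."""
    np.savetxt(path, np.asarray(times, dtype=float), fmt="%.6f")


def detect_spikes(v_soma: np.ndarray, axon: AxonParams, dt: float
                  ) -> np.ndarray:
    """Spike times [ms] from the feed-forward axonal compartment."""
    v_soma = np.asarray(v_soma, dtype=float)
    if not np.all(np.isfinite(v_soma)):
        raise ValueError("somatic voltage trace contains non-finite values")
    return axon_spikes(v_soma, dt, axon.tau_m, axon.tau_couple,
                       axon.threshold, axon.reset, axon.refractory,
                       axon.v_rest)


def input_resistance(spec: CellSpec, mode: str = "control",
                     i_step_nA: float = -0.01, T: float = 50.0,
                     dt: float = 0.01) -> float:
    """Somatic input resistance [MOhm] from a small current step.

    ``mode='klt_blocked'`` zeroes the KLT conductance while keeping the
    calibrated leak reversal, and measures the deflection from the
    blocked model's own resting potential (which is then E_L).
    """
    if mode not in ("control", "klt_blocked"):
        raise ValueError("mode must be 'control' or 'klt_blocked'")
    if mode == "klt_blocked":
        # g_KLT_bar = 0 makes E_L the fixed point; start there
        spec = replace(spec, g_KLT_bar=0.0)
        v0 = spec.E_L
    else:
        v0 = spec.V_rest
    grid = discretize_cell(spec)
    n_steps = int(round(T / dt))
    inj = np.full((1, n_steps + 1), i_step_nA)
    trace = simulate(grid, spec, T, dt,
                     i_inj=(np.array([grid.soma_index]), inj), v_init=v0)
    tail = max(1, int(round(5.0 / dt)))
    v_ss = float(np.mean(trace.v_soma[-tail:]))
    return (v_ss - v0) / i_step_nA
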