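"""Ion-counting energy budget.

The Na/K pump is not modelled explicitly; instead every transmembrane
ionic current is split into its sodium and potassium components and the
sodium influx is integrated over the whole cell.  The pump extrudes
three sodium ions per ATP, so the mean sodium current converts directly
into an ATP consumption rate.  The leak conductance is split so that
its components' weighted reversal reproduces E_L; the synaptic
conductance splits 2:1 (Na:K) for a 0 mV reversal given E_Na = 53 mV
and E_K = -106 mV; the KLT current carries potassium only.  Capacitive
and axial currents transfer no net ion-specific charge and are
excluded.
"""

from __future__ import annotations

import json
from dataclasses import dataclass

import numpy as np

from .model_core import StateTrace

__all__ = [
    "ConductanceSplit", "EnergyLedger", "split_leak", "split_synaptic",
    "accumulate_fluxes", "ledger_from_trace", "atp_rate", "energy_density",
    "ELEMENTARY_PER_COULOMB",
]

ELEMENTARY_PER_COULOMB = 6.242e18  # elementary charges per coulomb
NA_PER_ATP = 3.0                   # pump stoichiometry


@dataclass(frozen=True)
class ConductanceSplit:
    """Sodium/potassium decomposition of a conductance."""

    g_na: float
    g_k: float

    @property
    def total(self) -> float:
        return self.g_na + self.g_k

    def reversal(self, e_na: float = 53.0, e_k: float = -106.0) -> float:
        return (self.g_na * e_na + self.g_k * e_k) / self.total


def split_leak(g_l: float, e_l: float, e_k: float = -106.0,
               e_na: float = 53.0) -> ConductanceSplit:
    """Split the leak so that the mixture reversal equals ``e_l``."""
    if not e_k <= e_l <= e_na:
        raise ValueError("E_L must lie within [E_K, E_Na]")
    f_na = (e_l - e_k) / (e_na - e_k)
    return ConductanceSplit(g_na=g_l * f_na, g_k=g_l * (1.0 - f_na))


def split_synaptic(g_syn, e_syn: float = 0.0, e_k: float = -106.0,
                   e_na: float = 53.0):
    """Split a synaptic conductance (scalar or series); 2:1 for E_syn = 0."""
    g_syn = np.asarray(g_syn, dtype=float)
    if np.any(g_syn < 0):
        raise ValueError("synaptic conductance must be non-negative")
    f_na = (e_syn - e_k) / (e_na - e_k)
    return ConductanceSplit(g_na=g_syn * f_na, g_k=g_syn * (1.0 - f_na))


@dataclass
class EnergyLedger:
    """Whole-cell Na/K charge transfer per source and derived ATP rate.

    Charges are in nC with influx positive for Na and efflux positive
    for K; ``duration_s`` in seconds.
    """

    na_nC: dict          # {"leak": .., "syn": .., "klt": 0.0}
    k_nC: dict
    duration_s: float

    @property
    def total_na_nC(self) -> float:
        return float(sum(self.na_nC.values()))

    @property
    def total_k_nC(self) -> float:
        return float(sum(self.k_nC.values()))

    @property
    def mean_na_current_nA(self) -> float:
        # nC per second is nA
        return self.total_na_nC / self.duration_s

    @property
    def atp_per_s(self) -> float:
        return atp_rate(self.mean_na_current_nA)

    def __add__(self, other: "EnergyLedger") -> "EnergyLedger":
        na = {k: self.na_nC[k] + other.na_nC[k] for k in self.na_nC}
        kk = {k: self.k_nC[k] + other.k_nC[k] for k in self.k_nC}
        return EnergyLedger(na, kk, self.duration_s + other.duration_s)

    def to_json(self, path=None) -> str:
        obj = {"na_nC": self.na_nC, "k_nC": self.k_nC,
               "duration_s": self.duration_s,
               "mean_na_current_nA": self.mean_na_current_nA,
               "atp_per_s": self.atp_per_s}
        s = json.dumps(obj, indent=2)
        if path is not None:
            with open(path, "w") as fh:
                fh.write(s)
        return s


def ledger_from_trace(trace: StateTrace) -> EnergyLedger:
    """Ledger from the charges accumulated during integration."""
    f = trace.fluxes_nC
    return EnergyLedger(
        na_nC={"leak": f["leak_na_in"], "syn": f["syn_na_in"], "klt": 0.0},
        k_nC={"leak": f["leak_k_out"], "syn": f["syn_k_out"],
              "klt": f["klt_k_out"]},
        duration_s=trace.duration / 1000.0)


def accumulate_fluxes(trace: StateTrace, drive=None) -> EnergyLedger:
    """Recompute the ledger from recorded state (independent of the
    integrator's running sums).

    Requires a trace recorded with all compartments and the gate
    (``record_idx=range(n), record_w=True``).  Leak and synaptic fluxes
    use trapezoidal integration on the voltage nodes; the KLT flux uses
    the midpoint rule with the half-step gate values, matching the
    integrator's quadrature so both routes agree to round-off.
    """
    spec, grid = trace.spec, trace.grid
    if drive is None:
        drive = trace.drive
    if trace.v is None or trace.rec_idx is None \
            or trace.rec_idx.shape[0] != grid.n:
        raise ValueError("trace must record every compartment")
    order = np.argsort(trace.rec_idx)
    v = trace.v[order]                       # (n, n_steps+1), grid order
    dt = trace.dt

    leak = split_leak(spec.g_L, spec.E_L, spec.E_K, spec.E_Na)
    a = grid.areas_cm2
    # mS per compartment
    g_na_leak = leak.g_na * a
    g_k_leak = leak.g_k * a

    def trapz_t(x):
        return dt * (np.sum(x) - 0.5 * (x[0] + x[-1]))

    na_leak = trapz_t(g_na_leak @ (spec.E_Na - v))
    k_leak = trapz_t(g_k_leak @ (v - spec.E_K))

    na_syn = k_syn = 0.0
    if drive is not None:
        syn = split_synaptic(1.0, drive.e_syn, spec.E_K, spec.E_Na)
        g = drive.g_nS * drive.scale * 1e-6  # nS -> mS
        vs = v[drive.comp_idx]
        na_syn = trapz_t(np.sum(syn.g_na * g * (spec.E_Na - vs), axis=0))
        k_syn = trapz_t(np.sum(syn.g_k * g * (vs - spec.E_K), axis=0))

    if trace.w is None:
        raise ValueError("trace must record the gate for the KLT flux")
    g_klt = spec.g_KLT_bar * a[:, None] * spec.z_frozen * trace.w ** 4
    v_mid = 0.5 * (v[:, :-1] + v[:, 1:])
    k_klt = dt * float(np.sum(g_klt * (v_mid - spec.E_K)))

    return EnergyLedger(
        na_nC={"leak": float(na_leak), "syn": float(na_syn), "klt": 0.0},
        k_nC={"leak": float(k_leak), "syn": float(k_syn),
              "klt": float(k_klt)},
        duration_s=trace.duration / 1000.0)


def atp_rate(mean_na_current_nA: float) -> float:
    """ATP/s to extrude the sodium carried by ``mean_na_current_nA``.

    |I| * 6.242e18 / 3 with the current in amperes: 3 nA -> 6.2e9 ATP/s.
    """
    return abs(mean_na_current_nA) * 1e-9 * ELEMENTARY_PER_COULOMB \
        / NA_PER_ATP


def energy_density(atp_per_s: float, volume_um3: float) -> float:
    """ATP consumption per um^3 per second (3600 um^3 -> 1.7e6 for the
    default model's 6.2e9 ATP/s)."""
    if volume_um3 <= 0:
        raise ValueError("volume must be positive")
    return atp_per_s / volume_um3
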