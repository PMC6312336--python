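"""Electrophysiological protocols and the conductance-density fit.

Mirrors the in-vitro characterization of MSO principal cells: an
EPSC-shaped current (alpha function, tau = 0.2 ms) is injected into a
dendrite at a given distance from the soma, its amplitude adjusted
until the somatic EPSP peaks at 10 mV, and the dendrite-to-soma
attenuation and the somatic EPSP halfwidth are read out.  Together
with the somatic input resistance (control and KLT-blocked) these
observables drive a grid search over the leak and KLT conductance
densities.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np
import pandas as pd

from .input_gen import FiberTrains, alpha_conductance, build_drive, \
    place_synapses
from .model_core import CellSpec, discretize_cell, input_resistance, simulate

__all__ = ["EpscProtocolResult", "FitResult", "epsc_response",
           "dendritic_saturation", "fit_densities", "fit_observables",
           "fit_error", "TargetUnreachableError", "MultiPeakError"]

DEFAULT_FIT_DISTANCES = (0.0, 25.0, 50.0, 75.0, 100.0)


class TargetUnreachableError(RuntimeError):
    """The somatic response saturates below the requested amplitude."""


class MultiPeakError(RuntimeError):
    """Halfwidth undefined: the somatic response has multiple peaks."""


@dataclass
class EpscProtocolResult:
    distance_um: float
    amplitude_nA: float          # fitted EPSC peak amplitude
    dendritic_amp_mV: float
    somatic_amp_mV: float
    attenuation: float           # dendritic / somatic, >= 1
    halfwidth_ms: float


def _halfwidth(t: np.ndarray, x: np.ndarray) -> float:
    """Width of the (single-peaked) deflection at half its maximum."""
    peak = float(np.max(x))
    half = 0.5 * peak
    above = x >= half
    # contiguous block around the absolute peak
    edges = np.flatnonzero(np.diff(above.astype(int)))
    ipk = int(np.argmax(x))
    rising = edges[edges < ipk]
    falling = edges[edges >= ipk]
    if rising.size == 0 or falling.size == 0:
        raise MultiPeakError("half-maximum crossings not found")
    i0, i1 = rising[-1], falling[0]
    if rising.size + falling.size > 2:
        raise MultiPeakError("multiple half-maximum crossings; "
                             "response is not single-peaked")
    # linear interpolation of the crossing times
    t0 = t[i0] + (half - x[i0]) / (x[i0 + 1] - x[i0]) * (t[i0 + 1] - t[i0])
    t1 = t[i1] + (half - x[i1]) / (x[i1 + 1] - x[i1]) * (t[i1 + 1] - t[i1])
    return float(t1 - t0)


def _bisect_amplitude(run, target: float, tol: float, max_iter: int = 40):
    """Find the stimulus amplitude giving a somatic peak of ``target`` mV.

    ``run(amp)`` returns the somatic peak deflection.  Doubles upward
    from 1 until bracketed, then bisects to ``tol``.
    """
    hi = 1.0
    peak_hi = run(hi)
    grow = 0
    while peak_hi < target and grow < 40:
        hi *= 2.0
        peak_hi = run(hi)
        grow += 1
    if peak_hi < target:
        raise TargetUnreachableError(
            f"somatic response saturates at {peak_hi:.2f} mV "
            f"below the {target} mV target")
    lo = 0.0
    amp = hi
    for _ in range(max_iter):
        if abs(peak_hi - target) <= tol:
            break
        amp = 0.5 * (lo + hi)
        peak = run(amp)
        if peak < target:
            lo = amp
        else:
            hi, peak_hi = amp, peak
    return hi


def epsc_response(spec: CellSpec, distance_um: float,
                  target_mV: float = 10.0, tol_mV: float = 0.05,
                  tau: float = 0.2, T: float = 15.0, dt: float = 0.01
                  ) -> EpscProtocolResult:
    """EPSC injection protocol at ``distance_um`` from the soma."""
    if not 0.0 <= distance_um <= max(spec.dendrite_length, 0.0):
        raise ValueError("distance outside the dendrite")
    grid = discretize_cell(spec)
    comp = grid.compartment_at(distance_um, dendrite=0) \
        if spec.dendrite_length > 0 and distance_um > 0 else grid.soma_index
    n_steps = int(round(T / dt))
    t = np.arange(n_steps + 1) * dt
    t0 = 1.0
    wave = np.where(t >= t0, (t - t0) / tau * np.exp(1 - (t - t0) / tau),
                    0.0)

    cache = {}

    def run(amp):
        trace = simulate(grid, spec, T, dt,
                         i_inj=(np.array([comp]), amp * wave[None, :]),
                         record_idx=np.array([comp]))
        cache["trace"] = trace
        return float(np.max(trace.v_soma) - spec.V_rest)

    amp = _bisect_amplitude(run, target_mV, tol_mV)
    run(amp)
    trace = cache["trace"]
    soma_v = trace.v_soma - spec.V_rest
    row = int(np.where(trace.rec_idx == comp)[0][0])
    dend_amp = float(np.max(trace.v[row]) - spec.V_rest)
    soma_amp = float(np.max(soma_v))
    return EpscProtocolResult(
        distance_um=distance_um, amplitude_nA=amp,
        dendritic_amp_mV=dend_amp, somatic_amp_mV=soma_amp,
        attenuation=dend_amp / soma_amp,
        halfwidth_ms=_halfwidth(t, soma_v))


def dendritic_saturation(spec: CellSpec, n_fibers: int = 6,
                         target_mV: float = 10.0, tol_mV: float = 0.05,
                         tau: float = 0.2, dt: float = 0.01) -> float:
    """Peak dendritic depolarization / (E_syn - V_rest) when all
    synapses fire once synchronously, scaled for a 10 mV somatic EPSP.
    """
    grid = discretize_cell(spec)
    syn = place_synapses(grid, n_fibers, spec.dendrite_length)
    T = 15.0
    cache = {}

    def run(epsg):
        trains = FiberTrains(times=[np.array([1.0])] * syn.size,
                             comp_idx=syn, duration=T)
        drive = build_drive(trains, tau, T, dt, g_peak=epsg)
        trace = simulate(grid, spec, T, dt, drive=drive)
        cache["trace"] = trace
        return float(np.max(trace.v_soma) - spec.V_rest)

    _bisect_amplitude(run, target_mV, tol_mV)
    trace = cache["trace"]
    peak = float(np.max(trace.v_peak)) - spec.V_rest
    return peak / (0.0 - spec.V_rest)


def fit_observables(spec: CellSpec,
                    distances=DEFAULT_FIT_DISTANCES) -> dict:
    """The four fitted observables for one candidate model."""
    res = [epsc_response(spec, d) for d in distances]
    return {
        "r_in_control": input_resistance(spec, "control"),
        "r_in_blocked": input_resistance(spec, "klt_blocked"),
        "attenuation": np.array([r.attenuation for r in res]),
        "halfwidth": np.array([r.halfwidth_ms for r in res]),
    }


@dataclass
class FitResult:
    table: pd.DataFrame          # g_L, g_KLT_bar, error
    best: CellSpec
    best_error: float


def fit_error(observables: dict, targets: dict) -> float:
    """Total fit error: per observable, the mean squared deviation
    normalized by the squared mean of its targets, summed over the four
    observables.  Dimensionless, hence invariant to a change of units
    of any one observable."""

    def norm_mse(model, target):
        model = np.atleast_1d(np.asarray(model, dtype=float))
        target = np.atleast_1d(np.asarray(target, dtype=float))
        return float(np.mean((model - target) ** 2)
                     / np.mean(target) ** 2)

    return sum(norm_mse(observables[k], targets[k])
               for k in ("r_in_control", "r_in_blocked",
                         "attenuation", "halfwidth"))


def fit_densities(targets: dict, g_l_grid, g_klt_grid,
                  base: CellSpec | None = None,
                  distances=DEFAULT_FIT_DISTANCES) -> FitResult:
    """Grid search over (g_L, g_KLT_bar) against target observables.

    ``targets`` carries 'r_in_control', 'r_in_blocked' (MOhm) and
    'attenuation'/'halfwidth' arrays sampled at ``distances``.  Each
    observable contributes its mean squared error normalized by the
    squared mean of its target values (dimensionless, so the total is
    invariant to unit changes of any one observable); the candidate
    minimizing the sum wins.  Every candidate is recalibrated to rest
    at -60 mV before evaluation.
    """
    g_l_grid = np.atleast_1d(np.asarray(g_l_grid, dtype=float))
    g_klt_grid = np.atleast_1d(np.asarray(g_klt_grid, dtype=float))
    if g_l_grid.size == 0 or g_klt_grid.size == 0:
        raise ValueError("empty parameter grid")
    base = base or CellSpec()
    rows = []
    best = None
    for gl in g_l_grid:
        for gk in g_klt_grid:
            cand = replace(base, g_L=float(gl),
                           g_KLT_bar=float(gk)).calibrated()
            obs = fit_observables(cand, distances)
            err = fit_error(obs, targets)
            rows.append({"g_L": gl, "g_KLT_bar": gk, "error": err})
            if best is None or err < best[0]:
                best = (err, cand)
    table = pd.DataFrame(rows)
    return FitResult(table=table, best=best[1], best_error=best[0])
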