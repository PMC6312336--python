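"""Parameter-sweep studies: performance versus ATP cost, pareto front.

Every swept model is rebuilt from scratch: the leak reversal is
recalibrated so the cell rests at -60 mV, the EPSG peak is re-optimized
for rate modulation, and the ATP rate is taken from the in-phase
(ITD = 0) stimulus at that optimal EPSG.  Records collect into
(parameter, optimal EPSG, modulation, reciprocal performance, ATP rate)
rows that feed the trade-off and pareto analyses.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, replace

import numpy as np
import pandas as pd

from .energy_accounting import ledger_from_trace
from .input_gen import (StimulusSpec, build_drive,
                        generate_phase_locked_trains,
                        generate_spontaneous_trains, place_synapses)
from .itd_performance import EpsgOptimum, optimize_epsg
from .model_core import AxonParams, CellSpec, discretize_cell, simulate

__all__ = ["SweepRecord", "run_sweep", "constrained_sweep_constant_area",
           "constrained_sweep_densities", "spontaneous_cost_ratio",
           "pareto_front", "records_to_frame"]

SWEEPABLE = ("dendrite_length", "dendrite_diameter", "soma_area",
             "g_L", "g_KLT_bar", "tau_w_scale")


@dataclass
class SweepRecord:
    parameter: str
    value: float
    optimal_epsg_nS: float
    max_modulation: float        # spikes/s
    atp_per_s: float             # at optimal EPSG, ITD = 0
    spec: CellSpec | None = None
    optimum: EpsgOptimum | None = None
    feasible: bool = True

    @property
    def reciprocal_performance(self) -> float:
        if self.max_modulation <= 0:
            return float("inf")
        return 1000.0 / self.max_modulation


def _evaluate_spec(spec: CellSpec, stim: StimulusSpec, parameter: str,
                   value: float, axon=None, **opt_kwargs) -> SweepRecord:
    opt = optimize_epsg(spec, stim, axon=axon, **opt_kwargs)
    atp = opt.ledger_at_optimum.atp_per_s if opt.ledger_at_optimum else 0.0
    return SweepRecord(parameter=parameter, value=value,
                       optimal_epsg_nS=opt.optimal_epsg,
                       max_modulation=opt.max_modulation,
                       atp_per_s=atp, spec=spec, optimum=opt)


def run_sweep(base: CellSpec, parameter: str, values, stim: StimulusSpec,
              axon: AxonParams | None = None, verbose: bool = False,
              **opt_kwargs) -> list:
    """Sweep one cell parameter; every model is recalibrated and gets
    its own EPSG optimization."""
    if parameter not in SWEEPABLE:
        raise ValueError(f"unknown sweep parameter {parameter!r}; "
                         f"choose one of {SWEEPABLE}")
    records = []
    for v in values:
        spec = replace(base, **{parameter: float(v)}).calibrated()
        rec = _evaluate_spec(spec, stim, parameter, float(v),
                             axon=axon, **opt_kwargs)
        records.append(rec)
        if verbose:
            print(f"{parameter}={v:g}: EPSG* {rec.optimal_epsg_nS:.1f} nS, "
                  f"mod {rec.max_modulation:.0f} sp/s, "
                  f"ATP {rec.atp_per_s:.3g}/s")
    return records


def constrained_sweep_constant_area(base: CellSpec, pairs,
                                    stim: StimulusSpec,
                                    axon: AxonParams | None = None,
                                    rel_tol: float = 1e-3,
                                    **opt_kwargs) -> list:
    """Sweep (length, diameter) pairs with pi*d*L held constant."""
    pairs = [(float(length), float(diam)) for length, diam in pairs]
    areas = [math.pi * d * length for length, d in pairs]
    if max(areas) - min(areas) > rel_tol * np.mean(areas):
        raise ValueError("pairs do not conserve dendritic surface area")
    records = []
    for length, d in pairs:
        spec = replace(base, dendrite_length=length,
                       dendrite_diameter=d).calibrated()
        rec = _evaluate_spec(spec, stim, "length_diameter", length,
                             axon=axon, **opt_kwargs)
        records.append(rec)
    return records


def constrained_sweep_densities(base: CellSpec, g_l_values, g_klt_values,
                                stim: StimulusSpec,
                                axon: AxonParams | None = None,
                                **opt_kwargs) -> list:
    """Grid over leak and KLT densities, each cell recalibrated to rest
    at -60 mV; combinations whose required E_L exceeds E_Na are flagged
    infeasible and skipped."""
    records = []
    for gl in g_l_values:
        for gk in g_klt_values:
            cand = replace(base, g_L=float(gl), g_KLT_bar=float(gk))
            el = cand.calibrated().E_L
            if el > base.E_Na:
                records.append(SweepRecord(
                    parameter="g_L,g_KLT_bar", value=float(gl),
                    optimal_epsg_nS=float("nan"), max_modulation=0.0,
                    atp_per_s=float("nan"), spec=None, feasible=False))
                continue
            spec = replace(cand, E_L=el)
            rec = _evaluate_spec(spec, stim, "g_L,g_KLT_bar", float(gl),
                                 axon=axon, **opt_kwargs)
            records.append(rec)
    return records


def spontaneous_cost_ratio(spec: CellSpec, stim: StimulusSpec,
                           spontaneous_rate: float = 55.0,
                           dt: float = 0.01) -> float:
    """ATP rate under spontaneous Poisson drive divided by the ATP rate
    during in-phase tone processing, both at ``stim.epsg_peak``."""
    grid = discretize_cell(spec)
    syn = place_synapses(grid, stim.fibers_per_dendrite,
                         spec.dendrite_length)

    tone = generate_phase_locked_trains(replace(stim, itd=0.0))
    tone.comp_idx = syn
    drive = build_drive(tone, stim.tau_syn, stim.duration, dt,
                        e_syn=stim.e_syn, g_peak=stim.epsg_peak)
    atp_tone = ledger_from_trace(
        simulate(grid, spec, stim.duration, dt, drive=drive)).atp_per_s

    spont = generate_spontaneous_trains(spontaneous_rate, stim.duration,
                                        stim.seed + 1,
                                        n_fibers=2 * stim.fibers_per_dendrite)
    spont.comp_idx = syn
    drive_s = build_drive(spont, stim.tau_syn, stim.duration, dt,
                          e_syn=stim.e_syn, g_peak=stim.epsg_peak)
    atp_spont = ledger_from_trace(
        simulate(grid, spec, stim.duration, dt, drive=drive_s)).atp_per_s
    return atp_spont / atp_tone


def pareto_front(records) -> list:
    """Records non-dominated in (ATP rate, reciprocal performance).

    A record dominates another if it is no worse on both axes and
    strictly better on at least one; ties are kept.
    """
    recs = [r for r in records if r.feasible]
    if not recs:
        raise ValueError("no feasible records")
    pts = [(r.atp_per_s, r.reciprocal_performance) for r in recs]
    keep = []
    for i, (ci, pi) in enumerate(pts):
        dominated = any(
            (cj <= ci and pj <= pi) and (cj < ci or pj < pi)
            for j, (cj, pj) in enumerate(pts) if j != i)
        if not dominated:
            keep.append(recs[i])
    return keep


def records_to_frame(records) -> pd.DataFrame:
    return pd.DataFrame([{
        "parameter": r.parameter, "value": r.value,
        "optimal_epsg_nS": r.optimal_epsg_nS,
        "max_modulation": r.max_modulation,
        "reciprocal_performance": r.reciprocal_performance,
        "atp_per_s": r.atp_per_s, "feasible": r.feasible,
    } for r in records])
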