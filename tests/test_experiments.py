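"""Sweep machinery, spontaneous-cost ratio and pareto extraction."""

from dataclasses import replace

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from msoenergy import (CellSpec, StimulusSpec, SweepRecord,
                       constrained_sweep_constant_area,
                       constrained_sweep_densities, optimize_epsg,
                       pareto_front, records_to_frame, run_sweep,
                       spontaneous_cost_ratio)

FAST = StimulusSpec(duration=500.0, seed=21)
FAST_GRID = np.array([10.0, 20.0, 40.0])


def brute_force_front(records):
    out = []
    for r in records:
        dominated = False
        for s in records:
            if s is r:
                continue
            if (s.atp_per_s <= r.atp_per_s
                    and s.reciprocal_performance
                    <= r.reciprocal_performance
                    and (s.atp_per_s < r.atp_per_s
                         or s.reciprocal_performance
                         < r.reciprocal_performance)):
                dominated = True
                break
        if not dominated:
            out.append(r)
    return out


def make_records(points):
    return [SweepRecord(parameter="x", value=float(i),
                        optimal_epsg_nS=20.0,
                        max_modulation=(1000.0 / rp if rp > 0
                                        else float("inf")),
                        atp_per_s=cost)
            for i, (cost, rp) in enumerate(points)]


class TestParetoFront:
    def test_single_record_survives(self):
        recs = make_records([(1.0, 3.0)])
        assert pareto_front(recs) == recs

    def test_worked_example(self):
        recs = make_records([(1.0, 3.0), (2.0, 3.5)])
        assert pareto_front(recs) == [recs[0]]

    def test_front_members_pairwise_nondominated(self):
        rng = np.random.default_rng(17)
        recs = make_records(list(zip(rng.uniform(1, 10, 200),
                                     rng.uniform(2, 30, 200))))
        front = pareto_front(recs)
        for a in front:
            for b in front:
                if a is b:
                    continue
                assert not (b.atp_per_s <= a.atp_per_s
                            and b.reciprocal_performance
                            <= a.reciprocal_performance
                            and (b.atp_per_s < a.atp_per_s
                                 or b.reciprocal_performance
                                 < a.reciprocal_performance))

    @settings(max_examples=30, deadline=None, derandomize=True)
    @given(st.lists(st.tuples(
        st.floats(0.1, 100.0, allow_nan=False),
        st.floats(2.0, 1000.0, allow_nan=False)), min_size=1,
        max_size=60))
    def test_matches_brute_force_oracle(self, points):
        recs = make_records(points)
        assert set(map(id, pareto_front(recs))) \
            == set(map(id, brute_force_front(recs)))

    def test_large_random_set_matches_oracle(self):
        rng = np.random.default_rng(99)
        recs = make_records(list(zip(rng.uniform(1, 5, 1000),
                                     rng.uniform(2, 10, 1000))))
        assert set(map(id, pareto_front(recs))) \
            == set(map(id, brute_force_front(recs)))

    def test_empty_input_rejected(self):
        with pytest.raises(ValueError):
            pareto_front([])


class TestSweeps:
    def test_single_value_sweep_equals_direct_evaluation(self,
                                                         default_spec):
        recs = run_sweep(default_spec, "g_KLT_bar", [13.6], FAST,
                         epsg_grid=FAST_GRID, refine=False)
        assert len(recs) == 1
        direct = optimize_epsg(default_spec.calibrated(), FAST,
                               epsg_grid=FAST_GRID, refine=False)
        assert recs[0].max_modulation == pytest.approx(
            direct.max_modulation)
        assert recs[0].optimal_epsg_nS == pytest.approx(
            direct.optimal_epsg)
        assert recs[0].atp_per_s == pytest.approx(
            direct.ledger_at_optimum.atp_per_s)

    def test_sweep_deterministic_under_same_seed(self, default_spec):
        a = run_sweep(default_spec, "dendrite_length", [100.0], FAST,
                      epsg_grid=FAST_GRID, refine=False)
        b = run_sweep(default_spec, "dendrite_length", [100.0], FAST,
                      epsg_grid=FAST_GRID, refine=False)
        assert a[0].max_modulation == b[0].max_modulation
        assert a[0].atp_per_s == b[0].atp_per_s

    def test_unknown_parameter_rejected(self, default_spec):
        with pytest.raises(ValueError):
            run_sweep(default_spec, "axial_wiggle", [1.0], FAST)

    def test_constant_area_pairs_validated(self, default_spec):
        with pytest.raises(ValueError):
            constrained_sweep_constant_area(
                default_spec, [(150.0, 2.5), (300.0, 2.5)], FAST)

    def test_constant_area_sweep_runs(self, default_spec):
        # pi d L conserved: (150, 2.5) <-> (250, 1.5)
        recs = constrained_sweep_constant_area(
            default_spec, [(150.0, 2.5), (250.0, 1.5)], FAST,
            epsg_grid=FAST_GRID, refine=False)
        assert len(recs) == 2
        assert all(r.feasible for r in recs)

    def test_density_grid_flags_infeasible_calibration(self,
                                                       default_spec):
        # g_KLT/g_L so large that the required E_L exceeds E_Na
        recs = constrained_sweep_densities(
            default_spec, [0.2], [40.0], FAST,
            epsg_grid=FAST_GRID, refine=False)
        assert len(recs) == 1
        assert not recs[0].feasible

    def test_records_frame_columns(self, default_spec):
        recs = run_sweep(default_spec, "soma_area", [1256.0], FAST,
                         epsg_grid=FAST_GRID, refine=False)
        df = records_to_frame(recs)
        assert {"parameter", "value", "max_modulation",
                "atp_per_s"} <= set(df.columns)


class TestSpontaneousCost:
    def test_ratio_increases_with_spontaneous_rate(self, default_spec):
        stim = replace(FAST, epsg_peak=20.0, duration=1000.0)
        ratios = [spontaneous_cost_ratio(default_spec, stim, r)
                  for r in (0.0, 30.0, 55.0)]
        assert ratios[0] < ratios[1] < ratios[2]
        # zero spontaneous input leaves only the leak/KLT resting cost
        assert 0.0 < ratios[0] < 1.0
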