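"""Cyclic tensile processing: segmentation, zeroing, moduli, resilience."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from raptormech import synthetic, tensile
from raptormech.synthetic import TendonModelParams, generate_tendon_trace
from raptormech.tensile import (
    SegmentationError,
    TensileTrace,
    aggregate_results,
    final_leg_load,
    loop_areas_resilience,
    process_trace,
    region_moduli,
    region_windows,
    rising_falling_split,
    segment_cycles,
    strain,
    stress,
    zero_load_offset,
)


def _noise_free_trace(**kw):
    kw.setdefault("noise_sd", 0.0)
    return generate_tendon_trace(TendonModelParams(**kw))


class TestSegmentation:
    def test_five_cycles_with_exact_apexes(self, jcurve_params):
        trace = generate_tendon_trace(jcurve_params)
        cycles = segment_cycles(trace)
        assert len(cycles) == 5
        apex_disp = trace.displacement[[c.apex_index for c in cycles]]
        assert np.allclose(apex_disp, jcurve_params.eps_max * jcurve_params.L0)

    def test_apex_indices_match_generator_ground_truth(self):
        trace = generate_tendon_trace(TendonModelParams(noise_sd=0.05, seed=3))
        cycles = segment_cycles(trace)
        gt = trace.metadata["ground_truth"]["apex_indices"]
        assert [c.apex_index for c in cycles] == list(gt)

    def test_monotone_ramp_rejected(self):
        t = np.arange(100) / 50.0
        trace = TensileTrace(
            species="x", leg="L", increment_pct=10,
            time=t, load=t.copy(), displacement=t.copy(), L0=15.0, A0=5.0,
        )
        with pytest.raises(SegmentationError):
            segment_cycles(trace)

    def test_cycles_partition_trace(self, jcurve_params):
        trace = generate_tendon_trace(jcurve_params)
        cycles = segment_cycles(trace)
        for prev, cur in zip(cycles, cycles[1:]):
            assert cur.start_index == prev.end_index
        assert cycles[0].start_index == 0
        assert cycles[-1].end_index == len(trace) - 1


class TestZeroOffset:
    def test_recovers_exact_pretension(self):
        trace = _noise_free_trace(pretension=2.0)
        cycles = segment_cycles(trace)
        assert zero_load_offset(cycles, trace) == pytest.approx(2.0, abs=1e-12)

    def test_mean_of_trough_minima(self):
        # Pre-tension lifts the whole trace to 1 N; minima injected at the
        # last three troughs are then the per-trough minimum loads.
        trace = _noise_free_trace(pretension=1.0)
        cycles = segment_cycles(trace)
        troughs = trace.metadata["ground_truth"]["trough_indices"]
        # Inject distinct minima into the last three cycle troughs.
        load = trace.load.copy()
        load[troughs[-3]] = 0.10
        load[troughs[-2]] = 0.12
        load[troughs[-1]] = 0.14
        patched = TensileTrace(
            species="x", leg="L", increment_pct=10,
            time=trace.time, load=load, displacement=trace.displacement,
            L0=trace.L0, A0=trace.A0,
        )
        assert zero_load_offset(cycles, patched) == pytest.approx(0.12)

    def test_noisy_pretension_recovery(self):
        trace = generate_tendon_trace(
            TendonModelParams(pretension=1.5, noise_sd=0.02, seed=11)
        )
        cycles = segment_cycles(trace)
        assert zero_load_offset(cycles, trace) == pytest.approx(1.5, abs=0.1)

    def test_requires_three_cycles(self):
        trace = _noise_free_trace(n_cycles=2)
        cycles = segment_cycles(trace, n_cycles=2)
        with pytest.raises(ValueError):
            zero_load_offset(cycles, trace)

    def test_zeroing_idempotent(self, jcurve_params):
        trace = generate_tendon_trace(jcurve_params)
        cycles = segment_cycles(trace)
        offset = zero_load_offset(cycles, trace)
        rezeroed = TensileTrace(
            species="x", leg="L", increment_pct=10,
            time=trace.time, load=trace.load - offset,
            displacement=trace.displacement, L0=trace.L0, A0=trace.A0,
        )
        assert zero_load_offset(segment_cycles(rezeroed), rezeroed) == pytest.approx(
            0.0, abs=1e-12
        )


class TestFinalLoad:
    def test_mean_of_central_cycle_peaks(self):
        trace = _noise_free_trace()
        cycles = segment_cycles(trace)
        apexes = [c.apex_index for c in cycles]
        load = trace.load.copy()
        peak = load.max()
        for idx, val in zip(apexes, [10.0, 9.0, 9.5, 9.3, 9.1]):
            load[idx] = peak + val  # keep apexes the cycle maxima
        patched = TensileTrace(
            species="x", leg="L", increment_pct=10,
            time=trace.time, load=load, displacement=trace.displacement,
            L0=trace.L0, A0=trace.A0,
        )
        expected = peak + np.mean([9.0, 9.5, 9.3])
        assert final_leg_load(segment_cycles(patched), patched, 0.0) == pytest.approx(
            expected
        )

    def test_noise_free_equals_closed_form_peak(self, jcurve_params):
        p = TendonModelParams(
            a=jcurve_params.a, b=jcurve_params.b, eps_max=jcurve_params.eps_max,
            A0=jcurve_params.A0, L0=jcurve_params.L0,
            resilience=jcurve_params.resilience,
            pretension=2.0, noise_sd=0.0, seed=1,
        )
        trace = generate_tendon_trace(p)
        cycles = segment_cycles(trace)
        offset = zero_load_offset(cycles, trace)
        # Pre-tension cancels through the zero offset.
        assert final_leg_load(cycles, trace, offset) == pytest.approx(
            p.sigma_m * p.A0, rel=1e-9
        )

    def test_requires_four_cycles(self):
        trace = _noise_free_trace(n_cycles=3)
        cycles = segment_cycles(trace, n_cycles=3)
        with pytest.raises(ValueError):
            final_leg_load(cycles, trace, 0.0)


class TestStressStrain:
    @pytest.mark.parametrize(
        "F,A0,expected",
        [(21.7, 5.05, 4.297), (28.0, 17.56, 1.594), (0.0, 5.0, 0.0)],
    )
    def test_stress_reference_values(self, F, A0, expected):
        assert stress(F, A0) == pytest.approx(expected, abs=0.005)

    def test_strain_reference_values(self):
        assert strain(14.43 - 13.12, 13.12) == pytest.approx(0.0999, abs=5e-4)
        assert 1.1 * 20.25 == pytest.approx(22.275)  # stretched length at 10 %
        assert strain(0.0, 13.12) == 0.0

    def test_domain_errors(self):
        with pytest.raises(ValueError):
            stress(1.0, 0.0)
        with pytest.raises(ValueError):
            strain(1.0, -2.0)

    @given(k=st.floats(0.1, 50.0))
    @settings(max_examples=25, deadline=None)
    def test_unit_consistent_rescaling(self, k):
        assert stress(21.7 * k, 5.05 * k) == pytest.approx(stress(21.7, 5.05))


class TestSplit:
    def test_rising_curve_matches_loading_curve(self, jcurve_params):
        trace = generate_tendon_trace(jcurve_params)
        cycles = segment_cycles(trace)
        (eps_r, sig_r), _ = rising_falling_split(cycles[1], trace, 0.0)
        expected = synthetic.analytic_loading_stress(eps_r, jcurve_params)
        assert np.allclose(sig_r, expected, rtol=1e-3, atol=1e-9)

    def test_apex_belongs_to_rising(self, jcurve_params):
        trace = generate_tendon_trace(jcurve_params)
        cycles = segment_cycles(trace)
        (eps_r, _), (eps_f, _) = rising_falling_split(cycles[0], trace, 0.0)
        assert eps_r[-1] == pytest.approx(jcurve_params.eps_max)
        assert eps_f[0] < jcurve_params.eps_max

    def test_offset_equal_to_loads_zeroes_stress(self):
        trace = _noise_free_trace(pretension=0.0)
        flat = TensileTrace(
            species="x", leg="L", increment_pct=10,
            time=trace.time, load=np.full(len(trace), 3.0),
            displacement=trace.displacement, L0=trace.L0, A0=trace.A0,
        )
        cycles = segment_cycles(flat)
        (_, sig_r), (_, sig_f) = rising_falling_split(cycles[1], flat, 3.0)
        assert np.allclose(sig_r, 0.0) and np.allclose(sig_f, 0.0)


class TestRegionModuli:
    def test_linear_curve_gives_constant_slope(self):
        eps = np.linspace(0.0, 0.1, 30)
        res = region_moduli(eps, 40.0 * eps)
        assert res["slopes"] == pytest.approx([40.0, 40.0, 40.0])
        assert not res["degraded"]

    def test_slopes_match_analytic_windows(self, jcurve_params):
        # Oracle: OLS (polyfit) of the closed-form curve on the identical
        # five strain values of each region window.
        trace = generate_tendon_trace(jcurve_params)
        cycles = segment_cycles(trace)
        (eps_r, sig_r), _ = rising_falling_split(cycles[1], trace, 0.0)
        res = region_moduli(eps_r, sig_r)
        for w, slope in zip(res["windows"], res["slopes"]):
            ora = np.polyfit(
                eps_r[w], synthetic.analytic_loading_stress(eps_r[w], jcurve_params), 1
            )[0]
            assert slope == pytest.approx(ora, rel=1e-6)

    def test_convex_curve_orders_regions(self, jcurve_params):
        trace = generate_tendon_trace(jcurve_params)
        cycles = segment_cycles(trace)
        (eps_r, sig_r), _ = rising_falling_split(cycles[1], trace, 0.0)
        res = region_moduli(eps_r, sig_r)
        assert res["toe"] < res["early"] < res["late"]

    def test_degraded_mode_and_errors(self):
        eps = np.linspace(0.0, 0.1, 9)
        res = region_moduli(eps, 40.0 * eps)
        assert res["degraded"]
        with pytest.raises(ValueError):
            region_moduli(np.linspace(0, 1, 5), np.linspace(0, 1, 5))

    def test_window_layout(self):
        ws = region_windows(30)
        assert [w.size for w in ws] == [5, 5, 5]
        assert all(ws[i][-1] < ws[i + 1][0] for i in range(2))
        # remainder goes to earlier regions
        ws = region_windows(31)
        assert ws[0][0] >= 0 and ws[-1][-1] < 31


class TestLoopAreas:
    def test_lossless_triangle_loop(self):
        rising = (np.array([0.0, 0.5, 1.0]), np.array([0.0, 0.5, 1.0]))
        falling = (np.array([1.0, 0.0]), np.array([1.0, 0.0]))
        up, down, r = loop_areas_resilience(rising, falling)
        assert up == pytest.approx(0.5)
        assert r == pytest.approx(1.0)

    def test_zero_falling_curve(self):
        rising = (np.array([0.0, 0.5, 1.0]), np.array([0.0, 0.5, 1.0]))
        falling = (np.array([1.0, 0.0]), np.array([0.0, 0.0]))
        assert loop_areas_resilience(rising, falling)[2] == 0.0

    def test_trapezoid_matches_closed_form(self, jcurve_params):
        trace = generate_tendon_trace(jcurve_params)
        cycles = segment_cycles(trace)
        rising, falling = rising_falling_split(cycles[1], trace, 0.0)
        closed_falling = (
            np.concatenate([rising[0][-1:], falling[0]]),
            np.concatenate([rising[1][-1:], falling[1]]),
        )
        up, down, _ = loop_areas_resilience(rising, closed_falling)
        assert up == pytest.approx(
            synthetic.analytic_loading_area(jcurve_params), rel=1e-3
        )
        assert down == pytest.approx(
            synthetic.analytic_unloading_area(jcurve_params), rel=1e-3
        )

    def test_non_positive_rising_area_rejected(self):
        rising = (np.array([0.0, 1.0]), np.array([0.0, -1.0]))
        falling = (np.array([1.0, 0.0]), np.array([0.0, 0.0]))
        with pytest.raises(ValueError):
            loop_areas_resilience(rising, falling)


class TestFullPipeline:
    def test_noise_free_resilience_recovery(self, jcurve_params):
        result = process_trace(generate_tendon_trace(jcurve_params))
        assert result.resilience == pytest.approx(0.75, abs=1e-3)

    @pytest.mark.parametrize("seed", range(5))
    def test_noisy_parameter_recovery(self, seed):
        p = TendonModelParams(
            resilience=0.75, pretension=0.5, noise_sd=0.02, seed=seed
        )
        result = process_trace(generate_tendon_trace(p))
        assert result.resilience == pytest.approx(0.75, abs=0.02)
        assert result.zero_offset == pytest.approx(0.5, abs=0.1)

    def test_toe_early_late_ordering_on_j_curves(self):
        for seed in range(5):
            p = TendonModelParams(noise_sd=0.005, seed=seed)
            table = process_trace(generate_tendon_trace(p)).cycles
            assert (table["toe_modulus"] < table["early_modulus"]).all()
            assert (table["early_modulus"] < table["late_modulus"]).all()


class TestAggregation:
    def _leg(self, species, leg, seed):
        p = TendonModelParams(noise_sd=0.005, seed=seed)
        return process_trace(generate_tendon_trace(p, species=species, leg=leg))

    def test_species_load_is_leg_mean(self):
        l1 = self._leg("sp", "L", 1)
        l2 = self._leg("sp", "R", 2)
        agg = aggregate_results([l1, l2])
        assert agg.final_load == pytest.approx((l1.final_load + l2.final_load) / 2)
        assert len(agg.cycles) == 6  # 2 legs x cycles 2-4

    def test_published_leg_averages(self):
        # Great horned owl legs measured 24.1 N (L) and 31 N (R); the
        # species value is their mean, and peak stress follows from the
        # 19.35 mm^2 junction area.
        import pandas as pd

        from raptormech.tensile import LegResult

        def leg(label, load):
            return LegResult(
                species="Bubo virginianus", leg=label, increment_pct=10,
                L0=20.25, A0=19.35, zero_offset=0.0, final_load=load,
                peak_stress=load / 19.35, peak_strain=0.1,
                cycles=pd.DataFrame(
                    {"peak_load": [load] * 3, "late_modulus": [20.0] * 3,
                     "resilience": [0.8] * 3}
                ),
                modulus=20.0, resilience=0.8,
            )

        agg = aggregate_results([leg("L", 24.1), leg("R", 31.0)])
        assert agg.final_load == pytest.approx(27.55)
        assert agg.peak_stress == pytest.approx(27.55 / 19.35)

    def test_identical_legs(self):
        l1 = self._leg("sp", "L", 7)
        l2 = self._leg("sp", "R", 7)
        agg = aggregate_results([l1, l2])
        assert agg.final_load == pytest.approx(l1.final_load)
        assert agg.modulus == pytest.approx(l1.modulus)

    def test_single_leg_flagged(self):
        agg = aggregate_results([self._leg("sp", "L", 3)])
        assert agg.single_leg

    def test_mixed_species_rejected(self):
        with pytest.raises(ValueError):
            aggregate_results([self._leg("a", "L", 1), self._leg("b", "R", 2)])


class TestTraceIO:
    def test_roundtrip(self, tmp_path, jcurve_params):
        trace = generate_tendon_trace(jcurve_params, species="sp", leg="R")
        tensile.write_trace(trace, tmp_path / "t.csv")
        back = tensile.read_trace(tmp_path / "t.csv")
        assert back.species == "sp" and back.leg == "R"
        assert np.allclose(back.load, trace.load)
        assert back.L0 == trace.L0 and back.A0 == trace.A0
        assert back.metadata["ground_truth"]["q"] == pytest.approx(
            trace.metadata["ground_truth"]["q"]
        )
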