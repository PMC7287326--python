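import numpy as np
import numpy.testing as npt
import pytest

from strainfit.strain_metrics import (FitWindow, ObjectiveWeights, extract_indices,
                                      fit_window, indices_vector, segment_area_error,
                                      total_error)
from strainfit.toy_model import ModelResult, StrainTrace

SEGS = ("RV_apex", "RV_mid", "RV_base", "IVS", "LVfw")


def trace_from_nodes(nodes_t, nodes_y, t_pvc, T, n=1001, segments=SEGS):
    """Uniformly sampled piecewise-linear strain trace, same curve in all segments."""
    t = np.linspace(0.0, T, n)
    y = np.interp(t, nodes_t, nodes_y)
    return StrainTrace(t=t, strain={s: y.copy() for s in segments},
                       t_qrs=0.0, t_pvc=t_pvc, T=T)


class TestIndices:
    def test_ramp_and_plateau_curve(self):
        # 0% falling linearly to -20% at 0.30 s, constant afterwards
        tr = trace_from_nodes([0.0, 0.30, 0.50], [0.0, -20.0, -20.0], t_pvc=0.35, T=0.50)
        ix = extract_indices(tr, "RV_mid")
        assert ix.t50 == pytest.approx(0.15)
        assert ix.t10 == pytest.approx(0.03)
        assert ix.t90 == pytest.approx(0.27)
        assert ix.peak_strain == pytest.approx(-20.0)
        assert ix.systolic_strain == pytest.approx(-20.0)
        assert ix.post_systolic_strain == pytest.approx(0.0)
        assert ix.prestretch == pytest.approx(0.0)
        assert not ix.degenerate

    def test_prestretch_bump_shifts_the_shortening_baseline(self):
        # +2% bump at 0.05 s before the fall: span is 22%, tX measured from +2%
        tr = trace_from_nodes([0.0, 0.05, 0.30, 0.50], [0.0, 2.0, -20.0, -20.0],
                              t_pvc=0.35, T=0.50, n=2001)
        ix = extract_indices(tr, "IVS")
        assert ix.prestretch == pytest.approx(2.0)
        span = ix.prestretch - ix.peak_strain
        assert span == pytest.approx(22.0)
        # first crossing of 2 - 0.1*22 = -0.2%: linear from (0.05, 2) to (0.30, -20)
        assert ix.t10 == pytest.approx(0.05 + 0.25 * 2.2 / 22.0)

    def test_flat_curve_uses_degenerate_convention(self):
        tr = trace_from_nodes([0.0, 0.5], [0.0, 0.0], t_pvc=0.3, T=0.5)
        ix = extract_indices(tr, "LVfw")
        assert ix.degenerate
        assert ix.t10 == ix.t50 == ix.t90 == 0.0
        assert ix.prestretch == 0.0 and ix.peak_strain == 0.0

    def test_index_ordering_invariants(self, demo_model, demo_space):
        rng = np.random.default_rng(8)
        for _ in range(10):
            res = demo_model.evaluate(rng.random(demo_space.D))
            if not res.ok:
                continue
            for seg in SEGS:
                ix = extract_indices(res.trace, seg)
                assert ix.t10 <= ix.t50 <= ix.t90
                assert ix.peak_strain <= ix.systolic_strain + 1e-12
                assert ix.prestretch >= 0.0
                assert ix.post_systolic_strain >= -1e-12

    def test_vector_has_all_35_outputs(self, demo_model, demo_space):
        res = demo_model.evaluate(demo_space.reference_normalized)
        assert indices_vector(res.trace).shape == (35,)


class TestFitWindow:
    def test_triangular_recovery_crosses_half_way(self):
        tr = trace_from_nodes([0.0, 0.35, 0.70], [0.0, -20.0, 0.0], t_pvc=0.4, T=0.70)
        w = fit_window(tr)
        assert w.t_start == 0.0
        assert w.t_end == pytest.approx(0.525, abs=1e-9)

    def test_global_strain_equals_each_segment_when_identical(self):
        tr = trace_from_nodes([0.0, 0.35, 0.70], [0.0, -20.0, 0.0], t_pvc=0.4, T=0.70)
        npt.assert_allclose(tr.global_rv(), tr.strain["RV_apex"])

    def test_non_recovering_curve_falls_back_to_cycle_end(self):
        tr = trace_from_nodes([0.0, 0.70], [0.0, -20.0], t_pvc=0.4, T=0.70)
        with pytest.warns(UserWarning, match="relaxation"):
            w = fit_window(tr)
        assert w.t_end == pytest.approx(0.70)

    def test_half_relaxation_is_measured_toward_end_of_cycle_value(self):
        # drifted curve ending at -4%: midpoint is (peak + end)/2 = -12%
        tr = trace_from_nodes([0.0, 0.35, 0.70], [0.0, -20.0, -4.0], t_pvc=0.4, T=0.70)
        w = fit_window(tr)
        crossing = 0.35 + 0.35 * (20.0 - 12.0) / 16.0
        assert w.t_end == pytest.approx(crossing, abs=1e-9)


class TestAreaError:
    def test_identical_curves_give_zero(self):
        t = np.linspace(0, 1, 501)
        y = -10 * np.sin(np.pi * t)
        w = FitWindow(0.0, 0.8)
        assert segment_area_error(t, y, t, y, w) == pytest.approx(0.0)

    def test_constant_offset_integrates_to_delta_squared_times_length(self):
        t = np.linspace(0, 1, 501)
        y = -10 * np.sin(np.pi * t)
        w = FitWindow(0.1, 0.5)
        err = segment_area_error(t, y + 1.0, t, y, w)
        assert err == pytest.approx(1.0 ** 2 * 0.4, rel=1e-9)

    def test_halving_the_offset_quarters_the_error(self):
        t = np.linspace(0, 1, 501)
        y = np.zeros_like(t)
        w = FitWindow(0.0, 0.4)
        e1 = segment_area_error(t, y + 1.0, t, y, w)
        e2 = segment_area_error(t, y + 0.5, t, y, w)
        assert e2 == pytest.approx(e1 / 4)

    def test_window_outside_support_raises(self):
        t = np.linspace(0, 0.5, 100)
        y = np.zeros_like(t)
        with pytest.raises(ValueError, match="support"):
            segment_area_error(t, y, t, y, FitWindow(0.0, 0.9))

    def test_refinement_invariance(self):
        w = FitWindow(0.0, 0.6)
        t1 = np.linspace(0, 1, 501)
        t2 = np.linspace(0, 1, 5001)
        f = lambda t: -15 * np.sin(np.pi * t) ** 2
        e1 = segment_area_error(t1, f(t1) + 0.7, t1, f(t1), w)
        e2 = segment_area_error(t2, f(t2) + 0.7, t2, f(t2), w)
        assert e1 == pytest.approx(e2, rel=1e-3)


class TestTotalError:
    def test_perfect_fit_scores_zero(self):
        tr = trace_from_nodes([0.0, 0.35, 0.70], [0.0, -20.0, 0.0], t_pvc=0.4, T=0.70)
        assert total_error(tr, tr) == pytest.approx(0.0)

    def test_cycle_time_mismatch_alone_scores_beta_delta_t_squared(self):
        meas = trace_from_nodes([0.0, 0.35, 0.70, 1.0], [0.0, -20.0, 0.0, 0.0],
                                t_pvc=0.4, T=1.0)
        model = trace_from_nodes([0.0, 0.35, 0.70, 2.0], [0.0, -20.0, 0.0, 0.0],
                                 t_pvc=0.4, T=2.0)
        e = total_error(model, meas, ObjectiveWeights(alpha=1.0, beta=0.1))
        assert e == pytest.approx(0.1 * 1.0 ** 2, rel=1e-9)

    def test_crashed_model_scores_infinity(self):
        meas = trace_from_nodes([0.0, 0.35, 0.70], [0.0, -20.0, 0.0], t_pvc=0.4, T=0.70)
        assert total_error(ModelResult(status="crashed"), meas) == np.inf

    def test_missing_segment_raises(self):
        meas = trace_from_nodes([0.0, 0.35, 0.70], [0.0, -20.0, 0.0], t_pvc=0.4, T=0.70)
        partial = trace_from_nodes([0.0, 0.35, 0.70], [0.0, -20.0, 0.0], t_pvc=0.4,
                                   T=0.70, segments=("RV_apex", "RV_mid"))
        with pytest.raises(ValueError, match="missing"):
            total_error(partial, meas)

    def test_positive_unless_curves_and_cycle_times_agree(self):
        meas = trace_from_nodes([0.0, 0.35, 0.70], [0.0, -20.0, 0.0], t_pvc=0.4, T=0.70)
        model = trace_from_nodes([0.0, 0.35, 0.70], [0.0, -19.0, 0.0], t_pvc=0.4, T=0.70)
        assert total_error(model, meas) > 0.0

    def test_indices_are_invariant_to_sampling_refinement(self):
        coarse = trace_from_nodes([0.0, 0.05, 0.30, 0.50], [0.0, 2.0, -20.0, -20.0],
                                  t_pvc=0.35, T=0.50, n=251)
        fine = trace_from_nodes([0.0, 0.05, 0.30, 0.50], [0.0, 2.0, -20.0, -20.0],
                                t_pvc=0.35, T=0.50, n=5001)
        a = extract_indices(coarse, "RV_apex").as_array()
        b = extract_indices(fine, "RV_apex").as_array()
        npt.assert_allclose(a, b, atol=1e-6)
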