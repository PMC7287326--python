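import numpy as np
import pandas as pd
import pytest

from strainfit.param_space import SubsetMask
from strainfit.pso import PSOConfig
from strainfit.qmc import run_qmc
from strainfit.reduction import (ReductionConfig, propose_reduction, rank_parameters,
                                 run_reduction, rv_stem_groups, validate_reduction)
from strainfit.synthetic_cohort import NoiseConfig, make_cohort


def table(entries, subjects=("s0", "s1")):
    return pd.DataFrame(entries, columns=list(subjects))


class TestRanking:
    def test_orders_ascending_by_max_diaphony(self):
        t = table({"s0": [0.1, 0.9], "s1": [0.05, 0.2]})
        t.index = ["p_low", "p_high"]
        assert rank_parameters(t, ["p_high", "p_low"]) == ["p_low", "p_high"]

    def test_max_over_subjects_governs(self):
        t = pd.DataFrame({"s0": [1.0, 0.3], "s1": [0.0, 0.3]}, index=["a", "b"])
        # a has diaphony 1 for one subject, 0 for the other: ranked by 1
        assert rank_parameters(t, ["a", "b"]) == ["b", "a"]

    def test_ties_break_by_registry_order(self):
        t = pd.DataFrame({"s0": [0.5, 0.5, 0.5]}, index=["c", "a", "b"])
        assert rank_parameters(t, ["b", "c", "a"]) == ["b", "c", "a"]

    def test_single_parameter(self):
        t = pd.DataFrame({"s0": [0.5]}, index=["only"])
        assert rank_parameters(t, ["only"]) == ["only"]

    def test_missing_entries_rejected(self):
        t = pd.DataFrame({"s0": [0.5, np.nan]}, index=["a", "b"])
        with pytest.raises(ValueError, match="missing"):
            rank_parameters(t, ["a", "b"])


class TestProposal:
    def test_zero_omission_rejected(self, demo_space):
        mask = SubsetMask.full(demo_space)
        with pytest.raises(ValueError, match="k_omit"):
            propose_reduction(mask, demo_space.names, 0)

    def test_omit_then_restore_recovers_the_original_subset(self, demo_space):
        mask = SubsetMask.full(demo_space)
        ranked = list(demo_space.names)
        smaller = propose_reduction(mask, ranked, 3)
        assert set(smaller.active) | set(ranked[:3]) == set(mask.active)
        restored = SubsetMask.from_active(demo_space, smaller.active + ranked[:3])
        assert restored.active == mask.active

    def test_omitted_parameters_fixed_at_reference(self, demo_space):
        mask = SubsetMask.full(demo_space)
        smaller = propose_reduction(mask, list(demo_space.names), 2)
        ref = demo_space.reference_normalized
        for n in demo_space.names[:2]:
            assert smaller.fixed_values[n] == pytest.approx(ref[demo_space.index(n)])

    def test_grouped_omission_is_all_or_none_across_rv_segments(self, full_space):
        mask = SubsetMask.full(full_space)
        groups = rv_stem_groups(full_space.names)
        # rank VWall of one RV segment lowest: the whole stem goes together
        ranked = ["VWall_RV_mid"] + [n for n in full_space.names if n != "VWall_RV_mid"]
        smaller = propose_reduction(mask, ranked, 1, groups=groups)
        omitted = set(mask.active) - set(smaller.active)
        assert omitted == {"VWall_RV_apex", "VWall_RV_mid", "VWall_RV_base"}


@pytest.fixture(scope="module")
def tiny_setup(demo_model):
    """Two-subject cohort and a coarse qMC sweep for fast validation tests."""
    subs = make_cohort(demo_model, 2, rng=np.random.default_rng(3))
    traces = [s.measured for s in subs]
    mask = SubsetMask.full(demo_model.space)
    qr = run_qmc(demo_model, mask, traces, n=2 ** 10, n_best=40)
    cfg = ReductionConfig(qmc_n=2 ** 10, n_best=40,
                          pso=PSOConfig(max_iter=60))
    return subs, traces, mask, qr, cfg


class TestValidation:
    def test_identity_reduction_is_accepted(self, demo_model, tiny_setup):
        subs, traces, mask, qr, cfg = tiny_setup
        accepted, before, after = validate_reduction(
            demo_model, mask, mask, traces, qr, cfg, np.random.default_rng(0))
        assert accepted
        assert np.mean(after) <= (1 + cfg.tol) * np.mean(before)

    def test_removing_a_noop_placeholder_is_accepted(self, demo_model, tiny_setup):
        subs, traces, mask, qr, cfg = tiny_setup
        accepted, before, after = validate_reduction(
            demo_model, mask, mask.without(["aux_a_RV_mid"]), traces, qr, cfg,
            np.random.default_rng(0))
        assert accepted

    def test_removing_the_structural_deficit_parameter_is_rejected(self, demo_model):
        # cohort of structural subjects only: basal/mid stiffness carries the
        # abnormality; freezing it at reference must degrade the fits
        subs = make_cohort(demo_model, 4, stage_mix={"structural": 1.0},
                           rng=np.random.default_rng(9))
        traces = [s.measured for s in subs]
        mask = SubsetMask.full(demo_model.space)
        qr = run_qmc(demo_model, mask, traces, n=2 ** 11, n_best=40)
        cfg = ReductionConfig(qmc_n=2 ** 11, n_best=40, pso=PSOConfig(max_iter=150))
        accepted, before, after = validate_reduction(
            demo_model, mask, mask.without(["k_lin_RV_mid", "k_lin_RV_base"]),
            traces, qr, cfg, np.random.default_rng(0))
        assert not accepted
        assert np.mean(after) > (1 + cfg.tol) * np.mean(before)


class TestLoop:
    def test_floor_at_initial_size_runs_zero_rounds(self, demo_model, tiny_setup):
        subs, traces, mask, qr, cfg = tiny_setup
        frozen = ReductionConfig(qmc_n=2 ** 8, n_best=20, floor=mask.d,
                                 pso=PSOConfig(max_iter=20))
        record = run_reduction(demo_model, mask, traces, frozen,
                               rng=np.random.default_rng(0))
        assert record.rounds == []
        assert record.final_active == mask.active

    def test_audit_trail_shrinks_over_accepted_rounds(self, demo_model, tiny_setup):
        subs, traces, mask, qr, cfg = tiny_setup
        quick = ReductionConfig(qmc_n=2 ** 9, n_best=30, max_rounds=3,
                                pso=PSOConfig(max_iter=40))
        record = run_reduction(demo_model, mask, traces, quick,
                               rng=np.random.default_rng(1))
        sizes = [len(mask.active)]
        for r in record.rounds:
            if r.accepted:
                assert len(r.subset_after) < sizes[-1]
                sizes.append(len(r.subset_after))
                assert set(r.subset_after) < set(r.subset_before)

    def test_accepted_rounds_respect_the_error_tolerances(self, demo_model, tiny_setup):
        subs, traces, mask, qr, cfg = tiny_setup
        quick = ReductionConfig(qmc_n=2 ** 9, n_best=30, max_rounds=3,
                                pso=PSOConfig(max_iter=40))
        record = run_reduction(demo_model, mask, traces, quick,
                               rng=np.random.default_rng(1))
        baseline = None
        for r in record.rounds:
            if baseline is None:
                baseline = np.mean(r.pso_errors_before)
            if r.accepted:
                assert np.mean(r.pso_errors_after) <= (1 + quick.tol) * np.mean(r.pso_errors_before)
                assert np.mean(r.pso_errors_after) <= (1 + quick.tol_total) * baseline

    def test_empty_subset_rejected(self, demo_model, tiny_setup):
        subs, traces, mask, qr, cfg = tiny_setup
        with pytest.raises(ValueError, match="empty"):
            run_reduction(demo_model, SubsetMask.from_active(demo_model.space, []),
                          traces, cfg, rng=np.random.default_rng(0))

    def test_record_serializes_to_json(self, demo_model, tiny_setup, tmp_path):
        subs, traces, mask, qr, cfg = tiny_setup
        quick = ReductionConfig(qmc_n=2 ** 8, n_best=20, max_rounds=1,
                                pso=PSOConfig(max_iter=20))
        record = run_reduction(demo_model, mask, traces, quick,
                               rng=np.random.default_rng(2))
        out = tmp_path / "reduction.json"
        record.to_json(out)
        import json
        payload = json.loads(out.read_text())
        assert payload["final_subset"] == record.final_active
        assert len(payload["rounds"]) == len(record.rounds)
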