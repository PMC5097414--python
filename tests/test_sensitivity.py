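"""Scenario engine: deltas, subgroups, leave-one-out, ladders."""

import numpy as np
import pytest

from harmsynth.data_model import EventDelta, ScenarioSpec, TrialSet, ValidationError
from harmsynth.pooling import pool_tables
from harmsynth.sensitivity import (
    apply_deltas,
    apply_scenario,
    ladder_frame,
    leave_one_out,
    run_ladder,
    subgroup_filter,
)
from harmsynth.simulate import SimulationConfig, gen_binary_trialset

from .conftest import make_binary_study


class TestApplyDeltas:
    def test_removal_changes_one_arm_only(self, sae_trials):
        out = apply_deltas(sae_trials, [EventDelta("S03", "treatment", -4, "cancer out")])
        assert out.get("S03").treatment_binary.events == sae_trials.get("S03").treatment_binary.events - 4
        assert out.get("S03").control_binary == sae_trials.get("S03").control_binary
        for sid in sae_trials.study_ids:
            if sid != "S03":
                assert out.get(sid) == sae_trials.get(sid)
        # original untouched
        assert sae_trials.get("S03").treatment_binary.events == 5

    def test_multi_study_additions(self, sae_trials):
        deltas = [
            EventDelta("S02", "treatment", +4, "severe knee swelling"),
            EventDelta("S04", "control", +1, "cerebral hemorrhage"),
            EventDelta("S07", "control", +1, "breast cancer"),
        ]
        out = apply_deltas(sae_trials, deltas)
        changed = {sid for sid in out.study_ids if out.get(sid) != sae_trials.get(sid)}
        assert changed == {"S02", "S04", "S07"}

    def test_empty_delta_list_is_identity(self, sae_trials):
        assert apply_deltas(sae_trials, []) == sae_trials

    def test_delta_inverse_restores_base(self, sae_trials):
        deltas = [
            EventDelta("S02", "treatment", +4, "a"),
            EventDelta("S05", "control", -2, "b"),
        ]
        out = apply_deltas(apply_deltas(sae_trials, deltas), [d.inverse() for d in deltas])
        assert out == sae_trials

    def test_out_of_range_delta_rejected(self, sae_trials):
        with pytest.raises(ValidationError, match="outside"):
            apply_deltas(sae_trials, [EventDelta("S01", "control", -5, "too many")])
        with pytest.raises(ValidationError, match="unknown study"):
            apply_deltas(sae_trials, [EventDelta("S99", "control", 1, "ghost")])


class TestSubgroupFilter:
    def test_large_blinded_threshold(self):
        ts = TrialSet(
            studies=(
                make_binary_study("big_b", 2, 150, 1, 150, blinded=True),
                make_binary_study("small_b", 1, 60, 1, 60, blinded=True),
                make_binary_study("big_open", 2, 200, 1, 200, blinded=False),
            ),
            ae_category="x",
        )
        out = subgroup_filter(ts, "large_blinded", min_total_n=200)
        assert out.study_ids == ["big_b"]

    def test_all_predicate_is_identity(self, sae_trials):
        assert subgroup_filter(sae_trials, "all") == sae_trials

    def test_empty_subgroup_errors(self, sae_trials):
        with pytest.raises(ValidationError, match="empty subgroup"):
            subgroup_filter(sae_trials, "large_blinded", min_total_n=10_000)

    def test_unknown_predicate_errors(self, sae_trials):
        with pytest.raises(ValidationError, match="unknown subgroup"):
            subgroup_filter(sae_trials, "huge_trials")


class TestLeaveOneOut:
    def test_k2_reduces_to_single_study_estimates(self):
        ts = TrialSet(
            studies=(
                make_binary_study("A", 6, 100, 3, 100),
                make_binary_study("B", 4, 120, 5, 110),
            ),
            ae_category="x",
        )
        table = leave_one_out(ts, method="dl_random")
        for _, row in table.iterrows():
            other = [s for s in ts.studies if s.study_id != row["excluded_study"]][0]
            single = pool_tables([other.table()], method="dl_random")
            assert row["estimate"] == pytest.approx(single.ratio, rel=1e-12)
            assert row["k"] == 1

    def test_weights_sum_to_one(self, sae_trials):
        table = leave_one_out(sae_trials, method="dl_random")
        assert table["weight_in_full"].sum() == pytest.approx(1.0, abs=1e-9)

    def test_needs_two_studies(self):
        ts = TrialSet(studies=(make_binary_study("A", 1, 50, 1, 50),), ae_category="x")
        with pytest.raises(ValidationError, match="at least two"):
            leave_one_out(ts)

    def test_excluding_injected_outlier_recenters_estimate(self):
        """Dropping a ratio-discrepant outlier moves the pooled RR toward truth.

        Null trial sets (true RR = 1) plus one injected study whose treated
        arm runs at three times the baseline rate: in at least 90 % of 500
        replicates the leave-one-out row for the outlier lands at least as
        close to the generating RR as the full pooling does. Uses MH
        pooling, whose weights do not dampen outliers the way DL's inflated
        tau^2 does, at a baseline risk high enough that the remaining
        studies pin the estimate.
        """
        import numpy as np

        from harmsynth.data_model import ArmSummaryBinary, StudyRecord

        p0, improved, usable = 0.08, 0, 0
        for seed in range(500):
            ts = gen_binary_trialset(
                SimulationConfig(k=6, n_range=(400, 800), p0=p0, true_rr=1.0, seed=50_000 + seed)
            )
            rng = np.random.default_rng([50_000 + seed, 99])
            n = 600
            outlier = StudyRecord(
                study_id="OUT",
                binary=(
                    ArmSummaryBinary("treatment", n, int(rng.binomial(n, 3 * p0))),
                    ArmSummaryBinary("control", n, int(rng.binomial(n, p0))),
                ),
            )
            ts = TrialSet(studies=ts.studies + (outlier,), ae_category=ts.ae_category)
            try:
                full = pool_tables(ts.tables(), method="mh", study_ids=ts.study_ids)
                table = leave_one_out(ts, method="mh")
            except ValidationError:
                continue
            usable += 1
            row = table[table["excluded_study"] == "OUT"].iloc[0]
            if abs(np.log(row["estimate"])) <= abs(np.log(full.ratio)) + 1e-12:
                improved += 1
        assert usable >= 450
        assert improved / usable >= 0.90


class TestRunLadder:
    def test_base_plus_exclusion_two_rows(self, sae_trials):
        rows = run_ladder(
            sae_trials,
            [ScenarioSpec(name="base"), ScenarioSpec(name="no_outlier", excluded_study_ids=("S05",))],
            methods=("mh",),
        )
        assert len(rows) == 2
        assert rows[0].estimate.k == 8 and rows[1].estimate.k == 7

    def test_exclusion_applies_before_deltas(self, sae_trials):
        """A delta on an excluded study is skipped, not applied."""
        sc = ScenarioSpec(
            name="combo",
            excluded_study_ids=("S05",),
            event_deltas=(
                EventDelta("S05", "treatment", +3, "ghost"),
                EventDelta("S02", "treatment", +1, "real"),
            ),
        )
        out = apply_scenario(sae_trials, sc)
        assert "S05" not in out.study_ids
        assert out.get("S02").treatment_binary.events == sae_trials.get("S02").treatment_binary.events + 1

    def test_noop_scenario_equals_direct_pooling(self, sae_trials):
        rows = run_ladder(sae_trials, [ScenarioSpec(name="noop")], methods=("dl_random", "mh", "exact_conditional"))
        for row in rows:
            direct = pool_tables(sae_trials.tables(), method=row.method, study_ids=sae_trials.study_ids)
            assert row.estimate.theta_pooled == direct.theta_pooled
            assert row.estimate.ci_low == direct.ci_low

    def test_ladder_is_deterministic(self, sae_trials, scenarios):
        a = ladder_frame(run_ladder(sae_trials, scenarios, methods=("dl_random", "mh")))
        b = ladder_frame(run_ladder(sae_trials, scenarios, methods=("dl_random", "mh")))
        assert a.equals(b)

    def test_full_scenario_ladder_shape(self, sae_trials, scenarios):
        rows = run_ladder(sae_trials, scenarios, methods=("dl_random",))
        assert len(rows) == len(scenarios)
        frame = ladder_frame(rows)
        assert set(frame["scenario"]) == {sc.name for sc in scenarios}
        assert frame["ci_defined"].all()

    def test_significance_flag_tracks_ci_boundary(self):
        """The flag flips exactly when a CI endpoint crosses the null."""
        base = [
            make_binary_study("A", 30, 200, 10, 200),
            make_binary_study("B", 28, 210, 11, 205),
        ]
        ts = TrialSet(studies=tuple(base), ae_category="x")
        est = pool_tables(ts.tables(), method="mh")
        assert est.ratio_ci[0] > 1.0 and est.significant
        # drain treated events until the lower bound crosses 1
        drained = ts
        while True:
            s = drained.get("A")
            if s.treatment_binary.events == 0:
                break
            drained = drained.replace_study(s.with_binary_events("treatment", s.treatment_binary.events - 1))
            e = pool_tables(drained.tables(), method="mh")
            assert e.significant == (e.ratio_ci[0] > 1.0 or e.ratio_ci[1] < 1.0)
            if not e.significant:
                break
        assert not pool_tables(drained.tables(), method="mh").significant
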