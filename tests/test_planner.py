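"""Candidate generation, feasibility, ranking, multi-electrode planning,
risk-stratified iteration and manual override."""

import numpy as np
import pytest

from seegplan import geometry, planner
from seegplan.metrics import RiskParams, TrajectoryEvaluator
from seegplan.planner import (
    CandidateSet,
    NoFeasibleTrajectoryError,
    Plan,
    PlanningConstraints,
    PlanningError,
    SelectedElectrode,
    generate_candidates,
    is_feasible,
    next_entry,
    next_target,
    plan_implantation,
    plan_summary,
    rank_trajectories,
    set_manual,
)
from tests.conftest import ball_model


@pytest.fixture(scope="module")
def phantom_ev(tiny_phantom):
    model, schema = tiny_phantom
    return model, schema, TrajectoryEvaluator(model)


def _composite_oracle(m, c: PlanningConstraints) -> float:
    w_r, w_g, w_l, w_a = c.ranking_weights
    return (
        w_r * m.risk / 2
        + w_g * (1 - m.gm_ratio)
        + w_l * m.length_mm / c.max_length_mm
        + w_a * m.drilling_angle_deg / c.max_angle_deg
    )


class TestGenerateCandidates:
    def test_target_count_equals_roi_voxel_count(self, phantom_ev):
        model, schema, ev = phantom_ev
        _, entry_label, target_label = schema.electrodes[0]
        cand = generate_candidates(model, entry_label, target_label, 3, 1, evaluator=ev)
        assert len(cand.target_points) == int((model.roi_labels == target_label).sum())

    def test_stride_subsample_exact_count(self, phantom_ev):
        model, schema, ev = phantom_ev
        _, entry_label, target_label = schema.electrodes[0]
        cand = generate_candidates(model, entry_label, target_label, 3, 2, evaluator=ev)
        # independent count: voxels on the even sublattice anchored at the bbox min
        idx = np.argwhere(model.roi_labels == target_label)
        anchor = idx.min(axis=0)
        expected = int(((idx - anchor) % 2 == 0).all(axis=1).sum())
        assert len(cand.target_points) == expected
        assert 0 < expected < len(idx)

    def test_entries_lie_on_scalp_surface(self, phantom_ev):
        model, schema, ev = phantom_ev
        _, entry_label, target_label = schema.electrodes[0]
        cand = generate_candidates(model, entry_label, target_label, 3, 3, evaluator=ev)
        # phantom scalp is a sphere: surface points sit at the scalp radius
        radii = np.linalg.norm(cand.entry_points, axis=1)
        assert np.allclose(radii, 28.0, atol=1.0)

    def test_missing_label_rejected(self, phantom_ev):
        model, _, ev = phantom_ev
        with pytest.raises(PlanningError, match="99"):
            generate_candidates(model, 99, 1, evaluator=ev)


class TestIsFeasible:
    def test_clean_radial_trajectory(self):
        model = ball_model()
        ok, violations = is_feasible((0, 0, 36.0), (0, 0, 5.0), model)
        assert ok and violations == []

    def test_vessel_too_close(self):
        # tube of vessel voxels 2 mm from the trajectory line
        vv = [(42, 40, z) for z in range(45, 70)]
        model = ball_model(vessel_voxels=vv)
        ok, violations = is_feasible((0.0, 0.0, 36.0), (0.0, 0.0, 2.0), model)
        assert not ok
        assert violations == ["min_vessel_distance"]

    def test_length_threshold(self):
        model = ball_model()
        c = PlanningConstraints(max_length_mm=20.0)
        ok, violations = is_feasible((0, 0, 36.0), (0, 0, 5.0), model, c)
        assert not ok and "max_length" in violations

    def test_oblique_angle_violation(self):
        model = ball_model()
        # steep tangential entry: large deviation from the surface normal
        ok, violations = is_feasible((0, 0, 36.0), (0, 25.0, 15.0), model)
        assert not ok and "max_angle" in violations

    def test_sulcal_crossing_detected_and_toggle(self):
        # 2x2 voxel column so the trajectory (between voxel centers)
        # interpolates to a full-foreground value
        sulci = [(x, y, z) for x in (39, 40) for y in (39, 40) for z in range(58, 70)]
        model = ball_model(sulci_voxels=sulci)
        ok, violations = is_feasible((0, 0, 36.0), (0, 0, 5.0), model)
        assert not ok and "sulcal_crossing" in violations
        c = PlanningConstraints(sulcal_no_entry=False)
        ok2, _ = is_feasible((0, 0, 36.0), (0, 0, 5.0), model, c)
        assert ok2

    def test_all_violations_reported(self):
        vv = [(42, 40, z) for z in range(45, 70)]
        model = ball_model(vessel_voxels=vv)
        c = PlanningConstraints(max_length_mm=20.0)
        ok, violations = is_feasible((0, 0, 36.0), (0, 0, 2.0), model, c)
        assert not ok
        assert set(violations) >= {"min_vessel_distance", "max_length"}


class TestRankTrajectories:
    def _small_candidates(self, phantom_ev, n_e=3, n_t=3):
        model, schema, ev = phantom_ev
        _, entry_label, target_label = schema.electrodes[0]
        cand = generate_candidates(model, entry_label, target_label, 3, 2, evaluator=ev)
        return CandidateSet(
            cand.entry_points[:n_e], cand.target_points[:n_t], 3, 2
        )

    def test_matches_exhaustive_oracle(self, phantom_ev):
        model, _, ev = phantom_ev
        c = PlanningConstraints()
        cand = self._small_candidates(phantom_ev)
        ranked = rank_trajectories(cand, model, c, evaluator=ev)
        # independent path: single-pair evaluation + python-side scoring
        oracle = []
        for i, e in enumerate(cand.entry_points):
            for j, t in enumerate(cand.target_points):
                ok, _ = is_feasible(e, t, model, c, evaluator=ev)
                if ok:
                    m = ev.evaluate(e, t)
                    oracle.append((_composite_oracle(m, c), i, j))
        oracle.sort()
        assert len(ranked.items) == len(oracle)
        if oracle:
            top = ranked.items[0]
            assert (top.entry_index, top.target_index) == (oracle[0][1], oracle[0][2])
            assert top.score == pytest.approx(oracle[0][0], abs=1e-9)
            scores = [it.score for it in ranked.items]
            assert scores == sorted(scores)

    def test_risk_only_weights_order_by_risk(self, phantom_ev):
        model, _, ev = phantom_ev
        c = PlanningConstraints(ranking_weights=(1.0, 0.0, 0.0, 0.0))
        cand = self._small_candidates(phantom_ev, 4, 4)
        ranked = rank_trajectories(cand, model, c, evaluator=ev)
        risks = [it.metrics.risk for it in ranked.items]
        assert risks == sorted(risks)

    def test_all_infeasible_reports_rejection_counts(self, phantom_ev):
        model, _, ev = phantom_ev
        c = PlanningConstraints(min_vessel_distance_mm=500.0)
        cand = self._small_candidates(phantom_ev)
        ranked = rank_trajectories(cand, model, c, evaluator=ev)
        assert ranked.items == []
        n_pairs = len(cand.entry_points) * len(cand.target_points)
        assert ranked.rejection_counts["min_vessel_distance"] == n_pairs

    def test_risk_map_tabulates_best_risk(self, phantom_ev):
        model, _, ev = phantom_ev
        cand = self._small_candidates(phantom_ev, 4, 4)
        ranked = rank_trajectories(cand, model, evaluator=ev)
        if ranked.items:
            best = min(it.metrics.risk for it in ranked.items)
            assert ranked.entry_risk_map["best_risk"].min() == pytest.approx(best)


class TestPlanImplantation:
    def test_single_electrode_reduces_to_rank_top(self, phantom_ev):
        from seegplan.phantom import ImplantationSchema

        model, schema, ev = phantom_ev
        single = ImplantationSchema(schema.electrodes[:1])
        plan = plan_implantation(model, single, entry_stride=3, target_stride=2)
        name, entry_label, target_label = single.electrodes[0]
        cand = generate_candidates(model, entry_label, target_label, 3, 2, evaluator=ev)
        ranked = rank_trajectories(cand, model, evaluator=ev)
        assert np.allclose(plan.electrodes[0].entry, ranked.items[0].entry)
        assert np.allclose(plan.electrodes[0].target, ranked.items[0].target)

    def test_constraints_hold_on_full_plan(self, phantom_ev):
        model, schema, ev = phantom_ev
        c = PlanningConstraints()
        plan = plan_implantation(model, schema, c, entry_stride=3, target_stride=2)
        assert [e.name for e in plan.electrodes] == [n for n, _, _ in schema]
        for e in plan.electrodes:
            assert e.provenance == "plan2"
            assert e.metrics.min_vessel_distance_mm >= c.min_vessel_distance_mm
            assert e.metrics.length_mm < c.max_length_mm
            assert e.metrics.drilling_angle_deg < c.max_angle_deg
        for i, a in enumerate(plan.electrodes):
            for b in plan.electrodes[i + 1:]:
                d = geometry.min_segment_distance((a.entry, a.target), (b.entry, b.target))
                assert d >= c.min_inter_electrode_mm

    def test_two_electrode_toy_matches_exhaustive(self, phantom_ev):
        model, schema, ev = phantom_ev
        c = PlanningConstraints()
        plan = plan_implantation(model, schema, c, entry_stride=4, target_stride=3)
        got = sum(
            _composite_oracle(e.metrics, c) for e in plan.electrodes
        )
        # exhaustive search over the same per-electrode ranked alternatives
        ranked = {}
        for name, el, tl in schema:
            cand = generate_candidates(model, el, tl, 4, 3, evaluator=ev)
            ranked[name] = rank_trajectories(cand, model, c, evaluator=ev).items
        names = [n for n, _, _ in schema]
        best = np.inf
        import itertools

        for combo in itertools.product(*(ranked[n][:40] for n in names)):
            ok = all(
                geometry.min_segment_distance(
                    (a.entry, a.target), (b.entry, b.target)
                ) >= c.min_inter_electrode_mm
                for a, b in itertools.combinations(combo, 2)
            )
            if ok:
                best = min(best, sum(it.score for it in combo))
        assert np.isfinite(best)
        # greedy with one backtracking round: feasible always, near-optimal score
        assert got <= 1.5 * best + 1e-9

    def test_forced_conflict_fails_with_diagnosis(self, phantom_ev):
        from seegplan.phantom import ImplantationSchema

        model, schema, _ = phantom_ev
        _, el, tl = schema.electrodes[0]
        clones = ImplantationSchema(tuple((f"X{i}", el, tl) for i in range(3)))
        with pytest.raises(NoFeasibleTrajectoryError) as err:
            plan_implantation(model, clones, entry_stride=3, target_stride=2)
        assert "inter_electrode_conflict" in err.value.rejection_counts

    def test_empty_schema_rejected(self, phantom_ev):
        from seegplan.phantom import ImplantationSchema

        model, _, _ = phantom_ev
        with pytest.raises(PlanningError):
            plan_implantation(model, ImplantationSchema(()))

    def test_deterministic_documents(self, phantom_ev):
        model, schema, _ = phantom_ev
        d1 = planner.plan_to_document(
            plan_implantation(model, schema, entry_stride=3, target_stride=2), model
        )
        d2 = planner.plan_to_document(
            plan_implantation(model, schema, entry_stride=3, target_stride=2), model
        )
        assert d1.model_dump_json() == d2.model_dump_json()


class TestIteration:
    @pytest.fixture()
    def single_state(self, phantom_ev):
        from seegplan.phantom import ImplantationSchema

        model, schema, _ = phantom_ev
        single = ImplantationSchema(schema.electrodes[:1])
        return plan_implantation(
            model, single, entry_stride=3, target_stride=2, return_state=True
        )

    def test_next_target_walks_same_entry_ranking(self, single_state):
        state = single_state
        name = state.order[0]
        rt = state.ranked[name]
        e0 = rt.items[state.selection[name]].entry_index
        same_entry = [k for k, it in enumerate(rt.items) if it.entry_index == e0]
        for k in range(1, min(3, len(same_entry))):
            next_target(state, name)
            assert state.selection[name] == same_entry[k]
            assert rt.items[state.selection[name]].entry_index == e0
            assert state.provenance[name] == "plan3"

    def test_next_target_wraps_with_flag(self, single_state):
        state = single_state
        name = state.order[0]
        rt = state.ranked[name]
        e0 = rt.items[state.selection[name]].entry_index
        n_same = sum(1 for it in rt.items if it.entry_index == e0)
        for _ in range(n_same):
            next_target(state, name)
        assert state.last_wrapped
        assert state.selection[name] == 0  # back at the top-ranked selection

    def test_next_entry_moves_to_next_best_entry(self, single_state):
        state = single_state
        name = state.order[0]
        rt = state.ranked[name]
        rmap = rt.entry_risk_map.sort_values(["best_risk", "index"], kind="mergesort")
        order = [int(i) for i in rmap["index"]]
        cur = rt.items[state.selection[name]].entry_index
        if len(order) > 1:
            next_entry(state, name)
            got = rt.items[state.selection[name]].entry_index
            assert got == order[(order.index(cur) + 1) % len(order)]
            assert state.provenance[name] == "plan3"


class TestManualOverride:
    def test_idempotent_override_is_plan4(self, phantom_ev):
        model, schema, _ = phantom_ev
        state = plan_implantation(model, schema, entry_stride=3, target_stride=2, return_state=True)
        name = state.order[0]
        cur = state.ranked[name].items[state.selection[name]]
        plan = set_manual(state, name, cur.entry, cur.target)
        e = plan.electrode(name)
        assert e.provenance == "plan4"
        assert e.warnings == []
        assert e.metrics.risk == pytest.approx(cur.metrics.risk, abs=1e-9)

    def test_vessel_violation_demotes_with_warning(self, phantom_ev):
        model, schema, _ = phantom_ev
        state = plan_implantation(model, schema, entry_stride=3, target_stride=2, return_state=True)
        name = state.order[0]
        # aim straight at a vessel voxel
        from seegplan.io_model import voxel_to_world

        v = np.argwhere(model.vessel_mask)[0]
        target = voxel_to_world(v, model.affine)
        entry = target / np.linalg.norm(target) * 28.0 if np.linalg.norm(target) > 1 else np.array([0, 0, 28.0])
        plan = set_manual(state, name, entry, target)
        e = plan.electrode(name)
        assert e.provenance == "manual"
        assert any("min_vessel_distance" in w for w in e.warnings)
        doc = planner.plan_to_document(state, model)
        assert doc.electrodes[[el.name for el in doc.electrodes].index(name)].warnings

    def test_spacing_violation_names_both_electrodes(self, phantom_ev):
        model, schema, _ = phantom_ev
        state = plan_implantation(model, schema, entry_stride=3, target_stride=2, return_state=True)
        a, b = state.order[0], state.order[1]
        seg_b = state._current_segment(b)
        # override a to sit 1 mm from b's trajectory
        plan = set_manual(state, a, seg_b[0] + 1.0, seg_b[1] + 1.0)
        e = plan.electrode(a)
        assert e.provenance == "manual"
        assert any(a in w and b in w for w in e.warnings)


class TestPlanSummary:
    def _electrode(self, name, risk):
        from seegplan.metrics import TrajectoryMetrics

        m = TrajectoryMetrics(
            risk=risk, min_vessel_distance_mm=5.0, gm_ratio=0.4,
            length_mm=40.0, intracerebral_length_mm=30.0, drilling_angle_deg=10.0,
        )
        return SelectedElectrode(name, np.zeros(3), np.ones(3), m)

    def test_single_electrode_summary_is_its_metrics(self):
        p = Plan([self._electrode("E1", 0.7)], PlanningConstraints())
        s = plan_summary(p)
        assert s["risk"] == pytest.approx(0.7)
        assert s["length_mm"] == pytest.approx(40.0)

    def test_mean_of_two(self):
        p = Plan(
            [self._electrode("E1", 0.4), self._electrode("E2", 0.6)],
            PlanningConstraints(),
        )
        assert plan_summary(p)["risk"] == pytest.approx(0.5)

    def test_empty_plan_rejected(self):
        with pytest.raises(ValueError):
            plan_summary(Plan([], PlanningConstraints()))

    def test_invalid_constraints_rejected(self):
        with pytest.raises(ValueError):
            PlanningConstraints(max_length_mm=-1.0)
        with pytest.raises(ValueError):
            PlanningConstraints(ranking_weights=(-1.0, 0, 0, 0))
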