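"""Computer-assisted multi-electrode trajectory planning.

Given a head model and an implantation schema (entry region, target
region per electrode), the planner generates candidate entry and
target points, filters them through hard safety constraints (minimum
vessel distance, maximum length, drilling angle from orthogonal,
sulcal no-entry), ranks survivors by a composite score dominated by
the vessel risk, and resolves inter-electrode conflicts so no two
trajectories come within the minimum spacing. The surgeon-facing
iteration ("next entry" / "next target") walks the ranked
alternatives in risk-stratified order, and manual overrides are
re-scored and flagged rather than silently accepted.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import TYPE_CHECKING

import numpy as np
import pandas as pd

from . import geometry
from .metrics import METRIC_COLUMNS, RiskParams, TrajectoryEvaluator, TrajectoryMetrics

if TYPE_CHECKING:  # pragma: no cover
    from .phantom import HeadModel, ImplantationSchema

__all__ = [
    "PlanningConstraints",
    "CandidateSet",
    "RankedTrajectories",
    "Plan",
    "PlanState",
    "PlanningError",
    "NoFeasibleTrajectoryError",
    "generate_candidates",
    "is_feasible",
    "rank_trajectories",
    "plan_implantation",
    "next_entry",
    "next_target",
    "set_manual",
    "plan_summary",
]


class PlanningError(RuntimeError):
    """Candidate generation or planning failed."""


class NoFeasibleTrajectoryError(PlanningError):
    """No trajectory satisfies the hard constraints; carries rejection counts."""

    def __init__(self, message: str, rejection_counts: dict[str, int]):
        super().__init__(f"{message}; rejections: {rejection_counts}")
        self.rejection_counts = dict(rejection_counts)


@dataclass(frozen=True)
class PlanningConstraints:
    """All hard thresholds and ranking parameters in one place.

    Defaults follow established SEEG practice: trajectories must stay
    at least 3 mm from the vessel segmentation, be shorter than 90 mm,
    pierce the skull within 30° of orthogonal, never cross a sulcal
    fold, and keep 10 mm from every other electrode. The ranking
    weights are risk-dominant with secondary preference for gray-matter
    sampling, then length and angle.
    """

    min_vessel_distance_mm: float = 3.0
    max_length_mm: float = 90.0
    max_angle_deg: float = 30.0
    min_inter_electrode_mm: float = 10.0
    sulcal_no_entry: bool = True
    risk_params: RiskParams = field(default_factory=RiskParams)
    ranking_weights: tuple[float, float, float, float] = (1.0, 0.5, 0.25, 0.25)

    def __post_init__(self):
        for name in ("min_vessel_distance_mm", "max_length_mm", "max_angle_deg",
                     "min_inter_electrode_mm"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be > 0")
        if any(w < 0 for w in self.ranking_weights):
            raise ValueError("ranking weights must be non-negative")

    def as_dict(self) -> dict:
        return {
            "min_vessel_distance_mm": self.min_vessel_distance_mm,
            "max_length_mm": self.max_length_mm,
            "max_angle_deg": self.max_angle_deg,
            "min_inter_electrode_mm": self.min_inter_electrode_mm,
            "sulcal_no_entry": self.sulcal_no_entry,
            "risk_params": {
                "n_nodes": self.risk_params.n_nodes,
                "d_safe": self.risk_params.d_safe,
                "d_max": self.risk_params.d_max,
                "branch": self.risk_params.branch,
                "node_span": self.risk_params.node_span,
            },
            "ranking_weights": list(self.ranking_weights),
        }


@dataclass
class CandidateSet:
    """Candidate entry/target world points for one electrode.

    Entry points are scalp-surface projections of the entry region's
    voxels; target points are target-ROI voxel centers. Both are
    subsampled by a deterministic per-axis stride and kept in
    lexicographic voxel order.
    """

    entry_points: np.ndarray  # (E, 3) world mm, on the scalp surface
    target_points: np.ndarray  # (T, 3) world mm
    entry_stride: int
    target_stride: int


@dataclass
class RankedTrajectory:
    entry: np.ndarray
    target: np.ndarray
    metrics: TrajectoryMetrics
    score: float
    entry_index: int
    target_index: int


@dataclass
class RankedTrajectories:
    """Feasible trajectories ordered by composite score (ascending).

    ``entry_risk_map`` / ``target_risk_map`` tabulate, per candidate
    entry (target), the best achievable risk and score — the "risk
    map" a surgeon iterates through.
    """

    items: list[RankedTrajectory]
    rejection_counts: dict[str, int]
    entry_risk_map: pd.DataFrame
    target_risk_map: pd.DataFrame
    n_evaluated: int = 0


@dataclass
class SelectedElectrode:
    name: str
    entry: np.ndarray
    target: np.ndarray
    metrics: TrajectoryMetrics
    provenance: str = "plan2"  # plan2 | plan3 | plan4 | manual
    warnings: list[str] = field(default_factory=list)


@dataclass
class Plan:
    """A set of mutually conflict-free trajectories with summaries."""

    electrodes: list[SelectedElectrode]
    constraints: PlanningConstraints

    def electrode(self, name: str) -> SelectedElectrode:
        for e in self.electrodes:
            if e.name == name:
                return e
        raise KeyError(f"no electrode named {name!r} in plan")

    @property
    def summary(self) -> dict[str, float]:
        return plan_summary(self)


def plan_summary(plan: Plan) -> dict[str, float]:
    """Arithmetic mean of each trajectory metric over the plan's electrodes."""
    if not plan.electrodes:
        raise ValueError("cannot summarize an empty plan")
    keys = list(METRIC_COLUMNS)
    return {
        k: float(np.mean([getattr(e.metrics, k) for e in plan.electrodes])) for k in keys
    }


# ---------------------------------------------------------------------------
# candidate generation

def _strided_voxels(label_volume: np.ndarray, label: int, stride: int) -> np.ndarray:
    """Lexicographically ordered voxel indices of a label, per-axis strided.

    Strides are anchored at the region's bounding-box minimum so the
    subsample is stable under translation of the region.
    """
    idx = np.argwhere(label_volume == label)
    if len(idx) == 0:
        raise PlanningError(f"region label {label} is empty in roi_labels")
    if stride > 1:
        anchor = idx.min(axis=0)
        keep = ((idx - anchor) % stride == 0).all(axis=1)
        idx = idx[keep]
    return idx


def _project_to_scalp(evaluator: TrajectoryEvaluator, points: np.ndarray) -> np.ndarray:
    """Project interior points outward along the local normal onto the scalp.

    The outward direction is the gradient of the smoothed scalp signed
    distance (uphill = toward and beyond the surface); the crossing of
    the unsmoothed signed distance is then bracketed and bisected.
    Points whose ray never crosses the surface are dropped.
    """
    model = evaluator.model
    sdf = evaluator._scalp_sdf
    out = []
    for p in points:
        try:
            d = evaluator.scalp_normal(p)
        except geometry.SurfaceNormalError:
            continue
        ts = np.arange(0.0, 120.0, 2.0)
        vals = geometry.interpolate_volume(sdf, model.affine, p[None, :] + ts[:, None] * d)
        sign = vals > 0
        if not sign.any():
            continue
        k = int(np.argmax(sign))
        lo = ts[k - 1] if k > 0 else 0.0
        hi = ts[k]
        for _ in range(40):
            mid = 0.5 * (lo + hi)
            v = geometry.interpolate_volume(sdf, model.affine, p + mid * d)[0]
            if v > 0:
                hi = mid
            else:
                lo = mid
        out.append(p + 0.5 * (lo + hi) * d)
    return np.asarray(out, dtype=float).reshape(-1, 3)


def generate_candidates(
    model: "HeadModel",
    entry_label: int,
    target_label: int,
    entry_stride: int = 2,
    target_stride: int = 2,
    evaluator: TrajectoryEvaluator | None = None,
) -> CandidateSet:
    """Enumerate candidate entry and target points for one electrode.

    Target candidates are the centers of the target ROI's voxels;
    entry candidates are the entry region's voxels projected outward
    onto the scalp surface along the local surface normal.
    """
    if evaluator is None:
        evaluator = TrajectoryEvaluator(model)
    from .io_model import voxel_to_world  # local import keeps module layering clean

    tgt_idx = _strided_voxels(model.roi_labels, target_label, target_stride)
    targets = np.array([voxel_to_world(i, model.affine) for i in tgt_idx])
    ent_idx = _strided_voxels(model.roi_labels, entry_label, entry_stride)
    seeds = np.array([voxel_to_world(i, model.affine) for i in ent_idx])
    entries = _project_to_scalp(evaluator, seeds)
    if len(entries) == 0:
        raise PlanningError(f"entry region {entry_label}: no point projects onto the scalp")
    return CandidateSet(entries, targets, entry_stride, target_stride)


# ---------------------------------------------------------------------------
# feasibility

CONSTRAINT_NAMES = ("min_vessel_distance", "max_length", "max_angle", "sulcal_crossing")


def _feasibility_matrix(
    evaluator: TrajectoryEvaluator,
    entries: np.ndarray,
    targets: np.ndarray,
    constraints: PlanningConstraints,
) -> tuple[dict[str, np.ndarray], np.ndarray, dict[str, int], dict[str, np.ndarray]]:
    """Vectorized metrics + constraint verdicts for paired trajectories."""
    model = evaluator.model
    m = evaluator.metrics_many(entries, targets)
    ok = np.ones(len(entries), dtype=bool)
    counts: dict[str, int] = {k: 0 for k in CONSTRAINT_NAMES}
    viol = {}
    viol["min_vessel_distance"] = m["min_vessel_distance_mm"] < constraints.min_vessel_distance_mm
    viol["max_length"] = ~(m["length_mm"] < constraints.max_length_mm)
    viol["max_angle"] = ~(m["drilling_angle_deg"] < constraints.max_angle_deg)
    if constraints.sulcal_no_entry and (model.sulci_mask > 0).any():
        n = evaluator.params.n_nodes
        t = np.linspace(0.0, 1.0, n)[None, :, None]
        nodes = entries[:, None, :] * (1 - t) + targets[:, None, :] * t
        vals = geometry.interpolate_volume(
            model.sulci_mask > 0, model.affine, nodes.reshape(-1, 3)
        ).reshape(len(entries), n)
        viol["sulcal_crossing"] = (vals > 0.5).any(axis=1)
    else:
        viol["sulcal_crossing"] = np.zeros(len(entries), dtype=bool)
    # NaN angle or extracerebral target can never be accepted
    bad = ~np.isfinite(m["drilling_angle_deg"]) | ~np.isfinite(m["intracerebral_length_mm"])
    viol["max_angle"] |= bad
    for k in CONSTRAINT_NAMES:
        counts[k] = int(viol[k].sum())
        ok &= ~viol[k]
    return m, ok, counts, viol


def is_feasible(
    entry,
    target,
    model: "HeadModel",
    constraints: PlanningConstraints = PlanningConstraints(),
    evaluator: TrajectoryEvaluator | None = None,
) -> tuple[bool, list[str]]:
    """Check one trajectory against all hard constraints.

    Returns (feasible, violated-constraint names); every violated
    constraint is reported, not just the first. Checks, in order:
    minimum vessel distance, maximum length, drilling angle, sulcal
    crossing (when enabled).
    """
    if evaluator is None:
        evaluator = TrajectoryEvaluator(model, constraints.risk_params)
    e = np.asarray(entry, float)[None, :]
    t = np.asarray(target, float)[None, :]
    _, ok, _, viol = _feasibility_matrix(evaluator, e, t, constraints)
    violations = [k for k in CONSTRAINT_NAMES if viol[k][0]]
    return bool(ok[0]), violations


# ---------------------------------------------------------------------------
# ranking

def composite_score(m: dict[str, np.ndarray], constraints: PlanningConstraints) -> np.ndarray:
    """Risk-dominant weighted score, lower is better.

    score = w_r·R/2 + w_g·(1−GM ratio) + w_l·(length/max_length)
          + w_a·(angle/max_angle); each term is normalized to [0, 1]
    for feasible trajectories.
    """
    w_r, w_g, w_l, w_a = constraints.ranking_weights
    return (
        w_r * m["risk"] / 2.0
        + w_g * (1.0 - m["gm_ratio"])
        + w_l * m["length_mm"] / constraints.max_length_mm
        + w_a * m["drilling_angle_deg"] / constraints.max_angle_deg
    )


def rank_trajectories(
    candidates: CandidateSet,
    model: "HeadModel",
    constraints: PlanningConstraints = PlanningConstraints(),
    evaluator: TrajectoryEvaluator | None = None,
) -> RankedTrajectories:
    """Evaluate all (entry, target) pairs and rank the feasible ones.

    Infeasible pairs are tallied per violated constraint. Ties in the
    composite score break on (risk, −GM ratio, length, angle,
    candidate order), making the ordering fully deterministic.
    """
    if evaluator is None:
        evaluator = TrajectoryEvaluator(model, constraints.risk_params)
    E, T = len(candidates.entry_points), len(candidates.target_points)
    if E == 0 or T == 0:
        raise PlanningError("empty candidate set")
    ei, ti = np.meshgrid(np.arange(E), np.arange(T), indexing="ij")
    ei, ti = ei.ravel(), ti.ravel()
    entries = candidates.entry_points[ei]
    targets = candidates.target_points[ti]
    m, ok, counts, _ = _feasibility_matrix(evaluator, entries, targets, constraints)

    scores = composite_score(m, constraints)
    order = np.lexsort(
        (ti, ei, m["drilling_angle_deg"], m["length_mm"], -m["gm_ratio"], m["risk"], scores)
    )
    order = order[ok[order]]
    items = [
        RankedTrajectory(
            entry=entries[k].copy(),
            target=targets[k].copy(),
            metrics=TrajectoryMetrics(
                **{f: float(m[f][k]) for f in METRIC_COLUMNS}
            ),
            score=float(scores[k]),
            entry_index=int(ei[k]),
            target_index=int(ti[k]),
        )
        for k in order
    ]

    def _risk_map(indices: np.ndarray, n: int) -> pd.DataFrame:
        rows = []
        for idx in range(n):
            sel = ok & (indices == idx)
            if sel.any():
                rows.append({
                    "index": idx,
                    "best_risk": float(m["risk"][sel].min()),
                    "best_score": float(scores[sel].min()),
                    "n_feasible": int(sel.sum()),
                })
        return pd.DataFrame(rows, columns=["index", "best_risk", "best_score", "n_feasible"])

    return RankedTrajectories(
        items=items,
        rejection_counts=counts,
        entry_risk_map=_risk_map(ei, E),
        target_risk_map=_risk_map(ti, T),
        n_evaluated=E * T,
    )


# ---------------------------------------------------------------------------
# multi-electrode planning

def _segments_conflict(a, b, min_mm: float) -> bool:
    return geometry.min_segment_distance(a, b) < min_mm


def _compatible(item: RankedTrajectory, chosen: list[tuple[np.ndarray, np.ndarray]], min_mm: float) -> bool:
    seg = (item.entry, item.target)
    return all(not _segments_conflict(seg, other, min_mm) for other in chosen)


class PlanState:
    """Mutable planning state supporting risk-stratified iteration.

    Holds the per-electrode ranked alternatives and the current
    selection; ``next_target`` / ``next_entry`` advance a single
    electrode through the ranked list the way the planning UI's
    buttons do, skipping alternatives that would violate the
    inter-electrode spacing against the other current selections.
    ``last_wrapped`` is set when an advance cycled past the end of the
    available alternatives.
    """

    def __init__(
        self,
        model: "HeadModel",
        constraints: PlanningConstraints,
        ranked: dict[str, RankedTrajectories],
        selection: dict[str, int],
        order: list[str],
        evaluator: TrajectoryEvaluator,
    ):
        self.model = model
        self.constraints = constraints
        self.ranked = ranked
        self.selection = selection  # electrode name -> index into ranked.items
        self.order = order  # schema order
        self.evaluator = evaluator
        self.provenance: dict[str, str] = {n: "plan2" for n in order}
        self.warnings: dict[str, list[str]] = {n: [] for n in order}
        self.manual: dict[str, tuple[np.ndarray, np.ndarray, TrajectoryMetrics]] = {}
        self.last_wrapped = False

    def _current_segment(self, name: str) -> tuple[np.ndarray, np.ndarray]:
        if name in self.manual:
            e, t, _ = self.manual[name]
            return e, t
        item = self.ranked[name].items[self.selection[name]]
        return item.entry, item.target

    def _other_segments(self, name: str) -> list[tuple[np.ndarray, np.ndarray]]:
        return [self._current_segment(n) for n in self.order if n != name]

    @property
    def plan(self) -> Plan:
        electrodes = []
        for n in self.order:
            if n in self.manual:
                e, t, met = self.manual[n]
                electrodes.append(SelectedElectrode(
                    n, e, t, met, self.provenance[n], list(self.warnings[n])
                ))
            else:
                item = self.ranked[n].items[self.selection[n]]
                electrodes.append(SelectedElectrode(
                    n, item.entry, item.target, item.metrics,
                    self.provenance[n], list(self.warnings[n]),
                ))
        return Plan(electrodes, self.constraints)


def plan_implantation(
    model: "HeadModel",
    schema: "ImplantationSchema",
    constraints: PlanningConstraints = PlanningConstraints(),
    entry_stride: int = 2,
    target_stride: int = 2,
    return_state: bool = False,
):
    """Plan all schema electrodes jointly; returns the automated plan.

    Electrodes are placed sequentially, most-constrained first (fewest
    feasible candidates); after each selection the remaining
    electrodes may not come within the inter-electrode minimum of it.
    If a later electrode becomes unplannable, one round of
    backtracking re-selects an earlier electrode's alternative. The
    result is deterministic for fixed inputs.
    """
    if len(schema) == 0:
        raise PlanningError("empty implantation schema")
    evaluator = TrajectoryEvaluator(model, constraints.risk_params)
    ranked: dict[str, RankedTrajectories] = {}
    for name, entry_label, target_label in schema:
        cand = generate_candidates(
            model, entry_label, target_label, entry_stride, target_stride, evaluator
        )
        rt = rank_trajectories(cand, model, constraints, evaluator)
        if not rt.items:
            raise NoFeasibleTrajectoryError(
                f"electrode {name}: no feasible trajectory", rt.rejection_counts
            )
        ranked[name] = rt

    schema_order = [n for n, _, _ in schema]
    order_by_freedom = sorted(schema_order, key=lambda n: (len(ranked[n].items), schema_order.index(n)))

    min_mm = constraints.min_inter_electrode_mm
    selection: dict[str, int] = {}
    placed: list[str] = []

    def _pick(name: str, start: int, chosen_segs) -> int | None:
        for j in range(start, len(ranked[name].items)):
            if _compatible(ranked[name].items[j], chosen_segs, min_mm):
                return j
        return None

    for name in order_by_freedom:
        segs = [( ranked[n].items[selection[n]].entry, ranked[n].items[selection[n]].target) for n in placed]
        j = _pick(name, 0, segs)
        if j is None:
            # one round of backtracking: advance one earlier electrode
            resolved = False
            for prev in reversed(placed):
                others = [
                    (ranked[n].items[selection[n]].entry, ranked[n].items[selection[n]].target)
                    for n in placed if n != prev
                ]
                for alt in range(selection[prev] + 1, len(ranked[prev].items)):
                    if not _compatible(ranked[prev].items[alt], others, min_mm):
                        continue
                    trial = others + [
                        (ranked[prev].items[alt].entry, ranked[prev].items[alt].target)
                    ]
                    j2 = _pick(name, 0, trial)
                    if j2 is not None:
                        selection[prev] = alt
                        j = j2
                        resolved = True
                        break
                if resolved:
                    break
            if not resolved:
                raise NoFeasibleTrajectoryError(
                    f"electrode {name}: all {len(ranked[name].items)} feasible "
                    f"trajectories conflict with already-placed electrodes "
                    f"({', '.join(placed)}) at < {min_mm} mm",
                    {**ranked[name].rejection_counts, "inter_electrode_conflict": len(ranked[name].items)},
                )
        selection[name] = j
        placed.append(name)

    state = PlanState(model, constraints, ranked, selection, schema_order, evaluator)
    return state if return_state else state.plan


def next_target(state: PlanState, electrode: str) -> Plan:
    """Advance to the next-ranked feasible trajectory with the same entry.

    Alternatives conflicting with the other electrodes' current
    selections are skipped; cycling past the last alternative wraps to
    the first and sets ``state.last_wrapped``.
    """
    state.last_wrapped = False
    rt = state.ranked[electrode]
    cur = rt.items[state.selection[electrode]]
    same_entry = [k for k, it in enumerate(rt.items) if it.entry_index == cur.entry_index]
    pos = same_entry.index(state.selection[electrode])
    others = state._other_segments(electrode)
    for step in range(1, len(same_entry) + 1):
        k = same_entry[(pos + step) % len(same_entry)]
        if pos + step >= len(same_entry):
            state.last_wrapped = True
        if _compatible(rt.items[k], others, state.constraints.min_inter_electrode_mm):
            state.selection[electrode] = k
            state.manual.pop(electrode, None)
            state.provenance[electrode] = "plan3"
            state.warnings[electrode] = []
            return state.plan
    state.last_wrapped = True
    return state.plan


def next_entry(state: PlanState, electrode: str) -> Plan:
    """Jump to the best trajectory from the next-best entry point.

    Entry points are ordered by the entry risk map (best achievable
    risk ascending, candidate order on ties); the selection moves to
    the best-ranked compatible trajectory from the next entry in that
    order, wrapping with ``state.last_wrapped`` set.
    """
    state.last_wrapped = False
    rt = state.ranked[electrode]
    rmap = rt.entry_risk_map.sort_values(
        ["best_risk", "index"], kind="mergesort"
    ).reset_index(drop=True)
    entry_order = [int(i) for i in rmap["index"]]
    cur = rt.items[state.selection[electrode]]
    pos = entry_order.index(cur.entry_index)
    others = state._other_segments(electrode)
    for step in range(1, len(entry_order) + 1):
        eidx = entry_order[(pos + step) % len(entry_order)]
        if pos + step >= len(entry_order):
            state.last_wrapped = True
        for k, it in enumerate(rt.items):
            if it.entry_index != eidx:
                continue
            if _compatible(it, others, state.constraints.min_inter_electrode_mm):
                state.selection[electrode] = k
                state.manual.pop(electrode, None)
                state.provenance[electrode] = "plan3"
                state.warnings[electrode] = []
                return state.plan
    state.last_wrapped = True
    return state.plan


def set_manual(state: PlanState, electrode: str, entry, target) -> Plan:
    """Override one electrode with surgeon-specified endpoints.

    Metrics are recomputed from the model. If the override passes all
    hard constraints and spacing it is recorded as the precise
    adjustment (plan4); any violation demotes it to manual-with-warning
    — the violations (naming conflicting electrodes for spacing
    breaches) stay attached to the electrode, never silently dropped.
    """
    entry = np.asarray(entry, float)
    target = np.asarray(target, float)
    met = state.evaluator.evaluate(entry, target)
    ok, violations = is_feasible(entry, target, state.model, state.constraints, state.evaluator)
    warn = [f"violates {v}" for v in violations]
    for other in state.order:
        if other == electrode:
            continue
        seg = state._current_segment(other)
        d = geometry.min_segment_distance((entry, target), seg)
        if d < state.constraints.min_inter_electrode_mm:
            warn.append(
                f"electrodes {electrode} and {other} are {d:.1f} mm apart "
                f"(< {state.constraints.min_inter_electrode_mm} mm)"
            )
    state.manual[electrode] = (entry, target, met)
    state.provenance[electrode] = "plan4" if not warn else "manual"
    state.warnings[electrode] = warn
    return state.plan


def plan_to_document(state_or_plan, model: "HeadModel", provenance_info: dict | None = None):
    """Freeze a plan into a serializable, fingerprinted PlanDocument."""
    from .io_model import PlanDocument, PlannedElectrode, WorldPoint, model_fingerprint

    plan = state_or_plan.plan if isinstance(state_or_plan, PlanState) else state_or_plan
    return PlanDocument(
        electrodes=[
            PlannedElectrode(
                name=e.name,
                entry=WorldPoint.of(e.entry),
                target=WorldPoint.of(e.target),
                metrics={k: float(v) for k, v in e.metrics.as_dict().items()},
                provenance=e.provenance,
                warnings=list(e.warnings),
            )
            for e in plan.electrodes
        ],
        plan_summary=plan.summary,
        constraints=plan.constraints.as_dict(),
        model_fingerprint=model_fingerprint(model),
        provenance_info=provenance_info or {},
    )
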