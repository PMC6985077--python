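"""Synthetic head phantoms for desk-scale SEEG planning.

Real planning inputs are patient-specific: co-registered binary masks
for scalp, brain, gray matter and sulci, a vessel segmentation from
catheter angiography, and a parcellation supplying entry and target
regions. No such data can ship with a library, so this module grows a
deterministic geometric stand-in with the same structure: a spherical
head, a brain with a cortical gray-matter ribbon and radial sulcal
folds, an intracerebral branching vessel tree rasterized as tubes, and
labeled target ROIs paired with gyral entry patches projected to the
scalp. Same seed and config always produce bit-identical volumes.

The phantom is deliberately simple geometry, not anatomy: it gives
every downstream module (distance fields, risk scoring, constraint
filtering, multi-electrode planning) a world in which the planner's
assumptions hold and answers can be checked against closed forms.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterator

import numpy as np
import pandas as pd
from scipy import ndimage

from . import geometry

__all__ = [
    "PhantomConfig",
    "HeadModel",
    "ImplantationSchema",
    "make_phantom",
    "phantom_report",
    "PhantomError",
]

ENTRY_LABEL_OFFSET = 100  # entry-region labels = target label + offset


class PhantomError(RuntimeError):
    """Unsatisfiable phantom configuration or exhausted placement retries."""


@dataclass(frozen=True)
class PhantomConfig:
    """Geometry and randomness knobs of the synthetic head.

    All lengths in mm. Defaults give a 160 mm cube at 1 mm isotropic
    spacing holding a 75 mm-radius head with a 65 mm brain, a 3 mm
    cortical GM ribbon, six 2 mm-wide sulcal folds reaching 10 mm deep,
    two branching vessel trees of 1.5 mm-radius tubes, and four 6 mm
    spherical target ROIs.
    """

    seed: int = 0
    voxel_spacing_mm: tuple[float, float, float] = (1.0, 1.0, 1.0)
    grid_shape: tuple[int, int, int] = (160, 160, 160)
    scalp_radius_mm: float = 75.0
    brain_radius_mm: float = 65.0
    gm_thickness_mm: float = 3.0
    n_sulci: int = 6
    sulcus_depth_mm: float = 10.0
    sulcus_width_mm: float = 2.0
    n_vessel_trees: int = 2
    vessel_radius_mm: float = 1.5
    vessel_branching_prob: float = 0.08
    n_target_rois: int = 4
    roi_radius_mm: float = 6.0

    def __post_init__(self):
        lengths = {
            "scalp_radius_mm": self.scalp_radius_mm,
            "brain_radius_mm": self.brain_radius_mm,
            "gm_thickness_mm": self.gm_thickness_mm,
            "vessel_radius_mm": self.vessel_radius_mm,
            "roi_radius_mm": self.roi_radius_mm,
        }
        for name, v in lengths.items():
            if v <= 0:
                raise PhantomError(f"{name} must be > 0, got {v}")
        if self.brain_radius_mm >= self.scalp_radius_mm:
            raise PhantomError("brain_radius_mm must be smaller than scalp_radius_mm")
        if self.roi_radius_mm >= self.brain_radius_mm:
            raise PhantomError("roi_radius_mm must be smaller than brain_radius_mm")
        half_extent = min(
            s * sp / 2 for s, sp in zip(self.grid_shape, self.voxel_spacing_mm)
        )
        if self.scalp_radius_mm >= half_extent:
            raise PhantomError(
                f"scalp radius {self.scalp_radius_mm} mm does not fit in the "
                f"grid (half extent {half_extent:.1f} mm)"
            )


@dataclass(eq=False)
class HeadModel:
    """Co-registered voxel masks, ROI labels and affine: the planner's world.

    All volumes share one grid and one voxel-to-world affine (mm,
    voxel-center convention). ``roi_labels`` holds both target ROIs and
    entry regions; ``region_names`` maps each label to a name.
    """

    scalp_mask: np.ndarray
    brain_mask: np.ndarray
    gm_mask: np.ndarray
    sulci_mask: np.ndarray
    vessel_mask: np.ndarray
    roi_labels: np.ndarray
    affine: np.ndarray
    region_names: dict[int, str] = field(default_factory=dict)

    @property
    def shape(self) -> tuple[int, ...]:
        return self.scalp_mask.shape

    @property
    def voxel_spacing(self) -> np.ndarray:
        return np.sqrt((self.affine[:3, :3] ** 2).sum(axis=0))

    def validate(self) -> None:
        """Assert the containment invariants voxelwise."""
        vols = {
            "brain": self.brain_mask, "gm": self.gm_mask,
            "sulci": self.sulci_mask, "vessels": self.vessel_mask,
            "rois": self.roi_labels,
        }
        for name, v in vols.items():
            if v.shape != self.scalp_mask.shape:
                raise ValueError(f"{name} volume shape {v.shape} != grid {self.scalp_mask.shape}")
        if ((self.gm_mask > 0) & ~(self.brain_mask > 0)).any():
            raise ValueError("gm_mask must be contained in brain_mask")
        if ((self.sulci_mask > 0) & ~(self.brain_mask > 0)).any():
            raise ValueError("sulci_mask must be contained in brain_mask")
        if ((self.brain_mask > 0) & ~(self.scalp_mask > 0)).any():
            raise ValueError("brain_mask must be contained in scalp_mask")
        if ((self.vessel_mask > 0) & ~(self.scalp_mask > 0)).any():
            raise ValueError("vessel_mask must be contained in scalp_mask")


@dataclass(frozen=True)
class ImplantationSchema:
    """Ordered electrode list: (name, entry-region label, target-region label)."""

    electrodes: tuple[tuple[str, int, int], ...]

    def __iter__(self) -> Iterator[tuple[str, int, int]]:
        return iter(self.electrodes)

    def __len__(self) -> int:
        return len(self.electrodes)

    def validate_against(self, model: HeadModel) -> None:
        names = [e[0] for e in self.electrodes]
        if len(set(names)) != len(names):
            raise ValueError(f"electrode names not unique: {names}")
        present = set(np.unique(model.roi_labels)) - {0}
        for name, entry, target in self.electrodes:
            for lbl in (entry, target):
                if lbl not in present:
                    raise ValueError(f"electrode {name}: label {lbl} absent from roi_labels")


def _radius_volume(shape, spacing) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """World coordinates (grid centered on world origin) and radius volume."""
    spacing = np.asarray(spacing, float)
    shape = np.asarray(shape)
    # voxel-center convention: world origin at grid center
    origin = -(shape - 1) * spacing / 2.0
    axes = [origin[d] + spacing[d] * np.arange(shape[d]) for d in range(3)]
    X, Y, Z = np.meshgrid(*axes, indexing="ij")
    R = np.sqrt(X**2 + Y**2 + Z**2)
    affine = np.eye(4)
    affine[:3, :3] = np.diag(spacing)
    affine[:3, 3] = origin
    return (X, Y, Z), R, affine


def _random_unit(rng: np.random.Generator, n: int = 1) -> np.ndarray:
    v = rng.normal(size=(n, 3))
    return v / np.linalg.norm(v, axis=1, keepdims=True)


def _grow_vessel_trees(cfg: PhantomConfig, rng: np.random.Generator) -> list[tuple[np.ndarray, np.ndarray]]:
    """Seeded branching random walk; returns line segments (start, end) in mm.

    Each tree starts at mid-depth inside the brain and takes 2 mm steps
    whose direction diffuses slowly; at each step the walker spawns a
    branch with probability ``vessel_branching_prob``. Walkers stop at
    the brain surface or after a step budget.
    """
    step = 2.0
    max_steps = 80
    max_walkers = 40
    segments: list[tuple[np.ndarray, np.ndarray]] = []
    limit = cfg.brain_radius_mm - cfg.vessel_radius_mm - 0.5
    for _ in range(cfg.n_vessel_trees):
        start = _random_unit(rng)[0] * 0.5 * cfg.brain_radius_mm
        walkers = [(start, _random_unit(rng)[0])]
        spawned = 1
        steps = 0
        while walkers and steps < max_steps:
            steps += 1
            nxt = []
            for pos, drn in walkers:
                drn = drn + 0.35 * rng.normal(size=3)
                drn /= np.linalg.norm(drn)
                new = pos + step * drn
                if np.linalg.norm(new) > limit:
                    continue
                segments.append((pos, new))
                nxt.append((new, drn))
                if spawned < max_walkers and rng.random() < cfg.vessel_branching_prob:
                    bd = drn + rng.normal(size=3)
                    bd /= np.linalg.norm(bd)
                    nxt.append((new, bd))
                    spawned += 1
            walkers = nxt
    return segments


def _rasterize_tubes(segments, radius_mm, shape, affine) -> np.ndarray:
    """Mark voxels within ``radius_mm`` of any centerline segment."""
    if not segments:
        return np.zeros(shape, dtype=bool)
    spacing = np.sqrt((affine[:3, :3] ** 2).sum(axis=0))
    pts = []
    for a, b in segments:
        n = max(2, int(np.ceil(np.linalg.norm(b - a) / (0.5 * spacing.min()))) + 1)
        t = np.linspace(0, 1, n)[:, None]
        pts.append(a[None, :] * (1 - t) + b[None, :] * t)
    pts = np.vstack(pts)
    vox = np.rint(geometry.world_to_voxel_coords(pts, affine)).astype(int)
    vox = vox[((vox >= 0) & (vox < np.asarray(shape))).all(axis=1)]
    center = np.zeros(shape, dtype=bool)
    center[tuple(vox.T)] = True
    dist = ndimage.distance_transform_edt(~center, sampling=spacing)
    return dist <= radius_mm


def _place_rois(cfg: PhantomConfig, rng: np.random.Generator, existing: list[np.ndarray]) -> np.ndarray:
    """Draw one ROI center inside the brain, far from previously placed ones."""
    lo = 0.25 * cfg.brain_radius_mm
    hi = cfg.brain_radius_mm - cfg.roi_radius_mm - cfg.gm_thickness_mm - 2.0
    # keep ROIs well apart (scaled to head size) so the 10 mm
    # inter-electrode spacing is attainable
    min_sep = max(2 * cfg.roi_radius_mm + 4.0, 0.37 * cfg.brain_radius_mm)
    for _ in range(200):
        r = rng.uniform(lo, min(hi, 0.62 * cfg.brain_radius_mm))
        c = _random_unit(rng)[0] * r
        if all(np.linalg.norm(c - e) >= min_sep for e in existing):
            return c
    raise PhantomError(
        f"could not place {cfg.n_target_rois} ROIs of radius {cfg.roi_radius_mm} mm "
        f"with pairwise separation {min_sep:.0f} mm inside the brain"
    )


def make_phantom(config: PhantomConfig) -> tuple[HeadModel, ImplantationSchema]:
    """Generate a synthetic head model and its implantation schema.

    Deterministic in (seed, config). Each target ROI is paired with an
    entry region: the patch of cortical GM within a 15° cap around the
    ROI's radial direction, so a roughly radial (near-orthogonal)
    trajectory exists. A brute-force feasibility probe re-draws an
    ROI/entry pair (bounded retries) if no candidate trajectory passes
    the default hard constraints, guaranteeing every schema electrode
    is plannable on the emitted phantom.
    """
    cfg = config
    rng = np.random.default_rng(cfg.seed)
    (X, Y, Z), R, affine = _radius_volume(cfg.grid_shape, cfg.voxel_spacing_mm)

    scalp = R <= cfg.scalp_radius_mm
    brain = R <= cfg.brain_radius_mm
    gm = brain & (R > cfg.brain_radius_mm - cfg.gm_thickness_mm)

    # sulci: thin radial slabs through the outer brain shell, localized
    # to a hemisphere cap so they do not wall off the whole surface
    sulci = np.zeros_like(brain)
    for _ in range(cfg.n_sulci):
        nrm = _random_unit(rng)[0]
        side = _random_unit(rng)[0]
        coord = X * nrm[0] + Y * nrm[1] + Z * nrm[2]
        cap = X * side[0] + Y * side[1] + Z * side[2] > 0
        band = (np.abs(coord) < cfg.sulcus_width_mm / 2) & cap
        shell = brain & (R > cfg.brain_radius_mm - cfg.sulcus_depth_mm)
        sulci |= band & shell

    segments = _grow_vessel_trees(cfg, rng)
    vessels = _rasterize_tubes(segments, cfg.vessel_radius_mm, cfg.grid_shape, affine) & scalp

    model = HeadModel(
        scalp_mask=scalp, brain_mask=brain, gm_mask=gm, sulci_mask=sulci,
        vessel_mask=vessels, roi_labels=np.zeros(cfg.grid_shape, dtype=np.int16),
        affine=affine,
    )

    # place target ROIs + entry patches, retrying until each electrode
    # has at least one feasible trajectory under default constraints
    from . import planner  # deferred: planner never imports phantom at runtime

    constraints = planner.PlanningConstraints()
    evaluator = None
    centers: list[np.ndarray] = []
    labels = np.zeros(cfg.grid_shape, dtype=np.int16)
    names: dict[int, str] = {}
    electrodes = []
    gm_idx = np.argwhere(gm)
    gm_world = gm_idx * model.voxel_spacing + affine[:3, 3]
    gm_unit = gm_world / np.linalg.norm(gm_world, axis=1, keepdims=True)

    for k in range(cfg.n_target_rois):
        tgt_label = k + 1
        ent_label = tgt_label + ENTRY_LABEL_OFFSET
        placed = False
        for attempt in range(8):
            c = _place_rois(cfg, rng, centers)
            roi = (X - c[0]) ** 2 + (Y - c[1]) ** 2 + (Z - c[2]) ** 2 <= cfg.roi_radius_mm**2
            u = c / np.linalg.norm(c)
            patch_sel = gm_unit @ u > np.cos(np.radians(15.0))
            if not roi.any() or not patch_sel.any():
                continue
            trial = labels.copy()
            trial[roi & (labels == 0)] = tgt_label
            pidx = gm_idx[patch_sel]
            trial[tuple(pidx.T)] = np.where(
                trial[tuple(pidx.T)] == 0, ent_label, trial[tuple(pidx.T)]
            )
            model.roi_labels = trial
            if evaluator is None:
                from .metrics import TrajectoryEvaluator

                evaluator = TrajectoryEvaluator(model, constraints.risk_params)
            if _probe_feasible(model, evaluator, ent_label, tgt_label, constraints):
                labels = trial
                centers.append(c)
                names[tgt_label] = f"roi_{tgt_label}"
                names[ent_label] = f"entry_{tgt_label}"
                electrodes.append((f"E{tgt_label}", ent_label, tgt_label))
                placed = True
                break
        if not placed:
            raise PhantomError(
                f"electrode E{tgt_label}: no feasible trajectory found after retries; "
                "relax the config (fewer vessels/sulci or smaller ROI radius)"
            )
    model.roi_labels = labels
    model.region_names = names
    schema = ImplantationSchema(tuple(electrodes))
    model.validate()
    schema.validate_against(model)
    return model, schema


def _probe_feasible(model, evaluator, entry_label, target_label, constraints) -> bool:
    """Coarse brute-force check that some candidate pair is feasible."""
    from . import planner

    try:
        cand = planner.generate_candidates(
            model, entry_label, target_label,
            entry_stride=3, target_stride=3, evaluator=evaluator,
        )
    except planner.PlanningError:
        return False
    n_e = min(len(cand.entry_points), 20)
    n_t = min(len(cand.target_points), 20)
    for e in cand.entry_points[:n_e]:
        for t in cand.target_points[:n_t]:
            ok, _ = planner.is_feasible(e, t, model, constraints, evaluator=evaluator)
            if ok:
                return True
    return False


def phantom_report(model: HeadModel) -> pd.DataFrame:
    """Per-structure voxel counts and volumes (mm³), plus label inventory."""
    voxel_vol = float(np.prod(model.voxel_spacing))
    rows = []
    for name, mask in [
        ("scalp", model.scalp_mask), ("brain", model.brain_mask),
        ("gm", model.gm_mask), ("sulci", model.sulci_mask),
        ("vessels", model.vessel_mask),
    ]:
        n = int((np.asarray(mask) > 0).sum())
        rows.append({"structure": name, "label": None, "voxels": n, "volume_mm3": n * voxel_vol})
    for lbl in sorted(set(np.unique(model.roi_labels)) - {0}):
        n = int((model.roi_labels == lbl).sum())
        rows.append({
            "structure": model.region_names.get(int(lbl), f"label_{lbl}"),
            "label": int(lbl), "voxels": n, "volume_mm3": n * voxel_vol,
        })
    return pd.DataFrame(rows)
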