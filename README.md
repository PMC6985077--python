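# seegplan

Computer-assisted trajectory planning for stereoelectroencephalography
(SEEG), at desk scale. SEEG localizes the seizure onset zone in
drug-resistant focal epilepsy by stereotactically implanting 10–16
depth electrodes into predefined brain regions; the dominant hazard is
hemorrhage from conflict with a blood vessel, so each straight
entry→target trajectory must thread an avascular corridor while also
drilling near-orthogonally through the skull, staying short, sampling
gray matter (where epileptic activity is recorded), avoiding sulcal
pia, and keeping clear of the other electrodes.

`seegplan` implements that planning problem as a library and CLI
operating on co-registered voxel masks (scalp, brain, gray matter,
sulci, vessel segmentation) plus a labeled region volume. It provides:

* a **vessel-proximity risk score** per trajectory,
* **hard-constraint filtering** and **risk-stratified ranking** of
  candidate trajectories,
* **multi-electrode planning** with inter-electrode conflict
  resolution, "next entry"/"next target" iteration, and audited manual
  overrides,
* **plan-level comparison** with cluster-aware bootstrap summaries and
  the clustered sample-size arithmetic for paired risk comparisons,
* a **deterministic synthetic head phantom** so the full pipeline runs
  and is testable without any patient data.

## The risk score

A trajectory is discretized into N = 128 equally spaced sampling nodes
from scalp entry to target. With Dist(i) the Euclidean distance (mm)
of node i to the vessel segmentation, d_safe = 3 mm the safety margin
and d_max = 10 mm the outer range:

```
        ⎧ Σᵢ (d_max − Dist(i)) / (N·(d_max − d_safe)),   all Dist(i) > d_safe
    R = ⎨
        ⎩ 1 + Σ_{i: Dist(i) ≤ d_safe} (d_safe − Dist(i)) / (d_safe·N),  otherwise
```

with distances clamped to [d_safe, d_max] in the first branch. R lies
in [0, 2]; R = 0 when every node is ≥ 1 cm from a vessel, and R > 1
exactly when some node is within the 3 mm safety margin. Alongside R,
each trajectory reports its minimum vessel distance, gray-matter
sampling ratio, full and intracerebral lengths, and drilling angle
from the local scalp normal.

Hard constraints (all configurable via `PlanningConstraints`):
minimum vessel distance ≥ 3 mm, length < 90 mm, drilling angle < 30°
from orthogonal, no sulcal crossing, pairwise electrode spacing
≥ 10 mm.

## Worked example

```python
from seegplan import PhantomConfig, make_phantom, plan_implantation

config = PhantomConfig(
    seed=1,
    grid_shape=(96, 96, 96),
    scalp_radius_mm=44, brain_radius_mm=38,
    n_target_rois=3, roi_radius_mm=5,
    n_sulci=4, sulcus_depth_mm=8,
)
model, schema = make_phantom(config)
plan = plan_implantation(model, schema)

for e in plan.electrodes:
    m = e.metrics
    print(f"{e.name}: risk={m.risk:.3f}  min_vessel={m.min_vessel_distance_mm:.1f} mm  "
          f"GM={m.gm_ratio:.2f}  length={m.length_mm:.1f} mm  angle={m.drilling_angle_deg:.1f} deg")
print("mean risk:", round(plan.summary["risk"], 3))
```

prints

```
E1: risk=0.000  min_vessel=24.3 mm  GM=0.18  length=25.1 mm  angle=1.3 deg
E2: risk=0.000  min_vessel=16.2 mm  GM=0.17  length=23.7 mm  angle=0.3 deg
E3: risk=0.095  min_vessel=4.9 mm  GM=0.16  length=24.8 mm  angle=0.6 deg
mean risk: 0.032
```

Each electrode threads its corridor: E1 and E2 never come within 1 cm
of the synthetic vessel tree (risk 0), E3 passes between 3 and 10 mm
of a vessel and accrues a small sub-threshold risk, and all three
drill within ~1° of orthogonal. The plan mean risk (0.032) is the
quantity compared between competing plans — the plan with the lowest
mean risk is the one a surgical team would implement.

The same pipeline is scriptable from a shell:

```sh
seegplan phantom --seed 7 --out head/          # synthetic head + schema
seegplan plan --model head --schema head/schema.json \
              --out plan.json --metrics-csv metrics.csv
seegplan iterate --model head --schema head/schema.json \
              --electrode E1 --action next-target --out plan3.json
seegplan summary plan.json
seegplan samplesize --delta 0.1 --sd 0.1 --power 0.9 --m 10 --icc 0.2
```

## Scope

Inputs arrive as co-registered masks: vessel extraction, image
registration, parcellation and mesh/stereotactic-frame export are out
of scope, as is mixed-effects regression fitting (plan comparisons
here are descriptive, cluster-aware bootstrap summaries). See
`docs/methods.md` for the model, parameter and design details.
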