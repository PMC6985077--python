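"""Study-design arithmetic and cluster-aware plan comparison.

Electrodes are clustered within patients (one plan of ~10 electrodes
per patient), so a paired comparison of per-electrode risk scores must
inflate its sample size by the design effect 1 + (m−1)·ρ, where m is
the cluster size and ρ the intracluster correlation. The module
implements the two-group normal-approximation sample size, the design
effect, and a descriptive cluster-bootstrap comparison of paired
plans. It deliberately does not fit mixed-effects regressions — the
bootstrap summaries are descriptive, not a mixed-model replacement.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.stats import norm, t as t_dist

from .metrics import METRIC_COLUMNS

__all__ = [
    "SampleSizeSpec",
    "unadjusted_sample_size",
    "design_effect",
    "cluster_adjusted_size",
    "paired_cluster_bootstrap",
    "compare_plans",
]


@dataclass(frozen=True)
class SampleSizeSpec:
    """Inputs of the clustered sample-size calculation.

    delta
        Smallest difference worth detecting, in the outcome's units
        (risk-score units here).
    sd
        Outcome standard deviation, same units.
    alpha
        Two-tailed significance level.
    power
        1 − β.
    cluster_size
        Electrodes per plan (m).
    icc
        Intracluster correlation coefficient (ρ).
    """

    delta: float = 0.1
    sd: float = 0.1
    alpha: float = 0.05
    power: float = 0.9
    cluster_size: int = 10
    icc: float = 0.2

    def __post_init__(self):
        if not (0 < self.alpha < 1) or not (0 < self.power < 1):
            raise ValueError("alpha and power must lie in (0, 1)")
        if self.sd <= 0 or self.delta <= 0:
            raise ValueError("sd and delta must be > 0")
        if self.cluster_size < 1:
            raise ValueError("cluster_size must be >= 1")
        if not (0 <= self.icc <= 1):
            raise ValueError("icc must lie in [0, 1]")


def unadjusted_sample_size(spec: SampleSizeSpec) -> int:
    """Total comparisons needed, two-group normal approximation.

    n = round(4 · (z_{1−α/2} + z_{power})² · σ²/δ²). Depends on σ and
    δ only through their ratio; rounded to the nearest integer (the
    convention that reproduces the printed design numbers — see the
    methods note, since rounding conventions differ across texts).
    """
    z_a = norm.ppf(1 - spec.alpha / 2)
    z_b = norm.ppf(spec.power)
    n = 4 * (z_a + z_b) ** 2 * (spec.sd / spec.delta) ** 2
    return int(round(n))


def design_effect(cluster_size: int, icc: float) -> float:
    """Variance inflation from clustering: 1 + (m − 1)·ρ; always ≥ 1."""
    if cluster_size < 1:
        raise ValueError("cluster_size must be >= 1")
    if not (0 <= icc <= 1):
        raise ValueError("icc must lie in [0, 1]")
    return 1.0 + (cluster_size - 1) * icc


def cluster_adjusted_size(n_total: int, cluster_size: int, icc: float) -> int:
    """Electrodes required after design-effect inflation (ceiling)."""
    return int(np.ceil(n_total * design_effect(cluster_size, icc)))


def paired_cluster_bootstrap(
    differences: np.ndarray,
    cluster_ids: np.ndarray,
    n_boot: int = 200,
    seed: int | np.random.Generator = 0,
    ci: float = 0.95,
) -> dict[str, float]:
    """Percentile CI for a mean paired difference, resampling clusters.

    Clusters (patients) are resampled with replacement; within a
    resampled cluster all its per-electrode differences are kept
    together, respecting the within-patient correlation. Returns the
    observed mean and the percentile interval.

    With few clusters the naive equal-tailed percentile interval is
    systematically narrow, so the percentile levels are widened the
    standard small-sample way (Hesterberg's "expanded" percentile
    interval): the nominal z quantile is replaced by
    t_{G−1} · sqrt(G/(G−1)) with G the number of clusters, and the
    corresponding normal tail probability picks the percentiles.
    """
    differences = np.asarray(differences, float)
    cluster_ids = np.asarray(cluster_ids)
    if differences.shape != cluster_ids.shape:
        raise ValueError("differences and cluster_ids must align")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    clusters = np.unique(cluster_ids)
    groups = [differences[cluster_ids == c] for c in clusters]
    g = len(groups)
    means = np.empty(n_boot)
    for b in range(n_boot):
        pick = rng.integers(0, g, size=g)
        means[b] = np.concatenate([groups[i] for i in pick]).mean()
    alpha = 1 - ci
    if g > 1:
        z_exp = t_dist.ppf(1 - alpha / 2, g - 1) * np.sqrt(g / (g - 1))
        tail = float(norm.cdf(-z_exp))
    else:
        tail = alpha / 2
    lo, hi = np.percentile(means, [100 * tail, 100 * (1 - tail)])
    return {
        "mean_difference": float(differences.mean()),
        "ci_low": float(lo),
        "ci_high": float(hi),
        "n": int(differences.size),
        "n_clusters": int(len(groups)),
    }


def compare_plans(
    plans_a,
    plans_b,
    n_boot: int = 200,
    seed: int = 0,
    ci: float = 0.95,
) -> pd.DataFrame:
    """Descriptive paired comparison of two sets of plans, per metric.

    ``plans_a`` / ``plans_b`` are paired plans (one pair per patient;
    a single plan pair is accepted). Electrodes are matched by name
    within each pair; each pair is one cluster for the bootstrap.
    Differences are A − B, so a positive mean risk difference means
    plan A is riskier.

    Descriptive only — this is a cluster-respecting bootstrap summary,
    not a mixed-effects model fit.
    """
    if not isinstance(plans_a, (list, tuple)):
        plans_a = [plans_a]
    if not isinstance(plans_b, (list, tuple)):
        plans_b = [plans_b]
    if len(plans_a) != len(plans_b):
        raise ValueError("plan lists must pair up")

    def _metric_map(plan):
        # accepts planner.Plan or io_model.PlanDocument
        out = {}
        for e in plan.electrodes:
            met = e.metrics if isinstance(e.metrics, dict) else e.metrics.as_dict()
            out[e.name] = met
        return out

    rows = []
    rng = np.random.default_rng(seed)
    for key, col in METRIC_COLUMNS.items():
        diffs, cids = [], []
        for c, (pa, pb) in enumerate(zip(plans_a, plans_b)):
            ma, mb = _metric_map(pa), _metric_map(pb)
            if set(ma) != set(mb):
                raise ValueError(f"plan pair {c}: electrode names differ")
            for name in ma:
                diffs.append(ma[name][key] - mb[name][key])
                cids.append(c)
        res = paired_cluster_bootstrap(
            np.array(diffs), np.array(cids), n_boot=n_boot, seed=rng, ci=ci
        )
        rows.append({"metric": col, **res})
    df = pd.DataFrame(rows)
    df.attrs["note"] = "descriptive cluster bootstrap; not a mixed-effects model"
    return df
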