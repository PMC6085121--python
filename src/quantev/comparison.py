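"""Transport distances between densities and the replicate-aware
condition-comparison test.

Two per-axis densities are compared with the first-order Wasserstein (Earth
Mover's) distance: on a line it is the L1 distance between cumulative
distribution functions; on the circle the cumulation start bin is a free
choice and the Circular EMD minimizes over it.

For a study with labeled replicate experiments, each experiment e gets an
*intra-condition* distance (mean distance to the other replicates of its own
condition), an *inter-condition* distance (mean distance to all experiments
of the other conditions), and the *condition difference*
``delta_e = inter(e) - intra(e)``.  If the conditions genuinely differ, the
deltas should be systematically positive, which a one-sided Wilcoxon
signed-rank test assesses without any distributional model.
"""

from __future__ import annotations

import itertools
import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy import stats

from .density import Density1D

__all__ = [
    "Experiment",
    "ConditionStudy",
    "emd",
    "cemd",
    "condition_difference",
    "wilcoxon_condition_test",
    "same_condition_control",
]

AXES = ("radius", "angle", "depth")


def _masses(d: Density1D) -> np.ndarray:
    v = np.asarray(d.values, float)
    total = v.sum()
    if total <= 0:
        raise ValueError("density has zero mass")
    return v / total


def emd(f1: Density1D, f2: Density1D) -> float:
    """Earth Mover's Distance between two linear densities on one grid.

    Each input is renormalized to sum to 1 over its K bins; the distance is
    the sum of absolute differences of the cumulative sums, in bin units
    (point masses at opposite ends of a K-grid are K - 1 apart).
    """
    if len(f1.grid) != len(f2.grid) or not np.allclose(f1.grid, f2.grid):
        raise ValueError("densities must share the same grid")
    c1 = np.cumsum(_masses(f1))
    c2 = np.cumsum(_masses(f2))
    return float(np.abs(c1 - c2).sum())


def cemd(f1: Density1D, f2: Density1D) -> float:
    """Circular EMD between two circular densities on one grid.

    For each start bin k the cumulative sums are restarted at k and wrapped;
    the distance is the minimum over k of the L1 difference of these wrapped
    CDFs.  Equivalently min_k sum_i |D(i) - D(k-1)| with D the difference of
    ordinary CDFs; ties in k resolve to the smallest k.  Rotation invariant.
    """
    if len(f1.grid) != len(f2.grid) or not np.allclose(f1.grid, f2.grid):
        raise ValueError("densities must share the same grid")
    d = np.cumsum(_masses(f1) - _masses(f2))
    # starting cumulation at bin k subtracts D(k-1) from every entry
    costs = np.abs(d[None, :] - d[:, None]).sum(axis=1)  # cost of start k = j+2
    cost_k1 = float(np.abs(d).sum())
    best = float(costs.min())
    return min(cost_k1, best)


def distance(f1: Density1D, f2: Density1D) -> float:
    """EMD on linear supports, CEMD on circular supports."""
    if f1.support != f2.support:
        raise ValueError("cannot compare linear with circular densities")
    return cemd(f1, f2) if f1.support == "circular" else emd(f1, f2)


@dataclass
class Experiment:
    """One replicate: an id, its condition label, and per-axis densities."""

    id: str
    condition: str
    densities: dict[str, Density1D]


@dataclass
class ConditionStudy:
    """Labeled replicate experiments plus derived distances and tests."""

    experiments: list[Experiment]
    distance_matrix: dict[str, np.ndarray] = field(default_factory=dict)
    condition_difference_: dict[str, np.ndarray] = field(default_factory=dict)
    p_values: dict[str, float] = field(default_factory=dict)

    @property
    def conditions(self) -> list[str]:
        seen: list[str] = []
        for e in self.experiments:
            if e.condition not in seen:
                seen.append(e.condition)
        return seen

    def axis_matrix(self, axis: str) -> np.ndarray:
        """Symmetric pairwise distance matrix for one axis (cached)."""
        if axis not in self.distance_matrix:
            n = len(self.experiments)
            m = np.zeros((n, n))
            for i, j in itertools.combinations(range(n), 2):
                dij = distance(
                    self.experiments[i].densities[axis],
                    self.experiments[j].densities[axis],
                )
                m[i, j] = m[j, i] = dij
            self.distance_matrix[axis] = m
        return self.distance_matrix[axis]


def condition_difference(study: ConditionStudy, axis: str) -> np.ndarray:
    """Per-experiment condition difference delta_e = inter(e) - intra(e).

    intra(e): mean distance to the other same-condition replicates;
    inter(e): mean distance to all experiments of the other condition(s)
    (pooled when there are more than two conditions).
    Raises on singleton conditions, which have no intra distance.
    """
    labels = np.array([e.condition for e in study.experiments])
    for cond in study.conditions:
        if (labels == cond).sum() < 2:
            raise ValueError(f"condition {cond!r} has a single experiment")
    if len(study.conditions) < 2:
        raise ValueError("need at least 2 conditions")
    m = study.axis_matrix(axis)
    n = len(labels)
    deltas = np.empty(n)
    for i in range(n):
        same = (labels == labels[i]) & (np.arange(n) != i)
        other = labels != labels[i]
        deltas[i] = m[i, other].mean() - m[i, same].mean()
    study.condition_difference_[axis] = deltas
    return deltas


def wilcoxon_condition_test(deltas) -> float:
    """One-sided Wilcoxon signed-rank p-value for median delta > 0.

    Zero differences are dropped (Wilcoxon's convention); the exact null is
    used up to n = 25 (no ties in |delta|), the normal approximation with
    continuity correction above.  Fewer than 5 nonzero deltas is flagged as
    low power; all-zero deltas return p = 1 with a warning.
    """
    d = np.asarray(deltas, float)
    d = d[d != 0.0]
    if d.size == 0:
        warnings.warn("all condition differences are zero: p = 1", stacklevel=2)
        return 1.0
    if d.size < 5:
        warnings.warn(
            f"only {d.size} nonzero differences: test has low power", stacklevel=2
        )
    ties = len(np.unique(np.abs(d))) < d.size
    method = "exact" if (d.size <= 25 and not ties) else "approx"
    res = stats.wilcoxon(
        d, alternative="greater", zero_method="wilcox", correction=True,
        method=method,
    )
    return float(res.pvalue)


def run_condition_test(study: ConditionStudy, axes=AXES) -> dict[str, float]:
    """Condition differences and Wilcoxon p-values for each axis present."""
    out = {}
    for axis in axes:
        if axis not in study.experiments[0].densities:
            continue
        deltas = condition_difference(study, axis)
        out[axis] = wilcoxon_condition_test(deltas)
    study.p_values.update(out)
    return out


def same_condition_control(
    experiments: list[Experiment],
    axis: str,
    n_splits: int = 100,
    seed: int = 0,
) -> np.ndarray:
    """Null control: random splits of one condition tested against itself.

    The experiments of a single condition are randomly partitioned into two
    pseudo-conditions (the larger half takes the extra experiment at odd
    counts) ``n_splits`` times; the full condition-difference + Wilcoxon
    procedure runs on every split.  If the replicates are exchangeable the
    returned p-values should center near 0.5 — a calibration check, not a
    test.
    """
    if len(experiments) < 4:
        raise ValueError("need at least 4 experiments to split")
    rng = np.random.default_rng(seed)
    n = len(experiments)
    half = n // 2
    # distances do not depend on labels: compute the matrix once
    base = ConditionStudy(
        experiments=[Experiment(e.id, "all", e.densities) for e in experiments]
    )
    m = base.axis_matrix(axis)
    pvals = np.empty(n_splits)
    idx = np.arange(n)
    for s in range(n_splits):
        perm = rng.permutation(idx)
        labels = np.empty(n, object)
        labels[perm[:half]] = "A"
        labels[perm[half:]] = "B"
        deltas = np.empty(n)
        for i in range(n):
            same = (labels == labels[i]) & (idx != i)
            other = labels != labels[i]
            deltas[i] = m[i, other].mean() - m[i, same].mean()
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            pvals[s] = wilcoxon_condition_test(deltas)
    return pvals
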