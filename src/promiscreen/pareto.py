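"""Dominance, Pareto fronts, optimistic screening and trade-off geometry.

A variant *a* dominates *b* when it is strictly better in every objective
(all objectives are maximized).  The Pareto set is the non-dominated
subset: the variants with optimal trade-offs between, e.g., a primary and
a promiscuous activity.  This module provides

* front extraction (sum-ordered sweep, validated against a brute-force
  all-pairs oracle in the test suite);
* the *optimistic* Pareto prediction: the non-dominated set of the pooled
  bootstrap-replica reconstructions, whose genotypes are the candidates
  for the next screening round;
* the screening-round bookkeeping (request sheet of unmeasured candidates,
  merge of new measurements);
* the linear-scale trade-off analyses: least-squares trade-off line
  through the front, the line connecting the per-objective maxima, and
  the triangular-occupancy statistic with its (1/2)^NDP chance bound.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .bootstrap import ReconstructionEnsemble
from .genotypes import genotype_string


@dataclass
class PointSet:
    """Labelled points in objective space with an explicit scale tag.

    ``values`` is (n, K); ``scale`` is ``"log"`` or ``"linear"`` — Pareto
    extraction is scale-agnostic (log is monotone) but the trade-off-line
    and triangle analyses require the linear scale and refuse a mismatch.
    """

    ids: list
    values: np.ndarray
    objectives: list
    scale: str = "log"

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 2:
            raise ValueError("values must be 2-D (points x objectives)")
        if not np.isfinite(self.values).all():
            raise ValueError("coordinates must be finite")
        if self.scale not in ("log", "linear"):
            raise ValueError("scale must be 'log' or 'linear'")
        if len(self.ids) != len(self.values):
            raise ValueError("ids and values differ in length")

    def __len__(self) -> int:
        return len(self.ids)

    @property
    def k(self) -> int:
        return self.values.shape[1]

    def to_linear(self) -> "PointSet":
        """Convert log10 activities to the linear scale."""
        if self.scale == "linear":
            return self
        return PointSet(
            ids=list(self.ids),
            values=10.0**self.values,
            objectives=list(self.objectives),
            scale="linear",
        )

    def subset(self, indices) -> "PointSet":
        return PointSet(
            ids=[self.ids[i] for i in indices],
            values=self.values[list(indices)],
            objectives=list(self.objectives),
            scale=self.scale,
        )


#: A Pareto front is simply the non-dominated PointSet returned by
#: :func:`pareto_front`; no separate container is needed.
ParetoFront = PointSet


def dominates(a, b, weak: bool = False) -> bool:
    """True if point a dominates point b (all objectives maximized).

    Strict by default: a must be strictly greater in *every* objective, so
    tied points never dominate each other.  ``weak=True`` uses >= in all
    objectives with > in at least one.
    """
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.shape != b.shape:
        raise ValueError("points differ in dimensionality")
    if weak:
        return bool(np.all(a >= b) and np.any(a > b))
    return bool(np.all(a > b))


def pareto_mask(values: np.ndarray, weak: bool = False) -> np.ndarray:
    """Boolean mask of non-dominated rows, by a sum-ordered sweep.

    Strict dominance implies a strictly larger coordinate sum, so any
    dominator of a point precedes it in decreasing-sum order and every
    dominated point is dominated by some front member (transitivity);
    each point therefore only needs checking against the current front.
    """
    values = np.asarray(values, dtype=float)
    n = len(values)
    if n == 0:
        return np.zeros(0, dtype=bool)
    if values.shape[1] == 2 and not weak:
        return _pareto_mask_2d_strict(values)
    order = np.argsort(-values.sum(axis=1), kind="stable")
    mask = np.zeros(n, dtype=bool)
    front_rows: list[np.ndarray] = []
    for i in order:
        v = values[i]
        dominated = False
        if front_rows:
            fr = np.array(front_rows)
            if weak:
                dominated = bool(
                    np.any(np.all(fr >= v, axis=1) & np.any(fr > v, axis=1))
                )
            else:
                dominated = bool(np.any(np.all(fr > v, axis=1)))
        if not dominated:
            mask[i] = True
            front_rows.append(v)
    return mask


def _pareto_mask_2d_strict(values: np.ndarray) -> np.ndarray:
    """Vectorized strict-dominance front for 2 objectives.

    A point is dominated iff some point has strictly larger x *and*
    strictly larger y; equivalently its y is below the running y-maximum
    over all strictly-larger x values.
    """
    x = values[:, 0]
    y = values[:, 1]
    order = np.lexsort((-y, -x))  # x desc, then y desc
    xs = x[order]
    ys = y[order]
    best_prev = np.full(len(xs), -np.inf)  # max y among strictly larger x
    run_max = -np.inf
    i = 0
    while i < len(xs):
        j = i
        while j < len(xs) and xs[j] == xs[i]:
            j += 1
        best_prev[i:j] = run_max
        run_max = max(run_max, ys[i])  # ys desc within the tie group
        i = j
    mask = np.zeros(len(xs), dtype=bool)
    mask[order] = ys >= best_prev  # equal y under larger x is not strict
    return mask


def pareto_front(points: PointSet, weak: bool = False) -> PointSet:
    """The non-dominated subset of a point set.

    Duplicated coordinates are all retained under strict dominance (no
    copy strictly dominates another).
    """
    if len(points) == 0:
        raise ValueError("need at least one point")
    mask = pareto_mask(points.values, weak=weak)
    return points.subset(np.flatnonzero(mask))


def pareto_front_brute_force(points: PointSet, weak: bool = False) -> PointSet:
    """All-pairs O(n^2) front extraction; the independent oracle."""
    vals = points.values
    keep = []
    for i in range(len(vals)):
        if not any(
            dominates(vals[j], vals[i], weak=weak)
            for j in range(len(vals))
            if j != i
        ):
            keep.append(i)
    return points.subset(keep)


def optimistic_pareto(
    ensemble: ReconstructionEnsemble, pool: bool = True, weak: bool = False
) -> list:
    """Genotypes in the non-dominated set of the bootstrap reconstruction.

    By default all B x 2^M replica predictions are pooled into one cloud
    and its Pareto front is taken; a genotype qualifies if *any* replica
    places it on that front (the optimistic reading of reconstruction
    uncertainty).  ``pool=False`` instead intersects nothing: it takes the
    union of per-replica fronts.
    """
    points, genotype_idx = ensemble.pooled()
    if pool:
        mask = pareto_mask(points, weak=weak)
        chosen = np.unique(genotype_idx[mask])
    else:
        n = len(ensemble.genotypes)
        chosen_set: set[int] = set()
        for rep in range(ensemble.n_replicas):
            mask = pareto_mask(ensemble.predictions[rep], weak=weak)
            chosen_set.update(np.flatnonzero(mask).tolist())
        chosen = np.array(sorted(chosen_set))
        del n
    return [ensemble.genotypes[i] for i in chosen]


def screening_round(measured, candidates) -> pd.DataFrame:
    """Request sheet for the next screening round.

    Returns the candidate genotypes not yet in the measured table, as a
    one-column DataFrame ready to be written as a TSV request.  Once the
    new measurements come back, merge them with
    :meth:`promiscreen.activity.ActivityTable.merged_with` and repeat the
    reconstruction/prediction cycle.
    """
    have = set(measured.genotypes)
    new = [g for g in candidates if g not in have]
    # preserve candidate order, drop duplicates
    seen: set = set()
    unique_new = []
    for g in new:
        if g not in seen:
            seen.add(g)
            unique_new.append(g)
    return pd.DataFrame({"genotype": [genotype_string(g) for g in unique_new]})


@dataclass
class TradeoffLine:
    """A line y = slope * x + intercept in the linear activity plane."""

    slope: float
    intercept: float
    rss: float = 0.0

    def __call__(self, x):
        return self.slope * np.asarray(x, dtype=float) + self.intercept


def fit_tradeoff_line(front: PointSet, scale: str = "linear") -> TradeoffLine:
    """Least-squares line through the Pareto-front points (linear scale).

    The second objective (promiscuous) is regressed on the first
    (primary).
    """
    if scale != "linear" or front.scale != "linear":
        raise ValueError("trade-off line is defined on the linear scale")
    if front.k != 2:
        raise ValueError("trade-off line requires exactly 2 objectives")
    if len(front) < 2:
        raise ValueError("need at least 2 front points")
    x = front.values[:, 0]
    y = front.values[:, 1]
    if np.ptp(x) < 1e-12:
        raise ValueError("front is vertical; slope undefined")
    coeffs, rss, *_ = np.polyfit(x, y, 1, full=True)
    slope, intercept = float(coeffs[0]), float(coeffs[1])
    resid = y - (slope * x + intercept)
    return TradeoffLine(slope=slope, intercept=intercept, rss=float(resid @ resid))


def max_connecting_line(points: PointSet) -> TradeoffLine:
    """Line connecting the observed per-objective maxima (linear scale).

    The chord from (x_max, 0) on the primary axis to (0, y_max) on the
    promiscuous axis, i.e. x/x_max + y/y_max = 1 — the default reference
    line for the triangular-occupancy statistic.
    """
    if points.scale != "linear":
        raise ValueError("reference line is defined on the linear scale")
    if points.k != 2:
        raise ValueError("reference line requires exactly 2 objectives")
    x_max = float(points.values[:, 0].max())
    y_max = float(points.values[:, 1].max())
    if x_max <= 0:
        raise ValueError("maximum primary activity must be positive")
    return TradeoffLine(slope=-y_max / x_max, intercept=y_max)


@dataclass
class TriangleStatistic:
    """Occupancy of the region at or below a reference line.

    If activities were uncorrelated, each point would fall below the line
    joining the per-objective maxima with probability about 1/2, so all
    NDP points landing there has chance on the order of (1/2)^NDP.
    """

    ndp: int
    count_below: int
    null_probability: float


def triangle_statistic(
    points: PointSet, line: TradeoffLine, tolerance: float = 0.0
) -> TriangleStatistic:
    """Count points at or below a reference line; (1/2)^count chance bound."""
    if points.scale != "linear":
        raise ValueError("triangle statistic is defined on the linear scale")
    if points.k != 2:
        raise ValueError("triangle statistic requires exactly 2 objectives")
    x = points.values[:, 0]
    y = points.values[:, 1]
    below = int(np.sum(y <= line(x) + tolerance))
    return TriangleStatistic(
        ndp=len(points),
        count_below=below,
        null_probability=0.5**below,
    )
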