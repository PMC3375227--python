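"""Stochastic activity clouds under conformational-diversity models.

The conformational diversity hypothesis pictures a native protein as an
equilibrium mixture of conformations; distinct conformations carry the
primary and promiscuous activities, and mutations shift the equilibrium.
With conformations a_i carrying activity coefficients (c_primary,
c_promiscuous) and statistical weights w_i drawn from flat distributions,
a simulated variant has mol fractions X(a_i) = w_i / sum(w) (summing to 1)
and activities

    A^k = sum_i X(a_i) * c_i^k        (linear scale, unit proportionality).

For the canonical three-state model (inactive a_0, promiscuous-optimal
a_1, primary-optimal a_2) the optimal situations X(a_0) = 0 satisfy
X(a_1) + X(a_2) = 1, which maps to the straight *trade-off line*
primary + promiscuous = 1 in the activity plane; suboptimal variants fill
the triangle below it.  Variant models with more conformations, leaky
suboptimal states, or no trade-off between the optimal states are
provided to contrast the resulting cloud shapes.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import stats

from .pareto import PointSet, max_connecting_line, pareto_mask


@dataclass
class ConformationModel:
    """Conformations with (primary, promiscuous) activity coefficients."""

    labels: list
    coefficients: np.ndarray  # (n_conformations, 2), rows (c_primary, c_prom)
    name: str = "custom"

    def __post_init__(self) -> None:
        self.coefficients = np.asarray(self.coefficients, dtype=float)
        if len(self.labels) < 2:
            raise ValueError("need at least 2 conformations")
        if self.coefficients.shape != (len(self.labels), 2):
            raise ValueError("coefficient matrix must be (n_conformations, 2)")
        if not np.isfinite(self.coefficients).all() or (self.coefficients < 0).any():
            raise ValueError("coefficients must be finite and non-negative")

    @property
    def n_conformations(self) -> int:
        return len(self.labels)


#: Default coefficient levels for the qualitative model variants.
LOW = 0.1
HIGH = 1.0

_BUILTINS = {
    # inactive a0; a1 promiscuous-optimal; a2 primary-optimal
    "three_state": (["a0", "a1", "a2"], [(0.0, 0.0), (0.0, HIGH), (HIGH, 0.0)]),
    # leaky suboptimal conformation
    "three_state_leaky": (["a0", "a1", "a2"], [(LOW, LOW), (0.0, HIGH), (HIGH, 0.0)]),
    # two inactive suboptimal conformations
    "four_state": (
        ["a0", "a1", "a2", "a3"],
        [(0.0, 0.0), (0.0, 0.0), (HIGH, 0.0), (0.0, HIGH)],
    ),
    # optimal conformations leak a low level of the alternative activity
    "four_state_leaky": (
        ["a0", "a1", "a2", "a3"],
        [(0.0, 0.0), (0.0, 0.0), (HIGH, LOW), (LOW, HIGH)],
    ),
    # no trade-off: both optimal conformations high in both activities
    "no_tradeoff": (
        ["a0", "a1", "a2", "a3"],
        [(0.0, 0.0), (0.0, 0.0), (HIGH, HIGH), (HIGH, HIGH)],
    ),
}


def builtin_model(name: str) -> ConformationModel:
    """A named conformational-diversity model (three_state, three_state_leaky..no_tradeoff)."""
    if name not in _BUILTINS:
        raise KeyError(
            f"unknown model {name!r}; choose from {sorted(_BUILTINS)}"
        )
    labels, coeffs = _BUILTINS[name]
    return ConformationModel(labels=list(labels), coefficients=coeffs, name=name)


@dataclass
class SimulatedPoint:
    """One simulated variant: mol fractions and the two linear activities."""

    mol_fractions: np.ndarray
    primary: float
    promiscuous: float


def simulate_variants(
    model: ConformationModel,
    n_variants: int,
    seed: int = 0,
    weights: np.ndarray | None = None,
) -> list[SimulatedPoint]:
    """Draw variants with flat statistical weights per conformation.

    Per variant, w_i ~ U[0, 1] independently; X(a_i) = w_i / sum(w); the
    two activities are X-weighted sums of the conformational coefficients.
    ``weights`` fixes the weight matrix explicitly (for worked examples).
    """
    if n_variants < 1:
        raise ValueError("need at least one variant")
    nc = model.n_conformations
    if weights is None:
        rng = np.random.default_rng(seed)
        w = rng.uniform(size=(n_variants, nc))
        # a fully-zero weight row is measure-zero but guard anyway
        while np.any(w.sum(axis=1) == 0):
            bad = w.sum(axis=1) == 0
            w[bad] = rng.uniform(size=(int(bad.sum()), nc))
    else:
        w = np.asarray(weights, dtype=float)
        if w.shape != (n_variants, nc):
            raise ValueError("weights must be (n_variants, n_conformations)")
        if np.any(w.sum(axis=1) == 0):
            raise ValueError("each variant needs a positive total weight")
    x = w / w.sum(axis=1, keepdims=True)
    acts = x @ model.coefficients
    return [
        SimulatedPoint(mol_fractions=x[i], primary=float(acts[i, 0]),
                       promiscuous=float(acts[i, 1]))
        for i in range(n_variants)
    ]


def points_to_set(points: list[SimulatedPoint]) -> PointSet:
    """Pack simulated variants into a linear-scale PointSet."""
    vals = np.array([[p.primary, p.promiscuous] for p in points])
    return PointSet(
        ids=list(range(len(points))),
        values=vals,
        objectives=["primary", "promiscuous"],
        scale="linear",
    )


@dataclass
class PatternSummary:
    """Summary statistics contrasting trade-off vs no-trade-off clouds."""

    correlation: float
    front_size: int
    fraction_below_line: float
    degenerate: bool = False


def pattern_summary(points: list[SimulatedPoint]) -> PatternSummary:
    """Pearson correlation, front size and below-line fraction of a cloud."""
    if len(points) < 3:
        raise ValueError("need at least 3 points")
    ps = points_to_set(points)
    x = ps.values[:, 0]
    y = ps.values[:, 1]
    degenerate = bool(np.std(x) < 1e-12 or np.std(y) < 1e-12)
    corr = float("nan") if degenerate else float(stats.pearsonr(x, y)[0])
    front_size = int(pareto_mask(ps.values).sum())
    line = max_connecting_line(ps)
    below = float(np.mean(y <= line(x) + 1e-12))
    return PatternSummary(
        correlation=corr,
        front_size=front_size,
        fraction_below_line=below,
        degenerate=degenerate,
    )
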