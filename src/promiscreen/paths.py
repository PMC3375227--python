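"""Constrained single-mutation walks over a reconstructed landscape.

Given full-library activities for every genotype (a reconstruction replica
or a synthetic ground truth), a mutational path is built by the loop:
test the single-mutation neighbours of the current variant against a rule,
pick one passer uniformly at random, repeat until no neighbour passes.
The rule requires strict monotone change of one objective (increase or
decrease) while the other objective stays at or above a floor — e.g.
"increase promiscuous activity while primary activity stays above a
threshold".
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .genotypes import as_genotype, enumerate_library, genotype_index, neighbors


@dataclass
class Landscape:
    """Activities A^k for every genotype of a 2^M library."""

    m: int
    objectives: list
    activities: np.ndarray  # (2^M, K), rows in enumerate_library order

    def __post_init__(self) -> None:
        self.activities = np.asarray(self.activities, dtype=float)
        if self.activities.shape != (2**self.m, len(self.objectives)):
            raise ValueError(
                f"activities must be (2^{self.m}, {len(self.objectives)})"
            )

    def activity(self, genotype, objective: str) -> float:
        k = self.objectives.index(objective)
        return float(self.activities[genotype_index(genotype), k])

    def to_frame(self) -> pd.DataFrame:
        from .genotypes import genotype_string

        df = pd.DataFrame(self.activities, columns=self.objectives)
        df.insert(
            0,
            "genotype",
            [genotype_string(g) for g in enumerate_library(self.m)],
        )
        return df

    def write_tsv(self, path) -> None:
        self.to_frame().to_csv(path, sep="\t", index=False)

    @classmethod
    def read_tsv(cls, path) -> "Landscape":
        df = pd.read_csv(path, sep="\t", dtype={"genotype": str})
        gts = [as_genotype(g) for g in df.pop("genotype")]
        m = len(gts[0])
        order = np.argsort([genotype_index(g) for g in gts])
        return cls(
            m=m,
            objectives=list(df.columns),
            activities=df.to_numpy(dtype=float)[order],
        )


@dataclass(frozen=True)
class PathRule:
    """Monotone-improvement rule with an activity floor on the other axis."""

    improve_objective: str
    direction: str  # "increase" or "decrease"
    constraint_objective: str
    threshold: float

    def __post_init__(self) -> None:
        if self.direction not in ("increase", "decrease"):
            raise ValueError("direction must be 'increase' or 'decrease'")
        if self.improve_objective == self.constraint_objective:
            raise ValueError("improve and constraint objectives must differ")

    def step_allowed(self, current: float, proposed: float) -> bool:
        """Strict improvement of the improve objective (ties never pass)."""
        if self.direction == "increase":
            return proposed > current
        return proposed < current

    def constraint_ok(self, value: float) -> bool:
        return value >= self.threshold


@dataclass
class MutationalPath:
    """One walk: visited genotypes (start first) and their activities."""

    genotypes: list
    activities: np.ndarray  # (len(path), K)
    objectives: list = field(default_factory=list)
    seed: int = 0

    @property
    def length(self) -> int:
        """Number of mutational steps (visited nodes minus one)."""
        return len(self.genotypes) - 1

    @property
    def terminal(self):
        return self.genotypes[-1]

    def to_frame(self) -> pd.DataFrame:
        from .genotypes import genotype_string

        df = pd.DataFrame(self.activities, columns=self.objectives)
        df.insert(0, "step", np.arange(len(self.genotypes)))
        df.insert(1, "genotype", [genotype_string(g) for g in self.genotypes])
        return df


def _passing_neighbors(
    landscape: Landscape, g, rule: PathRule
) -> list[tuple[int, ...]]:
    ki = landscape.objectives.index(rule.improve_objective)
    kc = landscape.objectives.index(rule.constraint_objective)
    cur = landscape.activities[genotype_index(g)]
    out = []
    for nb in neighbors(g):
        row = landscape.activities[genotype_index(nb)]
        if rule.step_allowed(cur[ki], row[ki]) and rule.constraint_ok(row[kc]):
            out.append(nb)
    return out


def random_walk(
    landscape: Landscape,
    start,
    rule: PathRule,
    seed: int = 0,
    n_paths: int = 10,
) -> list[MutationalPath]:
    """Draw constrained single-mutation walks from a start genotype.

    Path p uses its own generator seeded ``seed + p`` so individual paths
    are reproducible.  Strict improvement guarantees termination (the
    improve objective changes monotonically over a finite space).
    """
    start = as_genotype(start)
    kc = landscape.objectives.index(rule.constraint_objective)
    if not rule.constraint_ok(landscape.activities[genotype_index(start), kc]):
        raise ValueError("start genotype violates the activity floor")
    paths = []
    for p in range(n_paths):
        rng = np.random.default_rng(seed + p)
        visited = [start]
        current = start
        while True:
            passing = _passing_neighbors(landscape, current, rule)
            if not passing:
                break
            current = passing[rng.integers(len(passing))]
            visited.append(current)
        acts = landscape.activities[[genotype_index(g) for g in visited]]
        paths.append(
            MutationalPath(
                genotypes=visited,
                activities=acts,
                objectives=list(landscape.objectives),
                seed=seed + p,
            )
        )
    return paths


def check_path(landscape: Landscape, path: MutationalPath, rule: PathRule) -> None:
    """Independent post-hoc validation of one path; raises on violation.

    Checks Hamming-1 stepping, strict monotonicity of the improve
    objective, the floor on the constraint objective at every node, and
    that the terminal node is a local optimum under the rule.
    """
    ki = landscape.objectives.index(rule.improve_objective)
    kc = landscape.objectives.index(rule.constraint_objective)
    gts = [as_genotype(g) for g in path.genotypes]
    for a, b in zip(gts, gts[1:]):
        if sum(x != y for x, y in zip(a, b)) != 1:
            raise AssertionError(f"step {a} -> {b} is not a single mutation")
    acts = landscape.activities[[genotype_index(g) for g in gts]]
    diffs = np.diff(acts[:, ki])
    if rule.direction == "increase" and not np.all(diffs > 0):
        raise AssertionError("improve objective is not strictly increasing")
    if rule.direction == "decrease" and not np.all(diffs < 0):
        raise AssertionError("improve objective is not strictly decreasing")
    if not np.all(acts[:, kc] >= rule.threshold):
        raise AssertionError("constraint objective fell below the floor")
    if _passing_neighbors(landscape, gts[-1], rule):
        raise AssertionError("terminal genotype is not a local optimum")


@dataclass
class PathReport:
    """Tabular summary of a batch of walks."""

    table: pd.DataFrame
    fraction_both_enhanced: float


def path_report(paths: list[MutationalPath]) -> PathReport:
    """Terminal genotypes/activities, lengths, and dual-enhancement rate.

    ``fraction_both_enhanced`` is the fraction of paths containing at
    least one visited variant (after the start) that strictly exceeds the
    start in *both* objectives — the signature of a no-trade-off segment.
    """
    if not paths:
        raise ValueError("need at least one path")
    from .genotypes import genotype_string

    rows = []
    n_both = 0
    for i, path in enumerate(paths):
        start_act = path.activities[0]
        later = path.activities[1:]
        both = bool(len(later)) and bool(np.any(np.all(later > start_act, axis=1)))
        n_both += both
        row = {
            "path": i,
            "seed": path.seed,
            "length": path.length,
            "start": genotype_string(path.genotypes[0]),
            "terminal": genotype_string(path.terminal),
            "both_enhanced": both,
        }
        for k, obj in enumerate(path.objectives):
            row[f"terminal_{obj}"] = float(path.activities[-1, k])
        rows.append(row)
    return PathReport(
        table=pd.DataFrame(rows),
        fraction_both_enhanced=n_both / len(paths),
    )
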