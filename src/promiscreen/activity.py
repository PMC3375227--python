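"""The screen's data model: genotypes with per-objective log activities.

An :class:`ActivityTable` maps binary genotypes over M candidate mutations
to measured activities for K objectives (e.g. ``primary`` and
``promiscuous``), stored as log10 specific activities, with optional
standard-error columns named ``<objective>_se``.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .genotypes import as_genotype, genotype_string


@dataclass
class ActivityTable:
    """Genotype -> log10 activity mapping for one or more objectives."""

    genotypes: list
    activities: pd.DataFrame  # one column per objective, plus optional *_se
    objectives: list = field(default_factory=list)

    def __post_init__(self) -> None:
        self.genotypes = [as_genotype(g) for g in self.genotypes]
        if not self.objectives:
            self.objectives = [
                c for c in self.activities.columns if not c.endswith("_se")
            ]
        if len(self.genotypes) != len(self.activities):
            raise ValueError("genotype count does not match activity rows")
        if len(set(self.genotypes)) != len(self.genotypes):
            raise ValueError("duplicate genotypes in activity table")
        vals = self.activities[self.objectives].to_numpy(dtype=float)
        if not np.isfinite(vals).all():
            raise ValueError("activities must be finite")
        lengths = {len(g) for g in self.genotypes}
        if len(lengths) > 1:
            raise ValueError("genotypes differ in length")

    # -- basics ----------------------------------------------------------
    def __len__(self) -> int:
        return len(self.genotypes)

    @property
    def m(self) -> int:
        return len(self.genotypes[0]) if self.genotypes else 0

    def values(self) -> np.ndarray:
        """(n, K) array of log10 activities in objective order."""
        return self.activities[self.objectives].to_numpy(dtype=float)

    def contains(self, genotype) -> bool:
        return as_genotype(genotype) in set(self.genotypes)

    def subset(self, indices) -> "ActivityTable":
        return ActivityTable(
            genotypes=[self.genotypes[i] for i in indices],
            activities=self.activities.iloc[list(indices)].reset_index(drop=True),
            objectives=list(self.objectives),
        )

    def merged_with(self, other: "ActivityTable") -> "ActivityTable":
        """Union of two tables; overlapping genotypes keep this table's rows."""
        if self.objectives != other.objectives:
            raise ValueError("objective sets differ")
        seen = set(self.genotypes)
        new_idx = [i for i, g in enumerate(other.genotypes) if g not in seen]
        return ActivityTable(
            genotypes=self.genotypes + [other.genotypes[i] for i in new_idx],
            activities=pd.concat(
                [self.activities, other.activities.iloc[new_idx]],
                ignore_index=True,
            ),
            objectives=list(self.objectives),
        )

    # -- I/O ---------------------------------------------------------------
    def to_frame(self) -> pd.DataFrame:
        df = self.activities.copy()
        df.insert(0, "genotype", [genotype_string(g) for g in self.genotypes])
        return df

    def write_tsv(self, path) -> None:
        self.to_frame().to_csv(path, sep="\t", index=False)

    @classmethod
    def read_tsv(cls, path, objectives=None) -> "ActivityTable":
        df = pd.read_csv(path, sep="\t", dtype={"genotype": str})
        if "genotype" not in df.columns:
            raise ValueError("activity TSV must have a 'genotype' column")
        genotypes = [as_genotype(g) for g in df.pop("genotype")]
        return cls(genotypes=genotypes, activities=df, objectives=objectives or [])
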