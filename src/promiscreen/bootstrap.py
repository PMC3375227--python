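"""Bootstrap reconstruction of the full combinatorial library.

A single PLS fit to a sparse screen gives one point estimate per library
genotype.  To expose reconstruction uncertainty, the screen table is
resampled with replacement B times; each replica is refitted (its own
LOO-CV latent-count choice) and used to predict the whole 2^M library.
The ensemble of replica predictions feeds the optimistic Pareto
prediction.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np

from .activity import ActivityTable
from .genotypes import enumerate_library
from .pls import DegenerateScalingError, PlsModel, pls_fit, pls_predict

_MAX_REDRAWS = 10


@dataclass
class ReconstructionEnsemble:
    """B bootstrap replicas of full-library activity predictions.

    ``predictions`` has shape (B, 2^M, K); ``genotypes`` is the shared
    enumeration (integer bit order); ``models`` the fitted per-replica
    PLS models (latent counts may differ between replicas).
    """

    genotypes: list
    objectives: list
    predictions: np.ndarray
    models: list
    replica_seeds: list

    @property
    def n_replicas(self) -> int:
        return self.predictions.shape[0]

    def pooled(self) -> tuple[np.ndarray, np.ndarray]:
        """All replica predictions stacked: (B * 2^M, K) plus genotype index."""
        b, n, k = self.predictions.shape
        points = self.predictions.reshape(b * n, k)
        genotype_idx = np.tile(np.arange(n), b)
        return points, genotype_idx


def bootstrap_reconstruct(
    table: ActivityTable,
    b: int = 20,
    seed: int = 0,
    max_lv: int | None = None,
    include_pairs: bool = True,
) -> ReconstructionEnsemble:
    """Resample the screen, refit PLS per replica, predict the full library.

    Each replica draws n rows with replacement (rows sharing a genotype are
    grouped for the replica's leave-one-out cross-validation).  Replicas
    that are degenerate for fitting (e.g. a constant response after
    resampling) are redrawn a bounded number of times.
    """
    if b < 1:
        raise ValueError("need at least one replica")
    n = len(table)
    library = enumerate_library(table.m)
    preds = np.empty((b, len(library), len(table.objectives)))
    models: list[PlsModel] = []
    seeds: list[int] = []
    for rep in range(b):
        rep_seed = seed + rep
        rng = np.random.default_rng(rep_seed)
        model = None
        for attempt in range(_MAX_REDRAWS):
            idx = rng.integers(0, n, size=n)
            replica = _resampled(table, idx)
            try:
                model = pls_fit(
                    replica, max_lv=max_lv, include_pairs=include_pairs
                )
                break
            except (DegenerateScalingError, ValueError):
                continue
        if model is None:
            raise RuntimeError(
                f"replica {rep} remained degenerate after {_MAX_REDRAWS} redraws"
            )
        if attempt:
            warnings.warn(
                f"replica {rep}: {attempt} degenerate redraw(s)", stacklevel=2
            )
        preds[rep] = pls_predict(model, library)
        models.append(model)
        seeds.append(rep_seed)
    return ReconstructionEnsemble(
        genotypes=library,
        objectives=list(table.objectives),
        predictions=preds,
        models=models,
        replica_seeds=seeds,
    )


def _resampled(table: ActivityTable, idx: np.ndarray) -> "ActivityTable":
    """A bootstrap replica; duplicate genotypes allowed (PLS handles groups)."""
    # ActivityTable forbids duplicate genotypes, so a replica is represented
    # as a plain container mimicking the ActivityTable interface.
    return _ReplicaTable(table, idx)


class _ReplicaTable:
    """Resampled view of an ActivityTable (duplicates permitted)."""

    def __init__(self, table: ActivityTable, idx: np.ndarray):
        self.genotypes = [table.genotypes[i] for i in idx]
        self.activities = table.activities.iloc[idx].reset_index(drop=True)
        self.objectives = list(table.objectives)
        self.m = table.m

    def __len__(self) -> int:
        return len(self.genotypes)

    def values(self) -> np.ndarray:
        return self.activities[self.objectives].to_numpy(dtype=float)
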