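"""Synthetic MSAs and activity landscapes with known ground truth.

Every analysis stage in this package is testable without external data:

* :func:`generate_msa` plants signature-coupled columns into a random
  protein alignment — a signature position whose residue identity (e.g.
  H versus P) shifts the residue distribution at chosen columns, the
  statistical structure the coupling analysis is designed to detect;
* :func:`generate_activity_table` draws screen measurements from the
  pairwise-coupling activity model (known main effects and couplings,
  Gaussian noise on log10 activities) and returns the complete noiseless
  landscape alongside, the oracle for every downstream module;
* :func:`paper_scale_scenario` bundles the canonical study geometry:
  M = 10 mutations (1024-variant library), a 29-variant random training
  screen over 2 objectives, and 20 bootstrap replicas.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .activity import ActivityTable
from .alignment import AMINO_ACIDS, AA_INDEX, Alignment
from .genotypes import design_matrix, enumerate_library
from .paths import Landscape


@dataclass(frozen=True)
class PlantedColumn:
    """A column whose residue distribution shifts with the signature.

    In the complement (and background) the column concentrates on the
    ``baseline`` residue; in the signature sub-alignment a fraction
    ``shift`` of that baseline probability mass moves to ``shifted``.
    With ``positive_shift=False`` the column is still signature-coupled
    but the shift runs the *other* way: the complement carries the full
    ``shift`` move while the sub-alignment carries only half of it, so
    the shifted residue (the most frequent non-wild-type residue in the
    sub-alignment) *loses* weight under the signature — a negative-score
    column.
    """

    position: int
    baseline: str
    shifted: str
    shift: float
    positive_shift: bool = True

    def __post_init__(self) -> None:
        if not 0.0 <= self.shift <= 1.0:
            raise ValueError("shift strength must be in [0, 1]")
        if self.baseline == self.shifted:
            raise ValueError("baseline and shifted residues must differ")


@dataclass
class MsaSpec:
    """Specification of a synthetic signature-coupled alignment."""

    n_seq: int = 400
    length: int = 60
    signature_position: int = 34
    sub_residue: str = "H"
    complement_residue: str = "P"
    sub_fraction: float = 0.30
    planted: list = field(default_factory=list)
    conservation: float = 0.9
    background: np.ndarray | None = None  # length-20 distribution
    seed: int = 0

    def __post_init__(self) -> None:
        if self.background is None:
            self.background = np.full(20, 0.05)
        self.background = np.asarray(self.background, dtype=float)
        self.background = self.background / self.background.sum()
        for col in self.planted:
            if col.position == self.signature_position:
                raise ValueError("planted column cannot be the signature position")
            if not 1 <= col.position <= self.length:
                raise ValueError("planted column outside the alignment")
        if not 1 <= self.signature_position <= self.length:
            raise ValueError("signature position outside the alignment")


def _column_distributions(spec: MsaSpec, col: PlantedColumn):
    """(sub, complement) residue distributions for a planted column."""

    def moved(shift: float) -> np.ndarray:
        d = (1.0 - spec.conservation) * spec.background.copy()
        d[AA_INDEX[col.baseline]] += spec.conservation
        m = shift * d[AA_INDEX[col.baseline]]
        d[AA_INDEX[col.baseline]] -= m
        d[AA_INDEX[col.shifted]] += m
        return d

    if col.positive_shift:
        return moved(col.shift), moved(0.0)
    return moved(col.shift / 2.0), moved(col.shift)


def generate_msa(spec: MsaSpec) -> Alignment:
    """Draw an ungapped alignment with planted signature-coupled columns.

    A dedicated reference record ``ref`` (a complement-class sequence with
    the baseline residue at planted columns) is appended so reference
    numbering is the identity map.  Sequence class (sub versus complement)
    is drawn per sequence with probability ``sub_fraction``.
    """
    rng = np.random.default_rng(spec.seed)
    aa = np.frombuffer(AMINO_ACIDS.encode(), dtype="S1").astype("U1")
    n, length = spec.n_seq, spec.length
    is_sub = rng.uniform(size=n) < spec.sub_fraction
    # background columns
    seqs = rng.choice(aa, size=(n, length), p=spec.background)
    sig_col = spec.signature_position - 1
    seqs[is_sub, sig_col] = spec.sub_residue
    seqs[~is_sub, sig_col] = spec.complement_residue
    for col in spec.planted:
        d_sub, d_comp = _column_distributions(spec, col)
        c = col.position - 1
        n_sub = int(is_sub.sum())
        seqs[is_sub, c] = rng.choice(aa, size=n_sub, p=d_sub)
        seqs[~is_sub, c] = rng.choice(aa, size=n - n_sub, p=d_comp)
    ids = [f"seq{i}" for i in range(n)]
    sequences = ["".join(row) for row in seqs]
    # reference: complement class, baseline residues at planted columns
    ref = list("".join(rng.choice(aa, size=length, p=spec.background)))
    ref[sig_col] = spec.complement_residue
    for col in spec.planted:
        ref[col.position - 1] = col.baseline
    ids.append("ref")
    sequences.append("".join(ref))
    return Alignment(ids=ids, sequences=sequences, reference_id="ref")


def write_fasta(aln: Alignment, path) -> None:
    """Write an alignment as aligned FASTA (deterministic byte layout)."""
    with open(path, "w") as fh:
        for sid, seq in zip(aln.ids, aln.sequences):
            fh.write(f">{sid}\n{seq}\n")


@dataclass
class LandscapeSpec:
    """Ground-truth pairwise-coupling model for synthetic activity data."""

    m: int = 10
    objectives: list = field(default_factory=lambda: ["primary", "promiscuous"])
    main_effects: np.ndarray | None = None  # (M, K)
    couplings: np.ndarray | None = None  # (M(M-1)/2, K), lexicographic
    background_activity: np.ndarray | None = None  # (K,), log10 units
    noise_sd: float = 0.1
    seed: int = 0

    def __post_init__(self) -> None:
        k = len(self.objectives)
        n_pairs = self.m * (self.m - 1) // 2
        if self.main_effects is None:
            self.main_effects = np.zeros((self.m, k))
        if self.couplings is None:
            self.couplings = np.zeros((n_pairs, k))
        if self.background_activity is None:
            self.background_activity = np.zeros(k)
        self.main_effects = np.asarray(self.main_effects, dtype=float)
        self.couplings = np.asarray(self.couplings, dtype=float)
        self.background_activity = np.asarray(self.background_activity, dtype=float)
        if self.main_effects.shape != (self.m, k):
            raise ValueError("main_effects must be (M, K)")
        if self.couplings.shape != (n_pairs, k):
            raise ValueError(f"couplings must be ({n_pairs}, K)")
        if self.background_activity.shape != (k,):
            raise ValueError("background_activity must be (K,)")
        if self.noise_sd < 0:
            raise ValueError("noise sd must be non-negative")

    def coefficient_matrix(self) -> np.ndarray:
        """(M + M(M-1)/2, K) stacked true coefficients."""
        return np.vstack([self.main_effects, self.couplings])


def random_landscape_spec(
    m: int = 10,
    n_couplings: int = 5,
    main_scale: float = 0.5,
    coupling_scale: float = 0.3,
    noise_sd: float = 0.1,
    seed: int = 0,
    objectives=("primary", "promiscuous"),
    background_activity=None,
) -> LandscapeSpec:
    """Random ground truth: M main effects ~ U(-main_scale, main_scale)
    per objective, ``n_couplings`` nonzero pair couplings
    ~ U(-coupling_scale, coupling_scale), the rest zero."""
    rng = np.random.default_rng(seed)
    k = len(objectives)
    n_pairs = m * (m - 1) // 2
    main = rng.uniform(-main_scale, main_scale, size=(m, k))
    couplings = np.zeros((n_pairs, k))
    which = rng.choice(n_pairs, size=min(n_couplings, n_pairs), replace=False)
    couplings[which] = rng.uniform(-coupling_scale, coupling_scale, size=(len(which), k))
    return LandscapeSpec(
        m=m,
        objectives=list(objectives),
        main_effects=main,
        couplings=couplings,
        background_activity=background_activity,
        noise_sd=noise_sd,
        seed=seed,
    )


def true_landscape(spec: LandscapeSpec) -> Landscape:
    """Noiseless activities of every genotype under the ground-truth model."""
    library = enumerate_library(spec.m)
    X = design_matrix(library, include_pairs=True)
    acts = spec.background_activity + X @ spec.coefficient_matrix()
    return Landscape(m=spec.m, objectives=list(spec.objectives), activities=acts)


def generate_activity_table(
    spec: LandscapeSpec,
    genotypes=None,
    n_random: int | None = None,
    seed: int | None = None,
) -> tuple[ActivityTable, Landscape]:
    """Noisy screen measurements plus the complete noiseless landscape.

    Either pass explicit ``genotypes`` or ``n_random`` distinct genotypes
    drawn uniformly from the library.  Noise is homoscedastic Gaussian on
    the log10 activities.
    """
    if seed is None:
        seed = spec.seed
    rng = np.random.default_rng(seed)
    landscape = true_landscape(spec)
    library = enumerate_library(spec.m)
    if genotypes is None:
        if n_random is None:
            raise ValueError("pass genotypes or n_random")
        if n_random > len(library):
            raise ValueError("n_random exceeds the library size")
        idx = rng.choice(len(library), size=n_random, replace=False)
        genotypes = [library[i] for i in sorted(idx)]
    X = design_matrix(genotypes, include_pairs=True)
    clean = spec.background_activity + X @ spec.coefficient_matrix()
    noisy = clean + rng.normal(0.0, spec.noise_sd, size=clean.shape)
    table = ActivityTable(
        genotypes=list(genotypes),
        activities=pd.DataFrame(noisy, columns=spec.objectives),
        objectives=list(spec.objectives),
    )
    return table, landscape


@dataclass
class ScenarioBundle:
    """The canonical study geometry, ready for end-to-end runs."""

    spec: LandscapeSpec
    table: ActivityTable  # 29-variant training screen
    landscape: Landscape  # noiseless 1024-genotype ground truth
    n_bootstrap: int = 20


def paper_scale_scenario(seed: int = 0) -> ScenarioBundle:
    """M=10 library, 29-variant 2-objective screen, 20 bootstrap replicas.

    Ground truth uses 10 main effects ~ U(-0.5, 0.5), 5 nonzero pairwise
    couplings ~ U(-0.3, 0.3) and noise sd 0.1 on log10 activities;
    background log10 activities are 0 (primary) and -1 (promiscuous),
    emulating a strong primary activity and a weak promiscuous one.
    """
    spec = random_landscape_spec(
        m=10,
        n_couplings=5,
        noise_sd=0.1,
        seed=seed,
        background_activity=np.array([0.0, -1.0]),
    )
    table, landscape = generate_activity_table(spec, n_random=29, seed=seed + 1)
    return ScenarioBundle(spec=spec, table=table, landscape=landscape, n_bootstrap=20)
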