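"""Gapped protein alignments with reference-based position numbering.

The statistical coupling machinery in :mod:`promiscreen.sca` operates on a
multiple sequence alignment (MSA) together with a *reference* sequence whose
non-gap columns define the position numbering (1-based).  This module holds
the alignment container, FASTA input, the signature-based sub-alignment
split, and positional amino-acid frequencies.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from Bio import AlignIO

AMINO_ACIDS = "ACDEFGHIKLMNPQRSTVWY"
AA_INDEX = {aa: i for i, aa in enumerate(AMINO_ACIDS)}
GAP_CHARS = frozenset("-.")


class MalformedAlignmentError(ValueError):
    """Sequences of unequal length, or otherwise not an alignment."""


class EmptyPerturbationError(ValueError):
    """A signature criterion matched no sequences; SCA is undefined."""


@dataclass
class Alignment:
    """An aligned set of gapped protein sequences.

    Parameters
    ----------
    ids
        Sequence identifiers, in file order.
    sequences
        Upper-case gapped sequences, all of equal length.
    reference_id
        Identifier of the sequence that defines position numbering.
    reference_sequence
        The gapped reference sequence.  Needed only when the reference
        record itself is not among ``ids`` (e.g. in a sub-alignment);
        otherwise it is looked up.
    """

    ids: list[str]
    sequences: list[str]
    reference_id: str
    reference_sequence: str | None = None
    column_map: dict[int, int] = field(init=False)  # alignment col -> ref pos
    position_map: dict[int, int] = field(init=False)  # ref pos -> alignment col

    def __post_init__(self) -> None:
        if not self.sequences and self.reference_sequence is None:
            raise MalformedAlignmentError("alignment contains no sequences")
        lengths = {len(s) for s in self.sequences}
        if len(lengths) > 1:
            raise MalformedAlignmentError(
                f"unequal sequence lengths: {sorted(lengths)}"
            )
        if self.reference_sequence is None:
            if self.reference_id not in self.ids:
                raise KeyError(
                    f"reference sequence {self.reference_id!r} not found"
                )
            self.reference_sequence = self.sequences[
                self.ids.index(self.reference_id)
            ]
        if self.sequences and len(self.reference_sequence) != len(
            self.sequences[0]
        ):
            raise MalformedAlignmentError(
                "reference sequence length does not match alignment"
            )
        self.column_map = {}
        pos = 0
        for col, ch in enumerate(self.reference_sequence):
            if ch not in GAP_CHARS:
                pos += 1
                self.column_map[col] = pos
        self.position_map = {p: c for c, p in self.column_map.items()}

    # -- basic accessors -------------------------------------------------
    def __len__(self) -> int:
        return len(self.sequences)

    @property
    def n_columns(self) -> int:
        return len(self.reference_sequence or self.sequences[0])

    @property
    def reference(self) -> str:
        return self.reference_sequence  # type: ignore[return-value]

    def column(self, col: int) -> list[str]:
        return [s[col] for s in self.sequences]

    def column_at_position(self, position: int) -> list[str]:
        """Residues at a reference position (alignment column lookup)."""
        return self.column(self.position_map[position])

    def reference_residue(self, position: int) -> str:
        return self.reference[self.position_map[position]]

    def subset(self, indices: list[int]) -> "Alignment":
        """New alignment restricted to the given record indices.

        The reference numbering is inherited; the reference record itself
        need not be among the selected records.
        """
        return Alignment(
            ids=[self.ids[i] for i in indices],
            sequences=[self.sequences[i] for i in indices],
            reference_id=self.reference_id,
            reference_sequence=self.reference,
        )

    def identity_to_reference(self) -> np.ndarray:
        """Fraction of identical residues to the reference over mapped columns."""
        cols = sorted(self.column_map)
        ref = self.reference
        out = np.zeros(len(self.sequences))
        for i, seq in enumerate(self.sequences):
            match = sum(seq[c] == ref[c] for c in cols)
            out[i] = match / len(cols)
        return out

    def filter_identity(self, min_identity: float = 0.3) -> "Alignment":
        """Drop sequences below a given identity to the reference."""
        ident = self.identity_to_reference()
        keep = [i for i in range(len(self.sequences)) if ident[i] >= min_identity]
        return self.subset(keep)


def read_alignment(path, reference_id: str, format: str = "fasta") -> Alignment:
    """Read an aligned FASTA file and build the reference numbering map."""
    try:
        msa = AlignIO.read(str(path), format)
    except ValueError as exc:  # Bio raises ValueError on ragged input
        raise MalformedAlignmentError(str(exc)) from exc
    ids = [rec.id for rec in msa]
    seqs = [str(rec.seq).upper() for rec in msa]
    return Alignment(ids, seqs, reference_id)


@dataclass(frozen=True)
class SignatureCriterion:
    """A functional signature: residue identity at one reference position.

    ``residue_set`` selects the perturbed sub-alignment (e.g. ``{"H"}`` for
    folding-catalyst-like sequences), ``complement_residue_set`` the
    complementary class (e.g. ``{"P"}`` for reductase-like sequences).
    """

    position: int
    residue_set: frozenset
    complement_residue_set: frozenset

    def __post_init__(self) -> None:
        rs = frozenset(self.residue_set)
        cs = frozenset(self.complement_residue_set)
        object.__setattr__(self, "residue_set", rs)
        object.__setattr__(self, "complement_residue_set", cs)
        if not rs or not cs:
            raise ValueError("residue sets must be non-empty")
        if rs & cs:
            raise ValueError("residue sets must be disjoint")


def select_subalignment(
    aln: Alignment, crit: SignatureCriterion
) -> tuple[Alignment, Alignment]:
    """Split an alignment by the residue identity at the signature position.

    Sequences whose residue at the signature position is in neither set
    (including gaps) belong to neither output.
    """
    if crit.position not in aln.position_map:
        raise KeyError(f"position {crit.position} not mapped in alignment")
    col = aln.position_map[crit.position]
    sub_idx, comp_idx = [], []
    for i, seq in enumerate(aln.sequences):
        ch = seq[col]
        if ch in crit.residue_set:
            sub_idx.append(i)
        elif ch in crit.complement_residue_set:
            comp_idx.append(i)
    if not sub_idx:
        raise EmptyPerturbationError(
            f"no sequence carries {sorted(crit.residue_set)} at position "
            f"{crit.position}; the perturbation is undefined"
        )
    return aln.subset(sub_idx), aln.subset(comp_idx)


@dataclass
class FrequencyTable:
    """Per-position amino-acid frequencies (gaps excluded, pseudocounted).

    ``freqs`` has one row per mapped reference position and 20 columns in
    :data:`AMINO_ACIDS` order; each row sums to 1.  ``counts`` are the raw
    non-gap residue counts.  Positions whose column is entirely gaps are
    listed in ``all_gap_positions`` and carry NaN rows.
    """

    positions: np.ndarray
    freqs: np.ndarray
    counts: np.ndarray
    n_effective: np.ndarray
    pseudocount: float
    all_gap_positions: frozenset = frozenset()
    high_gap_positions: frozenset = frozenset()

    def row(self, position: int) -> np.ndarray:
        idx = int(np.searchsorted(self.positions, position))
        if idx >= len(self.positions) or self.positions[idx] != position:
            raise KeyError(f"position {position} not in table")
        return self.freqs[idx]

    def frequency(self, position: int, residue: str) -> float:
        return float(self.row(position)[AA_INDEX[residue]])


def positional_frequencies(
    aln: Alignment, pseudocount: float = 0.5, high_gap_fraction: float = 0.5
) -> FrequencyTable:
    """Gap-excluded residue frequencies with a symmetric pseudocount.

    f_{i,x} = (n_{i,x} + pc) / (N_i + 20 pc) over the 20 standard residues;
    columns with more than ``high_gap_fraction`` gaps are flagged, columns
    with only gaps are excluded from downstream analyses.
    """
    if pseudocount < 0:
        raise ValueError("pseudocount must be non-negative")
    positions = np.array(sorted(aln.position_map), dtype=int)
    n_seq = len(aln)
    counts = np.zeros((len(positions), 20))
    n_eff = np.zeros(len(positions))
    all_gap, high_gap = set(), set()
    for r, pos in enumerate(positions):
        col = aln.column_at_position(int(pos))
        for ch in col:
            if ch in AA_INDEX:
                counts[r, AA_INDEX[ch]] += 1
        n_eff[r] = counts[r].sum()
        if n_eff[r] == 0:
            all_gap.add(int(pos))
        elif 1.0 - n_eff[r] / n_seq > high_gap_fraction:
            high_gap.add(int(pos))
    with np.errstate(invalid="ignore", divide="ignore"):
        freqs = (counts + pseudocount) / (n_eff[:, None] + 20.0 * pseudocount)
    freqs[n_eff == 0] = np.nan
    return FrequencyTable(
        positions=positions,
        freqs=freqs,
        counts=counts,
        n_effective=n_eff,
        pseudocount=pseudocount,
        all_gap_positions=frozenset(all_gap),
        high_gap_positions=frozenset(high_gap),
    )
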