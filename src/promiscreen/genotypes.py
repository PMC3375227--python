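"""Binary combinatorial genotypes and the pairwise-coupling design matrix.

A variant in a combinatorial mutation library over M candidate mutations is
a bit vector delta = (delta_1 ... delta_M), delta_i = 1 when mutation i is
present.  The pairwise-epistasis activity model expands each genotype into
M main-effect indicators plus M(M-1)/2 pair indicators
delta_ij = delta_i * delta_j (i < j, lexicographic order).
"""

from __future__ import annotations

import itertools

import numpy as np

MAX_LIBRARY_M = 20


def as_genotype(g) -> tuple[int, ...]:
    """Normalize a genotype given as tuple/list/array/bitstring to a tuple."""
    if isinstance(g, str):
        if not set(g) <= {"0", "1"}:
            raise ValueError(f"genotype bitstring must be over 0/1: {g!r}")
        return tuple(int(c) for c in g)
    t = tuple(int(v) for v in g)
    if not set(t) <= {0, 1}:
        raise ValueError(f"genotype entries must be 0/1: {t}")
    return t


def genotype_string(g) -> str:
    return "".join(str(b) for b in as_genotype(g))


def enumerate_library(m: int) -> list[tuple[int, ...]]:
    """All 2^M genotypes, ordered by integer value (bit 1 least significant)."""
    if m < 0:
        raise ValueError("M must be non-negative")
    if m > MAX_LIBRARY_M:
        raise ValueError(
            f"M={m} would enumerate {2**m} genotypes; cap is M={MAX_LIBRARY_M}. "
            "Work with an explicit genotype subset instead."
        )
    out = []
    for value in range(2**m):
        out.append(tuple((value >> i) & 1 for i in range(m)))
    return out


def genotype_index(g) -> int:
    """Integer value of a genotype (the position in enumerate_library order)."""
    t = as_genotype(g)
    return sum(b << i for i, b in enumerate(t))


def pair_order(m: int) -> list[tuple[int, int]]:
    """Lexicographic (i, j) order of the pair-indicator columns (0-based)."""
    return list(itertools.combinations(range(m), 2))


def design_matrix(genotypes, include_pairs: bool = True) -> np.ndarray:
    """Binary design: M main-effect columns, then M(M-1)/2 pair columns.

    Rows follow the input genotype order; all entries are 0/1.
    """
    gts = [as_genotype(g) for g in genotypes]
    if not gts:
        raise ValueError("no genotypes given")
    m = len(gts[0])
    if any(len(g) != m for g in gts):
        raise ValueError("genotypes differ in length")
    main = np.array(gts, dtype=float)
    if not include_pairs:
        return main
    pairs = pair_order(m)
    pair_block = np.empty((len(gts), len(pairs)))
    for c, (i, j) in enumerate(pairs):
        pair_block[:, c] = main[:, i] * main[:, j]
    return np.hstack([main, pair_block])


def neighbors(g) -> list[tuple[int, ...]]:
    """The M genotypes at Hamming distance 1 (one mutation toggled)."""
    t = as_genotype(g)
    out = []
    for i in range(len(t)):
        flipped = list(t)
        flipped[i] = 1 - flipped[i]
        out.append(tuple(flipped))
    return out
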