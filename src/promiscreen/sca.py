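"""Function-targeted statistical coupling analysis (SCA).

SCA asks which alignment positions shift their amino-acid statistics when
the alignment is restricted to sequences carrying a functional signature
residue (here, the sub-alignment defined by a histidine-like residue at a
signature position versus the proline-like complement).  Positions whose
distributions shift strongly are candidate members of a co-evolving network
linked to the signature's function.

Two per-position association measures are provided:

* a *statistical free energy* in arbitrary kT* units, comparing
  binomial-weighted positional probabilities between the sub-alignment and
  the full alignment (the classical SCA form), with a simpler
  frequency-log-ratio variant available;
* a *covariance* score sigma, the root-sum-square difference of residue
  frequencies between sub-alignment and complement, used as an independent
  robustness cross-check on the SCA ranking.

On top of the per-position ranking, :func:`gamma_score` scores a specific
substitution wild-type -> X at a position by how strongly the signature
shifts the statistics toward residue X, and
:func:`top_candidate_mutations` assembles the ranked mutation shortlist.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass

import numpy as np
from scipy.special import gammaln

from .alignment import (
    AMINO_ACIDS,
    AA_INDEX,
    Alignment,
    FrequencyTable,
    SignatureCriterion,
    positional_frequencies,
    select_subalignment,
)

#: Virtual alignment size used to put sub- and full-alignment binomial
#: probabilities on a common footing (classical SCA convention).
VIRTUAL_N = 100


class SubalignmentTooSmallError(ValueError):
    """Perturbed sub-alignment too small for stable statistics."""


@dataclass
class ScaResult:
    """Per-position coupling statistics for one signature perturbation.

    ``energies`` are statistical free energies in kT* units (kT* = 1);
    ``sigma`` the covariance cross-check values.  The signature position
    itself is excluded.
    """

    positions: np.ndarray
    energies: np.ndarray
    sigma: np.ndarray
    criterion: SignatureCriterion
    n_sub: int
    n_full: int

    def ranked_positions(self) -> np.ndarray:
        """Positions sorted by decreasing statistical energy."""
        order = np.argsort(-self.energies, kind="stable")
        return self.positions[order]

    def energy_at(self, position: int) -> float:
        idx = np.flatnonzero(self.positions == position)
        if idx.size == 0:
            raise KeyError(f"position {position} not scored")
        return float(self.energies[idx[0]])

    def to_frame(self):
        import pandas as pd

        return pd.DataFrame(
            {
                "position": self.positions,
                "ddg_stat": self.energies,
                "sigma": self.sigma,
            }
        )


@dataclass(frozen=True)
class MutationCandidate:
    """A nominated substitution wild-type (Ec) -> X at one position."""

    position: int
    wild_type: str
    target: str
    sca_energy: float
    gamma_score: float
    rank: int


def _background_frequencies(freq_full: FrequencyTable) -> np.ndarray:
    """Mean residue frequencies over all mapped, non-all-gap columns."""
    ok = ~np.isnan(freq_full.freqs).any(axis=1)
    bg = freq_full.freqs[ok].mean(axis=0)
    return bg / bg.sum()


def _log_binomial_prob(freqs: np.ndarray, background: np.ndarray) -> np.ndarray:
    """Log binomial weight of observing composition ``freqs`` at a column.

    The column composition is rescaled to a virtual alignment of
    ``VIRTUAL_N`` sequences, and the count of each residue x is weighted by
    the binomial likelihood of drawing it from the background frequency.
    The continuous (gamma-function) extension of the binomial pmf keeps the
    expression smooth in the fractional counts.
    """
    n = float(VIRTUAL_N)
    k = np.clip(freqs, 1e-12, 1 - 1e-12) * n
    g = np.clip(background, 1e-12, 1 - 1e-12)
    return (
        gammaln(n + 1.0)
        - gammaln(k + 1.0)
        - gammaln(n - k + 1.0)
        + k * np.log(g)
        + (n - k) * np.log(1.0 - g)
    )


def sca_statistical_energy(
    aln: Alignment,
    crit: SignatureCriterion,
    pseudocount: float = 0.5,
    method: str = "binomial",
    min_sub_size: int = 20,
    force: bool = False,
    kt_star: float = 1.0,
) -> ScaResult:
    """Statistical free energies of coupling to the signature position.

    For each mapped position i (other than the signature position) the
    energy is

        ddG_stat(i) = kT* sqrt( sum_x [ ln P_x(i | sub) - ln P_x(i | full) ]^2 )

    where, for ``method="binomial"``, P_x is the binomial weight of the
    observed residue composition in a virtual 100-sequence alignment given
    background residue frequencies estimated from the full MSA (raw
    frequencies: the binomial weight is already defined at zero counts, and
    a fixed pseudocount would distort small sub-alignments); for
    ``method="logratio"`` P_x is the pseudocounted frequency f_{i,x}.
    Identical sub- and full-alignment compositions give zero energy either
    way.

    The covariance cross-check sigma (root-sum-square frequency difference
    between sub-alignment and complement) is computed alongside.
    """
    if method not in ("binomial", "logratio"):
        raise ValueError(f"unknown SCA method {method!r}")
    sub, comp = select_subalignment(aln, crit)
    if len(sub) < min_sub_size:
        msg = (
            f"sub-alignment has {len(sub)} sequences, below the minimum "
            f"{min_sub_size}; statistics will be noisy"
        )
        if not force:
            raise SubalignmentTooSmallError(msg)
        warnings.warn(msg, stacklevel=2)

    # raw frequencies drive the binomial weights; pseudocounted ones the
    # logratio variant and the sigma cross-check
    pc = 0.0 if method == "binomial" else pseudocount
    freq_full = positional_frequencies(aln, pc)
    freq_sub = positional_frequencies(sub, pc)
    freq_comp = positional_frequencies(comp, pseudocount) if len(comp) else None
    freq_sub_pc = positional_frequencies(sub, pseudocount)

    keep = [
        i
        for i, p in enumerate(freq_full.positions)
        if int(p) != crit.position and int(p) not in freq_full.all_gap_positions
        and int(p) not in freq_sub.all_gap_positions
    ]
    positions = freq_full.positions[keep]
    f_full = freq_full.freqs[keep]
    f_sub = freq_sub.freqs[keep]

    if method == "binomial":
        bg = _background_frequencies(freq_full)
        lp_sub = _log_binomial_prob(f_sub, bg)
        lp_full = _log_binomial_prob(f_full, bg)
    else:
        lp_sub = np.log(f_sub)
        lp_full = np.log(f_full)
    energies = kt_star * np.sqrt(((lp_sub - lp_full) ** 2).sum(axis=1))

    if freq_comp is not None:
        f_comp = freq_comp.freqs[keep]
        sigma = np.sqrt(np.nansum((freq_sub_pc.freqs[keep] - f_comp) ** 2, axis=1))
    else:
        sigma = np.full(len(positions), np.nan)

    return ScaResult(
        positions=positions.astype(int),
        energies=energies,
        sigma=sigma,
        criterion=crit,
        n_sub=len(sub),
        n_full=len(aln),
    )


def covariance_sigma(
    aln: Alignment,
    crit: SignatureCriterion,
    pseudocount: float = 0.5,
    min_sub_size: int = 20,
    force: bool = False,
) -> ScaResult:
    """Covariance-style association sigma between signature and each position.

    sigma(i) = sqrt( sum_x [ f_{i,x | sub} - f_{i,x | complement} ]^2 ).

    Returned inside an :class:`ScaResult` (the ``sigma`` field; ``energies``
    carries the companion SCA values so the two rankings can be compared
    directly, mirroring the covariance robustness check).
    """
    return sca_statistical_energy(
        aln, crit, pseudocount=pseudocount, min_sub_size=min_sub_size, force=force
    )


def gamma_score(
    freq_sub: FrequencyTable,
    freq_comp: FrequencyTable,
    position: int,
    wild_type: str,
    target: str,
) -> float:
    """Score how strongly the signature shifts statistics toward residue X.

    Gamma_{Ec->X} = ln( f_{X,H} / f_{X,P} ) - ln( f_{Ec,H} / f_{Ec,P} ),

    the log odds ratio of target X versus wild-type Ec between the
    signature sub-alignment (H) and its complement (P).  Gamma > 0 exactly
    when the signature shifts relative weight from Ec toward X; it vanishes
    when the two distributions coincide and flips sign when sub-alignment
    and complement are swapped.
    """
    if wild_type == target:
        raise ValueError("target residue must differ from the wild type")
    f_sub = freq_sub.row(position)
    f_comp = freq_comp.row(position)
    if np.isnan(f_sub).any() or np.isnan(f_comp).any():
        raise ValueError(f"frequencies undefined at position {position}")
    fx_h = f_sub[AA_INDEX[target]]
    fx_p = f_comp[AA_INDEX[target]]
    fe_h = f_sub[AA_INDEX[wild_type]]
    fe_p = f_comp[AA_INDEX[wild_type]]
    return math.log(fx_h / fx_p) - math.log(fe_h / fe_p)


def most_frequent_non_wildtype(
    freq_sub: FrequencyTable, position: int, wild_type: str
) -> str:
    """Most frequent residue other than the wild type in the sub-alignment.

    Ties are broken alphabetically by one-letter code.
    """
    row = freq_sub.row(position).copy()
    row[AA_INDEX[wild_type]] = -np.inf
    best = np.max(row)
    # alphabetical tie-break: AMINO_ACIDS is alphabetical, argmax takes first
    return AMINO_ACIDS[int(np.argmax(row == best))]


def top_candidate_mutations(
    aln: Alignment,
    crit: SignatureCriterion,
    n_top: int = 13,
    pseudocount: float = 0.5,
    method: str = "binomial",
    min_sub_size: int = 20,
    force: bool = False,
) -> list[MutationCandidate]:
    """Nominate substitutions at the top-ranked coupled positions.

    The ``n_top`` positions with the highest SCA statistical energies are
    taken; at each, the target residue X is the most frequent non-wild-type
    residue in the signature sub-alignment, and the candidate is retained
    only if its Gamma score is positive (the signature shifts statistics
    toward X).  Candidates are ranked by decreasing statistical energy.
    """
    if n_top <= 0:
        return []
    result = sca_statistical_energy(
        aln,
        crit,
        pseudocount=pseudocount,
        method=method,
        min_sub_size=min_sub_size,
        force=force,
    )
    sub, comp = select_subalignment(aln, crit)
    freq_sub = positional_frequencies(sub, pseudocount)
    freq_comp = positional_frequencies(comp, pseudocount)
    order = np.argsort(-result.energies, kind="stable")[:n_top]
    candidates: list[MutationCandidate] = []
    rank = 0
    for idx in order:
        pos = int(result.positions[idx])
        wt = aln.reference_residue(pos)
        if wt not in AA_INDEX:
            continue  # reference ambiguous/gapped here; cannot name a mutation
        try:
            x = most_frequent_non_wildtype(freq_sub, pos, wt)
            gam = gamma_score(freq_sub, freq_comp, pos, wt, x)
        except (KeyError, ValueError):
            continue
        if gam > 0:
            rank += 1
            candidates.append(
                MutationCandidate(
                    position=pos,
                    wild_type=wt,
                    target=x,
                    sca_energy=float(result.energies[idx]),
                    gamma_score=gam,
                    rank=rank,
                )
            )
    return candidates


def candidates_to_frame(candidates: list[MutationCandidate]):
    import pandas as pd

    return pd.DataFrame(
        [
            {
                "position": c.position,
                "wild_type": c.wild_type,
                "target": c.target,
                "sca_energy": c.sca_energy,
                "gamma": c.gamma_score,
                "rank": c.rank,
            }
            for c in candidates
        ]
    )
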