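# Methods

This note records the models implemented in `promiscreen`, the
conventions and defaults chosen where the design was genuinely open, and
what the synthetic-data tests do and do not establish about real data.

## Statistical coupling analysis

**Model.**  The alignment is split at a *signature position* into a
sub-alignment (sequences carrying the signature residue set, e.g. His)
and its complement (e.g. Pro); sequences with any other residue or a gap
there belong to neither.  For every other mapped position the statistical
free energy is

    ddG_stat(i) = kT* * sqrt( sum_x [ ln P_x(i|sub) - ln P_x(i|full) ]^2 )

with kT* = 1 (the scale is arbitrary).  By default P_x is the
binomial weight of the observed residue composition, rescaled to a
virtual alignment of 100 sequences, under a background distribution
estimated as the mean per-column residue frequency of the input MSA
itself (no external frequency table; the analysis is self-contained).
The binomial weight is evaluated through its gamma-function (continuous)
extension so fractional virtual counts pose no problem, and uses **raw**
frequencies: the weight is well defined at zero counts, and adding a
fixed pseudocount would systematically distort small sub-alignments.
A simpler variant (`method="logratio"`) replaces P_x by the
pseudocounted frequency itself.

**Properties worth knowing.**  The energy is zero exactly when sub- and
full-alignment compositions coincide, and is invariant to record order
and labels.  Its sampling variance grows with column conservation: a
highly conserved column shows larger chance fluctuations of ddG_stat
than a uniform column of the same size.  Comparisons of planted signals
against null columns are therefore only meaningful between columns of
matched conservation, which is how the test suite frames them.

**Covariance cross-check.**  sigma(i) = sqrt( sum_x [f_{i,x|sub} -
f_{i,x|comp}]^2 ) is computed alongside as an independent association
measure; agreement of the two rankings (Spearman, typically ~0.7-0.8 on
synthetic alignments) is the robustness argument for tolerating the
ambiguity in the exact binomial background.

**Substitution score.**  At a candidate position with wild-type residue
Ec, the target X is the most frequent non-Ec residue in the signature
sub-alignment (ties broken alphabetically by one-letter code).  The
score is the log odds ratio

    Gamma_{Ec->X} = ln( f_{X,H} / f_{X,P} ) - ln( f_{Ec,H} / f_{Ec,P} )

which is zero for identical class distributions, antisymmetric under
swapping the classes, and positive exactly when the signature shifts
relative weight from Ec toward X.  Candidates with Gamma <= 0 are
dropped; survivors are ranked by ddG_stat.

**Defaults.**  Pseudocount 0.5 (Jeffreys-like) wherever frequencies
enter logarithms; gaps excluded from the 20-residue normalization;
columns with > 50% gaps flagged, all-gap columns excluded; minimum
sub-alignment size 20 (refusal below, overridable with `force=True`);
optional identity-to-reference prefilter (default off — the MSA is an
input, already curated by its provider).

## Pairwise-coupling activity model and PLS

Variant log10 activities follow

    A^k(delta) = const^k + sum_i delta_i p_i^k + sum_{i<j} delta_i delta_j p_ij^k

per objective k.  Conventions:

* **Responses auto-scaled** per objective (mean subtracted, divided by
  the ddof=1 standard deviation); a zero-variance response is an error.
* **Predictors centered but not variance-scaled.**  The columns are
  binary indicators; variance scaling would overweight rare pair
  columns.
* **No explicit intercept column.**  Mean-centering supplies the
  intercept implicitly; the back-transformed model reports it
  explicitly (the background variant's activity is not zero).
* **Joint multi-response fit** by default (one NIPALS model for all
  objectives, matching joint auto-scaling of the dependent variables);
  `joint=False` fits objectives independently.
* **Latent count** chosen to minimize the mean leave-one-out squared
  error in auto-scaled response units, averaged over objectives.
  Leave-one-out groups are *distinct genotypes*: rows duplicated by
  bootstrap resampling leave together, otherwise LOO is optimistic.
  `max_lv` defaults to min(n-2, 15).
* **Log base 10** throughout; any base is consistent if used
  consistently.

NIPALS extracts components to a relative convergence tolerance of 1e-12
(up to 1000 iterations) and stops early when residual covariance is
exhausted; coefficients at every component count come from the rotation
recursion B_L = W (P'W)^{-1} C', so the whole nested path is available
for cross-validation at one fit per fold.  With L = rank(X) on an
overdetermined full-rank problem the coefficients equal the ordinary
least-squares solution — the suite verifies this against the normal
equations and, at fixed L, against an independent reference PLS
implementation.

**Identifiability caveat.**  With 29 training rows the centered pairwise
design (55 columns) has rank at most 28, so no method can pin down the
full coefficient vector; PLS regularizes toward the dominant covariance
directions.  The noiseless *additive* ground truth is exactly
recoverable only when the design is built without pair columns
(`include_pairs=False`, a full-rank n > p problem), and that is the
configuration the exact-recovery tests use.  With the pairwise design
the realistic claim — and the one the stochastic tests make — is
rank-correlation recovery (median full-library Spearman >= 0.8 under
10 main effects, 5 couplings, noise sd 0.1, 29 training variants).

## Bootstrap reconstruction and optimistic Pareto prediction

Each of B (default 20) replicas resamples the n screen rows with
replacement, refits PLS (its own LOO-CV latent count — replicas differ),
and predicts all 2^M genotypes.  Degenerate replicas (e.g. constant
response after resampling) are redrawn up to 10 times.  Replica b uses
seed `seed + b`.

Dominance is **strict in every objective** (all objectives maximized);
tied points coexist on the front.  A weak-dominance mode exists but is
off by default.  Front extraction uses a decreasing-coordinate-sum sweep
(a strict dominator always has a strictly larger sum, and dominance is
transitive, so checking against current front members suffices), with a
vectorized fast path for two objectives; the test suite validates both
against an all-pairs brute-force oracle.

The optimistic Pareto prediction pools all B x 2^M replica predictions
and takes the non-dominated set of the pooled cloud; a genotype
qualifies if any replica places it there.  (An alternative union of
per-replica fronts is available via `pool=False`; pooling is the
default reading of "non-dominated solutions in the ensemble".)
`screening_round` emits the not-yet-measured candidates as a request
sheet; merging measured results and repeating implements the iterative
screen.

Pareto analysis and screening operate on log activities; the
trade-off-line fit, the max-connecting reference line and the triangular
occupancy statistic operate on linear activities.  The scale is an
explicit tag on every point set and mismatches raise errors.  The
triangle statistic counts points with promiscuous <= line(primary) +
tolerance (tolerance 0 by default: "at or below") and reports the
order-of-magnitude chance bound (1/2)^count; its default reference line
connects the observed per-objective maxima, x/x_max + y/y_max = 1.

## Conformational-diversity simulations

A variant is an equilibrium mixture of conformations with activity
coefficient pairs (c_primary, c_promiscuous) >= 0.  Statistical weights
w_i ~ U[0,1] are drawn independently per conformation and variant; mol
fractions X(a_i) = w_i / sum(w) sum to one; activities are the
X-weighted coefficient sums on the linear scale with unit
proportionality constants (they only rescale axes; configurable).

Built-in models: the canonical three-state trade-off model (inactive
a0, promiscuous-optimal a1, primary-optimal a2 — its optimal situations
X(a0)=0 define the trade-off line primary + promiscuous = 1, and all
points obey primary + promiscuous <= 1); a leaky-suboptimal variant;
four-conformation variants with two suboptimal states, with and without
low cross-activity; and a no-trade-off variant whose optimal
conformations carry both activities at a high level.  "Low" = 0.1 and
"high" = 1.0 — no published numbers exist for these; the values were
chosen once to preserve the qualitative contrasts (trade-off models:
anticorrelated triangular clouds with sizeable fronts; no-trade-off
model: positively correlated cloud with a near-singleton front) and are
exposed in the model container.

## Mutational paths

Walks operate on a complete landscape (all 2^M genotypes, from a
reconstruction replica or ground truth).  Adjacency is one library
mutation toggled (amino-acid level; codon realism is out of scope).
A step must *strictly* improve the improve-objective in the rule's
direction (ties never pass — this guarantees termination) and land on a
genotype whose constraint objective is at or above the floor.  Among
passing neighbours one is chosen uniformly at random; the walk ends when
none pass.  Path p of a batch uses seed `seed + p`.  The floor is
required configuration; a natural choice is the background genotype's
activity.  An independent post-hoc checker (`check_path`) re-validates
every invariant, including terminal local optimality, without reusing
the walk code's logic.

## Synthetic generators

The MSA generator emulates the statistical structure the coupling
analysis targets: residues drawn i.i.d. from a background distribution
(default uniform over 20 residues — the SCA background is estimated
from the MSA itself, so a neutral fixture background avoids baking in a
preferred answer); a signature column drawn H-like with probability 0.30
per sequence (large enough that the minimum sub-alignment size of 20 is
met at the smallest alignment sizes the recovery analyses use, n = 200);
and planted columns concentrated on a baseline residue (conservation
0.9) whose mass shifts toward a designated residue in the sub-alignment
only, by the shift fraction.  Negative-signal columns put the larger
shift in the complement so the designated residue loses weight under the
signature.  A dedicated ungapped reference record makes numbering the
identity map.

The activity generator draws screens directly from the pairwise-coupling
model with homoscedastic Gaussian noise on log10 activities and returns
the complete noiseless landscape alongside as the oracle.
`paper_scale_scenario` bundles the canonical geometry: M = 10 (1024
variants), 29-variant random training screen, two objectives, 20
bootstrap replicas; ground-truth main effects ~ U(-0.5, 0.5), five
nonzero couplings ~ U(-0.3, 0.3), noise sd 0.1, background log10
activities 0 (primary) and -1 (promiscuous).

**What the synthetic tests do not show.**  Real alignments are
phylogenetically correlated, gapped and non-uniform; the generator's
i.i.d. columns make planted-signal recovery easier than detecting real
co-evolution, so recovery rates here bound the method's behaviour under
its own assumptions, not its field performance.  Likewise the activity
generator matches the fitted model family exactly (no third-order
epistasis, homoscedastic noise), so recovery statistics measure the
estimation pipeline, not model adequacy for a real enzyme.

## Problem sizes and determinism

All stochastic analyses run at the canonical geometry (29-variant
screens, 20 bootstrap replicas, 20-seed batteries, 10^3-10^5-point
simulation clouds) — sizes at which every quantity stabilizes while the
full suite and the acceptance script each complete in about two minutes.
Every random draw flows from an explicit integer seed through
`numpy.random.default_rng`; batch item i uses `seed + i`.

## Known limitations

* The exact binomial background of the classical SCA formulation is
  underdetermined; the covariance cross-check is the mitigation, and
  rankings — not absolute energies — are the supported output.
* PLS coefficients from underdetermined designs are regularized
  estimates, not identified parameters; interpret p_i, p_ij patterns,
  not individual values.
* The optimistic Pareto set is intentionally permissive: it trades
  assay economy for recall and should be followed by measurement, as in
  the iterative screening loop.
* Dominance is strict, so clouds with many exactly-tied points (e.g.
  heavily rounded data) can produce large fronts; use the weak mode if
  ties should collapse.
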