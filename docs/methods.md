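# Methods

## The coevolution model

Each gene's presence (1) / absence (0) across species is treated as a binary
character evolving along a rooted, time-calibrated phylogeny under a
continuous-time Markov chain.  Under the **independent (null) model** the
focal gene (PRDM9 in the motivating application) and a candidate gene each
follow their own two-state chain, with gain rate q01 and loss rate q10 in
events per million years — four free rates in total.  Under the **dependent
(alternative) model** the pair evolves on the joint state space ordered
((0,0), (0,1), (1,0), (1,1)), focal state first.  Each trait's gain and loss
rates are conditional on the other trait's current state, giving eight free
rates; both traits changing in the same instant is structurally impossible,
so those generator entries are exactly zero (the standard discrete-pair
convention; the two restricted models — candidate depends on focal, "X", or
focal depends on candidate, "Y" — force one trait's rates equal across the
other's states, leaving six free rates each).  The four models are nested:
independent ⊂ {X, Y} ⊂ dependent, compared by likelihood-ratio tests with
4 df (dependent vs independent) or 2 df (restricted vs independent).

Likelihoods come from Felsenstein's pruning algorithm with per-node
rescaling, so trees of several hundred tips pose no underflow problem.
Transition probabilities use the closed form for two states and an
eigendecomposition of the generator for four, falling back to
scaling-and-squaring (`scipy.linalg.expm`) whenever the eigenbasis is
ill-conditioned; rows are clipped to [0,1] and renormalized at a 1e-8
tolerance.

**Root priors.**  The screen's biological prior is that the focal gene was
present in the common ancestor: the joint root prior is (0, 0, ½, ½) —
focal fixed present, candidate 50/50.  Both marginals are configurable.

**Uncertain species.**  Species whose focal-gene status cannot be resolved
enter as ambiguous observations (partial likelihood 1 for both states), and
each uncertain observation additionally contributes a constant ½ prior
factor.  Because the factor is identical under every model it cancels from
all likelihood-ratio statistics; it is retained only so reported absolute
log-likelihoods include it.

## Fitting

Rates are optimized on the log scale with L-BFGS-B inside bounds
[1e-6, 1e3] events/My.  Multi-restart search uses one deterministic start
(rates at a scale of ~2 events per total tree length) plus log-uniform draws
within the bounds; each marginal chain and each dependent-family model draws
its restarts from its own seeded stream, so the start list for r restarts is
a prefix of the list for any larger r and the reported maximum cannot
decrease as restarts grow.  Every dependent-family fit additionally starts
from the independent MLE embedded in the joint rate space (computed with at
least eight tries regardless of the configured restart count): the dependent
model nests the independent one exactly, so this start guarantees the fitted
alternative log-likelihood respects the nesting and the LRT statistic is
nonnegative up to optimizer noise (clamped at 0 with slack 1e-6).

Data with no variation are fitted at the rate bounds and flagged
(`at_bound`); note that for an all-absent gene under the 50/50 root prior
the maximum-likelihood solution is a large loss rate (likelihood → 1), not
vanishing rates.

## The screen

`run_screen` tests every gene whose certain calls vary across species;
invariant genes carry no information for the test and are skipped with a
logged reason.  P-values are reported uncorrected and alongside Storey
q-values: π0 is estimated from π0(λ) = #{p > λ}/(n(1−λ)) on the grid
λ = 0.05…0.95, smoothed with a cubic polynomial and evaluated at λ = 0.95,
clipped to (0, 1]; with fewer than eight p-values, or a degenerate estimate,
π0 falls back to 1 (Benjamini–Hochberg).  QQ-plot bands use the exact Beta
order-statistic quantiles: the i-th of n uniform p-values ~ Beta(i, n−i+1).

## Gene status, losses, thinning

Status calls: a gene is **complete** in a species when every required
diagnostic domain is hit at e ≤ 1e-4, **partial** when some required domain
is detectable at e ≤ 0.1 but the full set is not complete, **absent**
otherwise; genes without detectable domains are called from hit presence
alone.  Binarization maps complete → 1 and partial/absent → 0, with an
explicit uncertain symbol.

Loss counting assumes single origin and no regain (Dollo): a subtree is
scored absent only if it contains a certainly-absent tip and no
certainly-present one; maximal such subtrees are the loss clades and their
count is the minimum number of 1→0 transitions (verified against exhaustive
enumeration on small trees).  Purely-uncertain subtrees never create losses.

Tree thinning resolves each k-furcation by dropping whole child subtrees
(k−2 of them), keeping the pair that retains the most species subject to
preserving every focal state observed at the node, then caps each focal-gene
loss clade at three representatives chosen to maximize summed pairwise path
length, breaking ties by assembly-quality score and then species name.  A
change in the focal loss count aborts thinning with an error.  Note that a
rooted binary tree is required downstream, so a 4-way star loses two
species, not one.

## Codon models

The Goldman–Yang generator on the 61 sense codons sets
q_ij = π_j · κ^[transition] · ω^[nonsynonymous] for single-nucleotide
changes and 0 otherwise, scaled to unit expected rate so branch lengths are
substitutions per codon.  Codon frequencies are equal, F1x4 or F3x4
(default F3x4, matching common practice; the equal option is used in
simulation-recovery tests so that the simulated and fitted frequency models
coincide).  Branch classes implement the relaxation tests: "present" vs
"absent" (loss-clade branches including each loss's stem), or additionally
one class per loss stem; degrees of freedom equal the number of distinct ω
values minus one.  Branch lengths, κ and per-class ω are optimized jointly
by L-BFGS-B on the log scale (bounds: t ∈ [1e-7, 60], κ ∈ [0.01, 100],
ω ∈ [1e-6, 100]), with a finite-difference step of 1e-6 — the likelihood's
numerical noise defeats smaller steps.  Alignment columns containing a gap
or ambiguous codon in any sequence are dropped alignment-wide before
fitting (pairwise-complete in the two-sequence mode); internal stop codons
are rejected.  Identical sequences make ω unidentifiable and are flagged
rather than failing.  The pairwise mode reports dN and dS by splitting the
fitted substitution flow into nonsynonymous and synonymous shares and
normalizing by the site proportions implied by the same κ and frequencies
at ω = 1.

## Conservation profiling

A column's residue distribution (pseudocount 1e-7) is compared to a
background distribution by base-2 Jensen–Shannon divergence, which is
symmetric and bounded in [0, 1].  The default background is the
distribution implied by the BLOSUM62 matrix's target frequencies, shipped
as a package data file.  Columns with more than 30% gaps are ignored and
scored exactly 0; otherwise the divergence is weighted by (1 − gap
fraction).  The windowed score mixes each position equally (λ_w = 0.5) with
the mean base score of its ≤3 neighbours each side, where gap-ignored and
zero-scoring positions do not contribute to the mean and gap-ignored
positions stay at 0.  Sequence weighting is not applied by default.

A caveat: "adding another copy of the majority residue never lowers the
score" holds exactly against a uniform background (and is tested there) but
can fail by ~1e-5 against the skewed BLOSUM62 background, because pulling
the minority residues' frequencies toward the background can outweigh the
majority's excess.

## Synthetic data: what it emulates, and what not

`simulate_tree` draws pure-birth (Yule) trees — ultrametric, bifurcating,
with a final Exp(nλ) stretch so terminal branches are nonzero.  Defaults
emulate the study conditions at desk scale: 64 tips, birth rate 1 (height
≈ log n ≈ 4.2, total length ≈ 63), trait gain 0.05 and loss 0.10 per unit
length.  These rates yield on average ~5 independent focal losses and ~25%
absent tips per tree, the same regime as the empirical focal gene (11–12
independent losses among 189 species).  Because the empirical focal gene is
variable by construction, focal realizations with fewer than 3 independent
losses are redrawn.

Traits are sampled exactly through P(t) (no time discretization).  For
planted coevolution the focal path is realized once by Gillespie simulation
within branches; conditional on it, each coevolving gene evolves with its
gain rate multiplied 20-fold while the focal gene is present and its loss
rate multiplied 20-fold while it is absent, endpoint-sampled exactly within
each constant-focal segment.  Candidate genes that end up invariant are
kept and flagged (mirroring the invariant/variable split a real screen
sees).  Codon alignments draw root codons from π and evolve sites
independently through the branch-class transition matrices.

The generator does not emulate assembly/annotation noise, alignment error,
rate heterogeneity across sites or lineages, or correlated gene loss through
unmodelled confounders (e.g. shared genome-quality artifacts).  Passing
tests therefore demonstrate correctness and calibration of the statistical
machinery under the model's own assumptions, not robustness of the
empirical inference to data-quality failure modes.

## Problem sizes and numerical choices in the shipped checks

The acceptance-style checks use: 200 null datasets (64-tip trees) for LRT
calibration against the exact binomial 99% band around 0.05; 20 replicate
screens of 25-gene matrices for planted-signal recovery at q ≤ 0.5;
20 replicates of 500-codon, 8-tip alignments for ω recovery (truth 0.2,
median within ±0.05) and ω = 1 calibration.  Trait fits in these runs use
2 restarts (the independent-MLE start plus one random) and codon fits the
single heuristic start — with the nested-start scheme these already achieve
the calibration above; the default of 100 restarts remains available for
empirical screens.  `scripts/acceptance.py` reports the same quantities at
reduced replicate counts (100 null datasets, 5 screens, 10 codon
replicates), chosen as comfortable desk-scale sizes.

## Known limitations

- Maximum likelihood only; no MCMC mode.
- At most two traits jointly; no hidden-rate/covarion extensions.
- Codon machinery has no site models (M1a/M2a) and does no alignment
  construction.
- The thinning heuristic enumerates subsets exhaustively only for small
  loss clades (greedy farthest-point selection beyond ~5000 combinations).
- χ² reference distributions are asymptotic; with very few state
  transitions the 4-df test is conservative (visible in the calibration
  run's rejection rate sitting slightly below 0.05).
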