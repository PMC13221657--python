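# Methods

This note documents the models implemented in cycadphylo, the defaults and
why they were chosen, what the synthetic-data generator does and does not
emulate, and the numerical choices a user relying on the results should
know about.

## Synthetic data generator (`simulate`)

The generator produces datasets with the statistical structure of a
transcriptome-based phylogenomic study of an ancient, slowly evolving
plant radiation: hundreds of short amino-acid loci, high but incomplete
taxon occupancy, a minority of loci carrying a second gene copy, and
gene-tree discordance driven by incomplete lineage sorting.

**Species trees** are pure birth (Yule), conditioned on the tip count and
rescaled so the crown age is exact. A pure-birth process is the simplest
one producing the short-internal-branch radiations of interest; an
extinction rate adds nothing the downstream stages are sensitive to.

**Gene trees** follow the censored multispecies coalescent: within a
species-tree branch of duration `t` Ma, `k` gene lineages coalesce at rate
`k(k−1)/2 / theta` per Ma (the branch spans `t/theta` coalescent units);
lineages surviving to the root coalesce in the ancestral population. For a
rooted triple separated by `T` coalescent units the probability that the
gene tree matches the species tree is `1 − (2/3)e^(−T)`, which the test
suite verifies against direct simulation. Discordance becomes substantial
when `theta` is comparable to internal branch durations; with the default
crown age of 300 Ma, `theta ≈ 100–200` Ma reproduces the low-gCF regime
(see `examples/03`).

**Branch rates.** Each (locus, species branch) pair draws an i.i.d.
log-normal rate multiplier with unit mean (`sigma_rate` is the log-scale
standard deviation); gene-tree segments inherit the multiplier of the
species branch they traverse, and the segment above the root uses the base
rate. Making rate variation *gene-specific* (rather than shared across
loci) is a deliberate design choice: it is the among-locus variance
component that gene-wise bootstrapping exists to propagate, and it keeps
the expected concatenation phylogram equal to the clock expectation, so
recovery experiments have a well-defined truth. A lineage effect shared by
all loci would be statistically invisible to locus resampling — no
resampling scheme can turn a fixed bias into an interval — and is therefore
not simulated.

**Paralogs.** A `dup_fraction` share of loci (Bernoulli per locus) gains a
second copy of one uniformly chosen accession, attached to the original
tip's pendant branch and carrying `dup_extra_depth` extra substitutions per
site; the injected copy's average patristic distance to all other
accessions exceeds the original's by exactly `dup_extra_depth`, so the
pruner's preference is testable. **Missingness** drops each accession from
each locus independently with probability `1 − occupancy_target`; loci
left with fewer than four tips redraw their drop pattern (logged).

**Sequences** evolve by the 20-state equal-exchangeability (Poisson) model
(or any PAML-format empirical matrix), single rate, site-independent, root
states from the stationary frequencies. For two sequences at distance `d`
the expected difference proportion is `(19/20)(1 − e^(−20d/19))`, used as a
closed-form oracle in the tests.

Defaults (`SimulationConfig`): 20 taxa, crown age 300 Ma, 200 loci × 300
sites, rate 5·10⁻⁴ subs/site/Ma (≈ 0.15 subs/site root to tip — gymnosperm-
slow), `theta` 10 Ma, occupancy 0.949, `dup_fraction` 0.10. All randomness
derives from the single config seed through named streams; no global state.

What the generator does **not** emulate: alignment error and trimming,
gene-tree estimation error (downstream concordance on simulated data uses
*true* gene trees, so gDFP reflects genuine polyphyly rather than
inference noise), indels, rate heterogeneity across sites, and gene
duplication–loss dynamics beyond a single extra copy. Passing tests
therefore validate the *machinery*, not the biological realism of any one
dataset.

## Orthology curation (`orthology`)

The presence cutoff is `ceil(min_presence_frac × n_accessions)` (the
ceiling is forced by the published-panel arithmetic: 0.75 × 346 → 260).
The second-copy cutoff is `floor(max_second_copy_frac × n_present)` by
default — relative to accessions *present* in the locus, so sparse loci
gain no duplicate headroom — with `relative_to="all"` available since the
rule admits either reading. The summary statistic "fraction of branches
below the gCF threshold" counts branches at the threshold as below (≤).

Paralog pruning uses patristic distances on the gene tree (not sequence
distances): for each accession with several copies, every copy's distance
to all tips of *other* accessions is averaged (including other accessions'
copies, which makes the operation order-independent), the minimum-average
copy is kept and relabeled to the bare accession id, and ties break toward
the lexicographically smaller label (logged).

## Likelihood engine (`likelihood`)

A reversible 20-state engine: Felsenstein pruning over compressed site
patterns with per-pattern rescaling (500-taxon × 1,000-site problems stay
finite), transition matrices from the symmetric eigendecomposition of
`π^½ Q π^(−½)`, and Q normalized to one expected substitution per site per
unit length. Gaps and X are missing data; all-gap columns contribute
exactly zero.

Branch-length optimization is coordinate-wise on the fixed topology. For a
single edge the per-pattern likelihood is `C_p · exp(Λ t)` with `C_p`
precomputable from the two flanking conditional vectors, so each branch is
fitted by root-finding on the analytic derivative (bracketed Brent on
`f′`), bounded to [10⁻⁸, 10] subs/site; sweeps repeat until the largest
length change is below 10⁻⁶ (cap 100), with an active-set shortcut that
skips converged branches until a neighbor moves. Under a reversible model
only the *sum* of the two root-child branch lengths is identifiable; the
optimizer fits the sum and redistributes it in proportion to the input
lengths. Single-rate models only: the engine's two roles here — bootstrap
branch-length refresh and quartet fits — do not require among-site rate
heterogeneity, and adding +G would slow the bootstrap several-fold for no
benefit on Poisson-simulated data.

## Concordance factors (`concordance`)

Each internal branch (in the unrooted sense) defines four taxon blocks:
the attachment node's two child clades and the two far-side blocks. A gene
tree is decisive iff it carries at least one taxon from every block; among
decisive trees the induced grouping is classified as the branch's own
bipartition (gCF), one of the two NNI alternatives (gDF1/gDF2, oriented
child-block-1-with-far-block-1 first — the orientation is conventional and
only their sum is biologically meaningful), or none (gDFP). The four
percentages sum to 100 exactly.

Site concordance samples quartets (one taxon per block, without
replacement, exhaustive when the block product is within `n_quartets`).
Counting mode — the default and the acceptance oracle — scores a site as
decisive iff its four residues are gap-free with exactly two distinct
residues twice each; the pairing votes for one of three topologies, a
quartet's sCF is its concordant fraction, and the branch sCF averages over
quartets that had decisive sites. Likelihood mode instead fits the three
quartet topologies with the engine and lets each site vote for its
highest-likelihood topology (strict argmax; ties non-decisive); it agrees
with counting mode on clean signal but is slower and not numerically
interchangeable. Under no signal each resolution is equally likely, so
sCF → 33.3%; "exceeding the random expectation" uses strict >.

## Penalized-likelihood dating (`chronos`)

Objective: `−Σ_b [x_b log(r_b d_b) − r_b d_b] + λ·[Σ (r_b − r_parent(b))²
+ Var(root-children rates)]`, where `x_b` is branch length × alignment
width (continuous Poisson — fractional counts avoid rounding pathologies
on short branches), `d_b` the branch duration, and rates act on expected
counts internally (reported as subs/site/Ma). Optimization is joint over
internal-node ages and rates with analytic gradients (SLSQP), box bounds
from the propagated calibration intervals, linear parent-older-than-child
constraints (margin 10⁻⁶ Ma), and five jittered feasible starts; the
returned solution is projected and re-checked against every constraint
independent of the optimizer. Infeasible calibration pairs and a root
without a finite maximum age are errors (the latter because the objective
is scale-free without one).

**Scale behavior worth knowing.** Given any node ages, free rates can
absorb an overall rescaling of time, so the data part of the objective is
invariant under stretching the tree, while the roughness penalty scales as
1/T² — the optimum therefore sits at the oldest root the calibrations
allow whenever the penalty is active. This is a property of the
rate-smoothing objective itself, and it is exactly the "crown ages
converge on the calibration maximum" behavior reported in empirical
rate-smoothing studies. Consequently the package's recovery and coverage
experiments pin the root to the true age (a degenerate [T, T]
calibration); with only a min/max window the absolute scale is
data-unidentified within the window and only relative ages are meaningful.

Cross-validation is leave-one-terminal-out: drop a tip's terminal branch,
date the pruned tree (calibrations whose MRCA collapses are skipped for
that fold; tips attached directly to the root have no surviving ancestor
and are skipped), predict the dropped tip's substitution count as
(sibling-lineage rate) × (surviving ancestor's reconstructed age), and
score `(obs − pred)²/pred` summed over folds. Among λ values tying the
minimum (10⁻⁹ relative) the largest wins, so noiseless clock data selects
the smoothest model. On near-clock concatenations (the per-locus-rate
generator averages rates out) the CV curve is flat-to-decreasing and the
chosen λ may sit at the grid edge; that is the correct answer there, not a
failure of the search.

## Gene-wise bootstrap (`bootstrap`)

Replicates draw `n_loci` locus indices with replacement. Site patterns are
pooled across loci once, so a replicate's supermatrix is a re-weighting of
the pooled patterns — the branch-length refresh then costs seconds, not
minutes. Each replicate optimizes branch lengths on the fixed topology
(initialized from the input lengths), prunes the outgroup if one is given,
dates under the same λ and calibrations (λ is *not* re-cross-validated per
replicate), and records internal-node ages keyed by bipartition — stable
because the topology is never re-estimated. The dating jitter seed derives
from the replicate's data, so byte-identical replicates date identically
(and identical loci give zero-width intervals). A replicate whose dating
fails retries with a fresh jitter seed; failures above 10% of the
replicate count abort the run. Intervals are linear-interpolation
percentiles (2.5/97.5 by default).

## Problem sizes used in the test suite

The acceptance-style experiments run at desk scale, chosen so the whole
suite completes comfortably on one CPU while keeping every statistical
tolerance intact: no-signal sCF at 10 × (8 taxa × 5,000 sites); rooted
triples at 10,000 loci; dating recovery and bootstrap coverage at 10
datasets of 12 taxa × 80 loci × 150 sites with 40 replicates (θ = 1 Ma in
those experiments so coalescent depth bias — a property of concatenation
under ILS, not of the dating machinery — does not contaminate the
measurement; the discordance-focused tests use larger θ); the end-to-end
pipeline at 20 taxa × 50 loci. Coverage of true node ages by the 95%
gene-wise intervals at these conditions is ~89%, with the misses
concentrated at the youngest nodes where the residual coalescent bias
(≈ θ) is comparable to the interval width.

## Known limitations

* Concordance on simulated data uses true gene trees; empirical gDFP also
  absorbs gene-tree estimation error, so simulated gDFP is lower than
  field values at matched θ.
* The dating engine fits one substitution model to the whole supermatrix;
  partition-specific models are out of scope.
* Percentile bootstrap intervals quantify among-locus sampling variation
  only; biases shared by all loci (concatenation-under-ILS depth,
  smoothing-induced shrinkage toward rate equality, calibration bounding)
  shift point estimates and intervals together.
* Quartet likelihood mode is exact per quartet but slow; counting mode is
  the supported default for genome-scale branch scoring.
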