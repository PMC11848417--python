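# Methods

This note documents the models, estimators, numerical choices and
known limitations of the package, in the order data flows through the
pipeline.

## Synthetic genotypes (Balding–Nichols)

Structured genotypes are simulated under the Balding–Nichols model.
Per locus an ancestral frequency `p` is drawn uniformly from a
configurable range (default 0.1–0.5, i.e. common variants); each
population's frequency is `p_k ~ Beta(p(1−F)/F, (1−p)(1−F)/F)`, which
has mean `p` and variance `F·p(1−p)`. `F` is therefore the expected
Weir & Cockerham differentiation among populations, which is what
makes parameter-recovery testing possible. `F = 0` is handled as the
degenerate point mass (all populations share `p` exactly; no division
by zero). Genotypes are `Binomial(2, p_k)`; admixed individuals draw
each of their two alleles from parental population A with probability
α, else B. Missingness is i.i.d. per genotype at a configured rate;
read depth is Poisson truncated at ≥ 1 (FORMAT `DP` is per genotype
because the depth filter downstream is applied per genotype). All
randomness flows from one `numpy` `default_rng(seed)`, so equal seeds
give byte-identical outputs.

What this generator does **not** emulate: linkage (loci are
independent, so there is no LD structure and bootstrap supports are
optimistic relative to real genomes), sequencing error, allele-depth
bias in missingness (missingness is independent of genotype), and
invariant sites (the matrix holds variant sites only). Passing tests
therefore validate estimator correctness and pipeline plumbing, not
robustness to those real-data features.

## VCF filter cascade

Stage one filters sites on the standard GATK hard-filter annotations:
`FS ≤ 60`, `HaplotypeScore ≤ 13.0`, `MQ ≥ 40`, `QD ≥ 2`,
`ReadPosRankSum ≥ −8.0`, `MQRankSum > −12.5`. Every comparison is
inclusive except `MQRankSum`, which is strict. An absent annotation
passes its criterion: rank-sum annotations are undefined at sites
lacking both allele classes, and failing such sites would discard
valid variants. A non-numeric annotation fails the record with a
logged parse error.

Stage two is applied to the genotype matrix in a fixed order:
(1) genotypes with depth < 3 are set missing; (2) loci with missing
fraction > 0.2 are dropped; (3) loci with minor-allele frequency
< 0.05 — computed on the calls remaining after steps 1–2 — are
dropped. The order is a design choice: it makes the MAF reflect
usable calls. The cascade is idempotent, and an all-loci-removed
result is a legal empty matrix, not an exception. The depth filter is
genotype-level (not site-level) because it belongs to the
genotype-quality family of filters; the missing-rate filter then acts
on its result.

VCF input goes through `cyvcf2`; multiallelic and non-SNP records are
dropped with a logged count; 1-based coordinates are kept and loci
are keyed `(chrom, pos)`.

## Diversity and differentiation

Per-population statistics are means over variant sites with at least
one called diploid in that population (sites uncalled in a population
are excluded from its means, not zero-filled):
`Hobs`, `Hexp = 2p(1−p)`, `π = 2n/(2n−1)·2p(1−p)` (equal to the mean
pairwise difference among the `2n` sampled alleles, verified by
exhaustive enumeration in the tests), and
`F_IS = mean(1 − Hobs/Hexp)` over polymorphic loci. Observed and
expected homozygosity are exact complements by construction. A fully
monomorphic population reports `π = 0` and `F_IS = 0` with a warning.

F_ST is Weir & Cockerham (1984) θ: per-locus variance components
`a` (among populations), `b` (among individuals within populations),
`c` (within individuals), combined across loci as
`θ = Σa / Σ(a+b+c)` (ratio of averages). θ was chosen because it is
the community default, supports unequal and missing sample sizes, and
is recovery-testable against the Balding–Nichols target. Slightly
negative estimates near zero differentiation are clamped to 0 only at
reporting time; `clamp=False` returns the raw value, which is what
the null-simulation tests assert on.

## Structure summaries

PCA operates on the dosage matrix after excluding loci with
MAF < 0.05: missing dosages are mean-imputed per locus, each locus is
centered by `2p̂` and scaled by `sqrt(2p̂(1−p̂))` (Patterson
normalization, the GCTA-style GRM scaling), and the sample–sample
covariance is eigendecomposed. Explained fractions are eigenvalues
over the trace; axis signs are arbitrary and tests compare up to
sign. Mean imputation slightly shrinks coordinates of high-missingness
samples toward the origin — the standard GRM trade-off.

Distances are allele-sharing (IBS): `d(i,j) = mean |g_i − g_j| / 2`
over co-called loci; a pair with no co-called locus is an error. The
tree is canonical Saitou–Nei neighbor joining with the Q-criterion;
ties in the Q matrix join the lowest-index pair, so results are
deterministic. A negative branch length is clamped to 0 with the
deficit shifted to its sister branch, preserving the pair's path
length. The tree is a distance-based summary built in place of an
external maximum-likelihood tool — it is fully specified and exactly
testable (NJ is guaranteed to reconstruct additive matrices), but it
is not a likelihood phylogeny. Outgroup rooting places the root on
the branch separating the outgroup from the ingroup. Bootstrap
support resamples loci with replacement and reports the fraction of
replicate trees containing each internal bipartition.

## Supervised assignment

Each Monte-Carlo resample draws `round(t·n)` individuals per source
group (without replacement, stratified) as training data. Loci whose
pooled training major-allele frequency is ≥ 0.95 are removed (the
"low variance" pre-filter; the threshold is interpreted as a
major-allele-frequency cutoff). Remaining loci are ranked by
among-source θ computed on the training subset only, and the top
fraction is kept; ties and undefined values rank by locus order. A
linear-kernel SVM (C = 1) is fit on training dosages with
training-mean imputation, then predicts the held-out source
individuals (cross-validation accuracy) and the query individuals.
Per-resample class probabilities are softmax-transformed one-vs-rest
margins; the headline statistic — membership proportion, the fraction
of resamples assigning a query to each source — does not depend on
that calibration. Because locus selection and imputation never see
held-out or query genotypes, there is no information leakage; the
tests verify this by scrambling query genotypes and checking that
cross-validation accuracy is unchanged. Cells whose training draw
would leave fewer than 2 individuals per group are skipped with a
warning. The default design (training fractions 0.5/0.7/0.9 × locus
fractions 0.6/0.8/1.0) is pooled for the headline membership unless a
single cell is requested.

## Trajectory model

Wind fields live on a regular (time, level, lat, lon) grid with a
land/sea mask and terrain on the horizontal plane (NetCDF I/O via
xarray). Interpolation is linear in time and altitude and bilinear in
the horizontal; altitude outside the level span clamps to the nearest
level; leaving the horizontal or temporal extent of the grid is a
recorded `exited_grid` outcome, not an error (deliberately probing
unreachable targets is a legitimate experiment).

Flight: departure at 19:00 local solar time (`local = UTC + lon/15`
h; the nightly window is photoperiod-driven, so solar rather than
civil time), strictly downwind ground velocity
`v_g = w + s·w/|w|` with airspeed `s = 3` m/s; below a 0.1 m/s wind
floor the downwind heading is undefined and the airspeed term is
dropped. Integration is first-order Euler with a 10-minute default
step: at ≤ 20 m/s that is ≤ 12 km per step, far below synoptic wind
length scales, and convergence is tested (halving the step reduces
the error against closed forms; uniform-wind displacement is exact to
0.1 %, a solid-body-rotation orbit closes to within 2 % of its
radius). Positions advance on a sphere of radius 6,371,000 m;
longitude wraps at ±180°; |lat| ≥ 89° raises (outside the biological
range). Land/sea is evaluated at the nearest grid cell centre.

Landing rules: at 05:00 local the flight stops if the position is a
land cell (duration exactly 10 h). Over the sea the stop is
suppressed and the insect lands at the *first* land cell crossed,
checked every timestep — not at the next 05:00. A 96-hour endurance
cap (configurable) bounds the extension; it comfortably exceeds any
plausible single-flight crossing in the scenarios the model targets.
Altitude is constant per trajectory: one of eight fixed levels
(500–2250 m a.s.l.) or terrain + 1500 m in terrain-following mode.
Multi-generation chains relaunch the next generation from the centres
of the previous generation's landing cells after a configured dwell.
Landing frequencies bin landed positions into half-open cells keyed
by the lower-left corner (boundary points go to the higher cell).

The rotational regime defines its angular velocity as `u0 / 10^6`
rad/s — tangential speed `u0` at 1000 km from the grid centre —
using the grid-centre latitude for the meters-per-degree conversion,
so orbits are closed to first order near the centre.

## Pipeline and reproducibility

One global seed drives every stochastic stage through
`SeedSequence([seed, stage_index])` substreams, so stages are
individually reproducible and mutually independent. The manifest
(inputs, parameters, seed, per-stage counts) fully determines the
numeric outputs; the pipeline config is YAML with a closed schema —
unknown keys fail fast. All computation is single-threaded, so
results cannot depend on thread scheduling. The filtered-VCF artifact
re-synthesizes INFO annotations (within the passing bounds) rather
than copying the originals; downstream stages only consume genotypes,
but the artifact should not be treated as carrying the input's site
annotations.

## Problem sizes

Test and demo scenarios use 2–4 populations of 15–50 diploids,
500–10,000 loci, 10–50 assignment resamples, and wind grids of a few
thousand nodes; these sizes give stable statistics for every check
(e.g. F_ST recovery to ±0.02 needs ~5,000 loci × 50 diploids) while
keeping the full suite around ten seconds. Larger inputs scale
linearly in loci and samples for all vectorised stages; the IBS
distance and assignment loops are quadratic in samples and linear in
resamples respectively.

## Known limitations

- No linkage or recombination model; bootstrap and assignment
  uncertainties assume independent loci.
- Diversity is over variant sites only; π is not genome-wide π.
- The NJ tree is a distance summary, not a likelihood phylogeny.
- The flight model has no vertical dynamics, no temperature- or
  rain-driven cessation, and no population dynamics between
  generations; the over-sea endurance cap is a numerical bound, not a
  physiological estimate.
- Civil time zones are not consulted; all local times are solar.
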