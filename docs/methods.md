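# Methods

## The cross and its data

The package models an F2 intercross: two parents from diverged lines (P),
an F1 sibling pair, and a cohort of F2 offspring genotyped at RAD markers
with per-allele read depths.  At a fully codominant marker the F2
segregates a : h : b = 1 : 2 : 1, where `a`/`b` are the two parental
homozygotes (by convention parent 1 is the dam, so `a` is the maternal
homozygote and `b` the paternal one).  Markers where only one parent was
heterozygous carry one-sided information and are kept with collapsed
codes: `c` = {h, b} (aa×ab types) and `d` = {a, h} (ab×aa types).  Types
ab×ab, ab×ac and ab×cc are fully codominant once alleles are matched to
parents and are treated as a/h/b for mapping; the type label is kept for
bookkeeping.

## Two-point estimation

For a marker pair, each F2 individual is the union of one maternal and one
paternal F1 gamete; a gamete is recombinant with probability `r`.  The 16
phased gamete-pair configurations give the joint genotype classes; an
observed (possibly collapsed) code pair is compatible with a subset of
them.  The EM algorithm's E-step distributes each observation over its
compatible configurations to get the expected recombinant-gamete count;
the M-step sets `r = E[recombinants] / 2n`.

Allele labels are arbitrary, so linkage phase is a nuisance parameter.
The likelihood is maximised over `r ∈ (0, 1)` (values above ½ are the
repulsion-phase image of values below), starting EM from 0.25 and 0.75;
because weakly informative collapsed pairs (notably a/c × b/d) can have a
global mode near a boundary that EM approaches slowly, the boundary
points are also evaluated and the overall likelihood argmax wins.  The
reported estimate is folded, `r̂ = min(r, 1 − r)`, with
`LOD = log₁₀ L(r̂) − log₁₀ L(½)` (clipped at 0).  A brute-force
likelihood grid (`grid_search_rf`, step 0.001 over (0, 1), written from
the classical 9-class probability table rather than the configuration
enumeration) serves as an independent validation route; the two agree to
±0.001 on random tables, including collapsed codes, except at exact
likelihood ties between modes, where the estimator is inherently
discontinuous.

Numerical details: EM runs at most 200 iterations to a tolerance of
1e-10 on `r`; `r` is kept in [1e-9, 1−1e-9] during iteration and snapped
to an exact 0 when it lands within 1e-8 of the boundary.

## Grouping

Markers are partitioned by single-linkage transitive closure over pairs
whose grouping LOD reaches a threshold (default 6.0).  The default
grouping statistic is the two-point linkage LOD.  The independence-test
LOD — `G²/(2 ln 10)` from the joint genotype table, attractive because it
is insensitive to segregation distortion — is implemented as
`grouping_stat="independence"`, but it is not the default: its null
distribution is roughly χ² with 4 degrees of freedom, whose tail at the
LOD 6 threshold (~2 × 10⁻⁵, measured on 2 × 10⁶ simulated null tables at
n = 343) yields several spurious links per ~10⁵ unlinked pairs in a
map-sized dataset, silently merging chromosomes.  The linkage LOD's null
tail at the same threshold (~½χ²₁, ≈ 7 × 10⁻⁸) keeps grouping stable
between LOD 6 and LOD 10, which is the observed behaviour of classical
two-point mapping at these thresholds.

## Ordering and distances

Each group is built regression-mapping style.  Pairs qualify for the fit
when `r̂ ≤ 0.400` and `LOD ≥ 1.0`.  The seed is the strongest qualifying
pair; remaining markers are inserted in decreasing order of total linkage
information (sum of weights to usable partners; ties broken by marker id
for determinism).  A candidate order is scored by weighted least squares:
non-negative adjacent interval lengths minimise
`Σ w_ij (d_ij − |x_i − x_j|)²`, with `d_ij` the pairwise Kosambi distance.

The weights are the inverse variances of the distance estimates,
`w_ij = 1 / Var(d̂_ij)`, computed from the empirical Fisher information of
each pair's likelihood (numerical derivative of the class probabilities at
the better-supported phase) mapped through the Kosambi derivative
`d'(r) = 100/(1 − 4r²)`.  At fixed `r` this weight is proportional to the
pair's LOD, but unlike a raw-LOD weight it puts the fit statistic on the
chi-square scale: a pair fitting within sampling error contributes ~1.
That scale is what the goodness-of-fit *jump* rule presupposes — a marker
whose best insertion raises the normalised statistic (weighted SSE per
pair used) by more than 5.00 is postponed to a second round, and dropped
as unplaced if it still jumps.  With raw-LOD weights a well-fitting pair
contributes ~20, and the jump rule rejects essentially everything.

After each insertion a *ripple* pass permutes every window of 3
consecutive markers overlapping the insertion point and keeps
improvements; a full-order ripple runs at the end.  Final positions are
the cumulative WLS interval lengths (multipoint-adjusted, not raw
adjacent r̂), reported to 2 decimals in map output.  Orientation is
canonicalised so the lexicographically smaller end marker comes first.

Map summary: mean spacing is `total cM / (markers − groups)`; a marker
"co-segregates" when its distance to the preceding marker in map order is
zero (≤ 1e-6 cM — the WLS fit returns exact zeros for such intervals, so
no looser tolerance is needed).

## The synthetic cross

The generator's defaults emulate the study scale: 25 linkage groups (23
spanning 51.5–72.2 cM plus two short groups of 2.5 and 2.0 cM, ~1427 cM
in total) carrying 755 markers allocated proportionally to length (the
short groups get 3 and 2), 343 F2 offspring, 18.5% of markers fixed
between the parental lines (the remainder spread evenly over the five
other informative types — the true type mix is not recoverable from
published summaries), negative-binomial read depth with mean 15 and size
20.4 (SD ≈ 5.1, overdispersed relative to Poisson as sequencing depth
is), 25% missing calls (independent per call), a small symmetric
adjacent-code miscall rate of 10⁻³, and de novo mutations at
6.6 × 10⁻⁸ per site per generation over 38 203 loci × 110 bp.

**Crossover process.**  Gametes receive crossovers from a stationary
gamma-renewal chiasma process (shape ν = 2.6, rate 2 per Morgan,
chiasmata thinned ½, 500 cM burn-in for stationarity).  ν was calibrated
against the Kosambi map function itself: the simulated two-point
recombination fraction matches `½ tanh(2d/100)` to |Δr| ≤ 0.0011 over
0–60 cM.  This matters because no valid crossover process reproduces
Kosambi exactly at all spans (`1 − tanh` is not completely monotone, so
it is not a mixture of Markov processes), and a no-interference Markov
chain over marker intervals — available as `interference="none"` —
composes Haldane-style across intervals: its long-pair Kosambi distances
under-add and shrink fitted 60 cM groups by 10–16%.  With the gamma
process the estimation target coincides with the simulated truth at every
span and fitted map lengths are unbiased (median error −1.8% over 20
seeds at n = 343).

**Viability selection.**  Each configured distortion block places one
causal locus at its midpoint, simulated jointly with the markers.
Relative fitnesses (maternal hom, het, paternal hom) are
`against_maternal: (1−s, 1−s/2, 1)`, `against_paternal` mirrored,
`het_advantage: (1−s, 1, 1−s)`, `het_disadvantage: (1, 1−s, 1)`.
Survival is the product over blocks; the driver rejects and resimulates
until the post-selection cohort reaches `n_f2`, so distortion at linked
markers arises mechanistically through linkage to the causal locus.  The
default blocks mirror the emulated study's five distorted regions (one
large paternal-excess block, two maternal-excess, two heterozygote-excess)
with s = 0.5 — strong enough (χ² noncentrality ≈ 14 at the causal locus,
n = 343) that blocks of adjacent significant markers appear, which is
what the scenario describes; weaker selection leaves isolated borderline
markers only.

**Mutations.**  Per progeny individual (both F1s and every F2), mutation
counts are Poisson with mean `2 L u` and placed uniformly over loci,
positions and genome copies.  The read-level survey materialises calls
for the surveyed individuals (both F1s plus a sampled F2 subset): locus
depths are negative-binomial per locus (RAD loci share depth across their
sites), a mutation appears as a novel allele on ~half the reads, and
sequencing error can spawn spurious novel alleles requiring ≥ 2
concordant erroneous reads (single-read errors never survive calling),
with support near that floor so the coverage filter removes them.

What the generator does not model: library batch effects (missingness is
independent per call), sex-specific recombination, chromatid
interference, allele dropout correlated with depth, inheritance of F1
mutations into F2 (rates are small enough that the double-counting
probability is negligible at realistic u), and mutations inside the
genotyped marker loci (755 × 110 bp is ~0.2% of the surveyed genome).
Passing recovery tests therefore show correctness of the estimators under
clean pedigree assumptions, not robustness to those artefacts.

## QC and marker selection

Individuals with mean per-call depth < 6 are removed first; then calls
with depth < 5 are masked and markers genotyped in < 90 individuals are
dropped (mask before count, since both thresholds act jointly).
Codominant markers are tested 1:2:1 (Pearson χ², df 2), one-sided markers
1:3 (df 1).  The mapping set is tiered: p ≥ 0.05 is the base set;
0.001 ≤ p < 0.05 markers are queued for step-wise addition from least to
most significant; p < 0.0001 markers are excluded as distortion severe
enough to distort distances.  The band 0.0001 ≤ p < 0.001 is unspecified
by the tier boundaries; it is appended to the tail of the step-wise queue
by default (`include_gap=False` drops it), keeping the addition order
monotone while making the ambiguity explicit.

SNPs/kb takes the effective locus length as an explicit parameter rather
than a constant, because published per-kilobase figures are only mutually
consistent under different effective lengths (100 vs 110 bp).

## Distortion blocks

Blocks are maximal runs of map-consecutive markers with p < 0.05,
allowing at most one undistorted marker inside a run (runs start and end
distorted); runs with fewer than 3 distorted members are dropped, except
that a group distorted end-to-end is always reported with a
`whole_group` flag (short groups can be entirely inside a selected
region).  Direction is the modal member direction; a member's direction
comes from the standardized residuals against 1:2:1 — a dominant
heterozygote residual gives het excess/deficit, otherwise the larger
positive homozygote residual names the allele, mapped to
paternal/maternal where the parental origin of the allele labels is
known (fixed-difference markers in the pipeline).

False positives: the run rule's intrinsic false-alarm rate, measured with
statistically independent marker tests, is ~1% of groups.  At dense map
spacing (~2 cM) neighbouring tests share most of their sampling noise
(correlation ≈ 0.85), chance dips cluster, and the group-level rate rises
to roughly 15–20% — so a single minimal block in a dense map is weak
evidence by itself, and the false-positive study quotes the
independent-test regime (50 cM spacing) while a test asserts the rate
grows with density.

## Synteny

Hits are read from 12-column tabular alignment output and filtered by
e-value (defaults: 10⁻¹⁵ for a within-family comparison, 10⁻¹⁰ for more
distant outgroups).  A multi-hit marker keeps its best hit only when it
leads the second best by more than 20 bits; retained hits on sequences
outside the user-supplied list of assembled chromosomes are excluded as
unlinked scaffolds.  For the percentage, markers whose reference group
attracted no other marker are excluded ("lone" hits), each focal group's
modal reference group is found, groups with fewer than two qualifying
markers or a tied mode are reported but excluded, and the statistic is
`100 × Σ on-modal / Σ qualifying`.  Oxford-grid coordinates are positions
divided by group length (cM) and reference length (bp), both in [0, 1];
reference lengths come from a two-column file so no genome is needed at
run time.

## Mutation rate

Candidates are progeny alleles absent from both parents at a locus the
parents were genotyped at.  Filters, in order: coverage (≥ 8 reads total,
≥ 4 per allele), hard allele-ratio bounds (original/novel within
[0.5, 2.0]), and the empirical 95% central interval of the
heterozygous-call allele-balance distribution (quantiles of depthA/depthB
over all het marker calls; ≥ 100 calls required).  The hard bounds and CI
are conjunctive.  The ratio is oriented original-over-novel, which makes
the 7-vs-3-read textbook exclusion (ratio 2.33 > 2.0) coherent with the
bounds; note that such a candidate also violates the ≥ 4-per-allele rule,
so it is recorded as a coverage failure in the pipeline while the ratio
filter alone would equally reject it.  Identical mutations (generation,
locus, position, novel allele) are counted once; extra observations are
flagged duplicates, and both raw and deduplicated counts are reported
because published candidate counts can be quoted either way.

The rate is `u = m / (2 n L)` over two genome copies per individual.  `L`
is the *callable* sites per surveyed individual — sites on loci meeting
the ≥ 8× inclusion rule — supplied explicitly because surveyed-site
counts are never recoverable from summary statistics; generation rates
are averaged unweighted (the convention under which the published
per-generation rates average exactly to their printed mean).

## Recovery studies and problem sizes

The studies in `radmap.studies` fix their own conditions: map recovery
uses 24 chromosomes × 30 evenly spaced markers on 60 cM, 343 F2,
error-free fully codominant data, 20 seeds (evenly spaced so adjacent
markers are resolvable at n = 343; medians over seeds absorb the ~2%
per-seed chance of one spurious LOD-6 link among ~250 000 unlinked
pairs).  Mutation recovery injects u = 5 × 10⁻⁷ (inflated so desk-scale
counts of ~50 arise) over 50 individuals × 10⁶ sites at 30× survey depth
— a pedigree mutation survey deliberately targets high-coverage
individuals, and at 15× the per-allele coverage filter censors enough
true heterozygous carriers to bias the estimate ~20% low.  Distortion
power uses one selected locus (s = 0.5) centred among 30 markers over
60 cM, 50 seeds; the false-positive study uses 100 seeds × 5 groups of 30
markers at 50 cM spacing (above).

## Known limitations

- Two-point only: no multipoint likelihood (Lander–Green) and no
  sex-specific maps; ordering quality rests on the WLS heuristic plus
  ripple, which is exact on clean data but can lock into local optima on
  very noisy groups.
- The jump statistic is a stand-in for proprietary regression-mapping
  internals: it is the increase in inverse-variance-weighted SSE per
  pair, which has the right scale but is not guaranteed to match any
  specific historical implementation.
- One-sided × one-sided marker pairs in opposite orientation carry very
  little linkage information; their r̂ is reported but near-useless, and
  the inverse-variance weights correctly down-weight them.
- The mutation-rate estimator does not correct for the residual ~5–10%
  of true mutations removed by the allele-balance filters; published
  pedigree estimates carry the same censoring.
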